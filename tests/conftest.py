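"""Shared fixtures: packaged toy data and random-DAG generation."""

from __future__ import annotations

import random

import pytest

from goeffects.ontology import GoDag, parse_obo
from goeffects.synthetic import toy_apoptosis_gaf, toy_apoptosis_obo

ROOT = "GO:0008150"
APOPTOSIS = "GO:0006915"
ANTI_APOPTOSIS = "GO:0006916"
REGULATION = "GO:0042981"
POS_REGULATION = "GO:0043065"
NEG_REGULATION = "GO:0043066"


@pytest.fixture(scope="session")
def apoptosis_dag() -> GoDag:
    return parse_obo(toy_apoptosis_obo())


@pytest.fixture(scope="session")
def apoptosis_gaf_text() -> str:
    return toy_apoptosis_gaf()


def random_dag_obo(rng: random.Random, max_terms: int = 50) -> tuple[str, dict[str, list[str]]]:
    """A random acyclic ontology as OBO text plus its parent edge list.

    Edges always point from a higher-numbered term to a lower-numbered one,
    which guarantees acyclicity; relation type is a coin flip between is_a
    and part_of.
    """
    n = rng.randint(2, max_terms)
    ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
    parents: dict[str, list[str]] = {ids[0]: []}
    stanzas = ["format-version: 1.2", "ontology: random-test-dag", ""]
    stanzas += ["[Term]", f"id: {ids[0]}", "name: term 1", ""]
    for i in range(1, n):
        k = rng.randint(1, min(3, i))
        chosen = rng.sample(ids[:i], k)
        parents[ids[i]] = chosen
        stanzas += ["[Term]", f"id: {ids[i]}", f"name: term {i + 1}"]
        for p in chosen:
            if rng.random() < 0.5:
                stanzas.append(f"is_a: {p}")
            else:
                stanzas.append(f"relationship: part_of {p}")
        stanzas.append("")
    return "\n".join(stanzas), parents


def closure(parents: dict[str, list[str]], start: str) -> set[str]:
    """Brute-force reachability over a parent edge list (the oracle)."""
    out: set[str] = set()
    stack = list(parents.get(start, []))
    while stack:
        node = stack.pop()
        if node not in out:
            out.add(node)
            stack.extend(parents.get(node, []))
    return out
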