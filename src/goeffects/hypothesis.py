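"""Hypothesis terms and their GO id sets (the HGT file).

A hypothesis term is a free-text biological concept ("apoptosis",
"chemotaxis") the user wants to test a gene set against.  Each term is bound
to one or more GO ids, either found by a stemmed substring search over the
ontology's names, synonyms and definitions, or supplied directly in an HGT
file of ``label, GO:id[, GO:id...]`` lines.

The search stems each word with the Porter algorithm so that inflected
hypothesis terms match related ontology wording ("inflammation" stems to
"inflamm", matching "inflammatory response").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from .ontology import GoDag

GO_ID_IN_TEXT_RE = re.compile(r"GO:\d{7}")


class HgtFormatError(ValueError):
    pass


class HgtValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm)
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel→consonant transitions (the algorithm's *m*)."""
    m = 0
    prev_cons = True
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and not prev_cons:
            m += 1
        prev_cons = cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        return w[:-1] if _measure(w[:-3]) > 0 else w
    flag = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _double_cons(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "ement", "ance", "ence", "able", "ible", "ment", "ant", "ent", "ion",
    "ism", "ate", "iti", "ous", "ive", "ize", "al", "er", "ic", "ou",
]


def _map_suffix(w: str, table: list[tuple[str, str]], min_m: int) -> str:
    for suffix, repl in sorted(table, key=lambda t: -len(t[0])):
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > min_m - 1:
                return stem + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    return w
                return stem
            return w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem
    if _measure(w) > 1 and _double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


def stem_term(word: str) -> str:
    """Porter stem of a single word (lowercased, whitespace-trimmed).

    Words of length <= 2 are returned unchanged, per the algorithm.
    Empty input yields the empty string.
    """
    w = word.strip().lower()
    if len(w) <= 2:
        return w
    for step in (_step1a, _step1b, _step1c):
        w = step(w)
    w = _map_suffix(w, _STEP2, 1)
    w = _map_suffix(w, _STEP3, 1)
    w = _step4(w)
    w = _step5(w)
    return w


def stem_phrase(text: str) -> list[str]:
    """Stems of every whitespace-separated word of *text*, in order."""
    return [stem_term(tok) for tok in text.split()]


# ---------------------------------------------------------------------------
# Hypothesis terms
# ---------------------------------------------------------------------------


@dataclass
class HypothesisTerm:
    label: str
    go_ids: list[str] = field(default_factory=list)
    source: dict[str, str] = field(default_factory=dict)  # id -> {"search","manual"}


@dataclass
class HypothesisSet:
    terms: list[HypothesisTerm] = field(default_factory=list)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def get(self, label: str) -> HypothesisTerm | None:
        wanted = label.strip().casefold()
        for t in self.terms:
            if t.label.strip().casefold() == wanted:
                return t
        return None


_FIELD_PRIORITY = {"name": 0, "synonym": 1, "definition": 2}


def search_ontology(dag: GoDag, label: str) -> list[tuple[str, str, str]]:
    """Find GO terms whose name, a synonym, or definition contains every
    word-stem of *label* as a substring.

    All stems must match within the same field (conjunctive matching), so a
    multi-word hypothesis cannot be satisfied by scattered coincidences.
    Obsolete terms are never candidates.  Results are ``(go_id, name,
    matched_field)`` triples ordered by field priority (name before synonym
    before definition) then id.
    """
    stems = [s for s in stem_phrase(label) if s]
    if not stems:
        return []
    hits: list[tuple[int, str, str, str]] = []
    for term in dag.terms.values():
        if term.obsolete:
            continue
        fields = [("name", term.name)]
        fields += [("synonym", syn) for syn in term.synonyms]
        fields += [("definition", term.definition)]
        for kind, text in fields:
            low = text.lower()
            if low and all(stem in low for stem in stems):
                hits.append((_FIELD_PRIORITY[kind], term.id, term.name, kind))
                break
    hits.sort(key=lambda h: (h[0], h[1]))
    return [(go_id, name, kind) for _, go_id, name, kind in hits]


def build_hypothesis_set(
    dag: GoDag,
    labels: Iterable[str],
    select: Union[str, dict[str, list[int]]] = "all",
) -> HypothesisSet:
    """Build an HGT set by searching the ontology for each hypothesis label.

    ``select='all'`` takes every candidate; a mapping label → index list
    takes only those positions from that label's candidate list (replacing
    the original tool's checkbox interface).
    """
    hset = HypothesisSet()
    seen_labels: set[str] = set()
    for raw in labels:
        label = raw.strip()
        if not label or label.startswith("#"):
            continue
        key = label.casefold()
        if key in seen_labels:
            raise HgtValidationError(f"duplicate hypothesis label: {label!r}")
        seen_labels.add(key)
        candidates = search_ontology(dag, label)
        if select == "all":
            chosen = candidates
        else:
            indices = select.get(label, [])
            chosen = [candidates[i] for i in indices]
        ids = [go_id for go_id, _, _ in chosen]
        hset.terms.append(
            HypothesisTerm(label, ids, {i: "search" for i in ids})
        )
    return hset


def read_hgt(source: Union[str, IO[str]], dag: GoDag) -> HypothesisSet:
    """Parse an HGT file: ``label, GO:id[, GO:id...]`` per line, ``#`` comments.

    Every id must be valid (present and non-obsolete) in *dag*.
    """
    text = source if isinstance(source, str) else source.read()
    hset = HypothesisSet()
    seen_labels: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        label, ids = parts[0], parts[1:]
        if not ids:
            raise HgtFormatError(f"line {lineno}: no GO id after label {label!r}")
        key = label.casefold()
        if key in seen_labels:
            raise HgtValidationError(f"line {lineno}: duplicate label {label!r}")
        seen_labels.add(key)
        for go_id in ids:
            status = dag.status(go_id)
            if status != "valid":
                raise HgtValidationError(
                    f"hypothesis {label!r}: GO id {go_id} is {status}"
                )
        resolved = []
        for go_id in ids:
            rid = dag.resolve(go_id)
            if rid not in resolved:
                resolved.append(rid)
        hset.terms.append(
            HypothesisTerm(label, resolved, {i: "manual" for i in resolved})
        )
    return hset


def write_hgt(hset: HypothesisSet) -> str:
    """Serialise to HGT text: one ``label, id, id`` line per term."""
    lines = [f"{t.label}, " + ", ".join(t.go_ids) for t in hset.terms]
    return "\n".join(lines) + ("\n" if lines else "")
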