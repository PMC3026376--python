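"""Gene → GO annotation sets, loaded from GAF 2.x or a simple id→GO map.

Annotations are validated against a loaded ontology at parse time: obsolete
and unknown GO ids are dropped with a logged warning, and GAF rows carrying a
NOT qualifier are excluded entirely (negated annotation is not evidence of an
opposite effect).  Genes whose every annotation was dropped are retained with
an empty set so they surface downstream as "undefined" rows rather than
silently disappearing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Union

from Bio.UniProt import GOA

from .ontology import GoDag

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """Structurally invalid annotation line, reported with its line number."""


@dataclass
class AnnotationRecord:
    gene_id: str
    go_id: str
    qualifier: str = ""
    evidence: str = ""
    line: int = 0


@dataclass
class AnnotationSet:
    """Map gene identifier → set of GO ids, with per-pair provenance.

    ``by_gene`` distinguishes a gene that was seen but lost all its
    annotations (empty set) from a gene never seen at all (absent key):
    :meth:`annotations_of` reports the difference via its ``seen`` flag.
    """

    by_gene: dict[str, set[str]] = field(default_factory=dict)
    provenance: list[AnnotationRecord] = field(default_factory=list)

    def annotations_of(self, gene_id: str) -> tuple[set[str], bool]:
        """Return (GO ids, seen-flag). Absent gene → (empty set, False)."""
        if gene_id in self.by_gene:
            return set(self.by_gene[gene_id]), True
        return set(), False

    def genes(self) -> list[str]:
        return list(self.by_gene)

    def __len__(self) -> int:
        return len(self.by_gene)


def _validate_gaf_lines(text: str) -> None:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        ncols = len(raw.split("\t"))
        if ncols < 15:
            raise AnnotationFormatError(
                f"GAF line {lineno} has {ncols} columns (expected >= 15)"
            )


def _parse_gaf(text: str, dag: GoDag, case_insensitive: bool) -> AnnotationSet:
    _validate_gaf_lines(text)
    aset = AnnotationSet()
    body = "\n".join(l for l in text.splitlines() if l.strip())
    if not body.startswith("!"):
        body = "!gaf-version: 2.1\n" + body
    for lineno, rec in enumerate(GOA.gafiterator(io.StringIO(body)), start=1):
        gene = rec["DB_Object_Symbol"]
        if case_insensitive:
            gene = gene.lower()
        go_id = rec["GO_ID"]
        qualifiers = [q for q in rec.get("Qualifier", []) if q]
        evidence = rec.get("Evidence", "")
        if any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
            logger.warning("dropping NOT-qualified annotation %s -> %s", gene, go_id)
            aset.by_gene.setdefault(gene, set())
            continue
        _admit(aset, gene, go_id, dag, "|".join(qualifiers), evidence, lineno)
    return aset


def _parse_idmap(text: str, dag: GoDag, case_insensitive: bool) -> AnnotationSet:
    aset = AnnotationSet()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        fields = [f.strip() for f in fields]
        if len(fields) != 2:
            raise AnnotationFormatError(
                f"idmap line {lineno} has {len(fields)} fields (expected 2)"
            )
        gene, go_id = fields
        if case_insensitive:
            gene = gene.lower()
        _admit(aset, gene, go_id, dag, "", "", lineno)
    return aset


def _admit(
    aset: AnnotationSet,
    gene: str,
    go_id: str,
    dag: GoDag,
    qualifier: str,
    evidence: str,
    lineno: int,
) -> None:
    status = dag.status(go_id)
    aset.by_gene.setdefault(gene, set())
    if status == "valid":
        aset.by_gene[gene].add(dag.resolve(go_id))
        aset.provenance.append(
            AnnotationRecord(gene, dag.resolve(go_id), qualifier, evidence, lineno)
        )
    else:
        logger.warning("dropping %s annotation %s -> %s", status, gene, go_id)


def parse_annotations(
    source: Union[str, IO[str]],
    format: str,
    dag: GoDag,
    case_insensitive: bool = False,
) -> AnnotationSet:
    """Parse annotations from GAF 2.x (``format='gaf'``) or two-column
    id→GO text (``format='idmap'``), validating every GO id against *dag*.

    Gene identifier matching is exact and case-sensitive unless
    ``case_insensitive`` is set (which lowercases gene symbols).
    """
    if format not in ("gaf", "idmap"):
        raise ValueError(f"unknown annotation format: {format!r}")
    text = source if isinstance(source, str) else source.read()
    if not text.strip():
        return AnnotationSet()
    if format == "gaf":
        return _parse_gaf(text, dag, case_insensitive)
    return _parse_idmap(text, dag, case_insensitive)


def annotations_of(aset: AnnotationSet, gene_id: str) -> tuple[set[str], bool]:
    """Functional alias for :meth:`AnnotationSet.annotations_of`."""
    return aset.annotations_of(gene_id)


def write_gene_info(
    aset: AnnotationSet, expressions: list[tuple[str, float]]
) -> str:
    """Emit a Gene Information File: gene id, expression value, GO ids.

    One line per gene, comma-separated, GO ids comma-joined after the value.
    """
    lines = []
    for gene, value in expressions:
        ids, _seen = aset.annotations_of(gene)
        parts = [gene, format(value, "g")]
        parts.extend(sorted(ids))
        lines.append(",".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")
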