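"""Gene Ontology DAG: OBO parsing, ancestor closure, term validity.

The ontology is the substrate for true-path-rule matching: an annotation to a
term implies annotation to every ancestor of that term, so effect matching
walks ``is_a``/``part_of`` edges upward.  ``regulates``-family edges are
parsed and stored but excluded from traversal by default, because a regulator
of a process is not a generalisation of it and following such edges would
silently change effect semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import networkx as nx
import obonet

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Relations followed by ancestor traversal (the true-path rule concerns
#: generalisation only).
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})
REGULATES_RELATIONS = frozenset(
    {"regulates", "positively_regulates", "negatively_regulates"}
)

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


class OboParseError(ValueError):
    """Malformed OBO stanza (missing id or name), reported with its line."""


class OboCycleError(ValueError):
    """The is_a/part_of graph contains a cycle; one witness cycle is listed."""


class UnknownTermError(KeyError):
    pass


class ObsoleteTermError(ValueError):
    pass


@dataclass
class GoTerm:
    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    definition: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)  # (parent_id, relation)
    obsolete: bool = False
    namespace: str = ""


class GoDag:
    """Parsed ontology: terms by id, parent edges, memoised ancestor queries.

    Alternate ids (``alt_id``) resolve transparently to their canonical term,
    so queries on an alt id behave exactly as queries on the canonical id.
    """

    def __init__(self, terms: dict[str, GoTerm], alt_ids: dict[str, str] | None = None):
        self.terms = terms
        self.alt_ids = alt_ids or {}
        self._ancestor_cache: dict[tuple[str, bool], frozenset[str]] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return self.resolve(term_id) in self.terms

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its canonical id; other ids pass through."""
        return self.alt_ids.get(term_id, term_id)

    def get(self, term_id: str) -> GoTerm | None:
        return self.terms.get(self.resolve(term_id))

    def __getitem__(self, term_id: str) -> GoTerm:
        term = self.get(term_id)
        if term is None:
            raise UnknownTermError(term_id)
        return term

    @property
    def roots(self) -> list[str]:
        return [
            t.id
            for t in self.terms.values()
            if not t.obsolete and not self._traversable_parents(t, False)
        ]

    @staticmethod
    def _traversable_parents(term: GoTerm, include_regulates: bool) -> list[str]:
        rels = DEFAULT_RELATIONS | (REGULATES_RELATIONS if include_regulates else frozenset())
        return [p for p, rel in term.parents if rel in rels]

    def parents_of(self, term_id: str, include_regulates: bool = False) -> list[str]:
        """Direct traversable parents (deduplicated, order-preserving)."""
        term = self[term_id]
        seen: dict[str, None] = {}
        for p in self._traversable_parents(term, include_regulates):
            seen.setdefault(self.resolve(p))
        return list(seen)

    def ancestors(self, term_id: str, include_regulates: bool = False) -> frozenset[str]:
        """Transitive closure over is_a/part_of edges, excluding the term itself.

        Memoised: repeated queries are answered from cache.
        """
        canonical = self.resolve(term_id)
        term = self.terms.get(canonical)
        if term is None:
            raise UnknownTermError(term_id)
        if term.obsolete:
            raise ObsoleteTermError(f"term is obsolete: {term_id}")
        key = (canonical, include_regulates)
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents_of(canonical, include_regulates):
            if p in self.terms:
                out.add(p)
                out |= self.ancestors(p, include_regulates)
        result = frozenset(out)
        self._ancestor_cache[key] = result
        return result

    def status(self, term_id: str) -> str:
        """Classify an arbitrary string: 'valid', 'obsolete', or 'unknown'."""
        term = self.terms.get(self.resolve(term_id))
        if term is None:
            return "unknown"
        return "obsolete" if term.obsolete else "valid"


def _validate_stanzas(text: str) -> None:
    """Line-numbered structural check: every [Term] stanza has id and name.

    Obsolete stanzas are exempt from the name requirement only if they carry
    an id (GO practice always names them, but an id-only tombstone parses).
    """
    in_term = False
    stanza_line = 0
    have_id = have_name = False

    def flush() -> None:
        if in_term and not (have_id and have_name):
            missing = "id" if not have_id else "name"
            raise OboParseError(
                f"[Term] stanza starting at line {stanza_line} is missing '{missing}'"
            )

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza_line = lineno
            have_id = have_name = False
        elif in_term:
            if line.startswith("id:"):
                have_id = True
            elif line.startswith("name:"):
                have_name = True
    flush()


def _clean_synonyms(raw: Iterable[str]) -> list[str]:
    out = []
    for entry in raw:
        m = _SYNONYM_RE.search(entry)
        out.append(m.group(1) if m else entry.strip())
    return out


def _clean_definition(raw: str) -> str:
    m = _SYNONYM_RE.search(raw)
    return m.group(1) if m else raw.strip()


def parse_obo(source: Union[str, IO[str]]) -> GoDag:
    """Parse OBO 1.2/1.4 text into a :class:`GoDag`.

    Interprets id, name, synonym, def, is_a, relationship, is_obsolete,
    alt_id and namespace; all other tags are ignored.  Obsolete terms are
    retained (flagged) but excluded from traversal.

    Raises
    ------
    OboParseError
        A [Term] stanza lacks an id or name (the offending line is named).
    OboCycleError
        The is_a/part_of graph is cyclic; one witness cycle is listed.
    """
    text = source if isinstance(source, str) else source.read()
    if not text.strip():
        return GoDag({})
    _validate_stanzas(text)

    import io

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: dict[str, GoTerm] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents: list[tuple[str, str]] = []
        for parent in data.get("is_a", []):
            parents.append((parent, "is_a"))
        for rel_line in data.get("relationship", []):
            parts = rel_line.split()
            if len(parts) >= 2:
                parents.append((parts[1], parts[0]))
        term = GoTerm(
            id=node,
            name=data.get("name", ""),
            synonyms=_clean_synonyms(data.get("synonym", [])),
            definition=_clean_definition(data.get("def", "")),
            parents=parents,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            namespace=data.get("namespace", ""),
        )
        terms[node] = term
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    _check_acyclic(terms)
    return GoDag(terms, alt_ids)


def _check_acyclic(terms: dict[str, GoTerm]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for term in terms.values():
        if term.obsolete:
            continue
        for parent, rel in term.parents:
            if rel in DEFAULT_RELATIONS and parent in terms:
                g.add_edge(term.id, parent)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
    raise OboCycleError(f"is_a/part_of graph contains a cycle: {path}")


def ancestors(dag: GoDag, term_id: str, include_regulates: bool = False) -> frozenset[str]:
    """Functional alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term_id, include_regulates)


def term_status(dag: GoDag, term_id: str) -> str:
    """Functional alias for :meth:`GoDag.status` (total: never raises)."""
    return dag.status(term_id)


def write_obo(dag: GoDag) -> str:
    """Serialise a GoDag back to minimal OBO text (round-trip safe)."""
    lines = ["format-version: 1.2", "ontology: goeffects", ""]
    for term in dag.terms.values():
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for alt, canonical in dag.alt_ids.items():
            if canonical == term.id:
                lines.append(f"alt_id: {alt}")
        if term.definition:
            lines.append(f'def: "{term.definition}" []')
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" RELATED []')
        for parent, rel in term.parents:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)
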