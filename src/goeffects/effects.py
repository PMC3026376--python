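"""Signed effect assignment: name parsing, true-path matching, conflict resolution.

The core idea: a gene annotated to ``negative regulation of apoptosis`` acts
against an "apoptosis" hypothesis, and that can be read off the term *name*.
GO names carry their sign in a handful of cue words ("positive", "anti",
"suppresses", ...), so a gene's qualitative effect on a hypothesis term is
found by (1) matching each of its GO ids — or, by the true-path rule, any
ancestor of them — against the hypothesis's GO id list, and (2) parsing the
matched annotation's name for a sign cue.

Terms whose names carry no cue ("regulation of apoptosis") are *unsigned*;
a user policy decides whether they count as no effect (0) or as positive
(+1, reflecting the publication bias toward positive findings).  A gene may
collect both +1 and −1 for the same hypothesis (context-dependent biology);
a conflict-resolution policy picks the reported value.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Union

from .hypothesis import HypothesisTerm
from .ontology import GoDag, ObsoleteTermError, UnknownTermError

logger = logging.getLogger(__name__)

UNSIGNED = "unsigned"
UNDEFINED = "undefined"

Sign = Union[int, str]  # +1 | -1 | "unsigned"

_TOKEN_SPLIT = re.compile(r"[\s\-_/]+")

#: Cue words matched as whole tokens.  Short cues ("pro", "anti") are
#: token-anchored so "process" and "antigen" never trigger them.
_POSITIVE_TOKENS = frozenset({"positive", "pro", "stimulates", "upregulates"})
_NEGATIVE_TOKENS = frozenset(
    {"negative", "anti", "suppresses", "inhibits", "downregulates"}
)
#: Cue stems matched as token prefixes (covers increases/increased etc.).
_POSITIVE_PREFIXES = ("increas", "stimulat", "upregulat")
_NEGATIVE_PREFIXES = ("decreas", "suppress", "inhibit", "downregulat")


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the effect-mapping stage.

    unsigned_policy
        ``"no_effect"``: unsigned terms score 0. ``"positive"``: they score
        +1 (the published study's setting).
    conflict_policy
        ``"positives_override"`` | ``"negatives_override"`` | ``"greater_of"``.
    sign_from
        ``"original"``: parse the gene's own (most specific) term name, fall
        back to the matched hypothesis-side name when unsigned — the default,
        because generalisation discards sign.  ``"matched"``: parse only the
        matched name.
    traverse_regulates
        Follow regulates-family edges during matching (off by default).
    max_depth
        Optional cap on upward steps; matches beyond it are skipped with a
        warning.
    """

    unsigned_policy: Literal["no_effect", "positive"] = "positive"
    conflict_policy: Literal[
        "positives_override", "negatives_override", "greater_of"
    ] = "positives_override"
    sign_from: Literal["original", "matched"] = "original"
    traverse_regulates: bool = False
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.unsigned_policy not in ("no_effect", "positive"):
            raise ValueError(f"bad unsigned_policy: {self.unsigned_policy!r}")
        if self.conflict_policy not in (
            "positives_override",
            "negatives_override",
            "greater_of",
        ):
            raise ValueError(f"bad conflict_policy: {self.conflict_policy!r}")
        if self.sign_from not in ("original", "matched"):
            raise ValueError(f"bad sign_from: {self.sign_from!r}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class EffectRecord:
    gene_go_id: str       # the originally annotated id
    matched_go_id: str    # hypothesis-side id where the match occurred
    depth: int            # parent steps taken; 0 = exact match
    sign: Sign            # +1 | -1 | "unsigned"


@dataclass
class EffectList:
    """Effects found for one (gene, hypothesis) pair."""

    records: list[EffectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def matched_ids(self) -> set[str]:
        return {r.matched_go_id for r in self.records}


def parse_effect_sign(term_name: str) -> Sign:
    """Read the effect sign off a GO term name.

    The name is lowercased and split on whitespace, hyphens, underscores and
    slashes; the leftmost cue token decides (GO names are left-modified:
    "negative regulation of pro-B cell differentiation" is a negative
    regulator, so its leading cue must win).
    """
    for token in _TOKEN_SPLIT.split(term_name.lower()):
        if not token:
            continue
        if token in _POSITIVE_TOKENS or token.startswith(_POSITIVE_PREFIXES):
            return +1
        if token in _NEGATIVE_TOKENS or token.startswith(_NEGATIVE_PREFIXES):
            return -1
    return UNSIGNED


def apply_unsigned_policy(sign: Sign, cfg: ScoringConfig) -> int:
    """Collapse a parser sign to a numeric effect under the unsigned policy."""
    if sign == UNSIGNED:
        return +1 if cfg.unsigned_policy == "positive" else 0
    return int(sign)


def _record_sign(dag: GoDag, gene_go_id: str, matched_go_id: str, cfg: ScoringConfig) -> Sign:
    if cfg.sign_from == "matched":
        return parse_effect_sign(dag[matched_go_id].name)
    sign = parse_effect_sign(dag[gene_go_id].name)
    if sign == UNSIGNED and matched_go_id != gene_go_id:
        sign = parse_effect_sign(dag[matched_go_id].name)
    return sign


def match_effects(
    dag: GoDag,
    gene_go_ids: Iterable[str],
    hyp: HypothesisTerm,
    cfg: ScoringConfig = ScoringConfig(),
) -> EffectList:
    """Match a gene's GO ids against a hypothesis term's GO id list.

    For each gene id: an exact match records an effect at depth 0; the
    search also walks upward through parents (is_a/part_of, regulates if
    enabled), recording a match at the first (shallowest) depth at which
    each hypothesis id is reached.  The matched ids are therefore exactly
    the hypothesis ids lying in {gene id} ∪ ancestors(gene id).  Records
    are deduplicated on (gene id, matched id) so DAG fan-in cannot inflate
    counts under the greater-of policy.
    """
    hyp_ids = {dag.resolve(i) for i in hyp.go_ids}
    elist = EffectList()
    seen_pairs: set[tuple[str, str]] = set()
    for raw_id in gene_go_ids:
        g = dag.resolve(raw_id)
        status = dag.status(g)
        if status != "valid":
            if status == "obsolete":
                raise ObsoleteTermError(f"gene GO id is obsolete: {raw_id}")
            raise UnknownTermError(raw_id)
        # breadth-first walk upward; visited set guarantees termination
        frontier: deque[tuple[str, int]] = deque([(g, 0)])
        visited = {g}
        while frontier:
            node, depth = frontier.popleft()
            if node in hyp_ids:
                pair = (g, node)
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    elist.records.append(
                        EffectRecord(g, node, depth, _record_sign(dag, g, node, cfg))
                    )
            if cfg.max_depth is not None and depth >= cfg.max_depth:
                logger.warning(
                    "match search for %s truncated at depth %d", g, depth
                )
                continue
            for parent in dag.parents_of(node, cfg.traverse_regulates):
                if parent not in visited and parent in dag.terms:
                    visited.add(parent)
                    frontier.append((parent, depth + 1))
    return elist


def resolve(
    elist: EffectList, cfg: ScoringConfig = ScoringConfig()
) -> tuple[Union[int, str], bool]:
    """Collapse an effect list to a single qualitative value.

    Returns ``(value, conflict)`` where value is +1, −1, 0 or ``"undefined"``
    (empty list).  Signs are first passed through the unsigned policy; a
    conflict is flagged when both +1 and −1 survive, and resolved per the
    configured policy (greater-of ties resolve to 0).
    """
    if not elist.records:
        return UNDEFINED, False
    values = [apply_unsigned_policy(r.sign, cfg) for r in elist.records]
    return resolve_values(values, cfg)


def resolve_values(
    values: Iterable[int], cfg: ScoringConfig = ScoringConfig()
) -> tuple[Union[int, str], bool]:
    """Resolve already-numeric effect values (+1/−1/0) to a single value."""
    values = list(values)
    if not values:
        return UNDEFINED, False
    pos = sum(1 for v in values if v > 0)
    neg = sum(1 for v in values if v < 0)
    if not (pos and neg):
        # no conflict: all values agree in sign (or are all zero)
        if pos:
            return +1, False
        if neg:
            return -1, False
        return 0, False
    if cfg.conflict_policy == "positives_override":
        return +1, True
    if cfg.conflict_policy == "negatives_override":
        return -1, True
    diff = pos - neg
    return (0 if diff == 0 else (1 if diff > 0 else -1)), True
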