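"""Lens-enrichment filtering, tiered candidate prioritization, inverse correlation.

Candidate target mRNAs are ranked into "top", "high" and "promising" tiers by
combining four evidence flags per pair:

* ``de_p4``   - the mRNA moves opposite to its miRNA at the early stage
* ``de_p30``  - ditto at the later stage
* ``enriched_p4`` / ``enriched_p30`` - lens-enriched expression at each stage
  (expression intensity >= floor and enrichment fold-change > 1)

The default rule set requires all four flags for "top", both differential
stages plus either enrichment stage for "high", and the early differential
stage plus either enrichment stage for "promising"; rules are applied in that
order, first match wins, and are fully configurable through a small
``tier: flag AND (flag OR flag)`` grammar.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .core import DifferentialRecord, LensEnrichmentRecord, normalize_id, signed_log2
from .pairing import MiRnaMrnaPair, unique_mrna_count

__all__ = [
    "TierRuleSet",
    "CorrelationResult",
    "enrichment_filter",
    "set_p30_directions",
    "pair_flags",
    "assign_tiers",
    "tier_counts",
    "inverse_correlation",
]

EVIDENCE_FLAGS = ("de_p4", "de_p30", "enriched_p4", "enriched_p30")
RANKED_TIERS = ("top", "high", "promising")

DEFAULT_RULES_TEXT = """\
top: de_p4 AND de_p30 AND enriched_p4 AND enriched_p30
high: de_p4 AND de_p30 AND (enriched_p4 OR enriched_p30)
promising: de_p4 AND (enriched_p4 OR enriched_p30)
"""


# --- tiny boolean expression grammar over evidence flags --------------------


class _BoolExpr:
    def evaluate(self, flags: Mapping[str, bool]) -> bool:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class _Flag(_BoolExpr):
    name: str

    def evaluate(self, flags: Mapping[str, bool]) -> bool:
        return bool(flags[self.name])


@dataclass(frozen=True)
class _Conn(_BoolExpr):
    op: str
    operands: tuple[_BoolExpr, ...]

    def evaluate(self, flags: Mapping[str, bool]) -> bool:
        results = (o.evaluate(flags) for o in self.operands)
        return all(results) if self.op == "AND" else any(results)


_TOKEN = re.compile(r"\s*(\(|\)|AND\b|OR\b|[A-Za-z_][A-Za-z0-9_]*)", re.IGNORECASE)


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ValueError(f"cannot tokenize rule near {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _parse_expr(tokens: list[str], pos: int = 0) -> tuple[_BoolExpr, int]:
    """expr := term (OR term)* ; term := atom (AND atom)* ; atom := flag | ( expr )"""

    def parse_atom(p: int) -> tuple[_BoolExpr, int]:
        if p >= len(tokens):
            raise ValueError("unexpected end of rule expression")
        tok = tokens[p]
        if tok == "(":
            node, p = parse_or(p + 1)
            if p >= len(tokens) or tokens[p] != ")":
                raise ValueError("unbalanced parenthesis in rule expression")
            return node, p + 1
        name = tok.lower()
        if name not in EVIDENCE_FLAGS:
            raise ValueError(f"unknown evidence flag {tok!r}")
        return _Flag(name), p + 1

    def parse_and(p: int) -> tuple[_BoolExpr, int]:
        node, p = parse_atom(p)
        operands = [node]
        while p < len(tokens) and tokens[p].upper() == "AND":
            nxt, p = parse_atom(p + 1)
            operands.append(nxt)
        return (operands[0] if len(operands) == 1 else _Conn("AND", tuple(operands))), p

    def parse_or(p: int) -> tuple[_BoolExpr, int]:
        node, p = parse_and(p)
        operands = [node]
        while p < len(tokens) and tokens[p].upper() == "OR":
            nxt, p = parse_and(p + 1)
            operands.append(nxt)
        return (operands[0] if len(operands) == 1 else _Conn("OR", tuple(operands))), p

    return parse_or(pos)


@dataclass
class TierRuleSet:
    """Ordered tier rules (top -> high -> promising, first match wins).

    Overlap between rules is resolved by application order, so a pair matching
    both the "top" and "high" expressions is "top"; a rule set whose tiers are
    unsatisfiable in order (a later rule strictly implied by an earlier one
    never fires for any pair the earlier one missed) is legal, but missing or
    duplicated tier names are rejected at load time.
    """

    rules: dict[str, _BoolExpr] = field(default_factory=dict)
    expression_floor: float = 100.0

    @classmethod
    def from_text(cls, text: str, expression_floor: float = 100.0) -> "TierRuleSet":
        rules: dict[str, _BoolExpr] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"rule line {lineno}: expected 'tier: expression'")
            tier, expr_text = (part.strip() for part in line.split(":", 1))
            tier = tier.lower()
            if tier not in RANKED_TIERS:
                raise ValueError(f"rule line {lineno}: unknown tier {tier!r}")
            if tier in rules:
                raise ValueError(f"rule line {lineno}: duplicate tier {tier!r}")
            node, end = _parse_expr(_tokenize(expr_text))
            if end != len(_tokenize(expr_text)):
                raise ValueError(f"rule line {lineno}: trailing tokens")
            rules[tier] = node
        missing = [t for t in RANKED_TIERS if t not in rules]
        if missing:
            raise ValueError(f"rule set missing tiers: {missing}")
        return cls(rules=rules, expression_floor=expression_floor)

    @classmethod
    def default(cls, expression_floor: float = 100.0) -> "TierRuleSet":
        return cls.from_text(DEFAULT_RULES_TEXT, expression_floor=expression_floor)

    def classify(self, flags: Mapping[str, bool]) -> str:
        for tier in RANKED_TIERS:
            if self.rules[tier].evaluate(flags):
                return tier
        return "unranked"


@dataclass
class CorrelationResult:
    """Pearson correlation of paired signed log2 fold changes."""

    r: float
    p: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of [-1,1]: {self.r!r}")


def enrichment_filter(
    pairs: Sequence[MiRnaMrnaPair],
    enrichment_table: Mapping[str, LensEnrichmentRecord],
    stage: str,
    expression_floor: float = 100.0,
) -> list[MiRnaMrnaPair]:
    """Attach stage-specific lens-enrichment evidence to pairs (in place).

    A pair's target is flagged enriched at ``stage`` iff it appears in the
    table with expression intensity >= ``expression_floor`` (inclusive) and
    enrichment fold-change > 1.  Returns the same pair list for chaining.
    """
    if stage not in ("p4", "p30"):
        raise ValueError(f"stage must be 'p4' or 'p30', got {stage!r}")
    for pair in pairs:
        rec = enrichment_table.get(normalize_id(pair.mrna_id))
        hit = (
            rec is not None
            and rec.expression_intensity >= expression_floor
            and rec.enrichment_fc > 1.0
        )
        setattr(pair, f"enrichment_{stage}", rec if hit else None)
    return list(pairs)


def set_p30_directions(
    pairs: Sequence[MiRnaMrnaPair], mrna_de_p30: Sequence[DifferentialRecord]
) -> list[MiRnaMrnaPair]:
    """Fill each pair's later-stage mRNA direction ('missing' if uncovered)."""
    directions = {normalize_id(r.feature_id): r.direction for r in mrna_de_p30}
    for pair in pairs:
        pair.mrna_direction_p30 = directions.get(normalize_id(pair.mrna_id), "missing")
    return list(pairs)


def pair_flags(pair: MiRnaMrnaPair) -> dict[str, bool]:
    """Evidence flags for one pair.

    ``de_p4``/``de_p30`` are true when the mRNA direction at that stage is
    opposite the miRNA's; every pair retained by inverse pairing has de_p4 by
    construction.
    """
    opposite = "down" if pair.mirna_direction == "up" else "up"
    return {
        "de_p4": pair.mrna_direction_p4 == opposite,
        "de_p30": pair.mrna_direction_p30 == opposite,
        "enriched_p4": pair.enrichment_p4 is not None,
        "enriched_p30": pair.enrichment_p30 is not None,
    }


def assign_tiers(
    pairs: Sequence[MiRnaMrnaPair], rules: TierRuleSet | None = None
) -> list[MiRnaMrnaPair]:
    """Assign each pair its first-matching tier (deterministic, order-free)."""
    rules = rules or TierRuleSet.default()
    for pair in pairs:
        pair.tier = rules.classify(pair_flags(pair))
    return list(pairs)


def tier_counts(pairs: Sequence[MiRnaMrnaPair], mirna_direction: str) -> dict[str, int]:
    """Unique-mRNA counts per tier within one miRNA-direction group.

    An mRNA shared by several miRNAs of the group counts once, at the best
    tier any of its pairs achieved; the ranked-tier counts therefore sum to
    the group's unique ranked-target total.
    """
    order = {t: i for i, t in enumerate((*RANKED_TIERS, "unranked"))}
    best: dict[str, str] = {}
    for pair in pairs:
        if pair.mirna_direction != mirna_direction:
            continue
        key = normalize_id(pair.mrna_id)
        if key not in best or order[pair.tier] < order[best[key]]:
            best[key] = pair.tier
    counts = {t: 0 for t in (*RANKED_TIERS, "unranked")}
    for tier in best.values():
        counts[tier] += 1
    return counts


def inverse_correlation(
    pairs: Sequence[MiRnaMrnaPair],
    mirna_de: Sequence[DifferentialRecord],
    mrna_de: Sequence[DifferentialRecord],
) -> CorrelationResult:
    """Pearson correlation between paired miRNA and mRNA fold changes.

    Fold changes are mapped to the symmetric signed log2 scale before
    correlating so that up- and down-regulation of equal magnitude contribute
    equal weight.  Two-sided p-value from the t transform of r.
    """
    mirna_fc = {normalize_id(r.feature_id): r.fc for r in mirna_de}
    mrna_fc = {normalize_id(r.feature_id): r.fc for r in mrna_de}
    xs, ys = [], []
    for pair in pairs:
        mk, gk = normalize_id(pair.mirna_id), normalize_id(pair.mrna_id)
        if mk in mirna_fc and gk in mrna_fc:
            xs.append(signed_log2(mirna_fc[mk]))
            ys.append(signed_log2(mrna_fc[gk]))
    n = len(xs)
    if n < 3:
        raise ValueError(f"inverse correlation needs >= 3 pairs, got {n}")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("inverse correlation undefined: zero variance in fold changes")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), p=float(p), n_pairs=n)
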