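"""Inverse miRNA-mRNA pairing and canonical seed-site classification.

A miRNA represses its targets, so a regulatory relationship between a
misexpressed miRNA and a predicted target mRNA is supported when the two move
in opposite directions: (miRNA up, mRNA down) or (miRNA down, mRNA up).
Pairing joins the differential calls through a score-filtered target map.

Seed sites are classified on the canonical hierarchy used by target-prediction
resources: the seed is miRNA nucleotides 2-7 (5'->3'); a UTR locus whose
sequence is the reverse complement of the seed is a 6mer, strengthened to
7mer-m8 by a match opposite miRNA position 8, to 7mer-A1 by an adenosine
opposite position 1, and to 8mer by both.  Pairing is strict Watson-Crick
(G:U wobble not counted) unless enabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    DifferentialRecord,
    LensEnrichmentRecord,
    TargetPrediction,
    normalize_id,
)

__all__ = [
    "MiRnaMrnaPair",
    "SeedSite",
    "filter_targets",
    "pair_inverse",
    "unique_mrna_count",
    "scan_seed_sites",
]

logger = logging.getLogger(__name__)

TIERS = ("top", "high", "promising", "unranked")


@dataclass
class MiRnaMrnaPair:
    """One (miRNA, target mRNA) edge with direction, enrichment and tier evidence.

    ``mrna_direction_p30`` is "missing" when the later-stage table does not
    cover the gene.  Enrichment references and the tier are filled in by the
    prioritization stage.
    """

    mirna_id: str
    mrna_id: str
    mirna_direction: str
    mrna_direction_p4: str
    mrna_direction_p30: str = "missing"
    prediction_score: float = 0.0
    enrichment_p4: Optional[LensEnrichmentRecord] = None
    enrichment_p30: Optional[LensEnrichmentRecord] = None
    tier: str = "unranked"

    def __post_init__(self) -> None:
        if self.mirna_direction not in ("up", "down"):
            raise ValueError(f"pair miRNA direction must be up/down, got {self.mirna_direction!r}")
        if self.tier not in TIERS:
            raise ValueError(f"invalid tier {self.tier!r}")


# site-type strength order, strongest first
SITE_HIERARCHY = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    """A classified seed-complementary site on a UTR (0-based, half-open)."""

    start: int
    end: int
    site_type: str

    @property
    def utr_position(self) -> int:
        return self.start


def filter_targets(
    predictions: Sequence[TargetPrediction], min_score: float = 50.0
) -> list[TargetPrediction]:
    """Keep predictions with score >= ``min_score`` (boundary inclusive)."""
    return [p for p in predictions if p.score >= min_score]


def pair_inverse(
    mirna_de: Sequence[DifferentialRecord],
    mrna_de: Sequence[DifferentialRecord],
    targets: Sequence[TargetPrediction],
) -> list[MiRnaMrnaPair]:
    """Build inversely-directed miRNA-mRNA pairs through the target map.

    Retains (miRNA up, mRNA down) and (miRNA down, mRNA up) pairs for every
    target-map edge whose miRNA and mRNA both carry a differential call.
    Differentially expressed miRNAs absent from the target map are dropped
    with a logged warning (no prediction evidence is available for them).
    Identifiers are matched case-insensitively; pairs are gene-symbol level
    (the map is assumed pre-collapsed from transcripts).
    """
    de_mirnas = {
        normalize_id(r.feature_id): r for r in mirna_de if r.direction in ("up", "down")
    }
    mrna_by_id = {normalize_id(r.feature_id): r for r in mrna_de}
    target_mirnas = {normalize_id(t.mirna_id) for t in targets}
    for key, rec in sorted(de_mirnas.items()):
        if key not in target_mirnas:
            logger.warning(
                "miRNA %s is differentially expressed but absent from the target map; "
                "excluded from pairing",
                rec.feature_id,
            )
    pairs: list[MiRnaMrnaPair] = []
    seen: set[tuple[str, str]] = set()
    for t in targets:
        mk, gk = normalize_id(t.mirna_id), normalize_id(t.mrna_id)
        if (mk, gk) in seen:
            continue
        mirna = de_mirnas.get(mk)
        mrna = mrna_by_id.get(gk)
        if mirna is None or mrna is None:
            continue
        if {mirna.direction, mrna.direction} == {"up", "down"}:
            seen.add((mk, gk))
            pairs.append(
                MiRnaMrnaPair(
                    mirna_id=mirna.feature_id,
                    mrna_id=mrna.feature_id,
                    mirna_direction=mirna.direction,
                    mrna_direction_p4=mrna.direction,
                    prediction_score=t.score,
                )
            )
    pairs.sort(key=lambda p: (normalize_id(p.mirna_id), normalize_id(p.mrna_id)))
    return pairs


def unique_mrna_count(pairs: Sequence[MiRnaMrnaPair]) -> int:
    """Distinct target genes among pairs (pairs >= unique mRNAs when shared)."""
    return len({normalize_id(p.mrna_id) for p in pairs})


_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE_PARTNERS = {"G": {"C", "U"}, "U": {"A", "G"}, "A": {"U"}, "C": {"G"}}
_RNA_ALPHABET = set("ACGU")


def _check_rna(seq: str, what: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)}")
    return s


def _pairs_with(mirna_base: str, utr_base: str, wobble: bool) -> bool:
    if wobble:
        return utr_base in _WOBBLE_PARTNERS[mirna_base]
    return _COMPLEMENT[mirna_base] == utr_base


def scan_seed_sites(
    mirna_seq: str, utr_seq: str, allow_wobble: bool = False
) -> list[SeedSite]:
    """Enumerate and classify all canonical seed sites of a miRNA on a UTR.

    Both sequences are given 5'->3'; the duplex is antiparallel, so the
    miRNA's 5' seed pairs with the 3' portion of the site on the UTR.  For a
    seed match at UTR offset i..i+6 (matching miRNA positions 7..2 reading the
    UTR 5'->3'), the base opposite miRNA position 8 sits at i-1 and the base
    opposite position 1 at i+6.  Each seed-match locus is reported once with
    its strongest type (8mer > 7mer-m8 > 7mer-A1 > 6mer); reported intervals
    cover the full matched span, including the m8 and A1 positions when they
    contribute.
    """
    m = _check_rna(mirna_seq, "miRNA sequence")
    u = _check_rna(utr_seq, "UTR sequence")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt to classify seed sites")
    seed = m[1:7]  # positions 2-7, 0-based slice
    pos8 = m[7]
    sites: list[SeedSite] = []
    for i in range(len(u) - 5):
        window = u[i : i + 6]
        # antiparallel: UTR position i+k pairs with seed position 7-(k+1)
        if not all(_pairs_with(seed[5 - k], window[k], allow_wobble) for k in range(6)):
            continue
        m8 = i >= 1 and _pairs_with(pos8, u[i - 1], allow_wobble)
        a1 = i + 6 < len(u) and u[i + 6] == "A"
        if m8 and a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        sites.append(SeedSite(start=start, end=end, site_type=site_type))
    return sites
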