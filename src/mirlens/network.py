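"""Signed regulatory network derivation and cross-perturbation concordance.

Edge signs are expressed in the wild-type frame: what the regulator normally
does to its target.  A miRNA elevated in the knockout implies the deleted gene
normally represses that miRNA (repressive regulator->miRNA edge); a reduced
miRNA implies normal activation.  miRNA->mRNA edges are always repressive
(miRNAs silence their targets).  The knockout-side observation is derived from
the sign chain, never stored.

Concordance asks, for each network target mRNA, whether independent
gene-perturbation experiments misexpress it in the same direction as the
reference knockout; gain-of-function perturbations have their observed
direction inverted before comparison so that all datasets are read in the
loss-of-function frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .core import DifferentialRecord, normalize_id
from .pairing import MiRnaMrnaPair

__all__ = [
    "RegulatoryEdge",
    "PerturbationDataset",
    "TargetConcordance",
    "ConcordanceReport",
    "build_module",
    "concordance",
    "export_graph",
    "read_sif",
]

SIGN_RELATION = {"activating": "activates", "repressive": "represses"}
RELATION_SIGN = {v: k for k, v in SIGN_RELATION.items()}


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed source -> target relation attributable to one dataset."""

    source: str
    target: str
    sign: str
    provenance: str = "reference"

    def __post_init__(self) -> None:
        if self.sign not in SIGN_RELATION:
            raise ValueError(f"edge sign must be activating/repressive, got {self.sign!r}")


@dataclass(frozen=True)
class PerturbationDataset:
    """One external perturbation DE table with its perturbation polarity."""

    dataset_id: str
    kind: str  # loss | gain
    records: tuple[DifferentialRecord, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"perturbation kind must be loss/gain, got {self.kind!r}")


@dataclass
class TargetConcordance:
    target: str
    reference_direction: str
    misexpressed_in: list[str] = field(default_factory=list)
    same_direction: dict[str, bool] = field(default_factory=dict)

    @property
    def any_same_direction(self) -> bool:
        return any(self.same_direction.values())


@dataclass
class ConcordanceReport:
    """Per-target perturbation evidence plus the headline fractions.

    ``fraction_misexpressed`` = targets misexpressed in >= 1 dataset over all
    network targets covered by >= 1 table; ``fraction_same_direction`` =
    targets with >= 1 same-direction call over the misexpressed targets.
    """

    targets: list[TargetConcordance]
    n_network_targets: int

    @property
    def n_misexpressed(self) -> int:
        return sum(1 for t in self.targets if t.misexpressed_in)

    @property
    def fraction_misexpressed(self) -> float:
        return self.n_misexpressed / self.n_network_targets if self.n_network_targets else float("nan")

    @property
    def fraction_same_direction(self) -> float:
        n = self.n_misexpressed
        if n == 0:
            return float("nan")
        return sum(1 for t in self.targets if t.misexpressed_in and t.any_same_direction) / n


def build_module(
    mirna_de: Sequence[DifferentialRecord],
    pairs: Sequence[MiRnaMrnaPair],
    regulator: str = "Tdrd7",
    provenance: str = "reference",
) -> list[RegulatoryEdge]:
    """Derive the signed regulator -> miRNA -> mRNA module in the wild-type frame.

    Every differentially expressed miRNA gets a regulator edge: repressive if
    the miRNA is elevated in the knockout, activating if reduced.  Every pair
    contributes one repressive miRNA -> mRNA edge.  Edge count is therefore
    n(DE miRNAs) + n(pairs).
    """
    edges: list[RegulatoryEdge] = []
    for rec in mirna_de:
        if rec.direction == "up":
            edges.append(RegulatoryEdge(regulator, rec.feature_id, "repressive", provenance))
        elif rec.direction == "down":
            edges.append(RegulatoryEdge(regulator, rec.feature_id, "activating", provenance))
    for pair in pairs:
        edges.append(RegulatoryEdge(pair.mirna_id, pair.mrna_id, "repressive", provenance))
    return edges


def knockout_observation(chain_signs: Sequence[str]) -> str:
    """Predicted direction of the chain's terminal node when the root is deleted.

    Deleting the root removes its influence: the first edge's effect flips,
    then each repressive edge inverts the signal.  A repressive root->miRNA
    edge (miRNA elevated on deletion) followed by a repressive miRNA->mRNA
    edge predicts the mRNA reduced, matching the pairing table.
    """
    state = "down"  # the deleted regulator itself
    for sign in chain_signs:
        if sign == "repressive":
            state = "up" if state == "down" else "down"
    return state


def concordance(
    network_targets: Sequence[str],
    perturbation_tables: Sequence[PerturbationDataset],
    reference_directions: Mapping[str, str],
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Direction concordance of network targets across perturbation datasets.

    A target is misexpressed in a dataset when |FC| >= threshold and
    p <= alpha there.  The observed direction (inverted for gain-of-function
    datasets) is compared with the reference-knockout direction; the summary
    fraction counts targets with >= 1 same-direction dataset among the
    misexpressed ones, mirroring the "out of these misexpressed targets"
    conditioning.  Targets absent from every table are excluded from the
    denominator.
    """
    ref = {normalize_id(k): v for k, v in reference_directions.items()}
    indexed = [
        (ds, {normalize_id(r.feature_id): r for r in ds.records}) for ds in perturbation_tables
    ]
    covered: list[TargetConcordance] = []
    n_covered = 0
    for target in sorted(set(network_targets), key=normalize_id):
        key = normalize_id(target)
        if key not in ref:
            raise ValueError(f"network target {target!r} has no reference direction")
        seen_anywhere = False
        tc = TargetConcordance(target=target, reference_direction=ref[key])
        for ds, table in indexed:
            rec = table.get(key)
            if rec is None:
                continue
            seen_anywhere = True
            if rec.p is not None and rec.p <= alpha and abs(rec.fc) >= fc_threshold:
                observed = "up" if rec.fc > 0 else "down"
                if ds.kind == "gain":
                    observed = "down" if observed == "up" else "up"
                tc.misexpressed_in.append(ds.dataset_id)
                tc.same_direction[ds.dataset_id] = observed == ref[key]
        if seen_anywhere:
            n_covered += 1
            covered.append(tc)
    return ConcordanceReport(targets=covered, n_network_targets=n_covered)


def export_graph(edges: Sequence[RegulatoryEdge], path: str | Path, format: str = "sif") -> Path:
    """Write the network as SIF (``source\\trelation\\ttarget``) or GraphML."""
    path = Path(path)
    if format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.source}\t{SIGN_RELATION[e.sign]}\t{e.target}\n")
    elif format == "graphml":
        g = nx.MultiDiGraph()
        for e in edges:
            g.add_edge(e.source, e.target, sign=e.sign, provenance=e.provenance)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return path


def read_sif(path: str | Path, provenance: str = "reference") -> list[RegulatoryEdge]:
    """Parse a SIF file written by :func:`export_graph` (round-trip support)."""
    edges: list[RegulatoryEdge] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 or fields[1] not in RELATION_SIGN:
                raise ValueError(f"{path}:{lineno}: malformed SIF line")
            edges.append(
                RegulatoryEdge(fields[0], fields[2], RELATION_SIGN[fields[1]], provenance)
            )
    return edges
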