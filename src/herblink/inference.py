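"""Shared-neighborhood inference of TKM-protein links.

A TKM (herbal medicine) and a protein are never directly linked in the
schema; evidence for an association is the number of distinct intermediate
nodes adjacent to both.  Two intermediate channels are counted:

* diseases  — TKM-Disease edges meeting Disease-Protein edges,
* drugs     — TKM-Drug edges meeting Drug-Protein edges.

Drug-mediated evidence (curated compound-protein interactions) is more
reliable than disease co-annotation, so the combined score up-weights the
drug count by a factor of 2 by default.  The combined retention filter
keeps a pair only when it shares at least one node from each channel —
"at least two nodes from two different categories".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .netmodel import EdgeCategory, EntityClass, NodeRef, PharmNetwork

__all__ = [
    "MODES",
    "Mode",
    "SharedNeighborEvidence",
    "ScoringWeights",
    "InferredLink",
    "shared_evidence",
    "combined_score",
    "candidate_evidence",
    "infer_links",
    "connection_probability_curve",
    "write_inferred_links",
]

Mode = Literal["disease_only", "drug_only", "combined"]
MODES: tuple[Mode, ...] = ("disease_only", "drug_only", "combined")


@dataclass(frozen=True)
class SharedNeighborEvidence:
    """Per-pair evidence: counts of distinct shared diseases and shared drugs."""

    tkm: NodeRef
    protein: NodeRef
    shared_disease_count: int
    shared_drug_count: int

    def __post_init__(self) -> None:
        if self.tkm.entity_class is not EntityClass.TKM:
            raise TypeError(f"expected a TKM node, got {self.tkm}")
        if self.protein.entity_class is not EntityClass.PROTEIN:
            raise TypeError(f"expected a PROTEIN node, got {self.protein}")
        if self.shared_disease_count < 0 or self.shared_drug_count < 0:
            raise ValueError("shared-neighbor counts must be non-negative")

    @property
    def total(self) -> int:
        return self.shared_disease_count + self.shared_drug_count


@dataclass(frozen=True)
class ScoringWeights:
    """Channel weights for the combined score; the drug channel defaults to 2."""

    w_drug: float = 2.0
    w_disease: float = 1.0

    def __post_init__(self) -> None:
        if self.w_drug <= 0 or self.w_disease <= 0:
            raise ValueError(
                f"weights must be positive, got w_drug={self.w_drug}, "
                f"w_disease={self.w_disease}"
            )


@dataclass(frozen=True)
class InferredLink:
    """A scored candidate TKM-protein pair with the two-channel retention flag."""

    evidence: SharedNeighborEvidence
    score: float
    passes_filter: bool

    @property
    def pair(self) -> tuple[NodeRef, NodeRef]:
        return (self.evidence.tkm, self.evidence.protein)


def shared_evidence(net: PharmNetwork, tkm: NodeRef, protein: NodeRef) -> SharedNeighborEvidence:
    """Count distinct shared diseases and shared drugs for one pair.

    Nodes absent from the network contribute empty neighborhoods, hence
    zero counts.
    """
    if tkm.entity_class is not EntityClass.TKM:
        raise TypeError(f"expected a TKM node, got {tkm}")
    if protein.entity_class is not EntityClass.PROTEIN:
        raise TypeError(f"expected a PROTEIN node, got {protein}")
    shared_diseases = net.neighbors(tkm, EdgeCategory.TKM_DISEASE) & net.neighbors(
        protein, EdgeCategory.DISEASE_PROTEIN
    )
    shared_drugs = net.neighbors(tkm, EdgeCategory.TKM_DRUG) & net.neighbors(
        protein, EdgeCategory.DRUG_PROTEIN
    )
    return SharedNeighborEvidence(tkm, protein, len(shared_diseases), len(shared_drugs))


def combined_score(ev: SharedNeighborEvidence, w: ScoringWeights = ScoringWeights()) -> float:
    """Weighted combination ``w_drug * drugs + w_disease * diseases``."""
    return w.w_drug * ev.shared_drug_count + w.w_disease * ev.shared_disease_count


def candidate_evidence(net: PharmNetwork) -> dict[tuple[NodeRef, NodeRef], SharedNeighborEvidence]:
    """Evidence for every pair reachable through >= 1 disease or drug intermediate.

    Sparse traversal TKM -> intermediate -> protein; the dense TKM x protein
    cross-product is never materialized.
    """
    out: dict[tuple[NodeRef, NodeRef], SharedNeighborEvidence] = {}
    for tkm in net.nodes_of_class(EntityClass.TKM):
        disease_hits: dict[NodeRef, int] = {}
        drug_hits: dict[NodeRef, int] = {}
        for disease in net.neighbors(tkm, EdgeCategory.TKM_DISEASE):
            for protein in net.neighbors(disease, EdgeCategory.DISEASE_PROTEIN):
                disease_hits[protein] = disease_hits.get(protein, 0) + 1
        for drug in net.neighbors(tkm, EdgeCategory.TKM_DRUG):
            for protein in net.neighbors(drug, EdgeCategory.DRUG_PROTEIN):
                drug_hits[protein] = drug_hits.get(protein, 0) + 1
        for protein in disease_hits.keys() | drug_hits.keys():
            out[(tkm, protein)] = SharedNeighborEvidence(
                tkm,
                protein,
                disease_hits.get(protein, 0),
                drug_hits.get(protein, 0),
            )
    return out


def infer_links(
    net: PharmNetwork,
    mode: Mode = "combined",
    weights: Optional[ScoringWeights] = None,
    min_disease: int = 1,
    min_drug: int = 1,
) -> list[InferredLink]:
    """Enumerate and score candidate TKM-protein links in one of three modes.

    ``disease_only``  — pairs with >= ``min_disease`` shared diseases,
    scored by the disease count alone.
    ``drug_only``     — pairs with >= ``min_drug`` shared drugs, scored by
    the drug count alone.
    ``combined``      — pairs meeting both per-channel minima (the
    two-category retention filter), scored by the weighted combination.

    Output is sorted by (score desc, tkm id, protein id).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    w = weights if weights is not None else ScoringWeights()
    links: list[InferredLink] = []
    for (tkm, protein), ev in candidate_evidence(net).items():
        retained = (
            ev.shared_disease_count >= min_disease and ev.shared_drug_count >= min_drug
        )
        if mode == "disease_only":
            if ev.shared_disease_count < min_disease:
                continue
            score = float(ev.shared_disease_count)
        elif mode == "drug_only":
            if ev.shared_drug_count < min_drug:
                continue
            score = float(ev.shared_drug_count)
        else:
            if not retained:
                continue
            score = combined_score(ev, w)
        links.append(InferredLink(ev, score, retained))
    links.sort(key=lambda l: (-l.score, l.evidence.tkm, l.evidence.protein))
    return links


def _mode_count(ev: SharedNeighborEvidence, mode: Mode) -> int:
    if mode == "disease_only":
        return ev.shared_disease_count
    if mode == "drug_only":
        return ev.shared_drug_count
    return ev.total


def connection_probability_curve(
    net: PharmNetwork,
    known: set[tuple[NodeRef, NodeRef]],
    mode: Mode = "combined",
    n_zero_sample: int = 2000,
    seed: int = 0,
) -> list[tuple[int, float, int]]:
    """Estimate P(known link | shared count = k) for each observed count k.

    Candidate pairs (count >= 1 in the selected channel) are binned by their
    count; the k = 0 bin is estimated over a uniform random sample of
    non-candidate TKM x protein pairs (at most ``n_zero_sample``, seeded).
    Returns ``(k, fraction known, bin size)`` rows sorted by k; empty bins
    are omitted.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not known:
        raise ValueError("known-positives set is empty: probability is undefined")
    candidates = candidate_evidence(net)
    bins: dict[int, list[int]] = {}
    counted: set[tuple[NodeRef, NodeRef]] = set()
    for pair, ev in candidates.items():
        k = _mode_count(ev, mode)
        if k >= 1:
            bins.setdefault(k, []).append(1 if pair in known else 0)
            counted.add(pair)

    tkms = net.nodes_of_class(EntityClass.TKM)
    proteins = net.nodes_of_class(EntityClass.PROTEIN)
    n_total = len(tkms) * len(proteins)
    n_zero_pop = n_total - len(counted)
    if n_zero_pop > 0 and n_zero_sample > 0:
        rng = np.random.default_rng(seed)
        labels: list[int] = []
        seen: set[tuple[int, int]] = set()
        # rejection-sample distinct non-candidate pairs
        budget = min(n_zero_sample, n_zero_pop)
        attempts = 0
        while len(labels) < budget and attempts < 50 * n_zero_sample:
            attempts += 1
            i = int(rng.integers(len(tkms)))
            j = int(rng.integers(len(proteins)))
            if (i, j) in seen:
                continue
            pair = (tkms[i], proteins[j])
            if pair in counted:
                continue
            seen.add((i, j))
            labels.append(1 if pair in known else 0)
        if labels:
            bins[0] = labels

    return [
        (k, sum(v) / len(v), len(v)) for k, v in sorted(bins.items()) if v
    ]


INFERRED_COLUMNS = (
    "tkm_id",
    "protein_id",
    "shared_disease_count",
    "shared_drug_count",
    "score",
    "passes_filter",
)


def write_inferred_links(links: Sequence[InferredLink], path: Union[str, Path]) -> None:
    """Write the inferred-links TSV in the deterministic sort order of infer_links."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(INFERRED_COLUMNS)
        for link in links:
            ev = link.evidence
            writer.writerow(
                [
                    ev.tkm.identifier,
                    ev.protein.identifier,
                    ev.shared_disease_count,
                    ev.shared_drug_count,
                    f"{link.score:g}",
                    str(link.passes_filter).lower(),
                ]
            )
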