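"""Synthetic five-partite network generator with planted TKM-protein truth.

The generator emulates the regime of the curated database: a set of true
TKM-protein associations is planted, each witnessed through a shared-drug
channel with high probability (curated compound-protein interactions are
high-fidelity) and through a shared-disease channel with lower probability
(disease co-annotation is noisier), while per-TKM noise wirings create
spurious intermediates that never complete a planted pair.  Disease noise
is heavier than drug noise by default, so disease-mediated inference is
the weaker of the two channels — the setting in which the combined,
drug-weighted score is expected to dominate.

All identifiers are minted in the real namespaces (sequential integers for
synthetic PubChem CIDs and Entrez Gene IDs, D-numbers for MeSH-style
descriptors), so namespace validation is exercised end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluation import compare_modes
from .inference import MODES, Mode, ScoringWeights
from .netmodel import EdgeCategory, EdgeRecord, EntityClass, NodeRef, PharmNetwork

__all__ = ["GenConfig", "GroundTruth", "ConfigError", "generate", "evidence_sweep",
           "write_truth", "read_truth"]

Pair = tuple[NodeRef, NodeRef]

PROVENANCE = "synthetic"


class ConfigError(ValueError):
    """An infeasible or out-of-range generator configuration."""


@dataclass(frozen=True)
class GenConfig:
    """Generator parameters.

    ``links_per_tkm`` planted associations are drawn per TKM (distinct
    proteins).  ``p_drug_evidence`` / ``p_disease_evidence`` are the
    per-link probabilities that the corresponding evidence channel is wired;
    when a channel fires it wires ``1 + Poisson(*_witness_extra)`` distinct
    intermediates, so true links can accumulate counts above 1.
    ``drug_noise`` / ``disease_noise`` are the expected numbers of spurious
    intermediate wirings per TKM.  Background edge counts populate the four
    categories not involved in inference.  Identical config + seed yields an
    identical network.
    """

    n_tkm: int = 50
    n_drug: int = 400
    n_disease: int = 150
    n_protein: int = 600
    n_side_effect: int = 100
    links_per_tkm: int = 5
    p_drug_evidence: float = 0.9
    p_disease_evidence: float = 0.6
    drug_noise: float = 2.0
    disease_noise: float = 6.0
    drug_witness_extra: float = 1.0
    disease_witness_extra: float = 1.0
    n_drug_drug: int = 150
    n_protein_protein: int = 200
    n_drug_disease: int = 150
    n_drug_side_effect: int = 150
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_tkm", "n_drug", "n_disease", "n_protein", "n_side_effect",
                     "links_per_tkm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("p_drug_evidence", "p_disease_evidence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in ("drug_noise", "disease_noise", "drug_witness_extra",
                     "disease_witness_extra"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_drug_drug", "n_protein_protein", "n_drug_disease",
                     "n_drug_side_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.links_per_tkm > self.n_protein:
            raise ConfigError(
                f"links_per_tkm={self.links_per_tkm} exceeds the number of distinct "
                f"proteins ({self.n_protein})"
            )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GenConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruth:
    """Planted TKM-protein associations and which evidence channels were wired."""

    planted: frozenset[Pair]
    channels: dict[Pair, tuple[bool, bool]] = field(compare=False)  # (drug, disease)

    @property
    def witnessed(self) -> frozenset[Pair]:
        """Planted pairs with at least one wired channel (i.e. recoverable)."""
        return frozenset(p for p, (d, s) in self.channels.items() if d or s)


def _mint_nodes(cfg: GenConfig):
    tkms = [NodeRef(EntityClass.TKM, f"KTKP{i:05d}") for i in range(1, cfg.n_tkm + 1)]
    drugs = [NodeRef(EntityClass.DRUG, str(i)) for i in range(1, cfg.n_drug + 1)]
    diseases = [NodeRef(EntityClass.DISEASE, f"D{i:06d}") for i in range(1, cfg.n_disease + 1)]
    proteins = [NodeRef(EntityClass.PROTEIN, str(i)) for i in range(1, cfg.n_protein + 1)]
    side_effects = [
        NodeRef(EntityClass.SIDE_EFFECT, f"D{900000 + i:06d}")
        for i in range(1, cfg.n_side_effect + 1)
    ]
    return tkms, drugs, diseases, proteins, side_effects


def generate(cfg: GenConfig) -> tuple[PharmNetwork, GroundTruth]:
    """Generate a schema-valid network plus its planted ground truth.

    Deterministic for a given config (the seed is part of the config).
    """
    rng = np.random.default_rng(cfg.seed)
    tkms, drugs, diseases, proteins, side_effects = _mint_nodes(cfg)

    net = PharmNetwork()
    for node in (*tkms, *drugs, *diseases, *proteins, *side_effects):
        net.add_node(node)

    def wire(a: NodeRef, b: NodeRef, cat: EdgeCategory) -> None:
        net.add_edge(EdgeRecord(a, b, cat, frozenset({PROVENANCE})))

    # -- planted truth -----------------------------------------------------
    planted: list[Pair] = []
    planted_by_tkm: dict[NodeRef, set[NodeRef]] = {}
    for tkm in tkms:
        chosen = rng.choice(cfg.n_protein, size=cfg.links_per_tkm, replace=False)
        prots = {proteins[int(i)] for i in chosen}
        planted_by_tkm[tkm] = prots
        planted.extend((tkm, p) for p in sorted(prots))

    def pick_witnesses(pool: Sequence[NodeRef], extra: float) -> list[NodeRef]:
        n = 1 + int(rng.poisson(extra))
        n = min(n, len(pool))
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[int(i)] for i in idx]

    channels: dict[Pair, tuple[bool, bool]] = {}
    for tkm, protein in planted:
        drug_ev = bool(rng.random() < cfg.p_drug_evidence)
        disease_ev = bool(rng.random() < cfg.p_disease_evidence)
        if drug_ev:
            for drug in pick_witnesses(drugs, cfg.drug_witness_extra):
                wire(tkm, drug, EdgeCategory.TKM_DRUG)
                wire(drug, protein, EdgeCategory.DRUG_PROTEIN)
        if disease_ev:
            for disease in pick_witnesses(diseases, cfg.disease_witness_extra):
                wire(tkm, disease, EdgeCategory.TKM_DISEASE)
                wire(disease, protein, EdgeCategory.DISEASE_PROTEIN)
        channels[(tkm, protein)] = (drug_ev, disease_ev)

    # -- noise wirings: spurious intermediates that never complete a planted
    #    pair.  A candidate wiring t-x, x-p is rejected if x already touches,
    #    or would come to touch, both sides of any planted pair.
    def noise_ok(tkm: NodeRef, inter: NodeRef, protein: NodeRef,
                 tkm_cat: EdgeCategory, prot_cat: EdgeCategory) -> bool:
        if protein in planted_by_tkm[tkm]:
            return False
        # t-inter would complete (t, p') for proteins p' already on inter
        for p2 in net.neighbors(inter, prot_cat):
            if p2 in planted_by_tkm[tkm]:
                return False
        # inter-protein would complete (t', protein) for TKMs t' already on inter
        for t2 in net.neighbors(inter, tkm_cat):
            if t2 in planted_by_tkm and protein in planted_by_tkm[t2]:
                return False
        return True

    def wire_noise(tkm: NodeRef, pool: Sequence[NodeRef],
                   tkm_cat: EdgeCategory, prot_cat: EdgeCategory, lam: float) -> None:
        for _ in range(int(rng.poisson(lam))):
            for _attempt in range(100):
                inter = pool[int(rng.integers(len(pool)))]
                protein = proteins[int(rng.integers(len(proteins)))]
                if noise_ok(tkm, inter, protein, tkm_cat, prot_cat):
                    wire(tkm, inter, tkm_cat)
                    wire(inter, protein, prot_cat)
                    break

    for tkm in tkms:
        wire_noise(tkm, drugs, EdgeCategory.TKM_DRUG, EdgeCategory.DRUG_PROTEIN,
                   cfg.drug_noise)
        wire_noise(tkm, diseases, EdgeCategory.TKM_DISEASE,
                   EdgeCategory.DISEASE_PROTEIN, cfg.disease_noise)

    # -- background edges in the remaining categories ----------------------
    def background(pool_a: Sequence[NodeRef], pool_b: Sequence[NodeRef],
                   cat: EdgeCategory, n: int) -> None:
        for _ in range(n):
            a = pool_a[int(rng.integers(len(pool_a)))]
            b = pool_b[int(rng.integers(len(pool_b)))]
            if a != b:
                wire(a, b, cat)

    background(drugs, drugs, EdgeCategory.DRUG_DRUG, cfg.n_drug_drug)
    background(proteins, proteins, EdgeCategory.PROTEIN_PROTEIN, cfg.n_protein_protein)
    background(drugs, diseases, EdgeCategory.DRUG_DISEASE, cfg.n_drug_disease)
    background(drugs, side_effects, EdgeCategory.DRUG_SIDE_EFFECT, cfg.n_drug_side_effect)

    return net, GroundTruth(frozenset(planted), channels)


def evidence_sweep(
    base_cfg: GenConfig,
    param_name: str,
    values: Sequence,
    replicates: int = 10,
    weights: Optional[ScoringWeights] = None,
    modes: Sequence[Mode] = MODES,
) -> pd.DataFrame:
    """Mean +/- sd AUC per mode while sweeping one generator parameter.

    Replicate seeds are derived deterministically from the base config's
    seed; sd is the sample standard deviation (0 for a single replicate).
    Returns a DataFrame with columns value, mode, mean_auc, sd.
    """
    if param_name not in {f.name for f in dataclasses.fields(GenConfig)}:
        raise ConfigError(f"unknown GenConfig field {param_name!r}")
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    rows = []
    for vi, value in enumerate(values):
        aucs: dict[Mode, list[float]] = {m: [] for m in modes}
        for rep in range(replicates):
            seed = (base_cfg.seed + 100003 * (vi + 1) + rep) % (2**31)
            cfg = dataclasses.replace(base_cfg, **{param_name: value, "seed": seed})
            net, truth = generate(cfg)
            table = compare_modes(net, set(truth.planted), weights=weights, modes=modes)
            for _, r in table.iterrows():
                aucs[r["mode"]].append(float(r["auc"]))
        for mode in modes:
            vals = np.array(aucs[mode])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {"value": value, "mode": mode, "mean_auc": float(vals.mean()), "sd": sd}
            )
    return pd.DataFrame(rows, columns=["value", "mode", "mean_auc", "sd"])


TRUTH_COLUMNS = ("tkm_id", "protein_id", "drug_evidence", "disease_evidence")


def write_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    lines = ["\t".join(TRUTH_COLUMNS)]
    for (tkm, protein) in sorted(truth.planted):
        drug_ev, disease_ev = truth.channels[(tkm, protein)]
        lines.append(
            f"{tkm.identifier}\t{protein.identifier}\t{int(drug_ev)}\t{int(disease_ev)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_truth(path: Union[str, Path]) -> GroundTruth:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    idx = {name: header.index(name) for name in TRUTH_COLUMNS}
    planted: list[Pair] = []
    channels: dict[Pair, tuple[bool, bool]] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        pair = (
            NodeRef(EntityClass.TKM, cells[idx["tkm_id"]]),
            NodeRef(EntityClass.PROTEIN, cells[idx["protein_id"]]),
        )
        planted.append(pair)
        channels[pair] = (
            bool(int(cells[idx["drug_evidence"]])),
            bool(int(cells[idx["disease_evidence"]])),
        )
    return GroundTruth(frozenset(planted), channels)
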