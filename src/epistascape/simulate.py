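"""Seeded generators for every input the pipeline consumes.

Three generators with stored ground truth: competitive-assay product tables
over a full 2**n genotype landscape with configurable effects of any
interaction order; gapped alignments evolved on a known tree (with indels
as a separately evolved presence/absence character) so true ancestral
sequences are known; and noisy Michaelis–Menten saturation curves.

The default landscape preset mirrors the ancestral-methyltransferase study
design this package was built around: four candidate replacements
(Y267Q, I322M, M329L, Y361F), a wild type that strongly prefers benzoic
over salicylic acid (preference ratio 0.09, i.e. an ~11-fold preference for
benzoic acid), one dominant single-site effect at Y267Q, small positive
pairwise interactions of the other sites with Y267Q, and one positive
third-order interaction — summing so the quadruple mutant reaches a
2.8-fold salicylate preference where strict additivity would predict
1.9-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .asr import SubstitutionModel, _node_name, load_tree
from .genotype import Genotype, MutationSite, enumerate_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "SimulationTruth",
    "samt_preset",
    "simulate_assay",
    "simulate_alignment",
    "simulate_saturation",
]

MEBA_REFERENCE_SIGNAL = 100.0  # fixed methyl-benzoate signal, arbitrary units
SIGNAL_FLOOR = 1e-6


@dataclass(frozen=True)
class EffectSpec:
    """Planted landscape: baseline plus per-term effects on ``scale``.

    ``effects`` maps term subsets (tuples of site labels) to effects; a
    singleton tuple is a single-mutant effect, larger subsets are
    epistatic interactions.  Noise is additive Gaussian on ``scale``
    (ratio-scale signal draws are floored at a small positive value).
    """

    wt_baseline: float
    effects: Mapping[tuple[str, ...], float]
    noise_sd: float = 0.05
    replicates: int = 3
    seed: int = 0
    scale: str = "ratio"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scale not in ("ratio", "log_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def genotype_value(self, genotype: Genotype) -> float:
        """Noise-free value of a genotype on the declared scale."""
        active = set(genotype.mutated_sites)
        v = self.wt_baseline
        for term, effect in self.effects.items():
            if set(term) <= active:
                v += effect
        return v


@dataclass
class SimulationTruth:
    """Ground truth stored alongside every generated dataset."""

    seed: int
    genotype_values: dict[str, float] | None = None
    coefficients: dict[tuple[str, ...], float] | None = None
    ancestral_sequences: dict[str, str] | None = None
    presence: dict[str, str] | None = None
    kinetic_params: dict[str, float] | None = None


def samt_preset() -> tuple[list[MutationSite], EffectSpec]:
    """The default four-site ancestral-methyltransferase landscape."""
    sites = [
        MutationSite.from_label("Y267Q"),
        MutationSite.from_label("I322M"),
        MutationSite.from_label("M329L"),
        MutationSite.from_label("Y361F"),
    ]
    effects = {
        ("Y267Q",): 1.25,
        ("I322M",): 0.15,
        ("M329L",): 0.25,
        ("Y361F",): 0.16,
        ("Y267Q", "I322M"): 0.15,
        ("Y267Q", "M329L"): 0.30,
        ("Y267Q", "Y361F"): 0.15,
        ("Y267Q", "I322M", "M329L"): 0.30,
    }
    return sites, EffectSpec(wt_baseline=0.09, effects=effects)


def simulate_assay(
    spec: EffectSpec, sites: Sequence[MutationSite]
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a competitive-assay product table over all 2**n genotypes.

    The methyl-benzoate signal is fixed at 100 units per replicate; the
    methyl-salicylate signal is the genotype's preference ratio times 100
    plus Gaussian noise on the declared scale.  Same seed, same table.
    """
    labels = {l for term in spec.effects for l in term}
    known = {s.label for s in sites}
    if not labels <= known:
        raise ValueError(f"effects reference unknown sites: {sorted(labels - known)}")
    rng = np.random.default_rng(spec.seed)
    genotypes = enumerate_genotypes(sites)
    rows = []
    truth_values: dict[str, float] = {}
    for g in genotypes:
        value = spec.genotype_value(g)
        truth_values[g.name] = value
        for rep in range(1, spec.replicates + 1):
            if spec.scale == "ratio":
                ratio = value + rng.normal(0.0, spec.noise_sd)
                if ratio <= 0:
                    logger.info(
                        "genotype %s replicate %d: non-positive draw floored", g.name, rep
                    )
                    ratio = SIGNAL_FLOOR
            else:
                ratio = float(np.exp(value + rng.normal(0.0, spec.noise_sd)))
            rows.append(
                {
                    "genotype": g.name,
                    "replicate": f"r{rep}",
                    "signal_mesa": ratio * MEBA_REFERENCE_SIGNAL,
                    "signal_meba": MEBA_REFERENCE_SIGNAL,
                }
            )
    truth = SimulationTruth(
        seed=spec.seed,
        genotype_values=truth_values,
        coefficients=dict(spec.effects),
    )
    return pd.DataFrame(rows), truth


def simulate_alignment(
    tree,
    model: SubstitutionModel,
    n_sites: int,
    indel_rate: float = 0.0,
    seed: int = 0,
    binary_model: SubstitutionModel | None = None,
) -> tuple[dict[str, str], SimulationTruth]:
    """Evolve an alignment on a known tree; true ancestors are stored.

    Residues evolve site-independently under ``model``.  Indels are a
    binary presence character evolved under ``binary_model`` (default: the
    symmetric two-state model) with branch lengths multiplied by
    ``indel_rate``; the root is fully present, and absence masks the
    residue with a gap.  Returns leaf sequences and a truth object whose
    ``ancestral_sequences`` cover every labelled internal node (gapped the
    same way).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if indel_rate < 0:
        raise ValueError("indel_rate must be non-negative")
    t = load_tree(tree)
    rng = np.random.default_rng(seed)
    k = model.n_states
    bmodel = binary_model or SubstitutionModel.binary()

    states: dict[int, np.ndarray] = {}
    presence: dict[int, np.ndarray] = {}
    root = t.seed_node
    states[id(root)] = rng.choice(k, size=n_sites, p=model.freqs)
    presence[id(root)] = np.ones(n_sites, dtype=np.int64)
    for node in t.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        P = model.transition_matrix(bl)
        parent = states[id(node.parent_node)]
        u = rng.random(n_sites)
        cum = np.cumsum(P[parent], axis=1)
        states[id(node)] = (u[:, None] > cum).sum(axis=1)
        if indel_rate > 0:
            Pb = bmodel.transition_matrix(bl * indel_rate)
            pparent = presence[id(node.parent_node)]
            ub = rng.random(n_sites)
            cumb = np.cumsum(Pb[pparent], axis=1)
            presence[id(node)] = (ub[:, None] > cumb).sum(axis=1)
        else:
            presence[id(node)] = presence[id(node.parent_node)]

    def render(node) -> str:
        s = states[id(node)]
        p = presence[id(node)]
        return "".join(
            model.alphabet[si] if pi else "-" for si, pi in zip(s, p)
        )

    leaves: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    pres_str: dict[str, str] = {}
    for node in t.preorder_node_iter():
        name = _node_name(node)
        if name is None:
            continue
        if node.is_leaf():
            leaves[name] = render(node)
        else:
            ancestors[name] = render(node)
        pres_str[name] = "".join(str(int(x)) for x in presence[id(node)])
    truth = SimulationTruth(
        seed=seed, ancestral_sequences=ancestors, presence=pres_str
    )
    return leaves, truth


def simulate_saturation(
    km: float,
    kcat: float,
    enzyme_conc: float,
    s_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Noisy Michaelis–Menten points: v = kcat*[E]*S/(K_M+S) + N(0, sd)."""
    if min(km, kcat, enzyme_conc) <= 0:
        raise ValueError("km, kcat and enzyme_conc must be positive")
    rng = np.random.default_rng(seed)
    S = np.asarray(s_grid, dtype=float)
    vmax = kcat * enzyme_conc
    v = vmax * S / (km + S)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=S.shape)
    v = np.clip(v, 0.0, None)
    df = pd.DataFrame({"S_uM": S, "v": v})
    truth = SimulationTruth(
        seed=seed,
        kinetic_params={"km": km, "kcat": kcat, "enzyme_conc": enzyme_conc},
    )
    return df, truth
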