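"""End-to-end orchestration: simulate → preference → epistasis → paths,
with optional kinetics, conservation and ancestral-reconstruction stages.

Every output JSON echoes the full configuration (scale, coding, alpha,
epsilon, thresholds, seed) so a result can always be traced back to the
choices that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import (
    fit_michaelis_menten,
    preference_estimates,
    read_measurements,
    read_saturation,
    specificity_fold,
)
from .conservation import conservation_counts, correlate, fitch_changes, read_site_records
from .epistasis import stepwise_select
from .genotype import (
    AccessibilityConfig,
    Genotype,
    MutationSite,
    accessible_paths,
    additive_expectation,
    enumerate_genotypes,
)
from .simulate import samt_preset, simulate_assay

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "epistascape_out"
    seed: int = 0
    alpha: float = 0.05
    epsilon: float = 0.0
    scale: str = "ratio"
    presence_threshold: float = 0.5
    measurements: str | None = None  # CSV; None → synthetic preset
    sites: str | None = None  # CSV of mutation sites; None → preset sites
    kinetics: str | None = None  # CSV of saturation curves (substrate, S_uM, v)
    enzyme_conc: float | None = None
    alignment: str | None = None
    tree: str | None = None
    asr_nodes: list[str] = field(default_factory=list)
    distances: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.scale not in ("ratio", "log_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not 0 <= self.presence_threshold <= 1:
            raise ValueError("presence_threshold must be in [0, 1]")
        for name in ("measurements", "sites", "kinetics", "alignment", "tree", "distances"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def read_sites(path) -> list[MutationSite]:
    df = pd.read_csv(path)
    required = {"label", "ancestral_residue", "position", "derived_residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns: {sorted(missing)}")
    return [
        MutationSite(r.label, r.ancestral_residue, int(r.position), r.derived_residue)
        for r in df.itertuples(index=False)
    ]


def _landscape_stage(config: RunConfig, out: Path) -> dict:
    """Preference estimation, epistasis regression and path accessibility."""
    if config.sites:
        sites = read_sites(config.sites)
        if config.measurements is None:
            raise ValueError("measurements CSV required when sites are supplied")
    else:
        sites, spec = samt_preset()
    if config.measurements:
        df = read_measurements(config.measurements)
        truth = None
    else:
        df, truth = simulate_assay(replace(spec, seed=config.seed), sites)
        df.to_csv(out / "simulated_assay.csv", index=False)

    prefs = preference_estimates(df)
    pref_map = {p.genotype: p.mean_ratio for p in prefs}
    site_order = [s.label for s in sites]
    genotypes = enumerate_genotypes(sites)
    wt = genotypes[0].name
    scale_value = (lambda v: float(np.log(v))) if config.scale == "log_ratio" else float
    values = {g: scale_value(v) for g, v in pref_map.items()}

    single_effects = {}
    for s, i in zip(site_order, range(len(site_order))):
        g = "".join("1" if j == i else "0" for j in range(len(site_order)))
        if g in values:
            single_effects[s] = values[g] - values[wt]
    quadruple = "1" * len(site_order)
    additive = additive_expectation(
        values[wt], single_effects, Genotype.from_string(quadruple, site_order), config.scale
    )

    obs_genotypes, response = [], []
    for _, row in df.iterrows():
        ratio = row.signal_mesa / row.signal_meba
        obs_genotypes.append(Genotype.from_string(str(row.genotype), site_order))
        response.append(np.log(ratio) if config.scale == "log_ratio" else ratio)
    fit, trace = stepwise_select(obs_genotypes, response, alpha=config.alpha)

    cfg = AccessibilityConfig(epsilon=config.epsilon, scale=config.scale)
    classified = accessible_paths({g: pref_map[g] for g in pref_map}, sites, cfg)

    return {
        "preferences": [asdict(p) for p in prefs],
        "wild_type_value": values[wt],
        "single_effects": single_effects,
        "additive_expectation_full_mutant": additive,
        "observed_full_mutant": values[quadruple],
        "selected_order": trace.selected_order,
        "selection_trace": [
            {
                "order_simple": s,
                "order_complex": c,
                "F": f.F,
                "df": [f.df_num, f.df_den],
                "p": f.p,
                "decision": d,
            }
            for s, c, f, d in trace.steps
        ],
        "coefficients": {"+".join(t) or "(intercept)": b for t, b in fit.coefficients.items()},
        "r2_per_term": {"+".join(t): r for t, r in fit.r2_per_term.items()},
        "r2_total": fit.r2_total,
        "paths": [
            {"steps": list(p.steps), "accessible": ok} for p, ok in classified
        ],
        "n_accessible_paths": sum(ok for _, ok in classified),
        "truth": None if truth is None else asdict_truth(truth),
    }


def asdict_truth(truth) -> dict:
    d = asdict(truth)
    if d.get("coefficients"):
        d["coefficients"] = {"+".join(k): v for k, v in d["coefficients"].items()}
    return d


def _kinetics_stage(config: RunConfig) -> dict:
    df = read_saturation(config.kinetics)
    if config.enzyme_conc is None:
        raise ValueError("enzyme_conc is required for the kinetics stage")
    fits = {}
    groups = df.groupby("substrate") if "substrate" in df.columns else [("", df)]
    for substrate, sub in groups:
        fit = fit_michaelis_menten(sub, config.enzyme_conc, substrate=str(substrate))
        fits[str(substrate)] = {
            "km_uM": fit.km,
            "km_se": fit.km_se,
            "kcat_per_s": fit.kcat,
            "kcat_se": fit.kcat_se,
            "specificity_per_s_per_M": fit.specificity,
        }
    result = {"fits": fits}
    if len(fits) == 2:
        (a, fa), (b, fb) = fits.items()
        result["specificity_fold"] = {
            f"{a}_over_{b}": fa["specificity_per_s_per_M"] / fb["specificity_per_s_per_M"]
        }
    return result


def _conservation_stage(config: RunConfig) -> dict:
    records = read_site_records(config.distances)
    out: dict = {"n_sites": len(records)}
    for x in ("distance_closest", "distance_ca"):
        for y in ("conservation_fraction", "parsimony_changes"):
            try:
                c = correlate(records, x=x, y=y)
            except (ValueError, TypeError):
                continue
            out[f"corr_{x}_vs_{y}"] = {"r": c.r, "p": c.p, "n": c.n}
    # metadata note: parsimony change counts exclude the branch into the
    # ancestor itself; only descendant-clade changes are counted
    out["parsimony_counts_include_ancestral_branch"] = False
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a JSON summary bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    manifest = {"complete": False, "stages_run": []}
    try:
        summary["stages"]["landscape"] = _landscape_stage(config, out)
        manifest["stages_run"].append("landscape")
        if config.kinetics:
            summary["stages"]["kinetics"] = _kinetics_stage(config)
            manifest["stages_run"].append("kinetics")
        if config.distances:
            summary["stages"]["conservation"] = _conservation_stage(config)
            manifest["stages_run"].append("conservation")
        if config.tree and config.alignment and config.asr_nodes:
            from .asr import SubstitutionModel, estimate_ancestral_sequence

            model = SubstitutionModel.equal_rates()
            recon = {}
            for node in config.asr_nodes:
                est = estimate_ancestral_sequence(
                    config.tree,
                    config.alignment,
                    model,
                    node,
                    presence_threshold=config.presence_threshold,
                )
                recon[node] = {
                    "sequence": est.sequence,
                    "mean_map_posterior": float(np.mean(est.map_posteriors)),
                }
            summary["stages"]["asr"] = recon
            manifest["stages_run"].append("asr")
        manifest["complete"] = True
    finally:
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
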