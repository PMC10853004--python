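"""Competitive-assay preference estimates and Michaelis–Menten kinetics.

Two routes to substrate preference are supported side by side:

* the competitive assay: both substrates at equimolar concentration in one
  reaction, preference measured as the ratio of methyl salicylate to methyl
  benzoate product signal (a direct proxy for the ratio of specificity
  constants);
* saturation kinetics: v = Vmax*S/(K_M+S) fitted per substrate, preference
  as the ratio of specificity constants k_cat/K_M.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "ProductMeasurement",
    "PreferenceEstimate",
    "SaturationPoint",
    "KineticsFit",
    "preference_estimates",
    "fit_michaelis_menten",
    "specificity_fold",
    "read_measurements",
    "read_saturation",
]


@dataclass(frozen=True)
class ProductMeasurement:
    """One replicate's integrated product signals for one genotype."""

    genotype: str
    replicate: str
    signal_mesa: float  # methyl salicylate
    signal_meba: float  # methyl benzoate

    def __post_init__(self) -> None:
        if self.signal_mesa < 0 or self.signal_meba < 0:
            raise ValueError(
                f"genotype {self.genotype} replicate {self.replicate}: "
                "signals must be non-negative"
            )


@dataclass(frozen=True)
class PreferenceEstimate:
    """Mean salicylate:benzoate product ratio across replicates."""

    genotype: str
    mean_ratio: float
    sd: float
    n: int


@dataclass(frozen=True)
class SaturationPoint:
    S: float  # substrate concentration, uM
    v: float  # velocity, product per second

    def __post_init__(self) -> None:
        if self.S < 0 or self.v < 0:
            raise ValueError("substrate concentration and velocity must be >= 0")


@dataclass(frozen=True)
class KineticsFit:
    """Apparent Michaelis–Menten parameter estimates for one enzyme/substrate.

    ``specificity`` is k_cat/K_M in s^-1 M^-1 (K_M converted from uM to M),
    always computed from the unrounded internal estimates.
    """

    km: float  # uM
    km_se: float
    kcat: float  # 1/s
    kcat_se: float
    enzyme_conc: float  # uM
    substrate: str = ""

    @property
    def vmax(self) -> float:
        return self.kcat * self.enzyme_conc

    @property
    def specificity(self) -> float:
        return self.kcat / (self.km * 1e-6)


class KineticsFitError(RuntimeError):
    """Raised when the saturation-curve fit fails; carries diagnostics."""

    def __init__(self, message: str, params=None, residuals=None):
        super().__init__(message)
        self.params = params
        self.residuals = residuals


def preference_estimates(
    measurements: Iterable[ProductMeasurement] | pd.DataFrame,
) -> list[PreferenceEstimate]:
    """Per-genotype mean and sd of per-replicate product ratios.

    The ratio is computed replicate by replicate and then averaged
    (mean-of-ratios), matching the per-assay replicate structure.
    Replicates with a zero methyl-benzoate signal have an undefined ratio
    and are excluded with a warning; a genotype whose replicates are all
    excluded is an error.  Genotypes are reported in canonical
    (lexicographic bit-string) order.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
        measurements = [
            ProductMeasurement(
                str(r.genotype), str(r.replicate), float(r.signal_mesa), float(r.signal_meba)
            )
            for r in df.itertuples(index=False)
        ]
    else:
        measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements supplied")
    seen: set[tuple[str, str]] = set()
    ratios: dict[str, list[float]] = {}
    for m in measurements:
        key = (m.genotype, m.replicate)
        if key in seen:
            raise ValueError(f"duplicate measurement for genotype/replicate {key}")
        seen.add(key)
        ratios.setdefault(m.genotype, [])
        if m.signal_meba == 0:
            logger.warning(
                "genotype %s replicate %s: zero methyl-benzoate signal, "
                "ratio undefined; replicate excluded",
                m.genotype,
                m.replicate,
            )
            continue
        ratios[m.genotype].append(m.signal_mesa / m.signal_meba)
    out = []
    for genotype in sorted(ratios):
        r = ratios[genotype]
        if not r:
            raise ValueError(
                f"genotype {genotype}: all replicates excluded, no usable ratio"
            )
        arr = np.asarray(r, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(PreferenceEstimate(genotype, float(arr.mean()), sd, arr.size))
    return out


def _michaelis_menten(S: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * S / (km + S)


def fit_michaelis_menten(
    points: Sequence[SaturationPoint] | pd.DataFrame,
    enzyme_conc: float,
    substrate: str = "",
) -> KineticsFit:
    """Nonlinear least-squares fit of v = Vmax*S/(K_M+S).

    k_cat = Vmax / [E]; standard errors come from the local curvature
    (covariance of the least-squares estimate); initial values are
    Vmax0 = max(v) and K_M0 = S at half of Vmax0 (interpolated), both
    bounded positive.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    if isinstance(points, pd.DataFrame):
        S = points["S_uM"].to_numpy(dtype=float)
        v = points["v"].to_numpy(dtype=float)
    else:
        S = np.array([p.S for p in points], dtype=float)
        v = np.array([p.v for p in points], dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")

    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all velocities are zero; nothing to fit")
    order = np.argsort(S)
    km0 = float(np.interp(vmax0 / 2.0, v[order], S[order]))
    km0 = max(km0, float(S[S > 0].min()) * 1e-2)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _michaelis_menten,
                S,
                v,
                p0=(vmax0, km0),
                bounds=((0.0, 0.0), (np.inf, np.inf)),
                maxfev=10000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
    except RuntimeError as exc:
        raise KineticsFitError(f"saturation fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise KineticsFitError(
            "non-positive parameter estimate",
            params=popt,
            residuals=v - _michaelis_menten(S, *popt),
        )
    se = np.sqrt(np.diag(pcov))
    return KineticsFit(
        km=float(km),
        km_se=float(se[1]),
        kcat=float(vmax / enzyme_conc),
        kcat_se=float(se[0] / enzyme_conc),
        enzyme_conc=float(enzyme_conc),
        substrate=substrate,
    )


def specificity_fold(fit_a: KineticsFit, fit_b: KineticsFit) -> float:
    """Fold preference of substrate a over substrate b: (k_cat/K_M)_a / (k_cat/K_M)_b."""
    if fit_b.specificity == 0:
        raise ZeroDivisionError("denominator specificity constant is zero")
    return fit_a.specificity / fit_b.specificity


def cpm_to_velocity(
    cpm: float, specific_activity: float, reaction_time_s: float
) -> float:
    """Convert scintillation counts per minute to a velocity.

    ``specific_activity`` is the user's calibration in cpm per unit of
    product (e.g. cpm/nmol); the velocity comes back in that product unit
    per second.  No radiochemistry constants are assumed.
    """
    if specific_activity <= 0 or reaction_time_s <= 0:
        raise ValueError("specific activity and reaction time must be positive")
    return cpm / specific_activity / reaction_time_s


def read_measurements(path) -> pd.DataFrame:
    """Read a competitive-assay CSV: genotype, replicate, signal_mesa, signal_meba."""
    df = pd.read_csv(path, dtype={"genotype": str, "replicate": str})
    required = {"genotype", "replicate", "signal_mesa", "signal_meba"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df


def read_saturation(path) -> pd.DataFrame:
    """Read a saturation-kinetics CSV: substrate, S_uM, v."""
    df = pd.read_csv(path)
    missing = {"S_uM", "v"} - set(df.columns)
    if missing:
        raise ValueError(f"kinetics CSV missing columns: {sorted(missing)}")
    return df
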