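"""Stepwise linear-regression analysis of epistasis on a 2**n landscape.

The response (a per-genotype substrate-preference measurement, replicate
level or genotype mean) is regressed on mutation indicators and their
products.  Terms are reference (0/1) coded, so each coefficient reads as an
effect relative to the all-ancestral background.  Model complexity grows by
interaction order; nested models are compared by F-tests, and selection
stops at the first order whose addition is not significant.  The variance
attributable to each term is its sequential sum of squares (terms entered
by order, then lexicographically) divided by the total sum of squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genotype import Genotype

__all__ = [
    "DesignMatrix",
    "EpistasisFit",
    "FTestResult",
    "ModelSelectionTrace",
    "build_design_matrix",
    "fit_order",
    "nested_f_test",
    "stepwise_select",
]

Term = tuple[str, ...]  # sorted tuple of site labels; () is the intercept


@dataclass(frozen=True)
class DesignMatrix:
    """0/1-coded design over interaction terms.

    Rows follow the genotype list given to :func:`build_design_matrix`
    (one per observation; pass repeated genotypes for replicate-level
    data).  Column ``T`` is the elementwise product of the single-site
    indicator columns in ``T``; the empty term is the intercept.
    """

    matrix: np.ndarray
    terms: tuple[Term, ...]
    genotype_names: tuple[str, ...]
    max_order: int

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]

    def is_full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.matrix) == self.n_terms


@dataclass(frozen=True)
class EpistasisFit:
    max_order: int
    coefficients: dict[Term, float]
    rss: float
    df_resid: int
    r2_total: float
    r2_per_term: dict[Term, float]
    n_obs: int
    terms: tuple[Term, ...]
    coefficient_se: dict[Term, float] = field(default_factory=dict)
    sst: float = 0.0  # total (mean-centred) sum of squares of the response

    def predict(self, design: DesignMatrix) -> np.ndarray:
        beta = np.array([self.coefficients[t] for t in design.terms])
        return design.matrix @ beta


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p: float
    alpha: float

    @property
    def reject_simple(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class ModelSelectionTrace:
    steps: tuple[tuple[int, int, FTestResult, str], ...]
    selected_order: int


def _canonical_terms(site_order: Sequence[str], max_order: int) -> tuple[Term, ...]:
    terms: list[Term] = [()]
    for k in range(1, max_order + 1):
        terms.extend(itertools.combinations(site_order, k))
    return tuple(terms)


def build_design_matrix(
    genotypes: Sequence[Genotype], max_order: int, coding: str = "reference"
) -> DesignMatrix:
    """Design with intercept plus all site subsets of size <= ``max_order``.

    Column order is canonical: by subset size, then lexicographic in the
    site order.  ``coding`` selects reference (0/1; effects relative to
    the all-ancestral background, the default) or ``"plusminus"`` (±1;
    orthogonal Walsh-style contrasts on a complete landscape).
    """
    if not genotypes:
        raise ValueError("no genotypes supplied")
    site_order = genotypes[0].site_order
    n_sites = len(site_order)
    if not 1 <= max_order <= n_sites:
        raise ValueError(
            f"max_order must be between 1 and the number of sites ({n_sites}); "
            f"got {max_order}"
        )
    if any(g.site_order != site_order for g in genotypes):
        raise ValueError("all genotypes must share one site order")
    if coding not in ("reference", "plusminus"):
        raise ValueError(f"unknown coding {coding!r}")
    idx = {label: i for i, label in enumerate(site_order)}
    terms = _canonical_terms(site_order, max_order)
    bits = np.array([g.bits for g in genotypes], dtype=float)
    if coding == "plusminus":
        bits = 2.0 * bits - 1.0
    cols = [
        np.ones(len(genotypes))
        if not t
        else np.prod(bits[:, [idx[s] for s in t]], axis=1)
        for t in terms
    ]
    return DesignMatrix(
        matrix=np.column_stack(cols),
        terms=terms,
        genotype_names=tuple(g.name for g in genotypes),
        max_order=max_order,
    )


def _sequential_ss(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sequential (type-I) sum of squares per column, in column order."""
    Q, R = np.linalg.qr(X)
    proj = Q.T @ y
    return proj**2


def fit_order(design: DesignMatrix, response: Sequence[float]) -> EpistasisFit:
    """Ordinary least squares of the response on the design.

    ``r2_per_term`` is each non-intercept term's sequential sum of squares
    divided by the total (mean-centred) sum of squares, with terms entered
    in the canonical column order.
    """
    y = np.asarray(response, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"response length {y.shape[0]} does not match design rows {X.shape[0]}"
        )
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer observations than model terms")
    if not design.is_full_rank():
        # name the offending columns via near-zero diagonal of R
        R = np.linalg.qr(X, mode="r")
        bad = [
            design.terms[j]
            for j in range(X.shape[1])
            if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))
        ]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")

    with warnings.catch_warnings():
        # a saturated fit has zero residual df; its (undefined) SEs are fine
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y, X).fit()
        rss = float(model.ssr)
        params = np.asarray(model.params, dtype=float)
        bse = np.asarray(model.bse, dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    r2_total = 1.0 - rss / sst if sst > 0 else 0.0

    seq = _sequential_ss(X, y)
    r2_per_term = {
        t: (float(seq[j]) / sst if sst > 0 else 0.0)
        for j, t in enumerate(design.terms)
        if t  # the intercept carries the mean, not explained variance
    }
    return EpistasisFit(
        max_order=design.max_order,
        coefficients={t: float(b) for t, b in zip(design.terms, params)},
        rss=rss,
        df_resid=int(model.df_resid),
        r2_total=r2_total,
        r2_per_term=r2_per_term,
        n_obs=int(X.shape[0]),
        terms=design.terms,
        coefficient_se={t: float(s) for t, s in zip(design.terms, bse)},
        sst=sst,
    )


def nested_f_test(
    fit_simple: EpistasisFit, fit_complex: EpistasisFit, alpha: float = 0.05
) -> FTestResult:
    """F-test of a simpler model nested within a more complex one."""
    if not set(fit_simple.terms) < set(fit_complex.terms):
        raise ValueError("models are not nested (simple terms not a strict subset)")
    if fit_simple.n_obs != fit_complex.n_obs:
        raise ValueError("fits use different numbers of observations")
    n = fit_complex.n_obs
    p0, p1 = len(fit_simple.terms), len(fit_complex.terms)
    df_num, df_den = p1 - p0, n - p1
    if df_den < 1:
        raise ValueError("complex model leaves no residual degrees of freedom")
    rss0, rss1 = fit_simple.rss, fit_complex.rss
    # residual sums below numerical precision of the response are zero
    zero_tol = 1e-12 * max(fit_complex.sst, fit_simple.sst)
    if rss0 <= zero_tol:
        rss0 = 0.0
    if rss1 <= zero_tol:
        rss1 = 0.0
    if rss1 == 0.0:
        if rss0 == 0.0:
            return FTestResult(0.0, df_num, df_den, 1.0, alpha)
        return FTestResult(float("inf"), df_num, df_den, 0.0, alpha)
    F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    F = max(F, 0.0)
    return FTestResult(float(F), df_num, df_den, float(stats.f.sf(F, df_num, df_den)), alpha)


def stepwise_select(
    genotypes: Sequence[Genotype],
    response: Sequence[float],
    alpha: float = 0.05,
) -> tuple[EpistasisFit, ModelSelectionTrace]:
    """Forward stepwise selection over interaction orders.

    Starts at the purely additive (first-order) model and keeps adding the
    next full order of interaction terms while the F-test rejects the
    simpler model at ``alpha``.  ``genotypes``/``response`` are aligned
    observation-level data; replicate-level observations provide residual
    degrees of freedom even for the saturated mean structure, whereas a
    single observation per genotype exhausts them at the saturated order
    (the trace then stops with a warning).
    """
    if not genotypes:
        raise ValueError("no genotypes supplied")
    n_sites = len(genotypes[0].site_order)
    y = np.asarray(response, dtype=float)
    fits = {1: fit_order(build_design_matrix(genotypes, 1), y)}
    steps: list[tuple[int, int, FTestResult, str]] = []
    current = 1
    while current < n_sites:
        nxt = current + 1
        design = build_design_matrix(genotypes, nxt)
        if design.n_obs - design.n_terms < 1:
            warnings.warn(
                f"order {nxt} leaves no residual degrees of freedom on "
                f"{design.n_obs} observations; stopping at order {current}",
                stacklevel=2,
            )
            break
        fits[nxt] = fit_order(design, y)
        ftest = nested_f_test(fits[current], fits[nxt], alpha)
        decision = "reject simpler" if ftest.reject_simple else "retain simpler"
        steps.append((current, nxt, ftest, decision))
        if not ftest.reject_simple:
            break
        current = nxt
    return fits[current], ModelSelectionTrace(tuple(steps), current)
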