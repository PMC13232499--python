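"""Additive and epistatic genomic relationship matrices and the
extended-GBLUP variance-component fit.

The additive genomic relationship matrix is GA = W W' / n with W the
column-mean-centered dosage matrix and n the number of individuals; the
additive-by-additive epistatic matrix is the Hadamard square of GA
normalized to trace n:

    GAA = (GA o GA) / (tr(GA o GA) / n).

The extended-GBLUP mixed model

    y = X beta + g_A + g_E + eps,
    g_A ~ N(0, GA sigma2_A), g_E ~ N(0, GAA sigma2_E), eps ~ N(0, I sigma2_e)

is fitted by REML: the restricted log-likelihood is maximized over the
log-variances with a bounded quasi-Newton method, which keeps every
component nonnegative (effective floor 1e-8). Each component is reported
both in squared trait units and as a proportion of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "compute_GA",
    "compute_GAA",
    "restricted_loglik",
    "fit_extended_gblup",
    "variance_summary",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix with its sample order."""

    values: np.ndarray
    kind: str  # "GA" or "GAA"
    sample_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceComponents:
    """REML variance components of the extended-GBLUP fit."""

    sigma2_additive: float
    sigma2_epistatic: float
    sigma2_residual: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int = 0
    population_id: str = ""
    environment: str = "combined"
    trait: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.sigma2_additive + self.sigma2_epistatic + self.sigma2_residual

    @property
    def proportions(self) -> dict:
        t = self.total
        return {
            "additive": self.sigma2_additive / t,
            "epistatic": self.sigma2_epistatic / t,
            "residual": self.sigma2_residual / t,
        }


def compute_GA(panel_or_dosage) -> KinshipMatrix:
    """Additive genomic relationship matrix GA = W W' / n.

    W is the column-mean-centered dosage matrix; n is the number of
    individuals (rows). Accepts a :class:`~ensgp.simulate.GenotypePanel` or
    a raw (n, p) dosage array.
    """
    if hasattr(panel_or_dosage, "genotypes"):
        dosage = panel_or_dosage.genotypes
        ids = list(panel_or_dosage.ril_ids)
    else:
        dosage = np.asarray(panel_or_dosage, dtype=float)
        ids = [f"s{i}" for i in range(dosage.shape[0])]
    if np.isnan(dosage).any():
        raise ValueError("GA requires an imputed panel (no missing genotypes)")
    n = dosage.shape[0]
    if n < 2:
        raise ValueError("GA needs at least 2 individuals")
    W = dosage - dosage.mean(axis=0, keepdims=True)
    GA = W @ W.T / n
    return KinshipMatrix(GA, "GA", ids)


def compute_GAA(GA: KinshipMatrix) -> KinshipMatrix:
    """Epistatic relationship matrix: Hadamard square of GA, trace-n
    normalized so that tr(GAA) = n exactly."""
    H = GA.values * GA.values
    tr = np.trace(H)
    if tr == 0:
        raise ValueError("tr(GA o GA) = 0: no additive variation to square")
    GAA = H / (tr / GA.n)
    return KinshipMatrix(GAA, "GAA", list(GA.sample_ids))


def restricted_loglik(
    sigma2: tuple[float, float, float],
    y: np.ndarray,
    X: np.ndarray,
    GA: np.ndarray,
    GAA: np.ndarray,
) -> float:
    """Restricted log-likelihood of the three-component Gaussian model at
    the given (sigma2_A, sigma2_E, sigma2_e). Used both by the fitter and by
    brute-force grid oracles."""
    sA, sE, se = sigma2
    n, p = X.shape
    V = sA * GA + sE * GAA + se * np.eye(n)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv_X = cho_solve(cf, X)
    Vinv_y = cho_solve(cf, y)
    XtVinvX = X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    resid = y - X @ beta
    quad = resid @ cho_solve(cf, resid)
    return -0.5 * (logdetV + logdetXVX + quad)


def fit_extended_gblup(
    y: np.ndarray,
    X: np.ndarray,
    GA: KinshipMatrix,
    GAA: KinshipMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    **labels,
) -> VarianceComponents:
    """REML fit of the extended-GBLUP model.

    Maximizes the restricted log-likelihood over log-variances with
    L-BFGS-B from several starts (variance floor 1e-8); the fixed effects
    are the GLS solution at the optimum. Raises ``RuntimeError`` carrying
    the last iterate and gradient norm on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    if GA.n != n or GAA.n != n:
        raise ValueError("kinship dimensions do not match y")
    vy = y.var() if y.var() > 0 else 1.0
    A, E = GA.values, GAA.values

    def neg_ll(log_s):
        return -restricted_loglik(np.exp(log_s), y, X, A, E)

    floor = 1e-8
    best = None
    # a few spread starting points guard against local optima
    starts = [
        (vy / 3, vy / 3, vy / 3),
        (vy * 0.8, vy * 0.1, vy * 0.1),
        (vy * 0.05, vy * 0.05, vy * 0.9),
    ]
    for s0 in starts:
        res = optimize.minimize(
            neg_ll,
            np.log(np.maximum(s0, floor)),
            method="L-BFGS-B",
            bounds=[(np.log(floor), np.log(vy * 50 + floor))] * 3,
            options={"maxiter": max_iter, "ftol": tol * 1e-3},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML failed: non-finite restricted likelihood")
    if not best.success and np.linalg.norm(best.jac) > 1e-2:
        raise RuntimeError(
            f"REML did not converge after {max_iter} iterations: "
            f"last iterate {np.exp(best.x)}, |grad| = {np.linalg.norm(best.jac):.3g}"
        )
    sA, sE, se = np.exp(best.x)
    # GLS fixed effects at the optimum
    V = sA * A + sE * E + se * np.eye(n)
    cf = cho_factor(V, lower=True)
    XtVinvX = X.T @ cho_solve(cf, X)
    beta = np.linalg.solve(XtVinvX, X.T @ cho_solve(cf, y))
    return VarianceComponents(
        sigma2_additive=float(sA),
        sigma2_epistatic=float(sE),
        sigma2_residual=float(se),
        beta=beta,
        loglik=float(-best.fun),
        converged=True,
        n_iter=int(best.nit),
        **labels,
    )


def variance_summary(
    components: list[VarianceComponents], mode: str = "population_level"
) -> pd.DataFrame:
    """Aggregate per-fit variance proportions to population and dataset level.

    ``mode="per_environment_then_average"`` first averages proportions over
    environments within each population (multi-environment designs);
    ``mode="population_level"`` uses each population's single fit directly.
    The dataset-level row reports the *median* across populations, which is
    robust to the extreme component values individual populations can show.
    """
    if not components:
        raise ValueError("need at least one fitted population")
    if mode not in ("per_environment_then_average", "population_level"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = [
        {
            "population_id": vc.population_id,
            "environment": vc.environment,
            "trait": vc.trait,
            **{f"prop_{k}": v for k, v in vc.proportions.items()},
        }
        for vc in components
    ]
    df = pd.DataFrame(rows)
    prop_cols = ["prop_additive", "prop_epistatic", "prop_residual"]
    per_pop = df.groupby(["trait", "population_id"], as_index=False)[prop_cols].mean()
    per_pop["level"] = "population"
    med = per_pop.groupby("trait", as_index=False)[prop_cols].median()
    med["population_id"] = "ALL"
    med["level"] = "dataset_median"
    return pd.concat([per_pop, med], ignore_index=True)
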