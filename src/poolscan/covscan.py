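"""Population-covariance (Omega) estimation and covariance-corrected
differentiation statistics.

Standardized allele frequencies z_i = (p_i - pi_bar) / sqrt(pi_bar (1 -
pi_bar)) computed over putatively neutral SNPs give a moment estimate of
the population relatedness matrix Omega = E[z z^T]. Per-SNP differentiation
is then the quadratic form

    XtX = z^T Omega^{-1} z,

which under the shared-ancestry null (z ~ MVN(0, Omega)) is chi-square with
npop degrees of freedom, and covariate association is scored with a
closed-form conjugate-normal Bayes factor after whitening by the Cholesky
factor of Omega. These are deterministic moment/closed-form analogs of the
MCMC machinery usually used for this scan: they share its model (Gaussian
allele-frequency deviations around a shared ancestral frequency with
covariance pi(1-pi) Omega) but trade the posterior-sampling treatment of
binomial read noise for reproducibility and analytic nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "OmegaMatrix",
    "CovariateSet",
    "standardize_freqs",
    "estimate_omega",
    "matrix_correlation",
    "xtx",
    "bayes_factor",
    "collapse_covariates",
]


@dataclass
class OmegaMatrix:
    """npop x npop covariance of standardized allele frequencies."""

    matrix: np.ndarray
    n_snps: int
    thin_bp: int = 0
    ridge: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("omega not symmetric")
        if np.linalg.eigvalsh(m)[0] <= 0:
            raise ValueError("omega not positive definite")
        self.matrix = m

    @property
    def inv(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def submatrix(self, idx) -> "OmegaMatrix":
        return OmegaMatrix(self.matrix[np.ix_(idx, idx)], self.n_snps,
                           self.thin_bp, self.ridge)


def standardize_freqs(
    freqs: np.ndarray, depths: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize per-SNP frequencies against the depth-weighted mean.

    Returns (zhat, keep_mask); SNPs whose weighted mean frequency is 0 or 1
    are masked out (zhat rows for them are dropped).
    """
    freqs = np.asarray(freqs, dtype=float)
    if depths is None:
        w = np.ones_like(freqs)
    else:
        w = np.asarray(depths, dtype=float)
    pi = (freqs * w).sum(axis=1) / w.sum(axis=1)
    keep = (pi > 0.0) & (pi < 1.0)
    z = (freqs[keep] - pi[keep, None]) / np.sqrt(
        pi[keep] * (1.0 - pi[keep])
    )[:, None]
    return z, keep


def _thin(contigs, positions, thin_bp: int) -> np.ndarray:
    keep = np.zeros(len(positions), dtype=bool)
    last: dict[str, int] = {}
    for i, (c, p) in enumerate(zip(contigs, positions)):
        if c not in last or p - last[c] >= thin_bp:
            keep[i] = True
            last[c] = p
    return keep


def estimate_omega(
    zhat: np.ndarray,
    contigs=None,
    positions=None,
    thin_bp: int = 0,
) -> OmegaMatrix:
    """Moment estimate Omega = (1/S) sum_s z_s z_s^T from neutral SNPs.

    With ``thin_bp > 0``, SNPs are first greedily thinned so retained sites
    are at least that many bp apart (an LD-robustness check). If the raw
    moment matrix is not positive definite it is ridge-regularized by
    adding delta*I (delta recorded on the result).
    """
    z = np.asarray(zhat, dtype=float)
    npop = z.shape[1]
    if thin_bp > 0:
        if contigs is None or positions is None:
            raise ValueError("thinning requires contigs and positions")
        keep = _thin(np.asarray(contigs), np.asarray(positions), thin_bp)
        z = z[keep]
    S = z.shape[0]
    if S < npop * npop:
        warnings.warn(
            f"only {S} neutral SNPs for a {npop}x{npop} omega; "
            "estimate may be unstable", stacklevel=2,
        )
    omega = z.T @ z / S
    ridge = 0.0
    mineig = np.linalg.eigvalsh(omega)[0]
    if mineig <= 0:
        ridge = abs(mineig) + 1e-6 * np.trace(omega) / npop
        omega = omega + ridge * np.eye(npop)
        warnings.warn(f"omega ridge-regularized with delta={ridge:.3g}",
                      stacklevel=2)
        if np.linalg.eigvalsh(omega)[0] <= 0:
            raise np.linalg.LinAlgError("omega singular after regularization")
    return OmegaMatrix(omega, S, thin_bp, ridge)


def matrix_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of upper-triangle (incl. diagonal) entries."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(A.shape[0])
    a, b = A[iu], B[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("matrix correlation undefined for constant matrix")
    return float(np.corrcoef(a, b)[0, 1])


def xtx(zhat: np.ndarray, omega: OmegaMatrix | np.ndarray) -> np.ndarray | float:
    """Covariance-corrected differentiation statistic z^T Omega^{-1} z.

    Accepts a single z vector or an (S, npop) matrix (returns per-SNP
    values). Null calibration: chi-square with npop df.
    """
    m = omega.matrix if isinstance(omega, OmegaMatrix) else np.asarray(omega)
    z = np.asarray(zhat, dtype=float)
    single = z.ndim == 1
    z2 = z[None, :] if single else z
    if z2.shape[1] != m.shape[0]:
        raise ValueError("dimension mismatch between zhat and omega")
    sol = np.linalg.solve(m, z2.T)  # (npop, S)
    vals = np.einsum("sp,ps->s", z2, sol)
    return float(vals[0]) if single else vals


def bayes_factor(
    zhat: np.ndarray,
    covariate: np.ndarray,
    omega: OmegaMatrix,
    prior_var: float = 1.0,
) -> np.ndarray | float:
    """Closed-form conjugate-normal Bayes factor for covariate association.

    The covariate is z-scored over the populations where it is observed;
    populations with missing values are dropped from zhat and Omega
    (submatrix) for this scan. After whitening by the Cholesky factor L of
    Omega (y = L^{-1} z, x = L^{-1} c), the evidence ratio of the model
    with a N(0, prior_var) effect of x on y against the ancestry-only model
    is

        BF = (1 + v x^T x)^{-1/2} * exp(v (x^T y)^2 / (2 (1 + v x^T x))).
    """
    c = np.asarray(covariate, dtype=float)
    obs = ~np.isnan(c)
    if obs.sum() < 2:
        raise ValueError("covariate observed in fewer than 2 populations")
    c = c[obs]
    if np.std(c) == 0:
        raise ValueError("covariate constant after masking")
    c = (c - c.mean()) / c.std()
    om = omega.submatrix(np.flatnonzero(obs)) if not obs.all() else omega
    L = np.linalg.cholesky(om.matrix)
    z = np.asarray(zhat, dtype=float)
    single = z.ndim == 1
    z2 = (z[None, :] if single else z)[:, obs]
    y = np.linalg.solve(L, z2.T)           # (k, S)
    x = np.linalg.solve(L, c)              # (k,)
    v = float(prior_var)
    xtx_ = float(x @ x)
    xty = x @ y                             # (S,)
    bf = (1.0 + v * xtx_) ** -0.5 * np.exp(
        v * xty**2 / (2.0 * (1.0 + v * xtx_))
    )
    return float(bf[0]) if single else bf


@dataclass
class CovariateSet:
    """Collapsed covariates plus per-population dummy indicators."""

    values: pd.DataFrame                       # pops x covariates
    groups: dict[str, list[str]] = field(default_factory=dict)
    dummies: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


def collapse_covariates(
    covariates: pd.DataFrame,
    corr_threshold: float = 0.8,
    add_dummies: bool = True,
    min_observed: int = 3,
) -> CovariateSet:
    """Collapse highly correlated covariates and append population dummies.

    Covariates observed in fewer than ``min_observed`` populations are
    dropped. Groups are single-linkage clusters under |Pearson r| >=
    ``corr_threshold`` over jointly observed populations; each group is
    represented by its first member (column order), with full provenance
    retained. ``add_dummies`` appends a 0/1 indicator per population.
    """
    df = covariates.copy()
    enough = df.notna().sum(axis=0) >= min_observed
    dropped = [c for c in df.columns if not enough[c]]
    if dropped:
        warnings.warn(
            f"covariates observed in <{min_observed} populations dropped: "
            f"{dropped}", stacklevel=2,
        )
    df = df.loc[:, enough]
    groups: dict[str, list[str]] = {}
    if df.shape[1] >= 2:
        corr = df.corr(min_periods=2).abs().to_numpy()
        np.fill_diagonal(corr, 1.0)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = squareform(1.0 - corr, checks=False)
        labels = fcluster(
            linkage(dist, method="single"), t=1.0 - corr_threshold,
            criterion="distance",
        )
        cols = list(df.columns)
        for lab in np.unique(labels):
            members = [cols[i] for i in np.flatnonzero(labels == lab)]
            groups[members[0]] = members
        kept = [c for c in cols if c in groups]
        df = df.loc[:, kept]
    else:
        groups = {c: [c] for c in df.columns}
    dummies = []
    if add_dummies:
        for pop in covariates.index:
            name = f"dummy-{pop}"
            df[name] = (df.index == pop).astype(float)
            dummies.append(name)
    return CovariateSet(df, groups, dummies)
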