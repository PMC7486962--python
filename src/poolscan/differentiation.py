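"""Pooled F_ST (identity-probability estimator) and isolation by distance.

F_ST is estimated from read counts with the unbiased identity-probability
construction used for pool-seq data: the within-pool identity of two
distinct chromosomes, Q1, is recovered from the identity of two distinct
reads after correcting for reads that resample the same chromosome (a pair
of distinct reads comes from one chromosome with probability 1/n for a pool
of n chromosomes); the between-pool identity Q2 comes from cross-pool read
products, which are unbiased as-is. Then

    F_ST = (Q1_bar - Q2_bar) / (1 - Q2_bar),

aggregated across SNPs as a ratio of sums (separately summed numerators and
denominators), which unlike a mean of per-SNP ratios is unbiased under
variable depth and invariant to SNP duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FstResult", "pooled_fst", "haversine_km", "IbdFit", "ibd_regression"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class FstResult:
    global_fst: float
    pairwise: pd.DataFrame           # symmetric, zero diagonal
    per_snp: np.ndarray              # per-SNP ratio (diagnostic track)
    numerator: np.ndarray            # per-SNP Q1_bar - Q2_bar
    denominator: np.ndarray          # per-SNP 1 - Q2_bar


def _identity_terms(ref: np.ndarray, alt: np.ndarray, pool_chroms: np.ndarray):
    """Per-SNP Q1 (per pool) and Q2 (per pool pair) unbiased estimates."""
    c = (ref + alt).astype(float)
    if (c < 2).any():
        raise ValueError("every pool needs depth >= 2 at every SNP")
    a, r = alt.astype(float), ref.astype(float)
    q_rr = (a * (a - 1) + r * (r - 1)) / (c * (c - 1))  # two distinct reads
    n = pool_chroms[None, :].astype(float)
    q1 = (q_rr - 1.0 / n) / (1.0 - 1.0 / n)
    npop = ref.shape[1]
    pairs = list(combinations(range(npop), 2))
    q2 = np.empty((ref.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        q2[:, k] = (a[:, i] * a[:, j] + r[:, i] * r[:, j]) / (c[:, i] * c[:, j])
    return q1, q2, pairs


def pooled_fst(table, pool_chroms=None, method: str = "ratio_of_sums") -> FstResult:
    """Multi-population and pairwise pooled F_ST from a filtered SnpTable.

    ``pool_chroms`` defaults to 2 * pool_diploids from the table metadata;
    a scalar is broadcast. ``method="mean_of_ratios"`` averages per-SNP
    ratios instead (kept only as a contrast; it is not duplication
    invariant).
    """
    if table.n_pops < 2:
        raise ValueError("need at least two populations")
    if pool_chroms is None:
        pool_chroms = 2 * table.pools["pool_diploids"].to_numpy()
    pool_chroms = np.broadcast_to(
        np.asarray(pool_chroms, dtype=float), (table.n_pops,)
    )
    q1, q2, pairs = _identity_terms(table.ref_counts, table.alt_counts,
                                    pool_chroms)
    q1_bar = q1.mean(axis=1)
    q2_bar = q2.mean(axis=1)
    num = q1_bar - q2_bar
    den = 1.0 - q2_bar
    if method == "ratio_of_sums":
        global_fst = float(num.sum() / den.sum())
    elif method == "mean_of_ratios":
        ok = den > 0
        global_fst = float(np.mean(num[ok] / den[ok]))
    else:
        raise ValueError(f"unknown method {method!r}")

    names = table.pool_names
    pw = np.zeros((table.n_pops, table.n_pops))
    for k, (i, j) in enumerate(pairs):
        nij = 0.5 * (q1[:, i] + q1[:, j]) - q2[:, k]
        dij = 1.0 - q2[:, k]
        pw[i, j] = pw[j, i] = float(nij.sum() / dij.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_snp = np.where(den != 0, num / den, np.nan)
    return FstResult(
        global_fst=global_fst,
        pairwise=pd.DataFrame(pw, index=names, columns=names),
        per_snp=per_snp,
        numerator=num,
        denominator=den,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a 6,371-km sphere."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


@dataclass
class IbdFit:
    slope: float       # F_ST per km
    intercept: float
    r_squared: float
    n_pairs: int


def ibd_regression(
    pairwise_fst: pd.DataFrame,
    coordinates: pd.DataFrame,
    exclude: str | None = None,
) -> IbdFit:
    """OLS of pairwise F_ST on great-circle distance (isolation by distance).

    ``coordinates`` must carry ``lat``/``long`` columns indexed by
    population name; ``exclude`` drops one population (e.g. a geographic
    outlier) from all pairs before fitting.
    """
    pops = [p for p in pairwise_fst.index if p != exclude]
    if len(pops) < 3:
        raise ValueError("need at least 3 populations after exclusion")
    dist, fst = [], []
    for i, j in combinations(pops, 2):
        dist.append(
            haversine_km(
                coordinates.loc[i, "lat"], coordinates.loc[i, "long"],
                coordinates.loc[j, "lat"], coordinates.loc[j, "long"],
            )
        )
        fst.append(pairwise_fst.loc[i, j])
    dist = np.asarray(dist)
    if np.allclose(dist, dist[0]):
        raise ValueError("all pairwise distances equal; singular fit")
    res = stats.linregress(dist, np.asarray(fst))
    return IbdFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=len(dist),
    )
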