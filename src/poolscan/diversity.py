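"""Windowed pooled diversity estimators and the theta/pi neutrality ratio.

Pooled reads resample chromosomes with replacement, so `depth` reads from a
pool of `n` chromosomes represent fewer than `depth` distinct chromosomes.
The estimators below correct Watterson's theta and pi for this through the
expected number of distinct chromosomes sampled,

    n_e = n * (1 - (1 - 1/n) ** depth),

evaluating the Watterson harmonic factor a(n) at the rounded mean n_e per
window and inflating per-site heterozygosity by the read- and
chromosome-sampling factors c/(c-1) and n_e/(n_e-1). A "naive" mode keeps
the uncorrected window estimator (harmonic factor at the full pool size)
for comparison; on ascertained SNP sets the two can differ substantially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pooldata import SnpTable, allele_freqs

__all__ = [
    "DiversityWindow",
    "effective_chromosomes",
    "harmonic",
    "window_theta_pi",
    "theta_pi_ratio",
]


def effective_chromosomes(depth, pool_chroms: int):
    """Expected distinct chromosomes among `depth` reads drawn with
    replacement from `pool_chroms` chromosomes."""
    depth = np.asarray(depth, dtype=float)
    if (depth < 1).any():
        raise ValueError("depth must be >= 1")
    if pool_chroms < 2:
        raise ValueError("pool_chroms must be >= 2")
    out = pool_chroms * (1.0 - (1.0 - 1.0 / pool_chroms) ** depth)
    return float(out) if out.ndim == 0 else out


def harmonic(n: int) -> float:
    """Watterson's a(n) = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("harmonic factor needs n >= 2")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class DiversityWindow:
    contig: str
    start: int  # 1-based inclusive
    end: int    # exclusive; length = end - start
    S: int
    theta_w: float
    pi: float
    n_eff: float


def window_theta_pi(
    table: SnpTable,
    pop: str | int = 0,
    window_bp: int = 10_000,
    pool_chroms: int | None = None,
    mode: str = "pooled",
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window Watterson's theta and pi for one population's pool.

    theta_w = S / (a(round(mean n_e)) * L); pi sums 2*p*(1-p) * c/(c-1) *
    n_e/(n_e-1) over sites (both per bp, conditioned on the ascertained SNP
    set). ``mode="naive"`` instead evaluates a() at the full pool size and
    drops the chromosome-resampling inflation. Windows whose mean n_e
    rounds below 2 are emitted as null (NaN) entries.
    """
    if mode not in ("pooled", "naive"):
        raise ValueError("mode must be 'pooled' or 'naive'")
    j = table.pool_names.index(pop) if isinstance(pop, str) else pop
    if pool_chroms is None:
        pool_chroms = int(2 * table.pools["pool_diploids"].iloc[j])
    freqs, depth = allele_freqs(table)
    p, c = freqs[:, j], depth[:, j].astype(float)
    ne = effective_chromosomes(c, pool_chroms)

    rows = []
    for contig, grp in table.sites.groupby("contig", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length = (
            contig_lengths[contig]
            if contig_lengths
            else int(np.ceil(pos.max() / window_bp)) * window_bp
        )
        for start in range(1, length + 1, window_bp):
            end = min(start + window_bp, length + 1)
            L = end - start
            sel = idx[(pos >= start) & (pos < end)]
            seg = (p[sel] > 0) & (p[sel] < 1)
            S = int(seg.sum())
            if S == 0:
                rows.append(DiversityWindow(contig, start, end, 0, 0.0, 0.0,
                                            float("nan")))
                continue
            sel = sel[seg]
            ne_bar = float(ne[sel].mean())
            n_har = round(ne_bar) if mode == "pooled" else pool_chroms
            if n_har < 2:
                rows.append(DiversityWindow(contig, start, end, S,
                                            float("nan"), float("nan"), ne_bar))
                continue
            theta = S / (harmonic(n_har) * L)
            het = 2.0 * p[sel] * (1.0 - p[sel]) * c[sel] / (c[sel] - 1.0)
            if mode == "pooled":
                het = het * ne[sel] / (ne[sel] - 1.0)
            pi = float(het.sum() / L)
            rows.append(DiversityWindow(contig, start, end, S, theta, pi,
                                        ne_bar))
    return pd.DataFrame([vars(w) for w in rows])


def theta_pi_ratio(theta: float, pi: float) -> float:
    """The theta/pi neutrality ratio; departures from 1 indicate
    non-neutral (or non-equilibrium) sampling of the site set."""
    if pi <= 0:
        raise ValueError("pi must be positive for the theta/pi ratio")
    return theta / pi
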