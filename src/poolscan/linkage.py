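"""Linkage disequilibrium from read pairs, rho from LD decay, and the
Ne -> map length -> sex-specific recombination chain.

Within-read phasing gives direct two-site gamete counts; r2 per pair comes
from those counts (maximum-likelihood EM when a symmetric per-base error is
modeled). The decay of mean r2 with distance d is fitted with the
Hill-Weir drift expectation plus a finite-sample inflation term,

    E[r2](d) = (10 + C) / (22 + 13 C + C^2) + 1/n,   C = rho_bp * d,

over distances up to 400 bp. The fitted rho_bp converts to a per-meiosis
rate r = rho / (4 Ne) and hence a sex-averaged map length; if a fraction of
the population is a non-recombining (heterogametic) class, the map length
in the recombining class is the sex-averaged length divided by the
recombining fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LdDecay",
    "RhoFit",
    "MapEstimate",
    "r2_from_gamete_counts",
    "ld_decay",
    "pair_ld",
    "bin_ld",
    "hill_weir_r2",
    "fit_rho",
    "effective_pop_size",
    "map_length",
    "sex_specific_map",
    "map_chain",
]


def _d2_het(f: np.ndarray) -> tuple[float, float]:
    """(D^2, heterozygosity product) from gamete frequencies (AB, Ab, aB, ab)."""
    fab, fAb, faB, _ = f
    fA = fab + fAb
    fB = fab + faB
    d = fab - fA * fB
    return float(d * d), float(fA * (1 - fA) * fB * (1 - fB))


def _r2_from_freqs(f: np.ndarray) -> float:
    d2, het = _d2_het(f)
    if het <= 0:
        return float("nan")
    return float(min(1.0, d2 / het))


def r2_from_gamete_counts(
    n_AB: int, n_Ab: int, n_aB: int, n_ab: int,
    seq_error: float = 0.0, min_reads: int = 10,
    tol: float = 1e-12, max_iter: int = 2000,
) -> float:
    """r2 from two-site gamete-class read counts.

    With ``seq_error=0`` the direct estimate (haplotype frequencies =
    counts/total). With error, an EM maximum-likelihood fit treating each
    read class as emitted from a true gamete with independent symmetric
    per-site flips; the EM fixed point at zero error equals the direct
    estimate. Returns NaN for pairs with fewer than ``min_reads`` covering
    reads or monomorphic at either site.
    """
    counts = np.array([n_AB, n_Ab, n_aB, n_ab], dtype=float)
    if counts.sum() < min_reads:
        return float("nan")
    return _r2_from_freqs(_gamete_freqs(counts, seq_error, tol, max_iter))


def _gamete_freqs(
    counts: np.ndarray, seq_error: float, tol: float = 1e-12,
    max_iter: int = 2000,
) -> np.ndarray:
    """Gamete-frequency estimate from read-class counts (EM if error > 0)."""
    total = counts.sum()
    if seq_error == 0.0:
        return counts / total
    e = seq_error
    # emission matrix M[g, o] = P(read class o | true gamete g)
    classes = [(1, 1), (1, 0), (0, 1), (0, 0)]
    M = np.empty((4, 4))
    for g, (ga, gb) in enumerate(classes):
        for o, (oa, ob) in enumerate(classes):
            d = (ga != oa) + (gb != ob)
            M[g, o] = e**d * (1 - e) ** (2 - d)
    f = (counts + 0.5) / (total + 2.0)
    for _ in range(max_iter):
        # E-step: responsibility of gamete g for observed class o
        joint = f[:, None] * M  # (gamete, class)
        denom = joint.sum(axis=0)
        resp = joint / denom[None, :]
        f_new = (resp * counts[None, :]).sum(axis=1) / total
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return f


@dataclass
class LdDecay:
    """Binned LD decay: per distance bin the sigma_d^2 form of r2
    (sum D^2 / sum het-product over pairs; see :func:`ld_decay`), bins
    non-overlapping and bounded at the maximum fit distance."""

    bin_edges: np.ndarray  # length n_bins + 1, bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay(
    pairs: pd.DataFrame,
    bin_width: int = 25,
    max_dist: int = 400,
    seq_error: float = 0.0,
    min_reads: int = 10,
) -> LdDecay:
    """Bin pairwise LD by distance as the sigma_d^2 form of r2.

    Each bin's value is sum(D^2) / sum(p_A(1-p_A) p_B(1-p_B)) over the
    pairs in the bin (the ratio-of-expectations form of r2, which is the
    quantity the Hill-Weir drift expectation approximates); a plain mean
    of per-pair r2 is biased far below that expectation at short distance
    and would not be fit by any closed form here. Pairs with fewer than
    ``min_reads`` covering reads, monomorphic pairs, and distances beyond
    ``max_dist`` are excluded.
    """
    comp = pair_ld(pairs, seq_error=seq_error, min_reads=min_reads)
    return bin_ld(comp, bin_width=bin_width, max_dist=max_dist)


def pair_ld(
    pairs: pd.DataFrame, seq_error: float = 0.0, min_reads: int = 10
) -> pd.DataFrame:
    """Per-pair D^2 and heterozygosity-product components of sigma_d^2.

    Monomorphic and under-covered pairs are dropped. The ``window`` column
    is carried through when present (block-bootstrap unit).
    """
    counts = pairs[["n_AB", "n_Ab", "n_aB", "n_ab"]].to_numpy(dtype=float)
    d2 = np.full(len(pairs), np.nan)
    het = np.full(len(pairs), np.nan)
    for k in range(len(pairs)):
        if counts[k].sum() < min_reads:
            continue
        d2[k], het[k] = _d2_het(_gamete_freqs(counts[k], seq_error))
    out = pd.DataFrame({"dist": pairs["dist"].to_numpy(float),
                        "d2": d2, "het": het})
    if "window" in pairs.columns:
        out["window"] = pairs["window"].to_numpy()
    return out[np.isfinite(d2) & (het > 0)].reset_index(drop=True)


def bin_ld(
    components: pd.DataFrame, bin_width: int = 25, max_dist: int = 400
) -> LdDecay:
    """Bin :func:`pair_ld` components into an :class:`LdDecay`."""
    sel = components["dist"] <= max_dist
    dist = components.loc[sel, "dist"].to_numpy()
    d2 = components.loc[sel, "d2"].to_numpy()
    het = components.loc[sel, "het"].to_numpy()
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=float)
    which = np.digitize(dist, edges) - 1
    mean_r2 = np.full(len(edges) - 1, np.nan)
    n_pairs = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        inb = which == b
        n_pairs[b] = int(inb.sum())
        if n_pairs[b]:
            mean_r2[b] = float(d2[inb].sum() / het[inb].sum())
    return LdDecay(edges, mean_r2, n_pairs)


def hill_weir_r2(d, rho_per_bp: float, sample_chroms: float):
    """Drift expectation of r2 at distance d plus 1/n sampling inflation."""
    C = rho_per_bp * np.asarray(d, dtype=float)
    return (10.0 + C) / (22.0 + 13.0 * C + C * C) + 1.0 / sample_chroms


@dataclass
class RhoFit:
    rho_per_bp: float
    ci_low: float
    ci_high: float
    rss: float


def fit_rho(
    decay: LdDecay,
    sample_chroms: float,
    n_boot: int = 200,
    seed: int = 0,
) -> RhoFit:
    """Weighted least-squares fit of the Hill-Weir decay for rho per bp.

    Bins are weighted by pair count; a bootstrap over occupied bins gives
    the confidence interval. A decay flat at the sampling floor triggers a
    warning (rho is then poorly identified; the CI reflects that).
    """
    ok = np.isfinite(decay.mean_r2) & (decay.n_pairs > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 occupied distance bins")
    d = decay.bin_mid[ok]
    y = decay.mean_r2[ok]
    w = decay.n_pairs[ok].astype(float)

    def _fit(dv, yv, wv):
        popt, _ = curve_fit(
            lambda x, rho: hill_weir_r2(x, rho, sample_chroms),
            dv, yv, p0=[0.005], sigma=1.0 / np.sqrt(wv),
            bounds=(1e-12, 10.0), maxfev=10000,
        )
        return float(popt[0])

    rho = _fit(d, y, w)
    resid = y - hill_weir_r2(d, rho, sample_chroms)
    floor = 10.0 / 22.0 + 1.0 / sample_chroms
    if np.all(np.abs(y - floor) < 0.01):
        warnings.warn(
            "LD decay flat at the no-decay floor; rho poorly identified",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        take = rng.integers(0, len(d), size=len(d))
        try:
            boots.append(_fit(d[take], y[take], w[take]))
        except RuntimeError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return RhoFit(rho, float(lo), float(hi), float(np.sum(w * resid**2)))


def effective_pop_size(theta: float, mu: float = 2.8e-9) -> float:
    """Ne = theta / (4 mu); theta per bp, mu per bp per gamete per
    generation (default: the Drosophila rate)."""
    if theta <= 0 or mu <= 0:
        raise ValueError("theta and mu must be positive")
    return theta / (4.0 * mu)


def map_length(rho_per_bp: float, ne: float, genome_bp: float) -> float:
    """Sex-averaged map length in cM: r = rho/(4 Ne), map = r * G * 100."""
    if rho_per_bp < 0 or ne <= 0 or genome_bp <= 0:
        raise ValueError("arguments must be positive (rho may be 0)")
    r = rho_per_bp / (4.0 * ne)
    return r * genome_bp * 100.0


def sex_specific_map(sex_averaged_cM: float, frac_nonrecombining: float) -> float:
    """Map length in the recombining class when a fraction of the
    population contributes zero crossovers."""
    if not (0.0 <= frac_nonrecombining < 1.0):
        raise ValueError("frac_nonrecombining must be in [0, 1)")
    return sex_averaged_cM / (1.0 - frac_nonrecombining)


@dataclass
class MapEstimate:
    rho_per_bp: float
    Ne: float
    mu: float
    genome_size_bp: float
    sex_averaged_cM: float
    frac_amphigenic: float
    recombining_sex_cM: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def map_chain(
    theta: float,
    rho_per_bp: float,
    genome_bp: float,
    mu: float = 2.8e-9,
    frac_amphigenic: float = 0.8,
) -> MapEstimate:
    """Full chain theta -> Ne, rho -> r -> sex-averaged and recombining-sex
    map lengths."""
    ne = effective_pop_size(theta, mu)
    cm = map_length(rho_per_bp, ne, genome_bp)
    return MapEstimate(
        rho_per_bp=rho_per_bp,
        Ne=ne,
        mu=mu,
        genome_size_bp=genome_bp,
        sex_averaged_cM=cm,
        frac_amphigenic=frac_amphigenic,
        recombining_sex_cM=sex_specific_map(cm, frac_amphigenic),
    )
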