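"""Two-state Gaussian HMM segmentation of genome-wide statistic tracks.

SNP-ordered statistic values (F_ST, XtX, ...) are decoded into a background
and a differentiated state with Viterbi under Gaussian emissions; HMM steps
are SNP-ordinal (inter-SNP basepair distance is ignored, matching how such
tracks are segmented in practice). Runs of the differentiated state become
intervals [first_pos, last_pos + 1] (so a single-SNP region has width 1),
intervals within ``merge_gap`` bp on a contig are merged, and regions are
annotated with genes whose span falls within a flank. Emission presets for
XtX-like (background N(20, 9) vs differentiated N(100, 200)) and F_ST-like
(N(0.24, 0.36) vs N(0.8, 1.6)) tracks are provided, with per-SNP-step
transition probability 0.001; emissions can also be fitted by Baum-Welch
with transitions held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "HmmParams",
    "RegionCall",
    "XTX_PRESET",
    "FST_PRESET",
    "viterbi_two_state",
    "decode_track",
    "call_regions",
    "fit_emission_params",
    "annotate_regions",
    "regions_summary",
    "regions_to_frame",
]

BACKGROUND, DIFFERENTIATED = 0, 1


@dataclass(frozen=True)
class HmmParams:
    bg_mean: float
    bg_sd: float
    diff_mean: float
    diff_sd: float
    trans_prob: float = 0.001

    def __post_init__(self) -> None:
        if self.bg_sd <= 0 or self.diff_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if not (0.0 < self.trans_prob < 0.5):
            raise ValueError("trans_prob must be in (0, 0.5)")


XTX_PRESET = HmmParams(20.0, 9.0, 100.0, 200.0)
FST_PRESET = HmmParams(0.24, 0.36, 0.8, 1.6)


def _log_emissions(values: np.ndarray, params: HmmParams) -> np.ndarray:
    return np.column_stack(
        [
            norm.logpdf(values, params.bg_mean, params.bg_sd),
            norm.logpdf(values, params.diff_mean, params.diff_sd),
        ]
    )


def viterbi_two_state(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable state path (0 = background, 1 = differentiated).

    Symmetric transition matrix, stationary (uniform) initial distribution,
    log-space arithmetic, ties broken toward background.
    """
    values = np.asarray(values, dtype=float)
    T = len(values)
    if T == 0:
        return np.zeros(0, dtype=np.int8)
    logB = _log_emissions(values, params)
    log_stay = float(np.log1p(-params.trans_prob))
    log_switch = float(np.log(params.trans_prob))
    # stationary distribution of the symmetric chain is uniform
    d_bg = float(logB[0, 0]) + np.log(0.5)
    d_df = float(logB[0, 1]) + np.log(0.5)
    psi = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        # into background (tie -> background predecessor)
        a = d_bg + log_stay
        b = d_df + log_switch
        if b > a:
            psi[t, 0] = DIFFERENTIATED
            best_bg = b
        else:
            best_bg = a
        # into differentiated
        a = d_bg + log_switch
        b = d_df + log_stay
        if b > a:
            psi[t, 1] = DIFFERENTIATED
            best_df = b
        else:
            best_df = a
        d_bg = best_bg + logB[t, 0]
        d_df = best_df + logB[t, 1]
    states = np.empty(T, dtype=np.int8)
    # final tie -> background
    states[-1] = DIFFERENTIATED if d_df > d_bg else BACKGROUND
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


def decode_track(track: pd.DataFrame, params: HmmParams) -> pd.DataFrame:
    """Viterbi-decode a (contig, pos, value) track, each contig
    independently; returns the track with a ``state`` column."""
    track = track.sort_values(["contig", "pos"]).reset_index(drop=True)
    states = np.empty(len(track), dtype=np.int8)
    for _, grp in track.groupby("contig", sort=False):
        states[grp.index.to_numpy()] = viterbi_two_state(
            grp["value"].to_numpy(), params
        )
    out = track.copy()
    out["state"] = states
    return out


@dataclass
class RegionCall:
    """A called differentiated interval; width = end - start (a single-SNP
    region spans [p, p+1] and has width 1)."""

    contig: str
    start: int  # 1-based first SNP position
    end: int    # last SNP position + 1
    n_snps: int
    mean_stat: float
    genes_within_5kb: int | None = None
    gene_ids: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


def call_regions(
    states: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray | None = None,
    contig: str = "",
    merge_gap: int = 100,
) -> list[RegionCall]:
    """Turn a decoded state sequence into merged differentiated regions.

    Maximal runs of the differentiated state become [first, last+1]
    intervals; intervals on the same contig whose gap is <= ``merge_gap``
    bp are combined. Deterministic and idempotent.
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    if values is None:
        values = np.full(len(states), np.nan)
    diff = np.flatnonzero(states == DIFFERENTIATED)
    if len(diff) == 0:
        return []
    runs: list[tuple[int, int]] = []
    run_start = diff[0]
    prev = diff[0]
    for i in diff[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    intervals = [(int(positions[a]), int(positions[b]) + 1) for a, b in runs]
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe <= merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        inside = (positions >= s) & (positions < e)
        vals = values[inside]
        mean_stat = (
            float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        )
        out.append(
            RegionCall(
                contig=contig,
                start=s,
                end=e,
                n_snps=int(inside.sum()),
                mean_stat=mean_stat,
            )
        )
    return out


def call_regions_track(
    track: pd.DataFrame, params: HmmParams, merge_gap: int = 100
) -> list[RegionCall]:
    """Decode and call regions over a whole (contig, pos, value) track."""
    decoded = decode_track(track, params)
    regions: list[RegionCall] = []
    for contig, grp in decoded.groupby("contig", sort=False):
        regions.extend(
            call_regions(
                grp["state"].to_numpy(),
                grp["pos"].to_numpy(),
                grp["value"].to_numpy(),
                contig=contig,
                merge_gap=merge_gap,
            )
        )
    return regions


def fit_emission_params(
    values,
    trans_prob: float = 0.001,
    init_quantile: float = 0.95,
    max_iter: int = 100,
    tol: float = 1e-6,
    fallback: HmmParams = XTX_PRESET,
) -> tuple[HmmParams, list[float]]:
    """Baum-Welch fit of the two Gaussian emissions, transitions fixed.

    ``values`` is one array or a list of per-contig arrays. Initialization
    splits at the ``init_quantile`` quantile (background below). Returns
    the fitted params and the per-iteration log-likelihood trace (monotone
    non-decreasing). A degenerate (zero-variance or empty) state falls back
    to ``fallback`` with a warning.
    """
    seqs = [np.asarray(v, float) for v in
            (values if isinstance(values, (list, tuple)) else [values])]
    allv = np.concatenate(seqs)
    if len(allv) < 100:
        raise ValueError("need at least 100 SNPs to fit emissions")
    cut = np.quantile(allv, init_quantile)
    lo, hi = allv[allv <= cut], allv[allv > cut]
    if len(hi) < 2 or lo.std() == 0 or hi.std() == 0:
        warnings.warn("degenerate initialization; using preset emissions",
                      stacklevel=2)
        return fallback, []
    params = HmmParams(float(lo.mean()), float(lo.std()),
                       float(hi.mean()), float(hi.std()), trans_prob)
    A = np.array([[1 - trans_prob, trans_prob],
                  [trans_prob, 1 - trans_prob]])
    start = np.array([0.5, 0.5])
    trace: list[float] = []
    for _ in range(max_iter):
        ll = 0.0
        g_sum = np.zeros(2)
        g_x = np.zeros(2)
        g_xx = np.zeros(2)
        for seq in seqs:
            T = len(seq)
            B = np.exp(_log_emissions(seq, params))
            B = np.maximum(B, 1e-300)
            alpha = np.empty((T, 2))
            scale = np.empty(T)
            alpha[0] = start * B[0]
            scale[0] = alpha[0].sum()
            alpha[0] /= scale[0]
            for t in range(1, T):
                alpha[t] = (alpha[t - 1] @ A) * B[t]
                scale[t] = alpha[t].sum()
                alpha[t] /= scale[t]
            beta = np.empty((T, 2))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            ll += float(np.log(scale).sum())
            g_sum += gamma.sum(axis=0)
            g_x += gamma.T @ seq
            g_xx += gamma.T @ (seq * seq)
        trace.append(ll)
        if g_sum.min() < 1e-8:
            warnings.warn("degenerate state during fitting; using preset",
                          stacklevel=2)
            return fallback, trace
        means = g_x / g_sum
        var = g_xx / g_sum - means**2
        if var.min() <= 0:
            warnings.warn("zero-variance state during fitting; using preset",
                          stacklevel=2)
            return fallback, trace
        new = HmmParams(float(means[0]), float(np.sqrt(var[0])),
                        float(means[1]), float(np.sqrt(var[1])), trans_prob)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            params = new
            break
        params = new
    # keep background as the lower-mean state
    if params.bg_mean > params.diff_mean:
        params = HmmParams(params.diff_mean, params.diff_sd,
                           params.bg_mean, params.bg_sd, trans_prob)
    return params, trace


def annotate_regions(
    regions: list[RegionCall],
    gff: str | gffutils.FeatureDB | None,
    flank: int = 5000,
) -> list[RegionCall]:
    """Count genes whose span intersects [start - flank, end + flank].

    A missing annotation leaves counts as None (distinct from zero).
    """
    if gff is None:
        for r in regions:
            r.genes_within_5kb = None
            r.gene_ids = []
        return regions
    db = (
        gff
        if isinstance(gff, gffutils.FeatureDB)
        else gffutils.create_db(gff, ":memory:",
                                merge_strategy="create_unique")
    )
    genes: dict[str, list[tuple[int, int, str]]] = {}
    for g in db.features_of_type("gene"):
        genes.setdefault(g.seqid, []).append((g.start, g.end, g.id))
    for r in regions:
        lo, hi = r.start - flank, (r.end - 1) + flank
        hits = [
            gid for (gs, ge, gid) in genes.get(r.contig, [])
            if gs <= hi and ge >= lo
        ]
        r.genes_within_5kb = len(hits)
        r.gene_ids = sorted(hits)
    return regions


def regions_summary(regions: list[RegionCall]) -> dict:
    """Arithmetic-mean width/SNP-count/gene-count summary of a call set."""
    if not regions:
        return {"n_regions": 0, "mean_width": float("nan"),
                "mean_n_snps": float("nan"), "mean_genes_within_5kb": None}
    gene_counts = [r.genes_within_5kb for r in regions]
    return {
        "n_regions": len(regions),
        "mean_width": float(np.mean([r.width for r in regions])),
        "mean_n_snps": float(np.mean([r.n_snps for r in regions])),
        "mean_genes_within_5kb": (
            float(np.mean([g for g in gene_counts]))
            if all(g is not None for g in gene_counts)
            else None
        ),
    }


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    """Table-style view: locus number, contig, 1-based range, SNP and gene
    counts."""
    return pd.DataFrame(
        {
            "locus": np.arange(1, len(regions) + 1),
            "contig": [r.contig for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "width": [r.width for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "mean_stat": [r.mean_stat for r in regions],
            "genes_within_5kb": [r.genes_within_5kb for r in regions],
        }
    )
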