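"""Tiled coverage normalization, Bonferroni overcoverage testing, and the
marker-downsampling power analysis.

Coverage is summarized in fixed-width tiles (550 bp by default, the average
size of called differentiated regions) and normalized per population to the
genome-wide mean tile coverage, so 1.0 means average coverage regardless of
a population's sequencing effort. A called region is flagged as overcovered
in a population when its mean normalized coverage exceeds that population's
empirical (1 - alpha / n_tests) tile quantile, with n_tests = populations x
regions (Bonferroni at family-wise alpha).

The power analysis drops markers uniformly at random, re-runs the HMM
region caller with identical parameters, and scores each full-density
region as recovered when any re-called region overlaps it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import HmmParams, RegionCall, call_regions_track

__all__ = [
    "CoverageTiles",
    "OvercoverageResult",
    "tile_coverage",
    "overcoverage_test",
    "downsample_power",
]


@dataclass
class CoverageTiles:
    """Per-contig fixed-width tiles (0-based half-open) with per-population
    normalized mean coverage; each population's genome-wide tile mean is 1."""

    tiles: pd.DataFrame  # contig, start, end, truncated + one column per pop
    pops: list[str]
    tile_bp: int
    genome_bp: int


def tile_coverage(
    depth_track: pd.DataFrame,
    contig_lengths: dict[str, int],
    tile_bp: int = 550,
) -> CoverageTiles:
    """Tile per-site depths and normalize per population.

    ``depth_track`` has columns contig, pos (1-based) plus one depth column
    per population (per-base or per-site tracks both work; a tile's value
    is the mean over the sites that fall in it, and tiles containing no
    sites are dropped). Contigs shorter than one tile yield a single
    truncated tile, flagged in the ``truncated`` column.
    """
    pops = [c for c in depth_track.columns if c not in ("contig", "pos")]
    frames = []
    for contig, length in contig_lengths.items():
        grp = depth_track[depth_track["contig"] == contig]
        if length < tile_bp:
            warnings.warn(
                f"contig {contig} shorter than one tile; single truncated "
                "tile emitted", stacklevel=2,
            )
        n_tiles = max(1, int(np.ceil(length / tile_bp)))
        if grp.empty:
            continue
        idx = np.minimum((grp["pos"].to_numpy() - 1) // tile_bp, n_tiles - 1)
        agg = grp[pops].groupby(idx).mean()
        tiles = pd.DataFrame(
            {
                "contig": contig,
                "start": agg.index.to_numpy() * tile_bp,
                "end": np.minimum((agg.index.to_numpy() + 1) * tile_bp, length),
            }
        )
        tiles["truncated"] = (tiles["end"] - tiles["start"]) < tile_bp
        for p in pops:
            tiles[p] = agg[p].to_numpy()
        frames.append(tiles)
    out = pd.concat(frames, ignore_index=True)
    for p in pops:
        out[p] = out[p] / out[p].mean()
    return CoverageTiles(
        out, pops, tile_bp, int(sum(contig_lengths.values()))
    )


@dataclass
class OvercoverageResult:
    flags: pd.DataFrame          # region, pop, mean_norm_cov, threshold, flagged
    n_tests: int
    per_test_alpha: float
    thresholds: pd.Series        # per-pop quantile threshold
    frac_tiles_flagged: float    # tiles exceeding their pop threshold in >=1 pop
    frac_genome_significant: float


def overcoverage_test(
    tiles: CoverageTiles,
    regions: list[RegionCall],
    overall_alpha: float = 0.05,
    paper_rounding: bool = False,
) -> OvercoverageResult:
    """Bonferroni-corrected empirical-quantile overcoverage test.

    n_tests = n_pops * n_regions; each population's threshold is the
    empirical (1 - alpha/n_tests) quantile of its genome-wide normalized
    tile coverage (``paper_rounding`` uses the 0.9997 percentile instead of
    the full-precision division). A region is flagged for a population when
    the mean normalized coverage of the tiles overlapping it exceeds the
    threshold; partially overlapping tiles count fully.
    """
    n_tests = len(tiles.pops) * len(regions)
    if n_tests == 0:
        raise ValueError("need at least one region and one population")
    per_test = overall_alpha / n_tests
    q = 0.9997 if paper_rounding else 1.0 - per_test
    n_tiles = len(tiles.tiles)
    if n_tiles < 1.0 / per_test:
        warnings.warn(
            f"only {n_tiles} tiles for a {per_test:.2e} tail quantile; "
            "threshold unreliable", stacklevel=2,
        )
    thresholds = pd.Series(
        {p: float(np.quantile(tiles.tiles[p], q)) for p in tiles.pops}
    )
    rows = []
    flagged_widths = 0
    tl = tiles.tiles
    for i, reg in enumerate(regions):
        # region [start, end) 1-based -> tile overlap on 0-based half-open
        sel = (
            (tl["contig"] == reg.contig)
            & (tl["end"] > reg.start - 1)
            & (tl["start"] < reg.end - 1)
        )
        any_flag = False
        for p in tiles.pops:
            mean_cov = float(tl.loc[sel, p].mean()) if sel.any() else float("nan")
            flag = bool(mean_cov > thresholds[p]) if np.isfinite(mean_cov) else False
            any_flag |= flag
            rows.append(
                {"region": i + 1, "contig": reg.contig, "start": reg.start,
                 "end": reg.end, "pop": p, "mean_norm_cov": mean_cov,
                 "threshold": thresholds[p], "flagged": flag}
            )
        if any_flag:
            flagged_widths += reg.width
    exceed = np.zeros(n_tiles, dtype=bool)
    for p in tiles.pops:
        exceed |= tl[p].to_numpy() > thresholds[p]
    return OvercoverageResult(
        flags=pd.DataFrame(rows),
        n_tests=n_tests,
        per_test_alpha=per_test,
        thresholds=thresholds,
        frac_tiles_flagged=float(exceed.mean()),
        frac_genome_significant=flagged_widths / tiles.genome_bp,
    )


def _overlaps(region: RegionCall, calls: list[RegionCall], min_bp: int) -> bool:
    for c in calls:
        if c.contig != region.contig:
            continue
        if min(c.end, region.end) - max(c.start, region.start) >= min_bp:
            return True
    return False


def downsample_power(
    track: pd.DataFrame,
    regions: list[RegionCall],
    params: HmmParams,
    fractions,
    n_reps: int = 20,
    seed: int = 0,
    merge_gap: int = 100,
    overlap_bp: int = 1,
) -> pd.DataFrame:
    """Region recovery under uniform random marker downsampling.

    For each fraction and replicate an exact subsample of
    round(fraction * n) SNPs is kept, the two-state HMM re-run with
    identical parameters, and a full-density region counted as recovered
    when a re-called region overlaps it by >= ``overlap_bp``. Fraction 1.0
    is an identical deterministic re-run (recovery exactly 100%). Returns
    one row per (fraction, rep) with the recovery percentage.
    """
    if not regions:
        raise ValueError("no full-density regions to recover")
    rng = np.random.default_rng(seed)
    n = len(track)
    rows = []
    for frac in fractions:
        reps = 1 if frac == 1.0 else n_reps
        for rep in range(reps):
            if frac == 1.0:
                sub = track
            else:
                keep = np.sort(
                    rng.choice(n, size=int(round(frac * n)), replace=False)
                )
                sub = track.iloc[keep]
                # contigs reduced below 2 SNPs cannot be decoded; drop them
                counts = sub.groupby("contig")["pos"].transform("size")
                if (counts < 2).any():
                    sub = sub[counts >= 2]
            calls = call_regions_track(sub, params, merge_gap=merge_gap)
            rec = sum(_overlaps(r, calls, overlap_bp) for r in regions)
            rows.append(
                {"fraction": frac, "rep": rep,
                 "recovery_pct": 100.0 * rec / len(regions)}
            )
    return pd.DataFrame(rows)
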