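"""End-to-end orchestration: simulate -> filter -> neutral-site Omega ->
scans -> region calls -> coverage -> power -> diversity/LD/map, with a
machine-readable summary and full parameter/seed logging.

All stage parameters default to the survey presets (min_qual 30, min_cov
10, 10-kb diversity windows, 550-bp coverage tiles, transition probability
0.001, 100-bp region merging, 5-kb gene flank, mu 2.8e-9, 80% amphigenic
fraction). Every random draw descends from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import covscan, differentiation, diversity, linkage, simulate
from .coverage import downsample_power, overcoverage_test, tile_coverage
from .degeneracy import fourfold_sites
from .pooldata import allele_freqs, filter_snps, read_snp_table
from .regions import (
    FST_PRESET,
    XTX_PRESET,
    HmmParams,
    annotate_regions,
    call_regions_track,
    regions_summary,
    regions_to_frame,
)

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Section):
    n_pops: int = 11
    pool_diploids: int = 100
    contigs: list[tuple[str, int]] = [("C0001", 400_000), ("C0002", 300_000)]
    snp_density: float = 1.0 / 85.0
    mean_coverage: float = 70.0
    seq_error: float = 0.001
    omega_scale: float = 0.05
    n_spiked_regions: int = 8
    spike_width_range: tuple[int, int] = (1, 2600)
    spike_min_snps: int = 5
    spike_effect: float = 0.5
    n_coverage_anomalies: int = 3
    anomaly_multiplier: float = 3.0


class FilterSection(_Section):
    min_qual: float = 30.0
    min_cov: int = 10


class DiversitySection(_Section):
    window_bp: int = 10_000
    pop: int = 0


class LdSection(_Section):
    rho_per_bp: float = 0.006
    ne_sim: int = 100
    window_bp: int = 5000
    n_windows: int = 20
    depth: int = 70
    bin_width: int = 25
    max_dist: int = 400


class ScanSection(_Section):
    prior_var: float = 1.0
    corr_threshold: float = 0.8
    bf_cutoff: float = 1e20  # conservative decision preset for BF tracks


class PeaksSection(_Section):
    preset: str = "xtx"
    trans_prob: float = 0.001
    merge_gap: int = 100
    flank: int = 5000


class CoverageSection(_Section):
    tile_bp: int = 550
    overall_alpha: float = 0.05


class PowerSection(_Section):
    fractions: list[float] = [1.0, 5.0 / 7.0, 0.25, 0.1]
    n_reps: int = 5


class MapSection(_Section):
    mu: float = 2.8e-9
    frac_amphigenic: float = 0.8
    genome_bp: Optional[float] = None  # default: simulated genome size


class FstSection(_Section):
    exclude: Optional[str] = None


class RunConfig(_Section):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "poolscan_out"
    sim: SimSection = SimSection()
    filter: FilterSection = FilterSection()
    diversity: DiversitySection = DiversitySection()
    ld: LdSection = LdSection()
    scan: ScanSection = ScanSection()
    peaks: PeaksSection = PeaksSection()
    coverage: CoverageSection = CoverageSection()
    power: PowerSection = PowerSection()
    map: MapSection = MapSection()
    fst: FstSection = FstSection()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _default_covariates(n_pops: int, rng: np.random.Generator) -> dict:
    """Field-style per-population covariates: coordinates plus a few
    abiotic/biotic variables (one with missing values)."""
    lat = 32.0 + rng.uniform(0, 2.5, n_pops)
    lon = -108.0 + rng.uniform(0, 2.5, n_pops)
    elevation = 1200 + 300 * (lat - 32.0) + rng.normal(0, 40, n_pops)
    salinity = rng.lognormal(0.0, 0.4, n_pops)
    pct_males = rng.uniform(0.0, 0.5, n_pops)
    ph = np.full(n_pops, np.nan)
    ph[rng.choice(n_pops, size=min(3, n_pops), replace=False)] = rng.uniform(
        6.5, 8.5, min(3, n_pops)
    )
    return {
        "lat": lat.tolist(),
        "long": lon.tolist(),
        "elevation": elevation.tolist(),
        "salinity": salinity.tolist(),
        "pct_males": pct_males.tolist(),
        "ph": ph.tolist(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the summary dictionary.

    Artifacts (FASTA, GFF3, VCF, sync, truth JSON, covariate TSV, stat
    tracks, region tables, coverage flags, power table, summary JSON) are
    written under ``config.outdir``. Reruns with the same config and seed
    are byte-identical.
    """
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    stage = "simulate"
    try:
        summary: dict = {"seed": config.seed,
                         "params": json.loads(config.model_dump_json())}
        cov_rng = np.random.default_rng(config.seed + 17)
        covariates = _default_covariates(config.sim.n_pops, cov_rng)
        sim = config.sim
        sc = simulate.SimConfig(
            n_pops=sim.n_pops,
            pool_diploids=sim.pool_diploids,
            genome=[tuple(c) for c in sim.contigs],
            snp_density=sim.snp_density,
            mean_coverage=sim.mean_coverage,
            seq_error=sim.seq_error,
            omega_spec=("identity", sim.omega_scale),
            n_spiked_regions=sim.n_spiked_regions,
            spike_width_range=tuple(sim.spike_width_range),
            spike_min_snps=sim.spike_min_snps,
            spike_effect=sim.spike_effect,
            covariates=covariates,
            seed=config.seed,
        )
        ref = simulate.gen_reference(sc)
        positions, freqs, truth = simulate.gen_frequencies(sc)
        anom_rng = np.random.default_rng(config.seed + 23)
        for reg in truth.spiked_regions[: sim.n_coverage_anomalies]:
            sc.coverage_anomaly_spec.append(
                simulate.CoverageAnomaly(
                    reg.contig, reg.start, reg.end,
                    int(anom_rng.integers(sim.n_pops)),
                    sim.anomaly_multiplier,
                )
            )
        table = simulate.gen_poolseq(positions, freqs, sc, reference=ref)
        fasta = os.path.join(out, "reference.fa")
        gff = os.path.join(out, "annotation.gff3")
        ref.to_fasta(fasta)
        ref.to_gff3(gff)
        contig_lengths = dict(sc.genome)
        table.to_vcf(os.path.join(out, "snps.vcf"), contig_lengths)
        table.to_sync(os.path.join(out, "snps.sync"))
        truth.to_json(os.path.join(out, "truth.json"))
        simulate.write_covariates(sc, os.path.join(out, "covariates.tsv"))

        stage = "filter"
        table = read_snp_table(os.path.join(out, "snps.vcf"), "vcf",
                               pools=table.pools)
        fres = filter_snps(table, config.filter.min_qual, config.filter.min_cov)
        table = fres.table
        summary["filter"] = {
            "n_snps": table.n_snps,
            "removed_qual": fres.n_removed_qual,
            "removed_cov": fres.n_removed_cov,
        }

        stage = "degeneracy"
        ff = fourfold_sites(fasta, gff)
        ff.to_bed(os.path.join(out, "fourfold.bed"))
        neutral = ff.mask(table.sites["contig"], table.sites["pos"])
        summary["n_fourfold_sites"] = int(ff.n_sites)
        summary["n_neutral_snps"] = int(neutral.sum())

        stage = "omega"
        fmat, depth = allele_freqs(table)
        zhat, keep = covscan.standardize_freqs(fmat, depth)
        neutral_kept = neutral[keep]
        if neutral_kept.sum() >= sc.n_pops + 1:
            omega = covscan.estimate_omega(zhat[neutral_kept])
        else:
            log.warning("too few neutral SNPs; estimating omega on all SNPs")
            omega = covscan.estimate_omega(zhat)
        pd.DataFrame(omega.matrix, index=table.pool_names,
                     columns=table.pool_names).to_csv(
            os.path.join(out, "omega.tsv"), sep="\t")
        summary["omega_n_snps"] = omega.n_snps

        stage = "scan"
        kept_sites = table.sites.loc[keep].reset_index(drop=True)
        xtx_vals = covscan.xtx(zhat, omega)
        xtx_track = pd.DataFrame(
            {"contig": kept_sites["contig"], "pos": kept_sites["pos"],
             "value": xtx_vals}
        )
        xtx_track.to_csv(os.path.join(out, "xtx.tsv"), sep="\t", index=False)
        cov_df = pd.DataFrame(covariates, index=table.pool_names).drop(
            columns=["lat", "long"]
        )
        covset = covscan.collapse_covariates(
            cov_df, config.scan.corr_threshold
        )
        bf_summary = {}
        for name in covset.names:
            bf = covscan.bayes_factor(
                zhat, covset.values[name].to_numpy(), omega,
                config.scan.prior_var,
            )
            track = pd.DataFrame(
                {"contig": kept_sites["contig"], "pos": kept_sites["pos"],
                 "value": bf}
            )
            safe = name.replace("/", "_")
            track.to_csv(os.path.join(out, f"bf_{safe}.tsv"), sep="\t",
                         index=False)
            bf_summary[name] = {
                "max_bf": float(np.max(bf)),
                "n_above_cutoff": int(np.sum(bf > config.scan.bf_cutoff)),
            }
        summary["bayes_factors"] = bf_summary

        stage = "fst"
        fst = differentiation.pooled_fst(table)
        fst.pairwise.to_csv(os.path.join(out, "pairwise_fst.tsv"), sep="\t")
        summary["fst_global"] = fst.global_fst
        coords = pd.DataFrame(
            {"lat": covariates["lat"], "long": covariates["long"]},
            index=table.pool_names,
        )
        ibd_full = differentiation.ibd_regression(fst.pairwise, coords)
        summary["ibd"] = {"slope": ibd_full.slope,
                          "intercept": ibd_full.intercept,
                          "r_squared": ibd_full.r_squared}
        if config.fst.exclude:
            ibd_ex = differentiation.ibd_regression(
                fst.pairwise, coords, exclude=config.fst.exclude
            )
            summary["ibd_excluded"] = {"excluded": config.fst.exclude,
                                       "slope": ibd_ex.slope,
                                       "intercept": ibd_ex.intercept,
                                       "r_squared": ibd_ex.r_squared}

        stage = "peaks"
        preset = XTX_PRESET if config.peaks.preset == "xtx" else FST_PRESET
        params = HmmParams(preset.bg_mean, preset.bg_sd, preset.diff_mean,
                           preset.diff_sd, config.peaks.trans_prob)
        regions = call_regions_track(xtx_track, params,
                                     merge_gap=config.peaks.merge_gap)
        regions = annotate_regions(regions, gff, flank=config.peaks.flank)
        regions_to_frame(regions).to_csv(
            os.path.join(out, "regions.tsv"), sep="\t", index=False
        )
        summary["regions"] = regions_summary(regions)

        stage = "coverage"
        depth_track = pd.concat(
            [table.sites[["contig", "pos"]],
             pd.DataFrame(table.depth(), columns=table.pool_names)],
            axis=1,
        )
        tiles = tile_coverage(depth_track, contig_lengths,
                              config.coverage.tile_bp)
        if regions:
            oc = overcoverage_test(tiles, regions,
                                   config.coverage.overall_alpha)
            oc.flags.to_csv(os.path.join(out, "coverage_flags.tsv"),
                            sep="\t", index=False)
            summary["coverage"] = {
                "n_tests": oc.n_tests,
                "per_test_alpha": oc.per_test_alpha,
                "frac_tiles_flagged": oc.frac_tiles_flagged,
                "frac_genome_significant": oc.frac_genome_significant,
            }
        else:
            summary["coverage"] = None

        stage = "power"
        if regions:
            power = downsample_power(
                xtx_track, regions, params, config.power.fractions,
                config.power.n_reps, seed=config.seed + 101,
                merge_gap=config.peaks.merge_gap,
            )
            power.to_csv(os.path.join(out, "power.tsv"), sep="\t",
                         index=False)
            summary["power"] = {
                str(f): float(g["recovery_pct"].mean())
                for f, g in power.groupby("fraction")
            }
        else:
            summary["power"] = None

        stage = "diversity"
        win = diversity.window_theta_pi(
            table, pop=config.diversity.pop,
            window_bp=config.diversity.window_bp,
            contig_lengths=contig_lengths,
        )
        win.to_csv(os.path.join(out, "diversity.tsv"), sep="\t", index=False)
        occupied = win[win["S"] > 0]
        theta_hat = float(occupied["theta_w"].mean())
        pi_hat = float(occupied["pi"].mean())
        summary["theta"] = theta_hat
        summary["pi"] = pi_hat
        summary["theta_pi_ratio"] = diversity.theta_pi_ratio(theta_hat, pi_hat)

        stage = "ld"
        pairs = simulate.gen_read_pairs(
            rho_per_bp=config.ld.rho_per_bp,
            ne_sim=config.ld.ne_sim,
            window_bp=config.ld.window_bp,
            n_windows=config.ld.n_windows,
            depth=config.ld.depth,
            max_dist=config.ld.max_dist,
            seed=config.seed + 211,
        )
        decay = linkage.ld_decay(pairs, bin_width=config.ld.bin_width,
                                 max_dist=config.ld.max_dist)
        decay.to_frame().to_csv(os.path.join(out, "ld_decay.tsv"),
                                sep="\t", index=False)
        n_eff = diversity.effective_chromosomes(config.ld.depth,
                                                2 * config.ld.ne_sim)
        rho_fit = linkage.fit_rho(decay, sample_chroms=n_eff,
                                  seed=config.seed + 307)
        summary["rho_per_bp"] = rho_fit.rho_per_bp
        summary["rho_ci"] = [rho_fit.ci_low, rho_fit.ci_high]

        stage = "map"
        genome_bp = config.map.genome_bp or float(
            sum(length for _, length in sc.genome)
        )
        est = linkage.map_chain(
            theta_hat, rho_fit.rho_per_bp, genome_bp,
            mu=config.map.mu, frac_amphigenic=config.map.frac_amphigenic,
        )
        summary["map"] = est.to_dict()
        with open(os.path.join(out, "map.json"), "w") as fh:
            json.dump(est.to_dict(), fh, indent=1, sort_keys=True)

        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
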