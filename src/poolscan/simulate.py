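"""Synthetic Poolseq study generator.

Emulates the data layout of a pooled-sequencing survey of isolated
metapopulation demes (vernal-pool crustacean pools of ~100 diploids each,
~70x coverage, ~1 SNP per 85 bp): a reference genome with gene models,
hierarchically covarying population allele frequencies, pooled read counts,
spiked differentiated regions, population-specific coverage anomalies, and
read-pair observations for LD estimation. Every draw flows from a single
seed and all outputs carry ground truth for recovery tests.

The allele-frequency model is the Gaussian shared-ancestry approximation:
an ancestral frequency pi is drawn per SNP from Beta(0.8, 0.8) (clipped to
[0.01, 0.99] to keep the Gaussian approximation honest), and population
frequencies are MVN(pi * 1, pi(1-pi) * Omega) truncated to [0, 1], where
Omega is the population covariance of standardized frequencies. This is
exactly the null model the covariance-corrected differentiation scan
assumes, which makes the generator the natural calibration instrument for
it.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np
import pandas as pd
from Bio import Phylo

from .pooldata import SnpTable

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SpikedRegion",
    "CoverageAnomaly",
    "ReferenceSet",
    "resolve_omega",
    "gen_reference",
    "gen_frequencies",
    "gen_poolseq",
    "gen_read_pairs",
    "gen_stat_track",
    "write_covariates",
]

# Minimum contig length able to host one gene model (see gen_reference).
_MIN_CONTIG = 4000


def resolve_omega(omega_spec, n_pops: int) -> np.ndarray:
    """Resolve an omega specification into a symmetric PD matrix.

    Accepts an explicit matrix, ``("identity", c)`` for c*I, or a newick
    string whose branch lengths are drift amounts: Omega[i,j] is the shared
    root-to-MRCA drift of leaves i and j (leaf order = newick order).
    """
    if isinstance(omega_spec, str):
        tree = Phylo.read(io.StringIO(omega_spec), "newick")
        leaves = tree.get_terminals()
        if len(leaves) != n_pops:
            raise ValueError(
                f"tree has {len(leaves)} leaves but n_pops={n_pops}"
            )
        depths = tree.depths(unit_branch_lengths=False)
        omega = np.empty((n_pops, n_pops))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i == j:
                    omega[i, j] = depths[a]
                else:
                    mrca = tree.common_ancestor(a, b)
                    omega[i, j] = depths[mrca]
    elif isinstance(omega_spec, tuple) and omega_spec[0] == "identity":
        omega = float(omega_spec[1]) * np.eye(n_pops)
    else:
        omega = np.asarray(omega_spec, dtype=float)
    if omega.shape != (n_pops, n_pops):
        raise ValueError(f"omega shape {omega.shape} != ({n_pops},{n_pops})")
    if not np.allclose(omega, omega.T):
        raise ValueError("omega not symmetric")
    eigs = np.linalg.eigvalsh(omega)
    # PSD suffices for generation (Omega = 0 is the no-drift limit)
    if eigs[0] < -1e-10:
        raise ValueError(
            f"omega not positive semidefinite: smallest eigenvalue "
            f"{eigs[0]:.3g}"
        )
    return omega


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults follow the emulated survey design: pools of 100 diploids,
    70x mean coverage per pool, one SNP per 85 bp, spiked differentiated
    regions 1-2,600 bp wide.
    """

    n_pops: int = 11
    pool_diploids: int = 100
    genome: Sequence[tuple[str, int]] = (("C0001", 400_000), ("C0002", 300_000))
    snp_density: float = 1.0 / 85.0
    mean_coverage: float = 70.0
    seq_error: float = 0.001
    omega_spec: object = ("identity", 0.05)
    n_spiked_regions: int = 8
    spike_width_range: tuple[int, int] = (1, 2600)
    spike_min_snps: int = 5
    spike_effect: float = 0.5
    spike_covariate: str | None = None
    coverage_anomaly_spec: list = field(default_factory=list)
    covariates: dict[str, Sequence[float]] = field(default_factory=dict)
    depth_overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("contig lengths must be positive")
        if not (0.0 <= self.seq_error < 0.01):
            raise ValueError("seq_error must be in [0, 0.01)")
        max_len = max(length for _, length in self.genome)
        if self.spike_width_range[1] > max_len:
            raise ValueError("spike widths exceed genome bounds")
        for name, vals in self.covariates.items():
            if len(vals) != self.n_pops:
                raise ValueError(f"covariate {name!r} has wrong length")
        # resolve early so invalid specs fail at config time
        self.omega = resolve_omega(self.omega_spec, self.n_pops)

    @property
    def pool_chroms(self) -> int:
        return 2 * self.pool_diploids

    @property
    def pop_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named stream of this config's seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )


@dataclass
class SpikedRegion:
    contig: str
    start: int  # 1-based first position
    end: int    # 1-based last position + 1 (width = end - start)
    pops: list[int]
    effect: float


@dataclass
class CoverageAnomaly:
    contig: str
    start: int
    end: int
    pop: int
    multiplier: float


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the data for recovery tests."""

    spiked_regions: list[SpikedRegion]
    true_omega: np.ndarray
    true_theta: float
    true_rho_per_bp: float | None
    true_pool_freqs: np.ndarray  # (n_snps, n_pops), pre-sampling frequencies
    pi_anc: np.ndarray | None = None  # per-SNP ancestral frequency

    def to_json(self, path: str) -> None:
        obj = {
            "spiked_regions": [
                {"contig": r.contig, "start": r.start, "end": r.end,
                 "pops": list(map(int, r.pops)), "effect": r.effect}
                for r in self.spiked_regions
            ],
            "true_omega": self.true_omega.tolist(),
            "true_theta": self.true_theta,
            "true_rho_per_bp": self.true_rho_per_bp,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------- reference


@dataclass
class ReferenceSet:
    """In-memory reference genome plus gene models."""

    sequences: dict[str, str]
    gff_lines: list[str]

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            fh.write("\n".join(self.gff_lines) + "\n")


def _gff(contig, ftype, start, end, strand, phase, attrs) -> str:
    return "\t".join(
        [contig, "poolscan_sim", ftype, str(start), str(end), ".", strand,
         str(phase), attrs]
    )


def gen_reference(config: SimConfig) -> ReferenceSet:
    """Random-composition contigs with CDS gene models on both strands.

    Gene models are deliberately simple (mostly single-exon CDS, one
    two-exon gene to exercise GFF phase, and one pair of overlapping
    transcripts in different reading frames to exercise the
    all-overlapping-transcripts degeneracy rule). Deterministic given the
    config seed.
    """
    rng = config.rng(0)
    if min(length for _, length in config.genome) < _MIN_CONTIG:
        raise ValueError(
            f"every contig must be at least {_MIN_CONTIG} bp to host a gene"
        )
    sequences: dict[str, str] = {}
    gff: list[str] = []
    gene_no = 0
    for ci, (contig, length) in enumerate(config.genome):
        comp = rng.dirichlet([10.0, 10.0, 10.0, 10.0])
        seq = rng.choice(list("ACGT"), size=length, p=comp)
        sequences[contig] = "".join(seq)
        # single-exon genes every ~4 kb, alternating strand
        pos = 600
        while pos + 900 < length - 600:
            gene_no += 1
            gid = f"g{gene_no:04d}"
            strand = "+" if gene_no % 2 else "-"
            start, end = pos, pos + 899  # 900 bp, divisible by 3
            gff.append(_gff(contig, "gene", start, end, strand, ".", f"ID={gid}"))
            gff.append(
                _gff(contig, "mRNA", start, end, strand, ".",
                     f"ID={gid}.t1;Parent={gid}")
            )
            gff.append(
                _gff(contig, "CDS", start, end, strand, 0,
                     f"ID={gid}.t1.cds;Parent={gid}.t1")
            )
            pos += 4000
        if ci == 0:
            # overlapping pair in different frames on the first contig
            gene_no += 1
            ga = f"g{gene_no:04d}"
            a0, a1 = 2001, 2900  # 900 bp
            gene_no += 1
            gb = f"g{gene_no:04d}"
            b0, b1 = 2102, 2701  # 600 bp, offset 101 => different frame
            for gid, s, e in ((ga, a0, a1), (gb, b0, b1)):
                gff.append(_gff(contig, "gene", s, e, "+", ".", f"ID={gid}"))
                gff.append(
                    _gff(contig, "mRNA", s, e, "+", ".",
                         f"ID={gid}.t1;Parent={gid}")
                )
                gff.append(
                    _gff(contig, "CDS", s, e, "+", 0,
                         f"ID={gid}.t1.cds;Parent={gid}.t1")
                )
            # one two-exon gene exercising non-zero CDS phase
            gene_no += 1
            gx = f"g{gene_no:04d}"
            e1s, e1e = 100, 199  # 100 bp -> next phase (3 - 100 % 3) % 3 = 2
            e2s, e2e = 300, 499  # 200 bp, total 300
            gff.append(_gff(contig, "gene", e1s, e2e, "+", ".", f"ID={gx}"))
            gff.append(
                _gff(contig, "mRNA", e1s, e2e, "+", ".",
                     f"ID={gx}.t1;Parent={gx}")
            )
            gff.append(
                _gff(contig, "CDS", e1s, e1e, "+", 0,
                     f"ID={gx}.t1.cds1;Parent={gx}.t1")
            )
            gff.append(
                _gff(contig, "CDS", e2s, e2e, "+", 2,
                     f"ID={gx}.t1.cds2;Parent={gx}.t1")
            )
    return ReferenceSet(sequences, gff)


# -------------------------------------------------------------- frequencies


def gen_frequencies(
    config: SimConfig,
) -> tuple[pd.DataFrame, np.ndarray, SyntheticTruth]:
    """Draw SNP positions and per-population allele frequencies.

    Returns ``(positions, freqs, truth)`` where positions is a DataFrame
    (contig, pos) sorted genomically, freqs has shape (n_snps, n_pops), and
    truth records the spiked regions, Omega and the pre-sampling pool
    frequencies. Spiked regions displace affected populations' frequencies
    by the configured effect (clamped to [0,1]); each spiked region is
    guaranteed to contain at least ``spike_min_snps`` SNPs (extra positions
    are injected if the uniform draw left too few).
    """
    rng = config.rng(1)
    omega = config.omega
    # PSD square root (cholesky would reject the Omega = 0 limit)
    w, v = np.linalg.eigh(omega)
    chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    per_contig: dict[str, np.ndarray] = {}
    for contig, length in config.genome:
        n = rng.binomial(length, config.snp_density)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        per_contig[contig] = pos

    # spiked regions, then SNP injection so every region holds >= min SNPs
    lengths = np.array([length for _, length in config.genome], dtype=float)
    spiked: list[SpikedRegion] = []
    for _ in range(config.n_spiked_regions):
        ci = rng.choice(len(config.genome), p=lengths / lengths.sum())
        contig, length = config.genome[ci]
        width = int(
            rng.integers(config.spike_width_range[0],
                         config.spike_width_range[1] + 1)
        )
        width = max(width, config.spike_min_snps)  # must hold min_snps sites
        start = int(rng.integers(1, length - width + 1))
        end = start + width
        if config.spike_covariate is not None:
            pops = list(range(config.n_pops))
        else:
            k = int(rng.integers(1, max(2, config.n_pops // 3) + 1))
            pops = sorted(rng.choice(config.n_pops, size=k, replace=False))
        spiked.append(SpikedRegion(contig, start, end, list(pops),
                                   config.spike_effect))
        pos = per_contig[contig]
        inside = (pos >= start) & (pos < end)
        deficit = config.spike_min_snps - int(inside.sum())
        if deficit > 0:
            have = set(pos.tolist())
            candidates = [p for p in range(start, end) if p not in have]
            extra = rng.choice(len(candidates), size=deficit, replace=False)
            new = np.sort(
                np.concatenate([pos, np.array([candidates[i] for i in extra])])
            )
            per_contig[contig] = new

    frames = [
        pd.DataFrame({"contig": contig, "pos": per_contig[contig]})
        for contig, _ in config.genome
    ]
    positions = pd.concat(frames, ignore_index=True)
    n_snps = len(positions)

    pi_anc = np.clip(rng.beta(0.8, 0.8, size=n_snps), 0.01, 0.99)
    z = rng.standard_normal((n_snps, config.n_pops)) @ chol.T
    freqs = pi_anc[:, None] + np.sqrt(pi_anc * (1 - pi_anc))[:, None] * z
    freqs = np.clip(freqs, 0.0, 1.0)

    if config.spike_covariate is not None:
        cvals = np.asarray(config.covariates[config.spike_covariate], float)
        cz = (cvals - cvals.mean()) / cvals.std()
    for region in spiked:
        mask = (
            (positions["contig"] == region.contig)
            & (positions["pos"] >= region.start)
            & (positions["pos"] < region.end)
        ).to_numpy()
        if config.spike_covariate is not None:
            freqs[np.ix_(mask, range(config.n_pops))] = np.clip(
                freqs[mask] + region.effect * cz[None, :], 0.0, 1.0
            )
        else:
            base = freqs[mask][:, region.pops]
            shift = np.where(base < 0.5, region.effect, -region.effect)
            freqs[np.ix_(mask, region.pops)] = np.clip(base + shift, 0.0, 1.0)

    # realized per-bp diversity of the metapopulation mean frequency
    genome_bp = float(lengths.sum())
    pbar = freqs.mean(axis=1)
    true_theta = float(np.sum(2 * pbar * (1 - pbar)) / genome_bp)
    truth = SyntheticTruth(spiked, omega.copy(), true_theta, None,
                           freqs.copy(), pi_anc.copy())
    return positions, freqs, truth


# ----------------------------------------------------------------- poolseq


def gen_poolseq(
    positions: pd.DataFrame,
    freqs: np.ndarray,
    config: SimConfig,
    reference: ReferenceSet | None = None,
) -> SnpTable:
    """Sample pooled read counts from population frequencies.

    Per site and pool: the pool's realized frequency is
    Binomial(2*pool_diploids, p) / (2*pool_diploids); read depth is
    Poisson(mean_coverage * anomaly multiplier) (Gamma-mixed when
    ``depth_overdispersion`` > 0); the alternate read count is
    Binomial(depth, pool frequency with symmetric error flips).
    """
    rng = config.rng(2)
    n_snps, n_pops = freqs.shape
    chroms = config.pool_chroms
    pool_freq = rng.binomial(chroms, np.clip(freqs, 0, 1)) / chroms

    lam = np.full((n_snps, n_pops), config.mean_coverage)
    for a in config.coverage_anomaly_spec:
        if not isinstance(a, CoverageAnomaly):
            a = CoverageAnomaly(*a)
        mask = (
            (positions["contig"] == a.contig)
            & (positions["pos"] >= a.start)
            & (positions["pos"] < a.end)
        ).to_numpy()
        lam[mask, a.pop] *= a.multiplier
    if config.depth_overdispersion > 0:
        k = 1.0 / config.depth_overdispersion
        lam = rng.gamma(k, lam / k)
    depth = rng.poisson(lam)

    e = config.seq_error
    p_obs = pool_freq * (1 - e) + (1 - pool_freq) * e
    alt = rng.binomial(depth, p_obs)
    ref = depth - alt

    qual = 30.0 + rng.exponential(300.0, size=n_snps)
    qual[rng.random(n_snps) < 0.05] = rng.uniform(5, 30)  # some failing sites

    bases = list("ACGT")
    if reference is not None:
        ref_base = np.array(
            [reference.sequences[c][p - 1]
             for c, p in zip(positions["contig"], positions["pos"])]
        )
    else:
        ref_base = rng.choice(bases, size=n_snps)
    alt_base = np.array(
        [bases[(bases.index(b) + int(s)) % 4]
         for b, s in zip(ref_base, rng.integers(1, 4, size=n_snps))]
    )

    sites = pd.DataFrame(
        {
            "contig": positions["contig"].to_numpy(),
            "pos": positions["pos"].to_numpy(),
            "ref": ref_base,
            "alt": alt_base,
            "qual": qual,
        }
    )
    pools = pd.DataFrame(
        {"pool_diploids": [config.pool_diploids] * n_pops},
        index=config.pop_names,
    )
    for name, vals in config.covariates.items():
        if name in ("lat", "long"):
            pools[name] = list(vals)
    return SnpTable(sites, ref, alt, pools)


def write_covariates(config: SimConfig, path: str) -> None:
    """Write the per-population covariate table (populations x variables)."""
    df = pd.DataFrame(config.covariates, index=config.pop_names)
    df.index.name = "pop"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------- read pairs


def gen_read_pairs(
    rho_per_bp: float,
    ne_sim: int = 100,
    window_bp: int = 5000,
    n_windows: int = 20,
    depth: int = 70,
    max_dist: int = 400,
    theta_per_bp: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired-site read observations for LD estimation.

    A haplotype pool of 2*ne_sim chromosomes is simulated per window under
    per-bp recombination r = rho_per_bp / (4*ne_sim) and mutation (coalescent
    sample of the whole deme), then ``depth`` reads covering each pair of
    SNPs <= ``max_dist`` bp apart are drawn with replacement from the pool.
    Returns one row per pair: window, pos1, pos2, dist, the four two-site
    gamete-class read counts, and the pool-truth r2.
    """
    if rho_per_bp <= 0:
        raise ValueError("rho_per_bp must be positive")
    r = rho_per_bp / (4.0 * ne_sim)
    mu = theta_per_bp / (4.0 * ne_sim)
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples=ne_sim,
        population_size=ne_sim,
        recombination_rate=r,
        sequence_length=window_bp,
        num_replicates=n_windows,
        random_seed=seed + 1,
    )
    rows = []
    for w, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seed + 1000 + w,
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix()  # (sites, 2*ne_sim), 0/1
        pos = np.array([s.position for s in mts.sites()])
        # keep strictly biallelic 0/1 sites
        ok = (geno.max(axis=1) <= 1) & (geno.min(axis=1) >= 0)
        poly = geno.sum(axis=1)
        ok &= (poly > 0) & (poly < geno.shape[1])
        geno, pos = geno[ok], pos[ok]
        if geno.shape[0] < 2:
            warnings.warn(f"window {w}: fewer than 2 SNPs, skipped",
                          stacklevel=2)
            continue
        n_hap = geno.shape[1]
        for i in range(geno.shape[0]):
            for j in range(i + 1, geno.shape[0]):
                d = pos[j] - pos[i]
                if d > max_dist:
                    break
                if d < 1:
                    continue
                ga, gb = geno[i], geno[j]
                fa, fb = ga.mean(), gb.mean()
                fab = (ga & gb).mean()
                dd = fab - fa * fb
                denom = fa * (1 - fa) * fb * (1 - fb)
                true_r2 = dd * dd / denom
                draw = rng.integers(0, n_hap, size=depth)
                a, b = ga[draw], gb[draw]
                rows.append(
                    {
                        "window": w,
                        "pos1": float(pos[i]),
                        "pos2": float(pos[j]),
                        "dist": float(d),
                        "n_AB": int(np.sum((a == 1) & (b == 1))),
                        "n_Ab": int(np.sum((a == 1) & (b == 0))),
                        "n_aB": int(np.sum((a == 0) & (b == 1))),
                        "n_ab": int(np.sum((a == 0) & (b == 0))),
                        "true_r2": float(true_r2),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["window", "pos1", "pos2", "dist",
                 "n_AB", "n_Ab", "n_aB", "n_ab", "true_r2"],
    )


# ------------------------------------------------------------- stat tracks


def gen_stat_track(
    genome: Sequence[tuple[str, int]] = (("C0001", 10_000_000),),
    snp_density: float = 1.0 / 85.0,
    bg: tuple[float, float] = (20.0, 9.0),
    diff: tuple[float, float] = (100.0, 200.0),
    n_spikes: int = 19,
    spike_width_range: tuple[int, int] = (1, 2600),
    spike_min_snps: int = 5,
    trunc_quantile: float = 0.999,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SpikedRegion]]:
    """Simulate a per-SNP statistic track with spiked differentiated regions.

    Background values are Normal(bg); each of ``n_spikes`` non-overlapping
    regions (widths drawn from ``spike_width_range``, widened minimally so
    each holds >= ``spike_min_snps`` SNPs) gets values from Normal(diff)
    truncated below at the background's ``trunc_quantile`` quantile, so
    spiked SNPs are genuinely elevated. Returns the track (contig, pos,
    value) and the spiked-region truth.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    frames, regions = [], []
    lo = stats.norm.ppf(trunc_quantile, loc=bg[0], scale=bg[1])
    a = (lo - diff[0]) / diff[1]
    for contig, length in genome:
        n = rng.binomial(length, snp_density)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        frames.append(pd.DataFrame({"contig": contig, "pos": pos}))
    track = pd.concat(frames, ignore_index=True)
    lengths = np.array([length for _, length in genome], dtype=float)

    taken: list[tuple[str, int, int]] = []
    attempts = 0
    while len(regions) < n_spikes:
        attempts += 1
        if attempts > 100 * n_spikes:
            raise RuntimeError("could not place non-overlapping spiked regions")
        ci = rng.choice(len(genome), p=lengths / lengths.sum())
        contig, length = genome[ci]
        width = int(rng.integers(spike_width_range[0], spike_width_range[1] + 1))
        width = max(width, spike_min_snps)
        start = int(rng.integers(1, length - width + 1))
        end = start + width
        if any(c == contig and s < end + 200 and start < e + 200
               for c, s, e in taken):
            continue
        taken.append((contig, start, end))
        mask = (
            (track["contig"] == contig)
            & (track["pos"] >= start)
            & (track["pos"] < end)
        ).to_numpy()
        deficit = spike_min_snps - int(mask.sum())
        if deficit > 0:
            have = set(track.loc[track.contig == contig, "pos"].tolist())
            cand = [p for p in range(start, end) if p not in have]
            extra = [cand[i] for i in
                     rng.choice(len(cand), size=deficit, replace=False)]
            track = pd.concat(
                [track, pd.DataFrame({"contig": contig, "pos": extra})],
                ignore_index=True,
            )
        regions.append(SpikedRegion(contig, start, end, [], float("nan")))

    track = track.sort_values(["contig", "pos"]).reset_index(drop=True)
    values = rng.normal(bg[0], bg[1], size=len(track))
    for reg in regions:
        mask = (
            (track["contig"] == reg.contig)
            & (track["pos"] >= reg.start)
            & (track["pos"] < reg.end)
        ).to_numpy()
        values[mask] = stats.truncnorm.rvs(
            a, np.inf, loc=diff[0], scale=diff[1], size=int(mask.sum()),
            random_state=rng,
        )
    track["value"] = values
    return track, regions
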