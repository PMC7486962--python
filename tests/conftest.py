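"""Shared fixtures: a small synthetic study, a written reference, and a
neutral msprime pool simulation reused by the diversity checks."""

from __future__ import annotations

import msprime
import numpy as np
import pandas as pd
import pytest

from poolscan import simulate
from poolscan.pooldata import SnpTable


def make_table(ref_counts, alt_counts, positions=None, contig="C1",
               quals=None, pool_diploids=100):
    """Build a SnpTable from count matrices (test helper)."""
    ref_counts = np.atleast_2d(np.asarray(ref_counts))
    alt_counts = np.atleast_2d(np.asarray(alt_counts))
    n, p = ref_counts.shape
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "qual": 60.0 if quals is None else quals,
        }
    )
    pools = pd.DataFrame(
        {"pool_diploids": [pool_diploids] * p},
        index=[f"P{i + 1:02d}" for i in range(p)],
    )
    return SnpTable(sites, ref_counts, alt_counts, pools)


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(
        n_pops=5,
        genome=[("C0001", 80_000), ("C0002", 50_000)],
        n_spiked_regions=3,
        seed=11,
        covariates={
            "lat": [32.0, 32.5, 33.0, 33.5, 34.0],
            "long": [-107.0, -106.5, -106.0, -105.5, -105.0],
        },
    )


@pytest.fixture(scope="session")
def reference(sim_config, tmp_path_factory):
    ref = simulate.gen_reference(sim_config)
    d = tmp_path_factory.mktemp("ref")
    fasta, gff = d / "ref.fa", d / "ref.gff3"
    ref.to_fasta(str(fasta))
    ref.to_gff3(str(gff))
    return ref, str(fasta), str(gff)


@pytest.fixture(scope="session")
def synthetic_study(sim_config):
    positions, freqs, truth = simulate.gen_frequencies(sim_config)
    table = simulate.gen_poolseq(positions, freqs, sim_config)
    return positions, freqs, truth, table


def simulate_neutral_pool(
    theta: float,
    n_windows: int,
    window_bp: int,
    pool_chroms: int = 200,
    depth: float = 70.0,
    seed: int = 0,
) -> SnpTable:
    """Coalescent oracle for the pooled diversity estimators.

    Each window is an independent neutral coalescent sample of
    ``pool_chroms`` chromosomes at per-bp theta; pooled reads are Poisson
    depth with binomial allele sampling. Windows are emitted as separate
    contigs named w0, w1, ...
    """
    N = 10_000
    mu = theta / (4 * N)
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples=pool_chroms // 2,
        population_size=N,
        sequence_length=window_bp,
        num_replicates=n_windows,
        random_seed=seed + 1,
    )
    frames, refs, alts = [], [], []
    for w, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seed + 100 + w,
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix()
        pos = np.array([int(s.position) + 1 for s in mts.sites()])
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = pos[1:] != pos[:-1]  # one record per site
        geno, pos = geno[keep], pos[keep]
        p = geno.mean(axis=1)
        c = rng.poisson(depth, size=len(p))
        c = np.maximum(c, 10)
        a = rng.binomial(c, p)
        seen = (a > 0) & (a < c)  # segregating among the sampled reads
        frames.append(pd.DataFrame({"contig": f"w{w}", "pos": pos[seen]}))
        refs.append((c - a)[seen])
        alts.append(a[seen])
    sites = pd.concat(frames, ignore_index=True)
    sites["ref"], sites["alt"], sites["qual"] = "A", "T", 60.0
    pools = pd.DataFrame({"pool_diploids": [pool_chroms // 2]}, index=["P01"])
    return SnpTable(
        sites[["contig", "pos", "ref", "alt", "qual"]],
        np.concatenate(refs)[:, None],
        np.concatenate(alts)[:, None],
        pools,
    )


@pytest.fixture(scope="session")
def neutral_pool_table():
    # 100 10-kb windows at theta = 0.005, 200 chromosomes, 70x
    return simulate_neutral_pool(0.005, 100, 10_000, seed=42)
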