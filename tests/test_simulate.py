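"""Generator correctness: determinism, reference structure, the Gaussian
allele-frequency model's moments, pooled read sampling, and read pairs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from poolscan import simulate
from poolscan.covscan import matrix_correlation


def _cfg(**kw):
    base = dict(
        n_pops=4,
        genome=[("C1", 50_000)],
        n_spiked_regions=2,
        seed=3,
    )
    base.update(kw)
    return simulate.SimConfig(**base)


# ------------------------------------------------------------ validation


def test_config_rejects_bad_values():
    with pytest.raises(ValueError, match="seq_error"):
        _cfg(seq_error=0.05)
    with pytest.raises(ValueError, match="exceed"):
        _cfg(genome=[("C1", 2000)], spike_width_range=(1, 2600))
    with pytest.raises(ValueError, match="positive"):
        _cfg(genome=[("C1", 0)])


def test_non_psd_omega_names_offending_eigenvalue():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.raises(ValueError, match="-1"):
        simulate.resolve_omega(bad, 2)


def test_omega_from_tree_shared_branch_lengths():
    omega = simulate.resolve_omega("((a:0.1,b:0.1):0.2,c:0.3):0;", 3)
    np.testing.assert_allclose(np.diag(omega), [0.3, 0.3, 0.3])
    assert omega[0, 1] == pytest.approx(0.2)
    assert omega[0, 2] == pytest.approx(0.0)


# ------------------------------------------------------------- reference


def test_reference_deterministic_and_sized(tmp_path):
    cfg = _cfg(genome=[("C1", 20_000), ("C2", 10_000)])
    r1 = simulate.gen_reference(cfg)
    r2 = simulate.gen_reference(cfg)
    assert r1.sequences == r2.sequences
    assert r1.gff_lines == r2.gff_lines
    assert len(r1.sequences["C1"]) == 20_000
    assert len(r1.sequences["C2"]) == 10_000
    f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
    r1.to_fasta(str(f1))
    r2.to_fasta(str(f2))
    assert f1.read_bytes() == f2.read_bytes()


def test_reference_rejects_tiny_contig():
    with pytest.raises(ValueError, match="at least"):
        simulate.gen_reference(_cfg(genome=[("C1", 3000)]))


def test_generated_cds_lengths_divisible_by_three(reference):
    ref, _, _ = reference
    # parse the GFF back and phase-adjust each transcript's CDS
    cds: dict[str, list[tuple[int, int, int]]] = {}
    for line in ref.gff_lines:
        f = line.split("\t")
        if f[2] == "CDS":
            parent = f[8].split("Parent=")[1].split(";")[0]
            cds.setdefault(parent, []).append(
                (int(f[3]), int(f[4]), int(f[7]))
            )
    assert cds
    for parts in cds.values():
        parts.sort()
        total = sum(e - s + 1 for s, e, _ in parts) - parts[0][2]
        assert total % 3 == 0


def test_reference_contains_overlapping_transcripts_in_different_frames(
    reference,
):
    ref, _, _ = reference
    spans = []
    for line in ref.gff_lines:
        f = line.split("\t")
        if f[2] == "mRNA" and f[0] == "C0001":
            spans.append((int(f[3]), int(f[4])))
    overlapping = [
        (a, b)
        for i, a in enumerate(spans)
        for b in spans[i + 1 :]
        if a[0] <= b[1] and b[0] <= a[1]
    ]
    assert any((b[0] - a[0]) % 3 != 0 for a, b in overlapping)


# ----------------------------------------------------------- frequencies


def test_zero_omega_collapses_all_pops_onto_ancestral_frequency():
    cfg = _cfg(omega_spec=np.zeros((4, 4)), n_spiked_regions=0)
    _, freqs, truth = simulate.gen_frequencies(cfg)
    np.testing.assert_allclose(freqs, truth.pi_anc[:, None] @ np.ones((1, 4)))


def test_standardized_frequency_covariance_matches_omega():
    # moment oracle: away from the [0,1] truncation boundary the sample
    # covariance of (p - pi)/sqrt(pi(1-pi)) must reproduce c*I elementwise
    c = 0.04
    cfg = _cfg(
        genome=[("C1", 900_000)],
        snp_density=1 / 60,
        omega_spec=("identity", c),
        n_spiked_regions=0,
        seed=5,
    )
    _, freqs, truth = simulate.gen_frequencies(cfg)
    mid = (truth.pi_anc > 0.2) & (truth.pi_anc < 0.8)
    z = (freqs[mid] - truth.pi_anc[mid, None]) / np.sqrt(
        truth.pi_anc[mid] * (1 - truth.pi_anc[mid])
    )[:, None]
    S = z.shape[0]
    assert S > 3000
    cov = z.T @ z / S
    prods_se = np.sqrt(
        np.array(
            [
                [np.var(z[:, i] * z[:, j]) / S for j in range(4)]
                for i in range(4)
            ]
        )
    )
    target = c * np.eye(4)
    assert np.all(np.abs(cov - target) < 3 * prods_se + 1e-12)


def test_spiked_regions_displace_affected_populations(synthetic_study):
    positions, freqs, truth, _ = synthetic_study
    for reg in truth.spiked_regions:
        inside = (
            (positions["contig"] == reg.contig)
            & (positions["pos"] >= reg.start)
            & (positions["pos"] < reg.end)
        ).to_numpy()
        assert inside.sum() >= 5  # spike_min_snps enforced
        others = [j for j in range(freqs.shape[1]) if j not in reg.pops]
        if not others:
            continue
        gap_in = np.abs(
            freqs[inside][:, reg.pops].mean(axis=1)
            - freqs[inside][:, others].mean(axis=1)
        ).mean()
        gap_bg = np.abs(
            freqs[~inside][:, reg.pops].mean(axis=1)
            - freqs[~inside][:, others].mean(axis=1)
        ).mean()
        assert gap_in > gap_bg + 0.1


# --------------------------------------------------------------- poolseq


def test_fixed_frequency_without_error_yields_pure_alt_reads():
    cfg = _cfg(seq_error=0.0, n_spiked_regions=0)
    pos = pd.DataFrame({"contig": "C1", "pos": np.arange(1, 201)})
    freqs = np.ones((200, 4))
    table = simulate.gen_poolseq(pos, freqs, cfg)
    np.testing.assert_array_equal(table.alt_counts, table.depth())


def test_mean_depth_matches_configured_coverage():
    cfg = _cfg(genome=[("C1", 200_000)], seed=9, n_spiked_regions=0)
    n = 100_000
    pos = pd.DataFrame({"contig": "C1", "pos": np.arange(1, n + 1)})
    freqs = np.full((n, 4), 0.5)
    table = simulate.gen_poolseq(pos, freqs, cfg)
    mean_depth = table.depth().mean()
    se = np.sqrt(70.0 / (n * 4))
    assert abs(mean_depth - 70.0) < max(3 * se, 0.01 * 70)


def test_coverage_anomaly_multiplies_normalized_depth():
    cfg = _cfg(
        genome=[("C1", 100_000)],
        n_spiked_regions=0,
        coverage_anomaly_spec=[("C1", 40_000, 42_000, 1, 3.0)],
        seed=13,
    )
    pos = pd.DataFrame({"contig": "C1", "pos": np.arange(1, 100_001, 10)})
    freqs = np.full((len(pos), 4), 0.5)
    table = simulate.gen_poolseq(pos, freqs, cfg)
    depth = table.depth()
    inside = (pos["pos"] >= 40_000) & (pos["pos"] < 42_000)
    ratio = depth[inside.to_numpy(), 1].mean() / depth[~inside.to_numpy(), 1].mean()
    assert ratio == pytest.approx(3.0, rel=0.05)
    ratio_other = depth[inside.to_numpy(), 0].mean() / depth[~inside.to_numpy(), 0].mean()
    assert ratio_other == pytest.approx(1.0, rel=0.05)


def test_poolseq_counts_bounded_by_depth(synthetic_study):
    *_, table = synthetic_study
    assert (table.alt_counts >= 0).all()
    assert (table.alt_counts <= table.depth()).all()


# ------------------------------------------------------------ read pairs


def test_read_pairs_deterministic_given_seed():
    a = simulate.gen_read_pairs(0.01, ne_sim=50, n_windows=3, seed=21)
    b = simulate.gen_read_pairs(0.01, ne_sim=50, n_windows=3, seed=21)
    pd.testing.assert_frame_equal(a, b)


def test_complete_linkage_pairs_show_two_gamete_classes():
    pairs = simulate.gen_read_pairs(1e-6, ne_sim=50, n_windows=5, seed=8)
    perfect = pairs[pairs["true_r2"] > 1 - 1e-9]
    assert len(perfect) > 0
    counts = perfect[["n_AB", "n_Ab", "n_aB", "n_ab"]].to_numpy()
    assert ((counts > 0).sum(axis=1) <= 2).all()


def test_free_recombination_limit_decays_to_sampling_floor():
    from poolscan.linkage import ld_decay

    tight = simulate.gen_read_pairs(0.004, ne_sim=50, n_windows=8, seed=31)
    loose = simulate.gen_read_pairs(1.0, ne_sim=50, n_windows=8, seed=31)
    d_t = ld_decay(tight)
    d_l = ld_decay(loose)
    far = slice(8, 16)  # 200-400 bp
    assert np.nanmean(d_l.mean_r2[far]) < np.nanmean(d_t.mean_r2[far])
    # near linkage equilibrium the sigma_d^2 level sits at the sampling
    # floor set by the pool size (1/2Ne) plus the residual drift term
    assert np.nanmean(d_l.mean_r2[far]) < 0.08


def test_rejects_nonpositive_rho():
    with pytest.raises(ValueError):
        simulate.gen_read_pairs(0.0)


# ----------------------------------------------------------- determinism


def test_full_generator_chain_deterministic(sim_config):
    cfg2 = dataclasses.replace(sim_config)
    p1, f1, _ = simulate.gen_frequencies(sim_config)
    p2, f2, _ = simulate.gen_frequencies(cfg2)
    pd.testing.assert_frame_equal(p1, p2)
    np.testing.assert_array_equal(f1, f2)
    t1 = simulate.gen_poolseq(p1, f1, sim_config)
    t2 = simulate.gen_poolseq(p2, f2, cfg2)
    np.testing.assert_array_equal(t1.alt_counts, t2.alt_counts)
    np.testing.assert_array_equal(t1.ref_counts, t2.ref_counts)


def test_omega_recovery_from_many_neutral_snps():
    # covariance recovery invariant: matrix correlation with truth > 0.99
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.15, (5, 5))
    omega_true = a @ a.T + 0.05 * np.eye(5)
    cfg = _cfg(
        n_pops=5,
        genome=[("C1", 3_000_000)],
        snp_density=1 / 60,
        omega_spec=omega_true,
        n_spiked_regions=0,
        seed=17,
    )
    from poolscan.covscan import estimate_omega, standardize_freqs

    _, freqs, truth = simulate.gen_frequencies(cfg)
    mid = (truth.pi_anc > 0.15) & (truth.pi_anc < 0.85)
    z = (freqs[mid] - truth.pi_anc[mid, None]) / np.sqrt(
        truth.pi_anc[mid] * (1 - truth.pi_anc[mid])
    )[:, None]
    assert z.shape[0] >= 20_000
    est = estimate_omega(z)
    assert matrix_correlation(est.matrix, omega_true) > 0.99
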