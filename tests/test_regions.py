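"""HMM segmentation: Viterbi against exhaustive search, region merging and
width conventions, emission fitting, and gene annotation."""

import numpy as np
import pytest
from scipy.stats import norm

from poolscan.regions import (
    FST_PRESET,
    XTX_PRESET,
    HmmParams,
    annotate_regions,
    call_regions,
    decode_track,
    fit_emission_params,
    regions_summary,
    viterbi_two_state,
)


def path_logprob(values, states, params):
    """Log probability of one state path (oracle scoring)."""
    logB = np.column_stack(
        [
            norm.logpdf(values, params.bg_mean, params.bg_sd),
            norm.logpdf(values, params.diff_mean, params.diff_sd),
        ]
    )
    t = params.trans_prob
    switches = int(np.sum(states[1:] != states[:-1]))
    return (
        np.log(0.5)
        + float(logB[np.arange(len(values)), states].sum())
        + switches * np.log(t)
        + (len(values) - 1 - switches) * np.log(1 - t)
    )


def brute_force_best(values, params):
    """Maximum path log-probability over all 2^T paths."""
    T = len(values)
    ints = np.arange(2**T, dtype=np.uint32)
    paths = (ints[:, None] >> np.arange(T)) & 1
    logB = np.column_stack(
        [
            norm.logpdf(values, params.bg_mean, params.bg_sd),
            norm.logpdf(values, params.diff_mean, params.diff_sd),
        ]
    )
    emis = logB[np.arange(T)[None, :], paths].sum(axis=1)
    switches = (paths[:, 1:] != paths[:, :-1]).sum(axis=1)
    t = params.trans_prob
    scores = (
        np.log(0.5)
        + emis
        + switches * np.log(t)
        + (T - 1 - switches) * np.log(1 - t)
    )
    return float(scores.max())


def test_params_validated():
    with pytest.raises(ValueError):
        HmmParams(0, -1, 1, 1)
    with pytest.raises(ValueError):
        HmmParams(0, 1, 1, 1, trans_prob=0.7)


def test_background_values_decode_to_background():
    values = np.full(5, XTX_PRESET.bg_mean)
    assert viterbi_two_state(values, XTX_PRESET).tolist() == [0] * 5


def test_single_observation_uses_emission_and_prior():
    assert viterbi_two_state(np.array([20.0]), XTX_PRESET).tolist() == [0]
    assert viterbi_two_state(np.array([500.0]), XTX_PRESET).tolist() == [1]


@pytest.mark.parametrize("preset", [XTX_PRESET, FST_PRESET])
def test_viterbi_equals_exhaustive_search_on_short_tracks(preset):
    rng = np.random.default_rng(99)
    for _ in range(250):
        T = int(rng.integers(1, 13))
        mix = rng.random(T) < 0.3
        values = np.where(
            mix,
            rng.normal(preset.diff_mean, preset.diff_sd, T),
            rng.normal(preset.bg_mean, preset.bg_sd, T),
        )
        states = viterbi_two_state(values, preset)
        assert path_logprob(values, states, preset) == pytest.approx(
            brute_force_best(values, preset), abs=1e-9
        )


def test_viterbi_agrees_with_hmmlearn_reference():
    hmm = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(5)
    values = np.concatenate(
        [
            rng.normal(20, 9, 300),
            rng.normal(100, 200, 30),
            rng.normal(20, 9, 300),
        ]
    )
    p = XTX_PRESET
    model = hmm.GaussianHMM(n_components=2, covariance_type="diag",
                            init_params="", params="")
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.999, 0.001], [0.001, 0.999]])
    model.means_ = np.array([[p.bg_mean], [p.diff_mean]])
    model.covars_ = np.array([[p.bg_sd**2], [p.diff_sd**2]])
    _, ref_states = model.decode(values[:, None], algorithm="viterbi")
    np.testing.assert_array_equal(viterbi_two_state(values, p), ref_states)


def test_injected_differentiated_run_is_detected():
    rng = np.random.default_rng(17)
    values = np.concatenate(
        [
            rng.normal(20, 9, 200),
            rng.normal(100, 200, 10),
            rng.normal(20, 9, 200),
        ]
    )
    states = viterbi_two_state(values, XTX_PRESET)
    assert states[200:210].any()
    assert states[:150].sum() == 0 and states[-150:].sum() == 0


def test_single_snp_region_width_convention():
    # one differentiated SNP at 1,833,709 -> region 1,833,709-1,833,710
    states = np.array([0, 1, 0])
    positions = np.array([1_833_600, 1_833_709, 1_833_800])
    regions = call_regions(states, positions, contig="C0001")
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.width, r.n_snps) == (
        1_833_709, 1_833_710, 1, 1
    )


@pytest.mark.parametrize("gap,n_expected", [(50, 1), (100, 1), (150, 2)])
def test_merge_rule_at_one_hundred_basepairs(gap, n_expected):
    # two differentiated runs separated by `gap` bp with one background
    # SNP between them; runs within 100 bp combine into a single peak
    s2 = 1010 + gap
    positions = np.array([1000, 1010, 1011 + gap // 2, s2, s2 + 10])
    states = np.array([1, 1, 0, 1, 1])
    regions = call_regions(states, positions, merge_gap=100, contig="C1")
    assert len(regions) == n_expected


def test_region_calling_idempotent_and_gaps_exceed_merge_threshold():
    rng = np.random.default_rng(23)
    positions = np.sort(rng.choice(100_000, 800, replace=False)) + 1
    states = (rng.random(800) < 0.15).astype(int)
    a = call_regions(states, positions, merge_gap=100, contig="C1")
    b = call_regions(states, positions, merge_gap=100, contig="C1")
    assert [(r.start, r.end) for r in a] == [(r.start, r.end) for r in b]
    for r1, r2 in zip(a, a[1:]):
        assert r2.start - r1.end > 100
    total_snps = sum(r.n_snps for r in a)
    assert total_snps >= int(states.sum())


def test_decode_track_handles_contigs_independently():
    import pandas as pd

    rng = np.random.default_rng(31)
    track = pd.DataFrame(
        {
            "contig": ["A"] * 50 + ["B"] * 50,
            "pos": list(range(1, 51)) * 2,
            "value": rng.normal(20, 9, 100),
        }
    )
    track.loc[49, "value"] = 800.0  # last SNP of contig A
    decoded = decode_track(track, XTX_PRESET)
    assert decoded.loc[49, "state"] == 1
    assert decoded.loc[50:, "state"].sum() == 0  # contig B untouched


def test_emission_fitting_recovers_preset_parameters():
    rng = np.random.default_rng(41)
    # simulate from the two-state chain at the XtX preset emissions
    T = 10_000
    states = np.empty(T, dtype=int)
    states[0] = 0
    flips = rng.random(T) < 0.001
    for t in range(1, T):
        states[t] = states[t - 1] ^ flips[t]
    values = np.where(
        states == 0, rng.normal(20, 9, T), rng.normal(100, 200, T)
    )
    params, trace = fit_emission_params(values, trans_prob=0.001)
    assert np.all(np.diff(trace) >= -1e-6)  # EM monotone
    assert params.bg_mean == pytest.approx(20, rel=0.15)
    assert params.diff_mean == pytest.approx(100, rel=0.15)
    assert params.bg_sd == pytest.approx(9, rel=0.2)


def test_emission_fitting_falls_back_on_degenerate_data():
    values = np.full(200, 5.0)
    with pytest.warns(UserWarning, match="degenerate"):
        params, _ = fit_emission_params(values, fallback=XTX_PRESET)
    assert params == XTX_PRESET


def _gff(tmp_path, gene_start, gene_end):
    p = tmp_path / "ann.gff3"
    p.write_text(
        "##gff-version 3\n"
        f"C1\tsrc\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\tID=gene1\n"
    )
    return str(p)


@pytest.mark.parametrize(
    "distance,expected", [(4_999, 1), (5_000, 1), (5_001, 0)]
)
def test_annotation_flank_boundary(tmp_path, distance, expected):
    region = call_regions(np.array([1]), np.array([50_000]), contig="C1")
    gene_end = 50_000 - distance
    gff = _gff(tmp_path, gene_end - 500, gene_end)
    out = annotate_regions(region, gff, flank=5000)
    assert out[0].genes_within_5kb == expected


def test_missing_annotation_gives_null_counts_not_zero():
    region = call_regions(np.array([1]), np.array([100]), contig="C1")
    out = annotate_regions(region, None)
    assert out[0].genes_within_5kb is None
    summary = regions_summary(out)
    assert summary["mean_genes_within_5kb"] is None
    assert summary["n_regions"] == 1


def test_summary_reports_arithmetic_means():
    states = np.array([1, 1, 0, 0, 1])
    positions = np.array([100, 150, 400, 800, 1000])
    regions = call_regions(states, positions, contig="C1")
    for i, r in enumerate(regions):
        r.genes_within_5kb = i + 2
    s = regions_summary(regions)
    assert s["n_regions"] == 2
    assert s["mean_width"] == pytest.approx((51 + 1) / 2)
    assert s["mean_genes_within_5kb"] == pytest.approx(2.5)
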