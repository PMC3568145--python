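import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncocis import eis
from oncocis.eis import (
    AMP,
    DEL,
    BackgroundModel,
    ReferenceStats,
    RunConfig,
    analyze,
    build_background,
    combine_stouffer,
    compute_sample_eis,
    observed_gene_eis,
    select_event_samples,
    significance,
    z_score,
)

from conftest import make_dataset


class TestSampleEis:
    def test_zero_deviation_gives_zero(self):
        ref = ReferenceStats(median_ref=5.0, iqr_ref=3.0, iqr_alt=1.0)
        assert compute_sample_eis(5.0, ref, 0.01) == 0.0

    def test_direct_evaluation(self):
        ref = ReferenceStats(median_ref=5.0, iqr_ref=2.0, iqr_alt=2.0)
        assert compute_sample_eis(9.0, ref, 0.01) == pytest.approx(1.0)

    def test_denominator_guard(self):
        ref = ReferenceStats(median_ref=5.0, iqr_ref=0.0, iqr_alt=0.0)
        assert compute_sample_eis(3.0, ref, 0.01) == pytest.approx(-200.0)

    def test_sign_follows_deviation(self):
        ref = ReferenceStats(median_ref=5.0, iqr_ref=1.0, iqr_alt=1.0)
        assert compute_sample_eis(6.0, ref, 0.01) > 0 > compute_sample_eis(4.0, ref, 0.01)


class TestObservedEis:
    @pytest.mark.parametrize(
        "scores,expected",
        [([1.0], 1.0), ([1.0, 3.0], 2.0), ([-2.0, 0.0, 5.0], 0.0)],
    )
    def test_median(self, scores, expected):
        assert observed_gene_eis(scores) == expected

    def test_empty_signals_skip(self):
        with pytest.raises(ValueError):
            observed_gene_eis([])


class TestBackground:
    def test_degenerate_constant_pool(self):
        bg = build_background(np.array([2.5]), n=3, n_reps=100, rng=np.random.default_rng(0))
        assert bg.mean == 2.5 and bg.sd == 0.0

    def test_enumeration_oracle_four_point_pool(self):
        # all 16 ordered draws of n=2 from {0,0,0,10}: mean of medians = 2.5
        pool = np.array([0.0, 0.0, 0.0, 10.0])
        meds = [np.median(t) for t in itertools.product(pool, repeat=2)]
        assert np.mean(meds) == 2.5
        bg = build_background(pool, n=2, n_reps=20_000, rng=np.random.default_rng(1))
        assert bg.mean == pytest.approx(2.5, abs=3 * np.std(meds) / np.sqrt(20_000))

    @pytest.mark.parametrize("seed,n", [(0, 2), (1, 3), (2, 3)])
    def test_enumeration_oracle_random_pools(self, seed, n):
        rng = np.random.default_rng(seed)
        pool = rng.normal(size=rng.integers(2, 7))
        meds = np.array([np.median(t) for t in itertools.product(pool, repeat=n)])
        exact_mean, exact_sd = meds.mean(), meds.std()
        reps = 10_000
        bg = build_background(pool, n=n, n_reps=reps, rng=np.random.default_rng(seed + 10))
        assert bg.mean == pytest.approx(exact_mean, abs=3 * exact_sd / np.sqrt(reps) + 1e-12)
        assert bg.sd == pytest.approx(exact_sd, abs=3 * exact_sd / np.sqrt(2 * (reps - 1)) + 1e-12)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            build_background(np.array([]), 2, 10, np.random.default_rng(0))


class TestZScore:
    def test_observed_equals_mean(self):
        assert z_score(1.0, BackgroundModel(1.0, 0.5, 10)) == 0.0

    def test_direct_arithmetic(self):
        assert z_score(2.0, BackgroundModel(1.0, 0.5, 10)) == pytest.approx(2.0)

    def test_zero_sd_cap(self):
        assert z_score(1.0, BackgroundModel(0.0, 0.0, 10)) == 50.0
        assert z_score(-1.0, BackgroundModel(0.0, 0.0, 10)) == -50.0
        assert z_score(0.0, BackgroundModel(0.0, 0.0, 10)) == 0.0


class TestStouffer:
    def test_equal_weights(self):
        assert combine_stouffer(1.0, 1.0) == pytest.approx(np.sqrt(2.0))

    def test_cancellation(self):
        assert combine_stouffer(2.0, -2.0) == 0.0

    def test_no_normals_fallback(self):
        assert combine_stouffer(None, 3.0) == 3.0
        assert combine_stouffer(float("nan"), 3.0) == 3.0


class TestSignificance:
    def test_zero_z_amp_is_half(self):
        p, _, _ = significance(np.array([0.0]), AMP)
        assert p[0] == pytest.approx(0.5)

    def test_del_tail_quantile(self):
        p, _, _ = significance(np.array([-1.6449]), DEL)
        assert p[0] == pytest.approx(0.05, abs=1e-4)

    def test_single_gene_correction_is_identity(self):
        z = 1.7507  # upper-tail p ~= 0.04
        p, p_adj, pos = significance(np.array([z]), AMP, alpha=0.05)
        assert p_adj[0] == pytest.approx(p[0])
        assert pos[0]

    def test_bonferroni_option(self):
        from scipy.stats import norm

        z = np.array([3.0, 0.0])
        p, p_bh, _ = significance(z, AMP, method="bh")
        _, p_bf, _ = significance(z, AMP, method="bonferroni")
        assert p_bf[0] == pytest.approx(2 * norm.sf(3.0))
        assert (p_bf >= p_bh - 1e-15).all()


class TestSelectEventSamples:
    def test_partition_rules(self, toy_dataset):
        ds = make_dataset(n_genes=1, n_tumors=5, amp_genes=(), del_genes=())
        ds.cna.iloc[0] = [2, 2, 0, 0, 1]
        altered, diploid, normals = select_event_samples(ds, "G0", AMP)
        assert altered == ["T0", "T1"]
        assert diploid == ["T2", "T3"]
        assert set(normals) == set(ds.normal_samples)

    def test_opposite_sign_excluded(self):
        ds = make_dataset(n_genes=1, n_tumors=3, amp_genes=(), del_genes=())
        ds.cna.iloc[0] = [-2, 2, 0]
        altered, diploid, _ = select_event_samples(ds, "G0", DEL)
        assert altered == ["T0"] and diploid == ["T2"]

    def test_all_neutral_gives_empty(self):
        ds = make_dataset(n_genes=1, n_tumors=3, amp_genes=(), del_genes=())
        altered, _, _ = select_event_samples(ds, "G0", DEL)
        assert altered == []


class TestAnalyze:
    def test_min_altered_filter(self):
        ds = make_dataset(n_genes=6, amp_genes=(0,), del_genes=(), n_events=2)
        res = analyze(ds, AMP, RunConfig(n_sampling=200, seed=1))
        assert res["gene"].tolist() == ["G0"]
        single = make_dataset(n_genes=6, amp_genes=(0,), del_genes=(), n_events=1)
        assert analyze(single, AMP, RunConfig(n_sampling=200, seed=1)).empty

    def test_detects_planted_signal_in_both_directions(self):
        ds = make_dataset(
            n_genes=12,
            amp_genes=(0,),
            del_genes=(1,),
            null_amp_genes=(2, 3, 4, 5),
            null_del_genes=(6, 7, 8, 9),
            n_events=3,
            shift=4.0,
        )
        cfg = RunConfig(n_sampling=500, seed=2)
        amp = analyze(ds, AMP, cfg)
        dl = analyze(ds, DEL, cfg)
        assert amp.iloc[0]["gene"] == "G0" and amp.iloc[0]["z_comb"] > 0
        assert dl.iloc[0]["gene"] == "G1" and dl.iloc[0]["z_comb"] < 0

    def test_no_normals_falls_back_to_z_tumor(self):
        ds = make_dataset(n_normals=0)
        res = analyze(ds, AMP, RunConfig(n_sampling=200, seed=3))
        assert res["z_normal"].isna().all()
        assert res["eis_normal"].isna().all()
        assert (res["z_comb"] == res["z_tumor"]).all()

    def test_ranking_orders(self):
        ds = make_dataset(amp_genes=(0, 2), del_genes=(1, 3), n_events=3)
        cfg = RunConfig(n_sampling=300, seed=4)
        amp = analyze(ds, AMP, cfg)
        dl = analyze(ds, DEL, cfg)
        assert (np.diff(amp["z_comb"]) <= 0).all()
        assert (np.diff(dl["z_comb"]) >= 0).all()
        assert amp.index[0] == 1  # rank index starts at 1

    def test_seed_determinism(self, toy_dataset):
        cfg = RunConfig(n_sampling=300, seed=5)
        a = analyze(toy_dataset, AMP, cfg)
        b = analyze(toy_dataset, AMP, cfg)
        pd.testing.assert_frame_equal(a, b)

    @given(offset=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_translation_and_scale_equivariance(self, offset, scale):
        """Shifting or positively rescaling one gene's expression leaves its
        EIS, Z and p unchanged (median and IQR transform together)."""
        ds = make_dataset(amp_genes=(0, 2), del_genes=(), n_events=3)
        cfg = RunConfig(n_sampling=300, seed=6)
        base = analyze(ds, AMP, cfg)
        ds.expression.loc["G0"] = ds.expression.loc["G0"] * scale + offset
        moved = analyze(ds, AMP, cfg)
        for col in ("eis_tumor", "eis_normal", "z_tumor", "z_normal", "z_comb", "p_value"):
            np.testing.assert_allclose(
                base.set_index("gene")[col].to_numpy(dtype=float),
                moved.set_index("gene").loc[base["gene"], col].to_numpy(dtype=float),
                rtol=1e-9,
                atol=1e-12,
            )

    def test_monotonicity_in_altered_expression(self):
        ds = make_dataset(amp_genes=(0, 2), del_genes=(), n_events=3, shift=1.0)
        cfg = RunConfig(n_sampling=500, seed=7)
        before = analyze(ds, AMP, cfg).set_index("gene")
        bumped = make_dataset(amp_genes=(0, 2), del_genes=(), n_events=3, shift=1.0)
        altered = bumped.cna.columns[(bumped.cna.loc["G0"] == 2).to_numpy()]
        bumped.expression.loc["G0", altered] += 2.0
        after = analyze(bumped, AMP, cfg).set_index("gene")
        assert after.loc["G0", "eis_tumor"] > before.loc["G0", "eis_tumor"]
        assert after.loc["G0", "z_comb"] >= before.loc["G0", "z_comb"] - 1e-9
        assert after.index.get_loc("G0") <= before.index.get_loc("G0")

    def test_null_calibration_over_seeds(self):
        """On expression independent of copy number, the corrected-p positive
        rate stays at or below alpha plus Monte-Carlo slack."""
        alpha = 0.05
        tested = positives = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ds = make_dataset(
                n_genes=30, n_tumors=24, n_normals=5,
                amp_genes=(), del_genes=(), seed=seed,
            )
            codes = np.zeros((30, 24), dtype=np.int8)
            for g in range(30):
                hit = rng.choice(24, size=4, replace=False)
                codes[g, hit] = rng.choice([-2, 2])
            ds.cna.iloc[:, :] = codes
            cfg = RunConfig(n_sampling=400, seed=seed, alpha=alpha)
            for direction in (AMP, DEL):
                res = analyze(ds, direction, cfg)
                tested += len(res)
                positives += int((res["corrected_p"] <= alpha).sum())
        rate = positives / tested
        assert tested > 400
        assert rate <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / tested)
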