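"""The trimmed labelled-fraction statistic: oracles, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clickcyto import (
    LabellingParams,
    MarginError,
    SceneConfig,
    background_correct,
    condition_ratio,
    estimate_labelled_fraction,
    generate_intensity_table,
    normalize_to_reference,
    trimmed_specific_signal,
)

from conftest import make_table


def brute_force_trimmed(signals, F, delta=0.1):
    """Independent oracle: full descending sort, direct slicing of the two
    tails, plain means.  (Means use np.mean so summation order matches the
    implementation bit-for-bit; the sort/slice path is independent.)"""
    import math

    s = np.sort(np.asarray(signals, dtype=float))[::-1]
    n = len(s)
    n_top = int(math.floor((F - delta) * n + 0.5))
    n_bottom = int(math.floor((1 - delta - F) * n + 0.5))
    return float(np.mean(s[:n_top]) - np.mean(s[n - n_bottom:]))


class TestEstimateLabelledFraction:
    def test_perfectly_separated_bimodal(self, bimodal_table):
        assert estimate_labelled_fraction(bimodal_table) == 0.5

    @pytest.mark.parametrize("method", ["otsu_log", "gmm2", "valley"])
    def test_methods_agree_on_separated_mixture(self, method):
        table = generate_intensity_table(SceneConfig(n_nuclei=10_000, labelled_fraction=0.45, seed=4))
        params = LabellingParams(fraction_method=method)
        assert estimate_labelled_fraction(table, params) == pytest.approx(0.45, abs=0.02)

    @pytest.mark.parametrize("truth", [0.2, 0.45, 0.75])
    def test_recovery_unbiased_across_operating_points(self, truth):
        estimates = [
            estimate_labelled_fraction(
                generate_intensity_table(
                    SceneConfig(n_nuclei=10_000, labelled_fraction=truth, seed=seed)
                )
            )
            for seed in range(20)
        ]
        assert abs(np.mean(estimates) - truth) < 0.02

    def test_degenerate_mixture_falls_back_to_otsu(self):
        # unimodal table: gmm2 components collapse
        rng = np.random.default_rng(0)
        table = make_table(rng.lognormal(5.0, 0.3, size=2000))
        params = LabellingParams(fraction_method="gmm2")
        with pytest.warns(UserWarning, match="degenerate"):
            F = estimate_labelled_fraction(table, params)
        assert 0.0 <= F <= 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_labelled_fraction(make_table([]))


class TestTrimmedSpecificSignal:
    def test_hand_countable_example(self):
        table = make_table([1000.0] * 5 + [0.0] * 5)
        res = trimmed_specific_signal(table, F=0.5)
        assert (res.n_top, res.n_bottom) == (4, 4)
        assert res.specific_signal == 1000.0
        assert res.mean_top == 1000.0 and res.mean_bottom == 0.0

    @pytest.mark.parametrize("F", [0.2, 0.5, 0.8])
    def test_constant_table_gives_zero_specific_signal(self, F):
        res = trimmed_specific_signal(make_table([42.0] * 100), F)
        assert res.specific_signal == 0.0

    @pytest.mark.parametrize("F", [0.15, 0.3, 0.6, 0.85])
    def test_matches_brute_force_oracle(self, F):
        rng = np.random.default_rng(99)
        signals = rng.uniform(0, 5000, size=1000)
        res = trimmed_specific_signal(make_table(signals), F)
        assert res.specific_signal == brute_force_trimmed(signals, F)

    def test_out_of_range_F_errors_by_default(self):
        table = make_table(np.linspace(0, 100, 50))
        with pytest.raises(MarginError, match="0.95"):
            trimmed_specific_signal(table, F=0.95)
        with pytest.raises(MarginError):
            trimmed_specific_signal(table, F=0.05)

    def test_clamp_policy_warns_and_clamps(self):
        table = make_table(np.linspace(0, 100, 50))
        params = LabellingParams(out_of_range_policy="clamp")
        with pytest.warns(UserWarning, match="clamped"):
            res = trimmed_specific_signal(table, F=0.95, params=params)
        assert res.F == 0.9

    def test_counts_follow_rounding_rule(self):
        res = trimmed_specific_signal(make_table(np.arange(1000.0)), F=0.6)
        assert res.n_top == 500 and res.n_bottom == 300

    def test_ties_broken_by_nucleus_id_stably(self):
        # many equal signals: statistic must not depend on row order
        signals = np.array([5.0] * 10 + [100.0] * 10)
        table = make_table(signals)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = trimmed_specific_signal(table, 0.5)
        b = trimmed_specific_signal(shuffled, 0.5)
        assert a.specific_signal == b.specific_signal

    @settings(derandomize=True, max_examples=25)
    @given(
        offset=st.floats(0.0, 1e4),
        scale=st.floats(0.01, 100.0),
        F=st.floats(0.15, 0.85),
        seed=st.integers(0, 1000),
    )
    def test_offset_invariance_and_scale_equivariance(self, offset, scale, F, seed):
        signals = np.random.default_rng(seed).uniform(0, 1000, size=200)
        base = trimmed_specific_signal(make_table(signals), F).specific_signal
        shifted = trimmed_specific_signal(make_table(signals + offset), F).specific_signal
        scaled = trimmed_specific_signal(make_table(signals * scale), F).specific_signal
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-6)
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 1000), F=st.floats(0.2, 0.8))
    def test_permutation_invariance(self, seed, F):
        rng = np.random.default_rng(seed)
        signals = rng.uniform(0, 1000, size=150)
        table = make_table(signals)
        perm = table.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert (
            trimmed_specific_signal(table, F).specific_signal
            == trimmed_specific_signal(perm, F).specific_signal
        )


class TestBackgroundCorrect:
    def test_identical_control_cancels(self, synthetic_table):
        F = estimate_labelled_fraction(synthetic_table)
        treated = trimmed_specific_signal(synthetic_table, F)
        corrected = background_correct(treated, synthetic_table, F)
        assert corrected.corrected_signal == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_unlabelled_control_subtracts_nothing(self):
        treated_cfg = SceneConfig(n_nuclei=1000, labelled_fraction=0.5, seed=2)
        control_cfg = SceneConfig(
            n_nuclei=1000, labelled_fraction=0.0, noise_sd=0.0, seed=3
        )
        table = generate_intensity_table(treated_cfg)
        F = estimate_labelled_fraction(table)
        treated = trimmed_specific_signal(table, F)
        corrected = background_correct(treated, generate_intensity_table(control_cfg), F)
        assert corrected.corrected_signal == treated.specific_signal

    def test_recovers_true_labelled_excess(self):
        """Corrected signal approximates the generating labelled-unlabelled gap.

        Uses a narrow labelled-signal spread so the trimmed top mean tracks
        the population mean (with a wide lognormal the trim excludes the
        dimmest labelled nuclei and sits above it by construction).
        """
        sigma = 0.05
        true_excess = 2000.0 * np.exp(sigma**2 / 2) - 50.0  # lognormal mean - unlabelled
        vals = []
        for seed in range(20):
            cfg = SceneConfig(n_nuclei=10_000, labelled_fraction=0.45,
                              labelled_signal_sigma_log=sigma, seed=seed)
            ctrl = SceneConfig(n_nuclei=10_000, labelled_fraction=0.0, seed=seed + 1000)
            table = generate_intensity_table(cfg)
            F = estimate_labelled_fraction(table)
            res = background_correct(
                trimmed_specific_signal(table, F), generate_intensity_table(ctrl), F
            )
            vals.append(res.corrected_signal)
        assert np.mean(vals) == pytest.approx(true_excess, rel=0.03)

    def test_plain_mean_control_mode(self, bimodal_table):
        treated = trimmed_specific_signal(bimodal_table, 0.5)
        control = make_table([7.0] * 100)
        res = background_correct(treated, control, 0.5, control_statistic="mean")
        assert res.corrected_signal == treated.specific_signal - 7.0


class TestConditionRatio:
    def test_exact_proportionality(self):
        res = condition_ratio([(2, 1), (2.2, 1.1), (1.8, 0.9)])
        assert res.mean_ratio == pytest.approx(2.0)
        assert res.sem == pytest.approx(0.0, abs=1e-12)
        assert res.n_experiments == 3

    def test_single_experiment_reports_zero_sem(self):
        res = condition_ratio([(5.0, 5.0)])
        assert res.mean_ratio == 1.0 and res.sem == 0.0

    def test_zero_denominator_identifies_experiment(self):
        with pytest.raises(ZeroDivisionError, match="experiment 2"):
            condition_ratio([(1, 1), (1, 0)])

    def test_sem_matches_definition(self):
        pairs = [(3.0, 1.0), (5.0, 1.0), (4.0, 1.0)]
        res = condition_ratio(pairs)
        expected_sem = np.std([3, 5, 4], ddof=1) / np.sqrt(3)
        assert res.sem == pytest.approx(expected_sem)

    def test_equal_signal_conditions_give_unit_ratio(self):
        """Two conditions with equal generating signal: mean ratio in [0.9, 1.1]."""
        pairs = []
        for rep in range(3):
            corrected = {}
            for j, cond in enumerate(("EdU", "EdC")):
                cfg = SceneConfig(n_nuclei=10_000, labelled_fraction=0.75,
                                  seed=100 * rep + j)
                ctrl = SceneConfig(n_nuclei=10_000, labelled_fraction=0.0,
                                   seed=100 * rep + j + 50)
                table = generate_intensity_table(cfg)
                F = estimate_labelled_fraction(table)
                res = background_correct(
                    trimmed_specific_signal(table, F),
                    generate_intensity_table(ctrl), F)
                corrected[cond] = res.corrected_signal
            pairs.append((corrected["EdU"], corrected["EdC"]))
        result = condition_ratio(pairs)
        assert 0.9 <= result.mean_ratio <= 1.1


class TestNormalizeToReference:
    def test_basic_normalization(self):
        assert normalize_to_reference({"a": 50.0, "ref": 200.0}, "ref") == {
            "a": 25.0,
            "ref": 100.0,
        }

    def test_all_equal_values_map_to_100(self):
        out = normalize_to_reference({"a": 3.0, "b": 3.0, "c": 3.0}, "b")
        assert all(v == 100.0 for v in out.values())

    def test_series_preserves_proportions(self):
        proportions = {"c1": 0.1, "c2": 0.25, "c3": 0.5, "c4": 0.8, "ref": 1.0}
        signals = {k: 340.0 * v for k, v in proportions.items()}
        out = normalize_to_reference(signals, "ref")
        for k, p in proportions.items():
            assert out[k] == pytest.approx(100.0 * p)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_to_reference({"a": 1.0, "ref": 0.0}, "ref")
        with pytest.raises(KeyError):
            normalize_to_reference({"a": 1.0}, "ref")
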