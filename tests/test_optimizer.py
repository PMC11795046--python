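"""Objective, acquisition functions, batch construction, random baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from induceopt import (
    AcquisitionConfig,
    Bounds,
    Dose,
    DomainError,
    KernelConfig,
    ObjectiveConfig,
    Observation,
    ResponseParams,
    evaluate_objective,
    expand_batch_to_wells,
    expected_improvement,
    fit_gp,
    gfp_true,
    random_batch,
    select_batch,
    ucb,
)
from conftest import gp_posterior_oracle

FROZEN = KernelConfig(
    length_scale_inducer=15.0,
    length_scale_plate=1.5,
    signal_variance=1.0,
    noise_variance=0.1,
    optimize=False,
    normalize_y=False,
)


class TestObjective:
    def test_pure_product_value(self):
        cfg = ObjectiveConfig(alpha_i=0.0, alpha_e=0.0, alpha_g=1.0)
        assert evaluate_objective(Dose(50.0), 5.0, cfg) == 5.0

    def test_direct_substitution(self):
        cfg = ObjectiveConfig(alpha_i=-1.0, alpha_e=0.0, alpha_g=1.0)
        assert evaluate_objective(Dose(10.0), 100.0, cfg) == 90.0

    def test_enzyme_cost_enters_additively(self):
        cfg = ObjectiveConfig(alpha_i=-1.0, alpha_e=-0.5, alpha_g=2.0)
        assert evaluate_objective(Dose(10.0, 20.0), 30.0, cfg) == -10.0 - 10.0 + 60.0

    def test_default_noiseless_optimum_in_target_band(self):
        """Dense grid of twin response + cost: argmax lies in [7, 9]."""
        r, obj = ResponseParams(), ObjectiveConfig()
        xs = np.arange(0.0, 100.0 + 1e-9, 0.1)
        fs = [evaluate_objective(Dose(float(x)), gfp_true(r, float(x)), obj) for x in xs]
        x_star = xs[int(np.argmax(fs))]
        assert 7.0 <= x_star <= 9.0

    def test_positive_inducer_price_rejected(self):
        with pytest.raises(DomainError):
            ObjectiveConfig(alpha_i=1.0)


class TestUcb:
    @pytest.mark.parametrize(
        "mean, sd, kappa, expected",
        [(1.0, 2.0, 0.0, 1.0), (1.0, 2.0, 2.5, 6.0), (0.0, 1.0, 40.0, 40.0)],
        ids=["kappa-zero-is-mean", "substitution", "escalated-kappa"],
    )
    def test_closed_form(self, mean, sd, kappa, expected):
        assert ucb(mean, sd, kappa) == pytest.approx(expected)

    def test_negative_sd_rejected(self):
        with pytest.raises(DomainError):
            ucb(1.0, -0.1, 2.0)


class TestExpectedImprovement:
    def test_no_uncertainty_no_improvement(self):
        assert expected_improvement(1.0, 0.0, 1.0) == 0.0

    def test_deterministic_improvement(self):
        assert expected_improvement(2.0, 0.0, 1.0) == 1.0

    def test_matches_monte_carlo_oracle(self):
        """E[max(0, Z)] over 1e6 standard-normal draws vs the closed form."""
        rng = np.random.default_rng(123)
        mc = np.maximum(rng.standard_normal(1_000_000), 0.0).mean()
        assert expected_improvement(0.0, 1.0, 0.0) == pytest.approx(mc, abs=1e-3)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        mean=st.floats(-50, 50, allow_nan=False),
        sd=st.floats(0, 20, allow_nan=False),
        f_best=st.floats(-50, 50, allow_nan=False),
    )
    def test_nonnegative_everywhere(self, mean, sd, f_best):
        assert expected_improvement(mean, sd, f_best) >= 0.0

    def test_strictly_increasing_in_sd_at_incumbent(self):
        sds = np.linspace(0.1, 5.0, 20)
        vals = expected_improvement(np.zeros_like(sds), sds, 0.0)
        assert np.all(np.diff(vals) > 0)


class TestRandomBatch:
    def test_points_in_bounds_and_seeded(self):
        bounds = Bounds()
        a = random_batch(5, bounds, np.random.default_rng(11))
        b = random_batch(5, bounds, np.random.default_rng(11))
        assert a == b
        assert all(bounds.contains(d) for d in a)

    def test_uniformity_ks(self):
        xs = [d.inducer for d in random_batch(10_000, Bounds(), np.random.default_rng(5))]
        assert kstest(np.array(xs) / 100.0, "uniform").pvalue > 0.01

    def test_expected_hits_in_target_band(self):
        """Analytic: 288 uniform draws x band width 2/100 -> 5.76 expected."""
        rng = np.random.default_rng(0)
        counts = [
            sum(1 for d in random_batch(288, Bounds(), rng) if 7.0 <= d.inducer <= 9.0)
            for _ in range(2000)
        ]
        assert np.mean(counts) == pytest.approx(5.76, rel=0.05)

    def test_rejects_empty_batch(self):
        with pytest.raises(DomainError):
            random_batch(0, Bounds(), np.random.default_rng(0))


class TestSelectBatch:
    def _history(self):
        return [Observation(Dose(0.0), 1, 0.0), Observation(Dose(50.0), 1, 1.0)]

    def test_empty_history_uniform_and_reproducible(self):
        cfg = AcquisitionConfig(kind="ei", batch_size=5)
        a = select_batch([], cfg, ObjectiveConfig(), Bounds(), 1, np.random.default_rng(3))
        b = select_batch([], cfg, ObjectiveConfig(), Bounds(), 1, np.random.default_rng(3))
        assert a.doses == b.doses and len(a.doses) == 5 and a.used_random
        assert all(Bounds().contains(d) for d in a.doses)

    def test_large_kappa_first_pick_maximizes_posterior_sd(self):
        """Against the closed-form sd argmax on the same grid."""
        cfg = AcquisitionConfig(kind="ucb", kappa=1e6, batch_size=1)
        res = select_batch(
            self._history(), cfg, ObjectiveConfig(), Bounds(), 1,
            np.random.default_rng(0), kernel_cfg=FROZEN,
        )
        xs = np.linspace(0, 100, cfg.grid_points_1d)
        X = np.array([[0.0, 1.0], [50.0, 1.0]])
        Xq = np.column_stack([xs, np.ones_like(xs)])
        _, o_sd = gp_posterior_oracle(
            X, [0.0, 1.0], Xq,
            length_scales=[FROZEN.length_scale_inducer, FROZEN.length_scale_plate],
            signal_var=FROZEN.signal_variance,
            noise_var=FROZEN.noise_variance,
        )
        assert res.doses[0].inducer == pytest.approx(xs[np.argmax(o_sd)], abs=0.1)

    def test_batch_size_respected_with_separation_or_fallback(self):
        cfg = AcquisitionConfig(kind="ei", batch_size=8)
        res = select_batch(
            self._history(), cfg, ObjectiveConfig(), Bounds(), 2,
            np.random.default_rng(1), kernel_cfg=FROZEN,
        )
        assert len(res.doses) == 8
        assert all(Bounds().contains(d) for d in res.doses)
        if not res.fallback_engaged:
            for i, a in enumerate(res.doses):
                for b in res.doses[i + 1:]:
                    assert a.distance(b) >= cfg.duplicate_tolerance

    def test_forced_fallback_surrounds_last_selection(self):
        """A huge duplicate tolerance degenerates every second argmax."""
        cfg = AcquisitionConfig(
            kind="ucb", batch_size=6, duplicate_tolerance=500.0, fallback_delta=1.0
        )
        res = select_batch(
            self._history(), cfg, ObjectiveConfig(), Bounds(), 2,
            np.random.default_rng(2), kernel_cfg=FROZEN,
        )
        assert res.fallback_engaged and len(res.doses) == 6
        anchor = res.doses[0].inducer
        fills = [d.inducer for d in res.doses[1:]]
        assert len(set(fills)) == len(fills)
        # every fill sits an integer number of delta steps from the anchor
        # (unless clipped onto a bound), and the nearest step is present
        for f in fills:
            k = abs(f - anchor)
            assert f in (0.0, 100.0) or k == pytest.approx(round(k), abs=1e-9)
        assert min(abs(f - anchor) for f in fills) == pytest.approx(1.0)

    def test_median_lie_is_stable_under_equal_values(self):
        """All-equal history: the constant-liar value equals that level and
        pseudo-points cannot move the median."""
        hist = [Observation(Dose(float(x)), 1, 3.0) for x in (10, 40, 70)]
        cfg = AcquisitionConfig(kind="ei", batch_size=3)
        res = select_batch(
            hist, cfg, ObjectiveConfig(), Bounds(), 2,
            np.random.default_rng(4), kernel_cfg=FROZEN,
        )
        lies = [r["median_lie"] for r in res.records if r.get("event") == "acquisition"]
        assert all(v == 3.0 for v in lies)

    def test_kappa_escalation_recorded_on_pseudo_refits(self):
        cfg = AcquisitionConfig(kind="ucb", kappa=2.0, kappa_escalation=20.0, batch_size=3)
        res = select_batch(
            self._history(), cfg, ObjectiveConfig(), Bounds(), 2,
            np.random.default_rng(5), kernel_cfg=FROZEN,
        )
        acq = [r for r in res.records if r.get("event") == "acquisition"]
        assert acq[0]["kappa"] == 2.0
        assert all(r["kappa"] == 40.0 for r in acq[1:])


class TestExpandBatch:
    def test_round_robin_replication(self):
        distinct = [Dose(float(x)) for x in (1, 2, 3)]
        wells = expand_batch_to_wells(distinct, 72, np.random.default_rng(0), shuffle=False)
        assert len(wells) == 72
        for d in distinct:
            assert wells.count(d) == 24

    def test_identity_up_to_shuffle(self):
        distinct = [Dose(float(x)) for x in range(72)]
        wells = expand_batch_to_wells(distinct, 72, np.random.default_rng(1))
        assert sorted(wells, key=Dose.sort_key) == distinct

    def test_shuffle_reproducible_by_seed(self):
        distinct = [Dose(float(x)) for x in range(24)]
        a = expand_batch_to_wells(distinct, 72, np.random.default_rng(9))
        b = expand_batch_to_wells(distinct, 72, np.random.default_rng(9))
        assert a == b
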