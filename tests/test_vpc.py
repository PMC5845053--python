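"""pcVPC machinery: replicate simulation, binning, prediction correction and
percentile summaries with simulation bands."""

import numpy as np
import pytest

from dexpopk.cohort import CohortConfig, simulate_cohort
from dexpopk.estimation import evaluate_model
from dexpopk.model import PopulationModel
from dexpopk.vpc import (
    bin_times,
    pcvpc,
    prediction_correct,
    simulate_replicates,
    vpc_summarize,
)


@pytest.fixture(scope="module")
def truth_fit(study_cohort_module=None):
    sim = simulate_cohort(CohortConfig(seed=77))
    return evaluate_model(CohortConfig().truth, sim.subjects)


class TestSimulateReplicates:
    def test_no_randomness_reproduces_pred(self):
        truth = PopulationModel(
            theta={"cl": 38.5, "v_c": 27.0, "v_t": 87.6, "q": 46.4},
            omega2={p: 0.0 for p in ("cl", "v_c", "v_t", "q")},
            sigma2=1e-12,
        )
        sim = simulate_cohort(CohortConfig(n_subjects=4, truth=truth, seed=55))
        fit = evaluate_model(truth, sim.subjects)
        sims = simulate_replicates(fit, n_sim=5, seed=1)
        pred = fit._design.predict(
            fit._objective.typical_values(truth.theta_vector(), np.array([]))
        )
        for k in range(5):
            np.testing.assert_allclose(sims[k], pred, rtol=1e-4)

    def test_seed_reproducibility_and_shape(self, truth_fit):
        a = simulate_replicates(truth_fit, n_sim=7, seed=4)
        b = simulate_replicates(truth_fit, n_sim=7, seed=4)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (7, truth_fit.n_obs)

    def test_replicate_mean_tracks_expected_concentration(self, truth_fit):
        """Across many replicates the pointwise mean approaches E[C_obs]."""
        sims = simulate_replicates(truth_fit, n_sim=800, seed=6)
        mc = sims.mean(axis=0)
        # E over lognormal eta is conc-scale heavy; compare medians instead of
        # means pointwise (finite-n Monte Carlo), with a global bias check
        obs_scale = np.median(truth_fit._design.y)
        assert np.median(mc) == pytest.approx(obs_scale, rel=0.35)
        assert np.all(sims >= 0)


class TestBinning:
    def test_single_time_single_bin(self):
        idx, edges, ref = bin_times(np.full(12, 3.0), n_bins=5)
        assert np.all(idx == 0)
        assert ref[0] == 3.0

    def test_equal_count_bins_on_spread_times(self):
        t = np.arange(100, dtype=float)
        idx, edges, ref = bin_times(t, n_bins=10)
        counts = np.bincount(idx)
        assert len(counts) == 10
        assert np.all(counts == 10)

    def test_distinct_strategy_reproduces_design_times(self):
        sched_times = np.array([0.5, 1, 4, 8, 12, 16, 20, 24.1])
        obs = np.repeat(sched_times, 5)
        idx, edges, ref = bin_times(obs, strategy="distinct")
        np.testing.assert_allclose(np.unique(ref), sched_times)
        assert len(np.unique(idx)) == len(sched_times)

    def test_more_bins_than_times_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            idx, edges, ref = bin_times(np.array([1.0, 1.0, 2.0]), n_bins=10)
        assert len(np.unique(idx)) <= 2


class TestPredictionCorrection:
    def test_identity_when_bin_pred_constant(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full(4, 2.5)
        out = prediction_correct(values, pred, np.zeros(4, dtype=int))
        np.testing.assert_array_equal(out, values)

    def test_formula_arithmetic(self):
        """Y = 4 with PRED twice the bin reference is halved to 2."""
        values = np.array([4.0, 1.0, 1.0])
        pred = np.array([2.0, 1.0, 1.0])  # bin median PRED = 1
        out = prediction_correct(values, pred, np.zeros(3, dtype=int))
        assert out[0] == pytest.approx(2.0)

    def test_applies_identically_to_simulation_matrix(self):
        rng = np.random.default_rng(2)
        pred = rng.uniform(0.5, 2.0, 6)
        bins = np.array([0, 0, 0, 1, 1, 1])
        obs = rng.uniform(0.5, 2.0, 6)
        sims = np.vstack([obs, obs * 2.0])
        pc_obs = prediction_correct(obs, pred, bins)
        pc_sims = prediction_correct(sims, pred, bins)
        np.testing.assert_allclose(pc_sims[0], pc_obs)
        np.testing.assert_allclose(pc_sims[1], 2.0 * pc_obs)

    def test_correction_commutes_with_ranking_for_constant_pred_within_bin(self):
        """If PRED is constant inside a bin the correction is a per-bin
        rescaling, so percentile ranks are unchanged."""
        values = np.array([3.0, 1.0, 2.0, 9.0, 7.0, 8.0])
        pred = np.array([2.0, 2.0, 2.0, 0.5, 0.5, 0.5])
        bins = np.array([0, 0, 0, 1, 1, 1])
        out = prediction_correct(values, pred, bins)
        for b in (0, 1):
            np.testing.assert_array_equal(
                np.argsort(out[bins == b]), np.argsort(values[bins == b])
            )

    def test_zero_pred_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = prediction_correct(
                np.array([1.0, 1.0]), np.array([0.0, 1.0]), np.zeros(2, dtype=int)
            )
        assert np.isnan(out[0])


class TestSummaries:
    def test_observed_sits_on_band_midline_when_sims_equal_obs(self, truth_fit):
        design = truth_fit._design
        obs = design.y
        sims = np.tile(obs, (30, 1))
        idx, _, ref = bin_times(design.t, n_bins=6)
        s = vpc_summarize(obs, sims, idx, ref)
        np.testing.assert_allclose(s.table["observed"], s.table["sim_median"], rtol=1e-12)
        np.testing.assert_allclose(s.table["ci_lo"], s.table["observed"], rtol=1e-12)

    def test_percentile_ordering_within_bins(self, truth_fit):
        summary = pcvpc(truth_fit, n_sim=60, seed=5, n_bins=8)
        for _, grp in summary.table.groupby("bin"):
            g = grp.sort_values("percentile")
            assert g["observed"].is_monotonic_increasing
            assert g["ci_lo"].le(g["ci_hi"]).all()

    def test_every_observation_binned_once(self, truth_fit):
        idx, _, _ = bin_times(truth_fit._design.t, n_bins=10)
        assert idx.shape == truth_fit._design.t.shape
        assert idx.min() >= 0

    def test_pooled_regimens_overlay_after_correction(self):
        """Prediction correction makes sub-cohorts dosed at different rates
        comparable: their corrected medians agree within Monte-Carlo error."""
        truth = CohortConfig().truth
        lo = simulate_cohort(CohortConfig(
            n_subjects=20, seed=91,
            initial_rate_range=(0.4, 0.5), maintenance_rate_range=(0.4, 0.5),
        ))
        hi = simulate_cohort(CohortConfig(
            n_subjects=20, seed=92,
            initial_rate_range=(1.3, 1.5), maintenance_rate_range=(1.3, 1.5),
        ))
        subjects = lo.subjects + [
            type(s)(id=f"h{s.id}", schedule=s.schedule, obs_times=s.obs_times,
                    dv=s.dv, covariates=s.covariates)
            for s in hi.subjects
        ]
        fit = evaluate_model(truth, subjects)
        design = fit._design
        pred = design.predict(
            fit._objective.typical_values(truth.theta_vector(), np.array([]))
        )
        idx, _, _ = bin_times(design.t, n_bins=6)
        pc = prediction_correct(design.y, pred, idx)
        is_hi = np.array([str(i).startswith("h") for i in
                          np.asarray(design.subject_ids, dtype=object)[design.sidx]])
        raw_gap, pc_gap = [], []
        for b in np.unique(idx):
            m = idx == b
            if (m & is_hi).sum() >= 5 and (m & ~is_hi).sum() >= 5:
                raw_gap.append(
                    np.median(design.y[m & is_hi]) / np.median(design.y[m & ~is_hi])
                )
                pc_gap.append(np.median(pc[m & is_hi]) / np.median(pc[m & ~is_hi]))
        raw_gap, pc_gap = np.array(raw_gap), np.array(pc_gap)
        # uncorrected sub-cohorts differ ~3-fold; corrected ones overlay
        assert np.median(raw_gap) > 1.8
        assert np.abs(np.log(pc_gap)).mean() < np.abs(np.log(raw_gap)).mean() / 2
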