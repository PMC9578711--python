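"""Generator contracts: photon statistics, determinism, cohort structure."""

import numpy as np
import pytest
from scipy import stats
from skimage import measure

import macroflim as mf
from macroflim.errors import DomainError, ParameterError, ScheduleError
from macroflim.synthetic_data import (
    default_condition_means,
    donor_shifts,
    generate_flux_timeseries,
)


def truncated_exp_mean(tau, window):
    """Closed-form mean of an exponential truncated to [0, window]."""
    q = np.exp(-window / tau)
    return tau - window * q / (1.0 - q)


class TestDecayHistogramGeneration:
    def test_zero_photons_zero_background_gives_empty_histogram(self, acq):
        gt = mf.GroundTruthParams(I0=1.0, alpha1=0.3, alpha2=0.7, tau1=2.5, tau2=0.4)
        counts = mf.generate_decay_histogram(gt, acq, 0, seed=0)
        assert counts.shape == (acq.n_bins,)
        assert counts.sum() == 0

    def test_negative_photons_rejected(self, acq, gt_params):
        with pytest.raises(DomainError):
            mf.generate_decay_histogram(gt_params, acq, -1, seed=0)

    def test_mono_exponential_sample_mean_matches_truncated_mean(self, acq):
        gt = mf.GroundTruthParams(I0=1.0, alpha1=1.0, alpha2=0.0, tau1=2.0, tau2=0.4)
        n = 400_000
        counts = mf.generate_decay_histogram(gt, acq, n, seed=5)
        centers = (np.arange(acq.n_bins) + 0.5) * acq.bin_width_ns
        sample_mean = float(np.sum(counts * centers) / counts.sum())
        expected = truncated_exp_mean(2.0, acq.window_ns)
        se = 2.0 / np.sqrt(n)  # sd of exp(tau=2) bounds the truncated sd
        assert abs(sample_mean - expected) < 3 * se + acq.bin_width_ns / 10

    def test_component_fraction_follows_intensity_fraction_law(self, acq, gt_params):
        n = 200_000
        _, parts = mf.generate_decay_histogram(
            gt_params, acq, n, seed=9, return_parts=True
        )
        w1 = gt_params.alpha1 * gt_params.tau1
        w2 = gt_params.alpha2 * gt_params.tau2
        expected = w1 / (w1 + w2)
        observed = parts["n_component1"] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se

    def test_photon_conservation_is_exact(self, acq):
        gt = mf.GroundTruthParams(
            I0=1.0, alpha1=0.3, alpha2=0.7, tau1=2.5, tau2=0.4, C=2.0
        )
        counts, parts = mf.generate_decay_histogram(
            gt, acq, 5000, seed=3, return_parts=True
        )
        assert counts.sum() == parts["n_signal"] + parts["n_background"]

    def test_same_seed_reproduces_histogram(self, acq, gt_params):
        a = mf.generate_decay_histogram(gt_params, acq, 10_000, seed=42)
        b = mf.generate_decay_histogram(gt_params, acq, 10_000, seed=42)
        np.testing.assert_array_equal(a, b)


class TestFieldGeneration:
    def test_field_has_configured_number_of_connected_cells(self, fccp_field, small_cohort):
        n_components = measure.label(fccp_field.labels > 0).max()
        assert n_components == small_cohort.cells_per_field
        assert fccp_field.truth.shape[0] == small_cohort.cells_per_field

    def test_same_seed_and_condition_bitwise_identical(self, small_cohort):
        cond = mf.Condition("B", "M1", "FCCP", 0)
        f1 = mf.generate_field(small_cohort, cond)
        f2 = mf.generate_field(small_cohort, cond)
        np.testing.assert_array_equal(f1.nadh_histograms, f2.nadh_histograms)
        np.testing.assert_array_equal(f1.fad_intensity, f2.fad_intensity)
        np.testing.assert_array_equal(f1.labels, f2.labels)

    def test_cell_positions_fixed_across_treatment_sequence(self):
        cfg = mf.CohortConfig(
            seed=21,
            n_donors=1,
            fields_per_condition=1,
            cells_per_field=5,
            cell_radius=4,
            photons_per_cell=3000.0,
            acq=mf.AcquisitionParams(image_size=64),
        )
        maps = [
            mf.generate_field(cfg, mf.Condition("A", "M1", t, 0)).labels
            for t in cfg.treatments
        ]
        for m in maps[1:]:
            np.testing.assert_array_equal(maps[0], m)

    def test_default_fccp_means_follow_phenotype_ordering(self):
        cfg = mf.CohortConfig(seed=1)
        assert cfg.fccp_ordering_ok()
        means = default_condition_means()
        # the contrast is largest under FCCP
        gaps = {
            t: means[("M2", t)]["tau1"] - means[("M1", t)]["tau1"]
            for t in mf.synthetic_data.TREATMENTS
        }
        assert max(gaps, key=gaps.get) == "FCCP"

    def test_ground_truth_fccp_tau_avg_ordering(self, small_cohort):
        m1 = mf.generate_field(small_cohort, mf.Condition("A", "M1", "FCCP", 0))
        m2 = mf.generate_field(small_cohort, mf.Condition("A", "M2", "FCCP", 0))
        assert m2.truth["tau_avg"].mean() > m1.truth["tau_avg"].mean()

    def test_unknown_condition_labels_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            mf.generate_field(small_cohort, mf.Condition("A", "M3", "FCCP", 0))
        with pytest.raises(ParameterError):
            mf.generate_field(small_cohort, mf.Condition("A", "M1", "DMSO", 0))


class TestCohortGeneration:
    def test_cohort_stack_and_truth_counts(self, small_cohort):
        stacks, truth = mf.generate_cohort(small_cohort)
        expected = (
            small_cohort.n_donors
            * len(small_cohort.phenotypes)
            * len(small_cohort.treatments)
            * small_cohort.fields_per_condition
        )
        assert len(stacks) == expected
        assert len(truth) == expected * small_cohort.cells_per_field

    def test_truth_means_recover_configured_means(self):
        cfg = mf.CohortConfig(
            seed=5,
            n_donors=1,
            fields_per_condition=10,
            cells_per_field=6,
            cell_radius=4,
            photons_per_cell=2000.0,
            treatments=("FCCP",),
            phenotypes=("M2",),
            field_sd=dict(tau1=0.0, tau2=0.0, alpha2=0.0, orr=0.0),
            donor_effect_sd=dict(tau1=0.0, tau2=0.0, alpha2=0.0, orr=0.0),
            acq=mf.AcquisitionParams(image_size=64),
        )
        _, truth = mf.generate_cohort(cfg)
        means = cfg.means_for("M2", "FCCP")
        n = len(truth)
        for var in ("tau1", "tau2", "alpha2", "orr"):
            se = cfg.cell_sd[var] / np.sqrt(n)
            assert abs(truth[var].mean() - means[var]) < 3.5 * se

    def test_seed_changes_layout_but_not_marginals(self):
        base = dict(
            n_donors=1,
            fields_per_condition=6,
            cells_per_field=6,
            cell_radius=4,
            photons_per_cell=2000.0,
            treatments=("FCCP",),
            phenotypes=("M1",),
            # silence donor/field random effects: with a single donor they
            # shift the whole marginal between seeds by design
            field_sd=dict(tau1=0.0, tau2=0.0, alpha2=0.0, orr=0.0),
            donor_effect_sd=dict(tau1=0.0, tau2=0.0, alpha2=0.0, orr=0.0),
            acq=mf.AcquisitionParams(image_size=64),
        )
        _, t1 = mf.generate_cohort(mf.CohortConfig(seed=101, **base))
        _, t2 = mf.generate_cohort(mf.CohortConfig(seed=202, **base))
        l1 = mf.generate_field(mf.CohortConfig(seed=101, **base), mf.Condition("A", "M1", "FCCP", 0)).labels
        l2 = mf.generate_field(mf.CohortConfig(seed=202, **base), mf.Condition("A", "M1", "FCCP", 0)).labels
        assert not np.array_equal(l1, l2)
        # same marginal distribution of ground-truth lifetimes
        assert stats.ks_2samp(t1["tau1"], t2["tau1"]).pvalue > 0.01

    def test_donor_shifts_deterministic(self):
        cfg = mf.CohortConfig(seed=33)
        assert donor_shifts(cfg, "C") == donor_shifts(cfg, "C")
        assert donor_shifts(cfg, "C") != donor_shifts(cfg, "D")


class TestFluxGeneration:
    SCHEDULE = (20.0, 40.0, 60.0, 80.0)
    MEANS = np.array(
        [[20.0, 50.0], [35.0, 20.0], [30.0, 90.0], [28.0, 10.0], [5.0, 10.0]]
    )

    def test_zero_noise_equals_phase_means(self):
        (series,) = generate_flux_timeseries(
            self.MEANS, self.SCHEDULE, noise_sd=0.0, seed=0
        )
        pm = mf.phase_means(series)
        for k, name in enumerate(mf.flux_metrics.PHASE_NAMES):
            assert pm[name] == (self.MEANS[k, 0], self.MEANS[k, 1])

    def test_four_injections_give_five_phases(self):
        (series,) = generate_flux_timeseries(
            self.MEANS, self.SCHEDULE, noise_sd=0.0, seed=0
        )
        assert set(series.phase_index()) == {0, 1, 2, 3, 4}

    def test_noisy_phase_means_recover_configuration(self):
        reps = generate_flux_timeseries(
            self.MEANS,
            self.SCHEDULE,
            noise_sd=2.0,
            n_replicates=40,
            seed=7,
            timepoints_per_phase=4,
        )
        basal_ecar = np.mean([mf.phase_means(r)["basal"][0] for r in reps])
        se = 2.0 / np.sqrt(40 * 4)
        assert abs(basal_ecar - 20.0) < 3 * se

    def test_bad_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            generate_flux_timeseries(self.MEANS, (20, 15, 60, 80), seed=0)
        with pytest.raises(ScheduleError):
            generate_flux_timeseries(self.MEANS[:3], self.SCHEDULE, seed=0)
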