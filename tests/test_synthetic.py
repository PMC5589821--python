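"""Generator determinism, censoring behaviour and analytic AUC recovery."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from sepsisphase.biomarkers import BELOW_LLOD, OBSERVED
from sepsisphase.features import build_feature_matrix
from sepsisphase.modeling import ModelSpec, auc, binarize_labels, repeated_cv
from sepsisphase.synthetic import (
    CATEGORIES, MarkerSpec, SimulationConfig, VitalSpec, calibrated_config,
    default_markers, default_vitals, generate_cohort, theoretical_auc,
)


def two_class_config(marker_shift=0.0, n=400, seed=0, **kwargs):
    """Categories 1 (negative) and 3 (positive) only, one informative marker."""
    probs = [0.0] * 11
    probs[0] = probs[2] = 0.5
    markers = [MarkerSpec("IL-6", log_mean=3.0, log_sd=1.0,
                          shifts={3: marker_shift},
                          llod=math.exp(3.0 - 8), ulod=math.exp(3.0 + 8))]
    return SimulationConfig(n_patients=n, category_probs=probs,
                            markers=markers, vitals=default_vitals()[:3],
                            batch_log_sd=0.0, seed=seed, **kwargs)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        cfg = SimulationConfig(n_patients=40, seed=5)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ra, rb in zip(a.records, b.records):
            assert ra.category == rb.category and ra.severity == rb.severity
            assert [m.concentration for m in ra.markers] == [m.concentration for m in rb.markers]
            for name in ra.vitals:
                assert np.array_equal(ra.vitals[name].times, rb.vitals[name].times)
                assert np.array_equal(ra.vitals[name].values, rb.vitals[name].values)
            assert ra.snapshot == rb.snapshot

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(n_patients=40, seed=5))
        b = generate_cohort(SimulationConfig(n_patients=40, seed=6))
        assert any(ra.severity != rb.severity for ra, rb in zip(a.records, b.records))


class TestStructure:
    def test_categories_in_range_and_censored_at_limits(self, small_cohort):
        by_name = {m.name: m for m in small_cohort.truth.markers}
        for rec in small_cohort.records:
            assert rec.category in CATEGORIES
            for m in rec.markers:
                spec = by_name[m.marker]
                if m.censor == BELOW_LLOD:
                    assert m.concentration == spec.llod
                elif m.censor == OBSERVED:
                    assert spec.llod <= m.concentration <= spec.ulod

    def test_vitals_grid_spans_window(self, small_cohort):
        rec = small_cohort.records[0]
        s = rec.vitals["pulse"]
        assert s.times[0] >= -48 * 60 and s.times[-1] <= 24 * 60
        assert np.all(np.diff(s.times) > 0)

    def test_marginal_censoring_fraction_matches_normal_cdf(self):
        cfg = two_class_config(0.0, n=5000, seed=3)
        m = cfg.markers[0]
        m = dataclasses.replace(m, llod=math.exp(m.log_mean - 1.0))
        cfg = dataclasses.replace(cfg, markers=[m])
        cohort = generate_cohort(cfg)
        frac = np.mean([rec.markers[0].censor == BELOW_LLOD for rec in cohort.records])
        expected = stats.norm.cdf((math.log(m.llod) - m.log_mean) / m.log_sd)
        assert frac == pytest.approx(expected, abs=0.02)


class TestValidation:
    def test_nonfinite_parameter_names_field(self):
        m = MarkerSpec("IL-6", log_mean=float("nan"), log_sd=1.0)
        with pytest.raises(ValueError, match="log_mean"):
            generate_cohort(SimulationConfig(n_patients=10, markers=[m]))

    def test_llod_above_ulod_rejected(self):
        m = MarkerSpec("IL-6", log_mean=0.0, log_sd=1.0, llod=10.0, ulod=1.0)
        with pytest.raises(ValueError, match="LLOD"):
            generate_cohort(SimulationConfig(n_patients=10, markers=[m]))

    def test_negative_category_weight_rejected(self):
        probs = [0.1] * 11
        probs[0] = -0.5
        with pytest.raises(ValueError, match="non-negative"):
            generate_cohort(SimulationConfig(n_patients=10, category_probs=probs))

    def test_bad_vital_range_rejected(self):
        v = VitalSpec("pulse", baseline=80, sd=10, normal_range=(90.0, 60.0),
                      excursion_gain=0.5)
        with pytest.raises(ValueError, match="L < U"):
            generate_cohort(SimulationConfig(n_patients=10, vitals=[v]))


class TestTheoreticalAuc:
    def test_zero_separation_is_chance(self):
        assert theoretical_auc(0.0) == 0.5

    def test_unit_separation_closed_form(self):
        assert theoretical_auc(1.0) == pytest.approx(0.7602, abs=5e-4)

    def test_monotone_approach_to_one(self):
        values = [theoretical_auc(d) for d in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.9999


class TestSignalRecovery:
    def test_single_marker_auc_matches_binormal_closed_form(self):
        d = 1.0
        cohort = generate_cohort(two_class_config(d, n=2000, seed=4))
        conc = np.array([rec.markers[0].concentration for rec in cohort.records])
        y = binarize_labels(cohort.categories)
        assert auc(conc, y) == pytest.approx(theoretical_auc(d), abs=0.03)

    def test_null_generator_chance_level_cv(self):
        """All shifts and gains zero: downstream CV AUC sits at chance.

        A fixed finite dataset carries spurious separation of order
        sqrt(p/n), so the null cohort is balanced and large relative to
        the feature count.
        """
        probs = [0.0] * 11
        probs[0] = probs[2] = 0.5
        cfg = SimulationConfig(
            n_patients=1500, seed=7, batch_log_sd=0.0, category_probs=probs,
            markers=[dataclasses.replace(m, shifts={}, severity_coupling=0.0)
                     for m in default_markers()[:3]],
            vitals=[dataclasses.replace(v, excursion_gain=0.0)
                    for v in default_vitals()[:3]],
        )
        fm = build_feature_matrix(generate_cohort(cfg))
        res = repeated_cv(fm, ModelSpec("logistic_regression"), repeats=20, seed=0)
        assert 0.46 <= res.mean <= 0.54

    def test_biomarker_signal_strictly_increases_auc(self):
        """3-point grid in biomarker effect size with EMR signal at zero."""
        means = []
        for signal in (0.3, 0.8, 1.5):
            cfg = two_class_config(1.0, n=300, seed=8,
                                   biomarker_signal=signal, emr_signal=0.0)
            fm = build_feature_matrix(generate_cohort(cfg))
            res = repeated_cv(fm.block("biomarkers"),
                              ModelSpec("logistic_regression"), repeats=5, seed=0)
            means.append(res.mean)
        assert means[0] < means[1] < means[2]

    def test_calibrated_config_hits_block_bayes_auc(self):
        cohort = generate_cohort(calibrated_config(seed=12, n_patients=600))
        fm = build_feature_matrix(cohort)
        y = fm.y.to_numpy()
        bio_auc = auc(fm.X["IL-6"].to_numpy(), y)
        assert bio_auc == pytest.approx(0.80, abs=0.05)
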