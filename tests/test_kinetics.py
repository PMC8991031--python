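"""Peptide rate fitting, Grubbs screening, protein aggregation, half-lives."""

import math

import numpy as np
import pytest

from d2okinetics.isotope import expected_M0
from d2okinetics.kinetics import (
    PeptideRateFit,
    PeptideTimeCourse,
    aggregate_protein,
    days_to_years,
    fit_peptide_k,
    grubbs_critical,
    grubbs_filter,
    half_life,
)

M0_NAT, M0_PLAT = 0.434, 0.097


def time_course(k, days, n_per_day=4, noise_cv=0.0, rng=None):
    t = np.repeat(days, n_per_day).astype(float)
    y = expected_M0(t, k, M0_NAT, M0_PLAT)
    if noise_cv:
        y = y * (1 + rng.normal(0, noise_cv, t.size))
    return PeptideTimeCourse("P", "PEPTIDEK", t, np.clip(y, 0, 1))


class TestFitPeptideK:
    def test_noise_free_exact_recovery(self):
        fit = fit_peptide_k(time_course(0.02, [15, 30, 45, 60]),
                            M0_NAT, M0_PLAT)
        assert fit.k == pytest.approx(0.02, abs=1e-8)
        assert fit.measurable and fit.converged

    def test_flat_at_natural_gives_zero_unmeasurable(self):
        tc = PeptideTimeCourse("P", "PEP", np.array([15.0, 30, 45, 60]),
                               np.full(4, M0_NAT))
        fit = fit_peptide_k(tc, M0_NAT, M0_PLAT)
        assert fit.k == 0.0
        assert not fit.measurable

    def test_single_duration_rejected(self):
        tc = PeptideTimeCourse("P", "PEP", np.array([15.0, 15.0]),
                               np.array([0.4, 0.41]))
        with pytest.raises(ValueError, match="distinct"):
            fit_peptide_k(tc, M0_NAT, M0_PLAT)

    def test_day0_rows_excluded_from_fit(self):
        tc_with0 = time_course(0.02, [0, 15, 30, 45, 60])
        tc_without = time_course(0.02, [15, 30, 45, 60])
        a = fit_peptide_k(tc_with0, M0_NAT, M0_PLAT)
        b = fit_peptide_k(tc_without, M0_NAT, M0_PLAT)
        assert a.k == pytest.approx(b.k, abs=1e-10)

    def test_observation_order_invariance(self, rng):
        tc = time_course(0.021, [15, 45, 60], noise_cv=0.01, rng=rng)
        perm = rng.permutation(tc.days.size)
        tc2 = PeptideTimeCourse("P", "PEP", tc.days[perm], tc.m0[perm])
        assert fit_peptide_k(tc, M0_NAT, M0_PLAT).k == pytest.approx(
            fit_peptide_k(tc2, M0_NAT, M0_PLAT).k, abs=1e-10)

    def test_monte_carlo_recovery_within_10pct(self):
        # 1% multiplicative noise, k = 0.021/d, durations 15/45/60, n = 4
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            tc = time_course(0.021, [15, 45, 60], noise_cv=0.01, rng=r)
            errs.append(fit_peptide_k(tc, M0_NAT, M0_PLAT).k / 0.021 - 1)
        assert abs(np.median(errs)) < 0.10


class TestGrubbs:
    def test_tight_triplet_retained(self):
        kept, removed = grubbs_filter([0.010, 0.011, 0.012], alpha=0.05)
        assert kept == [0.010, 0.011, 0.012] and removed == []

    def test_gross_outlier_removed(self):
        kept, removed = grubbs_filter([0.010, 0.011, 0.50], alpha=0.05)
        assert removed == [0.50]
        assert kept == [0.010, 0.011]

    def test_below_min_n_retained_with_warning(self):
        with pytest.warns(UserWarning, match="n=2"):
            kept, removed = grubbs_filter([0.010, 0.011])
        assert kept == [0.010, 0.011] and removed == []

    def test_order_invariance(self, rng):
        vals = [0.010, 0.013, 0.011, 0.25, 0.012]
        base_kept, base_rm = grubbs_filter(vals)
        for _ in range(5):
            perm = [vals[i] for i in rng.permutation(len(vals))]
            kept, rm = grubbs_filter(perm)
            assert sorted(kept) == sorted(base_kept)
            assert sorted(rm) == sorted(base_rm)

    @pytest.mark.parametrize("n,expected", [(3, 1.1543), (10, 2.2899),
                                            (20, 2.7082)])
    def test_critical_values_match_published_table(self, n, expected):
        # two-sided alpha = 0.05 critical values from the standard table
        assert grubbs_critical(n, 0.05) == pytest.approx(expected, abs=2e-3)


def make_fit(k, se=1e-4, n_obs=12, measurable=True):
    return PeptideRateFit(k=k, se=se, residual_sd=1e-3, n_obs=n_obs,
                          converged=True, measurable=measurable, protein="P")


class TestAggregate:
    def test_single_peptide_passthrough(self):
        res = aggregate_protein([make_fit(0.02, se=3e-4)])
        assert res.k == pytest.approx(0.02)
        assert res.pooled_sd == pytest.approx(3e-4)
        assert res.n_peptides == 1

    def test_symmetric_pooling(self):
        res = aggregate_protein([make_fit(0.02, se=2e-4),
                                 make_fit(0.04, se=2e-4)])
        assert res.k == pytest.approx(0.03)
        assert res.pooled_sd == pytest.approx(2e-4)

    def test_no_measurable_peptides_flagged(self):
        res = aggregate_protein([make_fit(0.0, measurable=False)])
        assert not res.measurable
        assert math.isnan(res.half_life_days)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_protein([])

    def test_coverage_of_pooled_interval(self):
        # 4 peptides sharing k = 0.0211: the protein mean should land inside
        # mean +/- 1.96 * pooled_sd in nearly all replicates
        true_k, sigma = 0.0211, 8e-4
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            fits = [make_fit(true_k + r.normal(0, sigma), se=sigma)
                    for _ in range(4)]
            res = aggregate_protein(fits)
            half = 1.96 * res.pooled_sd
            hits += abs(res.k - true_k) <= half
        assert hits >= 90


class TestHalfLife:
    def test_unit_case(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)

    def test_prg4_reported_value(self):
        # shortest half-life in the cartilage panel: 32.8 d at 25 wk
        assert half_life(0.021133) == pytest.approx(32.8, abs=0.05)

    def test_zero_rate_raises_not_measurable(self):
        with pytest.raises(ValueError, match="not measurable"):
            half_life(0.0)

    def test_round_trip_identity(self):
        for tau in (1.0, 32.8, 3081.0, 277259.0):
            assert half_life(math.log(2) / tau) == pytest.approx(
                tau, rel=1e-12)


class TestDaysToYears:
    @pytest.mark.parametrize("d,yr", [(365.0, 1.0), (0.0, 0.0)])
    def test_simple(self, d, yr):
        assert days_to_years(d) == pytest.approx(yr)

    def test_collagen_extreme(self):
        # 277,259 d prints as 760 yr at the nearest ten
        assert round(days_to_years(277259.0), -1) == 760

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            days_to_years(-1.0)
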