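"""Closed-form moments, master curve, moment closure and summaries."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from tfshare import (
    analytic_moments_single,
    cme_steady_state,
    count_modes,
    fano,
    fold_change,
    master_curve_variance,
    moment_closure_moments,
    promoter_correlation,
    sample_population,
)

from conftest import RATES, make_spec


class TestTelegraphMoments:
    def test_activator_anchor_values(self, activator_single):
        mom = analytic_moments_single(activator_single)
        assert mom.mean == pytest.approx(16.2, abs=1e-9)
        assert mom.variance == pytest.approx(169.8975, abs=1e-4)
        assert mom.fano == pytest.approx(10.4875, abs=1e-4)

    def test_repressor_anchor_values(self, repressor_single):
        mom = analytic_moments_single(repressor_single)
        assert mom.mean == pytest.approx(13.8, abs=1e-9)
        assert mom.variance == pytest.approx(167.4975, abs=1e-4)

    def test_abundant_activators_approach_poisson(self):
        mom = analytic_moments_single(make_spec(n_tf=100_000))
        assert mom.mean == pytest.approx(30.0, rel=1e-3)
        assert mom.fano == pytest.approx(1.0, abs=1e-2)

    def test_out_of_regime_rejected(self):
        with pytest.raises(ValueError, match="single promoter"):
            analytic_moments_single(make_spec(n_promoters=2))
        with pytest.raises(ValueError, match="single promoter"):
            analytic_moments_single(make_spec(n_competitors=1))

    @pytest.mark.parametrize("mode", ["activator", "repressor"])
    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_matches_cme_across_rate_grid(self, mode, scale):
        """The closed form is exact, not approximate: it matches the master
        equation steady state for scaled binding kinetics."""
        spec = make_spec(mode=mode, k_on=RATES["k_on"] * scale, k_off=RATES["k_off"] * scale)
        mom = analytic_moments_single(spec)
        dist = cme_steady_state(spec, tol=1e-10)
        assert dist.mean_m() == pytest.approx(mom.mean, rel=1e-6)
        assert dist.var_m() == pytest.approx(mom.variance, rel=1e-5)


class TestMasterCurve:
    @pytest.mark.parametrize("mode", ["activator", "repressor"])
    @pytest.mark.parametrize("n_tf", [1, 2, 5, 10, 40])
    def test_consistent_with_telegraph_moments(self, rates, mode, n_tf):
        """Plugging the closed-form mean into the master curve returns the
        closed-form variance — the defining property of the curve."""
        mom = analytic_moments_single(make_spec(mode=mode, n_tf=n_tf))
        assert master_curve_variance(rates, mode, mom.mean) == pytest.approx(
            mom.variance, rel=1e-10
        )

    def test_boundary_values(self, rates):
        assert master_curve_variance(rates, "activator", 0.0) == 0.0
        cap = rates["r"] / rates["gamma"]
        # fully occupied promoter transcribes constitutively: Poisson
        assert master_curve_variance(rates, "activator", cap) == pytest.approx(cap)

    def test_domain_enforced(self, rates):
        with pytest.raises(ValueError, match="mean"):
            master_curve_variance(rates, "activator", 31.0)

    def test_single_promoter_competition_stays_near_curve(self, rates):
        """CME points for one promoter sharing TFs with decoys stay within a
        few percent of the curve, and converge onto it as competitor
        kinetics get fast."""
        residual = {}
        for scale in (1.0, 5.0):
            spec = make_spec(
                n_tf=3, n_competitors=5,
                k_on_c=RATES["k_on"] * scale, k_off_c=RATES["k_off"] * scale,
            )
            dist = cme_steady_state(spec)
            pred = master_curve_variance(rates, "activator", dist.mean_m())
            residual[scale] = abs(dist.var_m() - pred) / pred
        assert residual[1.0] < 0.05
        assert residual[5.0] < residual[1.0]

    def test_two_promoters_leave_curve_then_return(self, rates):
        """Collapse failure at TF scarcity; recovery when TFs are abundant."""
        def residual(n_tf):
            dist = cme_steady_state(make_spec(n_promoters=2, n_tf=n_tf, n_competitors=4))
            pred = master_curve_variance(rates, "activator", dist.mean_m() / 2)
            return abs(dist.var_m() / 2 - pred) / pred

        assert residual(3) > 0.1
        assert residual(50) < 1e-3


class TestFoldChangeAndFano:
    def test_fold_change_of_anchor(self, activator_single):
        assert fold_change(16.2, activator_single) == pytest.approx(0.54)
        assert fold_change(0.0, activator_single) == 0.0
        assert fold_change(30.0, activator_single) == pytest.approx(1.0)

    def test_fano_values(self):
        assert fano(30.0, 30.0) == 1.0
        assert fano(16.2, 169.9) == pytest.approx(10.487, abs=1e-3)
        assert fano(10.0, 0.0) == 0.0
        assert math.isnan(fano(0.0, 0.0))


class TestMomentClosure:
    def test_exact_for_single_promoter(self, activator_single, repressor_single):
        for spec in (activator_single, repressor_single):
            approx = moment_closure_moments(spec)
            exact = analytic_moments_single(spec)
            assert approx.mean == pytest.approx(exact.mean, rel=1e-9)
            assert approx.variance == pytest.approx(exact.variance, rel=1e-8)

    def test_near_cme_at_parity(self):
        """At N_P = N_TF = 10 the second-order closure tracks the exact mean
        within 10% (a systematic deviation from neglected cumulants remains)."""
        spec = make_spec(n_promoters=10, n_tf=10)
        approx = moment_closure_moments(spec)
        dist = cme_steady_state(spec)
        assert approx.mean == pytest.approx(dist.mean_m(), rel=0.10)

    def test_silent_without_tfs(self):
        assert moment_closure_moments(make_spec(n_tf=0)).mean == pytest.approx(0.0, abs=1e-12)

    def test_competitors_out_of_scope(self):
        with pytest.raises(ValueError, match="n_competitors"):
            moment_closure_moments(make_spec(n_competitors=1))


class TestCountModes:
    def test_poisson_is_unimodal(self):
        pmf = poisson.pmf(np.arange(120), 30.0)
        report = count_modes(pmf / pmf.sum())
        assert report.n_modes == 1
        assert abs(report.mode_locations[0] - 30) <= 3

    def test_poisson_mixture_is_bimodal(self):
        grid = np.arange(140)
        pmf = 0.5 * poisson.pmf(grid, 30.0) + 0.5 * poisson.pmf(grid, 60.0)
        report = count_modes(pmf / pmf.sum())
        assert report.n_modes == 2
        lo, hi = report.mode_locations
        assert abs(lo - 30) <= 4 and abs(hi - 60) <= 4

    def test_point_mass_is_one_mode(self):
        pmf = np.zeros(50)
        pmf[12] = 1.0
        report = count_modes(pmf)
        assert report.n_modes == 1

    def test_boundary_pileup_counts_as_mode(self):
        """A monotone-decaying component peaked at m=0 is a mode."""
        grid = np.arange(100)
        pmf = 0.4 * poisson.pmf(grid, 0.5) + 0.6 * poisson.pmf(grid, 40.0)
        report = count_modes(pmf / pmf.sum())
        assert report.n_modes == 2
        assert report.mode_locations[0] <= 2

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            count_modes(np.ones(10))


class TestPromoterCorrelation:
    def test_perfect_and_anti_correlation(self):
        from tfshare import PopulationSample

        spec = make_spec(n_promoters=2, n_tf=2)
        mk = lambda mrna: PopulationSample(
            spec=spec, n_cells=len(mrna), burn_in=0.0, seed=0,
            occupancy=np.zeros((len(mrna), 2), dtype=np.int8),
            bound_competitors=np.zeros(len(mrna), dtype=np.int64),
            mrna=np.array(mrna),
        )
        same = mk([[1, 1], [4, 4], [2, 2]])
        assert promoter_correlation(same) == pytest.approx(1.0)
        anti = mk([[0, 1], [1, 0], [0, 1], [1, 0]])
        assert promoter_correlation(anti) == pytest.approx(-1.0)
        flat = mk([[2, 2], [2, 5]])
        assert math.isnan(promoter_correlation(flat))

    def test_abundant_tfs_uncorrelated_in_simulation(self):
        spec = make_spec(n_promoters=2, n_tf=50)
        sample = sample_population(spec, 2000, seed=77)
        assert abs(promoter_correlation(sample)) < 0.08
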