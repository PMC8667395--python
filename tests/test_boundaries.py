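"""Fixed and shrinkage decision boundaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gboins import (
    BINOMIAL,
    BoundaryParams,
    BoundaryRegime,
    boundary_table,
    decision_error_rate,
    g_gamma,
    gamma_schedule,
    gboin_boundaries,
    normal_family,
    optimal_phi1,
    optimal_phi2,
    preset_constants,
    shrinkage_boundaries,
    validate_schedule,
)


def boin_reference(phi0, phi1, phi2):
    """The interval-design boundary formulas coded directly from the
    binary log-ratio expressions (independent of natural_terms)."""
    lam_e = math.log((1 - phi1) / (1 - phi0)) / math.log(
        phi0 * (1 - phi1) / ((1 - phi0) * phi1)
    )
    lam_d = math.log((1 - phi0) / (1 - phi2)) / math.log(
        phi2 * (1 - phi0) / ((1 - phi2) * phi0)
    )
    return lam_e, lam_d


class TestFixedBoundaries:
    def test_binary_standard_target(self, binomial_family):
        pair = gboin_boundaries(
            binomial_family, BoundaryParams(phi0=0.2, phi1=0.12, phi2=0.28)
        )
        assert round(pair.lambda_e, 2) == 0.16
        assert round(pair.lambda_d, 2) == 0.24
        assert pair.lambda_e == pytest.approx(0.1574, abs=5e-4)
        assert pair.lambda_d == pytest.approx(0.2384, abs=5e-4)

    def test_normal_midpoints(self):
        pair = gboin_boundaries(
            normal_family(plugin_value=0.22),
            BoundaryParams(phi0=0.2, phi1=0.12, phi2=0.28),
        )
        assert pair.lambda_e == pytest.approx(0.16)
        assert pair.lambda_d == pytest.approx(0.24)

    def test_matches_reference_formulas(self, binomial_family):
        rng = np.random.default_rng(11)
        for _ in range(20):
            phi0 = rng.uniform(0.1, 0.5)
            phi1 = phi0 * rng.uniform(0.3, 0.9)
            phi2 = phi0 + (1 - phi0) * rng.uniform(0.1, 0.6)
            pair = gboin_boundaries(
                binomial_family, BoundaryParams(phi0=phi0, phi1=phi1, phi2=phi2)
            )
            ref = boin_reference(phi0, phi1, phi2)
            assert pair.lambda_e == pytest.approx(ref[0], abs=1e-12)
            assert pair.lambda_d == pytest.approx(ref[1], abs=1e-12)

    def test_degenerate_hypotheses_error(self, binomial_family):
        params = BoundaryParams(phi0=0.2)
        object.__setattr__(params, "phi1", 0.2)  # bypass construction guard
        with pytest.raises(ValueError, match="degenerate"):
            gboin_boundaries(binomial_family, params)

    def test_normal_sigma_free(self):
        params = BoundaryParams(phi0=0.3, sigma=0.1)
        pairs = {
            sig: gboin_boundaries(normal_family(plugin_value=sig), params)
            for sig in (0.1, 0.5, 2.0)
        }
        vals = {(p.lambda_e, p.lambda_d) for p in pairs.values()}
        assert len(vals) == 1

    def test_encloses_target(self, binomial_family):
        pair = gboin_boundaries(binomial_family, BoundaryParams(phi0=0.25))
        assert pair.lambda_e < 0.25 < pair.lambda_d


class TestGammaSchedule:
    @pytest.mark.parametrize(
        "c,eps,n,expected",
        [
            (math.log(1.1), 0.5, 9, 1.1**3),
            (math.log(1.05), 0.5, 16, 1.05**4),
            (math.log(1.2) / 3, 0.5, 9, 1.2),
        ],
    )
    def test_examples(self, c, eps, n, expected):
        assert gamma_schedule(c, eps, n) == pytest.approx(expected)

    def test_strictly_increasing_in_n(self):
        vals = [gamma_schedule(0.05, 0.5, n) for n in range(1, 60)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [dict(c=0.0), dict(eps=1.0), dict(n=0)])
    def test_preconditions(self, bad):
        kwargs = dict(c=0.1, eps=0.5, n=5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            gamma_schedule(**kwargs)


class TestValidateSchedule:
    def test_only_ordering_violated(self, binomial_family):
        params = BoundaryParams(
            phi0=0.2, c1=math.log(1.05), c2=math.log(1.05) / 3
        )
        warnings = validate_schedule(params, binomial_family, n=9)
        assert len(warnings) == 1
        assert "c1 < c2" in warnings[0]

    def test_all_satisfied(self, binomial_family):
        params = BoundaryParams(
            phi0=0.2, c1=math.log(1.05) / 3, c2=math.log(1.05)
        )
        assert validate_schedule(params, binomial_family, n=9) == []

    def test_nonpositive_c1_warns(self, binomial_family):
        params = BoundaryParams(phi0=0.2, c1=1e-12, c2=0.05)
        object.__setattr__(params, "c1", 0.0)
        warnings = validate_schedule(params, binomial_family, n=9)
        assert any("c1 must be positive" in w for w in warnings)


class TestGGamma:
    def test_normal_algebraic_identity(self):
        """For the normal family the objective reduces to
        sigma^2 log(gamma) / (mu - phi0) + n (mu + phi0) / 2, whose
        stationary point is the closed-form shrinking alternative."""
        nf = normal_family()
        for mu in (0.05, 0.15, 0.3, 0.5):
            for gamma in (1.0, 1.3, 2.5):
                got = g_gamma(nf, mu, 0.2, 9, gamma, sigma=0.22)
                want = (0.22**2) * math.log(gamma) / (mu - 0.2) + 9 * (
                    mu + 0.2
                ) / 2
                assert got == pytest.approx(want)

    def test_binomial_explicit_value(self, binomial_family):
        gamma = 1.157625
        got = g_gamma(binomial_family, 0.1, 0.2, 9, gamma)
        want = (
            math.log(gamma) - 9 * (math.log(0.9) - math.log(0.8))
        ) / (math.log(1 / 9) - math.log(0.25))
        assert got == pytest.approx(want)

    def test_unit_gamma_single_patient_reduces_to_fixed_form(
        self, binomial_family
    ):
        got = g_gamma(binomial_family, 0.12, 0.2, 1, 1.0)
        pair = gboin_boundaries(
            binomial_family, BoundaryParams(phi0=0.2, phi1=0.12, phi2=0.28)
        )
        assert got == pytest.approx(pair.lambda_e)

    def test_zero_denominator(self, binomial_family):
        with pytest.raises(ValueError):
            g_gamma(binomial_family, 0.2, 0.2, 9, 1.1)


class TestOptimalAlternatives:
    def test_normal_closed_forms(self):
        nf = normal_family(plugin_value=0.22)
        assert optimal_phi1(nf, 0.2, 9, 1.331, sigma=0.22) == pytest.approx(
            0.14453, abs=5e-5
        )
        assert optimal_phi2(nf, 0.2, 9, 1.1, sigma=0.22) == pytest.approx(
            0.23202, abs=5e-5
        )

    def test_unit_threshold_collapses(self):
        nf = normal_family(plugin_value=0.22)
        assert optimal_phi1(nf, 0.2, 9, 1.0, sigma=0.22) == 0.2
        assert optimal_phi2(nf, 0.2, 9, 1.0, sigma=0.22) == 0.2

    @pytest.mark.parametrize(
        "phi0,n,gamma", [(0.2, 9, 1.05**3), (0.47, 9, 1.2 ** (3 * 1.0)), (0.3, 15, 1.4)]
    )
    def test_binomial_agrees_with_grid_scan(self, phi0, n, gamma, binomial_family):
        """Brute-force 1e-5-step scan of the objective brackets the optimizer."""
        lo = np.arange(1e-5, phi0 - 1e-5, 1e-5)
        g_lo = [g_gamma(binomial_family, m, phi0, n, gamma) for m in lo]
        assert optimal_phi1(binomial_family, phi0, n, gamma) == pytest.approx(
            lo[int(np.argmax(g_lo))], abs=1e-4
        )
        hi = np.arange(phi0 + 1e-5, 1 - 1e-5, 1e-5)
        g_hi = [g_gamma(binomial_family, m, phi0, n, gamma) for m in hi]
        assert optimal_phi2(binomial_family, phi0, n, gamma) == pytest.approx(
            hi[int(np.argmin(g_hi))], abs=1e-4
        )

    def test_bracket_and_monotone_convergence(self, binomial_family):
        """phi1* < phi0 < phi2* always, both approaching phi0 in n."""
        phi0, c1, c2 = 0.3, math.log(1.1), math.log(1.1) / 3
        prev = (0.0, 1.0)
        for n in range(7, 60, 4):
            g1 = gamma_schedule(c1, 0.5, n)
            g2 = gamma_schedule(c2, 0.5, n)
            f1 = optimal_phi1(binomial_family, phi0, n, g1)
            f2 = optimal_phi2(binomial_family, phi0, n, g2)
            assert f1 < phi0 < f2
            assert f1 >= prev[0] and f2 <= prev[1]
            prev = (f1, f2)


class TestShrinkageBoundaries:
    def test_lead_in_uses_fixed_pair(self, table1_continuous_params):
        nf = normal_family(plugin_value=0.22)
        pair = shrinkage_boundaries(nf, table1_continuous_params, 3)
        assert pair.regime is BoundaryRegime.FIXED_GBOIN
        assert (round(pair.lambda_e, 2), round(pair.lambda_d, 2)) == (0.16, 0.24)

    def test_tabulated_continuous_cells(self, table1_continuous_params):
        nf = normal_family(plugin_value=0.22)
        pair = shrinkage_boundaries(nf, table1_continuous_params, 9)
        assert pair.regime is BoundaryRegime.SHRINKAGE
        assert (round(pair.lambda_e, 2), round(pair.lambda_d, 2)) == (0.17, 0.22)
        params3 = BoundaryParams(
            phi0=0.3, c1=math.log(1.1), c2=math.log(1.1) / 3, sigma=0.33
        )
        pair3 = shrinkage_boundaries(normal_family(plugin_value=0.33), params3, 12)
        assert round(pair3.lambda_e, 2) == 0.26

    def test_sigma_scales_offset_linearly(self):
        params = BoundaryParams(phi0=0.2, c1=math.log(1.1), c2=math.log(1.1) / 3)
        offsets = []
        for sig in (0.11, 0.22, 0.44):
            pair = shrinkage_boundaries(
                normal_family(plugin_value=sig), params, 12, sigma=sig
            )
            offsets.append(0.2 - pair.lambda_e)
        assert offsets[1] == pytest.approx(2 * offsets[0])
        assert offsets[2] == pytest.approx(4 * offsets[0])

    def test_quasi_binomial_scale_consistency(self, quasi_family, binomial_family):
        """Grade-score boundaries are the binary boundaries of the
        normalized target, rescaled by the maximal score."""
        params_raw = BoundaryParams(
            phi0=0.47, c1=math.log(1.2), c2=math.log(1.2) / 3
        )
        params_norm = BoundaryParams(
            phi0=0.47 / 1.5, c1=math.log(1.2), c2=math.log(1.2) / 3
        )
        for n in (3, 9, 15):
            q = shrinkage_boundaries(quasi_family, params_raw, n)
            b = shrinkage_boundaries(binomial_family, params_norm, n)
            assert q.lambda_e == pytest.approx(1.5 * b.lambda_e)
            assert q.lambda_d == pytest.approx(1.5 * b.lambda_d)


class TestBoundaryTable:
    def test_lead_in_covering_grid_is_all_fixed(self, binomial_family):
        params = BoundaryParams(
            phi0=0.2, c1=math.log(1.05), c2=math.log(1.05) / 3, n0=30
        )
        table = boundary_table(binomial_family, params, list(range(3, 31, 3)))
        assert set(table.regime) == {"fixed_gboin"}
        assert table.lambda_e.nunique() == 1

    def test_rejects_unsorted_grid(self, binomial_family, table1_binary_params):
        with pytest.raises(ValueError):
            boundary_table(binomial_family, table1_binary_params, [9, 3])

    def test_rounding_is_display_only(self, binomial_family, table1_binary_params):
        table = boundary_table(binomial_family, table1_binary_params, [3, 9])
        assert (table.lambda_e != table.lambda_e_raw).any()
        assert np.allclose(table.lambda_e, np.round(table.lambda_e_raw, 2), atol=5e-3)

    def test_nonoscillation_toward_target(self):
        """Both boundaries approach the target monotonically beyond the
        lead-in (2-dp plateaus allowed on the raw scale via a tolerance)."""
        for phi0 in (0.2, 0.3):
            c1, c2 = preset_constants("table1", "normal", phi0)
            params = BoundaryParams(phi0=phi0, c1=c1, c2=c2, sigma=1.1 * phi0)
            table = boundary_table(
                normal_family(plugin_value=1.1 * phi0), params, range(3, 31, 3)
            )
            gap_e = (phi0 - table.lambda_e_raw).to_numpy()
            gap_d = (table.lambda_d_raw - phi0).to_numpy()
            assert np.all(np.diff(gap_e) <= 1e-12)
            assert np.all(np.diff(gap_d) <= 1e-12)


class TestDecisionErrorRate:
    def test_single_patient_enumeration(self, binomial_family):
        # one binary outcome never lands inside (0.157, 0.238): retainment is
        # impossible, so H0 is always decided incorrectly; under H1 the
        # escalation fails on y=1; under H2 the de-escalation fails on y=0.
        alpha = decision_error_rate(
            binomial_family, 0.157, 0.238, 0.2, 0.12, 0.28, n=1
        )
        expected = (1.0 + 0.12 + (1 - 0.28)) / 3
        assert alpha == pytest.approx(expected)

    def test_always_retain_limit(self, binomial_family):
        alpha = decision_error_rate(
            binomial_family, -10.0, 10.0, 0.2, 0.12, 0.28, n=6
        )
        assert alpha == pytest.approx(2 / 3)

    def test_normal_closed_form_matches_simulation(self):
        nf = normal_family()
        rng = np.random.default_rng(3)
        n, sigma = 12, 0.22
        lam_e, lam_d = 0.16, 0.24
        alpha = decision_error_rate(nf, lam_e, lam_d, 0.2, 0.12, 0.28, n, sigma)
        draws = 200_000
        wrong = 0.0
        for mu, cond in ((0.2, "r"), (0.12, "e"), (0.28, "d")):
            means = rng.normal(mu, sigma / math.sqrt(n), draws)
            if cond == "r":
                wrong += np.mean((means <= lam_e) | (means >= lam_d))
            elif cond == "e":
                wrong += np.mean(means > lam_e)
            else:
                wrong += np.mean(means < lam_d)
        assert alpha == pytest.approx(wrong / 3, abs=5e-3)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    phi0=st.floats(0.1, 0.45),
    f1=st.floats(0.3, 0.9),
    f2=st.floats(1.1, 1.8),
    n=st.integers(7, 200),
)
def test_shrinkage_interval_always_brackets_target(phi0, f1, f2, n):
    """lambda_e < phi0 < lambda_d in every regime and at every sample size."""
    params = BoundaryParams(
        phi0=phi0,
        phi1=phi0 * f1,
        phi2=min(phi0 * f2, 0.97),
        c1=math.log(1.1),
        c2=math.log(1.1) / 3,
    )
    pair = shrinkage_boundaries(BINOMIAL, params, n)
    assert pair.lambda_e < phi0 < pair.lambda_d
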