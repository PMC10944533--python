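"""Activity curves, EC thresholds and effective Hill coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from switchnoise import activity as act
from switchnoise.model_core import Architecture, ParameterSet, ValidationError


def brute_force_cooperative_activity(x: float, c: float) -> float:
    """Independent oracle: Boltzmann sum over the 8 site-occupancy
    microstates with per-site weight x and sequential cooperativity factors
    (second binding /c, third /c^2 relative to independent binding)."""
    weights = {}
    for bits in range(8):
        occ = bin(bits).count("1")
        w = x**occ
        if occ == 2:
            w /= c
        elif occ == 3:
            w /= c**3
        weights[bits] = w
    z = sum(weights.values())
    return 1.0 - weights[0b111] / z


class TestCooperativeActivity:
    def test_symmetric_point(self):
        assert act.cooperative_activity(1.0, 1.0) == pytest.approx(1 - 0.5**3)

    def test_no_repressor(self):
        for c in (1.0, 0.1, 1e-3):
            assert act.cooperative_activity(0.0, c) == 1.0

    def test_against_boltzmann_enumeration(self):
        for x, c in [(2.0, 0.1), (0.5, 0.01), (1.7, 0.9), (0.05, 0.3)]:
            assert act.cooperative_activity(x, c) == pytest.approx(
                brute_force_cooperative_activity(x, c), rel=1e-12
            )

    @given(x=st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_independent_sites_closed_form(self, x):
        """c = 1 reduces to 1 - (x/(1+x))^3."""
        assert act.cooperative_activity(x, 1.0) == pytest.approx(
            1 - (x / (1 + x)) ** 3, abs=1e-12
        )

    def test_invalid_cooperativity(self):
        with pytest.raises(ValidationError):
            act.cooperative_activity(1.0, 0.0)
        with pytest.raises(ValidationError):
            act.cooperative_activity(1.0, 1.5)


class TestECThresholds:
    def _curve(self, f, grid):
        return act.ActivityCurve(grid, f(grid), Architecture.COOPERATIVE)

    def test_michaelis_menten(self):
        grid = np.geomspace(1e-3, 1e3, 400)
        f = lambda x: 1 / (1 + x)  # noqa: E731
        ec90, ec10 = act.ec_thresholds(self._curve(f, grid), f=f)
        assert ec90 == pytest.approx(1 / 9, rel=1e-5)
        assert ec10 == pytest.approx(9.0, rel=1e-5)

    def test_hill_3(self):
        grid = np.geomspace(1e-2, 1e2, 400)
        f = lambda x: 1 / (1 + x**3)  # noqa: E731
        ec90, ec10 = act.ec_thresholds(self._curve(f, grid), f=f)
        assert ec90 == pytest.approx((1 / 9) ** (1 / 3), rel=1e-5)
        assert ec10 == pytest.approx(9 ** (1 / 3), rel=1e-5)

    def test_noncooperative_three_site_curve(self):
        """EC values frozen from an independent root solve of
        1 - (x/(1+x))^3 crossing 0.9 and 0.1."""
        f = lambda x: 1 - (x / (1 + x)) ** 3  # noqa: E731
        ec90_oracle = brentq(lambda x: f(x) - 0.9, 1e-6, 10)
        ec10_oracle = brentq(lambda x: f(x) - 0.1, 1, 100)
        assert ec90_oracle == pytest.approx(0.8662, rel=1e-3)
        assert ec10_oracle == pytest.approx(27.9768, rel=1e-3)
        grid = np.geomspace(1e-2, 1e2, 400)
        ec90, ec10 = act.ec_thresholds(self._curve(f, grid), f=f)
        assert ec90 == pytest.approx(ec90_oracle, rel=1e-4)
        assert ec10 == pytest.approx(ec10_oracle, rel=1e-4)

    def test_unbracketed_target_raises(self):
        grid = np.linspace(0.0, 1.0, 50)
        curve = act.ActivityCurve(
            grid, 0.5 * np.ones_like(grid), Architecture.SEQUESTRATION
        )
        with pytest.raises(act.BracketingError, match="extend"):
            act.ec_thresholds(curve)


class TestEffectiveHill:
    @pytest.mark.parametrize(
        "ec90,ec10,expected",
        [
            (1 / 9, 9.0, 1.0),
            ((1 / 9) ** (1 / 3), 9 ** (1 / 3), 3.0),
            (0.8662, 27.977, 1.2646),
        ],
    )
    def test_values(self, ec90, ec10, expected):
        assert act.effective_hill(ec90, ec10) == pytest.approx(expected, rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            act.effective_hill(9.0, 1 / 9)

    @given(n=st.floats(0.5, 20.0), k=st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_recovers_hill_exponent(self, n, k):
        """For an exact Hill-n curve the effective Hill coefficient is n."""
        ec90 = k * (1 / 9) ** (1 / n)
        ec10 = k * 9 ** (1 / n)
        assert act.effective_hill(ec90, ec10) == pytest.approx(n, rel=1e-9)


class TestSequestrationActivity:
    def test_deep_titration_limits(self):
        """With sequestration much tighter than DNA binding (K_s << K_a,
        both far below A_T) the switch is all-or-none around the molar
        ratio 1: activity ~1 in activator excess, ~0 in repressor excess.
        (Free activator in repressor excess is ~ K_s*A_T/(load-1), so the
        off-state limit requires K_s << K_a, not merely both small.)"""
        p = ParameterSet(A_T=100, K_a=1e-2, K_s=1e-6, k_on=1.0)
        lo = act.meanfield_point(Architecture.SEQUESTRATION, p, R_T=50.0)["activity"]
        hi = act.meanfield_point(Architecture.SEQUESTRATION, p, R_T=150.0)["activity"]
        assert lo == pytest.approx(1.0, abs=1e-3)
        assert hi == pytest.approx(0.0, abs=1e-3)

    def test_meanfield_matches_cme_at_moderate_titration(self):
        p = ParameterSet(A_T=100, R_T=90, K_a=1.0, K_s=1.0, alpha=10.0, k_on=1.0)
        mf = act.meanfield_point(Architecture.SEQUESTRATION, p)["activity"]
        curve = act.sequestration_activity(
            Architecture.SEQUESTRATION, p, loads=[0.9], backend="cme"
        )
        assert mf == pytest.approx(curve.activity[0], rel=0.02)

    @pytest.mark.parametrize("ka", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("ks", [0.25, 1.0, 4.0])
    def test_meanfield_cme_agreement_grid(self, ka, ks):
        """Mean-field activity within 2% of the exact CME promoter marginal
        for A_T = 100 across a 3x3 grid of normalized constants."""
        p = ParameterSet(A_T=100, R_T=90, K_a=ka, K_s=ks, alpha=10.0, k_on=1.0)
        mf = act.meanfield_point(Architecture.SEQUESTRATION, p)["activity"]
        cme_val = act.sequestration_activity(
            Architecture.SEQUESTRATION, p, loads=[0.9], backend="cme"
        ).activity[0]
        assert abs(mf - cme_val) / cme_val < 0.02

    @pytest.mark.parametrize(
        "arch",
        [
            Architecture.COOPERATIVE,
            Architecture.SEQUESTRATION,
            Architecture.SEQ_BLOCK,
            Architecture.SEQ_BLOCK_DISP,
        ],
    )
    def test_activity_curves_monotone_non_increasing(self, arch, default_params):
        p = default_params(arch)
        curve = act.activity_curve(arch, p)
        assert (np.diff(curve.activity) <= 1e-8).all()
        assert ((curve.activity >= 0) & (curve.activity <= 1)).all()

    def test_cooperativity_sharpens_transition(self, default_params):
        p = default_params(Architecture.COOPERATIVE)
        n_effs = [
            act.hill_summary(Architecture.COOPERATIVE, p.replace(c=c)).n_eff
            for c in (1.0, 0.3, 0.1, 0.01)
        ]
        assert all(a < b for a, b in zip(n_effs, n_effs[1:]))

    def test_stronger_activator_sharpens_sequestration(self):
        """With tight sequestration, decreasing K_a (stronger DNA binding)
        sharpens the titration transition."""
        p = ParameterSet(A_T=100, K_s=1e-3, k_on=1.0)
        n_effs = [
            act.hill_summary(Architecture.SEQUESTRATION, p.replace(K_a=ka)).n_eff
            for ka in (10.0, 3.0, 1.0, 0.3)
        ]
        assert all(a < b for a, b in zip(n_effs, n_effs[1:]))

    def test_grid_auto_extension(self):
        """Hill summary succeeds when the default grid misses a crossing."""
        p = ParameterSet(A_T=100, K_a=1.0, K_s=2.0, k_on=1.0)
        hs = act.hill_summary(Architecture.SEQUESTRATION, p)
        assert hs.EC10 > 2.0  # found beyond the default [0, 2] grid
        assert hs.n_eff > 0
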