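"""Exactness and structural tests of the master-equation engine."""

import numpy as np
import pytest
from scipy import stats

from switchnoise import cme
from switchnoise.model_core import (
    Architecture,
    ParameterSet,
    build_network,
    constitutive_network,
    telegraph_network,
)

from conftest import scaled_default_params


class TestEnumeration:
    def test_sequestration_count(self):
        """A_T = R_T = 10: E_F admits n_RA 0..10 and E_A 0..9, so 21
        promoter/complex combinations times 51 mRNA levels."""
        p = ParameterSet(A_T=10, R_T=10, K_a=1.0, K_s=1.0, alpha=10.0, k_on=1.0)
        net = build_network(Architecture.SEQUESTRATION, p)
        assert cme.enumerate_states(net, 50).n_states == 21 * 51

    def test_cooperative_count(self):
        p = ParameterSet(K_r=100.0, c=1.0, R_T=5, alpha=10.0)
        net = build_network(Architecture.COOPERATIVE, p)
        assert cme.enumerate_states(net, 50).n_states == 8 * 51

    def test_mrna_cap_zero_gives_promoter_chain(self):
        p = ParameterSet(K_r=100.0, c=1.0, R_T=5, alpha=10.0)
        net = build_network(Architecture.COOPERATIVE, p)
        assert cme.enumerate_states(net, 0).n_states == 8

    def test_state_count_cap(self):
        p = ParameterSet(A_T=40, R_T=40, K_a=1.0, K_s=1.0, alpha=10.0, k_on=1.0)
        net = build_network(Architecture.SEQUESTRATION, p)
        with pytest.raises(cme.StateSpaceSizeError, match="reduce"):
            cme.enumerate_states(net, 50, max_states=100)


class TestGenerator:
    @pytest.mark.parametrize(
        "arch",
        [Architecture.SEQUESTRATION, Architecture.SEQ_BLOCK_DISP],
    )
    def test_columns_sum_to_zero(self, arch):
        p = scaled_default_params(arch, A_T=10)
        net = build_network(arch, p.replace(R_T=10))
        space = cme.enumerate_states(net, 20)
        Q = cme.build_generator(net, space)
        colsum = np.abs(np.asarray(Q.sum(axis=0))).max()
        assert colsum < 1e-12

    def test_birth_death_generator_is_tridiagonal(self):
        net = constitutive_network(5.0, 1.0)
        space = cme.enumerate_states(net, 40)
        Q = cme.build_generator(net, space).tocoo()
        m_col = space.states[:, net.index["M"]]
        assert (np.abs(m_col[Q.row] - m_col[Q.col]) <= 1).all()

    def test_detailed_balance_on_binding_edges(self):
        """Without the displacement drive, every binding edge satisfies
        pairwise flux balance at stationarity."""
        p = ParameterSet(A_T=8, R_T=8, K_a=0.5, K_s=2.0, K_b=1.5, alpha=5.0, k_on=1.0)
        net = build_network(Architecture.SEQ_BLOCK, p)
        space = cme.enumerate_states(net, 0)
        Q = cme.build_generator(net, space)
        dist = cme.steady_state(Q, space, check_tail=False)
        deltas = net.stoichiometry()
        by_name = {r.name: j for j, r in enumerate(net.reactions)}
        pairs = [
            ("activator_binding", "activator_unbinding"),
            ("sequestration", "complex_dissociation"),
            ("blocking", "unblocking"),
        ]
        for fwd, rev in pairs:
            jf, jr = by_name[fwd], by_name[rev]
            for i, s in enumerate(space.states):
                flux_f = net.propensity(s, jf) * dist.p[i]
                if flux_f == 0:
                    continue
                t = s + deltas[jf]
                k = space.lookup(t[None, :])[0]
                assert k >= 0
                flux_r = net.propensity(space.states[k], jr) * dist.p[k]
                assert flux_f == pytest.approx(flux_r, rel=1e-8)


class TestExactness:
    def test_poisson_limit(self):
        """Constitutive gene: stationary mRNA is exactly Poisson(alpha/beta)."""
        dist = cme.solve(constitutive_network(10.0, 1.0))
        pm = dist.mrna_marginal()
        ref = stats.poisson.pmf(np.arange(len(pm)), 10.0)
        assert np.abs(pm - ref).max() < 1e-9
        ns = cme.noise_summary(dist)
        assert ns.fano == pytest.approx(1.0, abs=1e-8)

    def test_telegraph_closed_form(self):
        """Two-state promoter closed form: mean alpha/(beta) * p_on and
        Fano 1 + alpha k_off / ((k_on+k_off)(k_on+k_off+beta))."""
        dist = cme.solve(telegraph_network(1.0, 1.0, 10.0, 1.0))
        ns = cme.noise_summary(dist)
        assert ns.mean == pytest.approx(5.0, abs=1e-8)
        assert ns.fano == pytest.approx(8.0 / 3.0, abs=1e-8)

    def test_moment_engine_matches_closed_forms(self):
        ns = cme.noise_moments(telegraph_network(1.0, 1.0, 10.0, 1.0))
        assert ns.mean == pytest.approx(5.0, abs=1e-8)
        assert ns.fano == pytest.approx(8.0 / 3.0, abs=1e-8)
        ns = cme.noise_moments(constitutive_network(10.0, 1.0))
        assert ns.fano == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "arch",
        [
            Architecture.COOPERATIVE,
            Architecture.SEQUESTRATION,
            Architecture.SEQ_BLOCK,
            Architecture.SEQ_BLOCK_DISP,
        ],
    )
    def test_moment_engine_matches_full_distribution(self, arch):
        """The promoter-chain moment equations agree with the full truncated
        joint solve to solver precision (dual-route internal consistency)."""
        p = scaled_default_params(arch, A_T=30, alpha=20.0)
        if arch is Architecture.COOPERATIVE:
            p = p.replace(alpha=20.0, R_T=25)
        else:
            p = p.replace(R_T=31)
        net = build_network(arch, p)
        mom = cme.noise_moments(net)
        full = cme.noise_summary(cme.solve(net))
        assert mom.mean == pytest.approx(full.mean, rel=1e-7)
        assert mom.variance == pytest.approx(full.variance, rel=1e-6)

    def test_stationary_mean_is_activity_times_burst_scale(self):
        """At stationarity E[m] = (alpha/beta) P(transcribing) exactly."""
        p = scaled_default_params(Architecture.SEQUESTRATION, A_T=20, alpha=15.0)
        net = build_network(Architecture.SEQUESTRATION, p.replace(R_T=21))
        dist = cme.solve(net)
        ns = cme.noise_summary(dist)
        assert ns.mean == pytest.approx(
            15.0 * dist.transcribing_probability(), rel=1e-8
        )


class TestTruncation:
    def test_tail_mass_control(self):
        """Doubling M_max changes mean and Fano by < 1e-6."""
        p = scaled_default_params(Architecture.SEQUESTRATION, A_T=20, alpha=15.0)
        net = build_network(Architecture.SEQUESTRATION, p.replace(R_T=21))
        m1 = cme.default_M_max(p)
        d1 = cme.noise_summary(cme.solve(net, M_max=m1))
        d2 = cme.noise_summary(cme.solve(net, M_max=2 * m1))
        assert d1.mean == pytest.approx(d2.mean, abs=1e-6)
        assert d1.fano == pytest.approx(d2.fano, abs=1e-6)

    def test_undersized_truncation_raises_then_autodoubles(self):
        net = constitutive_network(20.0, 1.0)
        space = cme.enumerate_states(net, 25)  # mean 20: cap 25 is too tight
        Q = cme.build_generator(net, space)
        with pytest.raises(cme.TruncationError):
            cme.steady_state(Q, space)
        dist = cme.solve(net, M_max=25)  # auto-doubling rescues it
        assert cme.noise_summary(dist).mean == pytest.approx(20.0, abs=1e-6)


class TestNoiseSummary:
    def test_poisson_marginal(self):
        pm = stats.poisson.pmf(np.arange(60), 10.0)
        ns = cme.NoiseSummary.from_marginal(pm)
        assert ns.fano == pytest.approx(1.0, abs=1e-6)
        assert ns.cv == pytest.approx(1 / np.sqrt(10.0), rel=1e-4)
        assert ns.modes == 1

    def test_zero_inflated_mixture_is_bimodal(self):
        pm = 0.5 * np.eye(1, 80, 0).ravel() + 0.5 * stats.poisson.pmf(np.arange(80), 20.0)
        ns = cme.NoiseSummary.from_marginal(pm)
        assert ns.modes == 2

    def test_degenerate_zero_distribution(self):
        pm = np.zeros(10)
        pm[0] = 1.0
        ns = cme.NoiseSummary.from_marginal(pm)
        assert ns.mean == 0 and ns.cv is None and ns.fano == 1.0

    def test_strong_activator_trp_marginal_bimodal_weak_unimodal(self):
        strong = scaled_default_params(Architecture.SEQUESTRATION, A_T=50)
        weak = strong.replace(K_a=5.0)  # normalized K_a = 0.1
        mods = {}
        for tag, p in (("strong", strong), ("weak", weak)):
            net = build_network(Architecture.SEQUESTRATION, p.replace(R_T=53))
            mods[tag] = cme.noise_summary(cme.solve(net)).modes
        assert mods["strong"] >= 2
        assert mods["weak"] == 1


class TestFanoCurve:
    def test_rows_in_grid_order_with_noise_columns(self):
        p = scaled_default_params(Architecture.SEQUESTRATION, A_T=20, alpha=15.0)
        loads = [0.5, 0.9, 1.1, 1.5]
        table = cme.fano_curve(Architecture.SEQUESTRATION, p, loads)
        assert list(table["load"]) == loads
        assert (table["fano"] > 0).all()
        assert (table["mean"].iloc[0] > table["mean"].iloc[-1])
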