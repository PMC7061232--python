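"""Unit tests of the structured-coalescent state spaces, generators,
densities and topology probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tasti.model import (
    _ABC_UNCOALESCED,
    CANONICAL_TOPOLOGIES,
    Configuration,
    ModelParameters,
    ParameterError,
    STATES_AB,
    STATES_ABC,
    all_configurations,
    build_generator,
    discordance_probability,
    internal_branch_bound,
    joint_density,
    map_state,
    marginal_density_h,
    topology_probabilities,
    transition_matrix,
)


def sym_omega(M, dtau, theta=0.005, tau1=0.0, config=None, N=5e4):
    config = config or Configuration(("A", "B", "C"), shared="B")
    return ModelParameters.symmetric(config, tau1, tau1 + dtau, theta, M, N)


class TestConfigurations:
    def test_six_distinct_configurations(self):
        configs = all_configurations(["A", "B", "C"])
        assert len(configs) == 6
        assert len(set(configs)) == 6
        assert {c.topology[2] for c in configs} == {"A", "B", "C"}

    def test_shared_must_be_ingroup(self):
        with pytest.raises(ParameterError):
            Configuration(("A", "B", "C"), shared="C")

    def test_gene_topology_role_mapping(self):
        cfg = Configuration(("A", "B", "C"), shared="B")
        assert cfg.solo == "A"
        assert cfg.gene_topology("((ab)c)") == frozenset("AB")
        assert cfg.gene_topology("((ac)b)") == frozenset("AC")
        assert cfg.gene_topology("((bc)a)") == frozenset("BC")


class TestGenerators:
    def test_pair_generator_entries(self):
        gen = build_generator("AB", (0.005, 0.005), (5.0, 5.0))
        q = gen.matrix
        assert q[0, 2] == 5.0  # a1b2 -> a1b1: b migrates to deme 1
        assert q[2, 4] == pytest.approx(400.0)  # a1b1 -> (ab)1 at 2/theta
        assert q[0, 1] == 0.0  # no simultaneous double migration
        assert q[4, 5] == 5.0 and q[5, 4] == 5.0  # coalesced pair migrates

    @pytest.mark.parametrize("kind", ["AB", "XY", "ABC"])
    @pytest.mark.parametrize(
        "theta,M", [((0.005, 0.005), (5.0, 5.0)), ((0.002, 0.01), (0.3, 40.0))]
    )
    def test_rows_sum_to_zero_offdiag_nonneg(self, kind, theta, M):
        q = build_generator(kind, theta, M).matrix
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-9)
        off = q - np.diag(np.diag(q))
        assert (off >= 0).all()

    def test_triple_coalescence_rates_from_all_in_one_deme(self):
        q = build_generator("ABC", (0.005, 0.005), (5.0, 5.0)).matrix
        s = _ABC_UNCOALESCED.index((1, 1, 1))  # a1b1c1
        coal = q[s, 8:]
        # each of the three pairs coalesces in deme 1 at 2/theta
        assert coal.sum() == pytest.approx(3 * 400.0)
        assert sorted(coal[coal > 0]) == pytest.approx([400.0] * 3)

    def test_coalesced_triple_states_are_absorbing(self):
        q = build_generator("ABC", (0.005, 0.005), (5.0, 5.0)).matrix
        assert np.all(q[8:, :] == 0.0)

    def test_single_event_transitions_only(self):
        q = build_generator("ABC", (0.005, 0.005), (5.0, 5.0)).matrix
        for i, src in enumerate(_ABC_UNCOALESCED):
            for j, dst in enumerate(_ABC_UNCOALESCED):
                if i != j and q[i, j] > 0:
                    assert sum(a != b for a, b in zip(src, dst)) == 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            build_generator("AB", (0.0, 0.005), (5.0, 5.0))
        with pytest.raises(ParameterError):
            build_generator("AB", (0.005, 0.005), (-1.0, 5.0))
        with pytest.raises(ParameterError):
            build_generator("XYZ", (0.005, 0.005), (5.0, 5.0))


class TestStateMappings:
    @pytest.mark.parametrize(
        "mapping,s,expected",
        [
            ("phi1", 5, 1),
            ("phi1", 6, 4),
            ("phi2", 1, 5),
            ("phi2", 2, 6),
            ("phi2", 3, 7),  # a1b1 joined by c in deme 2 -> a1b1c2
            ("phi2", 4, 8),
            ("phi3", 19, 2),  # (bc)2 with a in deme 1 -> x2y1
            ("phi3", 9, 3),
            ("phi3", 12, 4),
            ("phi3", 14, 1),
        ],
    )
    def test_worked_examples(self, mapping, s, expected):
        assert map_state(mapping, s) == expected

    @pytest.mark.parametrize("mapping,s", [("phi1", 1), ("phi2", 5), ("phi3", 3)])
    def test_domain_errors(self, mapping, s):
        with pytest.raises(ParameterError):
            map_state(mapping, s)

    def test_state_space_sizes_and_labels(self):
        assert len(STATES_AB) == 6
        assert len(STATES_ABC) == 20
        assert STATES_ABC[7] == "a2b2c2"
        assert STATES_ABC[18] == "(bc)2a1"


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        gen = build_generator("AB", (0.005, 0.005), (5.0, 5.0))
        assert np.allclose(transition_matrix(gen, 0.0), np.eye(6))

    def test_rows_stochastic_and_absorbing_limit(self):
        gen = build_generator("AB", (0.005, 0.005), (5.0, 5.0))
        p = transition_matrix(gen, 2.75e-3)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= -1e-12).all() and (p <= 1 + 1e-12).all()
        p_inf = transition_matrix(gen, 10.0)
        assert p_inf[0, 4] + p_inf[0, 5] == pytest.approx(1.0, abs=1e-9)

    def test_negative_time_rejected(self):
        gen = build_generator("AB", (0.005, 0.005), (5.0, 5.0))
        with pytest.raises(ParameterError):
            transition_matrix(gen, -1e-6)

    def test_matches_gillespie_frequencies(self, rng):
        """e^{Qt} row 1 vs empirical state occupancy of simulated paths."""
        gen = build_generator("AB", (0.005, 0.005), (5.0, 5.0))
        q = gen.matrix
        t_end, n = 2.75e-3, 30_000
        counts = np.zeros(6)
        for _ in range(n):
            s, t = 0, 0.0
            while True:
                rate = -q[s, s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if t + wait >= t_end:
                    break
                t += wait
                probs = np.clip(q[s], 0, None)
                probs[s] = 0
                s = rng.choice(6, p=probs / probs.sum())
            counts[s] += 1
        freq = counts / n
        expected = transition_matrix(gen, t_end)[0]
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(freq - expected) <= 3 * se + 1e-12).all()


class TestMarginalDensities:
    def test_process_starts_in_a1b2(self):
        om = sym_omega(5.0, 2.75e-3)
        assert marginal_density_h("hAB22", 0.0, 1, om) == pytest.approx(1.0)
        for s in (2, 3, 4):
            assert marginal_density_h("hAB22", 0.0, s, om) == pytest.approx(0.0)

    def test_total_probability_partition(self):
        """Integrated first-coalescence density plus surviving transient
        mass accounts for all probability on the internal branch."""
        from scipy.integrate import quad

        om = sym_omega(5.0, 2.75e-3)
        t_end = om.dtau
        absorbed, _ = quad(
            lambda t: marginal_density_h("hAB21", t, 5, om)
            + marginal_density_h("hAB21", t, 6, om),
            0.0,
            t_end,
            limit=200,
        )
        surviving = sum(
            marginal_density_h("hAB22", t_end, s, om) for s in (1, 2, 3, 4)
        )
        assert absorbed + surviving == pytest.approx(1.0, abs=1e-8)

    def test_first_passage_density_matches_simulated_times(self, rng):
        """hAB21 into deme 1 vs a histogram of simulated first-coalescence
        times (coalescences into (ab)1 before the root)."""
        from tasti.simulate import simulate_history

        om = sym_omega(50.0, 6.5e-3, tau1=0.0)
        n = 40_000
        lo, hi = 1e-3, 2e-3
        hits = 0
        for _ in range(n):
            h = simulate_history(om, rng)
            if h.t1 < om.tau2 and lo <= h.t1 < hi:
                ev = [e for e in h.path if e[2] == "(ab)1" and e[0] == h.t1]
                if ev:
                    hits += 1
        from scipy.integrate import quad

        expected, _ = quad(
            lambda t: marginal_density_h("hAB21", t, 5, om), lo, hi, limit=100
        )
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) <= 3 * se + 1e-12

    def test_state_domain_errors(self):
        om = sym_omega(5.0, 2.75e-3)
        with pytest.raises(ParameterError):
            marginal_density_h("hAB21", 1e-3, 3, om)
        with pytest.raises(ParameterError):
            marginal_density_h("hABC32", 1e-3, (1, 9), om)


class TestJointDensity:
    def test_internal_branch_supports_only_concordant(self):
        om = sym_omega(5.0, 2.75e-3, tau1=1e-3)
        assert joint_density(1, 2e-3, 5e-3, "((bc)a)", om) == 0.0
        assert joint_density(1, 2e-3, 5e-3, "((ab)c)", om) > 0.0

    def test_above_root_indicator(self):
        om = sym_omega(5.0, 2.75e-3, tau1=1e-3)
        # t1 below the root: f3 carries no mass
        assert joint_density(3, 2e-3, 5e-3, "((ac)b)", om) == 0.0
        assert joint_density(3, 4e-3, 5e-3, "((ac)b)", om) > 0.0
        # mismatched topology
        assert joint_density(3, 4e-3, 5e-3, "((bc)a)", om) == 0.0
        # t ordering violated
        assert joint_density(2, 5e-3, 4e-3, "((ab)c)", om) == 0.0

    def test_densities_integrate_to_one(self):
        """The quadrature route integrates all four joint densities over
        their supports; the total must be 1."""
        for M, dtau in ((0.5, 2.5e-4), (50.0, 2.75e-3)):
            om = sym_omega(M, dtau, tau1=1e-3)
            assert sum(topology_probabilities(om, "quadrature")) == pytest.approx(
                1.0, abs=1e-7
            )


class TestTopologyProbabilities:
    # reference concordance values; the internal branch lengths are those the
    # quadruples are mutually consistent with (confirmed by the
    # unstructured-limit closed form)
    @pytest.mark.parametrize(
        "M,dtau,expected",
        [
            (0.5, 2.5e-3, 3.62e-3),
            (5.0, 2.5e-3, 3.46e-2),
            (50.0, 2.5e-3, 0.236),
            (4e7, 2.5e-3, 0.596),
            (0.5, 2.5e-4, 1.83e-3),
            (5.0, 2.5e-4, 1.75e-2),
            (50.0, 2.5e-4, 0.122),
            (4e7, 2.5e-4, 0.366),
        ],
    )
    def test_concordance_probabilities(self, M, dtau, expected):
        p_ab, _, _ = topology_probabilities(sym_omega(M, dtau))
        assert p_ab == pytest.approx(expected, rel=5e-3)

    def test_probabilities_sum_to_one(self):
        for M in (0.5, 5.0, 4e7):
            probs = topology_probabilities(sym_omega(M, 2.75e-3))
            assert sum(probs) == pytest.approx(1.0, abs=1e-10)
            assert all(0 <= p <= 1 for p in probs)

    def test_quadrature_and_absorption_routes_agree(self):
        for M in (0.5, 50.0):
            for dtau in (2.5e-4, 2.75e-3):
                om = sym_omega(M, dtau, tau1=1e-3)
                pa = topology_probabilities(om, "absorption")
                pq = topology_probabilities(om, "quadrature")
                assert max(abs(a - b) for a, b in zip(pa, pq)) < 1e-6

    def test_maximal_migration_restores_minority_symmetry(self):
        _, p_ac, p_bc = topology_probabilities(sym_omega(4e7, 2.75e-3))
        assert abs(p_ac - p_bc) < 1e-9

    def test_low_migration_skews_to_shared_outgroup_pairing(self):
        _, _, p_bc = topology_probabilities(sym_omega(0.01, 2.75e-3))
        assert p_bc > 0.99

    def test_unstructured_limit_matches_standard_coalescent(self):
        """At the migration bound the two demes pool into one population of
        size 2N; with per-deme theta/2 the pooled diversity is theta and the
        concordance must match 1 - (2/3)exp(-2*dtau/theta)."""
        theta = 0.005
        for dtau in (1e-3, 2.75e-3):
            om = sym_omega(4 * 5e4 / (theta / 2), dtau, theta=theta / 2)
            p_ab, _, _ = topology_probabilities(om)
            assert 1 - p_ab == pytest.approx(
                discordance_probability(dtau, theta), rel=1e-4
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        M=st.floats(0.05, 1e4),
        dtau=st.floats(0.0, 8e-3),
        theta=st.floats(1e-3, 2e-2),
    )
    def test_valid_probability_vector_everywhere(self, M, dtau, theta):
        probs = topology_probabilities(sym_omega(M, dtau, theta=theta))
        assert sum(probs) == pytest.approx(1.0, abs=1e-8)
        assert all(-1e-12 <= p <= 1 + 1e-12 for p in probs)


class TestDiscordanceClosedForm:
    def test_zero_branch_gives_two_thirds(self):
        assert discordance_probability(0.0, 0.005) == pytest.approx(2 / 3)

    def test_bound_and_inverse_round_trip(self):
        b = internal_branch_bound(0.005, 0.05)
        assert b == pytest.approx(6.5e-3, rel=0.01)
        assert discordance_probability(b, 0.005) == pytest.approx(0.05)
        assert discordance_probability(6.476e-3, 0.005) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_decreasing_in_branch_length(self):
        vals = [discordance_probability(d, 0.005) for d in np.linspace(0, 0.01, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            discordance_probability(1e-3, 0.0)
        with pytest.raises(ParameterError):
            internal_branch_bound(0.005, 0.7)
        assert internal_branch_bound(0.005, 2 / 3 - 1e-12) == pytest.approx(0.0, abs=1e-9)


class TestModelParameters:
    def test_tau_ordering_enforced(self):
        cfg = Configuration(("A", "B", "C"), shared="B")
        with pytest.raises(ParameterError):
            ModelParameters.symmetric(cfg, 2e-3, 1e-3, 0.005, 5.0)

    def test_migration_bound_enforced(self):
        cfg = Configuration(("A", "B", "C"), shared="B")
        with pytest.raises(ParameterError):
            ModelParameters.symmetric(cfg, 0, 1e-3, 0.005, 5e7, 5e4)

    def test_coalescence_rate_is_two_over_theta(self):
        gen = build_generator("AB", (0.004, 0.01), (1.0, 1.0))
        assert gen.matrix[2, 4] == pytest.approx(500.0)
        assert gen.matrix[3, 5] == pytest.approx(200.0)
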