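"""Mass-action right-hand side, stoichiometry and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braferk import (ConfigurationError, RateConstants, conservation_weights,
                     conserved_totals, derive_rhs, simulate,
                     stoichiometric_matrix)
from braferk.network import Reaction, ReactionNetwork, classify_species
from braferk.simulate import SimulationSettings, Trajectory
from braferk.kinetics import conservation_residuals

from conftest import brute_force_rhs, random_states


def _r1_network():
    species = tuple(classify_species(n) for n in ("BRAF", "ATP", "BRAF·ATP"))
    return ReactionNetwork(
        species=species,
        reactions=(Reaction("R.1", "binding", ("BRAF", "ATP"), ("BRAF·ATP",),
                            "a1", "d1"),),
        include_dbf=False, include_tmt=False)


class TestRateConstants:
    def test_defaults_set_all_forward_constants_equal(self, constants):
        assert len(set(constants.a)) == 1 and constants.a[0] > 0

    def test_michaelis_constants(self):
        rc = RateConstants(a=(2.0,) * 8, d=(6.0,) * 8,
                           k={"k12": 4.0, "k3": 2.0, "k56": 4.0, "k7": 2.0})
        km = rc.michaelis_constants()
        assert km[2] == pytest.approx((6.0 + 4.0) / 2.0)   # substrate + k12
        assert km[4] == pytest.approx(3.0)                  # pure binding: d/a

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(a=(-1.0,) * 8, d=(1.0,) * 8,
                          k={"k12": 1, "k3": 1, "k56": 1, "k7": 1})

    def test_unknown_rate_ref_names_the_reaction(self, full_network):
        partial = {f"a{i}": 1.0 for i in range(1, 9)}
        partial.update({f"d{i}": 1.0 for i in range(1, 9)})
        partial.update({"k12": 1.0, "k3": 1.0, "k56": 1.0})  # k7 missing
        with pytest.raises(ConfigurationError, match="R.23"):
            derive_rhs(full_network, partial)


class TestRHS:
    def test_single_binding_reaction_worked_example(self):
        """R.1 alone with a1=1, d1=0: d[BRAF·ATP]/dt = [BRAF][ATP] = 6."""
        rhs = derive_rhs(_r1_network(), {"a1": 1.0, "d1": 0.0})
        dx = rhs(0.0, np.array([2.0, 3.0, 0.0]))
        assert dx == pytest.approx([-6.0, -6.0, 6.0])

    def test_reverse_term(self):
        rhs = derive_rhs(_r1_network(), {"a1": 1.0, "d1": 2.0})
        dx = rhs(0.0, np.array([0.0, 0.0, 5.0]))
        assert dx == pytest.approx([10.0, 10.0, -10.0])

    def test_zero_state_gives_zero_derivative(self, full_network, constants):
        rhs = derive_rhs(full_network, constants)
        assert np.all(rhs(0.0, np.zeros(36)) == 0.0)

    def test_matches_brute_force_oracle_on_many_random_states(
            self, full_network, constants, rng):
        rhs = derive_rhs(full_network, constants)
        for x in random_states(full_network, rng, 120):
            expected = brute_force_rhs(full_network, constants, x)
            got = rhs(0.0, x)
            scale = np.maximum(np.abs(expected), 1.0)
            assert np.max(np.abs(got - expected) / scale) < 1e-12

    def test_jacobian_matches_finite_differences(self, full_network, constants, rng):
        rhs = derive_rhs(full_network, constants)
        x = rng.uniform(0.5, 10.0, size=36)  # moderate scales limit FD noise
        J = rhs.jacobian(0.0, x)
        for j in rng.choice(36, size=12, replace=False):
            dx = np.zeros(36)
            dx[j] = 1e-7 * max(x[j], 1.0)
            num = (rhs(0.0, x + dx) - rhs(0.0, x - dx)) / (2 * dx[j])
            assert np.allclose(J[:, j], num, rtol=1e-3, atol=1e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(zero_idx=st.integers(0, 35), data=st.data())
    def test_species_at_zero_never_consumed(self, zero_idx, data,
                                            full_network, constants):
        """Nonnegativity: a species at zero has nonnegative derivative."""
        rhs = derive_rhs(full_network, constants)
        x = np.array(data.draw(st.lists(
            st.floats(0.0, 1e4, allow_nan=False), min_size=36, max_size=36)))
        x[zero_idx] = 0.0
        assert rhs(0.0, x)[zero_idx] >= 0.0


class TestStoichiometry:
    def test_r1_column(self, full_network):
        N = stoichiometric_matrix(full_network)
        idx = full_network.species_index()
        col = N[:, 0]  # R.1 is the first reaction
        assert col[idx["BRAF"]] == -1 and col[idx["ATP"]] == -1
        assert col[idx["BRAF·ATP"]] == 1
        assert np.abs(col).sum() == 3

    def test_every_reaction_touches_at_least_two_species(self, full_network):
        N = stoichiometric_matrix(full_network)
        assert np.all(np.abs(N).sum(axis=0) >= 2)

    def test_derivative_is_matrix_times_flux(self, full_network, constants, rng):
        rhs = derive_rhs(full_network, constants)
        N = stoichiometric_matrix(full_network)
        for x in random_states(full_network, rng, 5):
            assert np.allclose(N @ rhs.fluxes(x), rhs(0.0, x), rtol=1e-12)

    def test_conservation_weights_lie_exactly_in_left_null_space(self, full_network):
        N = stoichiometric_matrix(full_network)  # integer arithmetic throughout
        for name, w in conservation_weights(full_network).items():
            assert np.all(w @ N == 0), name


class TestConservedTotals:
    def test_all_free_initial_state_gives_erk_tot_equal_free_erk(
            self, full_network, baseline_initial):
        x0 = np.zeros(36)
        names = full_network.species_names
        for n, v in baseline_initial.items():
            x0[names.index(n)] = v
        totals = conserved_totals(full_network, x0)
        assert totals.ERK_tot == pytest.approx(baseline_initial["ERK"])
        assert totals.BRAF_tot == pytest.approx(baseline_initial["BRAF"])
        assert totals.DBF_tot == 0.0 and totals.TMT_tot == 0.0

    def test_totals_invariant_under_every_single_reaction_event(
            self, full_network, rng):
        """Brute force over all 36 reactions: applying any reaction's
        stoichiometry with an arbitrary step leaves all seven totals fixed."""
        N = stoichiometric_matrix(full_network)
        x = random_states(full_network, rng, 1)[0]
        before = conserved_totals(full_network, x).as_dict()
        for j in range(full_network.n_reactions):
            step = rng.uniform(-2.0, 2.0)
            after = conserved_totals(full_network, x + step * N[:, j]).as_dict()
            for law in before:
                assert after[law] == pytest.approx(before[law], abs=1e-9), (j, law)


class TestConservationResiduals:
    def test_zero_dose_tmt_residual_is_exactly_zero(self, model):
        traj = model.simulate(dbf_uM=0.5, tmt_uM=0.0, t_end=4.0)
        assert traj.residuals["TMT_tot"] == 0.0

    def test_corrupting_one_complex_at_one_time_breaks_a_law(
            self, full_network, model):
        traj = model.simulate(t_end=4.0)
        y = traj.y.copy()
        j = traj.species.index("ppMEK·ATP·ERK")
        y[len(y) // 2, j] = 0.0
        corrupted = Trajectory(t=traj.t, y=y, species=traj.species,
                               doses=traj.doses, clamp_atp=traj.clamp_atp)
        res = conservation_residuals(full_network, corrupted)
        assert max(res.values()) > 1e-6

    def test_accepted_simulation_is_within_threshold(self, model):
        traj = model.simulate(dbf_uM=0.3, tmt_uM=0.3, t_end=8.0)
        assert max(traj.residuals.values()) <= 1e-6
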