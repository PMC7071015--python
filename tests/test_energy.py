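"""Potential-energy model: invariances, gradients, minimisation contracts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyclomimic.errors import MinimizationError
from cyclomimic.forcefield import (EnergyModel, ForceFieldParams,
                                   minimize_conformation, total_energy)
from cyclomimic.noe import DistanceRestraint
from cyclomimic.peptide import build_initial_conformation, build_topology, \
    parse_design


@pytest.fixture(scope="module")
def conf11(topo11):
    return build_initial_conformation(topo11, "extended")


@pytest.fixture(scope="module")
def perturbed(topo11, conf11):
    rng = np.random.default_rng(0)
    x = conf11.coords + rng.normal(0.0, 0.05, conf11.coords.shape)
    return x


class TestEnergy:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, topo11, perturbed, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
        t = rng.normal(0.0, 20.0, 3)
        m = EnergyModel(topo11)
        e0 = m.energy(perturbed)
        e1 = m.energy(perturbed @ R.T + t)
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_translation_example(self, topo11, perturbed):
        m = EnergyModel(topo11)
        assert m.energy(perturbed + np.array([10.0, -3.0, 7.0])) == \
            pytest.approx(m.energy(perturbed), abs=1e-9)

    def test_breakdown_total_equals_sum_of_terms(self, topo11, perturbed):
        bd = EnergyModel(topo11).breakdown(perturbed)
        parts = [bd.bond, bd.angle, bd.torsion, bd.repulsion, bd.omega,
                 bd.chirality, bd.closure, bd.restraint]
        assert bd.total == pytest.approx(sum(parts), rel=1e-9)

    def test_compiled_and_numpy_paths_agree(self, topo11, perturbed):
        m = EnergyModel(topo11)
        assert m.energy(perturbed) == pytest.approx(
            m.energy_numpy(perturbed), rel=1e-12)
        bd_k = m.breakdown(perturbed).as_dict()
        bd_n = m.breakdown_numpy(perturbed).as_dict()
        for key in bd_k:
            assert bd_k[key] == pytest.approx(bd_n[key], abs=1e-9)
        e_k, g_k = m.energy_and_grad(perturbed)
        e_n, g_n = m.energy_and_grad_numpy(perturbed)
        assert e_k == pytest.approx(e_n, rel=1e-12)
        np.testing.assert_allclose(g_k, g_n, atol=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, topo11,
                                                          perturbed):
        m = EnergyModel(topo11)
        _e, g = m.energy_and_grad(perturbed)
        h = 1e-6
        rng = np.random.default_rng(5)
        # spot-check a random subset of coordinates
        for _ in range(60):
            i = int(rng.integers(perturbed.shape[0]))
            k = int(rng.integers(3))
            xp, xm = perturbed.copy(), perturbed.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (m.energy(xp) - m.energy(xm)) / (2 * h)
            assert g[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_ideal_extended_geometry_is_nearly_strain_free(self):
        topo = build_topology(parse_design("HYWSENLFQ", "PG", False))
        conf = build_initial_conformation(topo, "extended")
        bd = total_energy(conf)
        assert bd.bond < 1.0
        assert bd.angle < 1.0

    def test_restraint_term_present_iff_restraints_supplied(self, topo11,
                                                            conf11):
        r = DistanceRestraint(res_i=1, atom_i="HA", res_j=3, atom_j="HA",
                              r_ij=3.0, lower=2.5, upper=3.5)
        bd0 = total_energy(conf11)
        bd1 = total_energy(conf11, restraints=[r])
        assert bd0.restraint == 0.0
        assert bd1.restraint >= 0.0

    def test_flat_bottom_zero_at_upper_bound(self, topo11, conf11):
        i = topo11.proton_atom(1, "HA").atom_index
        j = topo11.proton_atom(3, "HA").atom_index
        d = float(np.linalg.norm(conf11.coords[i] - conf11.coords[j]))
        at_upper = DistanceRestraint(res_i=1, atom_i="HA", res_j=3,
                                     atom_j="HA", r_ij=d - 0.5,
                                     lower=d - 1.0, upper=d)
        assert total_energy(conf11, restraints=[at_upper]).restraint == 0.0
        just_below = DistanceRestraint(res_i=1, atom_i="HA", res_j=3,
                                       atom_j="HA", r_ij=d - 0.6,
                                       lower=d - 1.1, upper=d - 0.1)
        assert total_energy(conf11, restraints=[just_below]).restraint > 0.0

    def test_nonfinite_coordinates_rejected(self, topo11, conf11):
        bad = conf11.copy()
        coords = bad.coords.copy()
        coords[0, 0] = np.nan
        with pytest.raises((MinimizationError, ValueError)):
            bad.coords = coords
            bad.__post_init__()


class TestMinimize:
    def test_stretched_bond_restored(self):
        """A 2x-stretched carbonyl bond relaxes back to ideal length."""
        topo = build_topology(parse_design("AG", "", False))
        conf = build_initial_conformation(topo, "extended")
        i_c = topo.atom_index(1, "C")
        i_o = topo.atom_index(1, "O")
        x = conf.coords.copy()
        x[i_o] = x[i_c] + 2.0 * (x[i_o] - x[i_c])
        stretched = conf.copy()
        stretched.coords = x
        out = minimize_conformation(stretched, rms_gradient_tol=0.01)
        d = np.linalg.norm(out.coords[i_o] - out.coords[i_c])
        assert d == pytest.approx(1.231, abs=0.01)

    def test_reminimisation_is_a_fixed_point(self, topo11, conf11):
        m1 = minimize_conformation(conf11, rms_gradient_tol=0.01)
        m2 = minimize_conformation(m1, rms_gradient_tol=0.01)
        assert abs(m2.energy - m1.energy) < 1e-6

    def test_rms_gradient_tolerance_reported_and_met(self, topo11, conf11):
        out = minimize_conformation(conf11, rms_gradient_tol=0.01)
        assert out.meta["converged"]
        assert out.meta["rms_gradient"] <= 0.01

    def test_energy_never_increases(self, topo11, perturbed, conf11):
        start = conf11.copy()
        start.coords = perturbed.copy()
        e0 = EnergyModel(topo11).energy(perturbed)
        out = minimize_conformation(start, rms_gradient_tol=0.05,
                                    max_iter=50)
        assert out.energy <= e0

    def test_invalid_tolerance_rejected(self, conf11):
        with pytest.raises(ValueError):
            minimize_conformation(conf11, rms_gradient_tol=0.0)
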