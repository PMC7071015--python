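"""Annealing schedules, violation reports and short restrained runs."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyclomimic.annealing import (AnnealingSchedule, anneal,
                                  generate_ensemble, violation_report)
from cyclomimic.errors import RestraintError
from cyclomimic.forcefield import EnergyModel, minimize_conformation
from cyclomimic.noe import DistanceRestraint, resolve_restraints
from cyclomimic.peptide import IDEAL_BOND_LENGTHS, build_initial_conformation


SMALL = AnnealingSchedule(steps=300)


class TestSchedule:
    @pytest.mark.parametrize("cooling", ["geometric", "linear"])
    def test_temperatures_strictly_decreasing_with_exact_endpoints(self, cooling):
        s = AnnealingSchedule(steps=500, cooling=cooling)
        t = s.temperatures()
        assert t[0] == pytest.approx(s.t_start)
        assert t[-1] == pytest.approx(s.t_end)
        assert np.all(np.diff(t) < 0)

    def test_default_protocol_endpoints(self):
        s = AnnealingSchedule()
        assert (s.t_start, s.t_end, s.steps) == (3500.0, 100.0, 60000)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(t_start=100.0, t_end=100.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(steps=0)
        with pytest.raises(ValueError):
            AnnealingSchedule(cooling="sudden")
        with pytest.raises(ValueError):
            AnnealingSchedule(k_noe_start=50.0, k_noe_end=2.0)


class TestViolationReport:
    def _restraint(self, lo, hi, res_j=3):
        return DistanceRestraint(res_i=1, atom_i="HA", res_j=res_j,
                                 atom_j="HA", r_ij=(lo + hi) / 2,
                                 lower=lo, upper=hi)

    def test_all_inside_bounds(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        i = topo11.proton_atom(1, "HA").atom_index
        j = topo11.proton_atom(3, "HA").atom_index
        d = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
        vr = violation_report(conf, [self._restraint(d - 1.0, d + 1.0)])
        assert vr.fraction_satisfied == 1.0
        assert vr.max_violation == 0.0

    def test_known_violation_magnitude_and_count(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        i = topo11.proton_atom(1, "HA").atom_index
        j = topo11.proton_atom(3, "HA").atom_index
        d = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
        # upper bound 0.7 A below the actual distance
        vr = violation_report(conf, [self._restraint(d - 2.0, d - 0.7)])
        assert vr.max_violation == pytest.approx(0.7, abs=1e-9)
        assert vr.count_above_half == 1
        assert vr.fraction_satisfied == 0.0

    def test_invariant_under_rigid_rotation(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        rest = [self._restraint(2.0, 4.0), self._restraint(1.9, 2.1, res_j=5)]
        vr0 = violation_report(conf, rest)
        rot = conf.copy()
        R = Rotation.from_euler("zyx", [0.4, -1.0, 2.2]).as_matrix()
        rot.coords = conf.coords @ R.T + np.array([3.0, 4.0, -5.0])
        vr1 = violation_report(rot, rest)
        np.testing.assert_allclose(vr0.violations, vr1.violations, atol=1e-9)

    def test_empty_restraints_fully_satisfied(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        vr = violation_report(conf, [])
        assert vr.fraction_satisfied == 1.0 and vr.max_violation == 0.0


class TestAnneal:
    def test_unknown_restraint_atom_rejected_before_work(self, topo11):
        start = build_initial_conformation(topo11, "extended")
        bad = DistanceRestraint(res_i=10, atom_i="HN", res_j=1, atom_j="HA",
                                r_ij=3.0, lower=2.5, upper=3.5)
        with pytest.raises(RestraintError):
            anneal(start, [bad], SMALL, seed=0)

    def test_unrestrained_control_keeps_ring_closed(self, topo11):
        start = build_initial_conformation(topo11, "random", seed=11)
        out = anneal(start, [], SMALL, seed=11, n_refine=5)
        i, j = topo11.ring_closure_bond
        d = np.linalg.norm(out.coords[i] - out.coords[j])
        assert abs(d - IDEAL_BOND_LENGTHS["C-N"]) < 0.1
        assert out.meta["violations"].fraction_satisfied == 1.0

    def test_same_seed_bitwise_identical(self, topo11):
        start = build_initial_conformation(topo11, "random", seed=21)
        rest = [DistanceRestraint(res_i=1, atom_i="HA", res_j=4, atom_j="HA",
                                  r_ij=4.0, lower=3.5, upper=4.5)]
        a = anneal(start, rest, SMALL, seed=77, n_refine=5)
        b = anneal(start, rest, SMALL, seed=77, n_refine=5)
        assert np.array_equal(a.coords, b.coords)
        assert a.energy == b.energy

    def test_annealed_energy_not_above_minimised_start(self, topo11):
        start = build_initial_conformation(topo11, "random", seed=31)
        rest = [DistanceRestraint(res_i=2, atom_i="HA", res_j=6, atom_j="HA",
                                  r_ij=5.0, lower=4.5, upper=5.5)]
        out = anneal(start, rest, SMALL, seed=31, n_refine=5)
        bound = resolve_restraints(rest, topo11)
        model = EnergyModel(topo11, restraints=bound,
                            k_noe=SMALL.k_noe_end)
        start_min = minimize_conformation(start, rms_gradient_tol=0.01,
                                          max_iter=2000, model=model)
        assert out.energy <= start_min.energy + 1e-6

    def test_trans_omega_enforced_throughout(self, topo11):
        from cyclomimic.geometry import dihedrals
        start = build_initial_conformation(topo11, "random", seed=41)
        out = anneal(start, [], SMALL, seed=41, n_refine=5)
        om = np.rad2deg(dihedrals(out.coords, topo11.omega_quads))
        dev = np.abs((np.abs(om) - 180.0))
        assert dev.max() <= 20.0


class TestGenerateEnsemble:
    def test_single_member_ensemble(self, topo11):
        ens = generate_ensemble(topo11, [], n=1, sched=SMALL, base_seed=3,
                                n_refine=3)
        assert len(ens) == 1

    def test_replay_is_identical(self, topo11):
        rest = [DistanceRestraint(res_i=1, atom_i="HA", res_j=5, atom_j="HA",
                                  r_ij=4.0, lower=3.5, upper=4.5)]
        a = generate_ensemble(topo11, rest, n=2, sched=SMALL, base_seed=9,
                              n_refine=3)
        b = generate_ensemble(topo11, rest, n=2, sched=SMALL, base_seed=9,
                              n_refine=3)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.coords, cb.coords)

    def test_sorted_by_energy_with_violation_reports(self, topo11):
        ens = generate_ensemble(topo11, [], n=3, sched=SMALL, base_seed=5,
                                n_refine=3)
        assert np.all(np.diff(ens.energies) >= 0)
        for c in ens:
            assert "violations" in c.meta

    def test_n_must_be_positive(self, topo11):
        with pytest.raises(ValueError):
            generate_ensemble(topo11, [], n=0, sched=SMALL)
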