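"""NOESY volume calibration and proline cis/trans classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclomimic.errors import RestraintError
from cyclomimic.noe import (CalibrationReference, DistanceRestraint, NOEPeak,
                            calibrate, classify_proline, resolve_restraints)


def _peak(volume, atom_i="HA", atom_j="HA", peak_id="p001"):
    return NOEPeak(res_i=1, atom_i=atom_i, res_j=3, atom_j=atom_j,
                   volume=volume, peak_id=peak_id)


class TestCalibrate:
    def test_identity_volume_gives_reference_distance(self):
        ref = CalibrationReference(r_ref=2.5, alpha_ref=1000.0)
        [r] = calibrate([_peak(1000.0)], ref)
        assert r.r_ij == pytest.approx(2.5, abs=1e-12)

    def test_sixty_fourfold_weaker_volume_doubles_distance(self):
        ref = CalibrationReference(r_ref=2.5, alpha_ref=1000.0)
        [r] = calibrate([_peak(1000.0 / 64.0)], ref)
        assert r.r_ij == pytest.approx(5.0, abs=1e-12)

    def test_eightfold_ratio_is_sqrt2_scaling(self):
        ref = CalibrationReference(r_ref=1.8, alpha_ref=1000.0)
        [r] = calibrate([_peak(125.0)], ref)
        assert r.r_ij == pytest.approx(1.8 * np.sqrt(2.0), abs=1e-12)

    @given(st.floats(1.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_forward_inverse_round_trip(self, d):
        """Simulating a volume c*d^-6 and calibrating recovers d exactly."""
        c = 5.0e5
        ref = CalibrationReference(r_ref=2.0, alpha_ref=c * 2.0 ** -6)
        [r] = calibrate([_peak(c * d ** -6)], ref)
        assert r.r_ij == pytest.approx(d, abs=1e-9)

    def test_scale_invariance_of_volume_units(self):
        ref1 = CalibrationReference(r_ref=2.2, alpha_ref=100.0)
        ref2 = CalibrationReference(r_ref=2.2, alpha_ref=100.0 * 7.3)
        r1 = calibrate([_peak(40.0)], ref1)[0].r_ij
        r2 = calibrate([_peak(40.0 * 7.3)], ref2)[0].r_ij
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_larger_volume_means_strictly_smaller_distance(self):
        ref = CalibrationReference(r_ref=2.5, alpha_ref=1000.0)
        volumes = [10.0, 100.0, 1000.0, 10000.0]
        dists = [calibrate([_peak(v)], ref)[0].r_ij for v in volumes]
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_nonpositive_volume_identifies_peak(self):
        ref = CalibrationReference(r_ref=2.5, alpha_ref=1000.0)
        bad = NOEPeak.__new__(NOEPeak)     # bypass dataclass validation
        object.__setattr__(bad, "res_i", 1)
        object.__setattr__(bad, "atom_i", "HA")
        object.__setattr__(bad, "res_j", 2)
        object.__setattr__(bad, "atom_j", "HA")
        object.__setattr__(bad, "volume", -3.0)
        object.__setattr__(bad, "peak_id", "p099")
        with pytest.raises(RestraintError, match="p099"):
            calibrate([bad], ref)

    def test_bounds_margins_and_hard_sphere_clamp(self):
        ref = CalibrationReference(r_ref=2.0, alpha_ref=1000.0)
        [r] = calibrate([_peak(1000.0)], ref, bound_margin=0.5)
        assert r.lower == pytest.approx(1.8)        # clamped up from 1.5
        assert r.upper == pytest.approx(2.5)
        # short distance: lower clamp cannot exceed the target itself
        ref_short = CalibrationReference(r_ref=1.5, alpha_ref=1000.0)
        [r2] = calibrate([_peak(1000.0)], ref_short)
        assert r2.lower <= r2.r_ij

    def test_pseudo_atom_correction_on_upper_bound(self):
        ref = CalibrationReference(r_ref=3.0, alpha_ref=1000.0)
        [plain] = calibrate([_peak(1000.0)], ref)
        [one_hb] = calibrate([_peak(1000.0, atom_i="HB")], ref)
        [two_hb] = calibrate([_peak(1000.0, atom_i="HB", atom_j="HB")], ref)
        assert one_hb.upper == pytest.approx(plain.upper + 1.0)
        assert two_hb.upper == pytest.approx(plain.upper + 2.0)

    def test_order_preserved_one_restraint_per_peak(self):
        ref = CalibrationReference(r_ref=2.5, alpha_ref=1000.0)
        peaks = [_peak(100.0, peak_id=f"p{i}") for i in range(5)]
        out = calibrate(peaks, ref)
        assert [r.source_peak for r in out] == [p.peak_id for p in peaks]


class TestResolve:
    def test_unknown_proton_site_rejected(self, topo11):
        r = DistanceRestraint(res_i=10, atom_i="HN", res_j=1, atom_j="HA",
                              r_ij=3.0, lower=2.5, upper=3.5,
                              source_peak="p001")
        # residue 10 is the proline: no amide proton
        with pytest.raises(RestraintError, match="p001"):
            resolve_restraints([r], topo11)

    def test_hb_pseudo_maps_to_cb_position(self, topo11):
        r = DistanceRestraint(res_i=1, atom_i="HB", res_j=2, atom_j="HA",
                              r_ij=3.0, lower=2.5, upper=3.5)
        [b] = resolve_restraints([r], topo11)
        assert b.atom_index_i == topo11.atom_index(1, "CB")


class TestProlineClassification:
    def test_small_shift_difference_is_trans(self):
        # the observed 4.27 ppm difference classifies as trans
        assert classify_proline(31.0, 26.73) == "trans"

    def test_large_shift_difference_is_cis(self):
        assert classify_proline(34.0, 24.5) == "cis"

    def test_intermediate_band_is_ambiguous(self):
        assert classify_proline(31.0, 24.0) == "ambiguous"

    def test_band_edges(self):
        assert classify_proline(6.0, 0.0) == "trans"
        assert classify_proline(8.0, 0.0) == "cis"

    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ValueError):
            classify_proline(np.nan, 25.0)


class TestRestraintInvariants:
    def test_bound_ordering_enforced(self):
        with pytest.raises(RestraintError):
            DistanceRestraint(res_i=1, atom_i="HA", res_j=2, atom_j="HA",
                              r_ij=3.0, lower=3.5, upper=4.0)

    def test_identical_atoms_rejected_in_peak(self):
        with pytest.raises(RestraintError):
            NOEPeak(res_i=1, atom_i="HA", res_j=1, atom_j="HA", volume=5.0)
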