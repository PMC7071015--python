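"""NOESY cross-peak calibration into distance restraints.

Cross-peak volumes are converted to interproton distances through the
inverse-sixth-power relation r_ij = r_ref * (alpha_ref / alpha_ij)^(1/6),
referenced to a peak of known distance.  Restraints carry flat-bottom
bounds; restraints that involve the beta pseudo-proton receive the usual
+1.0 A pseudo-atom correction on their upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import RestraintError
from .peptide import Topology

__all__ = [
    "NOEPeak",
    "CalibrationReference",
    "DistanceRestraint",
    "calibrate",
    "resolve_restraints",
    "classify_proline",
    "HARD_SPHERE_LOWER",
    "PSEUDO_ATOM_CORRECTION",
]

HARD_SPHERE_LOWER = 1.8          # A, hard-sphere contact clamp on lower bounds
PSEUDO_ATOM_CORRECTION = 1.0     # A added to the upper bound per HB partner

PROTON_LABELS = ("HN", "HA", "HB")


@dataclass(frozen=True)
class NOEPeak:
    """One NOESY cross peak between two proton sites."""

    res_i: int
    atom_i: str           # HN | HA | HB
    res_j: int
    atom_j: str
    volume: float         # arbitrary units, > 0
    peak_id: str = ""

    def __post_init__(self):
        if self.atom_i not in PROTON_LABELS or self.atom_j not in PROTON_LABELS:
            raise RestraintError(
                f"peak {self.peak_id or '?'}: proton labels must be one of "
                f"{PROTON_LABELS}, got {self.atom_i!r}/{self.atom_j!r}")
        if (self.res_i, self.atom_i) == (self.res_j, self.atom_j):
            raise RestraintError(
                f"peak {self.peak_id or '?'}: atoms must be distinct")


@dataclass(frozen=True)
class CalibrationReference:
    """Known distance / noise-free volume of the reference proton pair."""

    r_ref: float          # A
    alpha_ref: float      # same units as the peak volumes

    def __post_init__(self):
        if not (self.r_ref > 0 and self.alpha_ref > 0):
            raise RestraintError("calibration reference must be positive")


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint between two proton sites.

    ``atom_index_i``/``atom_index_j`` are filled by :func:`resolve_restraints`
    when the restraint is bound to a topology; the energy model requires
    bound restraints.
    """

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    r_ij: float
    lower: float
    upper: float
    source_peak: str = ""
    atom_index_i: int = -1
    atom_index_j: int = -1

    def __post_init__(self):
        if not (0 < self.lower <= self.r_ij <= self.upper):
            raise RestraintError(
                f"restraint {self.source_peak or '?'}: bounds must satisfy "
                f"0 < lower <= r_ij <= upper, got "
                f"({self.lower:.3f}, {self.r_ij:.3f}, {self.upper:.3f})")

    @property
    def bound(self) -> bool:
        return self.atom_index_i >= 0 and self.atom_index_j >= 0


def calibrate(peaks: Sequence[NOEPeak], ref: CalibrationReference,
              bound_margin: float = 0.5) -> List[DistanceRestraint]:
    """Convert cross-peak volumes into distance restraints.

    r_ij = r_ref * (alpha_ref / alpha_ij)^(1/6); bounds are r_ij -/+
    ``bound_margin`` with the lower bound clamped to the 1.8 A hard-sphere
    contact (never above r_ij itself) and +1.0 A added to the upper bound
    for every beta pseudo-proton in the pair.  One restraint per peak,
    input order preserved.
    """
    out: List[DistanceRestraint] = []
    for k, p in enumerate(peaks):
        if not np.isfinite(p.volume) or p.volume <= 0:
            raise RestraintError(
                f"peak {p.peak_id or k}: non-positive volume {p.volume!r}")
        r = ref.r_ref * (ref.alpha_ref / p.volume) ** (1.0 / 6.0)
        lower = min(max(HARD_SPHERE_LOWER, r - bound_margin), r)
        upper = r + bound_margin
        upper += PSEUDO_ATOM_CORRECTION * ((p.atom_i == "HB") + (p.atom_j == "HB"))
        out.append(DistanceRestraint(
            res_i=p.res_i, atom_i=p.atom_i, res_j=p.res_j, atom_j=p.atom_j,
            r_ij=float(r), lower=float(lower), upper=float(upper),
            source_peak=p.peak_id or f"peak{k}"))
    return out


def resolve_restraints(restraints: Sequence[DistanceRestraint],
                       topo: Topology) -> List[DistanceRestraint]:
    """Bind restraints to topology atom indices (HB maps to the CB position).

    Raises :class:`RestraintError` before any computation if a restraint
    references a proton site the topology does not have.
    """
    bound = []
    for r in restraints:
        try:
            site_i = topo.proton_atom(r.res_i, r.atom_i)
            site_j = topo.proton_atom(r.res_j, r.atom_j)
        except KeyError as exc:
            raise RestraintError(
                f"restraint {r.source_peak or '?'}: {exc.args[0]}") from None
        bound.append(replace(r, atom_index_i=site_i.atom_index,
                             atom_index_j=site_j.atom_index))
    return bound


def classify_proline(delta_cb: float, delta_cg: float,
                     trans_max: float = 6.0,
                     cis_min: float = 8.0) -> str:
    """Classify an X-Pro peptide bond from the 13C Cb/Cg shift difference.

    A small |d(Cb) - d(Cg)| indicates trans (~4.5 ppm typical), a large one
    cis (~9.15 ppm typical); the gap between the decision bands returns
    ``ambiguous``.
    """
    if not (np.isfinite(delta_cb) and np.isfinite(delta_cg)):
        raise ValueError("chemical shifts must be finite")
    dd = abs(delta_cb - delta_cg)
    if dd <= trans_max:
        return "trans"
    if dd >= cis_min:
        return "cis"
    return "ambiguous"
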