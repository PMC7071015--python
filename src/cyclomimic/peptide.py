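"""Cyclic peptide design parsing, topology construction and coordinate building.

The molecular representation is deliberately reduced: per residue the backbone
atoms N, (H), CA, HA, C, O plus a CB carbon and, for side chains extending past
CB, a single pseudo-atom ``SC`` placed at a residue-specific distance standing
in for the distal side-chain centroid.  Protons available to NOE restraints are
the amide HN, the alpha HA, and a beta pseudo-proton HB that shares the CB
position (with the usual pseudo-atom bound correction applied downstream).
This keeps the restraint and annealing machinery desk-scale while preserving
the geometry that NOE distance classes actually probe.

Residue indices are 1-based in all user-facing APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from .errors import DesignError, RingClosureError
from .geometry import bond_angles, dihedrals, nerf_place

__all__ = [
    "PeptideSequence",
    "Topology",
    "Conformation",
    "parse_design",
    "build_topology",
    "build_initial_conformation",
    "STANDARD_AA",
    "IDEAL_BOND_LENGTHS",
    "IDEAL_ANGLES_DEG",
    "L_CHIRALITY_S0",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Ideal covalent geometry (Engh/Huber-like rounded values).
IDEAL_BOND_LENGTHS: Dict[str, float] = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,      # peptide bond, including the ring closure
    "C-O": 1.231,
    "CA-CB": 1.530,
    "N-H": 1.010,
    "CA-HA": 1.090,
}

# Distance (A) from CB to the single distal side-chain centroid pseudo-atom.
# Coarse values derived from average heavy-atom centroids; absent entries
# (G, A) carry no SC pseudo-atom.
SC_CENTROID_DIST: Dict[str, float] = {
    "R": 3.6, "N": 1.9, "D": 1.9, "C": 1.81, "Q": 2.5, "E": 2.5,
    "H": 2.4, "I": 1.9, "L": 2.0, "K": 3.0, "M": 2.7, "F": 2.9,
    "P": 1.5, "S": 1.43, "T": 1.40, "V": 1.20, "W": 3.4, "Y": 3.2,
}

IDEAL_ANGLES_DEG: Dict[Tuple[str, str, str], float] = {
    ("C", "N", "CA"): 121.7,
    ("C", "N", "H"): 119.2,
    ("H", "N", "CA"): 119.1,
    ("N", "CA", "C"): 111.0,
    ("N", "CA", "CB"): 110.5,
    ("N", "CA", "HA"): 109.5,
    ("C", "CA", "CB"): 108.16,   # implied by the +/-120 branch construction
    ("C", "CA", "HA"): 108.69,
    ("CB", "CA", "HA"): 108.94,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.6,
    ("O", "C", "N"): 122.6,
    ("CA", "CB", "SC"): 114.0,
}
_DEFAULT_ANGLE_DEG = 109.47

# Chirality scalar ((CA->N)^ x (CA->C)^).(CA->CB)^ for an ideal L residue;
# matches the value computed from CCD ideal amino-acid coordinates.
L_CHIRALITY_S0 = 0.766

# Branch torsion offsets about the N-CA axis relative to the C placement,
# chosen to give L configuration (verified against CCD ideal coordinates).
_CB_OFFSET_DEG = 120.0
_HA_OFFSET_DEG = -120.0


@dataclass(frozen=True)
class PeptideSequence:
    """An (optionally cyclic) peptide sequence in one-letter code."""

    residues: Tuple[str, ...]
    cyclic: bool
    proline_configs: Tuple[Tuple[int, str], ...] = ()  # (1-based pos, cis|trans)
    origin_labels: Tuple[Tuple[int, str], ...] = ()

    def __post_init__(self):
        for code in self.residues:
            if code not in STANDARD_AA:
                raise DesignError(f"non-standard residue code {code!r}")
        if self.cyclic and len(self.residues) < 3:
            raise DesignError(
                f"cyclic peptide needs >= 3 residues, got {len(self.residues)}"
            )
        for pos, cfg in self.proline_configs:
            if not (1 <= pos <= len(self.residues)) or self.residues[pos - 1] != "P":
                raise DesignError(f"proline config at position {pos} does not hit a P")
            if cfg not in ("cis", "trans"):
                raise DesignError(f"proline config must be cis/trans, got {cfg!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def proline_config_map(self) -> Dict[int, str]:
        return dict(self.proline_configs)

    def one_letter(self) -> str:
        return "".join(self.residues)


def parse_design(epitope: str, linker: str, cyclic: bool,
                 origin_offset: Optional[int] = None) -> PeptideSequence:
    """Build the design sequence: epitope followed by linker residues.

    Prolines default to the trans configuration.  ``origin_offset``, when
    given, records the source numbering of the epitope residues (e.g. the
    receptor loop positions) without affecting internal 1-based indices.
    """
    if not epitope:
        raise DesignError("epitope must be a non-empty residue string")
    full = (epitope + linker).upper()
    for ch in full:
        if ch not in STANDARD_AA:
            raise DesignError(f"non-standard residue code {ch!r} in design")
    residues = tuple(full)
    prolines = tuple((i + 1, "trans") for i, ch in enumerate(residues) if ch == "P")
    labels = ()
    if origin_offset is not None:
        labels = tuple(
            (i + 1, str(origin_offset + i)) for i in range(len(epitope))
        )
    return PeptideSequence(residues=residues, cyclic=cyclic,
                           proline_configs=prolines, origin_labels=labels)


@dataclass(frozen=True)
class AtomRecord:
    res_index: int          # 1-based
    res_name: str           # three-letter
    name: str               # N, H, CA, HA, C, O, CB, SC
    element: str


@dataclass(frozen=True)
class ProtonSite:
    res_index: int          # 1-based
    label: str              # HN, HA or HB (pseudo)
    atom_index: int         # 0-based index into Topology.atoms
    pseudo: bool


@dataclass
class Topology:
    """Atom-level realisation of a peptide design.

    Bond/angle/torsion index arrays are 0-based into ``atoms``; residue
    indices in atom records are 1-based.
    """

    sequence: PeptideSequence
    atoms: List[AtomRecord]
    bonds: List[Tuple[int, int, str]]               # (i, j, class)
    ring_closure_bond: Optional[Tuple[int, int]]
    proton_set: List[ProtonSite]
    # derived term arrays, filled by build_topology
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    angle_ideals: np.ndarray = field(default_factory=lambda: np.empty(0))
    omega_quads: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))
    omega_targets: np.ndarray = field(default_factory=lambda: np.empty(0))
    closure_term_mask: Dict[str, np.ndarray] = field(default_factory=dict)
    chirality_quads: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))
    backbone_torsions: List[dict] = field(default_factory=list)
    zmatrix: List[tuple] = field(default_factory=list)

    _index: Dict[Tuple[int, str], int] = field(default_factory=dict, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atom_index(self, res_index: int, name: str) -> int:
        key = (res_index, name)
        if key not in self._index:
            raise KeyError(f"no atom {name} in residue {res_index}")
        return self._index[key]

    def has_atom(self, res_index: int, name: str) -> bool:
        return (res_index, name) in self._index

    @property
    def peptide_bonds(self) -> List[Tuple[int, int]]:
        return [(i, j) for i, j, cls in self.bonds if cls == "C-N"]

    def proton_atom(self, res_index: int, label: str) -> ProtonSite:
        for site in self.proton_set:
            if site.res_index == res_index and site.label == label:
                return site
        raise KeyError(f"no proton site {label} in residue {res_index}")

    def backbone_indices(self, atom_names: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        idx = []
        for r in range(1, self.n_residues + 1):
            for nm in atom_names:
                idx.append(self.atom_index(r, nm))
        return np.asarray(idx, dtype=int)


@dataclass
class Conformation:
    """Cartesian coordinates (A) bound to a topology."""

    topology: Topology
    coords: np.ndarray
    energy: Optional[float] = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def copy(self, **changes) -> "Conformation":
        new = Conformation(self.topology, self.coords.copy(),
                           self.energy, self.label, dict(self.meta))
        for k, v in changes.items():
            setattr(new, k, v)
        return new

    def backbone_coords(self, atom_names: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        return self.coords[self.topology.backbone_indices(atom_names)]


def _ideal_angle(a: str, b: str, c: str) -> float:
    deg = IDEAL_ANGLES_DEG.get((a, b, c)) or IDEAL_ANGLES_DEG.get((c, b, a)) \
        or _DEFAULT_ANGLE_DEG
    return np.deg2rad(deg)


def build_topology(seq: PeptideSequence) -> Topology:
    """Materialise atoms, bonds and derived geometric terms for a design."""
    atoms: List[AtomRecord] = []
    bonds: List[Tuple[int, int, str]] = []
    index: Dict[Tuple[int, str], int] = {}

    def add_atom(res_i: int, code: str, name: str, element: str) -> int:
        atoms.append(AtomRecord(res_i, THREE_LETTER[code], name, element))
        index[(res_i, name)] = len(atoms) - 1
        return len(atoms) - 1

    n = len(seq)
    for i, code in enumerate(seq.residues, start=1):
        i_n = add_atom(i, code, "N", "N")
        if code != "P":          # proline nitrogen carries no amide proton
            i_h = add_atom(i, code, "H", "H")
            bonds.append((i_n, i_h, "N-H"))
        i_ca = add_atom(i, code, "CA", "C")
        bonds.append((i_n, i_ca, "N-CA"))
        i_ha = add_atom(i, code, "HA", "H")
        bonds.append((i_ca, i_ha, "CA-HA"))
        i_c = add_atom(i, code, "C", "C")
        bonds.append((i_ca, i_c, "CA-C"))
        i_o = add_atom(i, code, "O", "O")
        bonds.append((i_c, i_o, "C-O"))
        if code != "G":
            i_cb = add_atom(i, code, "CB", "C")
            bonds.append((i_ca, i_cb, "CA-CB"))
            if code in SC_CENTROID_DIST:
                i_sc = add_atom(i, code, "SC", "C")
                bonds.append((i_cb, i_sc, "CB-SC"))
        if i > 1:
            bonds.append((index[(i - 1, "C")], i_n, "C-N"))

    closure = None
    if seq.cyclic:
        closure = (index[(n, "C")], index[(1, "N")])
        bonds.append((closure[0], closure[1], "C-N"))

    proton_set: List[ProtonSite] = []
    for i, code in enumerate(seq.residues, start=1):
        if code != "P":
            proton_set.append(ProtonSite(i, "HN", index[(i, "H")], False))
        proton_set.append(ProtonSite(i, "HA", index[(i, "HA")], False))
        if code != "G":
            proton_set.append(ProtonSite(i, "HB", index[(i, "CB")], True))

    topo = Topology(sequence=seq, atoms=atoms, bonds=bonds,
                    ring_closure_bond=closure, proton_set=proton_set)
    topo._index = index
    _derive_terms(topo)
    _build_zmatrix(topo)
    _derive_backbone_torsions(topo)
    topo._zm_full = _encode_zmatrix(topo, backbone_only=False)
    topo._zm_backbone = _encode_zmatrix(topo, backbone_only=True)
    return topo


_ZM_KIND = {"seed0": 0, "seed1": 1, "seed2": 2}
_ZM_SRC = {"phi": 0, "psi": 1, "omega": 2, "chi": 3, "const": 4}


def _encode_zmatrix(topo: Topology, backbone_only: bool) -> tuple:
    """Flatten the z-matrix into arrays for the compiled chain builder."""
    backbone_names = {"N", "CA", "C"}
    sel = [e for e in topo.zmatrix
           if not backbone_only or topo.atoms[e[0]].name in backbone_names]
    n = len(sel)
    atom_idx = np.zeros(n, dtype=np.int64)
    ref_a = np.zeros(n, dtype=np.int64)
    ref_b = np.zeros(n, dtype=np.int64)
    ref_c = np.zeros(n, dtype=np.int64)
    bond_r = np.zeros(n)
    theta = np.zeros(n)
    kind = np.zeros(n, dtype=np.int64)
    src = np.zeros(n, dtype=np.int64)
    res = np.zeros(n, dtype=np.int64)
    offset = np.zeros(n)
    for e_i, (idx, a, b, c, r, th, kd, arg) in enumerate(sel):
        atom_idx[e_i] = idx
        ref_a[e_i] = a if a is not None else 0
        ref_b[e_i] = b if b is not None else 0
        ref_c[e_i] = c if c is not None else 0
        bond_r[e_i] = r
        theta[e_i] = th
        if kd in _ZM_KIND:
            kind[e_i] = _ZM_KIND[kd]
        else:
            kind[e_i] = 3
            src[e_i] = _ZM_SRC[kd]
            if kd == "const":
                offset[e_i] = arg
            else:
                res_i, off = arg
                res[e_i] = res_i - 1
                offset[e_i] = off
    return (n, atom_idx, ref_a, ref_b, ref_c, bond_r, theta, kind, src,
            res, offset)


def _derive_terms(topo: Topology) -> None:
    """Enumerate angle triples, omega planarity and chirality terms."""
    adj: Dict[int, List[int]] = {i: [] for i in range(topo.n_atoms)}
    for i, j, _cls in topo.bonds:
        adj[i].append(j)
        adj[j].append(i)

    triples, ideals, closure_angle_mask = [], [], []
    closure = set(topo.ring_closure_bond or ())
    for j in range(topo.n_atoms):
        nb = sorted(adj[j])
        for a_i in range(len(nb)):
            for b_i in range(a_i + 1, len(nb)):
                i, k = nb[a_i], nb[b_i]
                triples.append((i, j, k))
                ideals.append(_ideal_angle(topo.atoms[i].name,
                                           topo.atoms[j].name,
                                           topo.atoms[k].name))
                touches_closure = bool(closure and (
                    {i, j} == closure or {j, k} == closure))
                closure_angle_mask.append(touches_closure)
    topo.angles = np.asarray(triples, dtype=int).reshape(-1, 3)
    topo.angle_ideals = np.asarray(ideals)

    # omega (peptide-bond planarity) terms: CA(i)-C(i)-N(j)-CA(j)
    quads, targets, closure_omega_mask = [], [], []
    seqmap = topo.sequence.proline_config_map
    nres = topo.n_residues
    for i, j_at, cls in topo.bonds:
        if cls != "C-N":
            continue
        res_c = topo.atoms[i].res_index
        res_n = topo.atoms[j_at].res_index
        quads.append((topo.atom_index(res_c, "CA"), i, j_at,
                      topo.atom_index(res_n, "CA")))
        cfg = seqmap.get(res_n, "trans")
        targets.append(0.0 if cfg == "cis" else np.pi)
        closure_omega_mask.append(res_c == nres and res_n == 1)
    topo.omega_quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    topo.omega_targets = np.asarray(targets)

    chir = []
    for r in range(1, nres + 1):
        if topo.has_atom(r, "CB"):
            chir.append((topo.atom_index(r, "CA"), topo.atom_index(r, "N"),
                         topo.atom_index(r, "C"), topo.atom_index(r, "CB")))
    topo.chirality_quads = np.asarray(chir, dtype=int).reshape(-1, 4)

    bond_closure_mask = np.array(
        [bool(closure and {i, j} == closure) for i, j, _ in topo.bonds])
    topo.closure_term_mask = {
        "bond": bond_closure_mask,
        "angle": np.asarray(closure_angle_mask, dtype=bool),
        "omega": np.asarray(closure_omega_mask, dtype=bool),
    }


def _build_zmatrix(topo: Topology) -> None:
    """Internal-coordinate recipe to realise coordinates from torsions.

    Each entry is ``(atom_idx, a, b, c, r, theta, phi_kind, phi_arg)`` where
    ``phi_kind`` names the torsion variable ('phi', 'psi', 'omega', 'chi')
    or 'const', and ``phi_arg`` is an offset in radians (or the constant).
    Atom ``atom_idx`` is placed by NeRF from already-placed a, b, c.
    """
    z: List[tuple] = []
    seq = topo.sequence
    ai = topo.atom_index
    BL = IDEAL_BOND_LENGTHS
    cb_off = np.deg2rad(_CB_OFFSET_DEG)
    ha_off = np.deg2rad(_HA_OFFSET_DEG)

    for i in range(1, topo.n_residues + 1):
        code = seq.residues[i - 1]
        if i == 1:
            # seed atoms: N1 at origin, CA1 on x-axis, C1 in the xy-plane
            z.append((ai(1, "N"), None, None, None, 0.0, 0.0, "seed0", 0.0))
            z.append((ai(1, "CA"), None, None, ai(1, "N"),
                      BL["N-CA"], 0.0, "seed1", 0.0))
            z.append((ai(1, "C"), None, ai(1, "N"), ai(1, "CA"),
                      BL["CA-C"], _ideal_angle("N", "CA", "C"), "seed2", 0.0))
        else:
            prev = i - 1
            z.append((ai(i, "N"), ai(prev, "N"), ai(prev, "CA"), ai(prev, "C"),
                      BL["C-N"], _ideal_angle("CA", "C", "N"), "psi", (prev, 0.0)))
            z.append((ai(i, "CA"), ai(prev, "CA"), ai(prev, "C"), ai(i, "N"),
                      BL["N-CA"], _ideal_angle("C", "N", "CA"), "omega", (i, 0.0)))
            z.append((ai(i, "C"), ai(prev, "C"), ai(i, "N"), ai(i, "CA"),
                      BL["CA-C"], _ideal_angle("N", "CA", "C"), "phi", (i, 0.0)))
        # carbonyl O anti to the next amide nitrogen direction
        z.append((ai(i, "O"), ai(i, "N"), ai(i, "CA"), ai(i, "C"),
                  BL["C-O"], _ideal_angle("CA", "C", "O"), "psi", (i, np.pi)))
        if topo.has_atom(i, "H"):
            if i == 1:
                z.append((ai(1, "H"), ai(1, "C"), ai(1, "CA"), ai(1, "N"),
                          BL["N-H"], _ideal_angle("H", "N", "CA"), "const", np.pi))
            else:
                # amide H opposite CA(i) across the sp2 nitrogen
                z.append((ai(i, "H"), ai(i - 1, "CA"), ai(i - 1, "C"), ai(i, "N"),
                          BL["N-H"], _ideal_angle("C", "N", "H"),
                          "omega", (i, np.pi)))
        # branches about N-CA: C sits at phi; CB at phi+120, HA at phi-120 (L)
        if i == 1:
            ref_a = ai(1, "H") if topo.has_atom(1, "H") else ai(1, "O")
            kind, arg = "phi1_branch", None
        else:
            ref_a = ai(i - 1, "C")
            kind, arg = "phi", None
        if topo.has_atom(i, "CB"):
            if i == 1:
                z.append((ai(1, "CB"), ai(1, "C"), ai(1, "N"), ai(1, "CA"),
                          BL["CA-CB"], _ideal_angle("N", "CA", "CB"),
                          "const", cb_off))
            else:
                z.append((ai(i, "CB"), ref_a, ai(i, "N"), ai(i, "CA"),
                          BL["CA-CB"], _ideal_angle("N", "CA", "CB"),
                          "phi", (i, cb_off)))
        if i == 1:
            z.append((ai(1, "HA"), ai(1, "C"), ai(1, "N"), ai(1, "CA"),
                      BL["CA-HA"], _ideal_angle("N", "CA", "HA"),
                      "const", ha_off))
        else:
            z.append((ai(i, "HA"), ref_a, ai(i, "N"), ai(i, "CA"),
                      BL["CA-HA"], _ideal_angle("N", "CA", "HA"),
                      "phi", (i, ha_off)))
        if topo.has_atom(i, "SC"):
            z.append((ai(i, "SC"), ai(i, "N"), ai(i, "CA"), ai(i, "CB"),
                      SC_CENTROID_DIST[code], _ideal_angle("CA", "CB", "SC"),
                      "chi", (i, 0.0)))
    topo.zmatrix = z


def _derive_backbone_torsions(topo: Topology) -> None:
    """Rotatable torsion definitions (phi/psi/chi) with moved-atom sets.

    The moved set of a torsion about bond b-c is the connected component of
    c in the bond graph with the rotation bond and the ring closure removed.
    """
    adj: Dict[int, set] = {i: set() for i in range(topo.n_atoms)}
    closure = set()
    if topo.ring_closure_bond:
        closure = {frozenset(topo.ring_closure_bond)}
    for i, j, _cls in topo.bonds:
        if frozenset((i, j)) in closure:
            continue
        adj[i].add(j)
        adj[j].add(i)

    def moved_atoms(b: int, c: int) -> np.ndarray:
        seen = {b, c}
        stack = [c]
        comp = [c]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        comp.remove(c)  # pivot atom itself does not move
        return np.asarray(sorted(comp), dtype=int)

    defs: List[dict] = []
    nres = topo.n_residues
    cyc = topo.sequence.cyclic
    for i in range(1, nres + 1):
        prev = i - 1 if i > 1 else (nres if cyc else None)
        nxt = i + 1 if i < nres else (1 if cyc else None)
        if prev is not None:
            quad = (topo.atom_index(prev, "C"), topo.atom_index(i, "N"),
                    topo.atom_index(i, "CA"), topo.atom_index(i, "C"))
            defs.append({"name": f"phi{i}", "kind": "phi", "res": i,
                         "quad": quad,
                         "moved": moved_atoms(quad[1], quad[2])})
        if nxt is not None:
            quad = (topo.atom_index(i, "N"), topo.atom_index(i, "CA"),
                    topo.atom_index(i, "C"), topo.atom_index(nxt, "N"))
            defs.append({"name": f"psi{i}", "kind": "psi", "res": i,
                         "quad": quad,
                         "moved": moved_atoms(quad[1], quad[2])})
        if topo.has_atom(i, "SC"):
            quad = (topo.atom_index(i, "N"), topo.atom_index(i, "CA"),
                    topo.atom_index(i, "CB"), topo.atom_index(i, "SC"))
            defs.append({"name": f"chi{i}", "kind": "chi", "res": i,
                         "quad": quad,
                         "moved": moved_atoms(quad[1], quad[2])})
    topo.backbone_torsions = defs


def _omega_targets(topo: Topology) -> np.ndarray:
    seqmap = topo.sequence.proline_config_map
    return np.array([0.0 if seqmap.get(i, "trans") == "cis" else np.pi
                     for i in range(1, topo.n_residues + 1)])


def _coords_from_torsions(topo: Topology, phi: np.ndarray, psi: np.ndarray,
                          chi: np.ndarray, backbone_only: bool = False,
                          omega: Optional[np.ndarray] = None) -> np.ndarray:
    """Realise Cartesian coordinates from torsion values via the z-matrix.

    ``phi``, ``psi``, ``chi`` are per-residue arrays (radians); omega angles
    default to the sequence's proline configurations (pi for trans, 0 for
    cis) but may be supplied explicitly (small rings need slightly
    non-planar peptide bonds to close).
    """
    if omega is None:
        omega = _omega_targets(topo)
    from ._kernels import nerf_chain_kernel
    enc = topo._zm_backbone if backbone_only else topo._zm_full
    x = np.zeros((topo.n_atoms, 3))
    nerf_chain_kernel(*enc, np.asarray(phi, float), np.asarray(psi, float),
                      np.asarray(omega, float), np.asarray(chi, float), x)
    return x


_CLOSURE_TOL = 0.3          # max acceptable |bond - ideal| before bond formation
_CLOSURE_IDEAL = IDEAL_BOND_LENGTHS["C-N"]


def _closure_objective(topo: Topology):
    """Return f(torsion_vector) scoring ring-closure quality on the backbone.

    The vector holds phi, psi and omega deviations from their targets; the
    omega flexibility (with a stiff penalty) lets small, strained rings
    close — real cyclic tetrapeptides distort their peptide planes.
    """
    nres = topo.n_residues
    i_c = topo.atom_index(nres, "C")
    i_ca_l = topo.atom_index(nres, "CA")
    i_n = topo.atom_index(1, "N")
    i_ca_1 = topo.atom_index(1, "CA")
    th1 = _ideal_angle("CA", "C", "N")
    th2 = _ideal_angle("C", "N", "CA")
    om0 = _omega_targets(topo)

    def f(v: np.ndarray) -> float:
        phi, psi = v[:nres], v[nres:2 * nres]
        dom = v[2 * nres:]
        x = _coords_from_torsions(topo, phi, psi, np.zeros(nres),
                                  backbone_only=True, omega=om0 + dom)
        d = np.linalg.norm(x[i_c] - x[i_n])
        a1 = bond_angles(x, np.array([[i_ca_l, i_c, i_n]]))[0]
        a2 = bond_angles(x, np.array([[i_c, i_n, i_ca_1]]))[0]
        om = dihedrals(x, np.array([[i_ca_l, i_c, i_n, i_ca_1]]))[0]
        return (10.0 * (d - _CLOSURE_IDEAL) ** 2
                + 1.0 * ((a1 - th1) ** 2 + (a2 - th2) ** 2)
                + 0.5 * (1.0 + np.cos(om))
                + 2.0 * float(np.sum(dom ** 2)))

    return f, (i_c, i_n), om0


def _refine_closure(topo: Topology, phi: np.ndarray, psi: np.ndarray,
                    maxiter: int = 150
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    f, (i_c, i_n), om0 = _closure_objective(topo)
    nres = topo.n_residues
    v0 = np.concatenate([phi, psi, np.zeros(nres)])
    res = _sp_minimize(f, v0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12})
    phi_r, psi_r = res.x[:nres], res.x[nres:2 * nres]
    dom = res.x[2 * nres:]
    x = _coords_from_torsions(topo, phi_r, psi_r, np.zeros(nres),
                              backbone_only=True, omega=om0 + dom)
    gap = abs(np.linalg.norm(x[i_c] - x[i_n]) - _CLOSURE_IDEAL)
    return phi_r, psi_r, om0 + dom, gap


def build_initial_conformation(topo: Topology, mode: str = "extended",
                               seed: Optional[int] = None) -> Conformation:
    """Build starting coordinates with ideal internal geometry.

    ``extended`` uses canonical beta-strand torsions (deterministic); for a
    cyclic topology the backbone torsions are then refined so the ring-closure
    C-N distance reaches the ideal peptide bond length before the closure bond
    is considered formed.  ``random`` draws phi/psi/chi uniformly (seeded)
    and applies the same closure refinement, retrying with fresh draws if a
    draw cannot be closed.
    """
    nres = topo.n_residues
    if mode == "extended":
        phi = np.full(nres, np.deg2rad(-135.0))
        psi = np.full(nres, np.deg2rad(135.0))
        chi = np.full(nres, np.pi)
    elif mode == "random":
        if seed is None:
            raise ValueError("random mode requires a seed")
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, nres)
        psi = rng.uniform(-np.pi, np.pi, nres)
        chi = rng.uniform(-np.pi, np.pi, nres)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    omega = _omega_targets(topo)
    if topo.sequence.cyclic:
        attempts = 8 if mode == "random" else 1
        best_gap = np.inf
        rng2 = np.random.default_rng(seed) if mode == "random" else None
        for attempt in range(attempts):
            if attempt > 0:
                phi = rng2.uniform(-np.pi, np.pi, nres)
                psi = rng2.uniform(-np.pi, np.pi, nres)
            phi_r, psi_r, om_r, gap = _refine_closure(topo, phi, psi)
            if gap < best_gap:
                best_gap = gap
                phi, psi, omega = phi_r, psi_r, om_r
            if best_gap <= 0.05:
                break
        if best_gap > _CLOSURE_TOL:
            raise RingClosureError(best_gap, _CLOSURE_TOL)

    coords = _coords_from_torsions(topo, phi, psi, chi, omega=omega)
    label = f"{mode}" + (f"-seed{seed}" if seed is not None else "")
    return Conformation(topo, coords, label=label,
                        meta={"mode": mode, "seed": seed,
                              "phi": phi.copy(), "psi": psi.copy(),
                              "chi": chi.copy(), "omega": omega.copy()})
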