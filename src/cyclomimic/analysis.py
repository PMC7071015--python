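"""Superposition, RMSD, clustering and loop-mimicry ranking.

Backbone comparisons use the N, CA, C main-chain atoms.  Superposition is
the closed-form least-squares rigid alignment (SVD with reflection guard);
clustering is average-linkage hierarchical clustering on the pairwise
backbone-RMSD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import SuperpositionError
from .peptide import Conformation

__all__ = [
    "SuperpositionResult",
    "ResidueMapping",
    "ClusterSet",
    "kabsch_superpose",
    "backbone_rmsd",
    "pairwise_backbone_rmsd",
    "cluster",
    "mimicry_table",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid alignment of mobile onto reference coordinates."""

    rotation: np.ndarray        # (3, 3), orthonormal, det +1
    translation: np.ndarray     # (3,), applied after rotation
    rmsd: float                 # A
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Both inputs are (n, 3) with n >= 3 and must not be collinear.  The
    returned rotation/translation map mobile onto reference; ``rmsd`` is the
    minimised value in A.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError(
            f"coordinate sets must both be (n, 3), got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) coordinate set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


@dataclass(frozen=True)
class ResidueMapping:
    """Injective residue correspondence mobile -> reference (1-based)."""

    pairs: Tuple[Tuple[int, int], ...]
    backbone_atoms: Tuple[str, ...] = BACKBONE_ATOMS

    def __post_init__(self):
        refs = [b for _a, b in self.pairs]
        mobs = [a for a, _b in self.pairs]
        if len(set(refs)) != len(refs) or len(set(mobs)) != len(mobs):
            raise ValueError("residue mapping must be injective")

    @classmethod
    def identity(cls, n_residues: int,
                 backbone_atoms: Sequence[str] = BACKBONE_ATOMS) -> "ResidueMapping":
        return cls(tuple((i, i) for i in range(1, n_residues + 1)),
                   tuple(backbone_atoms))

    @classmethod
    def epitope(cls, n_epitope: int,
                backbone_atoms: Sequence[str] = BACKBONE_ATOMS) -> "ResidueMapping":
        """Map macrocycle epitope residues 1..n onto reference loop 1..n.

        Linker residues (beyond the epitope) are excluded, matching a design
        whose first residues reproduce the reference loop sequence.
        """
        return cls(tuple((i, i) for i in range(1, n_epitope + 1)),
                   tuple(backbone_atoms))


ReferenceLike = Union[Conformation, Sequence]


def _extract_backbone(structure: ReferenceLike, residue_positions: Sequence[int],
                      atom_names: Sequence[str]) -> np.ndarray:
    """Pull backbone coordinates for 1-based residue positions.

    Accepts a :class:`Conformation` or a parsed PDB residue list (objects
    with ``atoms`` dicts, as returned by :func:`cyclomimic.io.read_pdb`).
    """
    coords = []
    if isinstance(structure, Conformation):
        topo = structure.topology
        for pos in residue_positions:
            for nm in atom_names:
                try:
                    coords.append(structure.coords[topo.atom_index(pos, nm)])
                except KeyError:
                    raise SuperpositionError(
                        f"missing backbone atom {nm} in residue {pos}") from None
    else:
        residues = list(structure)
        for pos in residue_positions:
            if not (1 <= pos <= len(residues)):
                raise SuperpositionError(
                    f"reference has no residue at position {pos}")
            res = residues[pos - 1]
            for nm in atom_names:
                if nm not in res.atoms:
                    raise SuperpositionError(
                        f"missing backbone atom {nm} in reference residue "
                        f"{getattr(res, 'resnum', pos)}")
                coords.append(res.atoms[nm])
    return np.asarray(coords, dtype=float)


def backbone_rmsd(a: Conformation, b: ReferenceLike,
                  mapping: Optional[ResidueMapping] = None) -> float:
    """Backbone RMSD (A) after optimal superposition on mapped residues."""
    if mapping is None:
        mapping = ResidueMapping.identity(a.topology.n_residues)
    mob = _extract_backbone(a, [p[0] for p in mapping.pairs],
                            mapping.backbone_atoms)
    ref = _extract_backbone(b, [p[1] for p in mapping.pairs],
                            mapping.backbone_atoms)
    return kabsch_superpose(mob, ref).rmsd


def pairwise_backbone_rmsd(confs: Sequence[Conformation],
                           mapping: Optional[ResidueMapping] = None) -> np.ndarray:
    n = len(confs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = backbone_rmsd(confs[i], confs[j], mapping)
    return mat


@dataclass(frozen=True)
class ClusterSet:
    """Partition of an ensemble, largest cluster first."""

    clusters: Tuple[Tuple[int, ...], ...]   # conformer indices into the ensemble
    cutoff: float                           # linkage cutoff (A)

    @property
    def sizes(self) -> Tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)


def cluster(ensemble, cutoff: float = 2.0,
            mapping: Optional[ResidueMapping] = None) -> ClusterSet:
    """Average-linkage clustering on the pairwise backbone-RMSD matrix.

    ``ensemble`` is a :class:`cyclomimic.search.ConformerEnsemble` (or any
    sequence of conformations); clusters are sorted by size descending then
    by their lowest member energy.
    """
    confs = list(ensemble)
    if not confs:
        raise ValueError("cannot cluster an empty ensemble")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = len(confs)
    if n == 1:
        return ClusterSet(clusters=((0,),), cutoff=cutoff)
    mat = pairwise_backbone_rmsd(confs, mapping)
    Z = linkage(squareform(mat, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    groups: Dict[int, List[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)

    def sort_key(members: List[int]):
        energies = [confs[i].energy if confs[i].energy is not None else np.inf
                    for i in members]
        return (-len(members), min(energies))

    ordered = sorted(groups.values(), key=sort_key)
    return ClusterSet(clusters=tuple(tuple(m) for m in ordered), cutoff=cutoff)


def mimicry_table(structures: Sequence[Tuple[str, Conformation]],
                  reference: ReferenceLike,
                  mapping: ResidueMapping) -> pd.DataFrame:
    """Rank labelled structures by backbone RMSD to a reference loop.

    Returns a DataFrame with columns ``structure_label``, ``rmsd_A`` and
    ``mappable`` sorted by ascending RMSD; structures whose mapping cannot
    be resolved are flagged (rmsd NaN) and sorted last, never dropped.
    """
    rows = []
    for label, conf in structures:
        try:
            r = backbone_rmsd(conf, reference, mapping)
            rows.append({"structure_label": label, "rmsd_A": r,
                         "mappable": True})
        except SuperpositionError:
            rows.append({"structure_label": label, "rmsd_A": np.nan,
                         "mappable": False})
    df = pd.DataFrame(rows, columns=["structure_label", "rmsd_A", "mappable"])
    return df.sort_values("rmsd_A", na_position="last",
                          kind="mergesort").reset_index(drop=True)
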