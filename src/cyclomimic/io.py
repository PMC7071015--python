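"""File formats: PDB structures, TSV tables, pipeline configuration.

PDB reading/writing goes through gemmi; coordinates are serialised at the
format's 3-decimal precision.  Cyclic topologies additionally emit a
CONECT record linking the C-terminal carbonyl carbon to the N-terminal
nitrogen (gemmi itself records the closure as a LINK).  All TSV dialects
are tab-delimited with header rows and '.' decimal separators.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
import pandas as pd

from .errors import ConfigError, PDBFormatError
from .noe import CalibrationReference, DistanceRestraint, NOEPeak
from .peptide import Conformation, Topology

logger = logging.getLogger(__name__)

__all__ = [
    "PDBResidue",
    "read_pdb",
    "write_pdb",
    "read_peaks_tsv",
    "write_peaks_tsv",
    "read_restraints_tsv",
    "write_restraints_tsv",
    "write_ensemble_tsv",
    "write_mimicry_tsv",
    "read_plate_tsv",
    "write_plate_tsv",
    "PipelineConfig",
    "load_config",
    "file_digest",
]


# ---------------------------------------------------------------- PDB ------

@dataclass
class PDBResidue:
    """One residue parsed from a PDB model."""

    resnum: int
    resname: str
    icode: str
    atoms: Dict[str, np.ndarray]


def _validate_atom_lines(path: Path) -> int:
    """Pre-scan ATOM/HETATM records; returns their count.

    Gives precise line numbers for malformed fixed-column records, which
    gemmi would otherwise tolerate or report opaquely.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: ATOM record shorter than 54 columns")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PDBFormatError(
                    f"{path}:{lineno}: unparsable coordinates in ATOM record"
                ) from None
    return n


def read_pdb(path: Union[str, Path],
             chain: Optional[str] = None,
             residue_range: Optional[Tuple[int, int]] = None
             ) -> List[List[PDBResidue]]:
    """Parse ATOM records into one residue list per model.

    ``chain`` and ``residue_range`` (inclusive, by author numbering) select
    a subset; an empty selection or a file without ATOM records is an
    explicit error.  Insertion codes are preserved on the residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _validate_atom_lines(path) == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    st = gemmi.read_pdb(str(path))
    models: List[List[PDBResidue]] = []
    for model in st:
        residues: List[PDBResidue] = []
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                num = res.seqid.num
                if residue_range is not None and not (
                        residue_range[0] <= num <= residue_range[1]):
                    continue
                atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                         for a in res}
                residues.append(PDBResidue(
                    resnum=num, resname=res.name,
                    icode=(res.seqid.icode or " ").strip() or "",
                    atoms=atoms))
        models.append(residues)
    if all(len(m) == 0 for m in models):
        raise PDBFormatError(
            f"{path}: selection (chain={chain!r}, range={residue_range!r}) "
            f"matched no residues")
    return models


def _structure_from_conformations(confs: Sequence[Conformation]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "cyclomimic"
    for mi, conf in enumerate(confs, start=1):
        topo = conf.topology
        model = gemmi.Model(str(mi))
        ch = gemmi.Chain("A")
        cur_res = None
        cur_num = None
        for idx, atom in enumerate(topo.atoms):
            if atom.res_index != cur_num:
                if cur_res is not None:
                    ch.add_residue(cur_res)
                cur_res = gemmi.Residue()
                cur_res.name = atom.res_name
                cur_res.seqid = gemmi.SeqId(atom.res_index, " ")
                cur_num = atom.res_index
            a = gemmi.Atom()
            a.name = atom.name
            a.element = gemmi.Element(atom.element)
            x, y, z = conf.coords[idx]
            a.pos = gemmi.Position(round(x, 3), round(y, 3), round(z, 3))
            cur_res.add_atom(a)
        if cur_res is not None:
            ch.add_residue(cur_res)
        model.add_chain(ch)
        st.add_model(model)
    return st


def write_pdb(structures: Union[Conformation, Sequence[Conformation]],
              path: Union[str, Path]) -> None:
    """Write conformations as a (multi-model) PDB file.

    Ensembles are wrapped in MODEL/ENDMDL blocks; a cyclic topology's
    ring-closure bond is emitted as a CONECT pair between the C-terminal C
    and N-terminal N atom serials of each model.  Output bytes are
    deterministic for identical input.
    """
    if isinstance(structures, Conformation):
        confs = [structures]
    else:
        confs = list(structures)
    if not confs:
        raise ValueError("nothing to write")
    topo = confs[0].topology
    st = _structure_from_conformations(confs)
    text = st.make_pdb_string()

    closure = topo.ring_closure_bond
    if closure is not None:
        # atom serials are positional (1-based) in each model's ATOM block
        serial_c = closure[0] + 1
        serial_n = closure[1] + 1
        conect_line = f"CONECT{serial_c:>5}{serial_n:>5}\n"
        final: List[str] = []
        for line in text.splitlines(keepends=True):
            if line.startswith("END") and not line.startswith("ENDMDL"):
                final.append(conect_line)
            final.append(line)
        text = "".join(final)
    Path(path).write_text(text)


def conformation_from_pdb(path: Union[str, Path], topo: Topology
                          ) -> List[Conformation]:
    """Read a PDB written by :func:`write_pdb` back onto its topology."""
    models = read_pdb(path)
    out = []
    for residues in models:
        coords = np.zeros((topo.n_atoms, 3))
        by_num = {r.resnum: r for r in residues}
        for idx, atom in enumerate(topo.atoms):
            res = by_num.get(atom.res_index)
            if res is None or atom.name not in res.atoms:
                raise PDBFormatError(
                    f"{path}: missing atom {atom.name} in residue "
                    f"{atom.res_index}")
            coords[idx] = res.atoms[atom.name]
        out.append(Conformation(topo, coords, label=str(path)))
    return out


# ---------------------------------------------------------------- TSV ------

_PEAK_COLS = ["res_i", "atom_i", "res_j", "atom_j", "volume"]
_RESTRAINT_COLS = ["res_i", "atom_i", "res_j", "atom_j",
                   "distance_A", "lower_A", "upper_A", "source_peak"]


def write_peaks_tsv(peaks: Sequence[NOEPeak], path: Union[str, Path],
                    ref: Optional[CalibrationReference] = None) -> None:
    df = pd.DataFrame([{"res_i": p.res_i, "atom_i": p.atom_i,
                        "res_j": p.res_j, "atom_j": p.atom_j,
                        "volume": p.volume} for p in peaks],
                      columns=_PEAK_COLS)
    with open(path, "w") as fh:
        if ref is not None:
            fh.write(f"# r_ref_A\t{ref.r_ref:.6f}\n")
            fh.write(f"# alpha_ref\t{ref.alpha_ref:.6f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_peaks_tsv(path: Union[str, Path]
                   ) -> Tuple[List[NOEPeak], Optional[CalibrationReference]]:
    from io import StringIO
    r_ref = alpha_ref = None
    header_meta = []
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_meta.append(line[1:].strip().split("\t"))
            else:
                body_lines.append(line)
    df = pd.read_csv(StringIO("".join(body_lines)), sep="\t")
    for key, val in header_meta:
        if key == "r_ref_A":
            r_ref = float(val)
        elif key == "alpha_ref":
            alpha_ref = float(val)
    peaks = [NOEPeak(int(r.res_i), str(r.atom_i), int(r.res_j), str(r.atom_j),
                     float(r.volume), peak_id=f"p{k+1:03d}")
             for k, r in df.iterrows()]
    ref = None
    if r_ref is not None and alpha_ref is not None:
        ref = CalibrationReference(r_ref=r_ref, alpha_ref=alpha_ref)
    return peaks, ref


def write_restraints_tsv(restraints: Sequence[DistanceRestraint],
                         path: Union[str, Path]) -> None:
    df = pd.DataFrame([{
        "res_i": r.res_i, "atom_i": r.atom_i, "res_j": r.res_j,
        "atom_j": r.atom_j, "distance_A": r.r_ij, "lower_A": r.lower,
        "upper_A": r.upper, "source_peak": r.source_peak}
        for r in restraints], columns=_RESTRAINT_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_restraints_tsv(path: Union[str, Path]) -> List[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    return [DistanceRestraint(
        res_i=int(r.res_i), atom_i=str(r.atom_i), res_j=int(r.res_j),
        atom_j=str(r.atom_j), r_ij=float(r.distance_A),
        lower=float(r.lower_A), upper=float(r.upper_A),
        source_peak=str(r.source_peak)) for _k, r in df.iterrows()]


def write_ensemble_tsv(ensemble, path: Union[str, Path],
                       boltzmann=None) -> None:
    """Energies table: conformer_id, energy_kJ_mol, boltzmann_ratio."""
    rows = []
    for i, conf in enumerate(ensemble):
        row = {"conformer_id": i, "energy_kJ_mol": conf.energy}
        if boltzmann is not None:
            row["boltzmann_ratio"] = boltzmann.ratios_to_highest[i]
        vr = conf.meta.get("violations")
        if vr is not None:
            row["max_violation_A"] = vr.max_violation
            row["fraction_satisfied"] = vr.fraction_satisfied
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6f")


def write_mimicry_tsv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_plate_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"compound", "conc_uM", "a620", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_plate_tsv(readings: pd.DataFrame, path: Union[str, Path]) -> None:
    readings.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ------------------------------------------------------------- config ------

@dataclass
class PipelineConfig:
    """Resolved pipeline settings; every tunable with its default.

    Unknown keys in a config file are rejected, and the fully resolved
    mapping should be logged/echoed by every run that consumes one.
    """

    design: Dict = field(default_factory=lambda: {
        "epitope": "HYWSENLFQ", "linker": "PG", "cyclic": True})
    forcefield: Dict = field(default_factory=dict)     # ForceFieldParams overrides
    search: Dict = field(default_factory=lambda: {
        "steps": 5000, "max_displacement": 3.0, "temperature": 500.0,
        "rms_gradient_tol": 0.01})
    calibration: Dict = field(default_factory=lambda: {
        "bound_margin": 0.5})
    annealing: Dict = field(default_factory=lambda: {
        "t_start": 3500.0, "t_end": 100.0, "steps": 60000,
        "cooling": "geometric", "k_noe_start": 2.0, "k_noe_end": 50.0,
        "n_structures": 10})
    clustering: Dict = field(default_factory=lambda: {"cutoff": 2.0})
    assay: Dict = field(default_factory=lambda: {
        "bounds_low_pct": -20.0, "bounds_high_pct": 120.0})
    synthetic: Dict = field(default_factory=lambda: {
        "volume_scale": 1.0e6, "cutoff": 5.0, "sigma": 0.0,
        "subsample": 1.0})

    def as_dict(self) -> Dict:
        return {f.name: dict(getattr(self, f.name)) for f in dc_fields(self)}


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a TOML config; unknown sections or keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = PipelineConfig()
    known = {f.name for f in dc_fields(cfg)}
    for section, values in data.items():
        if section not in known:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a table")
        defaults = getattr(cfg, section)
        if section != "forcefield":     # forcefield keys validated downstream
            for key in values:
                if defaults and key not in defaults:
                    raise ConfigError(
                        f"unknown key {key!r} in section {section!r}")
        defaults.update(values)
    return cfg


def file_digest(path: Union[str, Path]) -> str:
    """Short sha256 digest for input/output drift detection in logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
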