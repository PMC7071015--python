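"""Metropolis Monte-Carlo conformational search with per-step minimisation.

Each step displaces every atom by an independent random vector of bounded
norm, minimises the perturbed structure, and applies Metropolis acceptance
on the minimised energies (basin hopping).  Distinct accepted minima are
collected into a :class:`ConformerEnsemble`; Boltzmann factors use
BF = exp(-E/RT) with energies shifted by the ensemble minimum so the
exponentials stay in (0, 1], and ratios are reported relative to the
highest-energy conformer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .analysis import kabsch_superpose
from .errors import MinimizationError
from .forcefield import (EnergyModel, ForceFieldParams, GAS_CONSTANT_KJ,
                         minimize_conformation)
from .peptide import Conformation, Topology, _coords_from_torsions

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "ConformerEnsemble",
    "BoltzmannWeights",
    "monte_carlo_search",
    "boltzmann_analysis",
    "deduplicate",
    "torsion_grid_scan",
]


@dataclass(frozen=True)
class SearchConfig:
    """Monte-Carlo search settings (defaults follow the published protocol)."""

    steps: int = 5000
    max_displacement: float = 3.0        # A per atom per move
    temperature: float = 500.0           # K, Metropolis acceptance
    rms_gradient_tol: float = 0.01       # kJ/mol/A, per-step minimisation
    seed: int = 0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.max_displacement <= 0 or self.temperature <= 0:
            raise ValueError("max_displacement and temperature must be > 0")


@dataclass
class ConformerEnsemble:
    """Conformations with energies, kept sorted ascending by energy."""

    conformations: List[Conformation] = field(default_factory=list)
    provenance: str = ""
    seed: Optional[int] = None

    def __post_init__(self):
        self._sort()

    def _sort(self) -> None:
        for c in self.conformations:
            if c.energy is None or not np.isfinite(c.energy):
                raise ValueError("every ensemble member needs a finite energy")
        self.conformations.sort(key=lambda c: c.energy)

    def add(self, conf: Conformation) -> None:
        self.conformations.append(conf)
        self._sort()

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformations])

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i):
        return self.conformations[i]

    @property
    def lowest(self) -> Conformation:
        return self.conformations[0]


@dataclass(frozen=True)
class BoltzmannWeights:
    """Shifted Boltzmann factors and ratios vs the highest-energy member."""

    factors: np.ndarray           # exp(-(E - E_min)/RT), in (0, 1]
    ratios_to_highest: np.ndarray  # exp(-(E - E_max)/RT), each >= 1
    temperature: float


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n independent vectors uniform in the ball of the given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def monte_carlo_search(start: Conformation, cfg: SearchConfig,
                       params: Optional[ForceFieldParams] = None,
                       max_minimize_iter: int = 600) -> ConformerEnsemble:
    """Basin-hopping search for low-energy conformers.

    Deterministic under a fixed ``cfg.seed``; a failed per-step minimisation
    is skipped and logged, never silently swallowed.  With ``steps=0`` the
    ensemble holds only the minimised start structure.
    """
    model = EnergyModel(start.topology, params)
    rng = np.random.default_rng(cfg.seed)
    current = minimize_conformation(start, params,
                                    rms_gradient_tol=cfg.rms_gradient_tol,
                                    max_iter=max_minimize_iter, model=model)
    current.label = "mc-0"
    minima: List[Conformation] = [current]
    energies_seen = [current.energy]
    rt = GAS_CONSTANT_KJ * cfg.temperature

    for step in range(1, cfg.steps + 1):
        trial = current.copy()
        trial.coords = current.coords + _uniform_ball(
            rng, current.coords.shape[0], cfg.max_displacement)
        # draw the acceptance variate unconditionally: the random stream then
        # does not depend on energy values, only on the seed and step count
        u = rng.random()
        try:
            cand = minimize_conformation(trial, params,
                                         rms_gradient_tol=cfg.rms_gradient_tol,
                                         max_iter=max_minimize_iter,
                                         model=model)
        except MinimizationError as exc:
            logger.warning("search step %d: minimisation failed (%s); skipped",
                           step, exc)
            continue
        de = cand.energy - current.energy
        if de <= 0 or u < np.exp(-de / rt):
            current = cand
            current.label = f"mc-{step}"
            if all(abs(current.energy - e) > 1e-6 for e in energies_seen):
                minima.append(current)
                energies_seen.append(current.energy)

    return ConformerEnsemble(conformations=[c.copy() for c in minima],
                             provenance="search", seed=cfg.seed)


def boltzmann_analysis(ensemble: ConformerEnsemble,
                       temperature: float) -> BoltzmannWeights:
    """Boltzmann factors BF = exp(-E/RT) with overflow-safe energy shifting.

    Energies are shifted by the ensemble minimum before exponentiation
    (ratios are unchanged); ratios are referenced to the highest-energy
    conformer, so every ratio is >= 1.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    e = ensemble.energies
    rt = GAS_CONSTANT_KJ * temperature
    factors = np.exp(-(e - e.min()) / rt)
    ratios = np.exp(-(e - e.max()) / rt)
    return BoltzmannWeights(factors=factors, ratios_to_highest=ratios,
                            temperature=temperature)


def deduplicate(ensemble: ConformerEnsemble, rmsd_tol: float) -> ConformerEnsemble:
    """Merge conformers whose all-atom superposed RMSD is within tolerance.

    The lower-energy member of each merged pair survives; ascending-energy
    ordering is preserved.
    """
    if rmsd_tol < 0:
        raise ValueError("rmsd_tol must be >= 0")
    kept: List[Conformation] = []
    for conf in ensemble:          # ascending energy: keepers win on energy
        dup = False
        for ref in kept:
            if kabsch_superpose(conf.coords, ref.coords).rmsd <= rmsd_tol:
                dup = True
                break
        if not dup:
            kept.append(conf)
    return ConformerEnsemble(conformations=[c.copy() for c in kept],
                             provenance=ensemble.provenance,
                             seed=ensemble.seed)


def torsion_grid_scan(topo: Topology, grid_deg: float = 30.0,
                      scan: str = "phi",
                      base_phi: Optional[np.ndarray] = None,
                      base_psi: Optional[np.ndarray] = None,
                      params: Optional[ForceFieldParams] = None,
                      minimize_best: bool = True,
                      rms_gradient_tol: float = 0.01) -> Tuple[float, Conformation, int]:
    """Exhaustive torsion-grid reference scan (search oracle).

    Enumerates every combination of the scanned torsion class ('phi' or
    'psi') on a regular grid while holding the other class at the supplied
    base values, evaluates the unminimised energy of each grid point, and
    (optionally) minimises the best point.  Returns (best energy, best
    conformation, points evaluated).  Exponential in residue count — meant
    for small toy systems.
    """
    n = topo.n_residues
    model = EnergyModel(topo, params)
    phi0 = np.zeros(n) if base_phi is None else np.asarray(base_phi, float)
    psi0 = np.zeros(n) if base_psi is None else np.asarray(base_psi, float)
    values = np.deg2rad(np.arange(-180.0, 180.0, grid_deg))
    best_e = np.inf
    best_combo = None
    count = 0
    for combo in itertools.product(values, repeat=n):
        if scan == "phi":
            phi, psi = np.asarray(combo), psi0
        else:
            phi, psi = phi0, np.asarray(combo)
        x = _coords_from_torsions(topo, phi, psi, np.full(n, np.pi))
        e = model.energy(x)
        count += 1
        if e < best_e:
            best_e = e
            best_combo = (phi.copy(), psi.copy())
    phi, psi = best_combo
    x = _coords_from_torsions(topo, phi, psi, np.full(n, np.pi))
    best = Conformation(topo, x, energy=float(best_e), label="grid-best")
    if minimize_best:
        best = minimize_conformation(best, params,
                                     rms_gradient_tol=rms_gradient_tol,
                                     max_iter=2000, model=model)
    return float(best.energy), best, count
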