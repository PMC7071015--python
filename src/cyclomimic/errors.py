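"""Exception hierarchy for the cyclomimic pipeline."""


class CyclomimicError(Exception):
    """Base class for all package-specific failures."""


class DesignError(CyclomimicError):
    """Invalid peptide design specification."""


class RingClosureError(CyclomimicError):
    """Macrocycle ring closure could not be refined below tolerance."""

    def __init__(self, gap: float, tol: float):
        self.gap = gap
        self.tol = tol
        super().__init__(
            f"ring closure unattainable: residual bond-length gap "
            f"{gap:.3f} A exceeds tolerance {tol:.3f} A"
        )


class MinimizationError(CyclomimicError):
    """Energy minimisation encountered non-finite values."""


class RestraintError(CyclomimicError):
    """Invalid NOE peak or restraint definition."""


class SuperpositionError(CyclomimicError):
    """Degenerate or mismatched coordinate sets for superposition."""


class FitError(CyclomimicError):
    """Dose-response fit could not converge or data are degenerate."""


class PDBFormatError(CyclomimicError):
    """Malformed or empty PDB input."""


class ConfigError(CyclomimicError):
    """Unknown or invalid pipeline configuration key."""
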