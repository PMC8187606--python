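"""Sequence-composition bookkeeping: A280 extinction coefficient and
Beer-Lambert concentration.

Uses the Pace chromophore coefficients (5500 Trp, 1490 Tyr, 125 cystine,
all M^-1 cm^-1 at 280 nm); a reduced protein contributes no cystine term.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ProteinComposition",
    "extinction_coefficient_280",
    "concentration_from_a280",
]

EPS_TRP = 5500.0
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0


@dataclass(frozen=True)
class ProteinComposition:
    """Chromophore counts of one polypeptide (cystines = disulfide pairs)."""

    n_trp: int
    n_tyr: int
    n_cystine: int = 0
    n_residues: int | None = None
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        for name in ("n_trp", "n_tyr", "n_cystine"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_residues is not None and self.n_residues < self.n_trp + self.n_tyr:
            raise ValueError("n_residues smaller than the chromophore count")

    @classmethod
    def from_sequence(cls, sequence: str, n_cystine: int = 0) -> "ProteinComposition":
        """Count chromophores from a one-letter sequence (FASTA accepted).

        Disulfide pairing cannot be read from sequence, so cystines are
        supplied separately (default 0, a reduced protein).
        """
        residues = "".join(
            line.strip()
            for line in sequence.splitlines()
            if line.strip() and not line.startswith((">", ";"))
        ).upper()
        if not residues.isalpha():
            raise ValueError("sequence contains non-letter characters")
        return cls(
            n_trp=residues.count("W"),
            n_tyr=residues.count("Y"),
            n_cystine=n_cystine,
            n_residues=len(residues),
        )

    def __add__(self, other: "ProteinComposition") -> "ProteinComposition":
        n_res = None
        if self.n_residues is not None and other.n_residues is not None:
            n_res = self.n_residues + other.n_residues
        return ProteinComposition(
            n_trp=self.n_trp + other.n_trp,
            n_tyr=self.n_tyr + other.n_tyr,
            n_cystine=self.n_cystine + other.n_cystine,
            n_residues=n_res,
        )


def extinction_coefficient_280(comp: ProteinComposition) -> float:
    """Molar extinction coefficient at 280 nm, M^-1 cm^-1."""
    return EPS_TRP * comp.n_trp + EPS_TYR * comp.n_tyr + EPS_CYSTINE * comp.n_cystine


def concentration_from_a280(a280: float, epsilon: float, pathlength_cm: float = 1.0) -> float:
    """Beer-Lambert molar concentration c = A280 / (epsilon * l)."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if pathlength_cm <= 0:
        raise ValueError(f"pathlength must be positive, got {pathlength_cm}")
    return a280 / (epsilon * pathlength_cm)
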