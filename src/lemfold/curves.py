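"""The DenaturationCurve container: one probe signal vs perturbant series."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PERTURBANT_KINDS = ("urea", "gdnhcl", "temperature")
PROBES = ("cd222", "fluor340", "lambda_max")

_TSV_COLUMNS = ["perturbant_kind", "x", "probe", "replicate", "y"]


@dataclass
class DenaturationCurve:
    """A single unfolding transition curve — the unit of fitting.

    ``x`` is denaturant concentration (M) for chemical perturbants or
    absolute temperature (K) for thermal melts; ``y`` is the probe signal
    (mean residue ellipticity, relative fluorescence intensity, or
    emission-maximum wavelength, in whatever units the instrument gives).
    """

    perturbant_kind: str
    x: np.ndarray
    y: np.ndarray
    probe: str = "cd222"
    replicate_id: str = "rep1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.perturbant_kind not in PERTURBANT_KINDS:
            raise ValueError(
                f"perturbant_kind must be one of {PERTURBANT_KINDS}, got {self.perturbant_kind!r}"
            )
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if len(self.x) != len(self.y):
            raise ValueError(f"len(x)={len(self.x)} != len(y)={len(self.y)}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains non-finite values")
        if self.perturbant_kind == "temperature":
            if np.any(self.x <= 0):
                raise ValueError("temperatures must be positive kelvin")
        elif np.any(self.x < 0):
            raise ValueError("denaturant concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_thermal(self) -> bool:
        return self.perturbant_kind == "temperature"

    def sorted(self) -> "DenaturationCurve":
        order = np.argsort(self.x, kind="stable")
        return DenaturationCurve(
            perturbant_kind=self.perturbant_kind,
            x=self.x[order],
            y=self.y[order],
            probe=self.probe,
            replicate_id=self.replicate_id,
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "perturbant_kind": self.perturbant_kind,
                "x": self.x,
                "probe": self.probe,
                "replicate": self.replicate_id,
                "y": self.y,
            }
        )


def curves_to_tsv(curves: list[DenaturationCurve], path) -> None:
    """Write curves as tidy TSV with columns (perturbant_kind, x, probe, replicate, y)."""
    frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)


def curves_from_tsv(path) -> list[DenaturationCurve]:
    """Read curves written by :func:`curves_to_tsv`, one per (probe, replicate)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"curve table {path} missing columns {missing}")
    out = []
    for (kind, probe, rep), grp in frame.groupby(
        ["perturbant_kind", "probe", "replicate"], sort=True
    ):
        grp = grp.sort_values("x")
        out.append(
            DenaturationCurve(
                perturbant_kind=str(kind),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                probe=str(probe),
                replicate_id=str(rep),
            )
        )
    return out
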