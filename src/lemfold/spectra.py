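"""Wavelength-scan handling: reading scan tables, mean residue ellipticity
conversion, probe extraction at a wavelength, and emission-maximum location.

A CD melt or titration arrives as one spectrum per condition; the analysis
consumes a single number per condition — the MRE at 222 nm (helix probe),
the relative fluorescence at 340 nm, or the emission maximum wavelength
(tryptophan-exposure probe). This module turns scan collections into
`DenaturationCurve` objects for fitting.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import PERTURBANT_KINDS, DenaturationCurve

__all__ = [
    "SpectrumScan",
    "ScanTableDialect",
    "ScanTableError",
    "read_scan_table",
    "ellipticity_to_mre",
    "extract_probe_curve",
    "extract_probe_curves",
    "emission_maximum",
]


class ScanTableError(ValueError):
    """Malformed scan table; the message names the offending line."""


@dataclass
class SpectrumScan:
    """A wavelength-resolved scan at one condition (CD or emission)."""

    wavelength: np.ndarray  # nm, strictly increasing
    signal: np.ndarray  # mdeg for CD, counts for fluorescence
    condition_kind: str = "urea"
    condition_value: float = 0.0
    excitation: float | None = None
    replicate_id: str = "rep1"
    pathlength: float | None = None  # cm
    concentration: float | None = None  # mol/L
    n_residues: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.wavelength) != len(self.signal):
            raise ValueError("wavelength and signal must have equal length")
        if len(self.wavelength) and np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.condition_kind not in PERTURBANT_KINDS:
            raise ValueError(f"condition_kind must be one of {PERTURBANT_KINDS}")

    def signal_at(self, wavelength: float) -> float:
        """Signal linearly interpolated at a wavelength inside the grid."""
        wl = self.wavelength
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside scan range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.signal))

    def shifted(self, delta_nm: float) -> "SpectrumScan":
        out = SpectrumScan.__new__(SpectrumScan)
        out.__dict__.update(self.__dict__)
        out.wavelength = self.wavelength + delta_nm
        return out


@dataclass(frozen=True)
class ScanTableDialect:
    """How a delimited scan table encodes conditions.

    ``layout='wide'``: first column is wavelength, one signal column per
    condition, condition value parsed from the header via ``header_pattern``
    (first capture group, e.g. '0M' -> 0.0).
    ``layout='long'``: tidy columns for wavelength, condition, replicate
    and signal.
    """

    layout: str = "wide"
    sep: str = "\t"
    condition_kind: str = "urea"
    header_pattern: str = r"([-+0-9.eE]+)"
    wavelength_col: str = "wavelength"
    condition_col: str = "condition"
    replicate_col: str = "replicate"
    signal_col: str = "signal"

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ValueError("layout must be 'wide' or 'long'")


def _read_frame(source, sep: str) -> pd.DataFrame:
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and "\n" in source
    ):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"scan table not found: {path}")
        frame = pd.read_csv(path, sep=sep)
    else:
        text = source.read() if hasattr(source, "read") else str(source)
        frame = pd.read_csv(io.StringIO(text), sep=sep)
    if frame.empty:
        raise ScanTableError("scan table is empty")
    return frame


def _check_wavelength(wl: pd.Series) -> None:
    values = wl.to_numpy(dtype=float)
    bad = np.nonzero(np.diff(values) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based rows
        line = int(wl.index[bad[0] + 1]) + 2
        raise ScanTableError(
            f"wavelength grid not strictly increasing at line {line} "
            f"(value {values[bad[0] + 1]} after {values[bad[0]]})"
        )


def read_scan_table(source, dialect: ScanTableDialect = ScanTableDialect()) -> list[SpectrumScan]:
    """Parse a delimited scan table into one SpectrumScan per condition x replicate."""
    frame = _read_frame(source, dialect.sep)
    scans: list[SpectrumScan] = []
    if dialect.layout == "wide":
        wl_col = frame.columns[0]
        _check_wavelength(frame[wl_col])
        if len(frame.columns) < 2:
            raise ScanTableError("wide scan table has no condition columns")
        pattern = re.compile(dialect.header_pattern)
        for col in frame.columns[1:]:
            match = pattern.search(str(col))
            if match is None:
                raise ScanTableError(
                    f"condition header {col!r} does not match pattern {dialect.header_pattern!r}"
                )
            scans.append(
                SpectrumScan(
                    wavelength=frame[wl_col].to_numpy(dtype=float),
                    signal=frame[col].to_numpy(dtype=float),
                    condition_kind=dialect.condition_kind,
                    condition_value=float(match.group(1)),
                )
            )
    else:
        needed = [
            dialect.wavelength_col,
            dialect.condition_col,
            dialect.replicate_col,
            dialect.signal_col,
        ]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ScanTableError(f"long scan table missing columns {missing}")
        for (cond_val, rep), grp in frame.groupby(
            [dialect.condition_col, dialect.replicate_col], sort=True
        ):
            grp = grp.sort_index()
            _check_wavelength(grp[dialect.wavelength_col])
            scans.append(
                SpectrumScan(
                    wavelength=grp[dialect.wavelength_col].to_numpy(dtype=float),
                    signal=grp[dialect.signal_col].to_numpy(dtype=float),
                    condition_kind=dialect.condition_kind,
                    condition_value=float(cond_val),
                    replicate_id=str(rep),
                )
            )
    return scans


def ellipticity_to_mre(
    theta_mdeg, pathlength_cm: float, concentration_molar: float, n_residues: int
):
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    MRE = theta / (10 * l * C * N_res) with the molar-concentration
    convention, yielding deg cm^2 dmol^-1.
    """
    if pathlength_cm <= 0:
        raise ValueError(f"pathlength must be positive, got {pathlength_cm}")
    if concentration_molar <= 0:
        raise ValueError(f"concentration must be positive, got {concentration_molar}")
    if n_residues <= 0:
        raise ValueError(f"n_residues must be positive, got {n_residues}")
    theta = np.asarray(theta_mdeg, dtype=float)
    out = theta / (10.0 * pathlength_cm * concentration_molar * n_residues)
    return float(out) if out.ndim == 0 else out


def emission_maximum(scan: SpectrumScan, with_edge_flag: bool = False):
    """Emission-maximum wavelength, parabola-refined around the peak sample.

    The top grid point and its two neighbours define a parabola whose
    vertex is returned; at a grid edge the raw argmax is returned (flagged
    when ``with_edge_flag``). A flat scan has no peak and raises.
    """
    wl, sig = scan.wavelength, scan.signal
    if len(wl) < 3:
        raise ValueError("emission maximum needs at least 3 points")
    if np.ptp(sig) == 0:
        raise ValueError("no emission peak: signal is constant")
    i = int(np.argmax(sig))
    if i == 0 or i == len(wl) - 1:
        result = float(wl[i])
        return (result, True) if with_edge_flag else result
    y0, y1, y2 = sig[i - 1], sig[i], sig[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # flat top: keep the grid point
        result = float(wl[i])
    else:
        # vertex offset in units of the (locally uniform) grid step
        offset = 0.5 * (y0 - y2) / denom
        step = 0.5 * (wl[i + 1] - wl[i - 1])
        result = float(wl[i] + offset * step)
    return (result, False) if with_edge_flag else result


def _probe_value(scan: SpectrumScan, wavelength: float, probe: str) -> float:
    if probe == "lambda_max":
        return emission_maximum(scan)
    return scan.signal_at(wavelength)


def extract_probe_curves(
    scans: list[SpectrumScan],
    wavelength: float = 222.0,
    probe: str = "cd222",
    relative: bool | None = None,
) -> dict[str, DenaturationCurve]:
    """One DenaturationCurve per replicate, from per-condition scans.

    ``relative`` controls subtraction of the value at the maximum
    perturbant condition (the relative-fluorescence convention); it
    defaults to True for the ``fluor340`` probe and False otherwise.
    """
    if relative is None:
        relative = probe == "fluor340"
    groups: dict[str, list[SpectrumScan]] = {}
    for scan in scans:
        groups.setdefault(scan.replicate_id, []).append(scan)
    out: dict[str, DenaturationCurve] = {}
    for rep, group in sorted(groups.items()):
        if len(group) < 2:
            raise ValueError(
                f"replicate {rep!r} has fewer than 2 conditions; no curve to extract"
            )
        kinds = {s.condition_kind for s in group}
        if len(kinds) > 1:
            raise ValueError(f"replicate {rep!r} mixes perturbant kinds {sorted(kinds)}")
        group = sorted(group, key=lambda s: s.condition_value)
        x = np.array([s.condition_value for s in group], dtype=float)
        y = np.array([_probe_value(s, wavelength, probe) for s in group])
        if relative:
            y = y - y[-1]  # minus the value at maximum perturbant
        out[rep] = DenaturationCurve(
            perturbant_kind=group[0].condition_kind,
            x=x,
            y=y,
            probe=probe,
            replicate_id=rep,
        )
    return out


def extract_probe_curve(
    scans: list[SpectrumScan],
    wavelength: float = 222.0,
    probe: str = "cd222",
    relative: bool | None = None,
    replicate_id: str | None = None,
) -> DenaturationCurve:
    """Single-replicate convenience wrapper around :func:`extract_probe_curves`."""
    curves = extract_probe_curves(scans, wavelength, probe, relative)
    if replicate_id is not None:
        if replicate_id not in curves:
            raise KeyError(f"replicate {replicate_id!r} not present in scans")
        return curves[replicate_id]
    if len(curves) != 1:
        raise ValueError(
            f"scans contain {len(curves)} replicates; pass replicate_id or use "
            "extract_probe_curves"
        )
    return next(iter(curves.values()))
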