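"""Simulated denaturation experiments with the statistical structure the
analysis assumes: closed-form transition signal plus homoscedastic Gaussian
noise scaled to the transition amplitude, on grids mirroring the real
experiments (urea 0-8 M, GdnHCl 0-6 M in 0.25 M steps; melts 20-90 degC in
1 degC steps; triplicates).

Noise is expressed as a fraction of the transition amplitude
|S_N(x_min) - S_U(x_max)| so that one noise level means the same thing for
an MRE curve, a fluorescence curve, or a melt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DenaturationCurve
from .models import (
    Conditions,
    ThermalParams,
    ThreeStateParams,
    TwoStateParams,
    thermal_fraction_unfolded,
    thermal_signal,
    three_state_fractions,
    three_state_signal,
    two_state_fractions,
    two_state_signal,
)
from .spectra import SpectrumScan

__all__ = [
    "SyntheticConfig",
    "default_grid",
    "simulate_curves",
    "simulate_emission_scans",
    "simulate_refolding_branch",
]

_DEFAULT_KIND = {"two_state": "urea", "three_state": "gdnhcl", "thermal": "temperature"}

#: Tryptophan emission-band endpoints (nm): native, intermediate, and
#: GdnHCl-unfolded maxima; the urea-unfolded endpoint 357 nm is available
#: through ``lambda_unfolded``.
LAMBDA_NATIVE = 340.0
LAMBDA_INTERMEDIATE = 345.0
LAMBDA_UNFOLDED_GDNHCL = 360.0
LAMBDA_UNFOLDED_UREA = 357.0


def default_grid(perturbant_kind: str) -> np.ndarray:
    """The experiment grids: urea 0-8 M, GdnHCl 0-6 M (0.25 M), melts 20-90 degC (1 K)."""
    if perturbant_kind == "urea":
        return np.arange(0.0, 8.0 + 1e-9, 0.25)
    if perturbant_kind == "gdnhcl":
        return np.arange(0.0, 6.0 + 1e-9, 0.25)
    if perturbant_kind == "temperature":
        return np.arange(293.15, 363.15 + 1e-9, 1.0)
    raise ValueError(f"unknown perturbant kind {perturbant_kind!r}")


@dataclass
class SyntheticConfig:
    """One simulated experiment: ground truth, grid, noise, replication."""

    model: str  # two_state | three_state | thermal
    truth: TwoStateParams | ThreeStateParams | ThermalParams
    perturbant_kind: str | None = None
    grid: np.ndarray | None = None
    noise_sd: float = 0.02  # Gaussian sigma as fraction of transition amplitude
    n_replicates: int = 3
    seed: int = 42
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _DEFAULT_KIND:
            raise ValueError(f"model must be one of {sorted(_DEFAULT_KIND)}")
        expected = {
            "two_state": TwoStateParams,
            "three_state": ThreeStateParams,
            "thermal": ThermalParams,
        }[self.model]
        if not isinstance(self.truth, expected):
            raise TypeError(f"{self.model} truth must be {expected.__name__}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.perturbant_kind is None:
            self.perturbant_kind = _DEFAULT_KIND[self.model]
        if self.model == "thermal" and self.perturbant_kind != "temperature":
            raise ValueError("thermal model requires temperature perturbant")
        if self.model != "thermal" and self.perturbant_kind == "temperature":
            raise ValueError("chemical model requires urea/gdnhcl perturbant")
        if self.grid is None:
            self.grid = default_grid(self.perturbant_kind)
        self.grid = np.sort(np.asarray(self.grid, dtype=float))


def _endpoint_fractions(cfg: SyntheticConfig, cond: Conditions):
    """(f_N, f_U) arrays over the grid, whatever the model."""
    if cfg.model == "two_state":
        return two_state_fractions(cfg.truth, cfg.grid, cond)
    if cfg.model == "three_state":
        f_n, _, f_u = three_state_fractions(cfg.truth, cfg.grid, cond)
        return f_n, f_u
    f_u = thermal_fraction_unfolded(cfg.truth, cfg.grid)
    return 1.0 - f_u, f_u


def _check_coverage(cfg: SyntheticConfig, cond: Conditions) -> None:
    """Require >= 3 grid points on each baseline of the truth.

    Each side is judged relative to its plateau: at least 3 grid points
    with the fraction within 10% of its maximum, and that maximum above
    0.8. A marginally stable protein with shallow m-values reaches
    neither 95% native at zero denaturant nor 95% unfolded at the top of
    the scan, yet both baselines are still resolved.
    """
    f_n, f_u = _endpoint_fractions(cfg, cond)
    for name, f in (("native", f_n), ("unfolded", f_u)):
        f_max = float(np.max(f))
        if f_max <= 0.8 or np.sum(f >= 0.9 * f_max) < 3:
            raise ValueError(
                "grid does not span both baselines of the truth "
                f"(fewer than 3 points on the {name} plateau)"
            )


def _signal(cfg: SyntheticConfig, x, cond: Conditions):
    if cfg.model == "two_state":
        return two_state_signal(cfg.truth, x, cond)
    if cfg.model == "three_state":
        return three_state_signal(cfg.truth, x, cond)
    return thermal_signal(cfg.truth, x)


def transition_amplitude(cfg: SyntheticConfig) -> float:
    """|S_N(x_min) - S_U(x_max)| from the truth baselines."""
    t = cfg.truth
    x0, x1 = float(cfg.grid[0]), float(cfg.grid[-1])
    s_native = t.a1 + t.b1 * x0
    if isinstance(t, ThreeStateParams):
        s_unfolded = t.e1 + t.g1 * x1
    else:
        s_unfolded = t.c1 + t.p1 * x1
    return abs(s_native - s_unfolded)


def simulate_curves(
    cfg: SyntheticConfig, cond: Conditions = Conditions()
) -> list[DenaturationCurve]:
    """n_replicates noisy probe curves from the ground truth; deterministic per seed."""
    _check_coverage(cfg, cond)
    rng = np.random.default_rng(cfg.seed)
    clean = np.asarray(_signal(cfg, cfg.grid, cond), dtype=float)
    sd = cfg.noise_sd * transition_amplitude(cfg)
    curves = []
    for i in range(cfg.n_replicates):
        y = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
        curves.append(
            DenaturationCurve(
                perturbant_kind=cfg.perturbant_kind,
                x=cfg.grid.copy(),
                y=y,
                probe=cfg.metadata.get("probe", "cd222"),
                replicate_id=f"rep{i + 1}",
                metadata={"synthetic": True, "model": cfg.model, "seed": cfg.seed},
            )
        )
    return curves


def simulate_emission_scans(
    cfg: SyntheticConfig,
    cond: Conditions = Conditions(),
    wavelength: np.ndarray | None = None,
    lambda_unfolded: float | None = None,
    fwhm: float = 25.0,
) -> list[SpectrumScan]:
    """Noisy tryptophan emission spectra across the titration.

    Each condition gets one Gaussian band (FWHM ``fwhm`` nm) whose center
    is the fraction-weighted mix of the native (340 nm), intermediate
    (345 nm) and unfolded (360 nm GdnHCl / 357 nm urea) maxima, and whose
    height is normalized so the 340-nm reading equals the closed-form
    probe signal — the titration curve extracted from these scans is the
    same curve :func:`simulate_curves` produces.
    """
    if cfg.model == "thermal":
        raise ValueError("emission scans are simulated for chemical models only")
    _check_coverage(cfg, cond)
    if wavelength is None:
        wavelength = np.arange(300.0, 400.0 + 1e-9, 1.0)
    if lambda_unfolded is None:
        lambda_unfolded = (
            LAMBDA_UNFOLDED_UREA if cfg.perturbant_kind == "urea" else LAMBDA_UNFOLDED_GDNHCL
        )
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise_sd * transition_amplitude(cfg)
    scans = []
    for i in range(cfg.n_replicates):
        rep = f"rep{i + 1}"
        for c in cfg.grid:
            if cfg.model == "two_state":
                f_n, f_u = two_state_fractions(cfg.truth, float(c), cond)
                center = f_n * LAMBDA_NATIVE + f_u * lambda_unfolded
            else:
                f_n, f_i, f_u = three_state_fractions(cfg.truth, float(c), cond)
                center = (
                    f_n * LAMBDA_NATIVE + f_i * LAMBDA_INTERMEDIATE + f_u * lambda_unfolded
                )
            s_340 = float(_signal(cfg, float(c), cond))
            band = np.exp(-((wavelength - center) ** 2) / (2.0 * sigma**2))
            anchor = np.exp(-((LAMBDA_NATIVE - center) ** 2) / (2.0 * sigma**2))
            signal = s_340 * band / anchor
            if sd > 0:
                signal = signal + rng.normal(0.0, sd, size=signal.shape)
            scans.append(
                SpectrumScan(
                    wavelength=wavelength.copy(),
                    signal=signal,
                    condition_kind=cfg.perturbant_kind,
                    condition_value=float(c),
                    excitation=295.0,
                    replicate_id=rep,
                    metadata={"synthetic": True, "model": cfg.model, "seed": cfg.seed},
                )
            )
    return scans


def simulate_refolding_branch(
    cfg: SyntheticConfig, cond: Conditions = Conditions()
) -> DenaturationCurve:
    """An irreversible refolding trace: the signal stays on the unfolded
    baseline over the whole grid (plus noise). Used to exercise the
    ill-conditioning failure mode of the fitters."""
    t = cfg.truth
    if isinstance(t, ThreeStateParams):
        clean = t.e1 + t.g1 * cfg.grid
    else:
        clean = t.c1 + t.p1 * cfg.grid
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise_sd * transition_amplitude(cfg)
    y = clean + rng.normal(0.0, sd, size=cfg.grid.shape) if sd > 0 else np.asarray(clean)
    return DenaturationCurve(
        perturbant_kind=cfg.perturbant_kind,
        x=cfg.grid.copy(),
        y=np.broadcast_to(y, cfg.grid.shape).copy(),
        probe=cfg.metadata.get("probe", "cd222"),
        replicate_id="refold",
        metadata={"synthetic": True, "branch": "refolding"},
    )
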