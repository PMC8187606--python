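"""Nonlinear least-squares estimation of unfolding parameters.

Each fit minimizes the sum of squared residuals between a probe curve and
the closed-form signal model (`lemfold.models`) with lmfit, using
multi-start initialization over candidate transition midpoints: the SSR
surface of baseline-plus-sigmoid models, and especially of double
sigmoids, is multimodal, so a single start is not trustworthy.

Conventions:

* baselines are pre-estimated from straight lines through the first and
  last three points of the sorted curve (the intermediate baseline starts
  flat at the mid-curve level);
* the three-state stability ordering dG_NU0 >= dG_NI0 is kept by fitting
  dG_NU0 = dG_NI0 + delta with delta >= 0;
* parameter uncertainties are linear-approximation standard errors from
  the covariance at the optimum — these are per-fit errors, distinct from
  the across-replicate SEMs of :func:`aggregate_replicates`;
* least squares is unweighted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .curves import DenaturationCurve
from .models import (
    Conditions,
    ThermalParams,
    ThreeStateParams,
    TwoStateParams,
    kelvin_to_celsius,
    three_state_signal,
    thermal_signal,
    two_state_signal,
)

__all__ = [
    "FitError",
    "FitConvergenceError",
    "IllConditionedError",
    "FitResult",
    "ModelSelection",
    "ReplicateSummary",
    "fit_two_state",
    "fit_three_state",
    "fit_thermal",
    "select_model",
    "aggregate_replicates",
]

_MIDPOINT_QUANTILES = (0.20, 0.35, 0.50, 0.65, 0.80)
_SSR_TIE = 1e-10
_SSR_FLOOR = 1e-300

# physical box bounds
_DG_MAX = 30.0
_M_MAX = 10.0
_DH_MAX = 1000.0


class FitError(RuntimeError):
    """Base class for fitting failures."""


class FitConvergenceError(FitError):
    """No optimizer start converged."""


class IllConditionedError(FitError):
    """The curve does not constrain a transition (all points on one baseline)."""


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and goodness metrics for one curve."""

    model: str
    params: TwoStateParams | ThreeStateParams | ThermalParams
    stderr: dict
    derived: dict  # name -> {"value": float, "stderr": float | None}
    residuals: np.ndarray
    ssr: float
    aicc: float
    n_starts_converged: int
    n_points: int
    n_varied: int
    warnings: list[str] = field(default_factory=list)
    probe: str | None = None
    replicate_id: str | None = None

    def to_dict(self) -> dict:
        """Flat key-value view, suitable for a TSV row or JSON record."""
        out = {"model": self.model, "probe": self.probe, "replicate": self.replicate_id}
        for name, value in dataclasses.asdict(self.params).items():
            out[name] = value
            if name in self.stderr:
                out[f"{name}_stderr"] = self.stderr[name]
        for name, rec in self.derived.items():
            out[name] = rec["value"]
            out[f"{name}_stderr"] = rec["stderr"]
        out.update(
            ssr=self.ssr,
            aicc=self.aicc,
            n_points=self.n_points,
            n_starts_converged=self.n_starts_converged,
            warnings=";".join(self.warnings),
        )
        return out


def aicc(ssr: float, n: int, n_varied: int, scale: float = 0.0) -> float:
    """Corrected Akaike score for a Gaussian SSR fit (+1 for the variance).

    ``scale`` (the data range) floors the SSR at numerical-noise level so
    that two fits which both interpolate the data to machine precision
    score as equally good rather than by meaningless residual rounding.
    """
    k = n_varied + 1
    ssr = max(ssr, n * (1e-9 * scale) ** 2, _SSR_FLOOR)
    aic = n * math.log(ssr / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / denom


def _line_baseline(x: np.ndarray, y: np.ndarray, idx: slice) -> tuple[float, float]:
    """Intercept and slope of a straight line through the selected points."""
    coeff = np.polyfit(x[idx], y[idx], 1)
    return float(coeff[1]), float(coeff[0])


def _check_conditioned(x: np.ndarray, y: np.ndarray, model_ssr: float) -> None:
    """Reject fits where the data contain no resolved transition.

    A curve with all points on one baseline (monotone drift, constant
    signal, a refolding branch stuck on the unfolded baseline) is
    explained by its linear trend alone: the unfolding model then only
    chases residual noise. The operational test is effect size — the
    model must cut the straight line's SSR by at least 20%. A real but
    poorly fitting transition (say, a double sigmoid under a single-
    transition model) clears this easily, while noise-chasing improves
    the line by roughly the parameter count over n and stays below it.
    """
    n = len(x)
    floor = n * (1e-9 * float(np.ptp(y))) ** 2
    ssr_line = max(
        float(np.sum((np.polyval(np.polyfit(x, y, 1), x) - y) ** 2)), floor
    )
    if max(model_ssr, floor) >= 0.8 * ssr_line:
        raise IllConditionedError(
            "transition not resolved: the unfolding model explains the curve "
            "no better than its linear drift (all points effectively on one "
            "baseline)"
        )


def _propagated_stderr(result, grad: dict) -> float | None:
    if result.covar is None:
        return None
    g = np.array([grad.get(name, 0.0) for name in result.var_names])
    var = float(g @ result.covar @ g)
    return math.sqrt(var) if var >= 0 else None


def _is_pinned(res) -> bool:
    """True when a varying parameter is slammed against its upper cap.

    Upper-cap pinning (cooperativity or stability at the physical
    ceiling) marks the degenerate step-function solutions; lower bounds
    are legitimate degenerate limits (zero stability, an ordering
    constraint active, a transition with no denaturant dependence) and
    are reported, not rejected.
    """
    for name in res.var_names:
        par = res.params[name]
        lo, hi = par.min, par.max
        if not np.isfinite(hi):
            continue
        tol = 1e-6 * ((hi - lo) if np.isfinite(lo) else abs(hi))
        if hi - par.value <= tol:
            return True
    return False


def _run_multistart(params_list, residual_fn):
    """Minimize from every start; return (best result, n_converged).

    Best SSR wins; ties within 1e-10 go to the start with smaller total
    stability (the least-stable reading of a degenerate optimum).
    """
    import warnings as _warnings

    best = None
    n_ok = 0
    for pars in params_list:
        try:
            with _warnings.catch_warnings():
                # a singular covariance during correlation bookkeeping is
                # routine for near-degenerate starts; stderr stays None
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(
                    residual_fn,
                    pars,
                    method="least_squares",
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                    max_nfev=20000,
                )
        except Exception:
            continue
        if not np.all(np.isfinite(res.residual)):
            continue
        n_ok += 1
        ssr = float(np.sum(res.residual**2))
        if (
            best is None
            or ssr < best[0] - _SSR_TIE
            or (abs(ssr - best[0]) <= _SSR_TIE and _total_dg(res) < _total_dg(best[1]))
        ):
            best = (ssr, res)
    if best is None:
        raise FitConvergenceError("no optimizer start converged")
    return best[1], n_ok


def _collect_multistart(params_list, residual_fn):
    """All converged starts as (ssr, result), best first."""
    import warnings as _warnings

    out = []
    for pars in params_list:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(
                    residual_fn,
                    pars,
                    method="least_squares",
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                    max_nfev=20000,
                )
        except Exception:
            continue
        if not np.all(np.isfinite(res.residual)):
            continue
        out.append((float(np.sum(res.residual**2)), res))
    out.sort(key=lambda t: (t[0], _total_dg(t[1])))
    return out


def _total_dg(res) -> float:
    v = res.params.valuesdict()
    return sum(v[k] for k in ("dg0", "dg_ni", "delta", "dh") if k in v)


def _prepare_chemical(curve: DenaturationCurve, min_points: int) -> DenaturationCurve:
    if curve.is_thermal:
        raise ValueError("chemical-denaturation fit requires a urea/gdnhcl curve")
    if len(curve) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(curve)}")
    return curve.sorted()


def fit_two_state(
    curve: DenaturationCurve,
    cond: Conditions = Conditions(),
    **opts,
) -> FitResult:
    """Fit the two-state LEM model to a chemical denaturation curve.

    Returns the parameters minimizing the SSR of
    :func:`lemfold.models.two_state_signal`, with the derived midpoint
    ``Dm = dG0/m`` and its propagated standard error.
    """
    curve = _prepare_chemical(curve, min_points=7)
    x, y = curve.x, curve.y
    a1, b1 = _line_baseline(x, y, slice(0, 3))
    c1, p1 = _line_baseline(x, y, slice(-3, None))

    def residual(pars):
        v = pars.valuesdict()
        p = TwoStateParams(
            dG0=v["dg0"], m=v["m"], a1=v["a1"], b1=v["b1"], c1=v["c1"], p1=v["p1"]
        )
        return two_state_signal(p, x, cond) - y

    span = (float(x[0]), float(x[-1]))
    starts = []
    for frac, m0 in [(q, 1.0) for q in _MIDPOINT_QUANTILES] + [
        (0.35, 2.5),
        (0.50, 2.5),
        (0.65, 2.5),
    ]:
        dm = span[0] + frac * (span[1] - span[0])
        pars = lmfit.Parameters()
        pars.add("dg0", value=min(max(m0 * dm, 1e-3), _DG_MAX), min=0.0, max=_DG_MAX)
        pars.add("m", value=m0, min=1e-6, max=_M_MAX)
        pars.add("a1", value=a1)
        pars.add("b1", value=b1)
        pars.add("c1", value=c1)
        pars.add("p1", value=p1)
        starts.append(pars)

    res, n_ok = _run_multistart(starts, residual)
    ssr = float(np.sum(res.residual**2))
    _check_conditioned(x, y, ssr)

    v = res.params.valuesdict()
    params = TwoStateParams(
        dG0=v["dg0"], m=v["m"], a1=v["a1"], b1=v["b1"], c1=v["c1"], p1=v["p1"]
    )
    warnings = ["solution pinned at a parameter bound"] if _is_pinned(res) else []
    stderr = {
        "dG0": res.params["dg0"].stderr,
        "m": res.params["m"].stderr,
        "a1": res.params["a1"].stderr,
        "b1": res.params["b1"].stderr,
        "c1": res.params["c1"].stderr,
        "p1": res.params["p1"].stderr,
    }
    dm = params.Dm
    dm_err = _propagated_stderr(
        res, {"dg0": 1.0 / params.m, "m": -params.dG0 / params.m**2}
    )
    return FitResult(
        model="two_state",
        params=params,
        stderr=stderr,
        derived={"Dm": {"value": dm, "stderr": dm_err}},
        residuals=res.residual.copy(),
        ssr=ssr,
        aicc=aicc(ssr, len(x), res.nvarys, float(np.ptp(y))),
        n_starts_converged=n_ok,
        n_points=len(x),
        n_varied=res.nvarys,
        warnings=warnings,
        probe=curve.probe,
        replicate_id=curve.replicate_id,
    )


def fit_three_state(
    curve: DenaturationCurve,
    cond: Conditions = Conditions(),
    **opts,
) -> FitResult:
    """Fit the three-state LEM model, keeping dG_NU0 >= dG_NI0.

    The ordering constraint is enforced by the reparameterization
    dG_NU0 = dG_NI0 + delta with delta >= 0; an optimum pinned at
    delta ~ 0 is returned with a boundary warning rather than rejected.

    The fit runs in two stages. First the baselines are held fixed at
    their drawn estimates and only the four thermodynamic parameters are
    optimized (multi-start); then all ten parameters are released for a
    local refinement. The refinement is kept only when it settles in the
    interior of the parameter box: the fully free double-sigmoid model
    has a degenerate ridge (both transitions driven to step functions
    while a free baseline tilts through the real transition) that can
    undercut the true basin's SSR at realistic noise, and those escapes
    end pinned against the cooperativity bound.
    """
    curve = _prepare_chemical(curve, min_points=11)
    x, y = curve.x, curve.y
    a1, b1 = _line_baseline(x, y, slice(0, 3))
    e1, g1 = _line_baseline(x, y, slice(-3, None))
    mid = slice(len(x) // 3, 2 * len(x) // 3)
    c1_init = float(np.median(y[mid]))

    def residual(pars):
        v = pars.valuesdict()
        p = ThreeStateParams(
            dG_NI0=v["dg_ni"],
            m_NI=v["m_ni"],
            dG_NU0=v["dg_ni"] + v["delta"],
            m_NU=v["m_nu"],
            a1=v["a1"],
            b1=v["b1"],
            c1=v["c1"],
            p1=v["p1"],
            e1=v["e1"],
            g1=v["g1"],
        )
        return three_state_signal(p, x, cond) - y

    span = (float(x[0]), float(x[-1]))

    def make_start(f_ni, f_nu, m_ni0, m_nu0, vary_baselines):
        dm_ni = span[0] + f_ni * (span[1] - span[0])
        dm_nu = span[0] + f_nu * (span[1] - span[0])
        dg_ni = min(max(m_ni0 * dm_ni, 1e-3), _DG_MAX)
        dg_nu = min(max(m_nu0 * dm_nu, 2e-3), _DG_MAX)
        pars = lmfit.Parameters()
        pars.add("dg_ni", value=dg_ni, min=0.0, max=_DG_MAX)
        pars.add("delta", value=max(dg_nu - dg_ni, 1e-3), min=0.0, max=_DG_MAX)
        pars.add("m_ni", value=m_ni0, min=1e-6, max=_M_MAX)
        pars.add("m_nu", value=m_nu0, min=1e-6, max=_M_MAX)
        pars.add("a1", value=a1, vary=vary_baselines)
        pars.add("b1", value=b1, vary=vary_baselines)
        pars.add("c1", value=c1_init, vary=vary_baselines)
        pars.add("p1", value=0.0, vary=vary_baselines)
        pars.add("e1", value=e1, vary=vary_baselines)
        pars.add("g1", value=g1, vary=vary_baselines)
        return pars

    # midpoint pairs from the quantile ladder, plus both orderings of which
    # transition sits at the lower concentration
    pair_starts = [
        (0.20, 0.50, 1.0, 1.5),
        (0.20, 0.65, 1.0, 1.5),
        (0.20, 0.80, 1.0, 1.5),
        (0.35, 0.65, 1.0, 1.5),
        (0.35, 0.80, 1.0, 1.5),
        (0.50, 0.80, 1.0, 1.5),
        (0.65, 0.20, 0.5, 2.5),
        (0.80, 0.35, 0.5, 2.5),
        (0.20, 0.50, 2.0, 3.0),
        (0.35, 0.65, 2.0, 3.0),
        (0.50, 0.80, 2.0, 3.0),
        (0.25, 0.70, 3.0, 4.5),
    ]
    stage1 = _collect_multistart(
        [make_start(*s, vary_baselines=False) for s in pair_starts], residual
    )
    if not stage1:
        raise FitConvergenceError("no optimizer start converged")
    n_ok = len(stage1)

    # stage 2: candidates with all ten parameters free — the quantile
    # multistart itself plus polishes of the leading fixed-baseline
    # basins. A free candidate is kept only when it stays off the
    # cooperativity/stability caps: solutions slammed against a cap model
    # step functions between grid points while a free baseline tilts
    # through the real transition (the degenerate ridge of the fully free
    # double sigmoid). If every free candidate is degenerate, the fixed-
    # baseline solution stands. (delta = 0, the ordering constraint,
    # stays a reportable boundary, not a rejection.)
    free_starts = [make_start(*s, vary_baselines=True) for s in pair_starts]
    for _, res1 in stage1[:3]:
        refine = lmfit.Parameters()
        for name, par in res1.params.items():
            refine.add(name, value=par.value, min=par.min, max=par.max, vary=True)
        free_starts.append(refine)
    free = [
        (ssr2, res2)
        for ssr2, res2 in _collect_multistart(free_starts, residual)
        if not _is_pinned(res2)
    ]

    # collapsed candidate: the model with the intermediate switched off
    # (delta = 0, flat N->I leg, S_I tied to S_U), i.e. an effective
    # two-state fit in three-state form with 6 free parameters. Overlapping
    # transitions let the full model absorb noise that the data do not
    # demand; comparing by AICc with each candidate's true parameter count
    # keeps an intermediate only where the curve supports one.
    collapsed_starts = []
    for frac, m0 in [(0.35, 1.0), (0.50, 1.0), (0.65, 1.0), (0.50, 2.5)]:
        dm = span[0] + frac * (span[1] - span[0])
        pars = lmfit.Parameters()
        pars.add("dg_ni", value=min(max(m0 * dm, 1e-3), _DG_MAX), min=0.0, max=_DG_MAX)
        pars.add("delta", value=0.0, vary=False)
        pars.add("m_ni", value=1e-6, vary=False)
        pars.add("m_nu", value=m0, min=1e-6, max=_M_MAX)
        pars.add("a1", value=a1)
        pars.add("b1", value=b1)
        pars.add("e1", value=e1)
        pars.add("g1", value=g1)
        pars.add("c1", expr="e1")
        pars.add("p1", expr="g1")
        collapsed_starts.append(pars)
    collapsed = [
        (ssr2, res2)
        for ssr2, res2 in _collect_multistart(collapsed_starts, residual)
        if not _is_pinned(res2)
    ]

    # candidates: (ssr, result, effective parameter count, label); the
    # fixed-baseline solution still charges ten (its baselines came from
    # the data), the collapsed one charges its six
    candidates = [(stage1[0][0], stage1[0][1], 10, "fixed")]
    if free:
        candidates.append((free[0][0], free[0][1], 10, "free"))
    if collapsed:
        candidates.append((collapsed[0][0], collapsed[0][1], 6, "collapsed"))
    scale = float(np.ptp(y))
    scored = [
        (aicc(ssr_c, len(x), k_c, scale), ssr_c, res_c, k_c, label)
        for ssr_c, res_c, k_c, label in candidates
    ]
    scored.sort(key=lambda t: t[0])
    # within the 2-unit support band, prefer the candidate with fewer
    # parameters (the least-intermediate reading the evidence allows)
    top = [t for t in scored if t[0] <= scored[0][0] + 2.0]
    top.sort(key=lambda t: (t[3], t[0]))
    _, ssr, res, n_eff, chosen = top[0]
    baselines_fixed = chosen == "fixed"
    collapsed_chosen = chosen == "collapsed"
    _check_conditioned(x, y, ssr)

    v = res.params.valuesdict()
    params = ThreeStateParams(
        dG_NI0=v["dg_ni"],
        m_NI=v["m_ni"],
        dG_NU0=v["dg_ni"] + v["delta"],
        m_NU=v["m_nu"],
        a1=v["a1"],
        b1=v["b1"],
        c1=v["c1"],
        p1=v["p1"],
        e1=v["e1"],
        g1=v["g1"],
    )
    warnings = []
    if v["delta"] < 1e-6:
        warnings.append("boundary: fitted dG_NU0 == dG_NI0 (ordering constraint active)")
    if baselines_fixed:
        warnings.append("baselines held at drawn estimates (free fit was degenerate)")
    if collapsed_chosen:
        warnings.append(
            "intermediate not supported by the data: collapsed to an effective "
            "two-state N->U transition"
        )
    if _is_pinned(res):
        warnings.append("solution pinned at a parameter bound")

    def err(name):
        return res.params[name].stderr

    dg_nu_err = _propagated_stderr(res, {"dg_ni": 1.0, "delta": 1.0})
    stderr = {
        "dG_NI0": err("dg_ni"),
        "dG_NU0": dg_nu_err,
        "m_NI": err("m_ni"),
        "m_NU": err("m_nu"),
        "a1": err("a1"),
        "b1": err("b1"),
        "c1": err("c1"),
        "p1": err("p1"),
        "e1": err("e1"),
        "g1": err("g1"),
    }
    derived = {
        "Dm_NI": {
            "value": params.Dm_NI,
            "stderr": _propagated_stderr(
                res,
                {"dg_ni": 1.0 / params.m_NI, "m_ni": -params.dG_NI0 / params.m_NI**2},
            ),
        },
        "Dm_NU": {
            "value": params.Dm_NU,
            "stderr": _propagated_stderr(
                res,
                {
                    "dg_ni": 1.0 / params.m_NU,
                    "delta": 1.0 / params.m_NU,
                    "m_nu": -params.dG_NU0 / params.m_NU**2,
                },
            ),
        },
        "dG_IU0": {"value": params.dG_IU0, "stderr": err("delta")},
        "m_IU": {
            "value": params.m_IU,
            "stderr": _propagated_stderr(res, {"m_nu": 1.0, "m_ni": -1.0}),
        },
    }
    return FitResult(
        model="three_state",
        params=params,
        stderr=stderr,
        derived=derived,
        residuals=res.residual.copy(),
        ssr=ssr,
        aicc=aicc(ssr, len(x), n_eff, float(np.ptp(y))),
        n_starts_converged=n_ok,
        n_points=len(x),
        n_varied=n_eff,
        warnings=warnings,
        probe=curve.probe,
        replicate_id=curve.replicate_id,
    )


def fit_thermal(curve: DenaturationCurve, **opts) -> FitResult:
    """Fit the van't Hoff two-state melt; the midpoint Tm is reported in degC.

    A fitted Tm outside the scanned temperature range is flagged in
    ``warnings``, not rejected.
    """
    if not curve.is_thermal:
        raise ValueError("thermal fit requires a temperature-perturbant curve")
    if len(curve) < 7:
        raise ValueError(f"need at least 7 points, got {len(curve)}")
    curve = curve.sorted()
    x, y = curve.x, curve.y
    a1, b1 = _line_baseline(x, y, slice(0, 3))
    c1, p1 = _line_baseline(x, y, slice(-3, None))

    def residual(pars):
        v = pars.valuesdict()
        p = ThermalParams(
            Tm=v["tm"], dH_vH=v["dh"], a1=v["a1"], b1=v["b1"], c1=v["c1"], p1=v["p1"]
        )
        return thermal_signal(p, x) - y

    span = (float(x[0]), float(x[-1]))
    starts = []
    for frac, dh0 in [(q, 50.0) for q in _MIDPOINT_QUANTILES] + [
        (0.35, 150.0),
        (0.50, 150.0),
        (0.65, 150.0),
    ]:
        pars = lmfit.Parameters()
        pars.add(
            "tm",
            value=span[0] + frac * (span[1] - span[0]),
            min=span[0] - 30.0,
            max=span[1] + 30.0,
        )
        pars.add("dh", value=dh0, min=1e-3, max=_DH_MAX)
        pars.add("a1", value=a1)
        pars.add("b1", value=b1)
        pars.add("c1", value=c1)
        pars.add("p1", value=p1)
        starts.append(pars)

    res, n_ok = _run_multistart(starts, residual)
    ssr = float(np.sum(res.residual**2))
    _check_conditioned(x, y, ssr)

    v = res.params.valuesdict()
    params = ThermalParams(
        Tm=v["tm"], dH_vH=v["dh"], a1=v["a1"], b1=v["b1"], c1=v["c1"], p1=v["p1"]
    )
    warnings = []
    if not (span[0] <= params.Tm <= span[1]):
        warnings.append("Tm outside scanned temperature range")
    if _is_pinned(res):
        warnings.append("solution pinned at a parameter bound")
    stderr = {
        "Tm": res.params["tm"].stderr,
        "dH_vH": res.params["dh"].stderr,
        "a1": res.params["a1"].stderr,
        "b1": res.params["b1"].stderr,
        "c1": res.params["c1"].stderr,
        "p1": res.params["p1"].stderr,
    }
    derived = {
        "Tm_C": {"value": kelvin_to_celsius(params.Tm), "stderr": res.params["tm"].stderr}
    }
    return FitResult(
        model="thermal",
        params=params,
        stderr=stderr,
        derived=derived,
        residuals=res.residual.copy(),
        ssr=ssr,
        aicc=aicc(ssr, len(x), res.nvarys, float(np.ptp(y))),
        n_starts_converged=n_ok,
        n_points=len(x),
        n_varied=res.nvarys,
        warnings=warnings,
        probe=curve.probe,
        replicate_id=curve.replicate_id,
    )


@dataclass
class ModelSelection:
    """Two- vs three-state comparison for one curve."""

    two_state: FitResult | None
    three_state: FitResult | None
    recommended: str | None
    delta_aicc: float | None
    ambiguous: bool
    errors: dict = field(default_factory=dict)


def select_model(curve: DenaturationCurve, cond: Conditions = Conditions()) -> ModelSelection:
    """Fit both chemical models and recommend the lower-AICc one.

    A difference below 2 AICc units is flagged as ambiguous (the lower
    score is still reported as recommended). If either fit fails, no
    recommendation is made and the failure message is recorded.
    """
    if len(curve) < 11:
        raise ValueError(
            f"insufficient points for three-state comparison: need >= 11, got {len(curve)}"
        )
    results: dict = {}
    errors: dict = {}
    for name, fn in (("two_state", fit_two_state), ("three_state", fit_three_state)):
        try:
            results[name] = fn(curve, cond)
        except (FitError, ValueError) as exc:
            results[name] = None
            errors[name] = str(exc)
    r2, r3 = results["two_state"], results["three_state"]
    if r2 is None or r3 is None:
        return ModelSelection(r2, r3, None, None, False, errors)
    delta = r3.aicc - r2.aicc
    if any("collapsed" in w for w in r3.warnings):
        # the three-state fit itself found no supportable intermediate
        return ModelSelection(r2, r3, "two_state", abs(delta), False, errors)
    recommended = "two_state" if delta >= 0 else "three_state"
    return ModelSelection(r2, r3, recommended, abs(delta), abs(delta) < 2.0, errors)


@dataclass
class ReplicateSummary:
    """Per-parameter mean and SEM across replicate fits of one model."""

    model: str
    n_replicates: int
    mean: dict
    sem: dict | None  # None when a single replicate makes SEM unavailable

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, mu in self.mean.items():
            rows.append(
                {
                    "parameter": name,
                    "mean": mu,
                    "sem": self.sem[name] if self.sem is not None else np.nan,
                    "n": self.n_replicates,
                }
            )
        return pd.DataFrame(rows)


def _flat_values(result: FitResult) -> dict:
    out = dict(dataclasses.asdict(result.params))
    for name, rec in result.derived.items():
        out[name] = rec["value"]
    return out


def aggregate_replicates(results: list[FitResult]) -> ReplicateSummary:
    """Mean and SEM (sample SD / sqrt(n)) of parameters across replicate fits.

    All results must come from the same model; a single result returns its
    values with SEM unavailable.
    """
    if not results:
        raise ValueError("no fit results to aggregate")
    models = {r.model for r in results}
    if len(models) > 1:
        raise ValueError(f"cannot aggregate mixed models: {sorted(models)}")
    values = [_flat_values(r) for r in results]
    keys = values[0].keys()
    n = len(values)
    mean = {k: float(np.mean([v[k] for v in values])) for k in keys}
    sem = None
    if n >= 2:
        sem = {
            k: float(np.std([v[k] for v in values], ddof=1) / math.sqrt(n)) for k in keys
        }
    return ReplicateSummary(model=results[0].model, n_replicates=n, mean=mean, sem=sem)
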