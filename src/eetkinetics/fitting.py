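"""Parameter estimation: trace fitting and Butler-Volmer analysis.

Two fits are provided, mirroring how the chronoamperometry data are
analysed:

* :func:`fit_trace` — Nelder-Mead minimization of the squared current
  residual over the six model constants (k_Ac, k_Omc, k_i^bef, k_i^aft,
  IM_total, Omc_total).  The constants span several orders of magnitude
  and are all positive, so the simplex runs in log-parameter space.
* :func:`fit_butler_volmer` — least-squares fit of the anodic
  Butler-Volmer expression to extracted (potential, k_i) pairs.

Butler-Volmer identifiability
-----------------------------
The anodic expression can be rewritten ``k_i = A·exp(B·E)`` with
``A = k0·exp(−B·E0)`` and ``B = (1−α)nF/RT``: only the pair (A, B) is
determined by rate-vs-potential data, and every (k0, α, E0) triple on the
one-dimensional family with the same (A, B) fits identically.  α is
therefore robustly identified while the reported (k0, E0) depend on where
along the family the optimizer lands, i.e. on the starting point.  The
default start is built from the data (slope from the two largest rates)
with E0 anchored at −0.212 V vs SHE, the formal potential of OmcS — the
cytochrome expected to set the interfacial couple in *G. sulfurreducens*
anodes.  Pass ``fixed={"e0": ...}`` to pin the gauge explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    ButlerVolmerParameters,
    FARADAY,
    GAS_CONSTANT,
    ModelParameters,
    OmcSModelParameters,
    RedoxState,
    Variant,
)
from .protocol import Protocol, TraceSeries, run_protocol

__all__ = ["FitResult", "fit_trace", "fit_butler_volmer", "OMCS_E0_PRIOR"]

#: Formal potential of OmcS (V vs SHE); default gauge anchor for the
#: Butler-Volmer fit.
OMCS_E0_PRIOR = -0.212

#: Names of the six fitted trace constants, in optimizer order.
TRACE_PARAM_NAMES = (
    "k_ac",
    "k_omc",
    "k_i_before",
    "k_i_after",
    "im_total",
    "omc_total",
)


@dataclass
class FitResult:
    """Outcome of a fit: best parameters, objective and diagnostics."""

    parameters: ModelParameters | ButlerVolmerParameters
    objective: float
    n_iterations: int
    converged: bool
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


def _simulate_current(
    params: ModelParameters,
    variant: Variant,
    protocol: Protocol,
    init,
    rtol: float,
    atol: float,
) -> np.ndarray:
    trace = run_protocol(
        params, variant=variant, protocol=protocol, init=init, rtol=rtol, atol=atol
    )
    return trace.current


def _protocol_from_trace(observed: TraceSeries) -> Protocol:
    t_switch = observed.meta.get("t_switch")
    if t_switch is None:
        raise ValueError(
            "observed trace must carry 't_switch' in meta to be fitted"
        )
    dt = observed.dt
    t_end = float(observed.time[-1])
    return Protocol(
        e_before=observed.meta.get("e_before", np.nan),
        e_after=observed.meta.get("e_after", np.nan),
        t_hold_before=float(t_switch),
        t_hold_after=t_end - float(t_switch),
        sample_rate=1.0 / dt,
    )


def _huber(r: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(r)
    return np.where(a <= delta, 0.5 * r**2, delta * (a - 0.5 * delta))


def fit_trace(
    observed: TraceSeries,
    variant: Variant = "wt",
    initial_guess: ModelParameters | None = None,
    fixed: Sequence[str] = (),
    init: RedoxState | Literal["steady"] = "steady",
    loss: Literal["sse", "huber"] = "sse",
    huber_delta: float = 1.0,
    max_iter: int = 5000,
    xatol: float = 1e-10,
    fatol: float = 1e-10,
    n_starts: int = 1,
    seed: int | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Fit the six model constants to an observed current trace.

    Deterministic given identical inputs and starting point.  ``fixed``
    names constants held at their initial-guess values.  ``n_starts > 1``
    adds seeded multiplicative jitters of the starting point (useful for
    noisy data); the best objective wins.  Non-convergence is reported via
    ``FitResult.converged``, never raised.
    """
    if initial_guess is None:
        raise ValueError("an initial guess is required")
    if observed.current.size < 10:
        raise ValueError("observed trace too short to fit")
    protocol = _protocol_from_trace(observed)
    if float(np.ptp(observed.current)) < 1e-12 * max(
        1.0, float(np.abs(observed.current).max())
    ):
        warnings.warn(
            "observed current is (near-)constant: the six constants are "
            "not identifiable from this trace",
            stacklevel=2,
        )

    unknown = [n for n in fixed if n not in TRACE_PARAM_NAMES]
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {unknown}")
    free = [n for n in TRACE_PARAM_NAMES if n not in fixed]
    i_obs = observed.current

    def build(theta_log: np.ndarray) -> ModelParameters:
        values = dict(zip(free, np.exp(theta_log)))
        return initial_guess.with_(**values)

    def objective(theta_log: np.ndarray) -> float:
        try:
            i_model = _simulate_current(
                build(theta_log), variant, protocol, init, rtol, atol
            )
        except Exception:
            return 1e30  # infeasible corner of log-parameter space
        r = i_model - i_obs
        if loss == "huber":
            return float(np.sum(_huber(r, huber_delta)))
        return float(np.dot(r, r))

    x0 = np.log([getattr(initial_guess, n) for n in free])
    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [
            x0 + rng.normal(0.0, 0.2, size=x0.size) for _ in range(n_starts - 1)
        ]

    best = None
    for start in starts:
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options=dict(
                xatol=xatol, fatol=fatol, maxiter=max_iter, maxfev=4 * max_iter
            ),
        )
        if best is None or res.fun < best.fun:
            best = res

    params = build(best.x)
    i_model = _simulate_current(params, variant, protocol, init, rtol, atol)
    return FitResult(
        parameters=params,
        objective=float(best.fun),
        n_iterations=int(best.nit),
        converged=bool(best.success),
        residuals=i_model - i_obs,
    )


def _bv_default_start(
    e: np.ndarray, k: np.ndarray, n: float, temperature: float, e0_prior: float
) -> tuple[float, float, float]:
    """Data-driven start: exponential slope from the two largest rates
    (which dominate the linear-scale objective), amplitude through the
    largest, E0 at the OmcS prior."""
    order = np.argsort(k)
    (e1, k1), (e2, k2) = (e[order[-2]], k[order[-2]]), (e[order[-1]], k[order[-1]])
    f = n * FARADAY / (GAS_CONSTANT * temperature)
    if e2 == e1 or k1 <= 0:
        slope_b = 0.5 * f
    else:
        slope_b = np.log(k2 / k1) / (e2 - e1)
    slope_b = float(np.clip(slope_b, 1e-6, f * (1 - 1e-6)))
    amp_a = k2 / np.exp(slope_b * e2)
    alpha0 = 1.0 - slope_b / f
    k00 = amp_a * np.exp(slope_b * e0_prior)
    return float(k00), float(alpha0), float(e0_prior)


def fit_butler_volmer(
    points: Sequence[tuple[float, float]],
    n: float = 1.0,
    temperature: float = 298.15,
    log_scale: bool = False,
    x0: tuple[float, float, float] | None = None,
    fixed: Optional[dict[str, float]] = None,
    e0_prior: float = OMCS_E0_PRIOR,
    max_iter: int = 5000,
) -> FitResult:
    """Fit (k0, α, E0) of the anodic Butler-Volmer expression to
    (potential, rate) pairs.

    Default objective is the sum of squared residuals on the linear rate
    scale, which lets the large high-overpotential rates dominate;
    ``log_scale=True`` weights all decades equally instead.  See the
    module docstring for the identifiability caveat; ``fixed`` may pin any
    of ``k0``, ``alpha``, ``e0``.
    """
    pts = [(float(e), float(k)) for e, k in points]
    if len(pts) < 3 - len(fixed or {}):
        raise ValueError(
            f"under-determined: {len(pts)} points for "
            f"{3 - len(fixed or {})} free parameters"
        )
    e = np.array([p[0] for p in pts])
    k = np.array([p[1] for p in pts])
    if np.any(k <= 0):
        raise ValueError("all rate constants must be > 0")

    fixed = dict(fixed or {})
    f = n * FARADAY / (GAS_CONSTANT * temperature)
    if x0 is None:
        x0 = _bv_default_start(e, k, n, temperature, e0_prior)
    start_full = dict(zip(("k0", "alpha", "e0"), x0))
    start_full.update(fixed)
    free = [name for name in ("k0", "alpha", "e0") if name not in fixed]

    def unpack(theta: np.ndarray) -> tuple[float, float, float]:
        vals = dict(fixed)
        vals.update(dict(zip(free, theta)))
        return vals["k0"], vals["alpha"], vals["e0"]

    target = np.log(k) if log_scale else k

    def objective(theta: np.ndarray) -> float:
        k0, alpha, e0 = unpack(theta)
        if k0 <= 0 or not 0.0 <= alpha <= 1.0:
            return 1e30
        pred = k0 * np.exp((1.0 - alpha) * f * (e - e0))
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return 1e30
        r = (np.log(pred) if log_scale else pred) - target
        return float(np.dot(r, r))

    theta0 = np.array([start_full[name] for name in free])
    res = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-10, maxiter=max_iter, maxfev=4 * max_iter),
    )
    k0, alpha, e0 = unpack(res.x)
    bv = ButlerVolmerParameters(
        k0=k0, alpha=alpha, e0=e0, n=n, temperature=temperature
    )
    pred = k0 * np.exp((1.0 - alpha) * f * (e - e0))
    residuals = (np.log(pred) - np.log(k)) if log_scale else (pred - k)
    return FitResult(
        parameters=bv,
        objective=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        residuals=residuals,
    )
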