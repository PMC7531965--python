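"""Core reaction kinetics of biofilm extracellular electron transfer.

The model lumps the redox carriers of a *Geobacter sulfurreducens* biofilm
into two pools: an intracellular mediator pool (IM) reduced by acetate
metabolism, and an outer-membrane cytochrome pool (Omc) that receives
electrons from IM and discharges them to the anode.  Because conduction
through the biofilm is much faster than either interfacial transfer or
IM→Omc transfer, the spatially resolved cytochrome populations collapse
into the single Omc pool used here.

Wild-type rate equations (amounts in nmol, time in s)::

    d[IM_red]/dt  = k_Ac [IM_ox] - k_Omc [IM_red][Omc_ox]
    d[Omc_red]/dt = k_Omc [IM_red][Omc_ox] - k_i [Omc_red]

with conservation [IM_ox] = IM_total - IM_red and
[Omc_ox] = Omc_total - Omc_red.  The interfacial constant ``k_i`` depends
on the poised anode potential through the anodic branch of the
Butler-Volmer expression and is stepped between a "before" and an "after"
value in the two-step chronoamperometry protocol (see
:mod:`eetkinetics.protocol`).

The ΔOmcS deletion mutant is modelled by replacing the bimolecular IM→Omc
transfer with a saturating (pseudo-zero-order) logistic flux; see
:func:`omcs_rhs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "ModelParameters",
    "OmcSModelParameters",
    "RedoxState",
    "ButlerVolmerParameters",
    "butler_volmer_rate",
    "wt_rhs",
    "omcs_rhs",
    "logistic_transfer_flux",
    "current_density",
    "steady_state",
    "derived_rates",
    "SteadyStateError",
]

#: Faraday constant, C·mol⁻¹.
FARADAY = 96485.3
#: Molar gas constant, C·V·K⁻¹·mol⁻¹.
GAS_CONSTANT = 8.314

#: Clamp for logistic exponents to keep ``exp`` finite.
_EXP_CLAMP = 500.0

Variant = Literal["wt", "omcs"]


class SteadyStateError(RuntimeError):
    """Raised when the steady-state solver cannot certify a fixed point."""


@dataclass(frozen=True)
class ModelParameters:
    """The six fitted rate/pool constants plus protocol geometry.

    Parameters
    ----------
    k_ac : float
        First-order acetate-driven IM reduction rate constant, s⁻¹.
    k_omc : float
        Second-order IM→Omc transfer rate constant, nmol⁻¹·s⁻¹.
    k_i_before, k_i_after : float
        Interfacial discharge rate constants before/after the potential
        step, s⁻¹.
    im_total, omc_total : float
        Total mediator pool sizes, nmol.
    t_switch : float
        Time of the potential step, s.
    electrode_area : float
        Exposed anode area, m².
    electrons_per_acetate : float
        Electrons liberated per acetate oxidized (8 for complete
        oxidation to CO₂).
    """

    k_ac: float
    k_omc: float
    k_i_before: float
    k_i_after: float
    im_total: float
    omc_total: float
    t_switch: float = 60.0
    electrode_area: float = 3.3e-3
    electrons_per_acetate: float = 8.0

    def __post_init__(self) -> None:
        for name in ("k_ac", "k_omc", "k_i_before", "k_i_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.im_total <= 0 or self.omc_total <= 0:
            raise ValueError("pool totals must be > 0")
        if self.electrode_area <= 0:
            raise ValueError("electrode_area must be > 0")
        if not np.isfinite(self.t_switch):
            raise ValueError("t_switch must be finite")

    def k_i_at(self, t: float) -> float:
        """Piecewise-constant interfacial rate: before the step for
        ``t < t_switch``, after for ``t >= t_switch``."""
        return self.k_i_before if t < self.t_switch else self.k_i_after

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class OmcSModelParameters(ModelParameters):
    """Parameters of the ΔOmcS (OmcS-deletion) model variant.

    In this variant ``k_omc`` is a saturating transfer *flux* in nmol·s⁻¹
    (not a bimolecular constant): the IM→Omc transfer is pseudo-zero-order
    in both pools, throttled by a logistic gate in IM_red centred at
    ``theta`` with scale ``s``.
    """

    theta: float = 1500.0
    s: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")


@dataclass(frozen=True)
class RedoxState:
    """Instantaneous reduced amounts of the two mediator pools (nmol)."""

    im_red: float
    omc_red: float

    def validate(self, p: ModelParameters, tol: float = 1e-9) -> None:
        """Check conservation bounds against the pool totals."""
        if not (-tol <= self.im_red <= p.im_total + tol):
            raise ValueError(
                f"IM_red={self.im_red} outside [0, {p.im_total}]"
            )
        if not (-tol <= self.omc_red <= p.omc_total + tol):
            raise ValueError(
                f"Omc_red={self.omc_red} outside [0, {p.omc_total}]"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.im_red, self.omc_red], dtype=float)


@dataclass(frozen=True)
class ButlerVolmerParameters:
    """Anodic Butler-Volmer parameters for the interfacial rate constant.

    ``k_i(E) = k0 · exp[(1−α)·nF/(RT)·(E − E0)]`` with the formal
    potential ``E0`` in V vs SHE.
    """

    k0: float
    alpha: float
    e0: float
    n: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be within [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def exponential_slope(self) -> float:
        """Slope of ln k_i vs E: (1−α)·nF/(RT), V⁻¹."""
        return (
            (1.0 - self.alpha)
            * self.n
            * FARADAY
            / (GAS_CONSTANT * self.temperature)
        )


def butler_volmer_rate(bv: ButlerVolmerParameters, e: float) -> float:
    """Anodic interfacial rate constant at poised potential ``e`` (V vs SHE).

    Strictly increasing in ``e`` for ``alpha < 1``; equals ``k0`` at
    ``e = e0``.  Raises ``ValueError`` on non-finite input or overflow.
    """
    e = float(e)
    if not np.isfinite(e):
        raise ValueError("potential must be finite")
    with np.errstate(over="ignore"):
        rate = bv.k0 * np.exp(bv.exponential_slope * (e - bv.e0))
    if not np.isfinite(rate):
        raise ValueError(f"Butler-Volmer rate overflowed at E={e} V")
    return float(rate)


def _split(state) -> tuple[float, float]:
    if isinstance(state, RedoxState):
        return state.im_red, state.omc_red
    im_red, omc_red = state
    return float(im_red), float(omc_red)


def wt_rhs(state, p: ModelParameters, k_i: float) -> tuple[float, float]:
    """Time derivatives (d IM_red/dt, d Omc_red/dt) of the wild-type model.

    ``state`` may be a :class:`RedoxState` or an (im_red, omc_red) pair;
    negative pools are rejected.
    """
    im_red, omc_red = _split(state)
    if im_red < 0 or omc_red < 0:
        raise ValueError(f"negative pool amounts: IM_red={im_red}, Omc_red={omc_red}")
    transfer = p.k_omc * im_red * (p.omc_total - omc_red)
    d_im = p.k_ac * (p.im_total - im_red) - transfer
    d_omc = transfer - k_i * omc_red
    return d_im, d_omc


def logistic_transfer_flux(im_red: float, p: OmcSModelParameters) -> float:
    """Ungated saturating IM→Omc flux of the ΔOmcS variant, nmol·s⁻¹.

    φ(IM_red) = k_omc / (1 + exp(−(IM_red − θ)/s)); the exponent is
    clamped so extreme arguments saturate instead of overflowing.
    """
    z = -(float(im_red) - p.theta) / p.s
    z = float(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP))
    return p.k_omc / (1.0 + np.exp(z))


def omcs_rhs(
    state,
    p: OmcSModelParameters,
    k_i: float,
    gate_omc: bool = True,
) -> tuple[float, float]:
    """Time derivatives of the ΔOmcS variant.

    The same saturating flux leaves IM_red and enters Omc_red, so
    electrons are conserved between the two pools.  By default the flux
    carries an acceptor-availability factor Omc_ox/Omc_total (``gate_omc``)
    so that a fully reduced Omc pool cannot be reduced further; the factor
    is ≈1 in the oxidized post-step regime where the pseudo-zero-order
    form was introduced.
    """
    im_red, omc_red = _split(state)
    if im_red < 0 or omc_red < 0:
        raise ValueError(f"negative pool amounts: IM_red={im_red}, Omc_red={omc_red}")
    flux = logistic_transfer_flux(im_red, p)
    if gate_omc:
        flux *= max(p.omc_total - omc_red, 0.0) / p.omc_total
    d_im = p.k_ac * (p.im_total - im_red) - flux
    d_omc = flux - k_i * omc_red
    return d_im, d_omc


def rhs_for(variant: Variant):
    """Return the rate function for a model variant name."""
    if variant == "wt":
        return wt_rhs
    if variant == "omcs":
        return omcs_rhs
    raise ValueError(f"unknown variant {variant!r} (expected 'wt' or 'omcs')")


def current_density(state, k_i: float, p: ModelParameters) -> float:
    """Anodic current density i = F·k_i·[Omc_red]·10⁻⁹ / A, in A·m⁻².

    The single nmol→mol conversion of the model lives here.
    """
    if p.electrode_area <= 0:
        raise ValueError("electrode_area must be > 0")
    _, omc_red = _split(state)
    return FARADAY * k_i * omc_red * 1e-9 / p.electrode_area


def steady_state(
    p: ModelParameters,
    k_i: float,
    variant: Variant = "wt",
    tol: float = 1e-9,
) -> RedoxState:
    """Solve the fixed point of the rate equations at a fixed ``k_i``.

    The 2-D root problem is reduced to a bracketed 1-D problem in IM_red
    by eliminating Omc_red through the Omc balance, then solved with
    Brent's method.  The result is certified by evaluating the full
    right-hand side; failure raises :class:`SteadyStateError` with
    diagnostics rather than returning a silently wrong state.
    """
    if k_i <= 0:
        raise ValueError("steady_state requires k_i > 0")
    if p.k_ac == 0.0:
        return RedoxState(0.0, 0.0)

    if variant == "wt":
        def omc_of_im(x: float) -> float:
            # k_Omc·x·(Omc_tot − y) = k_i·y  →  y = k_Omc·x·Omc_tot/(k_i + k_Omc·x)
            return p.k_omc * x * p.omc_total / (k_i + p.k_omc * x)
    elif variant == "omcs":
        def omc_of_im(x: float) -> float:
            # gated flux balance: φ(x)·(1 − y/Omc_tot) = k_i·y
            phi = logistic_transfer_flux(x, p)
            return phi * p.omc_total / (k_i * p.omc_total + phi)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    def im_balance(x: float) -> float:
        # at the fixed point the acetate supply equals the discharge flux
        return p.k_ac * (p.im_total - x) - k_i * omc_of_im(x)

    lo, hi = 0.0, p.im_total
    f_lo, f_hi = im_balance(lo), im_balance(hi)
    if f_lo == 0.0:
        im_red = lo
    elif f_hi == 0.0:
        im_red = hi
    elif f_lo * f_hi > 0:
        raise SteadyStateError(
            f"no sign change of the IM balance on [0, {p.im_total}] "
            f"(f(0)={f_lo:.3g}, f(IM_tot)={f_hi:.3g}); variant={variant}, k_i={k_i}"
        )
    else:
        im_red = brentq(im_balance, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    state = RedoxState(float(im_red), float(omc_of_im(im_red)))

    rhs = rhs_for(variant)
    residual = np.abs(np.asarray(rhs(state, p, k_i)))
    scale = max(p.k_ac * p.im_total, k_i * p.omc_total, 1.0)
    if residual.max() > tol * scale:
        raise SteadyStateError(
            f"steady-state residual {residual.max():.3g} exceeds "
            f"{tol * scale:.3g} (variant={variant}, k_i={k_i})"
        )
    return state


def derived_rates(
    state,
    d_state,
    p: ModelParameters,
    k_i: float,
) -> dict[str, float]:
    """Metabolic rates implied by an instantaneous model state.

    Returns a dict (all nmol·s⁻¹ except ``acetate_mol`` which is nmol of
    acetate per second):

    - ``omc_oxidation`` — electron flux into the electrode, k_i·Omc_red;
    - ``im_oxidation`` — net IM_red oxidation rate, −d IM_red/dt;
    - ``acetate_e`` — acetate-derived electron supply, k_Ac·IM_ox;
    - ``acetate_mol`` — acetate consumption, acetate_e / electrons-per-acetate;
    - ``nadh`` — NADH turnover, im_oxidation + acetate_e (for the
      wild-type model this equals the IM→Omc transfer flux identically).
    """
    im_red, omc_red = _split(state)
    d_im, _ = _split(d_state)
    acetate_e = p.k_ac * (p.im_total - im_red)
    im_oxidation = -d_im
    return {
        "omc_oxidation": k_i * omc_red,
        "im_oxidation": im_oxidation,
        "acetate_e": acetate_e,
        "acetate_mol": acetate_e / p.electrons_per_acetate,
        "nadh": im_oxidation + acetate_e,
    }
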