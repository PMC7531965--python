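"""Seeded synthetic potentiostat and spectrometer output.

Emulates the raw data the pipeline consumes so that every stage is
testable end-to-end: 10 Hz chronoamperometry traces with multiplicative
and additive Gaussian noise plus an optional brief negative artifact
spike at the potential step (the measured traces show a ~0.3 s, 3-sample
excursion reaching −12 A/m² that is not kinetic in origin), and Raman
spectral series with a Gaussian 747 cm⁻¹ band whose area follows the
modelled reduced-mediator total on a slowly drifting linear baseline with
shot-like noise, sampled every ~5 s (1 s integration × 5 accumulations).

All randomness flows from one ``numpy.random.Generator`` seeded through
:class:`NoiseModel`; identical seeds and parameters give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Optional

import numpy as np

from .model_core import ModelParameters, RedoxState, Variant
from .protocol import Protocol, TraceSeries, reduced_total, run_protocol
from .raman import SpectrumSeries

__all__ = ["NoiseModel", "generate_trace", "generate_spectra"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise and artifact structure of the synthetic instruments.

    ``current_sigma`` is the multiplicative Gaussian fraction on the
    current; ``current_floor`` an additive Gaussian sigma in A·m⁻²;
    ``spike`` an optional (amplitude A·m⁻², n_samples) additive artifact
    placed at the potential step; ``raman_shot_sigma`` per-channel
    Gaussian counts; ``baseline_drift`` in counts per cm⁻¹ per s.
    """

    current_sigma: float = 0.01
    current_floor: float = 0.002
    spike: Optional[tuple[float, int]] = None
    raman_shot_sigma: float = 2.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sigma < 0 or self.current_floor < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.raman_shot_sigma < 0:
            raise ValueError("raman_shot_sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_trace(
    p: ModelParameters,
    variant: Variant = "wt",
    protocol: Optional[Protocol] = None,
    noise: NoiseModel = NoiseModel(),
    init: RedoxState | Literal["steady"] = "steady",
) -> TraceSeries:
    """Simulate the protocol and overlay instrument noise on the current.

    The noiseless state channels are kept (they are the ground truth for
    recovery studies) and the generating constants are recorded in
    ``meta["truth"]``.
    """
    clean = run_protocol(p, variant=variant, protocol=protocol, init=init)
    rng = noise.rng()
    current = clean.current * (
        1.0 + rng.normal(0.0, noise.current_sigma, size=clean.current.size)
    )
    if noise.current_floor > 0:
        current = current + rng.normal(0.0, noise.current_floor, size=current.size)
    if noise.spike is not None:
        amplitude, n_samples = noise.spike
        start = int(np.searchsorted(clean.time, clean.meta["t_switch"]))
        current[start : start + int(n_samples)] += amplitude

    meta = dict(clean.meta)
    meta["truth"] = {
        name: getattr(p, name)
        for name in (
            "k_ac",
            "k_omc",
            "k_i_before",
            "k_i_after",
            "im_total",
            "omc_total",
        )
    }
    meta["noise"] = asdict(noise)
    return TraceSeries(
        time=clean.time,
        current=current,
        im_red=clean.im_red,
        omc_red=clean.omc_red,
        meta=meta,
    )


def _band_profile(
    wavenumber: np.ndarray,
    center: float,
    width: float,
    shape: Literal["gaussian", "lorentzian"],
) -> np.ndarray:
    """Unit-area line profile on the wavenumber grid."""
    x = wavenumber - center
    if shape == "gaussian":
        return np.exp(-0.5 * (x / width) ** 2) / (width * np.sqrt(2.0 * np.pi))
    if shape == "lorentzian":
        return (width / np.pi) / (x**2 + width**2)
    raise ValueError(f"unknown band shape {shape!r}")


def generate_spectra(
    time: np.ndarray,
    reduced: np.ndarray,
    gain: float = 0.05,
    floor: float = 20.0,
    center: float = 747.0,
    width: float = 4.0,
    shape: Literal["gaussian", "lorentzian"] = "gaussian",
    cadence: float = 5.0,
    grid: tuple[float, float, float] = (400.0, 1800.0, 1.0),
    baseline_level: float = 50.0,
    noise: NoiseModel = NoiseModel(),
) -> SpectrumSeries:
    """Emit a Raman spectral series tracking a reduced-mediator time series.

    Per timepoint (every ``cadence`` s across the span of ``time``) the
    band area is ``gain·reduced(t) + floor`` — the floor is the residual
    scattering of the oxidized-state hemes — placed on a linear baseline
    that may drift with time, plus per-channel Gaussian shot-like noise.
    """
    if gain < 0 or width <= 0:
        raise ValueError("gain must be >= 0 and width > 0")
    time = np.asarray(time, dtype=float)
    reduced = np.asarray(reduced, dtype=float)
    lo, hi, step = grid
    wavenumber = np.arange(lo, hi + step / 2, step)
    timestamps = np.arange(time[0], time[-1] + 1e-9, cadence)
    areas = gain * np.interp(timestamps, time, reduced) + floor

    profile = _band_profile(wavenumber, center, width, shape)
    # gentle linear baseline in wavenumber, optionally drifting in time
    base_slope = -baseline_level / (wavenumber[-1] - wavenumber[0])
    rng = noise.rng()
    intensities = np.empty((timestamps.size, wavenumber.size))
    for j, (t, area) in enumerate(zip(timestamps, areas)):
        baseline = (
            baseline_level
            + base_slope * (wavenumber - wavenumber[0])
            + noise.baseline_drift * t * (wavenumber - wavenumber[0]) / wavenumber[-1]
        )
        row = area * profile + baseline
        if noise.raman_shot_sigma > 0:
            row = row + rng.normal(0.0, noise.raman_shot_sigma, size=row.size)
        intensities[j] = row
    return SpectrumSeries(
        wavenumber=wavenumber, intensities=intensities, timestamps=timestamps
    )
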