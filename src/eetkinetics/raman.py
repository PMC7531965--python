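"""Resonance Raman peak tracking of the cytochrome redox state.

Reduced *c*-type cytochrome hemes scatter far more strongly than oxidized
ones, so the area of the 747 cm⁻¹ band — the most intense of the heme
bands (747, 1131, 1317, 1587 cm⁻¹) — tracks the total amount of reduced
mediator in the probed spot.  The band is integrated over a fixed
22 cm⁻¹ window above a linear baseline anchored at the window edges;
series are normalized by their area under the curve over time because a
single laser spot cannot be compared to the whole biofilm in absolute
terms.  The modelled reduced-mediator total is then aligned to the
normalized series by a single empirical scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumSeries",
    "PeakSeries",
    "integrate_peak",
    "peak_series",
    "normalize_series",
    "align_model",
]

#: Centre of the reduced-cytochrome marker band, cm⁻¹.
DEFAULT_CENTER = 747.0
#: Full integration window around the band, cm⁻¹.
DEFAULT_WINDOW = 22.0
#: Points per side used for the median baseline anchors.
_ANCHOR_POINTS = 3


@dataclass
class SpectrumSeries:
    """Per-timepoint spectra on a shared, strictly increasing wavenumber grid."""

    wavenumber: np.ndarray
    intensities: np.ndarray  # shape (n_timepoints, n_wavenumbers)
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.intensities.shape != (self.timestamps.size, self.wavenumber.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{self.timestamps.size} timepoints x {self.wavenumber.size} channels"
            )
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")


@dataclass
class PeakSeries:
    """Integrated band area per timepoint, optionally AUC-normalized."""

    timestamps: np.ndarray
    area: np.ndarray
    normalized_area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.timestamps.shape != self.area.shape:
            raise ValueError("timestamps/area length mismatch")
        if np.any(self.area < 0):
            raise ValueError("areas must be >= 0")


def integrate_peak(
    wavenumber: np.ndarray,
    intensity: np.ndarray,
    center: float = DEFAULT_CENTER,
    window: float = DEFAULT_WINDOW,
) -> float:
    """Baseline-subtracted trapezoidal area of one band in one spectrum.

    A linear baseline is drawn between the two window edges, each anchored
    at the median of the nearest ``_ANCHOR_POINTS`` samples just outside
    the window; post-baseline intensity is clipped at zero before the
    trapezoid.  The area is invariant under any added constant or linear
    ramp by construction.
    """
    wavenumber = np.asarray(wavenumber, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    lo, hi = center - window / 2.0, center + window / 2.0
    if lo < wavenumber[0] or hi > wavenumber[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] cm^-1 outside grid "
            f"[{wavenumber[0]}, {wavenumber[-1]}]"
        )
    inside = (wavenumber >= lo) & (wavenumber <= hi)
    idx = np.flatnonzero(inside)
    if idx.size < 2:
        raise ValueError("fewer than 2 grid points inside the window")

    # anchors: median of up to 3 points strictly outside each window edge
    # (median of 3 smooth samples is the middle one, so a linear ramp is
    # removed exactly)
    left = np.arange(max(idx[0] - _ANCHOR_POINTS, 0), idx[0])
    if left.size == 0:
        left = idx[:1]
    right = np.arange(idx[-1] + 1, min(idx[-1] + _ANCHOR_POINTS, wavenumber.size - 1) + 1)
    if right.size == 0:
        right = idx[-1:]
    x_l, y_l = float(np.median(wavenumber[left])), float(np.median(intensity[left]))
    x_r, y_r = float(np.median(wavenumber[right])), float(np.median(intensity[right]))
    slope = (y_r - y_l) / (x_r - x_l) if x_r != x_l else 0.0
    baseline = y_l + slope * (wavenumber[inside] - x_l)

    signal = np.clip(intensity[inside] - baseline, 0.0, None)
    return float(np.trapezoid(signal, wavenumber[inside]))


def peak_series(
    spectra: SpectrumSeries,
    center: float = DEFAULT_CENTER,
    window: float = DEFAULT_WINDOW,
) -> PeakSeries:
    """Integrate the band in every spectrum of a series."""
    areas = np.array(
        [
            integrate_peak(spectra.wavenumber, row, center, window)
            for row in spectra.intensities
        ]
    )
    return PeakSeries(timestamps=spectra.timestamps.copy(), area=areas)


def normalize_series(peaks: PeakSeries) -> PeakSeries:
    """Divide a peak series by its area under the curve over time.

    The output has unit trapezoidal AUC, making spots of different
    absolute intensity comparable; scaling the input by any positive
    constant leaves the output unchanged.
    """
    if peaks.timestamps.size < 2:
        raise ValueError("need >= 2 timepoints to normalize")
    auc = float(np.trapezoid(peaks.area, peaks.timestamps))
    if auc <= 0:
        raise ValueError("degenerate series: AUC is zero")
    return PeakSeries(
        timestamps=peaks.timestamps.copy(),
        area=peaks.area.copy(),
        normalized_area=peaks.area / auc,
    )


def align_model(
    model_time: np.ndarray,
    model_reduced_total: np.ndarray,
    peaks: PeakSeries,
    time_offset: float = 0.0,
) -> dict:
    """Scale the modelled reduced-mediator total onto a normalized Raman series.

    The model series is linearly interpolated at the Raman timestamps
    (shifted by ``time_offset`` to register the acquisition clocks) and
    multiplied by the closed-form least-squares factor
    ``scale = <model, raman>/<model, model>``.  Returns the scale, the
    aligned series, the RMSE and the Pearson correlation.
    """
    model_time = np.asarray(model_time, dtype=float) + time_offset
    model_reduced_total = np.asarray(model_reduced_total, dtype=float)
    target = (
        peaks.normalized_area if peaks.normalized_area is not None else peaks.area
    )
    t = peaks.timestamps
    overlap = (t >= model_time[0]) & (t <= model_time[-1])
    if not np.any(overlap):
        raise ValueError(
            f"no temporal overlap: model spans [{model_time[0]}, {model_time[-1]}] s, "
            f"Raman spans [{t[0]}, {t[-1]}] s"
        )
    t_o = t[overlap]
    y = np.asarray(target, dtype=float)[overlap]
    m = np.interp(t_o, model_time, model_reduced_total)

    denom = float(np.dot(m, m))
    if denom == 0.0:
        raise ValueError("model series is identically zero over the overlap")
    scale = float(np.dot(m, y)) / denom
    aligned = scale * m
    r = aligned - y
    rmse = float(np.sqrt(np.mean(r**2)))
    if np.std(m) == 0 or np.std(y) == 0:
        correlation = np.nan
    else:
        correlation = float(np.corrcoef(m, y)[0, 1])
    return {
        "scale": scale,
        "timestamps": t_o,
        "aligned": aligned,
        "rmse": rmse,
        "correlation": correlation,
        "sse": float(np.dot(r, r)),
    }
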