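"""CSV and YAML interchange for traces, spectra, peak series and run configs.

CSV is the interchange format throughout (potentiostat and spectrometer
exports are tabular); column names carry units (``time_s``,
``current_A_per_m2``, ``wavenumber_cm1``).  Trace metadata needed to
re-fit a file (switch time, sample rate, truth parameters of synthetic
runs) rides along as a single ``# meta: {...}`` JSON comment line, so a
written file round-trips losslessly through :func:`read_trace_csv`.

Configs are YAML.  Poised potentials appear in config files in mV vs SHE
(matching how such protocols are written down); the mV→V conversion
happens at this boundary and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model_core import ModelParameters, OmcSModelParameters
from .protocol import Protocol, TraceSeries
from .raman import PeakSeries, SpectrumSeries
from .synthetic import NoiseModel

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_peaks_csv",
    "read_peaks_csv",
    "write_fit_report_csv",
    "RunConfig",
    "load_config",
    "save_config",
]

_META_PREFIX = "# meta: "


def write_trace_csv(trace: TraceSeries, path: str | Path) -> None:
    """Write a trace with its metadata comment line."""
    path = Path(path)
    data = {"time_s": trace.time, "current_A_per_m2": trace.current}
    if trace.im_red is not None:
        data["IM_red_nmol"] = trace.im_red
    if trace.omc_red is not None:
        data["Omc_red_nmol"] = trace.omc_red
    if trace.rates:
        for key, ch in trace.rates.items():
            data[f"{key}_nmol_per_s"] = ch
    frame = pd.DataFrame(data)
    with path.open("w") as fh:
        if trace.meta:
            fh.write(_META_PREFIX + json.dumps(trace.meta, default=float) + "\n")
        frame.to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> TraceSeries:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith(_META_PREFIX):
            meta = json.loads(first[len(_META_PREFIX):])
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, comment="#")
    rates = {
        col[: -len("_nmol_per_s")]: frame[col].to_numpy()
        for col in frame.columns
        if col.endswith("_nmol_per_s")
    }
    return TraceSeries(
        time=frame["time_s"].to_numpy(),
        current=frame["current_A_per_m2"].to_numpy(),
        im_red=frame["IM_red_nmol"].to_numpy() if "IM_red_nmol" in frame else None,
        omc_red=frame["Omc_red_nmol"].to_numpy() if "Omc_red_nmol" in frame else None,
        rates=rates or None,
        meta=meta,
    )


def write_spectra_csv(spectra: SpectrumSeries, path: str | Path) -> None:
    """Long-format spectral series: timestamp_s, wavenumber_cm1, intensity."""
    n_t, n_w = spectra.intensities.shape
    frame = pd.DataFrame(
        {
            "timestamp_s": np.repeat(spectra.timestamps, n_w),
            "wavenumber_cm1": np.tile(spectra.wavenumber, n_t),
            "intensity": spectra.intensities.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectrumSeries:
    frame = pd.read_csv(path)
    timestamps = np.unique(frame["timestamp_s"].to_numpy())
    pivot = frame.pivot_table(
        index="timestamp_s", columns="wavenumber_cm1", values="intensity", sort=True
    )
    return SpectrumSeries(
        wavenumber=pivot.columns.to_numpy(dtype=float),
        intensities=pivot.to_numpy(),
        timestamps=timestamps,
    )


def write_peaks_csv(peaks: PeakSeries, path: str | Path) -> None:
    data = {"timestamp_s": peaks.timestamps, "area": peaks.area}
    if peaks.normalized_area is not None:
        data["normalized_area"] = peaks.normalized_area
    pd.DataFrame(data).to_csv(path, index=False)


def read_peaks_csv(path: str | Path) -> PeakSeries:
    frame = pd.read_csv(path)
    return PeakSeries(
        timestamps=frame["timestamp_s"].to_numpy(),
        area=frame["area"].to_numpy(),
        normalized_area=(
            frame["normalized_area"].to_numpy()
            if "normalized_area" in frame
            else None
        ),
    )


def write_fit_report_csv(params: ModelParameters, path: str | Path, **extra) -> None:
    """Flat key/value table of the six fitted constants plus the derived
    comparison row k_Omc × Omc_total (which has units of s⁻¹ and can be
    compared directly with the first-order constants)."""
    rows = [
        ("IM_tot_nmol", params.im_total),
        ("Omc_tot_nmol", params.omc_total),
        ("k_Ac_per_s", params.k_ac),
        ("k_Omc_per_nmol_s", params.k_omc),
        ("k_Omc_x_Omc_tot_per_s", params.k_omc * params.omc_total),
        ("k_i_before_per_s", params.k_i_before),
        ("k_i_after_per_s", params.k_i_after),
    ]
    rows += list(extra.items())
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from disk."""

    model: ModelParameters
    protocol: Protocol
    noise: NoiseModel = NoiseModel()
    variant: str = "wt"
    fitting: dict = field(default_factory=dict)
    raman: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0


def _model_to_dict(p: ModelParameters) -> dict:
    d = asdict(p)
    d["variant_params"] = isinstance(p, OmcSModelParameters)
    return d


def _model_from_dict(d: dict) -> ModelParameters:
    d = dict(d)
    is_omcs = d.pop("variant_params", False)
    cls = OmcSModelParameters if is_omcs else ModelParameters
    return cls(**d)


def save_config(config: RunConfig, path: str | Path) -> None:
    proto = asdict(config.protocol)
    doc = {
        "model": _model_to_dict(config.model),
        "protocol": {
            "e_before_mV": 1e3 * proto.pop("e_before"),
            "e_after_mV": 1e3 * proto.pop("e_after"),
            **proto,
        },
        "noise": asdict(config.noise),
        "variant": config.variant,
        "fitting": config.fitting,
        "raman": config.raman,
        "output_dir": str(config.output_dir),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        proto = dict(doc["protocol"])
        protocol = Protocol(
            e_before=1e-3 * proto.pop("e_before_mV"),
            e_after=1e-3 * proto.pop("e_after_mV"),
            **proto,
        )
        noise_doc = dict(doc.get("noise") or {})
        if noise_doc.get("spike") is not None:
            amp, n = noise_doc["spike"]
            noise_doc["spike"] = (float(amp), int(n))
        return RunConfig(
            model=_model_from_dict(doc["model"]),
            protocol=protocol,
            noise=NoiseModel(**noise_doc),
            variant=doc.get("variant", "wt"),
            fitting=doc.get("fitting") or {},
            raman=doc.get("raman") or {},
            output_dir=doc.get("output_dir", "."),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
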