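"""Reading, writing and trace-level quality control of OJIP fluorescence transients.

An OJIP transient is the fast rise of chlorophyll-a fluorescence recorded during a
strong saturation pulse (SP). Throughout the package the time axis is in
milliseconds with t = 0 at SP onset; samples recorded during the pre-pulse
baseline (weak measuring light only) carry negative times. Fluorescence is kept
in raw detector units (ADU) until it is explicitly normalized, e.g. by the SP
intensity for PEA-type instruments whose signal is proportional to the pulse
photon flux.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleOptics",
    "AcquisitionMeta",
    "QCReport",
    "OJIPTransient",
    "Dialect",
    "DIALECTS",
    "TransientFormatError",
    "DialectError",
    "read_transient",
    "write_transient",
    "split_baseline",
    "normalize_by_sp_intensity",
    "detect_saturation",
    "write_features_table",
    "write_qc_reports",
    "FEATURE_TABLE_COLUMNS",
    "REASON_SATURATION",
    "REASON_LOW_SNR",
    "REASON_NO_INFLECTION",
]

REASON_SATURATION = "saturation"
REASON_LOW_SNR = "low_snr"
REASON_NO_INFLECTION = "no_inflection_in_window"
_VALID_REASONS = {REASON_SATURATION, REASON_LOW_SNR, REASON_NO_INFLECTION}


class TransientFormatError(ValueError):
    """A trace file or trace array violates the transient contract."""


class DialectError(ValueError):
    """Unknown or inconsistent file dialect."""


@dataclass
class SampleOptics:
    """Optical properties of the measured suspension.

    chl_conc : chlorophyll-a concentration, mg Chl a L^-1.
    eps_path : effective path-averaged optical-density coefficient per (mg Chl a L^-1);
        controls how strongly the excitation pulse is attenuated across the cuvette.
    beta_reabs : emission reabsorption coefficient per (mg Chl a L^-1); controls the
        decline of the detected amplitude at high culture density.
    """

    chl_conc: float = 0.5
    eps_path: float = 0.08
    beta_reabs: float = 0.11

    def __post_init__(self) -> None:
        if self.chl_conc < 0:
            raise ValueError("chl_conc must be >= 0")
        if self.eps_path < 0 or self.beta_reabs < 0:
            raise ValueError("optical coefficients must be >= 0")


@dataclass
class AcquisitionMeta:
    """Per-trace acquisition metadata."""

    instrument_id: str = "generic"
    sp_intensity: float = 2000.0  # µmol photons m^-2 s^-1
    sp_wavelength: float = 440.0  # nm
    detector_max: float = 4095.0  # ADU
    gain: float = 1.0
    ml_present: bool = True
    baseline_ms: float = 10.0
    acclimation: str = "dark"  # {"dark", "light"}
    treatment_label: str = ""

    def __post_init__(self) -> None:
        if self.detector_max <= 0:
            raise ValueError("detector_max must be > 0")
        if self.baseline_ms < 0:
            raise ValueError("baseline_ms must be >= 0")
        if self.acclimation not in ("dark", "light"):
            raise ValueError("acclimation must be 'dark' or 'light'")


@dataclass
class QCReport:
    """Trace-level quality-control verdicts.

    ``excluded`` is true exactly when ``reasons`` is non-empty.
    """

    saturated: bool = False
    n_clipped: int = 0
    snr_ok: bool | None = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.reasons:
            if r not in _VALID_REASONS:
                raise ValueError(f"unknown QC reason: {r!r}")

    @property
    def excluded(self) -> bool:
        return bool(self.reasons)

    def add_reason(self, reason: str) -> None:
        if reason not in _VALID_REASONS:
            raise ValueError(f"unknown QC reason: {reason!r}")
        if reason not in self.reasons:
            self.reasons.append(reason)

    def to_dict(self) -> dict:
        return {
            "saturated": self.saturated,
            "n_clipped": self.n_clipped,
            "snr_ok": self.snr_ok,
            "excluded": self.excluded,
            "reasons": list(self.reasons),
        }


@dataclass
class OJIPTransient:
    """One recorded or simulated time/fluorescence trace plus metadata.

    times : strictly increasing, ms, t = 0 at SP onset (baseline samples t < 0).
    fluorescence : same length, ADU, or normalized units after SP normalization.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    sample: SampleOptics = field(default_factory=SampleOptics)
    normalized_by_sp: bool = False
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.ndim != 1 or self.fluorescence.ndim != 1:
            raise TransientFormatError("times and fluorescence must be 1-D")
        if self.times.size != self.fluorescence.size:
            raise TransientFormatError("times and fluorescence lengths differ")
        if self.times.size < 2:
            raise TransientFormatError("a transient needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise TransientFormatError("time column is not strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.fluorescence)):
            raise TransientFormatError("non-finite values in transient")
        if np.any(self.fluorescence < 0):
            raise TransientFormatError("fluorescence values must be >= 0")
        if not self.normalized_by_sp and np.any(self.fluorescence > self.meta.detector_max):
            raise TransientFormatError("raw fluorescence exceeds detector_max")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Dialect:
    """A delimited-text trace format: column layout, delimiter and time unit."""

    name: str
    delimiter: str = ","
    time_col: int = 0
    fluor_col: int = 1
    time_unit: str = "ms"  # {"s", "ms", "us"}


_TIME_FACTORS = {"s": 1e3, "ms": 1.0, "us": 1e-3}

DIALECTS: dict[str, Dialect] = {
    "generic-csv": Dialect("generic-csv", ",", 0, 1, "ms"),
    "generic-tsv": Dialect("generic-tsv", "\t", 0, 1, "ms"),
    # Named instrument-style presets. They differ only in delimiter/units here;
    # the associated sampling schemes live in the simulator's InstrumentProfile.
    "pam-like": Dialect("pam-like", ",", 0, 1, "ms"),
    "pea-coarse": Dialect("pea-coarse", ",", 0, 1, "us"),
    "pea-fine": Dialect("pea-fine", ",", 0, 1, "us"),
}


def _resolve_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise DialectError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None


def read_transient(
    path: str | Path,
    dialect: str | Dialect = "generic-csv",
    meta: AcquisitionMeta | None = None,
    sample: SampleOptics | None = None,
) -> OJIPTransient:
    """Read one trace file, convert times to ms and shift SP onset to t = 0.

    File times are assumed to count from the start of the recording; the SP
    onset is located ``meta.baseline_ms`` after that (0 if the file already
    uses pulse-onset time zero). A single non-numeric header line is skipped
    automatically.
    """
    d = _resolve_dialect(dialect)
    meta = meta if meta is not None else AcquisitionMeta()
    path = Path(path)
    rows = pd.read_csv(path, sep=d.delimiter, header=None, comment="#", dtype=str,
                       skip_blank_lines=True)
    ncol = max(d.time_col, d.fluor_col) + 1
    if rows.shape[1] < ncol:
        raise TransientFormatError(f"{path}: expected at least {ncol} columns")

    def _to_float(frame: pd.DataFrame) -> np.ndarray | None:
        try:
            return frame.iloc[:, [d.time_col, d.fluor_col]].astype(float).to_numpy()
        except (TypeError, ValueError):
            return None

    data = _to_float(rows)
    if data is None:
        data = _to_float(rows.iloc[1:])  # tolerate one header line
        if data is None:
            raise TransientFormatError(f"{path}: non-numeric cells in body")
    if data.shape[0] < 2:
        raise TransientFormatError(f"{path}: fewer than 2 samples")
    times_ms = data[:, 0] * _TIME_FACTORS[d.time_unit] - meta.baseline_ms
    return OJIPTransient(
        times=times_ms,
        fluorescence=data[:, 1],
        meta=meta,
        sample=sample if sample is not None else SampleOptics(),
        trace_id=path.stem,
    )


def write_transient(transient: OJIPTransient, path: str | Path,
                    dialect: str | Dialect = "generic-csv") -> Path:
    """Write a trace in a generic two-column dialect, times as stored (ms-shifted).

    Read back with ``meta.baseline_ms = 0``; values round-trip at 10 significant
    digits.
    """
    d = _resolve_dialect(dialect)
    path = Path(path)
    df = pd.DataFrame(
        {"time": transient.times / _TIME_FACTORS[d.time_unit],
         "fluorescence": transient.fluorescence}
    )
    df.to_csv(path, sep=d.delimiter, index=False, header=True, float_format="%.10g")
    return path


def split_baseline(
    transient: OJIPTransient,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Partition a transient at SP onset.

    Returns ``((t_base, f_base), (t_pulse, f_pulse))`` with the baseline holding
    all samples at t < 0 and the pulse all samples at t >= 0; their concatenation
    reproduces the input. Raises if the pulse segment is empty.
    """
    mask = transient.times < 0.0
    baseline = (transient.times[mask], transient.fluorescence[mask])
    pulse = (transient.times[~mask], transient.fluorescence[~mask])
    if pulse[0].size == 0:
        raise TransientFormatError("transient has no pulse segment (all t < 0)")
    return baseline, pulse


def normalize_by_sp_intensity(transient: OJIPTransient) -> OJIPTransient:
    """Divide the fluorescence by the SP photon flux density (PEA-type traces).

    The detected signal of instruments without measuring light scales with the
    pulse intensity, so traces recorded at different SP settings are comparable
    only after this normalization. Applying it twice is an error.
    """
    if transient.normalized_by_sp:
        raise ValueError("transient is already SP-normalized")
    sp = transient.meta.sp_intensity
    if sp is None or sp <= 0:
        raise ValueError("sp_intensity must be > 0 for SP normalization")
    return dataclasses.replace(
        transient,
        fluorescence=transient.fluorescence / sp,
        normalized_by_sp=True,
    )


def detect_saturation(transient: OJIPTransient, tol_adu: float = 0.0) -> QCReport:
    """Flag detector clipping on the pulse segment.

    A pulse sample is clipped iff its value >= detector_max - tol_adu (clipping
    is defined in raw ADU, so the trace must not be SP-normalized). Baseline
    samples are ignored: they sit far below the detector ceiling in practice.
    """
    if transient.normalized_by_sp:
        raise ValueError("saturation is defined on raw (non-SP-normalized) traces")
    _, (t_pulse, f_pulse) = split_baseline(transient)
    n_clipped = int(np.count_nonzero(f_pulse >= transient.meta.detector_max - tol_adu))
    report = QCReport(saturated=n_clipped >= 1, n_clipped=n_clipped)
    if report.saturated:
        report.add_reason(REASON_SATURATION)
    return report


FEATURE_TABLE_COLUMNS = [
    "id",
    "acclimation",
    "F0_or_FS",
    "FJ",
    "FM",
    "tJ_ms",
    "tP_ms",
    "VJ_or_VJprime",
    "excluded",
    "reasons",
]


def write_features_table(features: Sequence, path: str | Path) -> Path:
    """Write extracted landmark features as a CSV table, one row per transient.

    Excluded traces keep their row with the V_J cell empty and the QC reasons
    filled; numeric cells round-trip at 10 significant digits.
    """
    if len(features) == 0:
        raise ValueError("cannot write an empty features table")
    rows = []
    for f in features:
        rows.append(
            {
                "id": f.trace_id,
                "acclimation": f.mode,
                "F0_or_FS": f.F0,
                "FJ": None if f.qc.excluded else f.FJ,
                "FM": f.FM,
                "tJ_ms": None if f.qc.excluded else f.tJ,
                "tP_ms": f.tP,
                "VJ_or_VJprime": None if f.qc.excluded else f.VJ,
                "excluded": f.qc.excluded,
                "reasons": ";".join(f.qc.reasons),
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_qc_reports(features: Sequence, path: str | Path) -> Path:
    """Write per-trace QC reports as JSON lines."""
    path = Path(path)
    with path.open("w") as fh:
        for f in features:
            record = {"id": f.trace_id, **f.qc.to_dict()}
            fh.write(json.dumps(record) + "\n")
    return path
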