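"""Core ECG record containers.

A digital 12-lead ECG is a matrix of integer ADC counts (one row per lead)
plus sampling metadata.  Two record shapes are used throughout: a 1.2-s
"median" representative beat (600 samples at 500 Hz) and a 10-s "rhythm"
strip (5000 samples).  Fiducial points (wave onsets/offsets/peaks) and the
seven derived measurements (PR, QRS, QT, HR, R amplitude, T amplitude, STJ)
are carried in dedicated containers so that every model, explainer and
occlusion experiment can be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Standard clinical lead order.
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Index of lead V5, the reference lead for amplitude measurements.
V5 = LEAD_NAMES.index("V5")

#: The 8 linearly independent leads of a 12-lead ECG (I, II, V1-V6).
#: III, aVR, aVL and aVF are fixed linear combinations of I and II.
INDEPENDENT_LEADS = (0, 1, 6, 7, 8, 9, 10, 11)

DEFAULT_FS = 500.0      # Hz
DEFAULT_LSB = 4.88      # microvolt per ADC count
MEDIAN_SAMPLES = 600    # 1.2 s at 500 Hz
RHYTHM_SAMPLES = 5000   # 10 s at 500 Hz


@dataclass
class ECGRecord:
    """A quantized multichannel ECG signal.

    Parameters
    ----------
    voltages
        Integer matrix ``(n_leads, n_samples)`` in LSB (ADC count) units.
    fs
        Sampling rate in Hz.
    lsb
        Voltage of one least significant bit, in microvolt.
    record_kind
        ``"median"`` (single representative beat) or ``"rhythm"``.
    record_id
        Opaque label.
    """

    voltages: np.ndarray
    fs: float = DEFAULT_FS
    lsb: float = DEFAULT_LSB
    record_kind: str = "median"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a (leads, samples) matrix")
        if not np.issubdtype(self.voltages.dtype, np.integer):
            raise ValueError("voltages must be integer LSB counts; "
                             "use synth.quantize() first")
        if self.record_kind not in ("median", "rhythm"):
            raise ValueError(f"unknown record_kind {self.record_kind!r}")
        expected = MEDIAN_SAMPLES if self.record_kind == "median" else RHYTHM_SAMPLES
        if self.fs == DEFAULT_FS and self.voltages.shape[1] != expected:
            raise ValueError(
                f"{self.record_kind} records at {self.fs:g} Hz must have "
                f"{expected} samples, got {self.voltages.shape[1]}")

    @property
    def n_leads(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def microvolts(self) -> np.ndarray:
        """Dequantized signal in microvolt, float64 ``(n_leads, n_samples)``."""
        return self.voltages.astype(np.float64) * self.lsb

    def independent_channels(self) -> np.ndarray:
        """The 8 independent channels (I, II, V1-V6) in microvolt."""
        if self.n_leads != 12:
            raise ValueError("independent_channels requires a 12-lead record")
        return self.microvolts()[list(INDEPENDENT_LEADS)]

    def sample_index(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms from record start."""
        return int(round(t_ms * self.fs / 1000.0))


@dataclass
class FiducialSet:
    """Wave boundary/peak times of one beat, in ms from record start.

    ``None`` marks a fiducial that is genuinely absent (e.g. no P wave);
    downstream measurements derived from it are then undefined rather
    than zero.  ``beat_times`` lists all R-peak times for rhythm records.
    """

    P_on: Optional[float] = None
    P_off: Optional[float] = None
    QRS_on: Optional[float] = None
    QRS_off: Optional[float] = None
    T_on: Optional[float] = None
    T_off: Optional[float] = None
    P_peak_time: Optional[float] = None
    R_peak_time: Optional[float] = None
    T_peak_time: Optional[float] = None
    beat_times: Optional[Sequence[float]] = None

    _ORDER = ("P_on", "P_off", "QRS_on", "QRS_off", "T_on", "T_off")

    def __post_init__(self) -> None:
        vals = [(n, getattr(self, n)) for n in self._ORDER
                if getattr(self, n) is not None]
        for (na, va), (nb, vb) in zip(vals, vals[1:]):
            if va > vb:
                raise ValueError(f"fiducial ordering violated: {na}={va} > {nb}={vb}")

    def shifted(self, delta_ms: float) -> "FiducialSet":
        """All fiducials translated by ``delta_ms`` (augmentation support)."""
        kw = {}
        for name in (*self._ORDER, "P_peak_time", "R_peak_time", "T_peak_time"):
            v = getattr(self, name)
            kw[name] = None if v is None else v + delta_ms
        bt = self.beat_times
        kw["beat_times"] = None if bt is None else [t + delta_ms for t in bt]
        return FiducialSet(**kw)

    def check_within(self, duration_ms: float) -> None:
        for name in (*self._ORDER, "P_peak_time", "R_peak_time", "T_peak_time"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v < duration_ms):
                raise ValueError(f"fiducial {name}={v} outside [0, {duration_ms})")


@dataclass
class MeasurementSet:
    """The seven standard measurements plus an optional binary sex label.

    Intervals in ms, heart rate in beats/min, amplitudes in microvolt
    relative to the record baseline.  ``None`` means undefined.
    """

    PR: Optional[float] = None
    QRS: Optional[float] = None
    QT: Optional[float] = None
    HR: Optional[float] = None
    R_amp: Optional[float] = None
    T_amp: Optional[float] = None
    STJ: Optional[float] = None
    sex_label: Optional[int] = None

    REGRESSION_TASKS = ("PR", "QRS", "QT", "HR", "R_amp", "T_amp", "STJ")

    def __post_init__(self) -> None:
        if self.PR is not None and self.PR <= 0:
            raise ValueError("PR must be positive")
        if self.HR is not None and self.HR <= 0:
            raise ValueError("HR must be positive")
        if self.QT is not None and self.QRS is not None and self.QT <= self.QRS:
            raise ValueError("QT must exceed QRS duration")

    def label(self, task: str) -> float:
        """Ground-truth value for one named task (``sex`` or a regression task)."""
        if task == "sex":
            if self.sex_label is None:
                raise ValueError("record has no sex label")
            return float(self.sex_label)
        v = getattr(self, task)
        if v is None:
            raise ValueError(f"measurement {task} undefined for this record")
        return float(v)
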