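"""Synthetic 12-lead ECG generator with exact ground truth.

Each beat is a sum of Gaussian bumps (one per wave: P, Q, R, S, T, plus a
small ST-segment component anchored at the J point), projected onto the 12
leads by per-lead scale factors.  Fiducial points are *defined* from the
wave parameters (onset/offset at ``center +/- k_sigma * width``), so the
generator knows every interval and amplitude exactly, before noise and
quantization — the role an ECG manufacturer's annotation algorithm plays
for real population data.

The population generator draws the seven measurements from split-normal
distributions pinned at a median and 5th/95th percentiles (the summary
format of epidemiological ECG cohorts), builds wave parameters that realize
those values exactly, and emits quantized 500 Hz records at 4.88 uV per
least significant bit.  A binary "sex-like" class is planted whose only
systematic difference is the morphology of the R-wave downslope (an
earlier, deeper, and reshaped S wave at identical QRS-duration
distribution), so interval-based classifiers are weak and morphology-based
ones strong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import (DEFAULT_FS, DEFAULT_LSB, ECGRecord, FiducialSet,
                      LEAD_NAMES, MEDIAN_SAMPLES, MeasurementSet,
                      RHYTHM_SAMPLES, V5)

__all__ = [
    "GaussianWave", "WaveParams", "MeasurementDistribution", "PopulationSpec",
    "LabeledECG", "make_beat", "derive_fiducials", "measure", "quantize",
    "dequantize", "time_shift", "generate_population",
]

#: Default support half-width in sigma units: a wave "starts"/"ends" where
#: its Gaussian has fallen to exp(-k^2/2) ~ 4.4% of the peak.
DEFAULT_K_SIGMA = 2.5

#: Named physiological waves, in temporal order within one beat.
WAVE_ORDER = ("P", "Q", "R", "S", "T")


@dataclass
class GaussianWave:
    """One Gaussian wave component: ``amp * exp(-(t-center)^2 / (2 width^2))``."""
    center: float      # ms from record start
    width: float       # Gaussian sigma, ms
    amplitude: float   # signed, microvolt


@dataclass
class WaveParams:
    """Full parameterization of one beat across 12 leads.

    ``waves`` maps wave names to components.  Keys in :data:`WAVE_ORDER`
    are the physiological waves (checked for temporal ordering); other
    keys (e.g. ``"ST"``) are auxiliary shape components that never define
    fiducials.  ``lead_projection`` scales the (baseline-removed) template
    onto each lead; lead V5 is the amplitude reference and should keep
    scale 1.
    """

    waves: Dict[str, GaussianWave]
    baseline_level: float = 0.0
    lead_projection: np.ndarray = field(
        default_factory=lambda: np.ones(len(LEAD_NAMES)))
    rr_ms: Optional[float] = None   # underlying RR interval (HR ground truth)

    def __post_init__(self) -> None:
        self.lead_projection = np.asarray(self.lead_projection, dtype=float)
        for name, w in self.waves.items():
            if w.amplitude != 0.0 and w.width <= 0.0:
                raise ValueError(
                    f"wave {name!r} has non-zero amplitude but width {w.width}")
        present = [n for n in WAVE_ORDER if n in self.waves]
        centers = [self.waves[n].center for n in present]
        if any(a >= b for a, b in zip(centers, centers[1:])):
            raise ValueError(f"wave centers must be ordered {present}: {centers}")


def make_beat(params: WaveParams, fs: float = DEFAULT_FS,
              duration_ms: float = 1200.0) -> np.ndarray:
    """Evaluate the single-lead (template) waveform on the sampling grid.

    Returns a float array of ``round(duration_ms * fs / 1000)`` samples in
    microvolt: ``baseline + sum_w amp_w * exp(-(t - c_w)^2 / (2 s_w^2))``.
    Deterministic in the parameters; no noise, no quantization.
    """
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) * (1000.0 / fs)
    y = np.full(n, float(params.baseline_level))
    for w in params.waves.values():
        if w.amplitude == 0.0:
            continue
        y += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    return y


def derive_fiducials(params: WaveParams,
                     k_sigma: float = DEFAULT_K_SIGMA) -> FiducialSet:
    """Exact fiducials from wave supports: onset/offset at center +/- k*sigma.

    The QRS complex spans from the onset of its first wave (Q, else R) to
    the offset of its last (S, else R) — the J point.  No signal processing
    is involved; in the zero-width limit onset = offset = center.  If the
    P offset or T onset would cross into the QRS support a warning is
    emitted and the boundary is clipped.
    """
    w = params.waves

    def edge(name: str, sign: int) -> Optional[float]:
        if name not in w:
            return None
        return w[name].center + sign * k_sigma * w[name].width

    qrs_first = "Q" if "Q" in w else ("R" if "R" in w else None)
    qrs_last = "S" if "S" in w else ("R" if "R" in w else None)
    qrs_on = edge(qrs_first, -1) if qrs_first else None
    qrs_off = edge(qrs_last, +1) if qrs_last else None

    p_on, p_off = edge("P", -1), edge("P", +1)
    t_on, t_off = edge("T", -1), edge("T", +1)
    if p_off is not None and qrs_on is not None and p_off > qrs_on:
        warnings.warn("P-wave support overlaps QRS onset; clipping P_off")
        p_off = qrs_on
    if t_on is not None and qrs_off is not None and t_on < qrs_off:
        warnings.warn("T-wave support overlaps QRS offset; clipping T_on")
        t_on = qrs_off

    return FiducialSet(
        P_on=p_on, P_off=p_off, QRS_on=qrs_on, QRS_off=qrs_off,
        T_on=t_on, T_off=t_off,
        P_peak_time=w["P"].center if "P" in w else None,
        R_peak_time=w["R"].center if "R" in w else None,
        T_peak_time=w["T"].center if "T" in w else None,
    )


def measure(fid: FiducialSet, waveform: np.ndarray, baseline: float = 0.0,
            fs: float = DEFAULT_FS, rr_ms: Optional[float] = None,
            sex_label: Optional[int] = None) -> MeasurementSet:
    """Derive the seven measurements from fiducials and a reference-lead waveform.

    PR = QRS_on - P_on; QRS = QRS_off - QRS_on; QT = T_off - QRS_on (ms).
    HR = 60000 / RR beats/min, with RR the mean R-to-R spacing of
    ``fid.beat_times`` when available (rhythm records) and ``rr_ms``
    otherwise.  Amplitudes are the waveform sampled at the fiducial time
    minus the baseline: R_amp and T_amp at the respective peaks, STJ at the
    J point (QRS offset).  A missing fiducial leaves the dependent
    measurement ``None`` — undefined, never zero.
    """
    waveform = np.asarray(waveform, dtype=float)

    def diff(a: Optional[float], b: Optional[float]) -> Optional[float]:
        return None if (a is None or b is None) else b - a

    def amp_at(t: Optional[float]) -> Optional[float]:
        if t is None:
            return None
        i = int(round(t * fs / 1000.0))
        if not 0 <= i < waveform.size:
            return None
        return float(waveform[i]) - baseline

    if fid.beat_times is not None and len(fid.beat_times) >= 2:
        rr = float(np.mean(np.diff(np.asarray(fid.beat_times, dtype=float))))
    else:
        rr = rr_ms
    return MeasurementSet(
        PR=diff(fid.P_on, fid.QRS_on),
        QRS=diff(fid.QRS_on, fid.QRS_off),
        QT=diff(fid.QRS_on, fid.T_off),
        HR=None if rr is None else 60000.0 / rr,
        R_amp=amp_at(fid.R_peak_time),
        T_amp=amp_at(fid.T_peak_time),
        STJ=amp_at(fid.QRS_off),
        sex_label=sex_label,
    )


def quantize(waveform_uv: np.ndarray, lsb: float = DEFAULT_LSB) -> np.ndarray:
    """Microvolt -> integer LSB counts, rounding half away from zero.

    Round-half-away-from-zero keeps quantization symmetric for negative
    voltages (np.round would round halves to even).  4.88 uV -> 1 LSB.
    """
    x = np.asarray(waveform_uv, dtype=float) / lsb
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite values")
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int32)


def dequantize(counts: np.ndarray, lsb: float = DEFAULT_LSB) -> np.ndarray:
    """Integer LSB counts -> microvolt."""
    return np.asarray(counts, dtype=float) * lsb


def time_shift(record: ECGRecord, fid: FiducialSet,
               rng: np.random.Generator,
               max_shift_ms: float = 40.0
               ) -> Tuple[ECGRecord, FiducialSet, float]:
    """Random circular time shift of a median beat (training augmentation).

    Draws an integer sample shift uniformly from +/- ``max_shift_ms``
    (+/- 20 samples at 500 Hz for the default 40 ms), rolls the signal, and
    translates the fiducials consistently, leaving every interval
    unchanged.  Rhythm records are refused: no alignment is defined for
    them, their recording start is already random with respect to the beat.
    Returns ``(shifted_record, shifted_fiducials, shift_ms)``.
    """
    if record.record_kind != "median":
        raise ValueError("time_shift applies to median records only")
    max_samples = int(round(max_shift_ms * record.fs / 1000.0))
    s = int(rng.integers(-max_samples, max_samples + 1))
    return shift_record(record, fid, s)


def shift_record(record: ECGRecord, fid: FiducialSet, shift_samples: int
                 ) -> Tuple[ECGRecord, FiducialSet, float]:
    """Deterministic circular shift by an integer number of samples."""
    shift_ms = shift_samples * 1000.0 / record.fs
    if shift_samples == 0:
        return record, fid, 0.0
    volts = np.roll(record.voltages, shift_samples, axis=1)
    out = ECGRecord(volts, fs=record.fs, lsb=record.lsb,
                    record_kind=record.record_kind, record_id=record.record_id)
    fid2 = fid.shifted(shift_ms)
    fid2.check_within(record.duration_ms)
    return out, fid2, shift_ms


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------

@dataclass
class MeasurementDistribution:
    """A median with 5th/95th percentiles, sampled as a split normal."""
    median: float
    p5: float
    p95: float

    _Z95 = 1.6448536269514722  # standard-normal 95th percentile

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        z = rng.standard_normal(n)
        lo = (self.median - self.p5) / self._Z95
        hi = (self.p95 - self.median) / self._Z95
        return self.median + z * np.where(z < 0, lo, hi)


def _default_adult_distributions() -> Dict[str, MeasurementDistribution]:
    # Median [p5; p95] of each measurement in a general adult population.
    return {
        "HR": MeasurementDistribution(64.0, 48.0, 85.0),
        "QT": MeasurementDistribution(408.0, 364.0, 460.0),
        "PR": MeasurementDistribution(158.0, 126.0, 204.0),
        "QRS": MeasurementDistribution(92.0, 76.0, 118.0),
        "STJ": MeasurementDistribution(-5.0, -54.0, 48.0),
        "R_amp": MeasurementDistribution(1376.0, 698.0, 2426.0),
        "T_amp": MeasurementDistribution(346.0, 122.0, 698.0),
    }


#: Typical relative wave strength of each lead (V5 = 1, the reference).
_LEAD_PROJECTION = np.array(
    [0.55, 0.75, 0.25, -0.65, 0.18, 0.50,   # I, II, III, aVR, aVL, aVF
     -0.30, 0.45, 0.70, 0.90, 1.00, 0.85])  # V1..V6


@dataclass
class PopulationSpec:
    """Study-population description for :func:`generate_population`.

    ``distributions`` pins the marginal of each measurement (median and
    5th/95th percentiles).  ``sex_effect`` scales the planted R-downslope
    difference between the two classes (1.0 = the default effect; 0 makes
    the classes identical in distribution).  ``noise_sd`` is white
    measurement noise per lead in microvolt; median beats are averages of
    many beats, so their noise floor is low.  ``seed`` makes the population
    bit-reproducible.
    """

    distributions: Dict[str, MeasurementDistribution] = field(
        default_factory=_default_adult_distributions)
    noise_sd: float = 5.0                 # uV, white, per lead
    baseline_wander_amplitude: float = 0.0  # uV, slow sinusoid
    sex_effect: float = 1.0
    female_fraction: float = 0.5
    rr_jitter_ms: float = 15.0            # per-beat RR SD in rhythm strips
    lead_scale_jitter: float = 0.05       # per-record, per-lead projection SD
    k_sigma: float = DEFAULT_K_SIGMA
    seed: int = 0


@dataclass
class LabeledECG:
    """One synthetic record with its exact ground truth."""
    record: ECGRecord
    fiducials: FiducialSet
    measurements: MeasurementSet
    params: WaveParams


_GRID_MS = 1000.0 / DEFAULT_FS  # 2 ms sample spacing


def _snap(t: float) -> float:
    """Snap a time to the sampling grid so peak values are read exactly."""
    return round(t / _GRID_MS) * _GRID_MS


def _gauss_at(t: float, w: GaussianWave) -> float:
    return float(np.exp(-0.5 * ((t - w.center) / w.width) ** 2))


def _build_wave_params(m: Dict[str, float], sex_label: int,
                       spec: PopulationSpec, rng: np.random.Generator
                       ) -> WaveParams:
    """Construct Gaussian wave parameters realizing the target measurements.

    Interval targets are met exactly by placing wave supports; amplitude
    targets (R_amp, STJ, T_amp) are met exactly by solving a 4x4 linear
    system for the P, R, ST and T amplitudes given the freely drawn Q and S
    waves (whose tails would otherwise perturb the peak/J-point values).
    """
    k = spec.k_sigma
    qrs_on = 480.0                      # median-beat centering convention
    j = _snap(qrs_on + m["QRS"])
    sigma_q = 12.0 / k                  # Q support is 12 ms wide past QRS_on
    q_c = qrs_on + 12.0
    r_c = _snap(qrs_on + 0.42 * m["QRS"])
    sigma_r = 0.11 * m["QRS"]

    # S wave: carries part of the planted sex effect.  Class 1 gets a
    # slightly earlier and deeper S at unchanged J point (hence unchanged
    # QRS-duration distribution) — a steeper R downslope.  Most of the
    # class difference, however, lives in a mid-downslope notch component
    # (below) that wave-level features cannot express.
    e = spec.sex_effect if sex_label == 1 else 0.0
    s_jit = float(np.clip(rng.normal(0.0, 3.0), -6.0, 6.0))
    s_back = 22.0 + 4.0 * e + s_jit
    s_back = min(s_back, 0.5 * m["QRS"] - 2.0)
    s_c = j - s_back
    sigma_s = s_back / k
    a_q = float(np.clip(rng.normal(-70.0, 20.0), -150.0, -20.0))
    a_s = -abs(rng.normal(260.0, 55.0)) * (1.0 + 0.15 * e)

    # P wave: support spans [QRS_on - PR, QRS_on - PR + Pd].
    pd = min(80.0, 0.6 * m["PR"])
    p_on = qrs_on - m["PR"]
    p_c = p_on + pd / 2.0
    sigma_p = pd / (2.0 * k)

    # T wave: support ends exactly QT after QRS onset.
    t_off = _snap(qrs_on + m["QT"])
    td = min(170.0, 0.75 * (m["QT"] - m["QRS"]))
    t_c = _snap(t_off - td / 2.0)
    sigma_t = (t_off - t_c) / k

    # ST-segment component anchored at J controls the J-point elevation.
    st_c = float(j)
    sigma_st = 14.0

    # Downslope notch: a narrow class-1 deflection halfway down the R-S
    # descent.  It reshapes the R downslope without moving the R/S peaks
    # or the QRS boundaries, so it is invisible to wave-level features
    # (amplitudes and timings) but plain in the raw morphology.
    rs_c = 0.5 * (r_c + s_c)
    a_rs = -160.0 * e * max(0.0, float(rng.normal(1.0, 0.15)))

    waves = {
        "P": GaussianWave(p_c, sigma_p, 1.0),
        "Q": GaussianWave(q_c, sigma_q, a_q),
        "R": GaussianWave(r_c, sigma_r, 1.0),
        "S": GaussianWave(s_c, sigma_s, a_s),
        "T": GaussianWave(t_c, sigma_t, 1.0),
        "ST": GaussianWave(st_c, sigma_st, 1.0),
        "RS": GaussianWave(rs_c, 5.0, a_rs),
    }

    # Solve for (a_P, a_R, a_ST, a_T) so the waveform hits the targets at
    # the P peak, R peak, J point and T peak exactly.
    p_amp = float(np.clip(rng.normal(110.0, 25.0), 40.0, 200.0))
    eval_pts = [p_c, r_c, st_c, t_c]
    targets = np.array([p_amp, m["R_amp"], m["STJ"], m["T_amp"]])
    solve_names = ["P", "R", "ST", "T"]
    fixed = [("Q", a_q), ("S", a_s), ("RS", a_rs)]
    design = np.array([[_gauss_at(t, waves[n]) for n in solve_names]
                       for t in eval_pts])
    rhs = targets - np.array(
        [sum(a * _gauss_at(t, waves[n]) for n, a in fixed) for t in eval_pts])
    amps = np.linalg.solve(design, rhs)
    for name, a in zip(solve_names, amps):
        waves[name].amplitude = float(a)

    proj = _LEAD_PROJECTION * (1.0 + rng.normal(0.0, spec.lead_scale_jitter,
                                                size=_LEAD_PROJECTION.size))
    proj[V5] = 1.0  # amplitude reference lead
    baseline = float(rng.normal(0.0, 8.0))
    return WaveParams(waves=waves, baseline_level=baseline,
                      lead_projection=proj, rr_ms=60000.0 / m["HR"])


def _project_and_digitize(template: np.ndarray, params: WaveParams,
                          spec: PopulationSpec, rng: np.random.Generator,
                          fs: float, kind: str, record_id: str) -> ECGRecord:
    n = template.size
    centered = template - params.baseline_level
    leads = params.baseline_level + params.lead_projection[:, None] * centered
    if spec.noise_sd > 0:
        leads = leads + rng.normal(0.0, spec.noise_sd, size=leads.shape)
    if spec.baseline_wander_amplitude > 0:
        t = np.arange(n) / fs
        freq = rng.uniform(0.15, 0.4)
        phase = rng.uniform(0.0, 2 * np.pi, size=(leads.shape[0], 1))
        leads = leads + spec.baseline_wander_amplitude * np.sin(
            2 * np.pi * freq * t[None, :] + phase)
    return ECGRecord(quantize(leads), fs=fs, record_kind=kind,
                     record_id=record_id)


def _draw_measurements(spec: PopulationSpec, rng: np.random.Generator
                       ) -> Dict[str, float]:
    d = spec.distributions
    m = {k: float(v.sample(rng, 1)[0]) for k, v in d.items()}
    # Physiological sanity clips, then snap intervals to the sample grid so
    # interval ground truth is exactly representable.
    m["QRS"] = float(np.clip(m["QRS"], 64.0, 160.0))
    m["PR"] = float(np.clip(m["PR"], 100.0, 280.0))
    m["QT"] = float(np.clip(m["QT"], m["QRS"] + 160.0, 560.0))
    m["HR"] = float(np.clip(m["HR"], 35.0, 140.0))
    m["R_amp"] = float(np.clip(m["R_amp"], 300.0, 3500.0))
    m["T_amp"] = float(np.clip(m["T_amp"], 40.0, 1100.0))
    for k in ("QRS", "PR", "QT"):
        m[k] = _snap(m[k])
    return m


def _make_rhythm(params: WaveParams, fid_beat: FiducialSet,
                 spec: PopulationSpec, rng: np.random.Generator
                 ) -> Tuple[np.ndarray, FiducialSet]:
    """Tile the beat at jittered RR intervals over a 10-s strip."""
    fs = DEFAULT_FS
    duration = RHYTHM_SAMPLES / fs * 1000.0
    rr = params.rr_ms
    r_ref = params.waves["R"].center
    # R-peak times covering the strip plus margins for edge-truncated beats.
    n_beats = int(duration / rr) + 4
    start = _snap(float(rng.uniform(0.0, rr)) - rr)
    rrs = rr + rng.normal(0.0, spec.rr_jitter_ms, size=n_beats)
    r_times = np.array([_snap(t) for t in start + np.cumsum(rrs) - rrs[0]])
    t = np.arange(RHYTHM_SAMPLES) * (1000.0 / fs)
    y = np.full(RHYTHM_SAMPLES, params.baseline_level)
    for rt in r_times:
        off = rt - r_ref
        for w in params.waves.values():
            c = w.center + off
            if c < -300.0 or c > duration + 300.0:
                continue
            y += w.amplitude * np.exp(-0.5 * ((t - c) / w.width) ** 2)
    in_strip = [float(rt) for rt in r_times if 0.0 <= rt < duration]
    # Per-beat fiducials reported for the first fully contained beat.
    full = [rt for rt in r_times
            if rt - r_ref + (params.waves["P"].center - 3 * params.waves["P"].width) >= 0
            and rt - r_ref + params.waves["T"].center + 3 * params.waves["T"].width < duration]
    off0 = (full[0] - r_ref) if full else 0.0
    fid = fid_beat.shifted(off0)
    fid.beat_times = in_strip
    return y, fid


def generate_population(spec: PopulationSpec, n: int, kind: str = "median"
                        ) -> List[LabeledECG]:
    """Generate ``n`` labeled records (``kind`` = ``"median"`` or ``"rhythm"``).

    Reproducible bit-for-bit from ``spec.seed``.  ``n = 0`` returns an
    empty list.  Ground-truth measurements are computed from the clean
    reference-lead template (pre-noise, pre-quantization), so labels are
    exact even when the emitted signal is noisy.
    """
    if kind not in ("median", "rhythm"):
        raise ValueError(f"unknown record kind {kind!r}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(spec.seed)
    out: List[LabeledECG] = []
    for i in range(n):
        sex = int(rng.random() < 1.0 - spec.female_fraction)
        m = _draw_measurements(spec, rng)
        params = _build_wave_params(m, sex, spec, rng)
        fid = derive_fiducials(params, spec.k_sigma)
        if kind == "median":
            template = make_beat(params, DEFAULT_FS, 1200.0)
            meas = measure(fid, template, params.baseline_level,
                           rr_ms=params.rr_ms, sex_label=sex)
            rec = _project_and_digitize(template, params, spec, rng,
                                        DEFAULT_FS, "median", f"synth-{i:05d}")
        else:
            strip, fid = _make_rhythm(params, fid, spec, rng)
            meas = measure(fid, strip, params.baseline_level, sex_label=sex)
            # Interval/amplitude truth comes from the beat template, HR from
            # the realized beat times.
            beat_meas = measure(derive_fiducials(params, spec.k_sigma),
                                make_beat(params, DEFAULT_FS, 1200.0),
                                params.baseline_level, rr_ms=params.rr_ms)
            meas = replace(beat_meas, HR=meas.HR, sex_label=sex)
            rec = _project_and_digitize(strip, params, spec, rng,
                                        DEFAULT_FS, "rhythm", f"synth-{i:05d}")
        out.append(LabeledECG(rec, fid, meas, params))
    return out
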