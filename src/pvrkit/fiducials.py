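"""Beat segmentation, fiducial detection and quantitative PVR features.

The quantitative features follow the vascular-lab definitions:

* UST (upstroke time, ms): foot to systolic peak.
* USR (upstroke ratio): UST divided by the total wavelength (foot-to-foot).
* MSA (maximum systolic amplitude, mmHg): peak minus the preceding foot.

The foot is defined as the local minimum immediately preceding the point of
maximal upslope — robust at 1 ms sampling and matching how a reader marks
the waveform foot visually. All times are reported on the native sampling
grid; no sub-sample interpolation is used. Per-beat values are summarised
by the median across quality-accepted beats for robustness to a single
corrupted beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from pvrkit.errors import InsufficientDataError, ValidationError
from pvrkit.wavesim import PVRTrace

__all__ = [
    "BeatAnnotation",
    "PVRFeatures",
    "PVRFeatureExtractor",
    "smooth",
    "detect_pulsatility",
    "segment_beats",
    "detect_fiducials",
    "extract_features",
]

#: Peak-to-trough excursion (mmHg) below which a trace counts as non-pulsatile.
DEFAULT_MSA_FLOOR = 0.05
#: Plausible heart-period range (ms) for the periodic component.
PERIOD_RANGE_MS = (300.0, 2000.0)
#: Default zero-phase low-pass cutoff (Hz) applied before detection.
DEFAULT_CUTOFF_HZ = 25.0
#: Light low-pass cutoff (Hz) used to refine fiducial times: heavy smoothing
#: stabilises landmark search but rounds waveform corners by several ms, so
#: peak/foot times are re-located on a lightly smoothed copy nearby.
REFINE_CUTOFF_HZ = 80.0
#: Very heavy cutoff (Hz) for the slope signal used in foot detection: the
#: upstroke onset of flattened (severe) waveforms has a slope comparable to
#: derivative noise unless the derivative is estimated in a narrow band.
FOOT_SLOPE_CUTOFF_HZ = 8.0
#: Cutoff (Hz) of the signal used for the apex fit on flattened waveforms,
#: whose broad low-curvature peaks profit from extra noise suppression.
APEX_CUTOFF_HZ = 12.0
#: Half-width (samples at 1 ms) of the refinement search windows.
FOOT_REFINE_HALF = 40
#: Dicrotic-notch prominence threshold as a fraction of beat amplitude.
NOTCH_PROMINENCE_FRACTION = 0.02
#: Flat-interval rule: mean |slope| over the last this-fraction of the beat
#: must fall below FLAT_SLOPE_RATIO times the mean upstroke slope.
FLAT_TAIL_FRACTION = 0.15
FLAT_SLOPE_RATIO = 0.10
#: Beats shorter than this (ms) are rejected outright.
MIN_BEAT_MS = 200.0


@dataclass(frozen=True)
class BeatAnnotation:
    """Fiducial times (ms from trace start) and features of one beat."""

    foot_time: float
    peak_time: float
    notch_time: float | None
    next_foot_time: float
    beat_ust: float
    beat_msa: float
    beat_wavelength: float
    flat_interval: bool = False
    quality_flag: str = "ok"


@dataclass(frozen=True)
class PVRFeatures:
    """Limb-level quantitative summary of a PVR recording.

    For pulsatile traces ``usr == ust / wavelength`` exactly as computed.
    For non-pulsatile traces the time-domain features are undefined (None)
    and ``msa`` is 0.
    """

    pulsatile: bool
    msa: float
    ust: float | None = None
    usr: float | None = None
    wavelength: float | None = None
    n_beats_used: int = 0
    notch_present: bool = False
    flat_interval_present: bool = False
    upstroke_downslope_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.msa < 0:
            raise ValidationError(f"msa must be >= 0, got {self.msa}")
        if self.pulsatile:
            if self.usr is None or not 0 < self.usr < 1:
                raise ValidationError(f"pulsatile features require 0 < usr < 1, got {self.usr}")
        elif self.ust is not None or self.usr is not None or self.wavelength is not None:
            raise ValidationError("non-pulsatile features must leave ust/usr/wavelength unset")


def smooth(trace: PVRTrace, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> PVRTrace:
    """Zero-phase low-pass filter (4th-order Butterworth, filtfilt).

    Preserves DC and the pulse fundamental (~1-2 Hz) while suppressing
    wideband noise.
    """
    fs = 1000.0 / trace.sampling_interval
    if not 0 < cutoff_hz < fs / 2:
        raise ValidationError(f"cutoff_hz must be in (0, Nyquist={fs / 2}), got {cutoff_hz}")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * 2 + 1)  # filtfilt default for 2 second-order sections
    if trace.n_samples <= padlen:
        raise ValidationError(
            f"trace too short to filter: {trace.n_samples} samples <= warm-up {padlen}"
        )
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return PVRTrace(
        samples=filtered,
        sampling_interval=trace.sampling_interval,
        cuff_pressure=trace.cuff_pressure,
        limb_id=trace.limb_id,
        ground_truth=trace.ground_truth,
    )


def _bandpass(trace: PVRTrace, cutoff_hz: float) -> np.ndarray:
    """Drift-free pulse band: low-pass at cutoff minus low-pass at 0.4 Hz."""
    fs = 1000.0 / trace.sampling_interval
    low = signal.butter(4, min(cutoff_hz, 0.45 * fs), btype="low", fs=fs, output="sos")
    base = signal.butter(2, 0.4, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(low, trace.samples)
    return x - signal.sosfiltfilt(base, x)


def detect_pulsatility(
    trace: PVRTrace,
    msa_floor: float = DEFAULT_MSA_FLOOR,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> bool:
    """Decide whether a periodic pulse of meaningful excursion is present.

    True iff the drift-free pulse band shows (a) a peak-to-trough excursion
    (robust 2.5-97.5 percentile spread) of at least ``msa_floor`` and (b) a
    dominant autocorrelation peak at a lag within the plausible heart-period
    range.
    """
    if trace.duration_ms < 3000.0:
        raise ValidationError("pulsatility assessment requires at least 3 s of signal")
    x = _bandpass(trace, cutoff_hz)
    lo, hi = np.percentile(x, [2.5, 97.5])
    if hi - lo < msa_floor:
        return False
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var == 0.0:
        return False
    dt = trace.sampling_interval
    lag_min = int(PERIOD_RANGE_MS[0] / dt)
    lag_max = min(int(PERIOD_RANGE_MS[1] / dt), x.size - 1)
    if lag_max <= lag_min:
        return False
    ac = signal.correlate(x, x, mode="full")[x.size - 1 :]
    ac = ac / var
    return bool(np.max(ac[lag_min : lag_max + 1]) >= 0.3)


def _estimate_period(x: np.ndarray, dt: float) -> float:
    """Dominant period (ms) from the autocorrelation of the pulse band."""
    x = x - x.mean()
    ac = signal.correlate(x, x, mode="full")[x.size - 1 :]
    lag_min = int(PERIOD_RANGE_MS[0] / dt)
    lag_max = min(int(PERIOD_RANGE_MS[1] / dt), x.size - 1)
    lag = lag_min + int(np.argmax(ac[lag_min : lag_max + 1]))
    return lag * dt


@lru_cache(maxsize=8)
def _corner_bases(n: int, slope_jump: bool) -> tuple[np.ndarray, ...]:
    """Orthonormal bases Q(tb) of the corner model, per breakpoint candidate.

    Both variants share the structure "tail meets a convex upstroke onset
    whose slope starts at zero". The ``slope_jump`` variant,
    ``y = a + b min(t, tb) + d relu(t - tb)^2``, models a descending tail
    (slope b < 0) that stops dead at the corner where the parabolic onset
    begins — the slope jump at tb is structurally tied to the tail slope,
    which keeps the corner sharply identified under noise. The no-jump
    variant, ``y = a + b t + d relu(t - tb)^2``, models a flat (or gently
    drifting) interbeat interval running continuously into the onset. The
    least-squares corner is exact on clean waveforms of the matching kind.
    """
    x = np.arange(n, dtype=float)
    qs = []
    for tb in range(3, n - 3):
        r = np.maximum(x - tb, 0.0)
        base = np.minimum(x, tb) if slope_jump else x
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), base, r * r]))
        qs.append(q)
    return tuple(qs)


def _sse_profile(y: np.ndarray, qs: tuple[np.ndarray, ...]) -> np.ndarray:
    """Residual SSE of the corner fit for every breakpoint candidate."""
    yy = float(np.dot(y, y))
    return yy - np.array([float(np.sum((q.T @ y) ** 2)) for q in qs])


@lru_cache(maxsize=8)
def _apex_bases(n: int) -> tuple[np.ndarray, ...]:
    """Orthonormal bases of the two-parabola apex model, per apex candidate.

    ``y = a + cL relu(tb - t)^2 + cR relu(t - tb)^2``: two parabolic flanks
    meeting at the apex. The systolic peak of a pulse is locally of this
    form with distinct flank curvatures, so the least-squares apex is exact
    on clean beats and does not drift toward the flatter flank under noise
    the way a plain argmax does.
    """
    x = np.arange(n, dtype=float)
    qs = []
    for tb in range(3, n - 3):
        left = np.maximum(tb - x, 0.0)
        right = np.maximum(x - tb, 0.0)
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), left * left, right * right]))
        qs.append(q)
    return tuple(qs)


def _refine_apex(y: np.ndarray) -> int:
    return 3 + int(np.argmin(_sse_profile(y, _apex_bases(y.size))))


def _find_feet(
    slope: np.ndarray, light: np.ndarray, dt: float, period_ms: float
) -> tuple[np.ndarray, bool]:
    """Foot indices: the corner where the interbeat tail meets the upstroke.

    The steepest-upslope landmark and the walk-back both run on a
    narrow-band slope signal (noise ripples would stop the walk immediately
    otherwise). The foot is then refined by a corner-model fit on the
    lightly smoothed signal. Waveforms with a flat interbeat interval use
    the no-slope-jump corner model with the fit residuals summed across
    beats (a single common offset — the flat-to-onset corner is shallow and
    a per-beat fit would drift with noise); continuous-descent waveforms
    have a slope discontinuity at the foot and use a per-beat jump-model
    fit.
    """
    min_dist = max(int(0.6 * period_ms / dt), 1)
    # steepest-upslope landmarks, one per beat
    up_peaks, _ = signal.find_peaks(slope, distance=min_dist, height=0.3 * slope.max())
    stops = []
    for u in up_peaks:
        i = u
        while i > 0 and slope[i - 1] > 0:
            i -= 1
        stops.append(i)
    if not stops:
        return np.array([], dtype=int), False

    # flat interbeat tail <=> negligible slope just before the upstroke onset
    tail_slopes = []
    for i in stops:
        if i - 60 >= 0:
            seg = light[i - 60 : i - 20]
            tail_slopes.append(abs(np.polyfit(np.arange(seg.size), seg, 1)[0]))
    flat_tail = bool(tail_slopes) and float(np.median(tail_slopes)) < 0.15 * float(slope.max())

    if flat_tail:
        # centre each window at a small-amplitude threshold crossing rather
        # than at the walk-back stop: with a short flat interval the smeared
        # slope signal stops far from the onset
        half_period = int(0.5 * period_ms / dt)
        centers = []
        for u, stop in zip(up_peaks, stops):
            a = max(u - int(0.8 * half_period), 0)
            b = min(u + half_period, light.size)
            base = float(np.min(light[a : u + 1]))
            peak = float(np.max(light[u:b])) if b > u else base
            thr = base + 0.03 * (peak - base)
            i = u
            while i > a and light[i - 1] > thr:
                i -= 1
            centers.append(i)
        lo_off, hi_off = -55, 40
        qs = _corner_bases(hi_off - lo_off + 1, slope_jump=False)
        total = np.zeros(len(qs))
        n_used = 0
        for i in centers:
            lo, hi = i + lo_off, i + hi_off + 1
            if lo < 0 or hi > light.size:
                continue
            total += _sse_profile(light[lo:hi], qs)
            n_used += 1
        delta = (3 + int(np.argmin(total)) + lo_off) if n_used else 0
        feet = [min(max(i + delta, 0), light.size - 1) for i in centers]
    else:
        half = FOOT_REFINE_HALF
        qs = _corner_bases(2 * half + 1, slope_jump=True)
        feet = []
        for i in stops:
            lo, hi = i - half, i + half + 1
            if lo < 0 or hi > light.size:
                feet.append(i)
                continue
            sse = _sse_profile(light[lo:hi], qs)
            feet.append(lo + 3 + int(np.argmin(sse)))
    return np.unique(feet), flat_tail


def _segmentation(
    trace: PVRTrace, cutoff_hz: float, msa_floor: float
) -> tuple[list[tuple[int, int]], bool]:
    """Foot-to-foot windows plus the trace-level flat-tail flag."""
    if not detect_pulsatility(trace, msa_floor=msa_floor, cutoff_hz=cutoff_hz):
        return [], False
    x = _bandpass(trace, cutoff_hz)
    slope = np.gradient(smooth(trace, FOOT_SLOPE_CUTOFF_HZ).samples)
    light = smooth(trace, REFINE_CUTOFF_HZ).samples
    period = _estimate_period(x, trace.sampling_interval)
    feet, flat_tail = _find_feet(slope, light, trace.sampling_interval, period)
    windows = [(int(a), int(b)) for a, b in zip(feet[:-1], feet[1:])]
    return windows, flat_tail


def segment_beats(
    trace: PVRTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    msa_floor: float = DEFAULT_MSA_FLOOR,
) -> list[tuple[int, int]]:
    """Split a trace into foot-to-foot windows ``[(start, end), ...]``.

    Windows are disjoint, ordered and cover all complete periods. Returns an
    empty list when the trace is non-pulsatile.
    """
    return _segmentation(trace, cutoff_hz, msa_floor)[0]


def detect_fiducials(
    trace: PVRTrace,
    window: tuple[int, int],
    cutoff_hz: float | None = None,
    smoothed: np.ndarray | None = None,
    light: np.ndarray | None = None,
    apex_sig: np.ndarray | None = None,
    flat_tail: bool = True,
) -> BeatAnnotation:
    """Annotate one foot-to-foot window with fiducial points and features.

    peak = global maximum of the window (landmark on the smoothed signal,
    time refined by a two-parabola apex fit); notch = most prominent local
    minimum strictly between the peak and 85% of the window, ignored when
    its prominence is below 2% of the beat amplitude. Amplitudes (MSA) are
    read from the smoothed signal to stay noise-robust.
    """
    start, end = window
    dt = trace.sampling_interval
    if smoothed is None:
        smoothed = smooth(trace, cutoff_hz or DEFAULT_CUTOFF_HZ).samples
    if light is None:
        light = smooth(trace, REFINE_CUTOFF_HZ).samples
    seg = smoothed[start:end]
    wavelength = (end - start) * dt
    if wavelength < MIN_BEAT_MS:
        return BeatAnnotation(
            foot_time=start * dt, peak_time=start * dt, notch_time=None,
            next_foot_time=end * dt, beat_ust=0.0, beat_msa=0.0,
            beat_wavelength=wavelength, quality_flag="rejected",
        )
    peak_rel = int(np.argmax(seg))
    # refine the peak time with the apex fit; waveforms with a sharp peak
    # followed by a dicrotic wave (flat-tail morphology) get a narrow
    # symmetric window on the light signal, flattened waveforms a wider
    # asymmetric one on an extra-smoothed signal to pin the broad shallow
    # flanks under noise
    if flat_tail:
        lo = max(peak_rel - 25, 0)
        hi = min(peak_rel + 26, seg.size)
        sig = light[start + lo : start + hi]
    else:
        if apex_sig is None:
            apex_sig = smooth(trace, APEX_CUTOFF_HZ).samples
        lo = max(peak_rel - 30, 0)
        hi = min(peak_rel + 91, seg.size)
        sig = apex_sig[start + lo : start + hi]
    if sig.size >= 12:
        peak_rel = lo + _refine_apex(sig)
    msa = float(seg[peak_rel] - seg[0])
    if peak_rel == 0 or msa <= 0:
        return BeatAnnotation(
            foot_time=start * dt, peak_time=(start + peak_rel) * dt, notch_time=None,
            next_foot_time=end * dt, beat_ust=peak_rel * dt, beat_msa=max(msa, 0.0),
            beat_wavelength=wavelength, quality_flag="rejected",
        )

    notch_time = None
    hi = int(0.85 * seg.size)
    if hi - peak_rel >= 3:
        desc = seg[peak_rel:hi]
        troughs, props = signal.find_peaks(-desc, prominence=NOTCH_PROMINENCE_FRACTION * msa)
        if troughs.size:
            best = troughs[int(np.argmax(props["prominences"]))]
            notch_time = (start + peak_rel + best) * dt

    # flat-interval rule: mean |slope| over the last 15% of the beat is below
    # 10% of the mean upstroke slope (slope estimated by a line fit, which is
    # noise-robust and equals the mean slope for a monotone tail)
    tail = seg[int((1.0 - FLAT_TAIL_FRACTION) * seg.size) :]
    t_tail = np.arange(tail.size) * dt
    tail_slope = abs(float(np.polyfit(t_tail, tail, 1)[0])) if tail.size >= 3 else np.inf
    upstroke_slope = msa / (peak_rel * dt)
    flat = tail_slope < FLAT_SLOPE_RATIO * upstroke_slope

    return BeatAnnotation(
        foot_time=start * dt,
        peak_time=(start + peak_rel) * dt,
        notch_time=notch_time,
        next_foot_time=end * dt,
        beat_ust=peak_rel * dt,
        beat_msa=msa,
        beat_wavelength=wavelength,
        flat_interval=flat,
        quality_flag="ok",
    )


def annotate_beats(
    trace: PVRTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    msa_floor: float = DEFAULT_MSA_FLOOR,
) -> list[BeatAnnotation]:
    """Segment a trace and annotate every complete beat."""
    windows, flat_tail = _segmentation(trace, cutoff_hz, msa_floor)
    if not windows:
        return []
    smoothed = smooth(trace, cutoff_hz).samples
    light = smooth(trace, REFINE_CUTOFF_HZ).samples
    apex_sig = None if flat_tail else smooth(trace, APEX_CUTOFF_HZ).samples
    return [
        detect_fiducials(
            trace, w, smoothed=smoothed, light=light, apex_sig=apex_sig,
            flat_tail=flat_tail,
        )
        for w in windows
    ]


def extract_features(
    trace: PVRTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    msa_floor: float = DEFAULT_MSA_FLOOR,
    min_beats: int = 3,
) -> PVRFeatures:
    """Compute the limb-level feature summary of a recording.

    Non-pulsatile traces yield ``pulsatile=False`` and ``msa=0``. Otherwise
    per-beat values from quality-accepted beats are summarised by the median;
    ``usr = median_ust / median_wavelength``. At least ``min_beats`` usable
    beats are required.
    """
    beats = annotate_beats(trace, cutoff_hz=cutoff_hz, msa_floor=msa_floor)
    if not beats:
        return PVRFeatures(pulsatile=False, msa=0.0)
    good = [b for b in beats if b.quality_flag == "ok"]
    if len(good) < min_beats:
        raise InsufficientDataError(
            f"pulsatile trace but only {len(good)} usable beats (< {min_beats})"
        )
    ust = float(np.median([b.beat_ust for b in good]))
    wavelength = float(np.median([b.beat_wavelength for b in good]))
    msa = float(np.median([b.beat_msa for b in good]))
    usr = ust / wavelength
    updown = float(np.median([b.beat_ust / (b.beat_wavelength - b.beat_ust) for b in good]))
    notch_frac = np.mean([b.notch_time is not None for b in good])
    flat_frac = np.mean([b.flat_interval for b in good])
    return PVRFeatures(
        pulsatile=True,
        msa=msa,
        ust=ust,
        usr=usr,
        wavelength=wavelength,
        n_beats_used=len(good),
        notch_present=bool(notch_frac >= 0.5),
        flat_interval_present=bool(flat_frac >= 0.5),
        upstroke_downslope_ratio=updown,
    )


class PVRFeatureExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: PVR traces -> quantitative feature table.

    ``transform`` accepts a sequence of :class:`PVRTrace` and returns a
    pandas DataFrame with one row per trace (columns ``limb_id, ust_ms, usr,
    msa_mmhg, wavelength_ms, pulsatile, n_beats_used, notch_present,
    flat_interval_present, upstroke_downslope_ratio``). The extractor is
    stateless; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        cutoff_hz: float = DEFAULT_CUTOFF_HZ,
        msa_floor: float = DEFAULT_MSA_FLOOR,
        min_beats: int = 3,
    ) -> None:
        self.cutoff_hz = cutoff_hz
        self.msa_floor = msa_floor
        self.min_beats = min_beats

    def fit(self, X=None, y=None) -> "PVRFeatureExtractor":
        if not self.cutoff_hz > 0:
            raise ValidationError("cutoff_hz must be > 0")
        if not self.msa_floor >= 0:
            raise ValidationError("msa_floor must be >= 0")
        if self.min_beats < 1:
            raise ValidationError("min_beats must be >= 1")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        import pandas as pd

        self.fit()
        rows = []
        for trace in X:
            f = extract_features(
                trace, cutoff_hz=self.cutoff_hz, msa_floor=self.msa_floor,
                min_beats=self.min_beats,
            )
            rows.append(
                {
                    "limb_id": trace.limb_id,
                    "ust_ms": f.ust,
                    "usr": f.usr,
                    "msa_mmhg": f.msa,
                    "wavelength_ms": f.wavelength,
                    "pulsatile": f.pulsatile,
                    "n_beats_used": f.n_beats_used,
                    "notch_present": f.notch_present,
                    "flat_interval_present": f.flat_interval_present,
                    "upstroke_downslope_ratio": f.upstroke_downslope_ratio,
                }
            )
        return pd.DataFrame(rows)
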