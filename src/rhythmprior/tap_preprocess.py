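"""Turn raw onset streams into matched, filtered, averaged responses.

The pipeline per iteration is:

1. (optional) onset extraction from a mono audio recording: threshold
   crossings at 1.45% of the per-15-s-window maximal power, then merging of
   onsets closer than 80 ms (humans cannot tap that fast);
2. matching of each response onset to its nearest stimulus click, a single
   estimate of the mean asynchrony m, exclusion of responses outside a
   300 ms window centred on the perceptual centre (|(r - m) - s| > 150 ms),
   and at most one response retained per click;
3. cycle-relative averaging of tap times per pattern position, with missing
   taps imputed by the position mean, yielding an averaged three-interval
   response (r1, r2, r3) and a validity flag (each position tapped in at
   least 3 of 10 repetitions, no averaged interval below 285 ms).

All times are milliseconds.  Thresholds (150/285 ms) scale linearly with
the cycle period for the fast-tempo (1,000 ms) variant; the 80 ms merge
gap is a motor limit and does not scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rhythm_space import IntervalPattern

__all__ = [
    "OnsetStream",
    "IterationRecord",
    "stimulus_onsets",
    "extract_onsets",
    "extract_onsets_from_wav",
    "merge_close_onsets",
    "match_taps",
    "average_response",
    "preprocess_stream",
    "repetition_points",
]

REPETITIONS = 10


@dataclass(frozen=True)
class OnsetStream:
    """Stimulus and response onset times (ms) for one iteration."""

    stimulus_onsets: np.ndarray  # 3 * repetitions + 1 onsets, strictly increasing
    response_onsets: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.stimulus_onsets, dtype=float)
        r = np.sort(np.asarray(self.response_onsets, dtype=float))
        if s.ndim != 1 or len(s) < 2 or np.any(np.diff(s) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        object.__setattr__(self, "stimulus_onsets", s)
        object.__setattr__(self, "response_onsets", r)


@dataclass
class IterationRecord:
    """Matched, averaged response for one iteration.

    ``matches`` maps retained responses to stimulus-onset indices;
    ``cycle_times`` is a (repetitions, 3) matrix of cycle-relative tap
    times with NaN for missing taps (index 3*c + k folds to row c,
    column k; the final onset folds beyond the last row and is dropped).
    """

    matches: list[tuple[int, float]] = field(default_factory=list)
    mean_asynchrony: float = float("nan")
    cycle_times: np.ndarray | None = None
    counts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))
    response: np.ndarray | None = None
    valid: bool = False
    reasons: tuple[str, ...] = ()

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def stimulus_onsets(pattern: IntervalPattern, repetitions: int = REPETITIONS) -> np.ndarray:
    """Onset times of ``repetitions`` cycles plus the closing onset."""
    intervals = np.tile(pattern.intervals, repetitions)
    return np.concatenate([[0.0], np.cumsum(intervals)])


def extract_onsets(
    signal: np.ndarray,
    sample_rate: float,
    window_s: float = 15.0,
    threshold_frac: float = 0.0145,
) -> np.ndarray:
    """Onset times (ms) from a mono amplitude sequence.

    The signal is processed in non-overlapping windows of ``window_s``
    seconds; within each window the threshold is ``threshold_frac`` of the
    maximal power (squared amplitude), and onsets are upward threshold
    crossings.  Merging of nearby onsets is a separate step
    (:func:`merge_close_onsets`).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be mono (1-D)")
    if len(x) == 0:
        return np.array([])
    power = x * x
    win = max(1, int(round(window_s * sample_rate)))
    onsets = []
    for start in range(0, len(power), win):
        seg = power[start : start + win]
        peak = seg.max()
        if peak <= 0:
            continue
        above = seg >= threshold_frac * peak
        crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
        onsets.extend((start + crossings) * 1000.0 / sample_rate)
    return np.asarray(onsets)


def extract_onsets_from_wav(path, **kwargs) -> np.ndarray:
    """Onset times (ms) from a mono PCM WAV file."""
    from scipy.io import wavfile

    sample_rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    x = data.astype(float)
    if data.dtype.kind in "iu":
        x = x / np.iinfo(data.dtype).max
    return extract_onsets(x, float(sample_rate), **kwargs)


def merge_close_onsets(onsets: np.ndarray, min_gap: float = 80.0) -> np.ndarray:
    """Greedy left-to-right merge: keep the earliest onset of each cluster."""
    onsets = np.sort(np.asarray(onsets, dtype=float))
    kept: list[float] = []
    for t in onsets:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(float(t))
    return np.asarray(kept)


def match_taps(stream: OnsetStream, window: float = 150.0) -> IterationRecord:
    """Match responses to stimulus clicks; single-pass mean asynchrony.

    Every response is first assigned to its nearest stimulus onset and the
    mean asynchrony m is computed over all initial assignments.  Responses
    with |(r - m) - s| > window are then excluded, and if several survive
    for the same click only the one with the smallest centred asynchrony is
    retained (ties broken toward the earlier tap).
    """
    rec = IterationRecord()
    stim = stream.stimulus_onsets
    resp = stream.response_onsets
    if len(resp) == 0:
        rec.reasons = ("no responses",)
        return rec
    idx = np.clip(np.searchsorted(stim, resp), 1, len(stim) - 1)
    left, right = stim[idx - 1], stim[idx]
    nearest = np.where(resp - left <= right - resp, idx - 1, idx)
    asynchrony = resp - stim[nearest]
    m = float(np.mean(asynchrony))
    rec.mean_asynchrony = m
    centred = np.abs(asynchrony - m)
    keep = centred <= window
    best: dict[int, tuple[float, float]] = {}
    for r, i, c in zip(resp[keep], nearest[keep], centred[keep]):
        i = int(i)
        if i not in best or (c, r) < best[i]:
            best[i] = (float(c), float(r))
    rec.matches = sorted((i, r) for i, (_, r) in best.items())
    if not rec.matches:
        rec.reasons = ("no matched responses",)
    return rec


def average_response(
    rec: IterationRecord,
    stim_onsets: np.ndarray,
    repetitions: int = REPETITIONS,
    response_floor: float = 285.0,
    min_count: int = 3,
) -> IterationRecord:
    """Cycle-relative averaging of matched taps per pattern position.

    Tap times are expressed relative to the start of the cycle containing
    their matched click; missing taps are imputed with the position mean
    (which leaves the mean unchanged).  The averaged response intervals are
    r1 = t1 - t0, r2 = t2 - t1 and r3 = s - (t2 - t0) where s is the
    stimulus cycle duration, so r1 + r2 + r3 == s exactly.  Valid iff every
    position was tapped in at least ``min_count`` repetitions and no
    averaged interval falls below ``response_floor``.
    """
    period = float(stim_onsets[3] - stim_onsets[0])
    times = np.full((repetitions, 3), np.nan)
    for i, r in rec.matches:
        cycle, pos = divmod(i, 3)
        if cycle >= repetitions:  # closing onset of the sequence
            continue
        times[cycle, pos] = r - stim_onsets[3 * cycle]
    rec.cycle_times = times
    rec.counts = np.sum(~np.isnan(times), axis=0)
    reasons = list(rec.reasons)
    if np.any(rec.counts < min_count):
        reasons.append("insufficient taps")
    if np.all(rec.counts > 0):
        t = np.nanmean(times, axis=0)
        resp = np.array([t[1] - t[0], t[2] - t[1], period - (t[2] - t[0])])
        rec.response = resp
        if resp.min() < response_floor:
            reasons.append("interval below floor")
    rec.valid = not reasons
    rec.reasons = tuple(reasons)
    return rec


def preprocess_stream(
    stream: OnsetStream,
    repetitions: int = REPETITIONS,
    match_window: float = 150.0,
    response_floor: float = 285.0,
    min_count: int = 3,
) -> IterationRecord:
    """Matching plus averaging for one iteration."""
    rec = match_taps(stream, window=match_window)
    return average_response(
        rec,
        stream.stimulus_onsets,
        repetitions=repetitions,
        response_floor=response_floor,
        min_count=min_count,
    )


def repetition_points(rec: IterationRecord, period: float) -> np.ndarray:
    """Per-repetition proportion triples from the cycle-time matrix.

    Missing taps are imputed with the position mean; cycles with no
    detected tap at all are dropped (they would merely duplicate the mean).
    Each retained cycle yields intervals (t1-t0, t2-t1, s-(t2-t0)) which
    are normalized to proportions.
    """
    if rec.cycle_times is None:
        return np.empty((0, 3))
    times = rec.cycle_times.copy()
    produced = np.any(~np.isnan(times), axis=1)
    if not produced.any() or np.any(np.all(np.isnan(times), axis=0)):
        return np.empty((0, 3))
    col_mean = np.nanmean(times, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(times))
    times[nan_r, nan_c] = col_mean[nan_c]
    times = times[produced]
    intervals = np.column_stack(
        [
            times[:, 1] - times[:, 0],
            times[:, 2] - times[:, 1],
            period - (times[:, 2] - times[:, 0]),
        ]
    )
    return intervals / period
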