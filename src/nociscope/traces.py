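"""Fluorescence trace processing: annulus background correction, dF/F, and
calcium-transient detection.

The detection rules mirror standard practice for GCaMP population imaging at
5 Hz: a transient is a local maximum satisfying a minimum prominence, a
minimum absolute peak height, and a minimum inter-peak interval, its
amplitude being the difference between the peak and its preceding local
minimum.  Defaults: 4% dF/F prominence, 4% absolute peak and 0.6 s spacing
for spontaneous activity; 5% prominence with an onset-in-window gate for
heat responses; 5% prominence / 20% absolute height for time-locked brush
responses.

Detection never crosses episode boundaries: each episode is processed
independently, and peaks at the first or last sample of an episode are
ineligible (their prominence is undefined at the edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences


class TraceError(ValueError):
    """Raised for invalid trace inputs (length mismatch, bad baseline, ...)."""


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for transient detection, all in % dF/F and seconds."""

    min_prominence: float = 4.0
    min_abs_peak: float = 4.0
    min_interpeak: float = 0.6
    onset_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("min_prominence", "min_abs_peak", "min_interpeak"):
            if getattr(self, name) < 0:
                raise TraceError(f"{name} must be >= 0")

    def replace(self, **kw) -> "DetectionParams":
        return replace(self, **kw)


#: spontaneous-activity rules: 4% prominence, 4% absolute peak, 0.6 s spacing
SPONTANEOUS_PARAMS = DetectionParams(4.0, 4.0, 0.6)
#: heat-response rules: 5% prominence, 0.6 s spacing (onset gate added per event)
HEAT_PARAMS = DetectionParams(5.0, 0.0, 0.6)
#: brush time-locking rules: 5% prominence, 20% absolute peak height
BRUSH_PARAMS = DetectionParams(5.0, 20.0, 0.6)


@dataclass(frozen=True)
class Transient:
    """A detected calcium event.

    ``amplitude`` is peak minus the preceding local minimum (the onset);
    ``end_time`` is the first post-peak sample at which the trace falls below
    10% of the amplitude above the onset baseline (episode end if never).
    """

    peak_time: float
    peak_height: float
    prominence: float
    amplitude: float
    onset_time: float
    end_time: float
    peak_index: int
    onset_index: int
    end_index: int
    episode: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise TraceError("transient amplitude must be >= 0")
        if not (self.onset_time <= self.peak_time <= self.end_time):
            raise TraceError("transient requires onset <= peak <= end")


# ---------------------------------------------------------------------------
# background correction and dF/F
# ---------------------------------------------------------------------------

def subtract_background(f_cell: np.ndarray, f_annulus: np.ndarray, r: float = 1.0) -> np.ndarray:
    """Remove out-of-focus/neighbour contamination using the surrounding annulus.

    ``corrected(t) = f_cell(t) - r * (f_annulus(t) - median(f_annulus))``.

    The annulus is median re-centred so subtraction removes its fluctuation
    without shifting the absolute brightness that the later dF/F baseline
    relies on.  ``r`` scales the contamination (default 1.0).
    """
    f_cell = np.asarray(f_cell, dtype=float)
    f_annulus = np.asarray(f_annulus, dtype=float)
    if f_cell.shape != f_annulus.shape:
        raise TraceError(
            f"cell and annulus series differ in length ({f_cell.shape} vs {f_annulus.shape})"
        )
    if r < 0:
        raise TraceError("background scale r must be >= 0")
    return f_cell - r * (f_annulus - np.median(f_annulus))


def compute_dff(
    f: np.ndarray,
    episode_ids: np.ndarray | None = None,
    method: str = "percentile",
    percentile: float = 10.0,
    prestim_samples: int | None = None,
    cell_id: str = "?",
) -> np.ndarray:
    """Convert corrected fluorescence to dF/F in percent.

    F0 is estimated per episode: the ``percentile``-th percentile (default
    10th, robust to activity) or, with ``method='prestim_mean'``, the mean of
    the first ``prestim_samples`` samples of each episode.
    """
    f = np.asarray(f, dtype=float)
    if episode_ids is None:
        episode_ids = np.zeros(f.shape, dtype=int)
    episode_ids = np.asarray(episode_ids)
    if episode_ids.shape != f.shape:
        raise TraceError("episode_ids must match trace length")
    dff = np.empty_like(f)
    for ep in np.unique(episode_ids):
        sel = episode_ids == ep
        seg = f[sel]
        if method == "percentile":
            f0 = float(np.percentile(seg, percentile))
        elif method == "prestim_mean":
            n = prestim_samples if prestim_samples is not None else max(1, seg.size // 4)
            f0 = float(np.mean(seg[:n]))
        else:
            raise TraceError(f"unknown baseline method {method!r}")
        if f0 <= 0:
            raise TraceError(f"cell {cell_id}: non-positive baseline F0={f0:g} in episode {ep}")
        dff[sel] = 100.0 * (seg - f0) / f0
    return dff


# ---------------------------------------------------------------------------
# transient detection
# ---------------------------------------------------------------------------

def _interpeak_samples(min_interpeak: float, fs: float) -> int:
    # seconds -> samples, rounding half-up (0.6 s at 5 Hz -> 3 samples)
    return int(np.floor(min_interpeak * fs + 0.5))


def _preceding_minimum(x: np.ndarray, p: int) -> int:
    """Index of the preceding local minimum: walk back down the rising edge."""
    i = p
    while i > 0 and x[i - 1] < x[i]:
        i -= 1
    return i


def _response_end(x: np.ndarray, p: int, onset: int) -> int:
    """First post-peak sample below 10% of the amplitude above onset baseline."""
    base = x[onset]
    thresh = base + 0.1 * (x[p] - base)
    for j in range(p + 1, x.size):
        if x[j] < thresh:
            return j
    return x.size - 1


def _detect_episode(x: np.ndarray, fs: float, params: DetectionParams) -> list[tuple]:
    """Candidates within one episode as (peak, onset, end, prominence) indices."""
    if x.size < 3:
        return []
    peaks, _ = find_peaks(x)
    if peaks.size == 0:
        return []
    prom = peak_prominences(x, peaks)[0]
    keep = (prom >= params.min_prominence) & (x[peaks] >= params.min_abs_peak)
    peaks, prom = peaks[keep], prom[keep]
    # enforce inter-peak spacing: keep higher prominence first, then earlier peak
    spacing = _interpeak_samples(params.min_interpeak, fs)
    order = sorted(range(peaks.size), key=lambda k: (-prom[k], peaks[k]))
    kept: list[int] = []
    for k in order:
        if all(abs(int(peaks[k]) - int(peaks[j])) >= spacing for j in kept):
            kept.append(k)
    out = []
    for k in sorted(kept, key=lambda k: peaks[k]):
        p = int(peaks[k])
        o = _preceding_minimum(x, p)
        e = _response_end(x, p, o)
        out.append((p, o, e, float(prom[k])))
    return out


def detect_transients(
    dff: np.ndarray,
    fs: float = 5.0,
    episode_ids: np.ndarray | None = None,
    params: DetectionParams = SPONTANEOUS_PARAMS,
    t: np.ndarray | None = None,
) -> list[Transient]:
    """Detect calcium transients in a uniformly sampled dF/F trace.

    Returns transients sorted by peak time.  If ``params.onset_window`` is
    set, only transients whose onset (preceding minimum) lies inside the
    window (inclusive) are kept.  ``t`` supplies sample times; by default
    ``t[i] = i / fs``.  Raises :class:`TraceError` for non-uniform sampling.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size == 0:
        return []
    if not np.all(np.isfinite(dff)):
        raise TraceError("trace contains non-finite values")
    if t is None:
        t = np.arange(dff.size) / fs
    else:
        t = np.asarray(t, dtype=float)
        if t.shape != dff.shape:
            raise TraceError("t must match trace length")
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise TraceError("non-uniform sampling")
    if episode_ids is None:
        episode_ids = np.zeros(dff.shape, dtype=int)
    episode_ids = np.asarray(episode_ids)

    out: list[Transient] = []
    for ep in np.unique(episode_ids):
        sel = np.flatnonzero(episode_ids == ep)
        start = int(sel[0])
        x = dff[sel]
        for p, o, e, prom in _detect_episode(x, fs, params):
            tr = Transient(
                peak_time=float(t[start + p]),
                peak_height=float(x[p]),
                prominence=prom,
                amplitude=float(x[p] - x[o]),
                onset_time=float(t[start + o]),
                end_time=float(t[start + e]),
                peak_index=start + p,
                onset_index=start + o,
                end_index=start + e,
                episode=int(ep),
            )
            if params.onset_window is not None:
                lo, hi = params.onset_window
                if not (lo <= tr.onset_time <= hi):
                    continue
            out.append(tr)
    out.sort(key=lambda tr: tr.peak_time)
    return out


def spontaneous_activity(
    dff: np.ndarray,
    windows: Sequence[tuple[float, float]],
    fs: float = 5.0,
    episode_ids: np.ndarray | None = None,
    params: DetectionParams = SPONTANEOUS_PARAMS,
    required_duration: float | None = None,
    t: np.ndarray | None = None,
) -> float:
    """Summed amplitude (% dF/F) of transients peaking in unstimulated windows.

    Windows are concatenated up to ``required_duration`` (105 s for
    trigeminal, 40 s for DRG recordings): surplus time is trimmed from the
    last windows so every cell is scored over the same total duration, and a
    shortfall triggers a warning reporting the actual duration used.
    """
    windows = [(float(a), float(b)) for a, b in windows]
    total = sum(b - a for a, b in windows)
    if required_duration is not None:
        if total < required_duration - 1e-9:
            warnings.warn(
                f"unstimulated windows cover {total:g}s "
                f"< required {required_duration:g}s; using actual duration",
                stacklevel=2,
            )
        elif total > required_duration:
            clipped: list[tuple[float, float]] = []
            remaining = required_duration
            for a, b in windows:
                if remaining <= 0:
                    break
                take = min(b - a, remaining)
                clipped.append((a, a + take))
                remaining -= take
            windows = clipped
    transients = detect_transients(dff, fs=fs, episode_ids=episode_ids, params=params, t=t)
    return float(
        sum(tr.amplitude for tr in transients if any(a <= tr.peak_time <= b for a, b in windows))
    )


def transients_to_records(cell_id: str, transients: Sequence[Transient]) -> list[dict]:
    """Rows for the transients CSV (one per detected event)."""
    return [
        {
            "cell_id": cell_id,
            "peak_time_s": tr.peak_time,
            "peak_pct": tr.peak_height,
            "prominence_pct": tr.prominence,
            "amplitude_pct": tr.amplitude,
            "onset_s": tr.onset_time,
            "end_s": tr.end_time,
        }
        for tr in transients
    ]


# ---------------------------------------------------------------------------
# pixelwise activity maps
# ---------------------------------------------------------------------------

def activity_maps(
    stack: np.ndarray,
    sd_window: tuple[int, int],
    before_window: tuple[int, int],
    during_window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel activity maps from a T x H x W image stack.

    Mechanical activity: standard deviation over time of each pixel across
    ``sd_window``.  Heat activity: mean during stimulation minus mean before
    (``during_window`` minus ``before_window``).  Windows are frame-index
    ranges, right-open.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise TraceError("stack must be T x H x W")
    for name, (a, b) in (
        ("sd_window", sd_window),
        ("before_window", before_window),
        ("during_window", during_window),
    ):
        if not (0 <= a < b <= stack.shape[0]):
            raise TraceError(f"{name} ({a}, {b}) empty or outside stack of {stack.shape[0]} frames")
    sd_map = stack[sd_window[0] : sd_window[1]].std(axis=0)
    diff_map = stack[during_window[0] : during_window[1]].mean(axis=0) - stack[
        before_window[0] : before_window[1]
    ].mean(axis=0)
    return sd_map, diff_map
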