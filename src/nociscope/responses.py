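"""Stimulus-locked response scoring.

Heat: transients detected at 5% prominence whose onset (preceding minimum)
falls inside the stimulation window; the response runs from that onset to
the first sample below 10% of the peak amplitude above the onset baseline;
the area under the dF/F curve over that span (trapezoidal, baseline-
anchored) quantifies the response, and a cell is responsive if the AUC
strictly exceeds a minimum corresponding to a mean of 3.5% dF/F over the
stimulation window (14 %*s for a 4-s pulse).

Mechanical: a cell is mechanosensitive if its peak transient amplitude
during the application window strictly exceeds 15% dF/F.

Brush: a response is time-locked if a peak with >=5% prominence and >=20%
absolute height occurs within 1 s of application; a bona fide brush cell
responds to at least 50% of brushes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .protocol import StimulusEvent
from .traces import (
    BRUSH_PARAMS,
    HEAT_PARAMS,
    SPONTANEOUS_PARAMS,
    DetectionParams,
    TraceError,
    Transient,
    detect_transients,
)

#: mean dF/F over the stimulation window that the AUC must exceed (% dF/F)
HEAT_MEAN_THRESHOLD = 3.5
#: peak amplitude a mechanical response must exceed (% dF/F)
MECH_AMPLITUDE_THRESHOLD = 15.0
#: window after brush application within which a time-locked peak must occur (s)
BRUSH_LOCK_WINDOW = 1.0
# absolute guard for strict ">" threshold comparisons: an AUC equal to the
# threshold up to float rounding must not count as exceeding it
_STRICT_EPS = 1e-9


@dataclass(frozen=True)
class ResponseRecord:
    """Scored response of one cell to one stimulus event."""

    cell_id: str
    event_id: str
    modality: str
    auc: float
    peak_amplitude: float
    responsive: bool
    temperature: float | None = None
    time_locked: bool | None = None
    onset_time: float | None = None
    end_time: float | None = None

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise TraceError("response AUC must be >= 0")


def _check_support(t: np.ndarray, event: StimulusEvent) -> None:
    if event.onset < t[0] - 1e-9 or event.end > t[-1] + 1e-9:
        raise TraceError(
            f"event {event.event_id} ([{event.onset}, {event.end}]s) outside "
            f"trace support [{t[0]:g}, {t[-1]:g}]s"
        )


def window_auc(
    t: np.ndarray, dff: np.ndarray, start: float, end: float, baseline: float = 0.0
) -> float:
    """Trapezoidal area of ``max(dff - baseline, 0)`` over ``start <= t <= end``."""
    sel = (t >= start - 1e-9) & (t <= end + 1e-9)
    if sel.sum() < 2:
        return 0.0
    y = np.maximum(np.asarray(dff, dtype=float)[sel] - baseline, 0.0)
    return float(np.trapezoid(y, np.asarray(t, dtype=float)[sel]))


def is_heat_responsive(auc: float, duration: float, mean_threshold: float = HEAT_MEAN_THRESHOLD) -> bool:
    """Strict ">" comparison of the AUC against ``mean_threshold * duration``."""
    return auc > mean_threshold * duration + _STRICT_EPS


def _merged_span(main: Transient, others: Sequence[Transient]) -> tuple[float, float]:
    """Union of qualifying spans transitively overlapping the scored peak."""
    spans = sorted([(tr.onset_time, tr.end_time) for tr in others] + [(main.onset_time, main.end_time)])
    lo, hi = main.onset_time, main.end_time
    changed = True
    while changed:
        changed = False
        for a, b in spans:
            if a <= hi and lo <= b and (a < lo or b > hi):
                lo, hi = min(lo, a), max(hi, b)
                changed = True
    return lo, hi


def heat_response(
    t: np.ndarray,
    dff: np.ndarray,
    event: StimulusEvent,
    fs: float = 5.0,
    episode_ids: np.ndarray | None = None,
    params: DetectionParams = HEAT_PARAMS,
    mean_threshold: float = HEAT_MEAN_THRESHOLD,
    cell_id: str = "?",
) -> ResponseRecord:
    """Score one heat pulse; see module docstring for the rules."""
    if event.modality != "heat":
        raise TraceError(f"heat_response requires a heat event, got {event.modality}")
    t = np.asarray(t, dtype=float)
    _check_support(t, event)
    gated = params.replace(onset_window=(event.onset, event.end))
    transients = detect_transients(dff, fs=fs, episode_ids=episode_ids, params=gated, t=t)
    if not transients:
        return ResponseRecord(
            cell_id, event.event_id, "heat", auc=0.0, peak_amplitude=0.0,
            responsive=False, temperature=event.temperature,
        )
    main = max(transients, key=lambda tr: tr.amplitude)
    lo, hi = _merged_span(main, [tr for tr in transients if tr is not main])
    baseline = float(np.asarray(dff, dtype=float)[main.onset_index])
    auc = window_auc(t, dff, lo, hi, baseline=baseline)
    return ResponseRecord(
        cell_id,
        event.event_id,
        "heat",
        auc=auc,
        peak_amplitude=main.amplitude,
        responsive=is_heat_responsive(auc, event.duration, mean_threshold),
        temperature=event.temperature,
        onset_time=lo,
        end_time=hi,
    )


def mech_response(
    t: np.ndarray,
    dff: np.ndarray,
    event: StimulusEvent,
    fs: float = 5.0,
    episode_ids: np.ndarray | None = None,
    params: DetectionParams = SPONTANEOUS_PARAMS,
    amplitude_threshold: float = MECH_AMPLITUDE_THRESHOLD,
    cell_id: str = "?",
) -> ResponseRecord:
    """Score a pinch or brush for mechanosensitivity (peak amplitude > 15%)."""
    if event.modality not in ("pinch", "brush"):
        raise TraceError(f"mech_response requires pinch/brush, got {event.modality}")
    t = np.asarray(t, dtype=float)
    _check_support(t, event)
    transients = detect_transients(dff, fs=fs, episode_ids=episode_ids, params=params, t=t)
    in_window = [tr for tr in transients if event.onset <= tr.peak_time <= event.end]
    peak_amp = max((tr.amplitude for tr in in_window), default=0.0)
    if in_window:
        main = max(in_window, key=lambda tr: tr.amplitude)
        baseline = float(np.asarray(dff, dtype=float)[main.onset_index])
    else:
        sel = np.flatnonzero(t >= event.onset - 1e-9)
        baseline = float(np.asarray(dff, dtype=float)[sel[0]]) if sel.size else 0.0
    auc = window_auc(t, dff, event.onset, event.end, baseline=baseline)
    return ResponseRecord(
        cell_id,
        event.event_id,
        event.modality,
        auc=auc,
        peak_amplitude=float(peak_amp),
        responsive=peak_amp > amplitude_threshold,
    )


def brush_response(
    t: np.ndarray,
    dff: np.ndarray,
    event: StimulusEvent,
    fs: float = 5.0,
    episode_ids: np.ndarray | None = None,
    params: DetectionParams = BRUSH_PARAMS,
    lock_window: float = BRUSH_LOCK_WINDOW,
    cell_id: str = "?",
) -> ResponseRecord:
    """Score one brush for a time-locked response within 1 s of application."""
    if event.modality != "brush":
        raise TraceError(f"brush_response requires a brush event, got {event.modality}")
    t = np.asarray(t, dtype=float)
    _check_support(t, event)
    transients = detect_transients(dff, fs=fs, episode_ids=episode_ids, params=params, t=t)
    locked = [
        tr for tr in transients if event.onset <= tr.peak_time <= event.onset + lock_window
    ]
    peak_amp = max((tr.amplitude for tr in locked), default=0.0)
    auc = window_auc(
        t, dff, event.onset, event.onset + lock_window,
        baseline=float(np.asarray(dff, dtype=float)[np.searchsorted(t, event.onset - 1e-9)]),
    )
    return ResponseRecord(
        cell_id,
        event.event_id,
        "brush",
        auc=auc,
        peak_amplitude=float(peak_amp),
        responsive=bool(locked),
        time_locked=bool(locked),
    )


def is_brush_cell(brush_records: Sequence[ResponseRecord]) -> bool:
    """A bona fide brush cell responds (time-locked) to at least 50% of brushes."""
    if not brush_records:
        raise TraceError("is_brush_cell requires at least one scored brush")
    locked = sum(1 for r in brush_records if r.time_locked)
    return locked / len(brush_records) >= 0.5
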