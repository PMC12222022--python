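"""Stimulus protocols for in vivo somatosensory imaging sessions.

A recording session is a sequence of fixed-length episodes (40 s at 5 Hz by
default) during which the skin is held at a baseline temperature (30 degC)
and stimulated with brush strokes, pinches, 4-s heat pulses at a configured
temperature set, or chemical injections.  Unstimulated windows are reserved
for scoring spontaneous activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

MODALITIES = ("brush", "pinch", "heat", "chemical")

#: heat pulse temperatures used throughout (degC)
DEFAULT_TEMPERATURES = (37.0, 39.0, 42.0, 45.0, 50.0)


class ProtocolError(ValueError):
    """Raised when a protocol or protocol config is invalid."""


@dataclass(frozen=True)
class StimulusEvent:
    """One timed stimulus: modality, onset/duration in seconds from session start."""

    event_id: str
    modality: str
    onset: float
    duration: float
    temperature: float | None = None
    site: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ProtocolError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.onset < 0:
            raise ProtocolError(f"event {self.event_id}: onset must be >= 0")
        if self.duration <= 0:
            raise ProtocolError(f"event {self.event_id}: duration must be > 0")
        if self.modality == "heat" and self.temperature is None:
            raise ProtocolError(f"heat event {self.event_id} must carry a temperature")
        if self.modality != "heat" and self.temperature is not None:
            raise ProtocolError(
                f"{self.modality} event {self.event_id} must not carry a temperature"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def overlaps(self, other: "StimulusEvent") -> bool:
        return self.onset < other.end and other.onset < self.end


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus events plus episode structure and unstimulated windows."""

    events: tuple[StimulusEvent, ...]
    n_episodes: int
    episode_len: float = 40.0
    sampling_rate: float = 5.0
    baseline_temperature: float = 30.0
    unstimulated_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.onset)))
        object.__setattr__(
            self, "unstimulated_windows", tuple(tuple(w) for w in self.unstimulated_windows)
        )
        self.validate()

    # -- derived structure ------------------------------------------------
    @property
    def total_duration(self) -> float:
        return self.n_episodes * self.episode_len

    @property
    def episode_boundaries(self) -> tuple[float, ...]:
        return tuple(i * self.episode_len for i in range(self.n_episodes + 1))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    def episode_of(self, t: float) -> int:
        """Index of the episode containing time ``t`` (right-open intervals)."""
        if not 0 <= t < self.total_duration:
            raise ProtocolError(f"time {t} outside session [0, {self.total_duration})")
        return min(int(t // self.episode_len), self.n_episodes - 1)

    def episodes_of_event(self, event: StimulusEvent) -> tuple[int, ...]:
        """Episodes an event overlaps, by direct interval intersection."""
        out = []
        for i in range(self.n_episodes):
            lo, hi = i * self.episode_len, (i + 1) * self.episode_len
            if event.onset < hi and lo < event.end:
                out.append(i)
        return tuple(out)

    def heat_events(self) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.modality == "heat")

    def events_of(self, modality: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.modality == modality)

    @property
    def unstimulated_duration(self) -> float:
        return sum(b - a for a, b in self.unstimulated_windows)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_episodes < 1:
            raise ProtocolError("protocol needs at least one episode")
        if self.episode_len <= 0 or self.sampling_rate <= 0:
            raise ProtocolError("episode_len and sampling_rate must be > 0")
        by_modality: dict[str, list[StimulusEvent]] = {}
        for e in self.events:
            if e.end > self.total_duration + 1e-9:
                raise ProtocolError(
                    f"event {e.event_id} ends at {e.end:.1f}s, beyond the "
                    f"{self.total_duration:.1f}s session"
                )
            by_modality.setdefault(e.modality, []).append(e)
        for modality, evs in by_modality.items():
            for a, b in zip(evs, evs[1:]):
                if a.overlaps(b):
                    raise ProtocolError(
                        f"overlapping {modality} events: {a.event_id} "
                        f"([{a.onset}, {a.end}]s) and {b.event_id} ([{b.onset}, {b.end}]s)"
                    )
        for lo, hi in self.unstimulated_windows:
            if not 0 <= lo < hi <= self.total_duration + 1e-9:
                raise ProtocolError(f"unstimulated window ({lo}, {hi}) outside session")
            for e in self.events:
                if e.onset < hi and lo < e.end:
                    raise ProtocolError(
                        f"unstimulated window ({lo}, {hi}) contains event {e.event_id}"
                    )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "episode_len_s": self.episode_len,
            "n_episodes": self.n_episodes,
            "sampling_hz": self.sampling_rate,
            "baseline_temperature_c": self.baseline_temperature,
            "unstimulated_windows_s": [list(w) for w in self.unstimulated_windows],
            "events": [
                {
                    "event_id": e.event_id,
                    "modality": e.modality,
                    "onset_s": e.onset,
                    "duration_s": e.duration,
                    "temperature_c": e.temperature,
                    "site": e.site,
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        events = tuple(
            StimulusEvent(
                event_id=str(e["event_id"]),
                modality=e["modality"],
                onset=float(e["onset_s"]),
                duration=float(e["duration_s"]),
                temperature=None if e.get("temperature_c") is None else float(e["temperature_c"]),
                site=e.get("site", ""),
            )
            for e in d["events"]
        )
        return cls(
            events=events,
            n_episodes=int(d["n_episodes"]),
            episode_len=float(d["episode_len_s"]),
            sampling_rate=float(d["sampling_hz"]),
            baseline_temperature=float(d.get("baseline_temperature_c", 30.0)),
            unstimulated_windows=tuple(
                (float(a), float(b)) for a, b in d.get("unstimulated_windows_s", [])
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters from which :func:`make_protocol` lays out a session.

    The default values reproduce the mechanical + thermal regime: a series of
    brushes, a series of pinches, and one 4-s heat pulse per temperature in
    ``temperatures``, with inter-stimulus baseline holds at 30 degC and
    enough unstimulated episodes for spontaneous-activity scoring
    (105 s for trigeminal recordings).
    """

    episode_len: float = 40.0
    sampling_rate: float = 5.0
    baseline_temperature: float = 30.0
    spontaneous_duration: float = 105.0
    n_brushes: int = 10
    brush_duration: float = 1.0
    brush_spacing: float = 4.0
    n_pinches: int = 5
    pinch_duration: float = 2.0
    pinch_spacing: float = 6.0
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    heat_duration: float = 4.0
    heat_lead_in: float = 10.0  # seconds of baseline before each heat pulse
    site: str = "cheek"

    def replace(self, **kw) -> "ProtocolConfig":
        return replace(self, **kw)


def regime_mech_and_heat() -> ProtocolConfig:
    """Full mechanical + thermal characterization session."""
    return ProtocolConfig()


def regime_mech_only() -> ProtocolConfig:
    """Mechanical sensitization session (brush/pinch only, no heat)."""
    return ProtocolConfig(temperatures=())


def regime_pinch_and_heat() -> ProtocolConfig:
    """Thermal sensitization session (pinch series + heat, no brush)."""
    return ProtocolConfig(n_brushes=0)


def make_protocol(config: ProtocolConfig | None = None) -> StimulusProtocol:
    """Lay out a session from ``config``.

    Episodes are allocated in order: unstimulated episodes (covering
    ``spontaneous_duration``), brush episodes, pinch episodes, then one
    episode per heat temperature with the pulse after ``heat_lead_in``
    seconds of baseline.  Raises :class:`ProtocolError` for colliding events.
    """
    cfg = config or ProtocolConfig()
    events: list[StimulusEvent] = []
    ep_len = cfg.episode_len

    n_unstim = math.ceil(cfg.spontaneous_duration / ep_len) if cfg.spontaneous_duration > 0 else 0
    windows = [(i * ep_len, (i + 1) * ep_len) for i in range(n_unstim)]
    t = n_unstim * ep_len

    def _series(n: int, duration: float, spacing: float, modality: str, start: float) -> float:
        onset = start
        for i in range(n):
            events.append(
                StimulusEvent(
                    event_id=f"{modality}_{i:02d}",
                    modality=modality,
                    onset=onset,
                    duration=duration,
                    site=cfg.site,
                )
            )
            onset += spacing
        if n == 0:
            return start
        block_end = events[-1].end
        return math.ceil(block_end / ep_len) * ep_len  # next episode boundary

    t = _series(cfg.n_brushes, cfg.brush_duration, cfg.brush_spacing, "brush", t)
    t = _series(cfg.n_pinches, cfg.pinch_duration, cfg.pinch_spacing, "pinch", t)

    for i, temp in enumerate(cfg.temperatures):
        onset = t + i * ep_len + cfg.heat_lead_in
        events.append(
            StimulusEvent(
                event_id=f"heat_{temp:g}c",
                modality="heat",
                onset=onset,
                duration=cfg.heat_duration,
                temperature=float(temp),
                site=cfg.site,
            )
        )
    t += len(cfg.temperatures) * ep_len

    n_episodes = max(1, int(round(t / ep_len)))
    if events:
        n_episodes = max(n_episodes, math.ceil(max(e.end for e in events) / ep_len))
    return StimulusProtocol(
        events=tuple(events),
        n_episodes=n_episodes,
        episode_len=ep_len,
        sampling_rate=cfg.sampling_rate,
        baseline_temperature=cfg.baseline_temperature,
        unstimulated_windows=tuple(windows),
    )
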