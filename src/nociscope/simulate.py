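"""Ground-truthed synthetic data emulating in vivo ganglion imaging sessions.

The generator produces everything the analysis pipeline consumes, with known
ground truth: GCaMP-like dF/F traces (difference-of-exponentials transients,
fast rise / slow decay, additive Gaussian noise), class-specific heat and
mechanical tuning across ten sensory-neuron classes, PGE2-induced
spontaneous firing and heat sensitization in select nociceptor classes,
Trpv1-knockout attenuation of heat responses, noisy ternary expression
panels, and smoothly deformed guide-post fields for registration.

Tuning profiles are direction-correct defaults, not fitted magnitudes: LTMRs
are mechanically tuned and heat-insensitive, peptidergic and non-peptidergic
C-nociceptors are graded across the 37-50 degC range, and only
Adelta-NOC/PEP/NP2A/NP3 develop spontaneous activity after PGE2.  Tests
assert recovery of these configured effects, never literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import SimilarityParams
from .classify import CLASSES, PANEL, canonical_pattern, categorize, LEVELS
from .protocol import StimulusProtocol


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tuning profiles
# ---------------------------------------------------------------------------

DEFAULT_TEMPS = (37.0, 39.0, 42.0, 45.0, 50.0)
#: relative heat-response amplitude by temperature (graded recruitment)
DEFAULT_TEMP_SCALING = {37.0: 0.6, 39.0: 0.7, 42.0: 0.8, 45.0: 0.9, 50.0: 1.0}


@dataclass(frozen=True)
class ClassTuningProfile:
    """Generative tuning of one transcriptomic class.

    Rates are events/min; gains are peak dF/F in percent.
    ``warm_sensitization_gain`` multiplies heat amplitudes after PGE2;
    ``trpv1_dependence`` is the fraction of the heat response lost in the
    knockout.
    """

    class_label: str
    p_heat_by_temp: Mapping[float, float]
    heat_gain: float
    p_pinch: float
    p_brush: float
    mech_gain: float
    spont_rate_baseline: float
    spont_rate_pge2: float
    warm_sensitization_gain: float = 1.0
    trpv1_dependence: float = 0.0
    temp_scaling: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMP_SCALING)
    )

    def __post_init__(self) -> None:
        probs = list(self.p_heat_by_temp.values()) + [self.p_pinch, self.p_brush]
        if any(not 0 <= p <= 1 for p in probs):
            raise SimulationError(f"{self.class_label}: probabilities must lie in [0, 1]")
        if self.spont_rate_baseline < 0 or self.spont_rate_pge2 < 0:
            raise SimulationError(f"{self.class_label}: rates must be >= 0")
        if self.heat_gain < 0 or self.mech_gain < 0 or self.warm_sensitization_gain < 0:
            raise SimulationError(f"{self.class_label}: gains must be >= 0")
        if not 0 <= self.trpv1_dependence <= 1:
            raise SimulationError(f"{self.class_label}: trpv1_dependence must lie in [0, 1]")

    def replace(self, **kw) -> "ClassTuningProfile":
        return replace(self, **kw)


def _heat(p37, p39, p42, p45, p50):
    return {37.0: p37, 39.0: p39, 42.0: p42, 45.0: p45, 50.0: p50}


DEFAULT_PROFILES: dict[str, ClassTuningProfile] = {
    "Abeta-LTMR": ClassTuningProfile(
        "Abeta-LTMR", _heat(0, 0, 0, 0, 0), 0.0, 0.6, 0.95, 55.0, 0.02, 0.02
    ),
    "Adelta-LTMR": ClassTuningProfile(
        "Adelta-LTMR", _heat(0, 0, 0, 0, 0), 0.0, 0.6, 0.9, 50.0, 0.02, 0.02
    ),
    "C-LTMR": ClassTuningProfile(
        "C-LTMR", _heat(0, 0, 0, 0, 0), 0.0, 0.5, 0.85, 45.0, 0.02, 0.02
    ),
    "TRPM8": ClassTuningProfile(
        "TRPM8", _heat(0, 0, 0, 0, 0), 0.0, 0.05, 0.05, 45.0, 0.05, 0.05
    ),
    "Adelta-NOC": ClassTuningProfile(
        "Adelta-NOC", _heat(0, 0, 0.05, 0.1, 0.2), 45.0, 0.9, 0.05, 55.0,
        0.05, 2.5, warm_sensitization_gain=1.0, trpv1_dependence=0.2,
    ),
    "PEP": ClassTuningProfile(
        "PEP", _heat(0.5, 0.6, 0.75, 0.85, 0.95), 55.0, 0.45, 0.05, 50.0,
        0.05, 2.5, warm_sensitization_gain=1.8, trpv1_dependence=0.9,
    ),
    "NP1": ClassTuningProfile(
        "NP1", _heat(0, 0, 0.1, 0.3, 0.6), 45.0, 0.9, 0.05, 55.0,
        0.05, 0.05, warm_sensitization_gain=1.3, trpv1_dependence=0.3,
    ),
    "NP2A": ClassTuningProfile(
        "NP2A", _heat(0.3, 0.4, 0.5, 0.7, 0.8), 50.0, 0.6, 0.1, 50.0,
        0.05, 2.0, warm_sensitization_gain=1.5, trpv1_dependence=0.8,
    ),
    "NP2B": ClassTuningProfile(
        "NP2B", _heat(0, 0, 0.1, 0.3, 0.6), 45.0, 0.8, 0.1, 50.0,
        0.05, 0.05, warm_sensitization_gain=1.3, trpv1_dependence=0.3,
    ),
    "NP3": ClassTuningProfile(
        "NP3", _heat(0.4, 0.5, 0.6, 0.8, 0.9), 50.0, 0.3, 0.05, 45.0,
        0.1, 3.0, warm_sensitization_gain=1.7, trpv1_dependence=0.85,
    ),
}

#: classes whose spontaneous rate is configured to rise after PGE2
PGE2_AFFECTED_CLASSES = ("Adelta-NOC", "PEP", "NP2A", "NP3")

DEFAULT_CLASS_FREQUENCIES: dict[str, float] = {c: 0.1 for c in CLASSES}


def high_margin_profiles() -> dict[str, ClassTuningProfile]:
    """Profiles whose evoked amplitudes sit far (>= 3x) above the response
    thresholds, for detector/category recovery benchmarking: heat and
    mechanical gains of 55% dF/F with flat temperature scaling."""
    flat = {t: 1.0 for t in DEFAULT_TEMPS}
    return {
        c: p.replace(
            heat_gain=55.0 if any(p.p_heat_by_temp.values()) else 0.0,
            mech_gain=55.0,
            temp_scaling=flat,
        )
        for c, p in DEFAULT_PROFILES.items()
    }


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedCell:
    """Ground truth for one synthetic neuron."""

    cell_id: str
    class_label: str
    profile: ClassTuningProfile
    heat_responds: Mapping[float, bool]
    heat_amp: Mapping[float, float]  # baseline/wild-type amplitude per temp
    pinch_responder: bool
    brush_responder: bool
    pinch_amp: float
    brush_amp: float
    true_category: str  # under baseline wild-type conditions

    @property
    def true_heat_max(self) -> float:
        return max(
            (a for t, a in self.heat_amp.items() if self.heat_responds[t]), default=0.0
        )

    @property
    def true_mech_max(self) -> float:
        vals = []
        if self.pinch_responder:
            vals.append(self.pinch_amp)
        if self.brush_responder:
            vals.append(self.brush_amp)
        return max(vals, default=0.0)


def sample_population(
    n: int,
    frequencies: Mapping[str, float] | None = None,
    profiles: Mapping[str, ClassTuningProfile] | None = None,
    seed: int = 0,
    gain_jitter: float = 0.1,
) -> list[SimulatedCell]:
    """Draw ``n`` cells with class labels, tuning draws and ground truth.

    ``frequencies`` must sum to 1 over known class labels.  Per-cell gains
    are the profile gains jittered multiplicatively by U[1-j, 1+j].  The true
    functional category is assigned from the realized draws with the same
    ratio rule the analysis applies.
    """
    freqs = dict(frequencies) if frequencies is not None else dict(DEFAULT_CLASS_FREQUENCIES)
    profs = dict(profiles) if profiles is not None else DEFAULT_PROFILES
    unknown = set(freqs) - set(CLASSES)
    if unknown:
        raise SimulationError(f"unknown class labels {sorted(unknown)}; valid: {CLASSES}")
    labels = sorted(freqs)
    p = np.array([freqs[c] for c in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise SimulationError(f"class frequencies sum to {p.sum():g}, expected 1")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(labels), size=n, p=p)
    cells: list[SimulatedCell] = []
    for i, k in enumerate(drawn):
        cls = labels[int(k)]
        prof = profs[cls]
        heat_gain = prof.heat_gain * (1 + gain_jitter * (2 * rng.random() - 1))
        mech_gain = prof.mech_gain * (1 + gain_jitter * (2 * rng.random() - 1))
        heat_responds = {
            t: bool(rng.random() < prob) for t, prob in sorted(prof.p_heat_by_temp.items())
        }
        heat_amp = {
            t: heat_gain * prof.temp_scaling.get(t, 1.0) for t in sorted(prof.p_heat_by_temp)
        }
        pinch_responder = bool(rng.random() < prof.p_pinch)
        brush_responder = bool(rng.random() < prof.p_brush)
        cell = SimulatedCell(
            cell_id=f"cell_{i:05d}",
            class_label=cls,
            profile=prof,
            heat_responds=heat_responds,
            heat_amp=heat_amp,
            pinch_responder=pinch_responder,
            brush_responder=brush_responder,
            pinch_amp=mech_gain,
            brush_amp=mech_gain,
            true_category="",
        )
        cells.append(
            replace(cell, true_category=categorize(cell.true_heat_max, cell.true_mech_max))
        )
    return cells


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def transient_kernel(
    tau: np.ndarray, rise: float = 0.15, decay: float = 1.0
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient (GCaMP6f-like)."""
    if rise <= 0 or decay <= rise:
        raise SimulationError("kernel requires 0 < rise < decay")
    tau = np.asarray(tau, dtype=float)
    t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = np.where(tau >= 0, np.exp(-tau / decay) - np.exp(-tau / rise), 0.0)
    return out / peak


def kernel_auc_factor(rise: float = 0.15, decay: float = 1.0, cutoff: float = 0.1) -> float:
    """Area of the unit-peak kernel down to ``cutoff`` of its height (s).

    Multiplying by the event amplitude approximates the baseline-anchored
    response AUC, used to pick generator gains relative to the threshold.
    """
    dt = 1e-3
    tau = np.arange(0, decay * 20, dt)
    k = transient_kernel(tau, rise, decay)
    peak_idx = int(np.argmax(k))
    below = np.flatnonzero(k[peak_idx:] < cutoff)
    end = peak_idx + (int(below[0]) if below.size else k.size - peak_idx)
    return float(np.trapezoid(k[:end], dx=dt))


@dataclass
class TraceSet:
    """Uniformly sampled dF/F traces for a population (cells x time)."""

    t: np.ndarray
    dff: np.ndarray
    cell_ids: list[str]
    episode_ids: np.ndarray
    sampling_rate: float

    def get(self, cell_id: str) -> np.ndarray:
        return self.dff[self.cell_ids.index(cell_id)]

    def to_long_frame(self) -> pd.DataFrame:
        n_c, n_t = self.dff.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n_t),
                "t_s": np.tile(self.t, n_c),
                "dff_pct": self.dff.ravel(),
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dff, index=pd.Index(self.cell_ids, name="cell_id"),
                          columns=np.round(self.t, 6))
        df.columns.name = "t_s"
        return df


#: spontaneous event amplitude distribution: normal(mean, sd) clipped below (% dF/F)
SPONT_AMP_MEAN = 10.0
SPONT_AMP_SD = 3.0
SPONT_AMP_MIN = 1.0
#: evoked-response latencies after stimulus onset (s)
HEAT_LATENCY = 0.4
MECH_LATENCY = 0.2

CONDITIONS = ("baseline", "pge2")
GENOTYPES = ("wt", "trpv1_ko")
#: temperature at or below which PGE2 warm sensitization applies fully; above
#: it the same multiplier is applied (direction-correct simplification)
WARM_RANGE_MAX = 42.0


def simulate_traces(
    cells: Sequence[SimulatedCell],
    protocol: StimulusProtocol,
    condition: str = "baseline",
    genotype: str = "wt",
    noise_sd: float = 1.0,
    seed: int = 0,
    rise: float = 0.15,
    decay: float = 1.0,
    amp_jitter: float = 0.05,
) -> tuple[TraceSet, pd.DataFrame]:
    """Synthesize dF/F traces and the ground-truth event table.

    Evoked responses place a difference-of-exponentials kernel scaled by the
    cell's drawn amplitude shortly after stimulus onset (onset inside the
    stimulation window); spontaneous events follow a homogeneous Poisson
    process at the condition-specific class rate; Gaussian noise of
    ``noise_sd`` % dF/F is added throughout.  Under PGE2 heat amplitudes are
    multiplied by the class warm-sensitization gain; in the Trpv1 knockout
    they are multiplied by (1 - trpv1_dependence), and fully dependent
    responses disappear.
    """
    if condition not in CONDITIONS:
        raise SimulationError(f"condition must be one of {CONDITIONS}")
    if genotype not in GENOTYPES:
        raise SimulationError(f"genotype must be one of {GENOTYPES}")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")

    fs = protocol.sampling_rate
    n_t = protocol.n_samples
    t = np.arange(n_t) / fs
    episode_ids = np.minimum(
        (t / protocol.episode_len).astype(int), protocol.n_episodes - 1
    )
    dff = np.zeros((len(cells), n_t))
    kernel_span = int(np.ceil((decay * 12) * fs))

    def inject(row: np.ndarray, onset_s: float, amp: float) -> None:
        i0 = int(np.ceil(onset_s * fs - 1e-9))
        i1 = min(i0 + kernel_span, n_t)
        if i0 >= n_t:
            return
        row[i0:i1] += amp * transient_kernel(t[i0:i1] - onset_s, rise, decay)

    records: list[dict] = []
    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(len(cells))
    for ci, (cell, ss) in enumerate(zip(cells, child_seeds)):
        rng = np.random.default_rng(ss)
        prof = cell.profile
        row = dff[ci]
        # evoked events
        for ev in protocol.events:
            if ev.modality == "heat":
                if not cell.heat_responds.get(ev.temperature, False):
                    continue
                amp = cell.heat_amp[ev.temperature]
                if condition == "pge2":
                    amp *= prof.warm_sensitization_gain
                if genotype == "trpv1_ko":
                    amp *= 1.0 - prof.trpv1_dependence
                if amp <= 0:
                    continue
                onset = ev.onset + HEAT_LATENCY
            elif ev.modality == "pinch":
                if not cell.pinch_responder:
                    continue
                amp = cell.pinch_amp
                onset = ev.onset + MECH_LATENCY
            elif ev.modality == "brush":
                if not cell.brush_responder:
                    continue
                amp = cell.brush_amp
                onset = ev.onset + MECH_LATENCY
            else:  # chemical: no direct evoked transient modelled
                continue
            amp = amp * (1 + amp_jitter * (2 * rng.random() - 1))
            inject(row, onset, amp)
            records.append(
                {
                    "cell_id": cell.cell_id,
                    "kind": ev.modality,
                    "event_id": ev.event_id,
                    "onset_s": onset,
                    "amplitude_pct": amp,
                    "temperature_c": ev.temperature,
                }
            )
        # spontaneous events: homogeneous Poisson at the condition rate
        rate = (
            prof.spont_rate_pge2 if condition == "pge2" else prof.spont_rate_baseline
        ) / 60.0  # events/s
        if rate > 0:
            t_ev = 0.0
            while True:
                t_ev += rng.exponential(1.0 / rate)
                if t_ev >= protocol.total_duration:
                    break
                amp = max(rng.normal(SPONT_AMP_MEAN, SPONT_AMP_SD), SPONT_AMP_MIN)
                inject(row, t_ev, amp)
                records.append(
                    {
                        "cell_id": cell.cell_id,
                        "kind": "spontaneous",
                        "event_id": "spont",
                        "onset_s": t_ev,
                        "amplitude_pct": amp,
                        "temperature_c": None,
                    }
                )
        if noise_sd > 0:
            row += rng.normal(0.0, noise_sd, n_t)

    events = pd.DataFrame(
        records,
        columns=["cell_id", "kind", "event_id", "onset_s", "amplitude_pct", "temperature_c"],
    )
    traces = TraceSet(
        t=t,
        dff=dff,
        cell_ids=[c.cell_id for c in cells],
        episode_ids=episode_ids,
        sampling_rate=fs,
    )
    return traces, events


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------

def simulate_expression(
    cells: Sequence[SimulatedCell],
    panel: Sequence[str] = PANEL,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell ternary expression calls: the class canonical pattern with
    each gene independently corrupted (to one of the other two levels,
    uniformly) with probability ``flip_rate``."""
    if not 0 <= flip_rate < 0.5:
        raise SimulationError("flip_rate must lie in [0, 0.5)")
    unknown = set(panel) - set(PANEL)
    if unknown:
        raise SimulationError(
            f"panel genes {sorted(unknown)} absent from the rule table panel {PANEL}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for cell in cells:
        pattern = canonical_pattern(cell.class_label, panel)
        for gene in panel:
            call = pattern[gene]
            if flip_rate > 0 and rng.random() < flip_rate:
                others = [lv for lv in LEVELS if lv != call]
                call = others[int(rng.integers(len(others)))]
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "gene": gene,
                    "call": call,
                    "true_call": pattern[gene],
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "gene", "call", "true_call"])


# ---------------------------------------------------------------------------
# guide-post fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSet:
    """Paired point fields: ``invivo = T(ish) + warp(ish) + jitter`` with the
    similarity ``T`` mapping the ISH frame into the in vivo frame.  Points
    are corresponded by index; ``guidepost_idx`` marks the landmark subset."""

    ish: np.ndarray
    invivo: np.ndarray
    guidepost_idx: np.ndarray
    true_similarity: SimilarityParams
    nn_spacing: float

    def guideposts(self):
        from .align import GuidePostSet

        return GuidePostSet(
            ish=self.ish[self.guidepost_idx], invivo=self.invivo[self.guidepost_idx]
        )


def _sinusoid_warp(pts: np.ndarray, amplitude: float, wavelength: float) -> np.ndarray:
    """Smooth low-frequency displacement field used as the ground-truth morph."""
    x, y = pts[:, 0], pts[:, 1]
    dx = amplitude * np.sin(2 * np.pi * y / wavelength)
    dy = amplitude * np.cos(2 * np.pi * x / wavelength)
    return np.column_stack([dx, dy])


def simulate_fields(
    n_points: int = 150,
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    warp_amplitude: float = 0.0,
    warp_wavelength: float = 300.0,
    jitter_sd: float = 0.0,
    guidepost_fraction: float = 0.3,
    seed: int = 0,
    size: float = 512.0,
) -> FieldSet:
    """Generate a deformed, jittered pair of corresponded point fields.

    ISH-frame points are sampled quasi-uniformly (minimum-spacing rejection)
    in a ``size`` x ``size`` box; in vivo coordinates are their similarity
    transform plus a smooth sinusoidal warp plus i.i.d. Gaussian jitter.  A
    ``guidepost_fraction`` of points (at least 3) is flagged as guide-posts.
    """
    if scale <= 0:
        raise SimulationError("scale must be > 0")
    if not 0 < guidepost_fraction <= 1:
        raise SimulationError("guidepost_fraction must lie in (0, 1]")
    if jitter_sd < 0 or warp_amplitude < 0:
        raise SimulationError("jitter_sd and warp_amplitude must be >= 0")
    n_guide = int(round(guidepost_fraction * n_points))
    if n_guide < 3:
        raise SimulationError(
            f"{n_guide} guide-posts requested; need >= 3 for a similarity fit"
        )
    rng = np.random.default_rng(seed)
    min_spacing = 0.6 * size / np.sqrt(max(n_points, 1))
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_points and attempts < 200 * n_points:
        cand = rng.uniform(0, size, 2)
        attempts += 1
        if all(np.linalg.norm(cand - q) >= min_spacing for q in pts):
            pts.append(cand)
    if len(pts) < n_points:
        raise SimulationError("could not place requested number of points; lower n_points")
    ish = np.array(pts)
    sim = SimilarityParams(
        scale=float(scale), rotation_deg=float(rotation_deg),
        translation=(float(translation[0]), float(translation[1])),
    )
    invivo = sim.apply(ish)
    if warp_amplitude > 0:
        invivo = invivo + _sinusoid_warp(ish, warp_amplitude, warp_wavelength)
    if jitter_sd > 0:
        invivo = invivo + rng.normal(0.0, jitter_sd, invivo.shape)
    guidepost_idx = np.sort(rng.choice(n_points, size=n_guide, replace=False))
    d = np.linalg.norm(ish[:, None, :] - ish[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return FieldSet(
        ish=ish,
        invivo=invivo,
        guidepost_idx=guidepost_idx,
        true_similarity=sim,
        nn_spacing=float(np.median(d.min(axis=1))),
    )
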