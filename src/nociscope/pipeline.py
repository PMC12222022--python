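"""End-to-end orchestration: synthetic session -> transients -> responses ->
categories -> classes -> population statistics, from a single seeded config.

All randomness flows from one root seed split per stage; a run is
deterministic for a fixed config+seed, outputs are written atomically (all
tables are built in memory first), and every table carries the config hash
in the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import classify as cl
from . import responses as rp
from . import simulate as sim
from . import stats as st
from . import traces as tr
from .protocol import ProtocolConfig, StimulusProtocol, make_protocol

log = logging.getLogger("nociscope")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    seed: int = 0
    n_cells: int = 500
    noise_sd: float = 1.0
    genotype: str = "wt"
    pge2: bool = True
    flip_rate: float = 0.05
    magnitude: str = "amplitude"  # ratio-rule quantity: amplitude | auc
    spontaneous_duration: float = 105.0
    stats: bool = True
    alignment: bool = True
    protocol: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    rule_table: str | None = None  # YAML path; None -> shipped default

    def validate(self) -> None:
        errors = []
        if self.n_cells < 1:
            errors.append("n_cells must be >= 1")
        if self.noise_sd < 0:
            errors.append("noise_sd must be >= 0")
        if self.genotype not in sim.GENOTYPES:
            errors.append(f"genotype must be one of {sim.GENOTYPES}")
        if not 0 <= self.flip_rate < 0.5:
            errors.append("flip_rate must lie in [0, 0.5)")
        if self.magnitude not in ("amplitude", "auc"):
            errors.append("magnitude must be 'amplitude' or 'auc'")
        known = {f.name for f in dataclasses.fields(ProtocolConfig)}
        bad = set(self.protocol) - known
        if bad:
            errors.append(f"unknown protocol keys {sorted(bad)}")
        bad = set(self.detection) - {"min_prominence", "min_abs_peak", "min_interpeak"}
        if bad:
            errors.append(f"unknown detection keys {sorted(bad)}")
        if errors:
            raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys {sorted(bad)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _episode_slice(traces: sim.TraceSet, protocol: StimulusProtocol, onset: float):
    ep = protocol.episode_of(min(onset, protocol.total_duration - 1e-9))
    sel = np.flatnonzero(traces.episode_ids == ep)
    return sel


def score_responses(
    traces: sim.TraceSet,
    protocol: StimulusProtocol,
    detection_overrides: dict | None = None,
) -> pd.DataFrame:
    """Score every (cell, stimulus event) pair under the standard rules.

    Heat events are scored for AUC-based responsiveness, pinch and brush
    events for mechanosensitivity (15% amplitude rule), and brush events
    additionally for 1-s time-locking.  Detection is restricted to the
    episode containing the event (detection never crosses episodes).
    """
    ov = detection_overrides or {}
    heat_params = tr.HEAT_PARAMS.replace(**{k: v for k, v in ov.items() if k != "min_abs_peak"})
    mech_params = tr.SPONTANEOUS_PARAMS.replace(**ov)
    fs = traces.sampling_rate
    rows = []
    for ci, cid in enumerate(traces.cell_ids):
        x = traces.dff[ci]
        for ev in protocol.events:
            sel = _episode_slice(traces, protocol, ev.onset)
            t_ep, x_ep = traces.t[sel], x[sel]
            if ev.modality == "heat":
                rec = rp.heat_response(t_ep, x_ep, ev, fs=fs, params=heat_params, cell_id=cid)
                rows.append(_record_row(rec))
            elif ev.modality in ("pinch", "brush"):
                rec = rp.mech_response(t_ep, x_ep, ev, fs=fs, params=mech_params, cell_id=cid)
                row = _record_row(rec)
                if ev.modality == "brush":
                    brec = rp.brush_response(t_ep, x_ep, ev, fs=fs, cell_id=cid)
                    row["time_locked"] = brec.time_locked
                rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "event_id", "modality", "temperature_c",
            "auc_pct_s", "peak_pct", "responsive", "time_locked",
        ],
    )


def _record_row(rec: rp.ResponseRecord) -> dict:
    return {
        "cell_id": rec.cell_id,
        "event_id": rec.event_id,
        "modality": rec.modality,
        "temperature_c": rec.temperature,
        "auc_pct_s": rec.auc,
        "peak_pct": rec.peak_amplitude,
        "responsive": rec.responsive,
        "time_locked": rec.time_locked,
    }


def categorize_cells(responses: pd.DataFrame, magnitude: str = "amplitude") -> pd.DataFrame:
    """Per-cell functional category from the scored response table."""
    key = "peak_pct" if magnitude == "amplitude" else "auc_pct_s"
    rows = []
    for cid, sub in responses.groupby("cell_id", sort=True):
        heat = sub[sub["modality"] == "heat"]
        mech = sub[sub["modality"].isin(["pinch", "brush"])]
        brush = sub[sub["modality"] == "brush"]
        heat_max = float(heat.loc[heat["responsive"].astype(bool), key].max()) if heat["responsive"].any() else 0.0
        mech_max = float(mech.loc[mech["responsive"].astype(bool), key].max()) if mech["responsive"].any() else 0.0
        if len(brush):
            brush_cell = bool(brush["time_locked"].astype(bool).mean() >= 0.5)
        else:
            brush_cell = False
        rows.append(
            {
                "cell_id": cid,
                "category": cl.categorize(heat_max, mech_max),
                "brush_cell": brush_cell,
                "heat_max": heat_max,
                "mech_max": mech_max,
                "responding": heat_max > 0 or mech_max > 0 or brush_cell,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "category", "brush_cell", "heat_max", "mech_max", "responding"]
    )


def spontaneous_scores(
    traces: sim.TraceSet,
    protocol: StimulusProtocol,
    required_duration: float = 105.0,
    detection_overrides: dict | None = None,
) -> pd.DataFrame:
    params = tr.SPONTANEOUS_PARAMS.replace(**(detection_overrides or {}))
    rows = []
    for ci, cid in enumerate(traces.cell_ids):
        score = tr.spontaneous_activity(
            traces.dff[ci],
            protocol.unstimulated_windows,
            fs=traces.sampling_rate,
            episode_ids=traces.episode_ids,
            params=params,
            required_duration=required_duration,
            t=traces.t,
        )
        rows.append({"cell_id": cid, "spontaneous_sum_pct": score})
    return pd.DataFrame(rows, columns=["cell_id", "spontaneous_sum_pct"])


def detect_all(traces: sim.TraceSet, params: tr.DetectionParams = tr.SPONTANEOUS_PARAMS) -> pd.DataFrame:
    rows = []
    for ci, cid in enumerate(traces.cell_ids):
        trs = tr.detect_transients(
            traces.dff[ci], fs=traces.sampling_rate,
            episode_ids=traces.episode_ids, params=params, t=traces.t,
        )
        rows.extend(tr.transients_to_records(cid, trs))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "peak_time_s", "peak_pct", "prominence_pct",
                 "amplitude_pct", "onset_s", "end_s"],
    )


HEATMAP_SORT_KEYS = ("heat_max", "mech_max", "spontaneous_sum_pct")


def make_heatmap_matrix(
    cell_records: pd.DataFrame, matrix: pd.DataFrame, sort_key: str = "heat_max"
) -> pd.DataFrame:
    """Reorder a per-cell matrix for display: rows grouped by class (canonical
    order), sorted within class by ``sort_key`` descending (ties broken by
    cell_id for order-invariance).  Conditions are sorted independently by
    calling this once per condition."""
    if sort_key not in cell_records.columns:
        raise ConfigError(
            f"unknown sort key {sort_key!r}; available: {sorted(set(HEATMAP_SORT_KEYS) & set(cell_records.columns))}"
        )
    recs = cell_records.set_index("cell_id")
    order: list[str] = []
    class_order = [c for c in cl.CLASSES] + [cl.UNCLASSIFIED]
    for cls in class_order:
        sub = recs[recs["class_label"] == cls]
        sub = sub.sort_values([sort_key, "cell_id"], ascending=[False, True],
                              key=None)
        order.extend(sub.index.tolist())
    order = [c for c in order if c in matrix.index]
    return matrix.loc[order]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic pipeline and write tables to ``outdir``.

    Returns the run report (also written as run_report.json).  Outputs are
    only written once every stage has completed.
    """
    config.validate()
    outdir = Path(outdir)
    cfg_hash = config.hash()
    seeds = np.random.SeedSequence(config.seed).generate_state(6).tolist()
    log.info("run %s: seed=%d n_cells=%d", cfg_hash, config.seed, config.n_cells)

    proto_cfg = ProtocolConfig(**config.protocol) if config.protocol else ProtocolConfig()
    proto_cfg = proto_cfg.replace(spontaneous_duration=config.spontaneous_duration)
    protocol = make_protocol(proto_cfg)

    cells = sim.sample_population(config.n_cells, seed=seeds[0])
    traces_b, events_b = sim.simulate_traces(
        cells, protocol, condition="baseline", genotype=config.genotype,
        noise_sd=config.noise_sd, seed=seeds[1],
    )
    log.info("simulated %d cells, %d baseline ground-truth events", len(cells), len(events_b))

    table = (
        cl.ClassRuleTable.from_yaml(config.rule_table)
        if config.rule_table
        else cl.default_rule_table()
    )
    expression = sim.simulate_expression(cells, flip_rate=config.flip_rate, seed=seeds[3])
    calls_by_cell: dict[str, dict[str, str]] = {}
    for row in expression.itertuples(index=False):
        calls_by_cell.setdefault(row.cell_id, {})[row.gene] = row.call
    decoded = {cid: table.decode(calls) for cid, calls in calls_by_cell.items()}

    transients = detect_all(
        traces_b, tr.SPONTANEOUS_PARAMS.replace(**config.detection)
    )
    responses = score_responses(traces_b, protocol, config.detection)
    categories = categorize_cells(responses, magnitude=config.magnitude)
    spont_b = spontaneous_scores(
        traces_b, protocol, config.spontaneous_duration, config.detection
    )

    cell_records = categories.merge(spont_b, on="cell_id")
    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "class_true": [c.class_label for c in cells],
            "category_true": [c.true_category for c in cells],
        }
    )
    cell_records = cell_records.merge(truth, on="cell_id")
    cell_records["class_label"] = cell_records["cell_id"].map(decoded)
    cell_records["tested_classes"] = [tuple(cl.CLASSES)] * len(cell_records)

    outputs: dict[str, pd.DataFrame] = {
        "transients.csv": transients,
        "responses.csv": responses,
        "expression.csv": expression,
    }
    report: dict = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stage_seeds": seeds,
        "n_cells": len(cells),
        "n_ground_truth_events_baseline": int(len(events_b)),
        "n_transients_detected": int(len(transients)),
        "n_responding": int(cell_records["responding"].sum()),
        "n_classified": int((cell_records["class_label"] != cl.UNCLASSIFIED).sum()),
        "n_unclassified": int((cell_records["class_label"] == cl.UNCLASSIFIED).sum()),
        "rule_table_provisional": table.provisional,
    }

    if config.pge2:
        traces_p, events_p = sim.simulate_traces(
            cells, protocol, condition="pge2", genotype=config.genotype,
            noise_sd=config.noise_sd, seed=seeds[2],
        )
        spont_p = spontaneous_scores(
            traces_p, protocol, config.spontaneous_duration, config.detection
        ).rename(columns={"spontaneous_sum_pct": "spontaneous_sum_pge2_pct"})
        cell_records = cell_records.merge(spont_p, on="cell_id")
        report["n_ground_truth_events_pge2"] = int(len(events_p))

    if config.stats:
        cheek = cell_records[cell_records["responding"]]
        pct = st.class_percentages(cheek)
        heat_resp = responses[responses["modality"] == "heat"].rename(
            columns={"temperature_c": "temperature"}
        )
        recruit = st.recruitment_by_temperature(
            heat_resp[heat_resp["cell_id"].isin(cheek["cell_id"])], cheek
        )
        outputs["class_percentages.csv"] = pct
        outputs["recruitment_by_temperature.csv"] = recruit.reset_index()
        if config.pge2:
            baseline = {
                cls: sub["spontaneous_sum_pct"].to_numpy()
                for cls, sub in cheek.groupby("class_true")
            }
            post = {
                cls: sub["spontaneous_sum_pge2_pct"].to_numpy()
                for cls, sub in cheek.groupby("class_true")
            }
            outputs["pge2_spontaneous_test.csv"] = st.paired_condition_test(baseline, post)

    if config.alignment:
        field_set = sim.simulate_fields(
            n_points=120, scale=1.1, rotation_deg=8.0, translation=(12.0, -5.0),
            warp_amplitude=6.0, jitter_sd=1.0, guidepost_fraction=0.3, seed=seeds[4],
        )
        model = al.fit_warp(field_set.guideposts(), method="thin_plate_spline")
        result = al.transfer_labels(
            field_set.ish, field_set.invivo, model, max_dist=0.5 * field_set.nn_spacing
        )
        correct = sum(1 for i, j in result.pairs if i == j)
        report["alignment"] = {
            "similarity_scale": model.similarity.scale,
            "similarity_rotation_deg": model.similarity.rotation_deg,
            "guidepost_rms_px": float(np.sqrt(np.mean(model.residuals**2))),
            "n_matched": result.n_matched,
            "match_accuracy": correct / len(field_set.ish),
        }

    cell_records = cell_records.drop(columns=["tested_classes"])
    outputs["cell_records.csv"] = cell_records
    report["n_cells_out"] = int(len(cell_records))

    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in outputs.items():
        df.to_csv(outdir / name, index=False)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("wrote %d tables to %s", len(outputs) + 1, outdir)
    return report
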