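"""End-to-end orchestration: simulate/load -> detect -> UD -> HMM -> evaluate.

Every run is deterministic given (config, seed); every artifact is stamped
with the config hash. Stages write their outputs under the run directory so
later stages can be re-run individually from the cached intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbmm, evaluation, hmm, interaction, regularize, synthetic, trajectory

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ruttrack")

STAGES = ("simulate", "detect", "ud", "hmm", "evaluate")


@dataclass
class RunConfig:
    """Pipeline configuration. Defaults are the published analysis values:
    100 m proximity, 2-fix minimum run, 2 h delineation gap, DI > 0.5,
    10 m GPS error SD, 30 m UD cells, 2- and 3-state HMMs."""

    input_csv: str | None = None  # if None, simulate from the scenario below
    scenario: dict = field(default_factory=dict)  # Scenario field overrides
    tolerance_s: float = 300.0
    dist_threshold_m: float = 100.0
    min_run: int = 2
    gap_hours: float = 2.0
    di_threshold: float = 0.5
    delta_m: float = 10.0
    cell_size_m: float = 30.0
    buffer_m: float | None = None
    n_integration: int = 10
    phases: bool = False  # additionally fit per-breeding-phase UDs
    hmm_states: tuple[int, ...] = (2, 3)
    n_restarts: int = 10
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "ruttrack_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.hmm_states, list):
            cfg.hmm_states = tuple(cfg.hmm_states)
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # the analysis is defined by parameters, not paths
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def _grid_meta(vol: bbmm.VolumeGrid) -> dict:
    return {
        "origin": [vol.origin[0], vol.origin[1]],
        "cell_size": vol.cell_size,
        "shape": list(vol.volume.shape),
    }


def _grid_to_csv(vol: bbmm.VolumeGrid, path: Path) -> None:
    nx, ny = vol.volume.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame(
        {
            "x": vol.origin[0] + (ix.ravel() + 0.5) * vol.cell_size,
            "y": vol.origin[1] + (iy.ravel() + 0.5) * vol.cell_size,
            "volume": vol.volume.ravel(),
        }
    ).to_csv(path, index=False)


def _load_tracks(out: Path) -> list[trajectory.Track]:
    return trajectory.read_tracks(out / "tracks.csv")


def _events_with_fixes(out: Path, which: str) -> list[interaction.InteractionEvent]:
    summary = pd.read_csv(out / f"events_{which}.csv", parse_dates=["start", "end"])
    fixes = pd.read_csv(out / f"event_fixes_{which}.csv", parse_dates=["timestamp"])
    events = []
    for eid, row in summary.iterrows():
        evfix = fixes[fixes["event_id"] == eid].drop(columns="event_id").reset_index(drop=True)
        events.append(
            interaction.InteractionEvent(
                male_id=str(row["male_id"]),
                female_id=str(row["female_id"]),
                start=row["start"],
                end=row["end"],
                fixes=evfix,
                mean_distance=float(row["mean_distance_m"]),
                duration_h=float(row["duration_h"]),
                mean_DI=float(row["mean_DI"]),
                classification=str(row["classification"]),
            )
        )
    return events


def _write_events(events, out: Path, which: str) -> None:
    interaction.events_to_frame(events).to_csv(out / f"events_{which}.csv", index=False)
    if events:
        frames = []
        for i, ev in enumerate(events):
            f = ev.fixes.copy()
            f.insert(0, "event_id", i)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"event_fixes_{which}.csv", index=False
        )
    else:
        pd.DataFrame(
            columns=["event_id", "timestamp", "t_a", "t_b", "xa", "ya", "xb", "yb", "distance"]
        ).to_csv(out / f"event_fixes_{which}.csv", index=False)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns a dict of in-memory artifacts.

    Stage order is fixed (simulate -> detect -> ud -> hmm -> evaluate). A
    stage not in ``stages`` is loaded from the run directory instead of
    recomputed, so individual stages can be re-run against cached inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {"config_hash": config.config_hash()}
    _dump_json({"config": asdict(config), "hash": artifacts["config_hash"]},
               out / "config.json")
    try:
        # ---- simulate / load -------------------------------------------
        if "simulate" in stages:
            log.info("stage simulate (hash %s)", artifacts["config_hash"])
            if config.input_csv:
                tracks = trajectory.read_tracks(config.input_csv)
                truth = None
            else:
                scen = synthetic.Scenario(seed=config.seed, **config.scenario)
                male, female, truth = synthetic.simulate_pair(scen)
                tracks = [male, female]
                truth.to_csv(out / "ground_truth.csv", index=False)
            trajectory.write_tracks(tracks, out / "tracks.csv")
        else:
            tracks = _load_tracks(out)
            truth = None
        artifacts["tracks"] = tracks
        males = [t for t in tracks if t.sex == "male"]
        females = [t for t in tracks if t.sex == "female"]

        # ---- detect -----------------------------------------------------
        if "detect" in stages:
            log.info("stage detect")
            liberal = []
            for m in males:
                for f in females:
                    if m.study_area != f.study_area:
                        continue
                    dyad = trajectory.align_dyad(m, f, tolerance=config.tolerance_s)
                    evs = interaction.detect_events(
                        dyad,
                        dist_threshold=config.dist_threshold_m,
                        min_run=config.min_run,
                        gap_hours=config.gap_hours,
                    )
                    liberal.extend(interaction.attach_di(evs))
            conservative = interaction.conservative_filter(liberal, config.di_threshold)
            _write_events(liberal, out, "liberal")
            _write_events(conservative, out, "conservative")
        elif (out / "events_liberal.csv").exists():
            liberal = _events_with_fixes(out, "liberal")
            conservative = _events_with_fixes(out, "conservative")
        else:
            liberal, conservative = [], []
        artifacts["events_liberal"] = liberal
        artifacts["events_conservative"] = conservative

        # ---- ud ---------------------------------------------------------
        if "ud" in stages:
            log.info("stage ud")
            grids: dict[str, bbmm.VolumeGrid] = {}
            sigma2: dict[str, float] = {}
            for t in tracks:
                s2 = bbmm.fit_sigma2_m(t, delta=config.delta_m)
                sigma2[t.animal_id] = s2
                ud = bbmm.compute_ud(
                    t,
                    bbmm.BBMMParams(sigma2_m=s2, delta=config.delta_m),
                    cell_size=config.cell_size_m,
                    buffer=config.buffer_m,
                    n_integration=config.n_integration,
                )
                vol = bbmm.ud_volume(ud)
                grids[t.animal_id] = vol
                _grid_to_csv(vol, out / f"volume_{t.animal_id}_season.csv")
            if config.phases:
                for t in tracks:
                    if t.region is None:
                        continue
                    ph = t.fixes["timestamp"].map(
                        lambda ts: trajectory.assign_phase(ts, t.region)
                    )
                    for phase in ("early", "peak", "late"):
                        mask = (ph == phase).to_numpy()
                        if mask.sum() < 10:
                            continue
                        sub = t.subset(mask)
                        s2 = bbmm.fit_sigma2_m(sub, delta=config.delta_m)
                        ud = bbmm.compute_ud(
                            sub,
                            bbmm.BBMMParams(sigma2_m=s2, delta=config.delta_m),
                            cell_size=config.cell_size_m,
                            buffer=config.buffer_m,
                            n_integration=config.n_integration,
                        )
                        grids[f"{t.animal_id}:{phase}"] = bbmm.ud_volume(ud)
            _dump_json({"sigma2_m": sigma2}, out / "bbmm_params.json")
            artifacts["volume_grids"] = grids
            artifacts["sigma2_m"] = sigma2
        else:
            artifacts["volume_grids"] = {}
            artifacts["sigma2_m"] = json.load(open(out / "bbmm_params.json"))["sigma2_m"] \
                if (out / "bbmm_params.json").exists() else {}

        # ---- hmm --------------------------------------------------------
        if "hmm" in stages:
            log.info("stage hmm")
            reg_tracks = {
                t.animal_id: regularize.interpolate_hourly(
                    t, delta=config.delta_m,
                    sigma2_m=artifacts["sigma2_m"].get(t.animal_id),
                )
                for t in males  # single-sex (male) data, as in the assessment
            }
            series = {aid: hmm.make_series(r) for aid, r in reg_tracks.items()}
            fits = {}
            decoded = {}
            for n_states in config.hmm_states:
                fit = hmm.fit_hmm(
                    list(series.values()),
                    n_states=n_states,
                    n_restarts=config.n_restarts,
                    seed=config.seed + n_states,
                )
                fits[n_states] = fit
                decoded[n_states] = {
                    aid: hmm.viterbi_decode(fit, s) for aid, s in series.items()
                }
            _dump_json({str(k): f.to_dict() for k, f in fits.items()},
                       out / "hmm_fits.json")
            for n_states, seqs in decoded.items():
                frames = []
                for aid, seq in seqs.items():
                    frames.append(pd.DataFrame({
                        "animal_id": aid,
                        "timestamp": seq.timestamps,
                        "state": seq.states,
                    }))
                pd.concat(frames, ignore_index=True).to_csv(
                    out / f"states_{n_states}.csv", index=False
                )
            artifacts["hmm_fits"] = fits
            artifacts["state_sequences"] = decoded
        else:
            artifacts["hmm_fits"] = {}
            artifacts["state_sequences"] = {}

        # ---- evaluate ---------------------------------------------------
        if "evaluate" in stages:
            log.info("stage evaluate")
            report: dict = {"config_hash": artifacts["config_hash"]}
            grids = artifacts["volume_grids"]
            for which, events in (("liberal", liberal), ("conservative", conservative)):
                if not events:
                    report[which] = {"n_events": 0}
                    continue
                section: dict = {"n_events": len(events)}
                for sex in ("male", "female"):
                    ids = {ev.male_id if sex == "male" else ev.female_id for ev in events}
                    if grids and ids <= set(grids):
                        uds = evaluation.event_ud_summary(
                            events, grids, sex=sex, scope="season"
                        )
                        section[f"ud_{sex}"] = evaluation.consistency_report(
                            ud_summaries=uds
                        )["ud"]
                for n_states, seqs in artifacts["state_sequences"].items():
                    stsum = evaluation.event_state_summary(events, seqs, n_states)
                    rep = evaluation.consistency_report(state_summaries=stsum)["hmm"]
                    null = evaluation.permutation_baseline(
                        events, seqs, n_states,
                        n_permutations=config.n_permutations,
                        seed=config.seed + 1000 + n_states,
                    )
                    obs = rep["modal_state_agreement"]
                    rep["permutation_mean"] = float(null.mean())
                    rep["permutation_q95"] = float(np.quantile(null, 0.95))
                    rep["permutation_pvalue"] = float(
                        (1 + np.sum(null >= obs)) / (1 + len(null))
                    )
                    section[f"hmm_{n_states}state"] = rep
                report[which] = section
            _dump_json(report, out / "report.json")
            artifacts["report"] = report
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()
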