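"""End-to-end orchestration of the analysis stages.

``run_pipeline`` drives the full chain on a synthetic cohort (or loaded
fixtures): trace conditioning -> behavior classification -> ensemble
categorization -> decoding -> encoding GLM -> CoCA -> state discovery,
collecting one summary dict.  ``prepare_session`` performs the per-session
part (conditioning + behavior + time-base alignment) and is the unit other
entry points build on.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import behavior as bhv
from . import coca as coca_mod
from . import decoding as dec
from . import ensembles as ens
from . import glm as glm_mod
from . import preprocess as pre
from . import states as st
from .core import AssayKind, TraceMatrix
from .synthio import Cohort, Session, SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "PreparedSession", "prepare_session", "run_pipeline"]

_STAGES = ("ensembles", "decoding", "glm", "coca", "states")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Unknown keys are rejected at construction; thresholds default to the
    standard values used throughout the package (0.25 cm/s freezes, 3 cm/s
    approaches, 60 s / 10 s interleave, 100 permutations, 1000 random
    projections, ...).
    """

    seed: int = 0
    out_dir: str | None = None
    stages: tuple[str, ...] = _STAGES
    artifact_suppression: bool = False
    n_permutations: int = 100
    n_random_projections: int = 1000
    k_range: tuple[int, int] = (1, 10)
    hmm_states: int = 4
    coca_max_iter: int = 4000
    coca_restarts: int = 3
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sim = payload.pop("simulation", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = set(SimulationConfig.__dataclass_fields__)
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
        cfg = cls(**payload, simulation=SimulationConfig(**sim)) if sim else cls(**payload)
        bad = [s for s in cfg.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PreparedSession:
    """One session after conditioning, behavior extraction and alignment.

    Traces are z-scored on the neural clock; zone labels, scores and
    behavioral channels are downsampled onto that clock (block averages for
    continuous channels, any-within-block for binary ones).
    """

    session: Session
    traces: TraceMatrix
    zones: "bhv.ZoneLabels"
    zones_neural: "bhv.ZoneLabels"
    kin: "bhv.KinematicSeries"
    intervals: object
    scores: "bhv.ScoreSeries"
    score_neural: np.ndarray
    location_index_neural: np.ndarray | None
    speed_neural: np.ndarray
    channels_neural: dict[str, np.ndarray]
    binary_channels: list[str]
    qc: dict


def prepare_session(session: Session, artifact_suppression: bool = False) -> PreparedSession:
    """Condition the traces and derive all aligned behavioral series."""
    traces = session.traces
    qc: dict = {}
    if artifact_suppression:
        traces, report = pre.suppress_artifact_components(traces)
        qc["removed_pcs"] = report.removed_pcs
        qc["removed_variance"] = report.removed_variance
    traces, vreport = pre.variance_filter(traces)
    qc["reference_cell"] = vreport.reference_cell
    qc["discarded_cells"] = vreport.discarded_cells
    traces = pre.zscore_traces(traces)

    pose = session.pose
    kin = bhv.compute_kinematics(pose)
    zones = bhv.assign_zones(pose, session.geometry)
    intervals = bhv.detect_all_behaviors(pose, kin, zones if session.geometry.is_epm else None)
    scores = bhv.avoidance_approach_score(pose, intervals, session.geometry)
    channels, binary = bhv.assemble_behavior_variables(pose, kin, intervals, scores)

    ratio = int(round(pose.fps / traces.fs))
    n = min(traces.n_timepoints, pose.n_frames // ratio)
    traces = TraceMatrix(traces.values[:, :n], traces.fs, list(traces.cell_ids), True)
    zones_neural = ens.downsample_zone_labels(zones, ratio)
    zones_neural = bhv.ZoneLabels(zones_neural.labels[:n], zones_neural.assay)
    score_neural = pre.downsample_series(scores.score, ratio)[:n]
    speed_neural = pre.downsample_series(kin.speed_body, ratio)[:n]
    loc_neural = None
    if scores.location_index is not None:
        loc_neural = pre.downsample_series(scores.location_index, ratio)[:n]
    channels_neural = {
        name: pre.downsample_series(series, ratio, binary=name in binary).astype(float)[:n]
        for name, series in channels.items()
    }
    return PreparedSession(session, traces, zones, zones_neural, kin, intervals,
                           scores, score_neural, loc_neural, speed_neural,
                           channels_neural, binary, qc)


def _common_cells(prepared_a: PreparedSession, prepared_b: PreparedSession, coreg) -> list[str]:
    """Co-registered cell ids that survived conditioning in both sessions."""
    a_ids = set(prepared_a.traces.cell_ids)
    b_ids = set(prepared_b.traces.cell_ids)
    return [i for i, j in zip(coreg.ids_assay1, coreg.ids_assay2)
            if i in a_ids and j in b_ids]


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute the configured stages on a (synthetic) cohort.

    Returns the summary dict; when ``config.out_dir`` is set, the summary
    and the serialized config (both carrying the config hash) are written
    there as JSON.
    """
    if cohort is None:
        sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
        cohort = simulate_cohort(sim)
    summary: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}

    epm = prepare_session(cohort.epm, config.artifact_suppression)
    rat = prepare_session(cohort.rat, config.artifact_suppression)
    toy = prepare_session(cohort.toy, config.artifact_suppression)
    summary["qc"] = {"epm": epm.qc, "rat": rat.qc, "toy": toy.qc}
    summary["behavior"] = {
        name: {lab: int((p.intervals.table["label"] == lab).sum())
               for lab in sorted(p.intervals.labels())}
        for name, p in (("epm", epm), ("rat", rat), ("toy", toy))
    }

    if "ensembles" in config.stages:
        labels = ens.categorize_arm_cells(epm.traces, epm.zones_neural)
        scores = ens.compute_arm_scores(epm.traces, epm.zones_neural)
        summary["stages"]["ensembles"] = {
            "counts": labels.counts(),
            "mean_preference_open": float(np.mean(
                [scores.table.loc[c, "preference_score"] for c in labels.cells("open")]))
            if labels.cells("open") else None,
            "mean_preference_closed": float(np.mean(
                [scores.table.loc[c, "preference_score"] for c in labels.cells("closed")]))
            if labels.cells("closed") else None,
        }

    if "decoding" in config.stages:
        split = dec.make_interleaved_split(epm.traces.n_timepoints, epm.traces.fs)
        arm = dec.ArmDecoder(epm.traces, epm.zones_neural, split).fit(
            n_permutations=config.n_permutations, seed=config.seed)
        loc = dec.LocationIndexModel(epm.traces, epm.location_index_neural, split).fit()
        summary["stages"]["decoding"] = {
            "mcc": arm.mcc, "p_perm": arm.p_perm,
            "null_mcc_mean": float(arm.null_mcc.mean()),
            "location_index_r_test": loc.r_test,
        }

    if "glm" in config.stages:
        design = glm_mod.build_design_matrix(
            rat.intervals,
            {k: v for k, v in rat.channels_neural.items() if k not in rat.binary_channels},
            rat.traces.n_timepoints, rat.traces.fs,
            behavior_labels=[b for b in rat.binary_channels],
        )
        split = dec.make_interleaved_split(rat.traces.n_timepoints, rat.traces.fs)
        fit = glm_mod.EncodingGLM(rat.traces, design, split).fit()
        summary["stages"]["glm"] = {
            "mean_r2_train": float(np.nanmean(fit.r2_train)),
            "mean_r2_test": float(np.nanmean(fit.r2_test)),
        }

    if "coca" in config.stages:
        cells = _common_cells(epm, rat, cohort.coreg)
        if len(cells) < 2:
            warnings.warn("too few co-registered cells for CoCA; stage skipped")
        else:
            entries = []
            for name, p in (("EPM", epm), ("RAT", rat)):
                Y, _ = coca_mod.normalize_behavior_matrix(p.channels_neural, name)
                X = p.traces.select_cells(cells).values
                split = dec.make_interleaved_split(X.shape[1], p.traces.fs)
                entries.append(coca_mod.CoCAEntry("m1", name, X, Y, split.train, split.test))
            dataset = coca_mod.CoCADataset(entries)
            res = coca_mod.CoCA(dataset).fit(max_iter=config.coca_max_iter,
                                             restarts=config.coca_restarts, seed=config.seed)
            sig = res.significance(n_trials=config.n_random_projections, seed=config.seed)
            summary["stages"]["coca"] = {
                f"{m}_{a}": {"train_r": c["train"], "test_r": c["test"],
                             "p": sig[(m, a)]["p"]}
                for (m, a), c in res.correlations().items()
            }

    if "states" in config.stages:
        cells = _common_cells(epm, rat, cohort.coreg)
        out: dict = {}
        for name, p in (("epm", epm), ("rat", rat)):
            km = st.StateKMeans(p.traces, range(config.k_range[0], config.k_range[1] + 1))
            res = km.fit(seed=config.seed).label_states(p.score_neural)
            null = res.permutation_null(p.score_neural, config.n_permutations, config.seed)
            out[name] = {
                "k": res.k,
                "avoidance_score": float(res.cluster_scores[res.avoidance_cluster]),
                "approach_score": float(res.cluster_scores[res.approach_cluster]),
                "avoidance_significant": null.avoidance_significant,
                "approach_significant": null.approach_significant,
            }
        if len(cells) >= 2:
            train = st.StateKMeans(epm.traces.select_cells(cells),
                                   range(config.k_range[0], config.k_range[1] + 1))
            res = train.fit(seed=config.seed).label_states(epm.score_neural)
            for test_name, p in (("rat", rat), ("toy", toy)):
                tr = st.transfer_clusters(res, p.traces.select_cells(cells), None,
                                          p.score_neural)
                out[f"transfer_epm_to_{test_name}"] = {
                    "approach_mean": tr.approach_mean_score,
                    "avoidance_mean": tr.avoidance_mean_score,
                    "p_ranksum": tr.p_ranksum,
                }
        summary["stages"]["states"] = out

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        (out_dir / "config.json").write_text(
            json.dumps({"config_hash": config.hash(), **asdict(config)}, indent=2, default=str))
    return summary
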