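"""End-to-end orchestration of the synthetic phenotyping study.

``run_pipeline`` drives every analysis stage over a fully synthetic cohort:
simulate per-animal sessions, summarize movement fractions, diagnose POD vs
non-POD against the control group, select discriminative movements, build
the delirium-like behaviour space, detect object investigation and the DSP,
cluster POD animals into Hyper/Hypo subtypes, and evaluate a simulated
treated group with the cross-validated classifier.  Every artifact is a CSV
or JSON table under ``config.out_dir`` carrying the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics, delirium_space, dex_eval, investigation
from . import pose_features, subtype_clustering, synthetic_data
from .skeleton_io import novel_object_arena, open_field_arena

log = logging.getLogger("podscape")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run."""

    out_dir: str = "podscape_run"
    seed: int = 0
    # cohort
    n_control: int = 20
    n_model: int = 20
    n_dex: int = 16
    pod_rate: float = 0.5
    dex_pod_rate: float = 0.5
    # sessions
    session_frames: int = synthetic_data.DEFAULT_SESSION_FRAMES
    frame_rate: float = 30.0
    # features
    feature_list: tuple[str, ...] = pose_features.DEFAULT_FEATURES
    pmf_bins: int = 50
    # investigation geometry (mm) and vocabulary
    approach_distance: float = investigation.APPROACH_DISTANCE_MM
    climb_distance: float = investigation.CLIMB_DISTANCE_MM
    merge_gap: int = investigation.DEFAULT_MERGE_GAP
    deep_classes: tuple[int, ...] = tuple(sorted(investigation.DEFAULT_DEEP_CLASSES))
    # open-field centre radii (mm)
    centre_radius_oft: float = behavior_metrics.CENTRE_RADIUS_OFT_MM
    centre_radius_composite: float = behavior_metrics.CENTRE_RADIUS_COMPOSITE_MM
    # embedding / classifier
    neighbor_param: int = delirium_space.DEFAULT_NEIGHBOR_PARAM
    cv_folds: int = 5
    cv_iterations: int = 30
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_list"] = list(self.feature_list)
        d["deep_classes"] = list(self.deep_classes)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("feature_list", "deep_classes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with path.open("w") as fh:
        fh.write(f"# podscape config={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a synthetic cohort; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    seed = config.seed
    n_frames = config.session_frames
    log.info("pipeline start: config=%s seed=%d", config.config_hash, seed)

    # --- stage 1: simulate cohorts ----------------------------------------
    control_p = synthetic_data.control_profile()
    pod_p = synthetic_data.pod_profile()
    nonpod_p = synthetic_data.nonpod_profile()

    def simulate_group(name: str, profiles: Sequence, base: int):
        fractions, truth = [], []
        for i, profile in enumerate(profiles):
            labels = synthetic_data.generate_labels(profile, n_frames, seed=base + i)
            fractions.append(
                behavior_metrics.movement_fractions(
                    labels, animal_id=f"{name}{i:02d}"
                )
            )
            truth.append(profile.label)
        return fractions, truth

    n_pod = round(config.pod_rate * config.n_model)
    model_profiles = [pod_p] * n_pod + [nonpod_p] * (config.n_model - n_pod)
    control_fv, _ = simulate_group("C", [control_p] * config.n_control, seed * 10_000)
    model_fv, model_truth = simulate_group("M", model_profiles, seed * 10_000 + 1000)

    fraction_table = pd.DataFrame(
        np.vstack([fv.fractions for fv in control_fv + model_fv]),
        columns=[f"M{k}" for k in range(1, 41)],
    )
    fraction_table.insert(0, "animal_id",
                          [fv.animal_id for fv in control_fv + model_fv])
    fraction_table.insert(1, "group",
                          ["control"] * config.n_control + ["model"] * config.n_model)
    _write(fraction_table, out / "fractions.csv", config)

    # --- stage 2: diagnosis + behaviour space ------------------------------
    diagnosis = delirium_space.diagnose_pod(model_fv, control_fv, seed=seed)
    pod_fv = [fv for fv, lab in zip(model_fv, diagnosis.labels) if lab == "POD"]
    nonpod_fv = [fv for fv, lab in zip(model_fv, diagnosis.labels) if lab == "nonPOD"]

    if len(pod_fv) >= 2 and len(nonpod_fv) >= 2:
        comparison = behavior_metrics.select_significant_movements(
            pod_fv, nonpod_fv, alpha=config.alpha
        )
        _write(comparison.as_frame(), out / "movement_comparison.csv", config)
        # the 3-D embedding needs a few coordinates; small cohorts may select
        # fewer, in which case the designated discriminative set stands in
        selected = (comparison.selected if len(comparison.selected) >= 4
                    else synthetic_data.DISCRIMINATIVE_CLASSES)
    else:
        selected = synthetic_data.DISCRIMINATIVE_CLASSES
    diagnosis, space = delirium_space.build_delirium_space(
        model_fv, control_fv, selected, seed=seed,
        neighbor_param=config.neighbor_param,
    )
    diag_table = pd.DataFrame({
        "animal_id": [fv.animal_id for fv in model_fv],
        "true_profile": model_truth,
        "diagnosis": diagnosis.labels,
        "projection": space.projection_values,
        "raw_score": space.raw_scores,
        "y1": space.Y[:, 0], "y2": space.Y[:, 1], "y3": space.Y[:, 2],
    })
    _write(diag_table, out / "diagnosis.csv", config)

    # --- stage 3: investigation sessions + DSP ------------------------------
    arena = novel_object_arena()
    hyper = synthetic_data.hyper_profile()
    hypo = synthetic_data.hypo_profile()
    inv_rows = []
    inv_frames = min(n_frames, 3000)
    for i, (fv, lab) in enumerate(zip(model_fv, diagnosis.labels)):
        rng = np.random.default_rng(seed * 10_000 + 5000 + i)
        deep_share = 0.5 if lab == "POD" else 0.8
        bouts = []
        cursor = 200
        for b in range(6):
            length = int(rng.integers(40, 80))
            depth = "deep" if rng.random() < deep_share else "shallow"
            role = "novel" if b % 2 == 0 else "familiar"
            bouts.append(synthetic_data.ScheduledBout(
                start_frame=cursor, end_frame=cursor + length, role=role, depth=depth
            ))
            cursor += length + 200
        schedule = synthetic_data.InvestigationSchedule(
            bouts=tuple(bouts), n_frames=inv_frames
        )
        kin = hyper if i % 2 == 0 else hypo
        traj = synthetic_data.generate_investigation_session(
            schedule, arena, kin, seed=seed * 10_000 + 5000 + i,
            frame_rate=config.frame_rate,
        )
        record = investigation.investigation_record(
            traj, arena,
            labels=synthetic_data.generate_labels(
                synthetic_data.control_profile(), inv_frames,
                seed=seed * 10_000 + 7000 + i,
            ),
            deep_classes=(),  # depth from climb trigger: matches the schedule
            merge_gap=config.merge_gap,
        )
        inv_rows.append({
            "animal_id": fv.animal_id,
            "diagnosis": lab,
            "t_deep_s": record.t_deep,
            "t_shallow_s": record.t_shallow,
            "dsp_rad": record.dsp,
            "t_novel_s": record.per_object_time.get("novel", 0.0),
            "t_familiar_s": record.per_object_time.get("familiar", 0.0),
        })
    _write(pd.DataFrame(inv_rows), out / "investigation.csv", config)

    # --- stage 4: subtype clustering ----------------------------------------
    pod_idx = [i for i, lab in enumerate(diagnosis.labels) if lab == "POD"]
    subtype_table = None
    if len(pod_idx) >= 4 + 1:
        oft = open_field_arena()
        eig, subtype_truth = [], []
        pose_frames = min(n_frames, 3000)
        for j, i in enumerate(pod_idx):
            kin = hyper if j % 2 == 0 else hypo
            traj = synthetic_data.generate_skeleton(
                kin, oft, pose_frames, seed=seed * 10_000 + 8000 + i,
                frame_rate=config.frame_rate,
            )
            eig.extend(subtype_clustering.eigenvalue_matrix(
                [traj], config.feature_list, bins=config.pmf_bins
            ))
            subtype_truth.append(kin.label)
        neighbor = min(config.neighbor_param, len(pod_idx) - 1)
        subtypes = subtype_clustering.cluster_subtypes(
            eig, seed=seed, neighbor_param=neighbor
        )
        subtype_table = pd.DataFrame({
            "animal_id": [model_fv[i].animal_id for i in pod_idx],
            "true_subtype": subtype_truth,
            "subtype": subtypes.subtypes,
        })
        _write(subtype_table, out / "subtypes.csv", config)

    # --- stage 5: treatment evaluation ---------------------------------------
    cols = np.asarray(selected, dtype=int) - 1
    X_train = np.vstack([fv.fractions for fv in model_fv])[:, cols]
    report = dex_eval.train_classifier(
        X_train, np.asarray(diagnosis.labels),
        folds=config.cv_folds, iterations=config.cv_iterations, seed=seed,
    )
    n_dex_pod = round(config.dex_pod_rate * config.n_dex)
    dex_profiles = [pod_p] * n_dex_pod + [nonpod_p] * (config.n_dex - n_dex_pod)
    dex_fv, dex_truth = simulate_group("D", dex_profiles, seed * 10_000 + 9000)
    X_dex = np.vstack([fv.fractions for fv in dex_fv])[:, cols]
    incidence = dex_eval.predict_and_incidence(report, X_dex)
    model_incidence = dex_eval.predict_and_incidence(
        report, X_train
    )
    dex_table = pd.DataFrame({
        "animal_id": [fv.animal_id for fv in dex_fv],
        "true_profile": dex_truth,
        "predicted": incidence.labels,
    })
    _write(dex_table, out / "dex_predictions.csv", config)

    report_payload = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": seed,
        "selected_movements": list(selected),
        "n_pod": len(pod_fv),
        "n_nonpod": len(nonpod_fv),
        "cv_error": report.cv_error,
        "chosen_c": report.chosen_c,
        "model_incidence_pct": model_incidence.incidence,
        "dex_incidence_pct": incidence.incidence,
    }
    (out / "report.json").write_text(json.dumps(report_payload, indent=2))
    log.info("pipeline done: dex incidence %.1f%%", incidence.incidence)
    return report_payload
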