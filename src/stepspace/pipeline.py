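"""End-to-end orchestration: filter -> detect -> epochs -> templates -> stats.

These functions chain the per-module operations over a whole cohort and are
what both the command-line interface and the analysis scripts call. Every
stage's intermediate products (step events, epoch matrices, templates,
projections) are plain objects that can be written to disk and re-loaded, so
each stage is independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import FilterSpec, bandpass
from .sensor_io import MultiSensorRecording, SITES
from .steps import (
    EpochMatrix, PRE_S, POST_S, detect_steps, extract_epochs,
    foot_sagittal_profiles, harmonize_axes, rotational_step_mask, SENSOR_SIDE,
)
from .symmetry import COMBINATIONS, SymmetryPanel, symmetry_panel
from .template_rds import (
    N_PC_COHORT, RDSProjection, TemplateModel, build_template, project,
)

logger = logging.getLogger("stepspace")

SIGNAL_KINDS = ("acceleration", "velocity")
TRIGGERS = ("left", "right")


@dataclass
class SessionEpochs:
    """All step-aligned epoch matrices of one recording session."""

    participant_id: str
    session_id: str
    epochs: dict[tuple[str, str, str], EpochMatrix]  # (sensor, trigger, kind)
    n_detected: dict[str, int]
    n_ok: dict[str, int]
    n_rotational: dict[str, int]


def process_recording(
    rec: MultiSensorRecording,
    filter_spec: FilterSpec = FilterSpec(),
    pre_s: float = PRE_S,
    post_s: float = POST_S,
    rotational_n_sd: float = 1.0,
    rotational_direction: str = "below",
    signal_kinds: tuple[str, ...] = SIGNAL_KINDS,
    guard_s: float = 0.5,
) -> SessionEpochs:
    """Filter, detect steps on both feet, and extract all epoch matrices.

    The rotational-step PCA filter runs per foot on that foot's own sagittal
    profiles; a step it rejects is dropped from every sensor's epochs for that
    trigger (steps are whole-body events). ``guard_s`` keeps epochs away from
    the recording edges where the zero-phase filter's boundary transient lives.
    """
    filtered = {site: bandpass(arr, rec.sample_rate, filter_spec)
                for site, arr in rec.sites.items()}
    events = detect_steps(rec, filtered, pre_s=pre_s, post_s=post_s,
                          guard_s=guard_s)

    keep_masks: dict[str, np.ndarray] = {}
    stats_detected, stats_ok, stats_rot = {}, {}, {}
    for side, ev in events.items():
        n_ok = ev.ok_onsets.size
        stats_detected[side] = int(ev.onsets.size)
        stats_ok[side] = int(n_ok)
        if n_ok >= 3:
            profiles = foot_sagittal_profiles(
                rec, ev, filtered[f"{side}_foot"], pre_s=pre_s, post_s=post_s)
            keep = rotational_step_mask(
                profiles, n_sd=rotational_n_sd, direction=rotational_direction)
        else:
            keep = np.ones(n_ok, dtype=bool)
        keep_masks[side] = keep
        stats_rot[side] = int(n_ok - keep.sum())

    epochs: dict[tuple[str, str, str], EpochMatrix] = {}
    for side, ev in events.items():
        keep = keep_masks[side]
        for sensor in rec.sites:
            for kind in signal_kinds:
                em = extract_epochs(
                    rec, ev, sensor, pre_s=pre_s, post_s=post_s,
                    signal_kind=kind, site_data=filtered[sensor],
                )
                epochs[(sensor, side, kind)] = em.subset(keep)
    return SessionEpochs(
        participant_id=rec.participant_id, session_id=rec.session_id,
        epochs=epochs, n_detected=stats_detected, n_ok=stats_ok,
        n_rotational=stats_rot,
    )


def random_control_sessions(
    recordings: dict[tuple[str, str], MultiSensorRecording],
    n_events: int,
    rng: np.random.Generator,
    filter_spec: FilterSpec = FilterSpec(),
    signal_kinds: tuple[str, ...] = SIGNAL_KINDS,
) -> dict[tuple[str, str], SessionEpochs]:
    """Negative-control counterpart of ``process_recording`` over a cohort.

    Epochs are aligned to uniformly random trigger times instead of detected
    steps; everything downstream (templates, projections, statistics) runs
    unchanged on the result.
    """
    from .cohort_stats import random_event_control

    sessions = {}
    for (pid, sid), rec in recordings.items():
        filtered = {site: bandpass(arr, rec.sample_rate, filter_spec)
                    for site, arr in rec.sites.items()}
        epochs = random_event_control(rec, filtered, n_events, rng,
                                      signal_kinds=signal_kinds)
        sessions[(pid, sid)] = SessionEpochs(
            participant_id=pid, session_id=sid, epochs=epochs,
            n_detected={}, n_ok={}, n_rotational={},
        )
    return sessions


# -- cohort templates and projections --------------------------------------------

def build_cohort_templates(
    sessions: dict[tuple[str, str], SessionEpochs],
    cohort: pd.DataFrame,
    n_pc: int = N_PC_COHORT,
    reference_group: str = "HV",
    rows: str = "steps",
) -> dict[tuple[str, str, str], TemplateModel]:
    """Fit one healthy-reference template per (sensor, trigger, signal kind).

    ``rows="steps"`` stacks every valid step of every reference participant;
    ``rows="participant_means"`` uses each participant-session's mean step.
    """
    ref_keys = {
        (r.participant_id, r.session_id)
        for r in cohort.itertuples() if r.group == reference_group
    }
    templates = {}
    for combo in _epoch_keys(sessions):
        blocks = []
        for key, sess in sessions.items():
            if key not in ref_keys or combo not in sess.epochs:
                continue
            em = sess.epochs[combo]
            if em.n_steps == 0:
                continue
            blocks.append(em.rows.mean(axis=0, keepdims=True)
                          if rows == "participant_means" else em.rows)
        if not blocks:
            continue
        reference = np.vstack(blocks)
        sensor, trigger, kind = combo
        templates[combo] = build_template(
            reference, n_pc=n_pc, scope="cohort",
            sensor=sensor, trigger_side=trigger, signal_kind=kind,
        )
    return templates


def _epoch_keys(sessions) -> list[tuple[str, str, str]]:
    keys = set()
    for sess in sessions.values():
        keys.update(sess.epochs)
    return sorted(keys)


def project_sessions(
    sessions: dict[tuple[str, str], SessionEpochs],
    templates: dict[tuple[str, str, str], TemplateModel],
) -> dict[tuple[str, str], dict[tuple[str, str, str], RDSProjection]]:
    """Project every session's epochs on the cohort templates."""
    out = {}
    for key, sess in sessions.items():
        projs = {}
        for combo, model in templates.items():
            em = sess.epochs.get(combo)
            if em is None or em.n_steps == 0:
                continue
            projs[combo] = project(model, em)
        out[key] = projs
    return out


def session_mean_features(
    projections: dict[tuple[str, str], dict],
    combo: tuple[str, str, str],
) -> pd.DataFrame:
    """One row per session: mean RDS coordinates for one sensor/trigger/kind."""
    rows = []
    for (pid, sid), projs in projections.items():
        proj = projs.get(combo)
        if proj is None or proj.n_steps == 0:
            continue
        rec = {"participant_id": pid, "session_id": sid}
        mean = proj.coords.mean(axis=0)
        rec.update({f"pc{i + 1}": mean[i] for i in range(mean.size)})
        rows.append(rec)
    return pd.DataFrame(rows)


# -- symmetry ---------------------------------------------------------------------

def _harmonization_side(sensor: str, trigger: str) -> str:
    """Which 'left/right' label drives sign harmonization for a combo member.

    Lateral sensors are harmonized by their own body side; midline sensors
    (lumbar, sternum), compared across left- vs right-triggered epochs, are
    harmonized by the trigger side so that the mirrored mediolateral sway
    projects in the same direction.
    """
    side = SENSOR_SIDE[sensor]
    return trigger if side == "midline" else side


def build_symmetry_templates(
    sessions: dict[tuple[str, str], SessionEpochs],
    cohort: pd.DataFrame,
    signal_kind: str = "acceleration",
    n_pc: int = N_PC_COHORT,
    reference_group: str = "HV",
) -> dict[str, TemplateModel]:
    """One shared template per combination, on pooled sign-adjusted reference steps."""
    ref_keys = {
        (r.participant_id, r.session_id)
        for r in cohort.itertuples() if r.group == reference_group
    }
    templates = {}
    for combo, members in COMBINATIONS.items():
        blocks = []
        for key, sess in sessions.items():
            if key not in ref_keys:
                continue
            for sensor, trigger in members:
                em = sess.epochs.get((sensor, trigger, signal_kind))
                if em is None or em.n_steps == 0:
                    continue
                blocks.append(harmonize_axes(
                    em, _harmonization_side(sensor, trigger)).rows)
        if not blocks:
            continue
        templates[combo] = build_template(
            np.vstack(blocks), n_pc=n_pc, scope="cohort",
            sensor=f"symmetry:{combo}", trigger_side="both",
            signal_kind=signal_kind,
        )
    return templates


def session_symmetry_panel(
    sess: SessionEpochs,
    templates: dict[str, TemplateModel],
    signal_kind: str = "acceleration",
    normalized: bool = True,
) -> SymmetryPanel:
    """The four left/right similarity scores for one session."""
    projections = {}
    for combo, members in COMBINATIONS.items():
        model = templates.get(combo)
        if model is None:
            continue
        for sensor, trigger in members:
            em = sess.epochs.get((sensor, trigger, signal_kind))
            if em is None or em.n_steps == 0:
                continue
            harm = harmonize_axes(em, _harmonization_side(sensor, trigger))
            projections[(sensor, trigger)] = project(model, harm)
    return symmetry_panel(
        projections, participant_id=sess.participant_id,
        session_id=sess.session_id, normalized=normalized,
    )


def cohort_symmetry_table(
    sessions: dict[tuple[str, str], SessionEpochs],
    templates: dict[str, TemplateModel],
    cohort: pd.DataFrame,
    signal_kind: str = "acceleration",
    normalized: bool = True,
) -> pd.DataFrame:
    """Long table: one row per session per combination, joined with UPDRS."""
    records = []
    for sess in sessions.values():
        panel = session_symmetry_panel(
            sess, templates, signal_kind=signal_kind, normalized=normalized)
        records.extend(panel.as_records())
    table = pd.DataFrame(records)
    return table.merge(cohort, on=["participant_id", "session_id"], how="left")


# -- manifest ----------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    package_version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def manifest_id(self) -> str:
        payload = json.dumps(
            {"config": self.config, "seed": self.seed,
             "version": self.package_version, "inputs": self.input_hashes},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({
                "manifest_id": self.manifest_id,
                "config": self.config,
                "seed": self.seed,
                "package_version": self.package_version,
                "input_hashes": self.input_hashes,
                "outputs": self.outputs,
                "warnings": self.warnings,
            }, f, indent=2, default=str)
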