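"""PCA movement templates and the reduced dimensionality space (RDS).

A movement template summarizes the stereotyped step-aligned waveform of a
reference set of epochs: the mean vector plus the leading principal components
of the row-sample covariance. Projecting a new step onto the template's
components yields a low-dimensional coordinate vector (its RDS position);
reconstruction maps coordinates back to the waveform domain. Cohort-scope
templates (3 PCs, fitted on every step of a healthy reference cohort) measure
divergence from healthy movement; personalized templates (2 PCs, fitted on one
participant's own steps) resolve within-person contrasts such as medication
state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .steps import EpochMatrix

#: default number of components per scope
N_PC_COHORT = 3
N_PC_PERSONALIZED = 2

TEMPLATE_FORMAT_VERSION = 1


@dataclass
class TemplateModel:
    """Cohort mean + principal-component coefficients defining an RDS."""

    sensor: str
    trigger_side: str
    signal_kind: str
    mean: np.ndarray  # (3L,)
    components: np.ndarray  # n_pc x 3L, orthonormal rows
    eigenvalues: np.ndarray  # n_pc, non-increasing
    variance_fraction: np.ndarray  # n_pc, per-PC fraction of total variance
    n_reference_steps: int
    scope: str = "cohort"  # "cohort" | "personalized"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(self.variance_fraction < -1e-12) or np.any(self.variance_fraction > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")

    @property
    def n_pc(self) -> int:
        return self.components.shape[0]

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format_version": TEMPLATE_FORMAT_VERSION,
            "sensor": self.sensor,
            "trigger_side": self.trigger_side,
            "signal_kind": self.signal_kind,
            "scope": self.scope,
            "n_reference_steps": int(self.n_reference_steps),
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "TemplateModel":
        with open(path) as f:
            payload = json.load(f)
        version = payload.pop("format_version", None)
        if version != TEMPLATE_FORMAT_VERSION:
            raise ValueError(f"unsupported template format version {version}")
        return cls(
            sensor=payload["sensor"],
            trigger_side=payload["trigger_side"],
            signal_kind=payload["signal_kind"],
            scope=payload["scope"],
            n_reference_steps=payload["n_reference_steps"],
            mean=np.asarray(payload["mean"]),
            components=np.asarray(payload["components"]),
            eigenvalues=np.asarray(payload["eigenvalues"]),
            variance_fraction=np.asarray(payload["variance_fraction"]),
        )


@dataclass
class RDSProjection:
    """Per-step coordinates in a template's reduced dimensionality space."""

    coords: np.ndarray  # n_steps x n_pc
    step_ids: np.ndarray
    participant_id: str = ""
    session_id: str = ""
    sensor: str = ""
    trigger_side: str = ""
    signal_kind: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, self.coords.shape[-1] if self.coords.ndim > 1 else 0)
        self.step_ids = np.asarray(self.step_ids, dtype=int)
        if self.coords.shape[0] != self.step_ids.size:
            raise ValueError("one step id per coordinate row required")

    @property
    def n_steps(self) -> int:
        return self.coords.shape[0]

    @property
    def n_pc(self) -> int:
        return self.coords.shape[1]


# -- template construction ------------------------------------------------------

def build_template(
    reference: EpochMatrix | np.ndarray,
    n_pc: int = N_PC_COHORT,
    scope: str = "cohort",
    sensor: str = "",
    trigger_side: str = "",
    signal_kind: str = "",
) -> TemplateModel:
    """Fit a PCA movement template on reference epoch rows.

    The mean is the column mean of the reference rows; components and
    eigenvalues come from the eigendecomposition of the row-sample covariance
    (via SVD of the centered matrix), with the top ``n_pc`` retained.
    ``variance_fraction`` is each eigenvalue over the covariance trace. Each
    component's sign is fixed so its largest-magnitude coefficient is positive,
    making templates reproducible across eigensolvers.
    """
    if isinstance(reference, EpochMatrix):
        rows = reference.rows
        sensor = sensor or reference.sensor
        trigger_side = trigger_side or reference.trigger_side
        signal_kind = signal_kind or reference.signal_kind
    else:
        rows = np.atleast_2d(np.asarray(reference, dtype=float))
    n, p = rows.shape
    if n_pc < 1:
        raise ValueError("n_pc must be >= 1")
    if n < n_pc + 1:
        raise ValueError(f"need at least n_pc + 1 = {n_pc + 1} reference rows, got {n}")

    mean = rows.mean(axis=0)
    centered = rows - mean
    total_var = float(np.sum(centered ** 2) / (n - 1))
    if total_var == 0:
        raise ValueError("reference rows have zero total variance")

    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    comps = vt[:n_pc]
    eig = eigenvalues[:n_pc]

    # deterministic sign: largest-magnitude coefficient positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]

    return TemplateModel(
        sensor=sensor,
        trigger_side=trigger_side,
        signal_kind=signal_kind,
        mean=mean,
        components=comps,
        eigenvalues=eig,
        variance_fraction=eig / total_var,
        n_reference_steps=n,
        scope=scope,
    )


def participant_mean_rows(epochs: list[EpochMatrix]) -> np.ndarray:
    """One average-step row per epoch matrix (per participant-session).

    Alternative reference layout for template building: instead of every
    individual step contributing a row, each participant contributes their
    mean step.
    """
    return np.vstack([e.rows.mean(axis=0) for e in epochs if e.n_steps > 0])


# -- projection / reconstruction -------------------------------------------------

def project(model: TemplateModel, epochs: EpochMatrix | np.ndarray) -> RDSProjection:
    """Project epoch rows into the template's RDS.

    Coordinates are ``components @ (row - mean)``; external data (e.g. PD
    participants on a healthy-cohort template) are centered with the
    template's own reference mean, so coordinates measure divergence from the
    reference.
    """
    if isinstance(epochs, EpochMatrix):
        rows, ids = epochs.rows, epochs.step_ids
        meta = dict(
            participant_id=epochs.participant_id, session_id=epochs.session_id,
            sensor=epochs.sensor, trigger_side=epochs.trigger_side,
            signal_kind=epochs.signal_kind,
        )
    else:
        rows = np.atleast_2d(np.asarray(epochs, dtype=float))
        ids = np.arange(rows.shape[0])
        meta = {}
    if rows.shape[0] and rows.shape[1] != model.mean.size:
        raise ValueError(
            f"epoch row length {rows.shape[1]} != template length {model.mean.size}"
        )
    coords = (rows - model.mean) @ model.components.T if rows.size else \
        np.zeros((0, model.n_pc))
    return RDSProjection(coords=coords, step_ids=ids, **meta)


def reconstruct(model: TemplateModel, proj: RDSProjection | np.ndarray) -> np.ndarray:
    """Map RDS coordinates back to waveform rows: ``mean + componentsᵀ coords``."""
    coords = proj.coords if isinstance(proj, RDSProjection) else \
        np.atleast_2d(np.asarray(proj, dtype=float))
    if coords.shape[1] != model.n_pc:
        raise ValueError(f"coordinate dim {coords.shape[1]} != n_pc {model.n_pc}")
    return model.mean + coords @ model.components


def combine_features(acc: RDSProjection, vel: RDSProjection) -> np.ndarray:
    """Concatenate acceleration and velocity coordinates per step (acc block first)."""
    if acc.n_steps != vel.n_steps or not np.array_equal(acc.step_ids, vel.step_ids):
        raise ValueError("acceleration and velocity projections must share step ids")
    if acc.n_steps == 0:
        return np.zeros((0, acc.n_pc + vel.n_pc))
    return np.hstack([acc.coords, vel.coords])
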