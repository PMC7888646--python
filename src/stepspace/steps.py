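"""Step detection and step-aligned epoch extraction.

Step onsets are detected on each foot's band-passed acceleration as upward
crossings of a 2 m/s^2 threshold on the sagittal-plane magnitude (the Euclidean
norm of the anteroposterior and vertical components), which captures the start
of heel lift. A step is kept only if it lasts longer than 625 ms; steps whose
sagittal profile is atypical (rotational movement during turns) are removed by
a PCA outlier filter. Around each accepted onset, a window from 250 ms before
to 1000 ms after is cut from every sensor and the three axes are concatenated
into one row, giving the epoch matrices everything downstream consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import integrate_velocity
from .sensor_io import MultiSensorRecording

#: default epoch window in seconds around each onset
PRE_S = 0.250
POST_S = 1.000
#: sagittal-plane threshold on foot acceleration, m/s^2
STEP_THRESHOLD = 2.0
#: minimum successful step duration, s
MIN_STEP_DURATION_S = 0.625
#: detector refractory period suppressing secondary crossings within one
#: burst; shorter than the minimum step duration so that genuinely short
#: inter-step intervals are still seen (and then flagged too_short)
REFRACTORY_S = 0.3

FLAG_OK = "ok"
FLAG_TOO_SHORT = "too_short"
FLAG_EDGE = "edge"
FLAG_ROTATIONAL = "rotational"


@dataclass
class StepEventSeries:
    """Detected step onsets for one foot, with per-onset validity flags."""

    side: str  # "left" | "right"
    onsets: np.ndarray  # sample indices, strictly increasing
    flags: list[str]
    sample_rate: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.flags) != self.onsets.size:
            raise ValueError("one flag per onset required")

    @property
    def ok_onsets(self) -> np.ndarray:
        return self.onsets[[f == FLAG_OK for f in self.flags]]

    def onset_times_s(self) -> np.ndarray:
        return self.onsets / self.sample_rate


@dataclass
class EpochMatrix:
    """Steps x features matrix of concatenated X/Y/Z epoch samples.

    Each row is one valid step at one sensor: the three axis blocks over the
    epoch window laid end to end (x-block then y-block then z-block, length
    3L). ``step_ids`` ties rows back to the detected onsets; ``axis_directions``
    records the anatomical direction of each block so sign harmonization can
    find the mediolateral block.
    """

    sensor: str
    trigger_side: str
    signal_kind: str  # "acceleration" | "velocity"
    rows: np.ndarray  # n_steps x 3L
    step_ids: np.ndarray  # onset sample index per row
    participant_id: str = ""
    session_id: str = ""
    axis_directions: tuple[str, str, str] = (
        "anteroposterior", "mediolateral", "vertical",
    )

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        self.step_ids = np.asarray(self.step_ids, dtype=int)
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, self.rows.shape[-1] if self.rows.ndim > 1 else 0)
        if self.rows.shape[0] != self.step_ids.size:
            raise ValueError("one step id per row required")
        if self.rows.shape[1] % 3 != 0:
            raise ValueError("row length must be 3 * epoch length")

    @property
    def n_steps(self) -> int:
        return self.rows.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.rows.shape[1] // 3

    def axis_block(self, direction: str) -> np.ndarray:
        """View of the block for one anatomical direction (n_steps x L)."""
        i = self.axis_directions.index(direction)
        L = self.epoch_len
        return self.rows[:, i * L:(i + 1) * L]

    def subset(self, keep: np.ndarray) -> "EpochMatrix":
        return replace(self, rows=self.rows[keep], step_ids=self.step_ids[keep])


# -- detection ----------------------------------------------------------------

def sagittal_magnitude(foot: np.ndarray, ap_idx: int = 0, vert_idx: int = 2) -> np.ndarray:
    """Euclidean norm of the anteroposterior and vertical acceleration."""
    foot = np.asarray(foot, dtype=float)
    return np.hypot(foot[:, ap_idx], foot[:, vert_idx])


def detect_step_onsets(
    foot: np.ndarray,
    rate: float,
    side: str = "left",
    threshold: float = STEP_THRESHOLD,
    min_duration_s: float = MIN_STEP_DURATION_S,
    refractory_s: float = REFRACTORY_S,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
    guard_s: float = 0.0,
    ap_idx: int = 0,
    vert_idx: int = 2,
) -> StepEventSeries:
    """Detect step onsets on one foot's (filtered) tri-axial acceleration.

    An onset is the first sample at which the sagittal magnitude crosses the
    threshold upward, at least ``refractory_s`` after the previous accepted
    onset. Step duration is the interval to the next same-foot onset; onsets
    with duration <= ``min_duration_s`` are flagged ``too_short``, onsets whose
    epoch window does not fit inside the recording are flagged ``edge``. The
    last onset of a bout has undefined duration and is kept if its window fits.
    ``guard_s`` widens the edge test by a settle margin on each side, keeping
    epochs clear of the zero-phase filter's boundary transients.
    """
    mag = sagittal_magnitude(foot, ap_idx, vert_idx)
    above = mag >= threshold
    ups = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        ups = np.concatenate([[0], ups])

    refractory = int(round(refractory_s * rate))
    accepted: list[int] = []
    last = -np.inf
    for c in ups:
        if c - last >= refractory:
            accepted.append(int(c))
            last = c
    onsets = np.asarray(accepted, dtype=int)

    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))
    guard = int(round(guard_s * rate))
    min_dur = min_duration_s * rate
    T = mag.size
    flags = []
    for i, on in enumerate(onsets):
        if on - pre - guard < 0 or on + post + guard > T:
            flags.append(FLAG_EDGE)
        elif i + 1 < onsets.size and (onsets[i + 1] - on) <= min_dur:
            flags.append(FLAG_TOO_SHORT)
        else:
            flags.append(FLAG_OK)
    return StepEventSeries(side=side, onsets=onsets, flags=flags, sample_rate=rate)


def detect_steps(
    rec: MultiSensorRecording,
    filtered_sites: dict[str, np.ndarray],
    **kwargs,
) -> dict[str, StepEventSeries]:
    """Detect onsets for both feet of a recording, using the axis convention."""
    out = {}
    for side, site in (("left", "left_foot"), ("right", "right_foot")):
        if site not in filtered_sites:
            continue
        ap = rec.anatomical_axis_index(site, "anteroposterior")
        vert = rec.anatomical_axis_index(site, "vertical")
        out[side] = detect_step_onsets(
            filtered_sites[site], rec.sample_rate, side=side,
            ap_idx=ap, vert_idx=vert, **kwargs,
        )
    return out


# -- epoch extraction ----------------------------------------------------------

def extract_epochs(
    rec: MultiSensorRecording,
    events: StepEventSeries,
    sensor: str,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
    signal_kind: str = "acceleration",
    site_data: np.ndarray | None = None,
) -> EpochMatrix:
    """Cut step-aligned epochs from one sensor and concatenate the axes.

    The window is the half-open sample range
    ``[onset - round(pre_s * rate), onset + round(post_s * rate))`` — 160
    samples at 128 Hz, so each row has length 480. For ``signal_kind``
    "velocity" each epoch is integrated (trapezoid, zero initial velocity)
    before concatenation. ``site_data`` overrides the raw site array, letting
    the caller supply band-passed samples on the same clock.
    """
    if signal_kind not in ("acceleration", "velocity"):
        raise ValueError(f"unknown signal_kind {signal_kind!r}")
    data = rec.sites[sensor] if site_data is None else np.asarray(site_data, dtype=float)
    rate = rec.sample_rate
    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))
    L = pre + post
    T = data.shape[0]

    rows, ids = [], []
    for on, flag in zip(events.onsets, events.flags):
        if flag != FLAG_OK:
            continue
        lo, hi = on - pre, on + post
        if lo < 0 or hi > T:  # defensive; detect already flags edges
            continue
        ep = data[lo:hi]
        if signal_kind == "velocity":
            ep = integrate_velocity(ep, rate)
        rows.append(ep.T.reshape(-1))  # x-block ‖ y-block ‖ z-block
        ids.append(on)

    conv = rec.axis_convention.get(sensor, {})
    dirs = tuple(conv.get(a, d) for a, d in zip("xyz", (
        "anteroposterior", "mediolateral", "vertical")))
    return EpochMatrix(
        sensor=sensor,
        trigger_side=events.side,
        signal_kind=signal_kind,
        rows=np.asarray(rows, dtype=float).reshape(len(rows), 3 * L),
        step_ids=np.asarray(ids, dtype=int),
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        axis_directions=dirs,
    )


# -- rotational-step exclusion --------------------------------------------------

def first_pc_scores(rows: np.ndarray) -> np.ndarray:
    """Projection of each row on the first principal component of the rows."""
    rows = np.asarray(rows, dtype=float)
    centered = rows - rows.mean(axis=0)
    # SVD of the centered matrix: right singular vector 0 is PC1
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros(rows.shape[0])
    pc1 = vt[0]
    # deterministic sign (largest-magnitude coefficient positive), matching
    # the template-building convention, so "below mean - sd" is well defined
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return centered @ pc1


def rotational_step_mask(
    sagittal_rows: np.ndarray, n_sd: float = 1.0, direction: str = "below"
) -> np.ndarray:
    """Boolean mask of steps to KEEP after the PCA rotational-step filter.

    PCA is fitted on the per-step sagittal profiles of one foot; steps whose
    first-PC score is an outlier relative to the score distribution are marked
    rotational. ``direction="below"`` removes scores under mean - n_sd * sd
    (the outlier reading); ``direction="above"`` removes scores over
    mean - n_sd * sd instead, preserving a literal reading of the rule.
    """
    sagittal_rows = np.atleast_2d(np.asarray(sagittal_rows, dtype=float))
    n = sagittal_rows.shape[0]
    if n < 3:
        raise ValueError("need at least 3 steps to estimate the score spread")
    scores = first_pc_scores(sagittal_rows)
    cutoff = scores.mean() - n_sd * scores.std(ddof=0)
    if scores.std(ddof=0) == 0:
        return np.ones(n, dtype=bool)
    if direction == "below":
        return scores >= cutoff
    if direction == "above":
        return scores <= cutoff
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def exclude_rotational_steps(
    epochs: EpochMatrix, n_sd: float = 1.0, direction: str = "below",
    sagittal_rows: np.ndarray | None = None,
) -> EpochMatrix:
    """Drop rotational steps from an epoch matrix.

    By default the filter's PCA runs on the epoch rows themselves (appropriate
    when ``epochs`` holds the foot's own sagittal profiles); pass
    ``sagittal_rows`` to score on a separate per-step profile matrix aligned
    row-for-row with ``epochs``.
    """
    basis = epochs.rows if sagittal_rows is None else np.asarray(sagittal_rows, float)
    if basis.shape[0] != epochs.n_steps:
        raise ValueError("sagittal_rows must align with epoch rows")
    keep = rotational_step_mask(basis, n_sd=n_sd, direction=direction)
    return epochs.subset(keep)


def foot_sagittal_profiles(
    rec: MultiSensorRecording,
    events: StepEventSeries,
    filtered_foot: np.ndarray,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
) -> np.ndarray:
    """Per-step sagittal magnitude profiles of one foot (n_ok_steps x L)."""
    site = f"{events.side}_foot"
    ap = rec.anatomical_axis_index(site, "anteroposterior")
    vert = rec.anatomical_axis_index(site, "vertical")
    mag = sagittal_magnitude(filtered_foot, ap, vert)
    rate = rec.sample_rate
    pre, post = int(round(pre_s * rate)), int(round(post_s * rate))
    rows = [mag[on - pre:on + post] for on in events.ok_onsets]
    return np.asarray(rows, dtype=float).reshape(len(rows), pre + post)


# -- axis harmonization ----------------------------------------------------------

#: sensor sites on each side of the body; midline sites are left untouched
SENSOR_SIDE = {
    "left_foot": "left", "left_wrist": "left",
    "right_foot": "right", "right_wrist": "right",
    "lumbar": "midline", "sternum": "midline",
}


def harmonize_axes(epochs: EpochMatrix, side_of_sensor: str | None = None) -> EpochMatrix:
    """Make left- and right-side movements directionally comparable.

    For left-side sensors the mediolateral axis block is negated so that
    laterally-mirrored movements project in the same directions; right-side
    and midline sensors pass through unchanged. Applying the operation twice
    returns the original epochs.
    """
    side = SENSOR_SIDE[epochs.sensor] if side_of_sensor is None else side_of_sensor
    if side not in ("left", "right", "midline"):
        raise ValueError(f"side must be left/right/midline, got {side!r}")
    if side != "left":
        return replace(epochs, rows=epochs.rows.copy())
    rows = epochs.rows.copy()
    i = epochs.axis_directions.index("mediolateral")
    L = epochs.epoch_len
    rows[:, i * L:(i + 1) * L] *= -1.0
    return replace(epochs, rows=rows)
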