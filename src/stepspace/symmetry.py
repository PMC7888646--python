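"""Left/right body-symmetry scores from RDS projections.

Symmetry of gait is quantified as the similarity between the average RDS
positions of paired body-part/trigger combinations. Left and right epochs are
first made directionally comparable (mediolateral sign harmonization), then
projected on one shared template per combination; each side's step cloud is
summarized by its mean coordinate vector and the two means are compared with a
cosine (default) or raw dot-product similarity. Four combinations capture gait
coordination:

a. feet:    right foot at right steps vs left foot at left steps
b. wrists:  right wrist at left steps vs left wrist at right steps
   (arm swing is anti-phase with the stepping foot)
c. lumbar:  lumbar at right steps vs lumbar at left steps
d. sternum: sternum at right steps vs sternum at left steps
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .template_rds import RDSProjection

#: the four symmetry combinations as ((sensor, trigger), (sensor, trigger))
COMBINATIONS = {
    "feet": (("right_foot", "right"), ("left_foot", "left")),
    "wrists": (("right_wrist", "left"), ("left_wrist", "right")),
    "lumbar": (("lumbar", "right"), ("lumbar", "left")),
    "sternum": (("sternum", "right"), ("sternum", "left")),
}


def mean_projection(proj: RDSProjection | np.ndarray) -> np.ndarray:
    """Component-wise mean of the per-step coordinates (the cluster centre)."""
    coords = proj.coords if isinstance(proj, RDSProjection) else np.atleast_2d(proj)
    if coords.shape[0] == 0:
        raise ValueError("cannot average an empty projection")
    return coords.mean(axis=0)


def similarity(a: np.ndarray, b: np.ndarray, normalized: bool = True) -> float:
    """Dot-product similarity between two mean coordinate vectors.

    With ``normalized=True`` (default) this is the cosine of the angle,
    bounded in [-1, 1] and invariant to movement amplitude; ``False`` returns
    the raw dot product.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have the same dimension")
    dot = float(a @ b)
    if not normalized:
        return dot
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(dot / (na * nb), -1.0, 1.0))


@dataclass
class SymmetryPanel:
    """The four per-session similarity scores, NaN where a side lacked steps."""

    participant_id: str
    session_id: str
    scores: dict[str, float]
    reasons: dict[str, str]

    def as_records(self) -> list[dict]:
        return [
            {"participant_id": self.participant_id, "session_id": self.session_id,
             "combo": combo, "score": self.scores[combo],
             "reason": self.reasons.get(combo, "")}
            for combo in COMBINATIONS
        ]


def symmetry_panel(
    projections: dict[tuple[str, str], RDSProjection],
    participant_id: str = "",
    session_id: str = "",
    normalized: bool = True,
) -> SymmetryPanel:
    """Compute the four combination scores for one participant-session.

    ``projections`` maps (sensor, trigger_side) to the session's RDS
    projection, where epochs were axis-harmonized before projection on the
    combination's shared template. A combination missing steps (or a sensor)
    on either side scores NaN with a reason.
    """
    scores: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for combo, (key_a, key_b) in COMBINATIONS.items():
        pa, pb = projections.get(key_a), projections.get(key_b)
        if pa is None or pb is None:
            scores[combo] = math.nan
            reasons[combo] = f"missing projection for {key_a if pa is None else key_b}"
            continue
        if pa.n_steps == 0 or pb.n_steps == 0:
            scores[combo] = math.nan
            reasons[combo] = "no valid steps on one side"
            continue
        try:
            scores[combo] = similarity(
                mean_projection(pa), mean_projection(pb), normalized=normalized
            )
        except ValueError as err:
            scores[combo] = math.nan
            reasons[combo] = str(err)
    return SymmetryPanel(participant_id, session_id, scores, reasons)


def severity_regression(
    panels: pd.DataFrame, updrs_col: str = "updrs3_total", score_col: str = "score",
) -> pd.DataFrame:
    """Regress each combination's similarity on the UPDRS part-3 total.

    ``panels`` holds one row per participant-session per combination
    (columns: combo, score, updrs3_total); ON and OFF sessions count as
    independent observations. Returns per-combination r^2, p (overall-F of the
    simple regression), slope and n.
    """
    out = []
    for combo, g in panels.groupby("combo"):
        g = g.dropna(subset=[score_col, updrs_col])
        n = len(g)
        if n < 3:
            raise ValueError(f"combination {combo!r}: need >= 3 observations, got {n}")
        res = stats.linregress(g[updrs_col].astype(float), g[score_col].astype(float))
        out.append({
            "combo": combo, "r2": res.rvalue ** 2, "p": res.pvalue,
            "slope": res.slope, "n": n,
        })
    return pd.DataFrame(out).set_index("combo")
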