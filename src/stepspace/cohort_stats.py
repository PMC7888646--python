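"""Group comparisons, severity regression, classification and null controls.

All group-level inference runs on RDS coordinates. Distributions of wearable
gait features are typically non-normal, so group contrasts use the two-sided
Mann-Whitney U test with Bonferroni correction across the sensor/trigger/
signal grid. Severity is modelled by ordinary least squares of the UPDRS
part-3 total on per-session mean coordinates. HV-vs-PD classification runs
four standard classifiers (logistic regression, decision tree, random forest,
Gaussian naive Bayes) under participant-grouped 10-fold cross-validation so no
participant appears in both a fold's train and test split. Medication-state
(ON/OFF) discrimination fits a personalized 2-PC template per participant and
compares per-PC coordinate distributions. A random-event control rebuilds the
whole RDS from uniformly random (non-step) trigger times as a negative
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .steps import EpochMatrix, extract_epochs, StepEventSeries, FLAG_OK
from .template_rds import (
    N_PC_PERSONALIZED, RDSProjection, build_template, project,
)

ALPHA = 0.05
#: Bonferroni defaults: 12 = 6 sensors x 2 triggers for group U-tests;
#: 24 = 6 sensors x 2 triggers x 2 signal kinds for severity regressions.
M_GROUP_TESTS = 12
M_SEVERITY_TESTS = 24


# -- HV vs PD group comparison ---------------------------------------------------

@dataclass
class ComparisonResult:
    """Per-PC Mann-Whitney U contrast with Bonferroni-corrected significance."""

    sensor: str
    trigger_side: str
    signal_kind: str
    u_statistics: np.ndarray
    p_values: np.ndarray
    m_comparisons: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(np.min(self.p_values) < self.alpha / self.m_comparisons)


def _coord_matrix(proj) -> np.ndarray:
    if isinstance(proj, RDSProjection):
        return proj.coords
    return np.atleast_2d(np.asarray(proj, dtype=float))


def compare_groups(
    hv_proj, pd_proj, m: int = M_GROUP_TESTS,
    sensor: str = "", trigger_side: str = "", signal_kind: str = "",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U per PC coordinate, Bonferroni over ``m`` tests.

    Accepts RDS projections or plain coordinate matrices; rows are the
    observations (steps, or per-session means — the caller decides the unit of
    analysis).
    """
    a, b = _coord_matrix(hv_proj), _coord_matrix(pd_proj)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the coordinate dimension")
    us, ps = [], []
    for j in range(a.shape[1]):
        res = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided")
        us.append(res.statistic)
        ps.append(res.pvalue)
    return ComparisonResult(
        sensor=sensor, trigger_side=trigger_side, signal_kind=signal_kind,
        u_statistics=np.asarray(us), p_values=np.asarray(ps),
        m_comparisons=m, alpha=alpha,
    )


# -- severity regression ----------------------------------------------------------

def regress_severity(features: np.ndarray, updrs: np.ndarray) -> tuple[float, float]:
    """OLS of the UPDRS total on per-session mean RDS coordinates.

    ``features`` is n_sessions x k (k = 3 for one signal kind, 6 for combined
    acceleration + velocity). Returns (r^2, overall-F p-value).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(updrs, dtype=float)
    n, k = X.shape
    if n != y.size:
        raise ValueError("one UPDRS value per feature row required")
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations, got {n}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.rsquared), float(fit.f_pvalue)


# -- classification harness --------------------------------------------------------

CLASSIFIERS = ("LR", "DT", "RF", "NB")


def _make_classifier(name: str, seed: int):
    if name == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "NB":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class ClassifierReport:
    """Cross-validated metrics per classifier for one feature set."""

    sensor: str
    trigger_side: str
    signal_kind: str
    metrics: pd.DataFrame  # index classifier, columns accuracy/auc/precision/f1
    fold_scheme: str
    seed: int
    fold_errors: list[str] = field(default_factory=list)


def classify_groups(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    sensor: str = "", trigger_side: str = "", signal_kind: str = "",
) -> ClassifierReport:
    """Cross-validated HV-vs-PD discrimination with four standard classifiers.

    With ``groups`` given (participant ids), folds are participant-grouped
    10-fold so the same person never appears on both sides of a split;
    without groups a stratified 10-fold mirrors a literal ungrouped reading.
    Metrics (accuracy, AUC, precision, F1) are computed on the out-of-fold
    predictions pooled across folds. PD is the positive class.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    y = (labels == "PD").astype(int) if labels.dtype.kind in "UOS" else labels.astype(int)

    if groups is not None:
        groups = np.asarray(groups)
        n_folds_eff = min(n_folds, np.unique(groups).size)
        splitter = GroupKFold(n_splits=n_folds_eff)
        splits = list(splitter.split(X, y, groups))
        scheme = f"participant-grouped {n_folds_eff}-fold"
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
        scheme = f"stratified {n_folds}-fold"

    records, errors = [], []
    for name in classifiers:
        pred = np.full(y.size, -1, dtype=int)
        score = np.full(y.size, np.nan)
        for fold_i, (tr, te) in enumerate(splits):
            if np.unique(y[tr]).size < 2:
                errors.append(f"{name}: fold {fold_i} has a single training class")
                continue
            clf = _make_classifier(name, seed)
            clf.fit(X[tr], y[tr])
            pred[te] = clf.predict(X[te])
            score[te] = clf.predict_proba(X[te])[:, 1]
        seen = pred >= 0
        records.append({
            "classifier": name,
            "accuracy": accuracy_score(y[seen], pred[seen]),
            "auc": roc_auc_score(y[seen], score[seen]) if np.unique(y[seen]).size > 1 else np.nan,
            "precision": precision_score(y[seen], pred[seen], zero_division=0),
            "f1": f1_score(y[seen], pred[seen], zero_division=0),
        })
    return ClassifierReport(
        sensor=sensor, trigger_side=trigger_side, signal_kind=signal_kind,
        metrics=pd.DataFrame(records).set_index("classifier"),
        fold_scheme=scheme, seed=seed, fold_errors=errors,
    )


# -- ON/OFF discrimination ----------------------------------------------------------

@dataclass
class OnOffResult:
    significant: bool | None  # None = not assessable
    p_per_pc: np.ndarray | None
    reason: str = ""
    n_on: int = 0
    n_off: int = 0


def onoff_discrimination(
    on_rows: np.ndarray,
    off_rows: np.ndarray,
    n_pc: int = N_PC_PERSONALIZED,
    alpha: float = ALPHA,
) -> OnOffResult:
    """Personalized-template medication-state contrast for one participant.

    A 2-PC template is fitted on the pooled ON + OFF epoch rows of this
    participant/sensor/trigger; each PC coordinate is compared ON vs OFF with
    a two-sided Mann-Whitney U test, Bonferroni-corrected over the PCs:
    significant iff min p < alpha / n_pc.
    """
    on_rows = np.atleast_2d(np.asarray(on_rows, dtype=float))
    off_rows = np.atleast_2d(np.asarray(off_rows, dtype=float))
    if on_rows.shape[0] < 3 or off_rows.shape[0] < 3:
        return OnOffResult(
            None, None, reason="fewer than 3 steps in a state",
            n_on=on_rows.shape[0], n_off=off_rows.shape[0],
        )
    pooled = np.vstack([on_rows, off_rows])
    model = build_template(pooled, n_pc=n_pc, scope="personalized")
    pon = project(model, on_rows).coords
    poff = project(model, off_rows).coords
    ps = np.array([
        stats.mannwhitneyu(pon[:, j], poff[:, j], alternative="two-sided").pvalue
        for j in range(n_pc)
    ])
    return OnOffResult(
        significant=bool(ps.min() < alpha / n_pc),
        p_per_pc=ps,
        n_on=on_rows.shape[0], n_off=off_rows.shape[0],
    )


# -- random-event null control ---------------------------------------------------------

def random_event_series(
    n_samples: int,
    rate: float,
    n_events: int,
    rng: np.random.Generator,
    side: str = "left",
    pre_s: float = 0.250,
    post_s: float = 1.000,
) -> StepEventSeries:
    """Uniformly random trigger times whose epoch windows fit the recording."""
    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))
    lo, hi = pre, n_samples - post
    if hi <= lo:
        raise ValueError("recording shorter than the epoch window")
    if n_events == 0:
        return StepEventSeries(side=side, onsets=np.array([], dtype=int), flags=[],
                               sample_rate=rate)
    onsets = np.sort(rng.choice(np.arange(lo, hi), size=min(n_events, hi - lo),
                                replace=False))
    return StepEventSeries(side=side, onsets=onsets,
                           flags=[FLAG_OK] * onsets.size, sample_rate=rate)


def random_event_control(
    rec,
    filtered_sites: dict[str, np.ndarray],
    n_events: int,
    rng: np.random.Generator,
    signal_kinds: tuple[str, ...] = ("acceleration", "velocity"),
    pre_s: float = 0.250,
    post_s: float = 1.000,
) -> dict[tuple[str, str, str], EpochMatrix]:
    """Epochs aligned to random (non-step) events, for the negative control.

    One event series is drawn per recording and shared by every sensor (like
    real steps, random triggers are whole-body events). Templates and
    projections built from these epochs follow the identical code path as the
    step-aligned pipeline; with random alignment the step-locked structure is
    destroyed, so group separation and severity correlation should vanish.
    Keys use the pseudo-trigger side "random".
    """
    events = random_event_series(
        rec.n_samples, rec.sample_rate, n_events, rng, side="random",
        pre_s=pre_s, post_s=post_s,
    )
    out = {}
    for sensor in rec.sites:
        for kind in signal_kinds:
            out[(sensor, "random", kind)] = extract_epochs(
                rec, events, sensor, pre_s=pre_s, post_s=post_s,
                signal_kind=kind, site_data=filtered_sites.get(sensor),
            )
    return out
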