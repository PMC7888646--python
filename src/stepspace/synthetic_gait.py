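"""Synthetic multi-site gait accelerometry with ground truth.

The generator emulates the data model the pipeline expects: six body-worn
tri-axial accelerometers sampled on one clock, with stereotyped, step-locked
waveforms at each site. Every waveform is a sum of Gaussian-windowed sinusoid
bursts tied to the onsets of one foot (feet to their own steps, wrists to the
contralateral foot's steps, lumbar and sternum to both). The foot's main burst
uses a sine/cosine quadrature pair on the anteroposterior and vertical axes,
so its sagittal-plane magnitude equals the Gaussian envelope exactly and the
2 m/s^2 threshold-crossing time of the clean signal is known in closed form —
that crossing IS the ground-truth onset.

Disease effects are planted explicitly:

* severity (a UPDRS-like integer, 10-70 for PD, 0 for HV) scales down the
  amplitudes of designated severity-sensitive bursts (reduced arm swing and
  push-off, bradykinesia-like) in proportion to ``severity_morph_gain``;
* left/right asymmetry scales and slightly reshapes every left-side or
  left-triggered burst by delta = ``asymmetry_gain`` * severity;
* the ON medication state restores a fraction ``med_effect`` of the healthy
  waveform (effective severity = severity * (1 - med_effect));
* the recorded per-session UPDRS is the effective severity plus rater noise.

Because severity acts along the same amplitude directions that vary naturally
across healthy participants, a healthy-cohort PCA template can see the PD
divergence — the premise of the template method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sensor_io import MultiSensorRecording, SITES
from .steps import STEP_THRESHOLD


@dataclass(frozen=True)
class Burst:
    """One Gaussian-windowed sinusoid burst locked to a trigger onset."""

    name: str
    axis: str  # "ap" | "ml" | "vert" | "sagittal_quadrature"
    amplitude: float  # m/s^2 (envelope peak)
    freq_hz: float
    sigma_s: float  # envelope width
    delay_s: float  # envelope peak relative to the trigger onset
    severity_sensitive: bool = False
    ml_sign_by_trigger: bool = False  # mediolateral sway flips with trigger side


# The main foot burst: quadrature pair => sagittal magnitude == envelope.
FOOT_MAIN = Burst("foot_main", "sagittal_quadrature", 8.0, 5.0, 0.05, 0.0)

#: site -> (trigger rule, bursts). Trigger rules: "own" (the foot's own side),
#: "contra" (opposite foot), "both" (every step of either foot).
SITE_WAVEFORMS: dict[str, tuple[str, tuple[Burst, ...]]] = {
    "left_foot": ("own", (
        FOOT_MAIN,
        Burst("foot_ml_push", "ml", 2.0, 3.0, 0.08, 0.35),
        Burst("foot_pushoff", "ap", 1.2, 4.0, 0.07, 0.50),
    )),
    "right_foot": ("own", (
        FOOT_MAIN,
        Burst("foot_ml_push", "ml", 2.0, 3.0, 0.08, 0.35),
        Burst("foot_pushoff", "ap", 1.2, 4.0, 0.07, 0.50),
    )),
    "left_wrist": ("contra", (
        Burst("swing_ap", "ap", 2.5, 2.0, 0.12, 0.30, severity_sensitive=True),
        Burst("swing_vert", "vert", 1.5, 2.0, 0.12, 0.30, severity_sensitive=True),
        Burst("swing_ml", "ml", 0.8, 2.0, 0.12, 0.30, severity_sensitive=True),
    )),
    "right_wrist": ("contra", (
        Burst("swing_ap", "ap", 2.5, 2.0, 0.12, 0.30, severity_sensitive=True),
        Burst("swing_vert", "vert", 1.5, 2.0, 0.12, 0.30, severity_sensitive=True),
        Burst("swing_ml", "ml", 0.8, 2.0, 0.12, 0.30, severity_sensitive=True),
    )),
    "lumbar": ("both", (
        Burst("sway_ml", "ml", 1.0, 2.0, 0.10, 0.25, ml_sign_by_trigger=True),
        Burst("bob_vert", "vert", 1.5, 2.5, 0.10, 0.20, severity_sensitive=True),
        Burst("core_ap", "ap", 0.8, 2.0, 0.10, 0.15, severity_sensitive=True),
    )),
    "sternum": ("both", (
        Burst("sway_ml", "ml", 0.8, 2.0, 0.11, 0.28, ml_sign_by_trigger=True),
        Burst("bob_vert", "vert", 1.2, 2.5, 0.11, 0.22, severity_sensitive=True),
        Burst("core_ap", "ap", 0.7, 2.0, 0.11, 0.18, severity_sensitive=True),
    )),
}

_AXIS_COL = {"ap": 0, "ml": 1, "vert": 2}


@dataclass
class SimConfig:
    """Study-condition parameters of the gait simulator.

    Defaults emulate a mixed HV/PD cohort walking a straight corridor at a
    comfortable pace: 128 Hz sampling, ~1.1 s stride per foot with ~20 ms
    timing variability, additive sensor noise 0.3 m/s^2, severities 10-70 for
    PD with a medication ON state restoring 25% of the healthy waveform.
    """

    n_hv: int = 10
    n_pd: int = 10
    sample_rate: float = 128.0
    walk_duration_s: float = 60.0
    step_period_mean_s: float = 1.1  # per-foot stride period
    step_period_sd_s: float = 0.02
    severity_range: tuple[int, int] = (10, 70)
    severity_morph_gain: float = 0.006  # fractional amplitude loss / UPDRS unit
    asymmetry_gain: float = 0.005  # delta = gain * effective severity
    med_effect: float = 0.25  # ON restores this fraction of healthy waveform
    noise_sd: float = 0.3  # m/s^2 additive sensor noise
    amp_jitter_sd: float = 0.05  # per-step per-burst amplitude jitter
    participant_sd: float = 0.03  # participant scatter on severity-sensitive bursts
    participant_base_sd: float = 0.12  # participant scatter on the other bursts
    updrs_noise_sd: float = 4.0  # rater noise on the recorded UPDRS
    doublet_rate: float = 0.0  # fraction of steps gaining a short-interval extra burst
    doublet_lead_s: float = 0.42  # doublet onset this long before the next true onset
    asymmetry_delta: float | None = None  # override: plant delta directly
    seed: int = 0

    def validate(self) -> None:
        if self.n_hv < 0 or self.n_pd < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.step_period_sd_s >= self.step_period_mean_s:
            raise ValueError("step period sd must be below the mean period")
        for name in ("severity_morph_gain", "asymmetry_gain", "noise_sd",
                     "amp_jitter_sd", "participant_sd", "participant_base_sd",
                     "updrs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.med_effect <= 1:
            raise ValueError("med_effect must lie in [0, 1]")
        if self.walk_duration_s < self.step_period_mean_s + 2.0:
            raise ValueError("walk too short for even one full epoch window")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must lie in [0, 1]")
        if not 0 < self.doublet_lead_s < self.step_period_mean_s:
            raise ValueError("doublet lead must lie inside one stride")


@dataclass
class SessionTruth:
    """Planted ground truth for one participant-session."""

    participant_id: str
    session_id: str
    group: str
    med_state: str
    severity: float  # baseline (OFF-state) severity
    effective_severity: float  # after medication restoration
    updrs: float | None
    delta: float  # planted left/right asymmetry
    onsets_s: dict[str, np.ndarray]  # true threshold crossings per side
    doublets_s: dict[str, np.ndarray]  # planted short-interval extra bursts


# -- waveform synthesis ---------------------------------------------------------

def _add_burst(sig: np.ndarray, rate: float, t0: float, burst: Burst,
               amp_scale: float, width_scale: float, delay_shift: float,
               ml_sign: float) -> None:
    """Add one burst (envelope peak at t0 + delay) in place."""
    sigma = burst.sigma_s * width_scale
    peak = t0 + burst.delay_s + delay_shift
    lo = max(0, int((peak - 4 * sigma) * rate))
    hi = min(sig.shape[0], int(math.ceil((peak + 4 * sigma) * rate)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / rate
    env = burst.amplitude * amp_scale * np.exp(-((t - peak) ** 2) / (2 * sigma ** 2))
    phase = 2 * np.pi * burst.freq_hz * (t - peak)
    if burst.axis == "sagittal_quadrature":
        sig[lo:hi, _AXIS_COL["ap"]] += env * np.sin(phase)
        sig[lo:hi, _AXIS_COL["vert"]] += env * np.cos(phase)
    else:
        col = _AXIS_COL[burst.axis]
        sign = ml_sign if burst.axis == "ml" else 1.0
        sig[lo:hi, col] += sign * env * np.sin(phase + np.pi / 2)


def _crossing_offset(amplitude: float, sigma: float,
                     threshold: float = STEP_THRESHOLD) -> float:
    """Time from the clean envelope's upward threshold crossing to its peak."""
    if amplitude <= threshold:
        raise ValueError("main burst peak must exceed the detection threshold")
    return sigma * math.sqrt(2.0 * math.log(amplitude / threshold))


def _side_sign(site_or_trigger: str) -> float:
    return -1.0 if site_or_trigger.startswith("left") else 1.0


def _synthesize_session(
    cfg: SimConfig,
    participant_id: str,
    session_id: str,
    group: str,
    med_state: str,
    severity: float,
    participant_factors: dict[str, float],
    tempo: float,
    rng: np.random.Generator,
) -> tuple[MultiSensorRecording, SessionTruth]:
    rate = cfg.sample_rate
    T = int(round(cfg.walk_duration_s * rate))

    sev_eff = severity * (1.0 - cfg.med_effect) if med_state == "ON" else severity
    delta = cfg.asymmetry_delta if cfg.asymmetry_delta is not None \
        else cfg.asymmetry_gain * sev_eff
    delta = min(delta, 0.6)

    # -- step timing: alternating feet, per-foot stride ~ period -------------
    period = cfg.step_period_mean_s * tempo
    # with zero timing jitter, lock the half-stride to the sample grid so the
    # left and right feet sample the waveform at identical sub-sample phases
    # (exact mirror symmetry is then preserved through epoch extraction)
    half_base = period / 2.0
    if cfg.step_period_sd_s == 0:
        half_base = round(half_base * rate) / rate
    # Render a steady-state bout: the first and last onsets sit too close to
    # the recording edges for a full epoch window (the detector flags them
    # "edge"), but their bursts provide the neighbour context that makes every
    # retained epoch statistically identical to the others.
    onsets = {"left": [], "right": []}
    t, side = 0.15, "left"
    while t < cfg.walk_duration_s + 0.5:
        onsets[side].append(t)
        half = half_base
        if cfg.step_period_sd_s > 0:
            half += rng.normal(0.0, cfg.step_period_sd_s / math.sqrt(2.0))
        t += half
        side = "right" if side == "left" else "left"

    # per-step, per-burst amplitude jitter (independent across bursts so the
    # healthy reference PCA spans one direction per burst, not a single
    # overall-amplitude axis)
    jitter: dict[tuple[str, str, str], np.ndarray] = {}
    for site in SITES:
        _, bursts = SITE_WAVEFORMS[site]
        for trig in ("left", "right"):
            for burst in bursts:
                n = len(onsets[trig])
                jitter[(site, trig, burst.name)] = (
                    1.0 + rng.normal(0.0, cfg.amp_jitter_sd, n)
                    if cfg.amp_jitter_sd > 0 else np.ones(n)
                )

    # planted short-interval doublets (detection stress test)
    doublets = {"left": [], "right": []}
    if cfg.doublet_rate > 0:
        for s in ("left", "right"):
            ts = onsets[s]
            for i in range(len(ts) - 1):
                if rng.random() < cfg.doublet_rate:
                    doublets[s].append(ts[i + 1] - cfg.doublet_lead_s)

    sites: dict[str, np.ndarray] = {}
    morph = max(0.2, 1.0 - cfg.severity_morph_gain * sev_eff)

    for site in SITES:
        sig = np.zeros((T, 3))
        trigger_rule, bursts = SITE_WAVEFORMS[site]
        if trigger_rule == "own":
            trig_sides = [site.split("_")[0]]
        elif trigger_rule == "contra":
            trig_sides = ["right" if site.startswith("left") else "left"]
        else:
            trig_sides = ["left", "right"]

        for trig in trig_sides:
            # asymmetry hits left-side sensors and left-triggered core responses
            left_affected = (
                site.startswith("left") or
                (trigger_rule == "both" and trig == "left")
            )
            a_scale = (1.0 - delta) if left_affected else 1.0
            w_scale = (1.0 + 0.5 * delta) if left_affected else 1.0
            d_shift = 0.03 * delta if left_affected else 0.0

            for k, t0 in enumerate(onsets[trig]):
                for burst in bursts:
                    g = jitter[(site, trig, burst.name)][k]
                    # asymmetry scales the secondary bursts; the main foot
                    # burst keeps its amplitude (detection-critical) and
                    # expresses asymmetry through the width/delay morph only
                    amp_factor = 1.0 if burst.name == "foot_main" else a_scale
                    scale = g * amp_factor * participant_factors[burst.name]
                    if burst.severity_sensitive:
                        scale *= morph
                    ml_sign = _side_sign(trig) if burst.ml_sign_by_trigger \
                        else _side_sign(site)
                    _add_burst(sig, rate, t0, burst, scale, w_scale, d_shift, ml_sign)
            # doublet bursts reuse the main foot burst shape
            if trigger_rule == "own":
                for td in doublets[trig_sides[0]]:
                    _add_burst(sig, rate, td, FOOT_MAIN,
                               participant_factors["foot_main"],
                               w_scale, d_shift, 1.0)

        if cfg.noise_sd > 0:
            sig += rng.normal(0.0, cfg.noise_sd, sig.shape)
        sites[site] = sig

    # ground-truth onsets: clean threshold crossings of the main burst
    gt_onsets = {}
    for s in ("left", "right"):
        foot_site = f"{s}_foot"
        left_affected = foot_site.startswith("left")
        a_scale = (1.0 - delta) if left_affected else 1.0
        w_scale = (1.0 + 0.5 * delta) if left_affected else 1.0
        d_shift = 0.03 * delta if left_affected else 0.0
        cross = []
        for k, t0 in enumerate(onsets[s]):
            amp = (FOOT_MAIN.amplitude * jitter[(foot_site, s, "foot_main")][k]
                   * participant_factors["foot_main"])
            off = _crossing_offset(amp, FOOT_MAIN.sigma_s * w_scale)
            cross.append(t0 + FOOT_MAIN.delay_s + d_shift - off)
        gt_onsets[s] = np.asarray(cross)
        # doublet times as threshold crossings too (no vigor jitter applied)
        amp_d = FOOT_MAIN.amplitude * participant_factors["foot_main"]
        off_d = _crossing_offset(amp_d, FOOT_MAIN.sigma_s * w_scale)
        doublets[s] = [td + FOOT_MAIN.delay_s + d_shift - off_d for td in doublets[s]]

    rec = MultiSensorRecording(participant_id, session_id, rate, sites)
    if group == "PD":
        updrs = float(round(sev_eff + (rng.normal(0.0, cfg.updrs_noise_sd)
                                       if cfg.updrs_noise_sd > 0 else 0.0)))
        updrs = max(0.0, updrs)
    else:
        updrs = None
    truth = SessionTruth(
        participant_id=participant_id, session_id=session_id, group=group,
        med_state=med_state, severity=severity, effective_severity=sev_eff,
        updrs=updrs, delta=delta,
        onsets_s=gt_onsets,
        doublets_s={s: np.asarray(doublets[s]) for s in ("left", "right")},
    )
    return rec, truth


# -- cohort generation -----------------------------------------------------------

def simulate_cohort(
    cfg: SimConfig,
) -> tuple[dict[tuple[str, str], MultiSensorRecording], pd.DataFrame, dict]:
    """Generate a full cohort: HV one session each, PD an ON and an OFF session.

    Returns (recordings keyed by (participant_id, session_id), cohort metadata
    table, ground truth keyed the same way). Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    burst_sensitivity = {
        b.name: b.severity_sensitive
        for _, bursts in SITE_WAVEFORMS.values() for b in bursts
    }
    burst_names = sorted(burst_sensitivity)

    recordings: dict[tuple[str, str], MultiSensorRecording] = {}
    truths: dict[tuple[str, str], SessionTruth] = {}
    rows = []

    def participant_draws():
        factors = {}
        for name in burst_names:
            sd = cfg.participant_sd if burst_sensitivity[name] \
                else cfg.participant_base_sd
            factors[name] = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
        tempo = float(np.exp(rng.normal(0.0, 0.03)))
        return factors, tempo

    for i in range(cfg.n_hv):
        pid = f"HV{i:03d}"
        factors, tempo = participant_draws()
        rec, truth = _synthesize_session(
            cfg, pid, "s1", "HV", "NA", 0.0, factors, tempo, rng)
        recordings[(pid, "s1")] = rec
        truths[(pid, "s1")] = truth
        rows.append({"participant_id": pid, "session_id": "s1", "group": "HV",
                     "med_state": "NA", "updrs3_total": np.nan})

    lo, hi = cfg.severity_range
    for i in range(cfg.n_pd):
        pid = f"PD{i:03d}"
        severity = float(rng.integers(lo, hi + 1))
        factors, tempo = participant_draws()
        for sid, state in (("on", "ON"), ("off", "OFF")):
            rec, truth = _synthesize_session(
                cfg, pid, sid, "PD", state, severity, factors, tempo, rng)
            recordings[(pid, sid)] = rec
            truths[(pid, sid)] = truth
            rows.append({"participant_id": pid, "session_id": sid, "group": "PD",
                         "med_state": state, "updrs3_total": truth.updrs})

    cohort = pd.DataFrame(rows)
    return recordings, cohort, truths


# -- planted-effect oracle --------------------------------------------------------

def planted_effect_oracle(truths: dict) -> dict:
    """Reference statistics computed directly from planted parameters.

    Bypasses the sensing/detection/PCA pipeline entirely: regressions run on
    the planted effective severities and asymmetries themselves, giving the
    ceiling the pipeline's recovered statistics are compared against.

    Returns a dict with:

    * ``severity_r2`` / ``severity_p``: OLS of recorded UPDRS on the planted
      effective severity over PD sessions;
    * ``asymmetry_r2``: OLS of recorded UPDRS on the planted delta;
    * ``onoff_effect``: mean within-participant |OFF - ON| difference of the
      planted severity-morph factor (0 when med_effect = 0).
    """
    from scipy import stats as sstats

    pd_truths = [t for t in truths.values() if t.group == "PD"]
    out: dict[str, float] = {}
    if len(pd_truths) >= 3:
        updrs = np.array([t.updrs for t in pd_truths], dtype=float)
        sev = np.array([t.effective_severity for t in pd_truths])
        delta = np.array([t.delta for t in pd_truths])
        if np.std(sev) > 0:
            res = sstats.linregress(sev, updrs)
            out["severity_r2"] = res.rvalue ** 2
            out["severity_p"] = res.pvalue
        if np.std(delta) > 0:
            res = sstats.linregress(delta, updrs)
            out["asymmetry_r2"] = res.rvalue ** 2

    by_pid: dict[str, dict[str, float]] = {}
    for t in pd_truths:
        by_pid.setdefault(t.participant_id, {})[t.med_state] = t.effective_severity
    diffs = [abs(v["OFF"] - v["ON"]) for v in by_pid.values()
             if "ON" in v and "OFF" in v]
    out["onoff_effect"] = float(np.mean(diffs)) if diffs else 0.0
    return out


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)


def demo_config(seed: int = 2026) -> SimConfig:
    """The shipped demo study: 30 HV and 30 PD (ON + OFF), 30 s walks.

    All effect sizes and noise levels are the SimConfig defaults; only the
    cohort size, walk length and seed are pinned here.
    """
    return SimConfig(n_hv=30, n_pd=30, walk_duration_s=30.0, seed=seed)
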