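"""Reading, writing, validation and resampling of multi-sensor accelerometer recordings.

A recording is a set of synchronized tri-axial acceleration streams from named
body sites sharing one clock: sample ``i`` is simultaneous across sites and the
time base is implicit (``t = i / sample_rate``). The on-disk formats are a long
CSV (one row per site per sample) and an HDF5 layout with one ``T x 3`` dataset
per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("stepspace")

#: Body sites a recording may contain.
SITES = ("left_foot", "right_foot", "left_wrist", "right_wrist", "lumbar", "sternum")

#: Default anatomical meaning of the (x, y, z) columns at every site:
#: x = anteroposterior, y = mediolateral, z = vertical.
DEFAULT_AXIS_CONVENTION = {
    site: {"x": "anteroposterior", "y": "mediolateral", "z": "vertical"}
    for site in SITES
}

CSV_COLUMNS = ["participant_id", "session_id", "site", "sample_index", "ax", "ay", "az"]


class RecordingFormatError(ValueError):
    """Malformed file: wrong header, unknown site, non-numeric sample."""


class RecordingValidationError(ValueError):
    """Structurally parseable data that violates a recording invariant."""


@dataclass
class MultiSensorRecording:
    """Synchronized tri-axial acceleration streams from up to six body sites.

    Parameters
    ----------
    participant_id, session_id
        Identifiers keying the recording to cohort metadata.
    sample_rate
        Sampling rate in Hz; all sites share it.
    sites
        Mapping from site name to a ``T x 3`` float array of acceleration in
        m/s^2 on axes (x, y, z). All present sites must have equal ``T``.
    axis_convention
        Per-site mapping of axis letter to anatomical direction
        (anteroposterior / mediolateral / vertical).
    """

    participant_id: str
    session_id: str
    sample_rate: float
    sites: dict[str, np.ndarray]
    axis_convention: dict[str, dict[str, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AXIS_CONVENTION.items()}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise RecordingValidationError("sample_rate must be positive")
        if not self.sites:
            raise RecordingValidationError("recording has no sites")
        lengths = {}
        for name, arr in self.sites.items():
            if name not in SITES:
                raise RecordingValidationError(f"unknown site {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise RecordingValidationError(
                    f"site {name!r}: expected T x 3 array, got shape {arr.shape}"
                )
            if arr.shape[0] < 1:
                raise RecordingValidationError(f"site {name!r} is empty")
            bad = np.argwhere(~np.isfinite(arr))
            if bad.size:
                locs = ", ".join(f"({name}, row {r})" for r, _ in bad[:5])
                raise RecordingValidationError(f"non-finite samples at: {locs}")
            self.sites[name] = arr
            lengths[name] = arr.shape[0]
        if len(set(lengths.values())) > 1:
            raise RecordingValidationError(f"mismatched site lengths: {lengths}")
        missing = [s for s in SITES if s not in self.sites]
        if missing:
            logger.warning(
                "recording %s/%s missing sites: %s",
                self.participant_id, self.session_id, ", ".join(missing),
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.sites.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def anatomical_axis_index(self, site: str, direction: str) -> int:
        """Column index of an anatomical direction at a site."""
        conv = self.axis_convention.get(site, DEFAULT_AXIS_CONVENTION[site])
        for i, letter in enumerate("xyz"):
            if conv[letter] == direction:
                return i
        raise KeyError(f"direction {direction!r} not found for site {site!r}")


# -- CSV dialect -------------------------------------------------------------

def save_recording_csv(rec: MultiSensorRecording, path) -> None:
    """Write the long-format CSV dialect with full float precision."""
    frames = []
    for site in SITES:
        if site not in rec.sites:
            continue
        arr = rec.sites[site]
        frames.append(pd.DataFrame({
            "participant_id": rec.participant_id,
            "session_id": rec.session_id,
            "site": site,
            "sample_index": np.arange(arr.shape[0]),
            "ax": arr[:, 0],
            "ay": arr[:, 1],
            "az": arr[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def _load_recording_csv(path, sample_rate: float) -> MultiSensorRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordingFormatError(
            f"missing column(s) {missing_cols} in {path}; header must be "
            + ",".join(CSV_COLUMNS)
        )
    pids = df["participant_id"].unique()
    sids = df["session_id"].unique()
    if len(pids) != 1 or len(sids) != 1:
        raise RecordingFormatError(
            f"{path} holds more than one participant/session: {pids}, {sids}"
        )
    sites = {}
    for site, g in df.groupby("site"):
        g = g.sort_values("sample_index")
        idx = g["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise RecordingValidationError(
                f"site {site!r}: sample_index is not contiguous from 0"
            )
        sites[str(site)] = g[["ax", "ay", "az"]].to_numpy(dtype=float)
    return MultiSensorRecording(str(pids[0]), str(sids[0]), sample_rate, sites)


# -- HDF5 layout -------------------------------------------------------------

def save_recording_hdf5(rec: MultiSensorRecording, path) -> None:
    """Write `/sites/<name>` T x 3 float64 datasets with rate/convention attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["participant_id"] = rec.participant_id
        f.attrs["session_id"] = rec.session_id
        f.attrs["sample_rate"] = rec.sample_rate
        grp = f.create_group("sites")
        for name, arr in rec.sites.items():
            ds = grp.create_dataset(name, data=arr.astype(np.float64))
            conv = rec.axis_convention.get(name, DEFAULT_AXIS_CONVENTION[name])
            ds.attrs["axis_convention"] = ",".join(conv[a] for a in "xyz")


def _load_recording_hdf5(path) -> MultiSensorRecording:
    with h5py.File(path, "r") as f:
        if "sites" not in f:
            raise RecordingFormatError(f"{path}: missing /sites group")
        sites = {}
        convention = {}
        for name, ds in f["sites"].items():
            sites[name] = np.asarray(ds, dtype=float)
            conv_attr = ds.attrs.get("axis_convention")
            if conv_attr is not None:
                parts = str(conv_attr).split(",")
                convention[name] = dict(zip("xyz", parts))
        rec = MultiSensorRecording(
            str(f.attrs["participant_id"]),
            str(f.attrs["session_id"]),
            float(f.attrs["sample_rate"]),
            sites,
        )
        for name, conv in convention.items():
            rec.axis_convention[name] = conv
        return rec


def load_recording(path, fmt: str = "csv", sample_rate: float = 128.0) -> MultiSensorRecording:
    """Load a validated recording from the CSV or HDF5 dialect.

    The CSV dialect carries no rate, so ``sample_rate`` applies there; HDF5
    stores the rate as a file attribute.
    """
    if fmt == "csv":
        return _load_recording_csv(path, sample_rate)
    if fmt == "hdf5":
        return _load_recording_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")


# -- resampling --------------------------------------------------------------

def resample(rec: MultiSensorRecording, target_rate: float) -> MultiSensorRecording:
    """Linearly interpolate every site onto a uniform grid at ``target_rate``.

    The new grid covers the half-open interval [0, T/rate) at the target rate;
    linear interpolation is exact on affine signals and preserves amplitude
    for content well below Nyquist.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rec.n_samples < 2:
        raise ValueError("cannot interpolate a recording with fewer than 2 samples")
    if target_rate == rec.sample_rate:
        new_sites = {k: v.copy() for k, v in rec.sites.items()}
    else:
        t_old = np.arange(rec.n_samples) / rec.sample_rate
        t_end = rec.n_samples / rec.sample_rate
        n_new = int(np.ceil(t_end * target_rate - 1e-9))
        t_new = np.arange(n_new) / target_rate
        # clamp to the last old sample so interpolation never extrapolates
        t_new = np.minimum(t_new, t_old[-1])
        new_sites = {
            name: np.column_stack([
                np.interp(t_new, t_old, arr[:, j]) for j in range(3)
            ])
            for name, arr in rec.sites.items()
        }
    out = MultiSensorRecording(
        rec.participant_id, rec.session_id, target_rate, new_sites,
        axis_convention={k: dict(v) for k, v in rec.axis_convention.items()},
    )
    return out


# -- cohort metadata ----------------------------------------------------------

COHORT_COLUMNS = ["participant_id", "session_id", "group", "med_state", "updrs3_total"]


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate cohort metadata: one row per (participant, session).

    Healthy-volunteer (HV) rows must carry med_state NA; Parkinson's disease
    (PD) rows must carry a UPDRS part-3 total.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"cohort table missing column(s): {missing}")
    df = df.copy()
    dup = df.duplicated(subset=["participant_id", "session_id"])
    if dup.any():
        raise RecordingValidationError(
            f"duplicate (participant_id, session_id) rows: "
            f"{df.loc[dup, ['participant_id', 'session_id']].to_records(index=False)}"
        )
    bad_group = ~df["group"].isin(["HV", "PD"])
    if bad_group.any():
        raise RecordingValidationError(
            f"group must be HV or PD, got {df.loc[bad_group, 'group'].unique()}"
        )
    hv = df["group"] == "HV"
    if not df.loc[hv, "med_state"].isin([np.nan, None, "NA", ""]).all():
        raise RecordingValidationError("HV rows must have med_state = NA")
    pd_rows = df["group"] == "PD"
    updrs = pd.to_numeric(df["updrs3_total"], errors="coerce")
    if updrs[pd_rows].isna().any():
        raise RecordingValidationError("PD rows must have updrs3_total present")
    if (updrs[pd_rows] < 0).any():
        raise RecordingValidationError("updrs3_total must be non-negative")
    bad_state = pd_rows & ~df["med_state"].isin(["ON", "OFF"])
    if bad_state.any():
        raise RecordingValidationError("PD rows must have med_state ON or OFF")
    df["updrs3_total"] = updrs
    return df


def load_cohort_table(path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


def save_cohort_table(df: pd.DataFrame, path) -> None:
    validate_cohort_table(df).to_csv(path, index=False)
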