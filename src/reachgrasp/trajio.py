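"""Trajectory containers and the plain-text dataset dialect.

A dataset is one long-format CSV, one row per (trial, marker, frame), columns

    subject_id, trial_id, pronoun, verb_type, verb, is_catch, marker,
    t_ms, x_mm, y_mm, z_mm

UTF-8, '.' decimal, LF line endings, header mandatory. Time is stored on the
trial clock: t = 0 at verb-stem onset, so the anticipation check downstream is
a sign test on movement-onset time. Units are fixed at mm and ms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, VocabularyError
from .stimuli import PRONOUNS, VERB_TYPES, Condition, StimulusTimeline

MARKERS = ("wrist", "index", "thumb")

DATASET_COLUMNS = [
    "subject_id",
    "trial_id",
    "pronoun",
    "verb_type",
    "verb",
    "is_catch",
    "marker",
    "t_ms",
    "x_mm",
    "y_mm",
    "z_mm",
]

#: Sampling-uniformity tolerance on the frame interval (1 us, per contract).
UNIFORMITY_TOL_MS = 1e-3


@dataclass
class Trajectory:
    """Time-stamped 3-D positions of one marker (ms, mm)."""

    t_ms: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        n = self.t_ms.size
        if n < 2:
            raise DataError("trajectory needs at least 2 frames")
        for name in ("x_mm", "y_mm", "z_mm"):
            if getattr(self, name).size != n:
                raise DataError("trajectory vectors must have equal length")
        dt = np.diff(self.t_ms)
        if np.any(dt <= 0):
            raise DataError("t_ms must be strictly increasing")
        if np.ptp(dt) > UNIFORMITY_TOL_MS:
            raise DataError("t_ms must be uniformly sampled (within 1 us)")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    @property
    def n_frames(self) -> int:
        return int(self.t_ms.size)

    def positions(self) -> np.ndarray:
        """(n_frames, 3) position array."""
        return np.column_stack([self.x_mm, self.y_mm, self.z_mm])


@dataclass
class TrialRecord:
    """All markers plus condition labels and stimulus timeline for one trial.

    ``linguistic_error`` marks a wrong match/mismatch decision; it exists only
    in memory (the CSV schema is fixed) and is consumed by the QC stage.
    """

    subject_id: str
    trial_id: str
    condition: Condition
    markers: dict[str, Trajectory]
    timeline: StimulusTimeline = field(default_factory=StimulusTimeline)
    linguistic_error: bool = False
    #: Generator ground truth (realized parameter values), when synthetic.
    #: In-memory only; not part of the CSV schema.
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if "wrist" not in self.markers:
            raise DataError(f"trial {self.trial_id}: wrist marker is required")
        grids = [traj.t_ms for traj in self.markers.values()]
        for g in grids[1:]:
            if g.size != grids[0].size or np.max(np.abs(g - grids[0])) > UNIFORMITY_TOL_MS:
                raise DataError(
                    f"trial {self.trial_id}: markers must share one t_ms grid"
                )

    @property
    def wrist(self) -> Trajectory:
        return self.markers["wrist"]

    @property
    def rate_hz(self) -> float:
        return self.wrist.rate_hz


def _trial_frame(trial: TrialRecord) -> pd.DataFrame:
    blocks = []
    for marker in MARKERS:
        if marker not in trial.markers:
            continue
        traj = trial.markers[marker]
        blocks.append(
            pd.DataFrame(
                {
                    "subject_id": trial.subject_id,
                    "trial_id": trial.trial_id,
                    "pronoun": trial.condition.pronoun,
                    "verb_type": trial.condition.verb_type,
                    "verb": trial.condition.verb_label,
                    "is_catch": trial.condition.is_catch,
                    "marker": marker,
                    "t_ms": traj.t_ms,
                    "x_mm": traj.x_mm,
                    "y_mm": traj.y_mm,
                    "z_mm": traj.z_mm,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def dataset_to_frame(dataset: list[TrialRecord]) -> pd.DataFrame:
    """Long-format table for a list of trials (header-only frame if empty)."""
    if not dataset:
        return pd.DataFrame(columns=DATASET_COLUMNS)
    return pd.concat([_trial_frame(t) for t in dataset], ignore_index=True)


def write_dataset(dataset: list[TrialRecord], path) -> None:
    """Write trials as the long-format CSV dialect (UTF-8, LF, '.' decimal)."""
    frame = dataset_to_frame(dataset)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        frame.to_csv(fh, index=False, lineterminator="\n")


def dataset_to_csv_string(dataset: list[TrialRecord]) -> str:
    """Serialize to the CSV dialect in memory (used for byte-identity checks)."""
    buf = io.StringIO()
    dataset_to_frame(dataset).to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in ("true", "1"):
        return True
    if token in ("false", "0"):
        return False
    raise VocabularyError(f"unparseable boolean token {value!r} in is_catch")


def frame_to_dataset(frame: pd.DataFrame) -> list[TrialRecord]:
    """Build TrialRecords from a long-format table, validating all invariants."""
    for col in DATASET_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"dataset is missing required column {col!r}")
    if frame.empty:
        return []
    bad_pron = set(frame["pronoun"].unique()) - set(PRONOUNS)
    if bad_pron:
        raise VocabularyError(f"unknown pronoun token(s) {sorted(bad_pron)!r}")
    bad_vt = set(frame["verb_type"].unique()) - set(VERB_TYPES)
    if bad_vt:
        raise VocabularyError(f"unknown verb_type token(s) {sorted(bad_vt)!r}")

    dataset: list[TrialRecord] = []
    for (subject_id, trial_id), group in frame.groupby(
        ["subject_id", "trial_id"], sort=True
    ):
        markers: dict[str, Trajectory] = {}
        for marker, mgroup in group.groupby("marker", sort=False):
            mgroup = mgroup.sort_values("t_ms", kind="mergesort")
            t = mgroup["t_ms"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise DataError(
                    f"non-monotone t_ms in trial {trial_id!r} marker {marker!r}"
                )
            try:
                markers[str(marker)] = Trajectory(
                    t,
                    mgroup["x_mm"].to_numpy(dtype=float),
                    mgroup["y_mm"].to_numpy(dtype=float),
                    mgroup["z_mm"].to_numpy(dtype=float),
                )
            except DataError as exc:
                raise DataError(f"trial {trial_id!r} marker {marker!r}: {exc}") from exc
        first = group.iloc[0]
        condition = Condition(
            pronoun=str(first["pronoun"]),
            verb_type=str(first["verb_type"]),
            verb_label="" if pd.isna(first["verb"]) else str(first["verb"]),
            is_catch=_parse_bool(first["is_catch"]),
        )
        dataset.append(
            TrialRecord(
                subject_id=str(subject_id),
                trial_id=str(trial_id),
                condition=condition,
                markers=markers,
            )
        )
    return dataset


def read_dataset(path) -> list[TrialRecord]:
    """Read a dataset CSV; trials grouped by (subject, trial), frames sorted by t."""
    try:
        frame = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str},
                            float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("dataset file has no header row") from exc
    return frame_to_dataset(frame)


# ---------------------------------------------------------------------------
# Results writers (TSV)
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, float_format: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                     float_format=float_format)


PARAMS_TSV_COLUMNS = [
    "subject_id",
    "trial_id",
    "pronoun",
    "verb_type",
    "is_catch",
    "valid",
    "reach_time_ms",
    "vpeak_mm_s",
    "t_vpeak_ms",
    "pct_t_vpeak",
    "grasp_time_ms",
    "max_aperture_mm",
    "t_max_aperture_ms",
    "pct_t_max_aperture",
]


def write_params_table(params: pd.DataFrame, path) -> None:
    """Write the per-trial parameter table with the fixed public column set."""
    out = params.reindex(columns=PARAMS_TSV_COLUMNS)
    write_tsv(out, path)


def read_params_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str})
    missing = [c for c in PARAMS_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"params table missing column(s) {missing!r}")
    return frame
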