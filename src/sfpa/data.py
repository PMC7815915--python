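"""Domain containers and tabular I/O for the SFPA pipeline.

The pipeline ties together three clocks: fMRI volumes (TRs), movie
events (a sparse sampling of the stimulus time-course), and behavioral
responses (per participant, per event, per measure).  The containers
here enforce the alignment invariants that every downstream stage
relies on: the event table is the single source of temporal order, all
event-indexed vectors follow its row order, and every subject shares
one ROI set and one TR grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Measures collected on a 1-7 Likert scale.
RATING_MEASURES = (
    "surprise",
    "vividness",
    "emotional_intensity",
    "emotional_valence",
    "importance",
)
#: Measures scored as non-negative unit counts from free recall.
COUNT_MEASURES = ("episodic_memory", "theory_of_mind")
#: All behavioral measures, in canonical order.
MEASURES = RATING_MEASURES + COUNT_MEASURES

NETWORKS = ("DMN", "DAN", "Vis", "subcortical")


class DataError(ValueError):
    """Raised when an input table violates a pipeline invariant."""


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclasses.dataclass(frozen=True)
class EventTable:
    """Ordered probed movie events; the common clock for brain and behavior.

    Parameters
    ----------
    table : DataFrame with columns ``event_id``, ``onset_s``, ``onset_tr``,
        ``description``, sorted by onset.
    tr_seconds : fMRI sampling interval used to map onsets to TR indices.
    """

    table: pd.DataFrame
    tr_seconds: float

    def __post_init__(self) -> None:
        t = self.table
        required = {"event_id", "onset_s", "onset_tr", "description"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"event table missing columns: {sorted(missing)}")
        if t["event_id"].duplicated().any():
            dupes = t.loc[t["event_id"].duplicated(), "event_id"].tolist()
            raise DataError(f"duplicate event ids: {dupes}")
        onsets = t["onset_s"].to_numpy(dtype=float)
        if (onsets < 0).any():
            raise DataError("negative event onset times")
        if not (np.diff(onsets) > 0).all():
            raise DataError("event onsets must be strictly increasing")
        if self.tr_seconds <= 0:
            raise DataError("tr_seconds must be positive")

    @classmethod
    def from_onsets(
        cls,
        event_ids: Sequence[str],
        onset_s: Sequence[float],
        tr_seconds: float,
        descriptions: Sequence[str] | None = None,
    ) -> "EventTable":
        if descriptions is None:
            descriptions = ["" for _ in event_ids]
        df = pd.DataFrame(
            {
                "event_id": list(event_ids),
                "onset_s": np.asarray(onset_s, dtype=float),
                "description": list(descriptions),
            }
        ).sort_values("onset_s", kind="stable", ignore_index=True)
        df["onset_tr"] = _round_half_away(df["onset_s"].to_numpy() / tr_seconds)
        df = df[["event_id", "onset_s", "onset_tr", "description"]]
        return cls(df, tr_seconds)

    @property
    def event_ids(self) -> list[str]:
        return self.table["event_id"].tolist()

    @property
    def onset_trs(self) -> np.ndarray:
        return self.table["onset_tr"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


def read_events(path: str | Path, tr_seconds: float) -> EventTable:
    """Read an event table (CSV/TSV with event_id, onset_s, description).

    ``onset_tr`` is computed as round(onset_s / tr_seconds), half away
    from zero; rows are sorted by onset.
    """
    df = _read_table(path)
    for col in ("event_id", "onset_s"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if "description" not in df.columns:
        df["description"] = ""
    df["description"] = df["description"].fillna("")
    return EventTable.from_onsets(
        df["event_id"].astype(str).tolist(),
        df["onset_s"].to_numpy(dtype=float),
        tr_seconds,
        df["description"].astype(str).tolist(),
    )


def write_events(events: EventTable, path: str | Path) -> None:
    events.table.to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class RatingsTable:
    """Long-format participant x event x measure behavioral responses.

    Likert measures must lie in 1-7; free-recall unit counts
    (episodic_memory, theory_of_mind) are non-negative integers.  Each
    participant rates only a subset of events (the questionnaire splits
    events into three interleaved subsets across participants), so
    missing (participant, event) combinations are expected.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"participant_id", "event_id", "measure", "value"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"ratings table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise DataError("no responses in ratings table")
        unknown = set(t["measure"].unique()) - set(MEASURES)
        if unknown:
            raise DataError(f"unknown measures: {sorted(unknown)}")
        vals = t["value"].to_numpy(dtype=float)
        if not np.all(vals == np.round(vals)):
            raise DataError("ratings values must be integers")
        is_rating = t["measure"].isin(RATING_MEASURES).to_numpy()
        bad_rating = is_rating & ((vals < 1) | (vals > 7))
        if bad_rating.any():
            rows = t.index[bad_rating][:5].tolist()
            raise DataError(f"rating values outside 1-7 at rows {rows}")
        bad_count = ~is_rating & (vals < 0)
        if bad_count.any():
            rows = t.index[bad_count][:5].tolist()
            raise DataError(f"negative unit counts at rows {rows}")

    @property
    def participants(self) -> list[str]:
        return sorted(self.table["participant_id"].unique())


def read_ratings(path: str | Path) -> RatingsTable:
    """Read and validate a long-format ratings table."""
    df = _read_table(path)
    if len(df) == 0:
        raise DataError(f"{path}: no responses")
    df["participant_id"] = df["participant_id"].astype(str)
    df["event_id"] = df["event_id"].astype(str)
    return RatingsTable(df)


def write_ratings(ratings: RatingsTable, path: str | Path) -> None:
    ratings.table.to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class StateTimecourses:
    """Group-mean z-scored cognitive-state vector per measure over events.

    ``states[measure]`` is a length-n_events vector in event-table
    order; ``n_raters[measure]`` counts the participants contributing
    to each entry.
    """

    states: Mapping[str, np.ndarray]
    n_raters: Mapping[str, np.ndarray]
    event_ids: Sequence[str]

    def __post_init__(self) -> None:
        n = len(self.event_ids)
        for m, v in self.states.items():
            if len(v) != n:
                raise DataError(f"state vector for {m} has wrong length")
            if not np.all(np.isfinite(v)):
                raise DataError(f"missing entries in state vector for {m}")

    @property
    def measures(self) -> list[str]:
        return [m for m in MEASURES if m in self.states] + sorted(
            set(self.states) - set(MEASURES)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"event_id": list(self.event_ids)})
        for m in self.measures:
            df[m] = self.states[m]
            df[f"n_raters_{m}"] = self.n_raters[m]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StateTimecourses":
        measures = [c for c in df.columns if c in MEASURES or (
            c != "event_id" and not c.startswith("n_raters_"))]
        states = {m: df[m].to_numpy(dtype=float) for m in measures}
        n_raters = {
            m: df[f"n_raters_{m}"].to_numpy(dtype=int)
            if f"n_raters_{m}" in df.columns
            else np.full(len(df), -1)
            for m in measures
        }
        return cls(states, n_raters, df["event_id"].astype(str).tolist())

    def subset(self, event_ids: Sequence[str]) -> "StateTimecourses":
        """Restrict to the given events, preserving event-table order."""
        idx = [list(self.event_ids).index(e) for e in event_ids]
        return StateTimecourses(
            {m: v[idx] for m, v in self.states.items()},
            {m: v[idx] for m, v in self.n_raters.items()},
            list(event_ids),
        )


def write_states(states: StateTimecourses, path: str | Path) -> None:
    states.to_frame().to_csv(path, index=False)


def read_states(path: str | Path) -> StateTimecourses:
    return StateTimecourses.from_frame(_read_table(path))


@dataclasses.dataclass(frozen=True)
class SubjectTimeseries:
    """One subject's ROI x TR signal matrix.

    Rows are z-scored over TRs (population sd) at construction unless
    ``validate_only`` is set; ISFC assumes standardized inputs.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    roi_labels: Sequence[str]

    Z_TOL = 1e-6

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise DataError("subject data must be 2-D (ROI x TR)")
        if d.shape[0] != len(self.roi_labels):
            raise DataError("roi_labels length must match data rows")
        mu = d.mean(axis=1)
        sd = d.std(axis=1)
        if np.any(np.abs(mu) > self.Z_TOL) or np.any(np.abs(sd - 1) > self.Z_TOL):
            raise DataError(
                f"subject {self.subject_id}: ROI rows are not z-scored; "
                "use SubjectTimeseries.from_raw"
            )

    @classmethod
    def from_raw(
        cls,
        subject_id: str,
        data: np.ndarray,
        tr_seconds: float,
        roi_labels: Sequence[str],
    ) -> "SubjectTimeseries":
        """Z-score each ROI row over TRs and build the container."""
        d = np.asarray(data, dtype=float)
        sd = d.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            flat = [roi_labels[i] for i in np.where(sd[:, 0] == 0)[0]]
            raise DataError(f"subject {subject_id}: constant ROI rows {flat}")
        z = (d - d.mean(axis=1, keepdims=True)) / sd
        return cls(subject_id, z, tr_seconds, list(roi_labels))

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


def check_cohort(subjects: Sequence[SubjectTimeseries]) -> None:
    """All subjects must share ROI set, TR count and tr_seconds."""
    if not subjects:
        raise DataError("empty subject list")
    ref = subjects[0]
    for s in subjects[1:]:
        if list(s.roi_labels) != list(ref.roi_labels):
            raise DataError(f"subject {s.subject_id}: ROI set mismatch")
        if s.n_trs != ref.n_trs:
            raise DataError(f"subject {s.subject_id}: TR count mismatch")
        if s.tr_seconds != ref.tr_seconds:
            raise DataError(f"subject {s.subject_id}: tr_seconds mismatch")


def write_subjects(subjects: Sequence[SubjectTimeseries], directory: str | Path) -> None:
    """One CSV per subject (TR rows x ROI columns) plus an index sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    check_cohort(subjects)
    index = {
        "tr_seconds": subjects[0].tr_seconds,
        "roi_labels": list(subjects[0].roi_labels),
        "subjects": [s.subject_id for s in subjects],
    }
    (directory / "index.json").write_text(json.dumps(index, indent=2))
    for s in subjects:
        df = pd.DataFrame(s.data.T, columns=list(s.roi_labels))
        df.to_csv(directory / f"{s.subject_id}.csv", index=False, float_format="%.17g")


def read_subjects(directory: str | Path) -> list[SubjectTimeseries]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    subjects = []
    for sid in index["subjects"]:
        df = pd.read_csv(directory / f"{sid}.csv")
        subjects.append(
            SubjectTimeseries.from_raw(
                sid,
                df[index["roi_labels"]].to_numpy().T,
                index["tr_seconds"],
                index["roi_labels"],
            )
        )
    check_cohort(subjects)
    return subjects


@dataclasses.dataclass(frozen=True)
class ROISet:
    """Maps each ROI label to its network, hemisphere and region name."""

    table: pd.DataFrame  # columns: roi_label, network, hemisphere, region_name

    def __post_init__(self) -> None:
        t = self.table
        required = {"roi_label", "network", "hemisphere", "region_name"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"ROI set missing columns: {sorted(missing)}")
        if t["roi_label"].duplicated().any():
            raise DataError("duplicate ROI labels")
        bad = set(t["network"].unique()) - set(NETWORKS)
        if bad:
            raise DataError(f"unknown networks: {sorted(bad)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "ROISet":
        return cls(
            pd.DataFrame(
                records, columns=["roi_label", "network", "hemisphere", "region_name"]
            )
        )

    def network_of(self, roi_label: str) -> str:
        row = self.table.loc[self.table["roi_label"] == roi_label]
        if row.empty:
            raise DataError(f"unknown ROI {roi_label}")
        return row["network"].iloc[0]

    def rois_in(self, network: str) -> list[str]:
        return self.table.loc[self.table["network"] == network, "roi_label"].tolist()

    def validate_against(self, roi_labels: Sequence[str]) -> None:
        known = set(self.table["roi_label"])
        missing = set(roi_labels) - known
        if missing:
            raise DataError(f"ROIs not in ROI set: {sorted(missing)}")


def read_roiset(path: str | Path) -> ROISet:
    return ROISet(_read_table(path))


def write_roiset(roiset: ROISet, path: str | Path) -> None:
    roiset.table.to_csv(path, index=False)


def write_results(result, path: str | Path, manifest: Mapping | None = None) -> None:
    """Write a results table as CSV plus a JSON run manifest.

    ``result`` is anything with ``to_frame()`` (SFPA or peak results) or
    a plain DataFrame.  The manifest records the seed, iteration count
    and a hash of the configuration so a run can be reproduced exactly.
    """
    path = Path(path)
    df = result if isinstance(result, pd.DataFrame) else result.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    if manifest is not None:
        payload = dict(manifest)
        payload["config_hash"] = config_hash(payload)
        path.with_suffix(".manifest.json").write_text(json.dumps(payload, indent=2))


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(
        {k: v for k, v in sorted(config.items()) if k != "config_hash"},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)
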