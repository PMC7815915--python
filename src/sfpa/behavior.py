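"""Behavioral processing: from raw retrospective ratings to group
cognitive-state time-courses.

Each participant's responses are z-scored within participant and
measure (removing idiosyncratic scale use), then averaged across
participants per event, yielding one group time-course per measure.
Because participants rate only a subset of events, each event's mean
pools a different (overlapping) rater set; the rater count is kept
alongside every entry.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import EventTable, RatingsTable, StateTimecourses, DataError


@dataclasses.dataclass(frozen=True)
class ZScoredRatings:
    """Per participant-measure z-scored response vectors (long format).

    ``table`` has columns participant_id, event_id, measure, z.
    Participant-measure cells with zero variance are excluded (the
    participant's responses carry no ordering information) and listed
    in ``excluded``.
    """

    table: pd.DataFrame
    excluded: list[tuple[str, str]]


def zscore_ratings(ratings: RatingsTable) -> ZScoredRatings:
    """Z-score responses within each participant and measure (ddof=1).

    Zero-variance participant-measure cells are dropped with a warning;
    they cannot be standardized and would otherwise contribute
    arbitrary constants to the group mean.
    """
    df = ratings.table.copy()
    out = []
    excluded: list[tuple[str, str]] = []
    for (pid, measure), grp in df.groupby(["participant_id", "measure"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2 or np.std(vals, ddof=0) == 0:
            excluded.append((pid, measure))
            continue
        z = (vals - vals.mean()) / np.std(vals, ddof=1)
        out.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "event_id": grp["event_id"].to_numpy(),
                    "measure": measure,
                    "z": z,
                }
            )
        )
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} zero-variance participant-measure cells: "
            f"{excluded[:5]}{'...' if len(excluded) > 5 else ''}",
            stacklevel=2,
        )
    if not out:
        raise DataError("all participant-measure cells excluded")
    return ZScoredRatings(pd.concat(out, ignore_index=True), excluded)


def aggregate_states(z: ZScoredRatings, events: EventTable) -> StateTimecourses:
    """Average z-scores across participants per event and measure."""
    event_ids = events.event_ids
    order = {e: i for i, e in enumerate(event_ids)}
    unknown = set(z.table["event_id"]) - set(event_ids)
    if unknown:
        raise DataError(f"ratings reference unknown events: {sorted(unknown)[:5]}")
    states: dict[str, np.ndarray] = {}
    n_raters: dict[str, np.ndarray] = {}
    for measure, grp in z.table.groupby("measure", sort=True):
        agg = grp.groupby("event_id")["z"].agg(["mean", "count"])
        vec = np.full(len(event_ids), np.nan)
        cnt = np.zeros(len(event_ids), dtype=int)
        for eid, row in agg.iterrows():
            vec[order[eid]] = row["mean"]
            cnt[order[eid]] = int(row["count"])
        if np.isnan(vec).any():
            missing = [event_ids[i] for i in np.where(np.isnan(vec))[0]]
            raise DataError(
                f"measure {measure!r}: no raters for events {missing[:5]}"
            )
        states[measure] = vec
        n_raters[measure] = cnt
    return StateTimecourses(states, n_raters, event_ids)


def find_peaks(state: np.ndarray, events: EventTable, k: int = 5) -> list[str]:
    """Event ids of the k largest state values; ties broken by earlier onset.

    The default k=5 selects the top five peaks of each cognitive-state
    time-course for the event-triggered peak analysis.
    """
    state = np.asarray(state, dtype=float)
    if k > len(state):
        raise DataError(f"k={k} exceeds number of events {len(state)}")
    # stable sort on -state keeps earlier events first among ties
    idx = np.argsort(-state, kind="stable")[:k]
    idx = np.sort(idx)  # report in chronological order
    return [events.event_ids[i] for i in idx]


def pairwise_state_correlation(states: StateTimecourses) -> pd.DataFrame:
    """Measure x measure Pearson correlation matrix of the group states.

    Constant vectors yield NaN entries (flagged, not raised): a
    degenerate measure should not abort inspection of the others.
    """
    measures = states.measures
    n = len(states.event_ids)
    if n < 3:
        raise DataError("need at least 3 events for state correlations")
    mat = np.full((len(measures), len(measures)), np.nan)
    for i, mi in enumerate(measures):
        for j, mj in enumerate(measures):
            x, y = states.states[mi], states.states[mj]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            mat[i, j] = np.corrcoef(x, y)[0, 1]
        if np.std(states.states[mi]) > 0:
            mat[i, i] = 1.0
    return pd.DataFrame(mat, index=measures, columns=measures)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: Sequence[np.ndarray] | np.ndarray
) -> float:
    """Pearson correlation of x and y after regressing out covariates.

    Both vectors are residualized by least squares against the
    covariates plus an intercept; an empty covariate set reduces to the
    plain Pearson correlation.  Used as the collinearity control:
    e.g. ISFC vs surprise given the other six behavioral measures.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.size == 0:
        cov = np.empty((len(x), 0))
    elif cov.ndim == 1:
        cov = cov[:, None]
    elif cov.shape[0] != len(x):
        cov = cov.T  # accept a sequence of covariate vectors
    if len(x) <= cov.shape[1] + 2:
        raise DataError("need n > n_covariates + 2 observations")
    design = np.column_stack([np.ones(len(x)), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(
        1.0, np.std(y)
    ):
        raise DataError("zero-variance residual in partial correlation")
    return float(np.corrcoef(rx, ry)[0, 1])
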