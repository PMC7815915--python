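"""Control analyses: univariate activation and low-level stimulus features.

Control I asks whether plain regional activation (the group-mean BOLD
time-course, not coactivation) carries the same state information as
ISFC: the SFPA is re-run with per-ROI mean activation in place of the
pair ISFC time-course.  Control II asks whether low-level visual
features (per-frame luminance, spectral saliency) could drive apparent
state-ISFC coupling: the feature is averaged within every event's
15-TR window and used in place of the behavioral time-course.

Both controls reuse the exact permutation (event-shuffle) and BH-FDR
code paths of the main analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataError, EventTable, ROISet, StateTimecourses, check_cohort
from .sfpa import CorrelationSFPA, EventISFC, _child_rng, fisher_ci, parametric_p
from .resampling import event_shuffle_test, fdr_bh

UNIVARIATE_MODES = ("single_tr", "window15", "window5")


class UnivariateSFPA:
    """Control I: SFPA of the group-mean BOLD activation per ROI.

    ``mode`` selects the event score: the single TR at event onset
    (``single_tr``), or the mean over a 15-TR (``window15``) or 5-TR
    (``window5``) window centered on it.  Event retention follows the
    main analysis (onset TR at least 7 TRs from either edge) in every
    mode, so event vectors stay aligned with the ISFC analysis.
    """

    def __init__(
        self,
        subjects,
        events: EventTable,
        states: StateTimecourses,
        mode: str = "single_tr",
        roiset: ROISet | None = None,
        half_window: int = 7,
    ) -> None:
        if mode not in UNIVARIATE_MODES:
            raise DataError(f"mode must be one of {UNIVARIATE_MODES}")
        check_cohort(subjects)
        self.mode = mode
        self.roiset = roiset
        self.roi_labels = list(subjects[0].roi_labels)
        T = subjects[0].n_trs
        onsets = events.onset_trs
        keep = (onsets >= half_window) & (onsets <= T - 1 - half_window)
        if not keep.any():
            raise DataError("no events fall inside the valid range")
        self.retained_event_ids = [
            e for e, k in zip(events.event_ids, keep) if k
        ]
        self.states = states.subset(self.retained_event_ids)
        group = np.stack([s.data for s in subjects]).mean(axis=0)  # (R, T)
        w = {"single_tr": 0, "window5": 2, "window15": 7}[mode]
        cols = []
        for t in onsets[keep]:
            if w == 0:
                cols.append(group[:, t])
            else:
                cols.append(group[:, t - w : t + w + 1].mean(axis=1))
        self.event_values = np.column_stack(cols)  # (R, n_retained)

    def fit(
        self,
        n_iter: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
        measures: Sequence[str] | None = None,
    ) -> "UnivariateSFPAResults":
        measures = list(measures) if measures is not None else self.states.measures
        n = len(self.retained_event_ids)
        if n < 4:
            raise DataError("need at least 4 retained events")
        rows = []
        for mi, measure in enumerate(measures):
            y = self.states.states[measure]
            for ri, roi in enumerate(self.roi_labels):
                x = self.event_values[ri]
                row = {
                    "roi": roi,
                    "network": self.roiset.network_of(roi) if self.roiset else "",
                    "measure": measure,
                    "mode": self.mode,
                    "n_events": n,
                }
                if np.std(x) == 0 or np.std(y) == 0:
                    row.update(r=np.nan, ci_low=np.nan, ci_high=np.nan,
                               p_param=np.nan, p_perm=np.nan)
                else:
                    dec = event_shuffle_test(
                        x, y, n_iter=n_iter,
                        rng=_child_rng(seed, 3000, ri, mi), alpha=alpha,
                    )
                    lo, hi = fisher_ci(dec.observed, n)
                    row.update(
                        r=dec.observed, ci_low=lo, ci_high=hi,
                        p_param=parametric_p(dec.observed, n), p_perm=dec.p,
                    )
                rows.append(row)
        table = pd.DataFrame(rows)
        table["q"] = np.nan
        table["reject"] = False
        for measure in measures:
            m = table["measure"] == measure
            rej, q = fdr_bh(table.loc[m, "p_perm"].to_numpy(), alpha=alpha)
            table.loc[m, "q"] = q
            table.loc[m, "reject"] = rej
        return UnivariateSFPAResults(self, table, n_iter, seed, alpha)


class UnivariateSFPAResults:
    """Per ROI x measure activation-state correlations with inference."""

    def __init__(self, model, table: pd.DataFrame, n_iter, seed, alpha):
        self.model = model
        self.table = table
        self.n_iter = n_iter
        self.seed = seed
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> str:
        lines = [
            f"Univariate SFPA ({self.model.mode}) — group-mean BOLD vs. states",
            f"  ROIs: {len(self.model.roi_labels)}   "
            f"events: {len(self.model.retained_event_ids)}   "
            f"iterations: {self.n_iter}   seed: {self.seed}",
        ]
        for measure, grp in self.table.groupby("measure", sort=False):
            lines.append(
                f"  {measure:<20s} {int(grp['reject'].sum()):3d}/{len(grp)} "
                "ROIs significant after FDR"
            )
        return "\n".join(lines)


def univariate_sfpa(
    subjects,
    events: EventTable,
    states: StateTimecourses,
    mode: str = "single_tr",
    roiset: ROISet | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> UnivariateSFPAResults:
    """Convenience wrapper: build and fit the univariate control model."""
    return UnivariateSFPA(subjects, events, states, mode=mode, roiset=roiset).fit(
        n_iter=n_iter, seed=seed, alpha=alpha
    )


@dataclasses.dataclass(frozen=True)
class FeatureTimecourse:
    """A per-frame stimulus feature (luminance, saliency, ...)."""

    name: str
    values: np.ndarray
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.timestamps_s):
            raise DataError("feature values and timestamps differ in length")
        if not np.all(np.diff(self.timestamps_s) > 0):
            raise DataError("frame timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp_s": self.timestamps_s, self.name: self.values}
        )


def feature_event_timecourse(
    frames: FeatureTimecourse,
    events: EventTable,
    tr_seconds: float,
    n_trs: int | None = None,
    half_window: int = 7,
) -> tuple[np.ndarray, list[str]]:
    """Mean feature value within each retained event's 15-TR window.

    Frames are assigned to the half-open interval
    [(onset_tr - half) * tr, (onset_tr + half) * tr) in seconds,
    matching the temporal range of the ISFC window for that event.
    Returns the event-level vector and the retained event ids.
    """
    onsets = events.onset_trs
    if n_trs is not None:
        keep = (onsets >= half_window) & (onsets <= n_trs - 1 - half_window)
    else:
        keep = np.ones(len(onsets), dtype=bool)
    ts = frames.timestamps_s
    out = []
    ids = []
    for eid, tr, k in zip(events.event_ids, onsets, keep):
        if not k:
            continue
        start = (tr - half_window) * tr_seconds
        end = (tr + half_window) * tr_seconds
        m = (ts >= start) & (ts < end)
        if not m.any():
            raise DataError(f"no frames inside the window of event {eid}")
        out.append(float(frames.values[m].mean()))
        ids.append(eid)
    return np.array(out), ids


def feature_sfpa(
    event_isfc: EventISFC,
    frames: FeatureTimecourse,
    events: EventTable,
    tr_seconds: float,
    n_trs: int,
    roiset: ROISet | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Control II: SFPA with a stimulus feature in place of behavior.

    The feature's event-window means are wrapped as a one-measure state
    time-course and fed through the identical correlation-SFPA path.
    """
    vec, ids = feature_event_timecourse(
        frames, events, tr_seconds, n_trs=n_trs
    )
    if list(ids) != list(event_isfc.retained_event_ids):
        raise DataError("feature events do not match retained ISFC events")
    if np.std(vec) == 0:
        raise DataError(f"constant feature {frames.name}: correlation undefined")
    states = StateTimecourses(
        {frames.name: (vec - vec.mean()) / np.std(vec, ddof=1)},
        {frames.name: np.zeros(len(vec), dtype=int)},
        ids,
    )
    model = CorrelationSFPA(event_isfc, states, roiset=roiset)
    return model.fit(n_iter=n_iter, seed=seed, alpha=alpha, measures=[frames.name])
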