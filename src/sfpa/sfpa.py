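"""State-fluctuation pattern analysis (SFPA).

Two complementary analyses link cognitive-state time-courses to
region-pair coactivation:

* **Correlation SFPA** — the sliding-window ISFC time-course is
  downsampled to the probed movie events (one 15-TR window score per
  event) and the Pearson correlation with each group behavioral
  time-course is computed across events, with an event-shuffle
  permutation null and BH-FDR across region pairs.

* **Peak SFPA** — an event-triggered analysis: ISFC z-scores are
  averaged over the five highest-rated events of each measure within a
  29-time-bin window centered on event onset, with a max-difference
  permutation null for state contrasts and a random-five-event null for
  per-pair inference.

Both are exposed statsmodels-style: a model object built from data
whose ``fit()`` returns a results object carrying estimates,
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import find_peaks
from .data import DataError, EventTable, ROISet, StateTimecourses
from .isfc import ISFCSeries, fisher_z, fisher_z_inv
from .resampling import (
    TestDecision,
    event_shuffle_test,
    fdr_bh,
    pair_peak_test,
    peak_difference_test,
)

Z_CRIT_95 = stats.norm.ppf(0.975)   # 1.959964...


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    tanh(atanh(r) +- z_crit / sqrt(n - 3)).  With r = 0.44 and n = 49
    events this gives the interval [0.18, 0.64] at the 95% level.
    """
    if n < 4:
        raise DataError("need n >= 4 for a Fisher-z interval")
    if abs(r) >= 1:
        warnings.warn("|r| = 1: degenerate confidence interval", stacklevel=2)
        return (float(r), float(r))
    z_crit = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(r)
    half = z_crit / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def parametric_p(r: float, n: int) -> float:
    """Two-sided t-test p value for a Pearson correlation."""
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclasses.dataclass(frozen=True)
class EventISFC:
    """ISFC downsampled to the probed events.

    ``values[p, e]`` is the Fisher-z ISFC of pair p in the 15-TR window
    centered on retained event e's onset TR.  ``subject_values`` keeps
    the per-subject layer when available.
    """

    values: np.ndarray                  # (n_pairs, n_retained)
    pairs: np.ndarray
    roi_labels: Sequence[str]
    retained_event_ids: list[str]
    retained_onset_trs: np.ndarray
    subject_values: np.ndarray | None = None   # (n_subjects, n_pairs, n_retained)
    subject_ids: Sequence[str] = ()

    @property
    def n_retained(self) -> int:
        return len(self.retained_event_ids)

    def pair_index(self, roi_a: str, roi_b: str) -> int:
        labels = list(self.roi_labels)
        i, j = labels.index(roi_a), labels.index(roi_b)
        if i > j:
            i, j = j, i
        hits = np.where((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j))[0]
        if len(hits) == 0:
            raise DataError(f"pair ({roi_a}, {roi_b}) not present")
        return int(hits[0])

    def is_diagonal(self) -> np.ndarray:
        return self.pairs[:, 0] == self.pairs[:, 1]


def event_downsample(
    isfc: ISFCSeries, events: EventTable, half_window: int = 7
) -> EventISFC:
    """Assign each event the ISFC score of the window centered on its onset.

    Events whose onset TR has fewer than ``half_window`` TRs on either
    side (outside the valid sliding-window range) are discarded.
    """
    lo, hi = int(isfc.valid_trs[0]), int(isfc.valid_trs[-1])
    onsets = events.onset_trs
    keep = (onsets >= lo) & (onsets <= hi)
    if not keep.any():
        raise DataError("no events fall inside the valid ISFC range")
    cols = onsets[keep] - lo
    ids = [e for e, k in zip(events.event_ids, keep) if k]
    return EventISFC(
        values=isfc.z[:, cols],
        pairs=isfc.pairs,
        roi_labels=isfc.roi_labels,
        retained_event_ids=ids,
        retained_onset_trs=onsets[keep],
        subject_values=isfc.subject_z[:, :, cols] if isfc.subject_z is not None else None,
        subject_ids=isfc.subject_ids,
    )


def zscore_isfc(isfc: ISFCSeries) -> ISFCSeries:
    """Z-score each pair's ISFC series across the movie time-course (ddof=1).

    Applied before the peak analysis so that event windows are on a
    common scale across pairs.  Per-subject layers are z-scored within
    subject and pair.
    """
    if isfc.n_valid < 2:
        raise DataError("need at least 2 valid TRs to z-score")

    def _z(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=-1, keepdims=True, ddof=1)
        if np.any(sd == 0):
            raise DataError("constant pair series cannot be z-scored")
        return (a - a.mean(axis=-1, keepdims=True)) / sd

    return dataclasses.replace(
        isfc,
        z=_z(isfc.z),
        subject_z=_z(isfc.subject_z) if isfc.subject_z is not None else None,
    )


@dataclasses.dataclass(frozen=True)
class EventWindow:
    """Event-triggered windows of z-scored ISFC.

    ``per_event[e, p, b]`` is the z-scored ISFC of pair p in the 15-TR
    window centered ``offsets[b]`` TRs after event e's onset.  Bin
    index ``half`` (offset 0) is the event onset; bins that fall
    outside the valid ISFC range are NaN.
    """

    per_event: np.ndarray               # (n_events_sel, n_pairs, n_bins)
    offsets: np.ndarray                 # -half..+half
    event_ids: list[str]
    pairs: np.ndarray
    roi_labels: Sequence[str]
    per_event_subject: np.ndarray | None = None   # (n_sub, n_ev, n_pairs, n_bins)
    subject_ids: Sequence[str] = ()

    @property
    def half(self) -> int:
        return len(self.offsets) // 2

    def mean_over_events(self) -> np.ndarray:
        """(n_pairs, n_bins) mean across the selected events."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.per_event, axis=0)


def peak_event_windows(
    z_isfc: ISFCSeries,
    events: EventTable,
    peak_event_ids: Sequence[str],
    half: int = 14,
) -> EventWindow:
    """29-time-bin event windows around the given (peak) events.

    Each bin holds the sliding-window ISFC score centered at
    onset TR + offset; e.g. the bin at offset +1 is the window spanning
    event TR - 6 to event TR + 8.
    """
    lo = int(z_isfc.valid_trs[0])
    n_valid = z_isfc.n_valid
    offsets = np.arange(-half, half + 1)
    id_to_tr = dict(zip(events.event_ids, events.onset_trs))
    unknown = [e for e in peak_event_ids if e not in id_to_tr]
    if unknown:
        raise DataError(f"unknown peak events: {unknown}")
    n_missing = 0
    per_event = np.full((len(peak_event_ids), z_isfc.n_pairs, len(offsets)), np.nan)
    per_sub = (
        np.full(
            (len(z_isfc.subject_ids), len(peak_event_ids), z_isfc.n_pairs, len(offsets)),
            np.nan,
        )
        if z_isfc.subject_z is not None
        else None
    )
    for e, eid in enumerate(peak_event_ids):
        cols = id_to_tr[eid] - lo + offsets
        ok = (cols >= 0) & (cols < n_valid)
        n_missing += int((~ok).sum())
        per_event[e, :, ok] = z_isfc.z[:, cols[ok]].T
        if per_sub is not None:
            per_sub[:, e, :, ok] = np.moveaxis(
                z_isfc.subject_z[:, :, cols[ok]], -1, 0
            )
    if n_missing:
        warnings.warn(
            f"{n_missing} event-window bins fall outside the valid ISFC "
            "range and are marked missing",
            stacklevel=2,
        )
    return EventWindow(
        per_event=per_event,
        offsets=offsets,
        event_ids=list(peak_event_ids),
        pairs=z_isfc.pairs,
        roi_labels=z_isfc.roi_labels,
        per_event_subject=per_sub,
        subject_ids=z_isfc.subject_ids,
    )


def _network_pair_mask(
    pairs: np.ndarray, roi_labels: Sequence[str], roiset: ROISet, network: str,
    include_diagonal: bool = False,
) -> np.ndarray:
    """Pairs with both ROIs in ``network`` (ISC diagonal excluded by default)."""
    nets = np.array([roiset.network_of(l) for l in roi_labels])
    mask = (nets[pairs[:, 0]] == network) & (nets[pairs[:, 1]] == network)
    if not include_diagonal:
        mask &= pairs[:, 0] != pairs[:, 1]
    if not mask.any():
        raise DataError(f"no off-diagonal pairs in network {network!r}")
    return mask


def network_average_window(
    window: EventWindow, roiset: ROISet, network: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average event windows over events and all network pairs.

    Returns the group (n_bins,) curve and, when subject layers exist,
    the per-subject (n_subjects, n_bins) curves for error bars.
    Missing bins are excluded from averages rather than zero-filled.
    """
    mask = _network_pair_mask(window.pairs, window.roi_labels, roiset, network)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        group = np.nanmean(window.per_event[:, mask, :], axis=(0, 1))
        per_sub = (
            np.nanmean(window.per_event_subject[:, :, mask, :], axis=(1, 2))
            if window.per_event_subject is not None
            else None
        )
    return group, per_sub


def network_event_windows(
    z_isfc: ISFCSeries,
    events: EventTable,
    roiset: ROISet,
    network: str,
    retained_event_ids: Sequence[str],
    half: int = 14,
) -> np.ndarray:
    """(n_retained_events, n_bins) network-mean window per event.

    This is the input to the max-difference permutation null: each row
    is one event's network-averaged event-window curve.
    """
    window = peak_event_windows(z_isfc, events, retained_event_ids, half=half)
    mask = _network_pair_mask(window.pairs, window.roi_labels, roiset, network)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(window.per_event[:, mask, :], axis=1)


def network_peak_summary(
    window: EventWindow, roiset: ROISet, networks: Sequence[str]
) -> pd.DataFrame:
    """Mean and SEM across subjects of the onset-bin network ISFC."""
    rows = []
    c = window.half   # onset bin
    for net in networks:
        group, per_sub = network_average_window(window, roiset, net)
        if per_sub is None or len(per_sub) < 2:
            mean, sem = float(group[c]), np.nan
        else:
            vals = per_sub[:, c]
            mean = float(np.nanmean(vals))
            sem = float(np.nanstd(vals, ddof=1) / np.sqrt(np.sum(~np.isnan(vals))))
        rows.append({"network": net, "onset_mean": mean, "onset_sem": sem})
    return pd.DataFrame(rows)


def _child_rng(seed: int | None, *key: int) -> np.random.Generator:
    """Deterministic per-(pair, measure) stream, order-independent."""
    entropy = 0 if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=key))


class CorrelationSFPA:
    """Correlation SFPA model: event-level ISFC vs. cognitive states.

    Parameters
    ----------
    event_isfc : EventISFC
        ISFC downsampled to the probed events.
    states : StateTimecourses
        Group behavioral time-courses; automatically restricted to the
        retained events.
    roiset : ROISet, optional
        Enables network annotations and network-mean summaries.
    """

    def __init__(
        self,
        event_isfc: EventISFC,
        states: StateTimecourses,
        roiset: ROISet | None = None,
    ) -> None:
        missing = set(event_isfc.retained_event_ids) - set(states.event_ids)
        if missing:
            raise DataError(f"states lack retained events: {sorted(missing)[:5]}")
        self.event_isfc = event_isfc
        self.states = states.subset(event_isfc.retained_event_ids)
        self.roiset = roiset
        if roiset is not None:
            roiset.validate_against(event_isfc.roi_labels)

    @classmethod
    def from_dataset(
        cls,
        subjects,
        events: EventTable,
        states: StateTimecourses,
        roiset: ROISet | None = None,
        window_len: int = 15,
    ) -> "CorrelationSFPA":
        """Run sliding ISFC + event downsampling, then build the model."""
        from .isfc import sliding_isfc

        series = sliding_isfc(subjects, window_len=window_len)
        return cls(event_downsample(series, events, half_window=window_len // 2),
                   states, roiset)

    def fit(
        self,
        n_iter: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
        measures: Sequence[str] | None = None,
    ) -> "CorrelationSFPAResults":
        """Correlate every pair with every measure; permutation p + FDR.

        One event-shuffle null per (pair, measure), each drawn from its
        own child RNG stream of the root seed, so results do not depend
        on evaluation order.  FDR is applied across pairs within each
        measure.
        """
        ev = self.event_isfc
        measures = list(measures) if measures is not None else self.states.measures
        n = ev.n_retained
        if n < 4:
            raise DataError("need at least 4 retained events")
        labels = list(ev.roi_labels)
        nets = (
            [self.roiset.network_of(l) for l in labels]
            if self.roiset is not None
            else [""] * len(labels)
        )
        rows = []
        for mi, measure in enumerate(measures):
            y = self.states.states[measure]
            for pi in range(len(ev.pairs)):
                x = ev.values[pi]
                i, j = ev.pairs[pi]
                row = {
                    "roi_i": labels[i],
                    "roi_j": labels[j],
                    "network_i": nets[i],
                    "network_j": nets[j],
                    "is_isc": i == j,
                    "measure": measure,
                    "n_events": n,
                }
                if np.std(x) == 0 or np.std(y) == 0:
                    row.update(
                        r=np.nan, ci_low=np.nan, ci_high=np.nan,
                        p_param=np.nan, p_perm=np.nan,
                    )
                else:
                    rng = _child_rng(seed, pi, mi)
                    dec = event_shuffle_test(x, y, n_iter=n_iter, rng=rng, alpha=alpha)
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
        return CorrelationSFPAResults(self, table, n_iter, seed, alpha)


class CorrelationSFPAResults:
    """Per pair x measure correlation estimates with permutation inference."""

    def __init__(self, model, table: pd.DataFrame, n_iter: int, seed, alpha: float):
        self.model = model
        self.table = table
        self.n_iter = n_iter
        self.seed = seed
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def pair_matrix(self, measure: str, value: str = "r") -> pd.DataFrame:
        """Symmetric ROI x ROI matrix of ``value`` for one measure."""
        sub = self.table[self.table["measure"] == measure]
        labels = list(self.model.event_isfc.roi_labels)
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for _, row in sub.iterrows():
            mat.loc[row["roi_i"], row["roi_j"]] = row[value]
            mat.loc[row["roi_j"], row["roi_i"]] = row[value]
        return mat

    def network_mean_correlation(
        self, network: str, measure: str
    ) -> dict[str, float]:
        """Overall correlation between a state and the network-mean ISFC.

        The ISFC event vectors of all off-diagonal pairs within the
        network are averaged, then correlated with the state vector
        across events (Fisher-z CI and parametric p reported).
        """
        if self.model.roiset is None:
            raise DataError("network summaries need an ROISet")
        ev = self.model.event_isfc
        mask = _network_pair_mask(ev.pairs, ev.roi_labels, self.model.roiset, network)
        mean_series = ev.values[mask].mean(axis=0)
        y = self.model.states.states[measure]
        r = float(np.corrcoef(mean_series, y)[0, 1])
        lo, hi = fisher_ci(r, ev.n_retained)
        return {
            "network": network,
            "measure": measure,
            "r": r,
            "ci_low": lo,
            "ci_high": hi,
            "p_param": parametric_p(r, ev.n_retained),
            "n_events": ev.n_retained,
        }

    def summary(self) -> str:
        lines = [
            "Correlation SFPA results",
            f"  pairs: {len(self.model.event_isfc.pairs)}   "
            f"events: {self.model.event_isfc.n_retained}   "
            f"measures: {len(self.table['measure'].unique())}",
            f"  permutation iterations: {self.n_iter}   seed: {self.seed}   "
            f"alpha: {self.alpha}",
            "",
        ]
        for measure, grp in self.table.groupby("measure", sort=False):
            n_sig = int(grp["reject"].sum())
            lines.append(
                f"  {measure:<20s} {n_sig:3d}/{len(grp)} pairs significant after FDR"
            )
            top = grp.loc[grp["reject"]].nlargest(3, "r")
            for _, row in top.iterrows():
                lines.append(
                    f"      {row['roi_i']}-{row['roi_j']}: r={row['r']:+.3f} "
                    f"CI[{row['ci_low']:+.2f}, {row['ci_high']:+.2f}] "
                    f"p_perm={row['p_perm']:.4f} q={row['q']:.4f}"
                )
        return "\n".join(lines)

    def plot_pair_matrix(self, measure: str, ax=None):
        """Heatmap of pair correlations for one measure."""
        import matplotlib.pyplot as plt

        mat = self.pair_matrix(measure)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
        ax.set_title(f"ISFC-{measure} correlation")
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax


class PeakSFPA:
    """Peak SFPA model: event-triggered ISFC around top-rated events.

    Parameters
    ----------
    isfc : ISFCSeries
        Sliding-window ISFC (subject layers enable across-subject SEM).
    events, states, roiset : alignment, behavior and network structure.
    peak_k : number of top events per measure (default 5).
    half : event-window half width in time-bins (default 14 -> 29 bins).
    """

    def __init__(
        self,
        isfc: ISFCSeries,
        events: EventTable,
        states: StateTimecourses,
        roiset: ROISet,
        peak_k: int = 5,
        half: int = 14,
    ) -> None:
        self.isfc = isfc
        self.z_isfc = zscore_isfc(isfc)
        self.events = events
        self.roiset = roiset
        self.peak_k = peak_k
        self.half = half
        roiset.validate_against(isfc.roi_labels)
        # peak selection happens among retained events only
        retained = event_downsample(isfc, events, half_window=isfc.window_len // 2)
        self.retained_event_ids = retained.retained_event_ids
        self.states = states.subset(self.retained_event_ids)
        self.event_isfc = event_downsample(
            self.z_isfc, events, half_window=isfc.window_len // 2
        )

    def peak_events(self, measure: str) -> list[str]:
        state = self.states.states[measure]
        retained = EventTable.from_onsets(
            self.retained_event_ids,
            [
                self.events.table.set_index("event_id").loc[e, "onset_s"]
                for e in self.retained_event_ids
            ],
            self.events.tr_seconds,
        )
        return find_peaks(state, retained, k=self.peak_k)

    def fit(
        self,
        n_iter: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
        networks: Sequence[str] = ("DMN", "DAN", "Vis"),
        pair_test_network: str = "DMN",
        pair_test_measure: str = "surprise",
    ) -> "PeakSFPAResults":
        """Event-triggered curves, state contrasts and per-pair peak tests."""
        measures = self.states.measures
        peak_ids = {m: self.peak_events(m) for m in measures}
        # network curves: mean +- SEM across subjects, per measure
        curves: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        onset_rows = []
        net_windows: dict[str, np.ndarray] = {}
        for net in networks:
            net_windows[net] = network_event_windows(
                self.z_isfc, self.events, self.roiset, net,
                self.retained_event_ids, half=self.half,
            )
        id_pos = {e: k for k, e in enumerate(self.retained_event_ids)}
        for mi, m in enumerate(measures):
            window = peak_event_windows(
                self.z_isfc, self.events, peak_ids[m], half=self.half
            )
            for net in networks:
                group, per_sub = network_average_window(window, self.roiset, net)
                sem = (
                    np.nanstd(per_sub, axis=0, ddof=1)
                    / np.sqrt(np.sum(~np.isnan(per_sub), axis=0))
                    if per_sub is not None and len(per_sub) > 1
                    else np.full_like(group, np.nan)
                )
                curves[(net, m)] = {
                    "mean": group,
                    "sem": sem,
                    "per_subject": per_sub,
                }
                c = self.half
                if per_sub is not None and len(per_sub) > 1:
                    vals = per_sub[:, c]
                    onset_rows.append(
                        {
                            "network": net,
                            "measure": m,
                            "onset_mean": float(np.nanmean(vals)),
                            "onset_sem": float(
                                np.nanstd(vals, ddof=1)
                                / np.sqrt(np.sum(~np.isnan(vals)))
                            ),
                        }
                    )
                else:
                    onset_rows.append(
                        {
                            "network": net,
                            "measure": m,
                            "onset_mean": float(group[c]),
                            "onset_sem": np.nan,
                        }
                    )
        # state-vs-state max-difference contrasts per network
        contrast_rows = []
        for ni, net in enumerate(networks):
            W = net_windows[net]
            for mi, ma in enumerate(measures):
                for mj, mb in enumerate(measures):
                    if mj <= mi:
                        continue
                    ia = np.array([id_pos[e] for e in peak_ids[ma]])
                    ib_all = np.array([id_pos[e] for e in peak_ids[mb]])
                    ib = np.setdiff1d(ib_all, ia)
                    if len(ib) == 0:
                        continue   # identical peak sets: no contrast
                    ia_d = np.setdiff1d(ia, ib_all)
                    if len(ia_d) == 0:
                        continue
                    dec = peak_difference_test(
                        W, ia_d, ib,
                        n_iter=n_iter,
                        rng=_child_rng(seed, 1000 + ni, mi, mj),
                        alpha=alpha,
                    )
                    contrast_rows.append(
                        {
                            "network": net,
                            "measure_a": ma,
                            "measure_b": mb,
                            "observed_max_diff": dec.observed,
                            "threshold_95": dec.threshold,
                            "p": dec.p,
                            "reject": dec.reject,
                        }
                    )
        # per-pair peak tests within pair_test_network
        mask = _network_pair_mask(
            self.event_isfc.pairs, self.event_isfc.roi_labels,
            self.roiset, pair_test_network,
        )
        pair_rows = []
        labels = list(self.event_isfc.roi_labels)
        peak_idx = np.array([id_pos[e] for e in peak_ids[pair_test_measure]])
        for pi in np.where(mask)[0]:
            dec = pair_peak_test(
                self.event_isfc.values[pi],
                peak_idx,
                n_iter=n_iter,
                rng=_child_rng(seed, 2000, int(pi)),
                alpha=alpha,
            )
            i, j = self.event_isfc.pairs[pi]
            pair_rows.append(
                {
                    "roi_i": labels[i],
                    "roi_j": labels[j],
                    "measure": pair_test_measure,
                    "observed_peak_mean": dec.observed,
                    "p": dec.p,
                }
            )
        pair_table = pd.DataFrame(pair_rows)
        if len(pair_table):
            rej, q = fdr_bh(pair_table["p"].to_numpy(), alpha=alpha)
            pair_table["q"] = q
            pair_table["reject"] = rej
        return PeakSFPAResults(
            model=self,
            curves=curves,
            onset_summary=pd.DataFrame(onset_rows),
            state_contrasts=pd.DataFrame(contrast_rows),
            pair_tests=pair_table,
            peak_event_ids=peak_ids,
            n_iter=n_iter,
            seed=seed,
            alpha=alpha,
        )


class PeakSFPAResults:
    """Event-triggered network curves, state contrasts and pair tests."""

    def __init__(
        self,
        model: PeakSFPA,
        curves: Mapping,
        onset_summary: pd.DataFrame,
        state_contrasts: pd.DataFrame,
        pair_tests: pd.DataFrame,
        peak_event_ids: Mapping[str, list[str]],
        n_iter: int,
        seed,
        alpha: float,
    ) -> None:
        self.model = model
        self.curves = curves
        self.onset_summary = onset_summary
        self.state_contrasts = state_contrasts
        self.pair_tests = pair_tests
        self.peak_event_ids = peak_event_ids
        self.n_iter = n_iter
        self.seed = seed
        self.alpha = alpha

    def curve(self, network: str, measure: str) -> dict[str, np.ndarray]:
        return self.curves[(network, measure)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        offsets = np.arange(-self.model.half, self.model.half + 1)
        for (net, m), c in self.curves.items():
            for b, off in enumerate(offsets):
                rows.append(
                    {
                        "network": net,
                        "measure": m,
                        "offset": int(off),
                        "mean_z": c["mean"][b],
                        "sem": c["sem"][b],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Peak SFPA results",
            f"  peak events per measure: {self.model.peak_k}   "
            f"window: {2 * self.model.half + 1} time-bins   "
            f"iterations: {self.n_iter}   seed: {self.seed}",
            "",
            "  Onset-bin network ISFC (mean +- SEM across subjects):",
        ]
        for _, row in self.onset_summary.iterrows():
            lines.append(
                f"    {row['network']:<5s} {row['measure']:<20s} "
                f"{row['onset_mean']:+.3f} +- {row['onset_sem']:.3f}"
            )
        if len(self.state_contrasts):
            sig = self.state_contrasts[self.state_contrasts["reject"]]
            lines.append("")
            lines.append(
                f"  State contrasts exceeding the max-difference threshold: "
                f"{len(sig)}/{len(self.state_contrasts)}"
            )
        if len(self.pair_tests):
            lines.append(
                f"  Pair peak tests significant after FDR: "
                f"{int(self.pair_tests['reject'].sum())}/{len(self.pair_tests)}"
            )
        return "\n".join(lines)

    def plot_curves(self, networks=("DMN", "DAN", "Vis"), measure="surprise", ax=None):
        """Event-triggered network ISFC with SEM ribbons."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        offsets = np.arange(-self.model.half, self.model.half + 1)
        for net in networks:
            c = self.curves[(net, measure)]
            ax.plot(offsets, c["mean"], label=net)
            ax.fill_between(
                offsets, c["mean"] - c["sem"], c["mean"] + c["sem"], alpha=0.25
            )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time-bins from event onset")
        ax.set_ylabel("network ISFC (z)")
        ax.set_title(f"Event-triggered ISFC: peak {measure}")
        ax.legend()
        return ax
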