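"""Permutation nulls and false-discovery-rate control.

Three null constructions drive inference in the pipeline:

* event-shuffle — permute the events of an ISFC time-course and
  re-correlate with the intact behavioral time-course (two-tailed);
* peak max-difference — the max over event-window time-bins of the
  absolute difference between the means of two disjoint random
  five-event sets (one-tailed, 95th-percentile threshold);
* pair peak — the mean ISFC of five random events, against which the
  observed five-peak-event mean is ranked (one-tailed).

All p values use add-one smoothing, p = (1 + #{null >= obs}) / (1 + n_iter),
so a sampled permutation p is never exactly zero.  Every test is
reproducible bit-for-bit given its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import DataError


@dataclasses.dataclass(frozen=True)
class PermutationNull:
    """A null distribution of a permutation statistic."""

    values: np.ndarray
    statistic: str
    seed: int | None
    n_iter: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_iter:
            raise DataError("null length must equal n_iter")


@dataclasses.dataclass(frozen=True)
class TestDecision:
    """Outcome of one permutation test."""

    observed: float
    p: float
    null_mean: float
    threshold: float          # the null percentile used for rejection
    reject: bool
    n_iter: int
    seed: int | None
    null: PermutationNull | None = None


def _smoothed_p(count_ge: int, n_iter: int) -> float:
    return (1 + count_ge) / (1 + n_iter)


def event_shuffle_test(
    event_isfc_pair: np.ndarray,
    state: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    keep_null: bool = False,
    perm_index: np.ndarray | None = None,
) -> TestDecision:
    """Two-tailed event-shuffle permutation test of an ISFC-state correlation.

    The events of the ISFC vector are randomly shuffled and re-correlated
    with the intact state vector ``n_iter`` times; p is the (smoothed)
    fraction of null |r| at least as large as the observed |r|.

    ``perm_index`` lets a caller share one (n_iter, n_events) permutation
    matrix across many pairs so results are pair-order independent.
    """
    x = np.asarray(event_isfc_pair, dtype=float)
    y = np.asarray(state, dtype=float)
    if len(x) != len(y):
        raise DataError("ISFC and state vectors differ in length")
    if len(x) < 4:
        raise DataError("need at least 4 events")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("constant input vector")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = None
    if perm_index is None:
        perm_index = np.stack([rng.permutation(len(x)) for _ in range(n_iter)])
    else:
        n_iter = perm_index.shape[0]

    r_obs = float(np.corrcoef(x, y)[0, 1])
    # vectorized null: correlate every shuffled x row with intact y
    Xp = x[perm_index]                               # (n_iter, n_events)
    Xc = Xp - Xp.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (yc * yc).sum())
    r_null = (Xc @ yc) / denom
    count = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
    p = _smoothed_p(count, n_iter)
    return TestDecision(
        observed=r_obs,
        p=p,
        null_mean=float(r_null.mean()),
        threshold=float(np.percentile(np.abs(r_null), 100 * (1 - alpha))),
        reject=p < alpha,
        n_iter=n_iter,
        seed=seed,
        null=PermutationNull(r_null, "shuffled_pearson_r", seed, n_iter)
        if keep_null
        else None,
    )


def peak_difference_test(
    event_windows: np.ndarray,
    set_a: np.ndarray,
    set_b: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    keep_null: bool = False,
) -> TestDecision:
    """Max-difference permutation test between two five-event sets.

    ``event_windows`` is (n_events, n_bins): the network event-window
    ISFC of every retained event.  The observed statistic is the max
    over bins of |mean over set_a - mean over set_b|; the null draws
    two disjoint random sets of the same sizes each iteration.  The
    rejection threshold is the 95th percentile of the null maxima
    (one-tailed).
    """
    W = np.asarray(event_windows, dtype=float)
    a = np.asarray(set_a, dtype=int)
    b = np.asarray(set_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise DataError("peak event sets must be disjoint")
    n_events = W.shape[0]
    if n_events < len(a) + len(b):
        raise DataError("not enough events for two disjoint sets")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def max_abs_diff(ia: np.ndarray, ib: np.ndarray) -> float:
        d = np.nanmean(W[ia], axis=0) - np.nanmean(W[ib], axis=0)
        return float(np.nanmax(np.abs(d)))

    obs = max_abs_diff(a, b)
    null = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(n_events)
        null[it] = max_abs_diff(perm[: len(a)], perm[len(a) : len(a) + len(b)])
    threshold = float(np.percentile(null, 100 * (1 - alpha)))
    p = _smoothed_p(int((null >= obs - 1e-12).sum()), n_iter)
    return TestDecision(
        observed=obs,
        p=p,
        null_mean=float(null.mean()),
        threshold=threshold,
        reject=obs > threshold,
        n_iter=n_iter,
        seed=None,
        null=PermutationNull(null, "max_abs_bin_difference", None, n_iter)
        if keep_null
        else None,
    )


def pair_peak_test(
    event_means: np.ndarray,
    peak_idx: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    keep_null: bool = False,
) -> TestDecision:
    """One-tailed test of the five-peak-event mean ISFC for one pair.

    The null is the mean ISFC over five (or ``len(peak_idx)``) random
    events; the observed statistic is the mean over the peak events.
    """
    x = np.asarray(event_means, dtype=float)
    k = len(peak_idx)
    if len(x) < k + 1:
        raise DataError(f"need more than {k} events")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    obs = float(np.mean(x[np.asarray(peak_idx, dtype=int)]))
    # vectorized draw: one permutation per iteration, take first k
    idx = np.argsort(rng.random((n_iter, len(x))), axis=1)[:, :k]
    null = x[idx].mean(axis=1)
    p = _smoothed_p(int((null >= obs - 1e-12).sum()), n_iter)
    return TestDecision(
        observed=obs,
        p=p,
        null_mean=float(null.mean()),
        threshold=float(np.percentile(null, 100 * (1 - alpha))),
        reject=p < alpha,
        n_iter=n_iter,
        seed=None,
        null=PermutationNull(null, "random_five_event_mean", None, n_iter)
        if keep_null
        else None,
    )


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted q values).  NaN entries (undefined
    tests) are passed through as NaN / not rejected and do not count
    toward the number of hypotheses.
    """
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DataError("p values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    q = np.full(p.shape, np.nan)
    if ok.sum():
        rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        reject[ok] = rej
        q[ok] = adj
    return reject, q
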