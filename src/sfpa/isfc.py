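"""Inter-subject functional correlation (ISFC).

ISFC isolates the stimulus-driven, group-shared component of regional
coactivation: each subject's signal in region i is correlated with the
*average of all other subjects* in region j, so idiosyncratic and
spontaneous fluctuations (uncorrelated across subjects) cancel out of
one side of the correlation.  The sliding-window variant tracks this
coactivation over time; the full-length variant gives one value per
region pair, with a phase-randomization max-statistic null for
familywise inference.

The directional statistic (subject-in-i vs. others-in-j) is computed in
both directions and the Fisher-z values averaged, yielding a symmetric
pair matrix.  Diagonal entries (i == j) are the inter-subject
correlation (ISC).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataError, SubjectTimeseries, check_cohort
from .resampling import PermutationNull

logger = logging.getLogger(__name__)

#: Correlations are clipped to +-(1 - CLIP_EPS) before atanh so Fisher-z
#: values stay finite.
CLIP_EPS = 1e-7
_VAR_EPS = 1e-12


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping so z is finite even at |r| = 1."""
    return np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))


def fisher_z_inv(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def upper_pairs(n_rois: int) -> np.ndarray:
    """Ordered (i, j) index pairs with i <= j, diagonal included."""
    iu = np.triu_indices(n_rois)
    return np.column_stack(iu)


@dataclasses.dataclass(frozen=True)
class ISFCSeries:
    """Sliding-window ISFC time-courses for every region pair.

    ``z`` holds the group-mean Fisher-z coactivation, one row per pair
    (upper triangle including the ISC diagonal), one column per valid
    TR (window centers ``valid_trs``).  ``subject_z`` keeps the
    per-subject layer for analyses that need across-subject error bars.
    """

    z: np.ndarray                       # (n_pairs, n_valid)
    pairs: np.ndarray                   # (n_pairs, 2) ROI index pairs, i <= j
    roi_labels: Sequence[str]
    valid_trs: np.ndarray               # window-center TR indices
    window_len: int
    subject_ids: Sequence[str]
    subject_z: np.ndarray | None = None  # (n_subjects, n_pairs, n_valid)
    n_zero_variance_windows: int = 0

    @property
    def r(self) -> np.ndarray:
        """Group coactivation back on the correlation scale."""
        return fisher_z_inv(self.z)

    @property
    def n_pairs(self) -> int:
        return self.z.shape[0]

    @property
    def n_valid(self) -> int:
        return self.z.shape[1]

    def pair_index(self, roi_a: str, roi_b: str) -> int:
        labels = list(self.roi_labels)
        i, j = labels.index(roi_a), labels.index(roi_b)
        if i > j:
            i, j = j, i
        hits = np.where((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j))[0]
        if len(hits) == 0:
            raise DataError(f"pair ({roi_a}, {roi_b}) not present")
        return int(hits[0])

    def pair_series(self, roi_a: str, roi_b: str) -> np.ndarray:
        return self.z[self.pair_index(roi_a, roi_b)]

    def pair_labels(self) -> list[tuple[str, str]]:
        labels = list(self.roi_labels)
        return [(labels[i], labels[j]) for i, j in self.pairs]

    def is_diagonal(self) -> np.ndarray:
        return self.pairs[:, 0] == self.pairs[:, 1]

    def to_frame(self) -> pd.DataFrame:
        labels = self.pair_labels()
        df = pd.DataFrame(
            self.z,
            index=pd.MultiIndex.from_tuples(labels, names=["roi_i", "roi_j"]),
            columns=[f"tr_{t}" for t in self.valid_trs],
        )
        return df.reset_index()


def loo_average(
    subjects: Sequence[SubjectTimeseries], exclude: str
) -> np.ndarray:
    """Element-wise mean over all subjects except ``exclude``."""
    check_cohort(subjects)
    if len(subjects) < 2:
        raise DataError("leave-one-out average needs at least 2 subjects")
    ids = [s.subject_id for s in subjects]
    if exclude not in ids:
        raise DataError(f"unknown subject {exclude}")
    stack = np.stack([s.data for s in subjects if s.subject_id != exclude])
    return stack.mean(axis=0)


def _windowed_moments(a: np.ndarray, w: int):
    """Sliding sums and sums of squares along the last axis (cumsum trick)."""
    cs = np.concatenate(
        [np.zeros(a.shape[:-1] + (1,)), np.cumsum(a, axis=-1)], axis=-1
    )
    s = cs[..., w:] - cs[..., :-w]
    cs2 = np.concatenate(
        [np.zeros(a.shape[:-1] + (1,)), np.cumsum(a * a, axis=-1)], axis=-1
    )
    s2 = cs2[..., w:] - cs2[..., :-w]
    return s, s2


def _directional_window_r(X: np.ndarray, L: np.ndarray, w: int) -> tuple[np.ndarray, int]:
    """Sliding-window Pearson r between every row of X and every row of L.

    Returns (R, R, n_valid) with r[i, j, t] the correlation of X[i] and
    L[j] over the window centered at valid TR t, plus the count of
    zero-variance windows (their r is set to 0 so the subject count
    stays constant across TRs).
    """
    sx, sxx = _windowed_moments(X, w)
    sl, sll = _windowed_moments(L, w)
    # cross products for all ordered pairs
    P = X[:, None, :] * L[None, :, :]
    sxl, _ = _windowed_moments(P, w)
    var_x = sxx - sx * sx / w            # w * population variance
    var_l = sll - sl * sl / w
    cov = sxl - sx[:, None, :] * sl[None, :, :] / w
    denom = np.sqrt(np.maximum(var_x[:, None, :], 0.0) * np.maximum(var_l[None, :, :], 0.0))
    bad = denom < _VAR_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    return r, int(bad.sum())


def sliding_isfc(
    subjects: Sequence[SubjectTimeseries],
    window_len: int = 15,
    keep_subject_layers: bool = True,
) -> ISFCSeries:
    """Sliding-window ISFC over all region pairs.

    For each subject, TR window (length ``window_len``, centered on each
    valid TR) and ordered ROI pair (i, j): the Pearson correlation of
    the subject's ROI-i window with the leave-one-out group-average
    ROI-j window.  Correlations are Fisher-transformed, the two
    directions averaged, then averaged across subjects.
    """
    check_cohort(subjects)
    if len(subjects) < 2:
        raise DataError("ISFC needs at least 2 subjects")
    if window_len % 2 != 1:
        raise DataError("window_len must be odd")
    T = subjects[0].n_trs
    if T < window_len:
        raise DataError(f"need at least {window_len} TRs, got {T}")
    half = window_len // 2
    valid_trs = np.arange(half, T - half)
    R = len(subjects[0].roi_labels)
    pairs = upper_pairs(R)
    iu = (pairs[:, 0], pairs[:, 1])

    total = np.stack([s.data for s in subjects]).sum(axis=0)
    n_sub = len(subjects)
    group_z = np.zeros((len(pairs), len(valid_trs)))
    subject_z = (
        np.empty((n_sub, len(pairs), len(valid_trs))) if keep_subject_layers else None
    )
    n_zero = 0
    for k, s in enumerate(subjects):
        L = (total - s.data) / (n_sub - 1)
        r, nz = _directional_window_r(s.data, L, window_len)
        n_zero += nz
        z = fisher_z(r)
        z_sym = 0.5 * (z + np.swapaxes(z, 0, 1))   # average both directions
        zp = z_sym[iu[0], iu[1], :]
        group_z += zp
        if subject_z is not None:
            subject_z[k] = zp
    group_z /= n_sub
    if n_zero:
        logger.info("sliding_isfc: %d zero-variance windows set to r=0", n_zero)
    return ISFCSeries(
        z=group_z,
        pairs=pairs,
        roi_labels=list(subjects[0].roi_labels),
        valid_trs=valid_trs,
        window_len=window_len,
        subject_ids=[s.subject_id for s in subjects],
        subject_z=subject_z,
        n_zero_variance_windows=n_zero,
    )


def _directional_full_r(X: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Full-length Pearson r between every row of X and every row of L."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Lc = L - L.mean(axis=1, keepdims=True)
    nx = np.sqrt((Xc * Xc).sum(axis=1))
    nl = np.sqrt((Lc * Lc).sum(axis=1))
    nx = np.where(nx < _VAR_EPS, np.inf, nx)   # zero-variance rows -> r = 0
    nl = np.where(nl < _VAR_EPS, np.inf, nl)
    return (Xc / nx[:, None]) @ (Lc / nl[:, None]).T


def full_isfc(subjects: Sequence[SubjectTimeseries]) -> pd.DataFrame:
    """Single ISFC value per pair over the entire time-course.

    Equivalent to ``sliding_isfc`` with the window spanning all TRs:
    one correlation per subject and direction, Fisher-averaged.
    Diagonal entries are the full-length ISC.
    """
    check_cohort(subjects)
    if len(subjects) < 2:
        raise DataError("ISFC needs at least 2 subjects")
    R = len(subjects[0].roi_labels)
    pairs = upper_pairs(R)
    total = np.stack([s.data for s in subjects]).sum(axis=0)
    n_sub = len(subjects)
    acc = np.zeros((R, R))
    for s in subjects:
        L = (total - s.data) / (n_sub - 1)
        z = fisher_z(_directional_full_r(s.data, L))
        acc += 0.5 * (z + z.T)
    acc /= n_sub
    labels = list(subjects[0].roi_labels)
    return pd.DataFrame(
        {
            "roi_i": [labels[i] for i, _ in pairs],
            "roi_j": [labels[j] for _, j in pairs],
            "z": acc[pairs[:, 0], pairs[:, 1]],
            "r": fisher_z_inv(acc[pairs[:, 0], pairs[:, 1]]),
        }
    )


def phase_randomize(
    signal: np.ndarray, rng: np.random.Generator, mode: str = "uniform"
) -> np.ndarray:
    """Fourier phase-randomized surrogate of a real signal.

    The amplitude spectrum (hence autocorrelation) is preserved; the DC
    term and, for even length, the Nyquist term are untouched; positive-
    frequency phases are replaced (``mode='uniform'``: i.i.d. uniform on
    [0, 2pi); ``mode='permute'``: a permutation of the original phases)
    and mirrored conjugate-symmetrically so the surrogate is real.
    """
    signal = np.asarray(signal)
    if np.iscomplexobj(signal):
        raise DataError("phase_randomize expects a real signal")
    n = signal.shape[-1]
    if n < 4:
        raise DataError("signal too short to phase-randomize")
    spec = np.fft.rfft(signal, axis=-1)
    n_freq = spec.shape[-1]
    # indices 1..n_freq-1 are positive frequencies; the last one is the
    # Nyquist bin only when n is even, and must keep a real value then
    hi = n_freq - 1 if n % 2 == 0 else n_freq
    k = hi - 1
    if mode == "uniform":
        phases = rng.uniform(0.0, 2 * np.pi, size=spec.shape[:-1] + (k,))
    elif mode == "permute":
        orig = np.angle(spec[..., 1:hi])
        phases = rng.permuted(orig, axis=-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    amps = np.abs(spec[..., 1:hi])
    out = spec.copy()
    out[..., 1:hi] = amps * np.exp(1j * phases)
    return np.fft.irfft(out, n=n, axis=-1)


def max_null_isfc(
    subjects: Sequence[SubjectTimeseries],
    spec_n_iter: int = 1000,
    seed: int | None = None,
    mode: str = "uniform",
) -> tuple[float, PermutationNull]:
    """Familywise threshold for full-length ISFC via phase surrogates.

    Per iteration every subject's every ROI signal is phase-randomized;
    each surrogate subject is correlated (both directions, all pairs)
    against the leave-one-out mean of the surrogates, and the maximum
    |r| over pairs and subjects joins the null.  Returns the 95th
    percentile of that max-null and the null itself.
    """
    check_cohort(subjects)
    if spec_n_iter < 1:
        raise DataError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = len(subjects)
    null = np.empty(spec_n_iter)
    data = np.stack([s.data for s in subjects])     # (S, R, T)
    for it in range(spec_n_iter):
        surr = phase_randomize(data, rng, mode=mode)
        total = surr.sum(axis=0)
        max_abs = 0.0
        for k in range(n_sub):
            L = (total - surr[k]) / (n_sub - 1)
            r = _directional_full_r(surr[k], L)
            max_abs = max(max_abs, float(np.abs(r).max()))
        null[it] = max_abs
    threshold = float(np.percentile(null, 95))
    return threshold, PermutationNull(
        values=null, statistic="max_abs_r", seed=seed, n_iter=spec_n_iter
    )
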