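"""Synthetic multi-subject neural + behavioral datasets.

The generator encodes the statistical structure the ISFC logic relies
on: every subject's regional signal is a group-common, stimulus-driven
component plus idiosyncratic AR(1) noise.  A state-dependent
coactivation effect is planted *multiplicatively* on a shared signal
u(t) inside each event's +-7-TR window — the coupling gain
(a0 + beta * surprise(e)) scales a component common to all coupled
ROIs, so it alters inter-regional correlation without adding a
surprise-locked univariate activation of its own.

Defaults mirror the Sherlock-style configuration: 35 subjects, 946 TRs
at 1.5 s, 49 probed events at roughly 30-s intervals, 31 ROIs grouped
into DMN (10), DAN (12), Vis (4) and subcortical (5).  Behavioral
raters (45) are split into three chronologically interleaved event
subsets, as in the questionnaire design the pipeline ingests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .controls import FeatureTimecourse
from .data import (
    COUNT_MEASURES,
    MEASURES,
    RATING_MEASURES,
    DataError,
    EventTable,
    RatingsTable,
    ROISet,
    SubjectTimeseries,
)

_DMN_REGIONS = ("PCC", "AG", "MTG", "MFG", "mPFC")
_DAN_REGIONS = ("SPL", "PostC", "FEF", "OTC", "ParOcc", "PrCv")
_VIS_REGIONS = ("VisCent", "VisPeri")
_SUBCORTICAL = ("HC", "NAcc", "Cd", "Pt", "Thl")


def default_roiset() -> ROISet:
    """31 ROIs: bilateral cortical regions plus bilateral-pooled subcortex."""
    records = []
    for region in _DMN_REGIONS:
        for hemi in ("L", "R"):
            records.append((f"{region}_{hemi}", "DMN", hemi, region))
    for region in _DAN_REGIONS:
        for hemi in ("L", "R"):
            records.append((f"{region}_{hemi}", "DAN", hemi, region))
    for region in _VIS_REGIONS:
        for hemi in ("L", "R"):
            records.append((f"{region}_{hemi}", "Vis", hemi, region))
    for region in _SUBCORTICAL:
        records.append((region, "subcortical", "bilateral", region))
    return ROISet.from_records(records)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    The neural model per ROI r and TR t is
    ``c_r(t) = g_r(t) + [r coupled] * (a0 + coupling_beta * s(e(t))) * u(t)``
    inside event windows, where g_r and u are independent AR(1)
    group-common signals and s is the latent surprise of the event
    owning TR t; each subject adds independent AR(1) noise.
    """

    n_subjects: int = 35
    n_trs: int = 946
    tr_seconds: float = 1.5
    n_events: int = 49
    event_spacing_s: float = 30.0
    coupling_beta: float = 1.5
    baseline_gain: float = 1.5          # a0: event-window coupling at s = 0
    shared_signal_sd: float = 1.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.3                # BOLD-like smoothness at TR 1.5 s
    rating_noise_sd: float = 1.0
    n_raters: int = 45
    half_window: int = 7
    couple_subcortical: bool = False    # extend coupling to HC and NAcc
    collinearity: float = 0.0           # corr(surprise, emotional_intensity) latents
    vis_feature_gain: float = 1.0       # Vis shared-component amplitude coupling
    frame_rate_hz: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_trs < 15 or self.n_events < 1:
            raise DataError("invalid simulation dimensions")
        if not (0 <= self.ar1_phi < 1):
            raise DataError("ar1_phi must lie in [0, 1)")
        if self.coupling_beta < 0:
            raise DataError("coupling_beta must be non-negative")
        if not (-1 < self.collinearity < 1):
            raise DataError("collinearity must lie in (-1, 1)")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What was planted: latents, coupled ROIs and window ownership."""

    latents: Mapping[str, np.ndarray]    # measure -> per-event latent
    coupled_rois: list[str]
    event_onset_trs: np.ndarray
    window_event: np.ndarray             # per TR: owning event index or -1
    feature_envelope: np.ndarray         # Vis shared-component amplitude per TR
    config: SimConfig

    def coupled_pair(self, roi_a: str, roi_b: str) -> bool:
        return roi_a in self.coupled_rois and roi_b in self.coupled_rois

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latents": {m: v.tolist() for m, v in self.latents.items()},
            "coupled_rois": self.coupled_rois,
            "event_onset_trs": self.event_onset_trs.tolist(),
            "window_event": self.window_event.tolist(),
            "feature_envelope": self.feature_envelope.tolist(),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload))


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    eps = rng.standard_normal(shape)
    if phi == 0:
        return eps
    out = np.empty(shape)
    out[..., 0] = eps[..., 0]
    scale = np.sqrt(1 - phi * phi)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + scale * eps[..., t]
    return out


def _event_onsets(cfg: SimConfig) -> np.ndarray:
    """Event onset times: nominal spacing, compressed to fit the valid range.

    All events must keep half_window TRs on both sides so they survive
    downsampling; 49 events at a strict 30 s cannot fit in 946 x 1.5 s,
    so spacing shrinks to cover the range evenly (~28.6 s by default).
    """
    t_min = (cfg.half_window + 1) * cfg.tr_seconds
    t_max = (cfg.n_trs - 2 - cfg.half_window) * cfg.tr_seconds
    if cfg.n_events == 1:
        return np.array([(t_min + t_max) / 2])
    spacing = min(cfg.event_spacing_s, (t_max - t_min) / (cfg.n_events - 1))
    start = t_min + ((t_max - t_min) - spacing * (cfg.n_events - 1)) / 2
    return start + spacing * np.arange(cfg.n_events)


def _window_ownership(onset_trs: np.ndarray, n_trs: int, half: int) -> np.ndarray:
    """Per TR: index of the nearest event whose +-half window covers it, else -1.

    Recorded in the ground truth for diagnostics; the planted gain
    itself sums over all covering events (see ``_gain_timecourse``), so
    an event's modulation always spans its full window even when
    neighboring windows overlap.
    """
    own = np.full(n_trs, -1, dtype=int)
    trs = np.arange(n_trs)
    dist = np.abs(trs[:, None] - onset_trs[None, :])
    nearest = np.argmin(dist, axis=1)
    in_window = dist[trs, nearest] <= half
    own[in_window] = nearest[in_window]
    return own


def _gain_timecourse(
    onset_trs: np.ndarray, n_trs: int, half: int,
    a0: float, beta: float, s: np.ndarray,
) -> np.ndarray:
    """Per-TR coupling gain: sum of (a0 + beta * s_e) over covering windows."""
    gain = np.zeros(n_trs)
    for e, tr in enumerate(onset_trs):
        lo, hi = max(0, tr - half), min(n_trs, tr + half + 1)
        gain[lo:hi] += a0 + beta * s[e]
    return gain


def _latents(rng: np.random.Generator, cfg: SimConfig) -> dict[str, np.ndarray]:
    lat = {m: rng.standard_normal(cfg.n_events) for m in MEASURES}
    if cfg.collinearity != 0:
        rho = cfg.collinearity
        lat["emotional_intensity"] = (
            rho * lat["surprise"]
            + np.sqrt(1 - rho * rho) * lat["emotional_intensity"]
        )
    return lat


def _ratings(
    rng: np.random.Generator, cfg: SimConfig, latents: Mapping[str, np.ndarray],
    event_ids: Sequence[str],
) -> RatingsTable:
    rows = []
    for rater in range(cfg.n_raters):
        pid = f"rater{rater:03d}"
        subset = rater % 3
        eidx = [e for e in range(cfg.n_events) if e % 3 == subset]
        for m in MEASURES:
            s = latents[m]
            noise = rng.normal(0, cfg.rating_noise_sd, size=len(eidx))
            raw = 4 + 1.5 * s[eidx] + noise
            if m in RATING_MEASURES:
                vals = np.clip(np.round(raw), 1, 7).astype(int)
            else:
                # free-recall unit counts: non-negative, roughly 0-8
                vals = np.maximum(np.round(raw - 1), 0).astype(int)
            for e, v in zip(eidx, vals):
                rows.append((pid, event_ids[e], m, int(v)))
    return RatingsTable(
        pd.DataFrame(rows, columns=["participant_id", "event_id", "measure", "value"])
    )


def generate_dataset(cfg: SimConfig):
    """Generate one full synthetic study.

    Returns ``(subjects, events, ratings, features, ground_truth)``
    where ``features`` maps 'luminance' and 'saliency' to per-frame
    FeatureTimecourses coupled to the Vis shared-component amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    roiset = default_roiset()
    labels = roiset.table["roi_label"].tolist()
    R = len(labels)

    onset_s = _event_onsets(cfg)
    event_ids = [f"ev{k:03d}" for k in range(cfg.n_events)]
    events = EventTable.from_onsets(event_ids, onset_s, cfg.tr_seconds)
    own = _window_ownership(events.onset_trs, cfg.n_trs, cfg.half_window)

    latents = _latents(rng, cfg)
    coupled = [l for l in labels if roiset.network_of(l) == "DMN"]
    if cfg.couple_subcortical:
        coupled += ["HC", "NAcc"]

    # group-common components
    g = cfg.shared_signal_sd * _ar1(rng, (R, cfg.n_trs), cfg.ar1_phi)
    u = _ar1(rng, (cfg.n_trs,), cfg.ar1_phi)
    gain = _gain_timecourse(
        events.onset_trs, cfg.n_trs, cfg.half_window,
        cfg.baseline_gain, cfg.coupling_beta, latents["surprise"],
    )
    coupled_mask = np.array([l in coupled for l in labels])
    common = g.copy()
    common[coupled_mask] += gain * u

    # Vis shared component with a smooth positive amplitude envelope
    h = _ar1(rng, (cfg.n_trs,), 0.95)
    envelope = np.exp(0.4 * h)
    v = envelope * _ar1(rng, (cfg.n_trs,), cfg.ar1_phi)
    vis_mask = np.array([roiset.network_of(l) == "Vis" for l in labels])
    common[vis_mask] += cfg.vis_feature_gain * v

    subjects = []
    for k in range(cfg.n_subjects):
        noise = cfg.noise_sd * _ar1(rng, (R, cfg.n_trs), cfg.ar1_phi)
        subjects.append(
            SubjectTimeseries.from_raw(
                f"sub{k:03d}", common + noise, cfg.tr_seconds, labels
            )
        )

    ratings = _ratings(rng, cfg, latents, event_ids)

    # per-frame features tracking the Vis amplitude envelope
    n_frames = int(cfg.n_trs * cfg.tr_seconds * cfg.frame_rate_hz)
    ts = np.arange(n_frames) / cfg.frame_rate_hz
    env_frames = np.interp(ts, np.arange(cfg.n_trs) * cfg.tr_seconds, envelope)
    features = {
        name: FeatureTimecourse(
            name, env_frames + rng.normal(0, 0.05, n_frames), ts
        )
        for name in ("luminance", "saliency")
    }

    truth = GroundTruth(
        latents=latents,
        coupled_rois=coupled,
        event_onset_trs=events.onset_trs,
        window_event=own,
        feature_envelope=envelope,
        config=cfg,
    )
    return subjects, events, ratings, features, truth


def generate_null_dataset(cfg: SimConfig):
    """Same generative model with no planted coupling (beta = 0, a0 = 0)."""
    null_cfg = dataclasses.replace(cfg, coupling_beta=0.0, baseline_gain=0.0)
    subjects, events, ratings, features, truth = generate_dataset(null_cfg)
    truth = dataclasses.replace(truth, coupled_rois=[])
    return subjects, events, ratings, features, truth
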