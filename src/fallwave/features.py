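"""Per-recording features: the wavelet similarity score and UPV/LPV baselines.

The wavelet feature scans the SV series for samples above a 1.5 g trigger;
each supra-threshold sample that admits a full 2-second centered window
becomes a candidate, scored by the maximum CWT coefficient over the
restricted (scale, translation) box; the feature is the overall maximum over
candidates, clipped below at zero.  Recordings that never cross the trigger
score exactly zero.

The baselines are the classic impact features: UPV (upper peak value), the
global SV maximum, and LPV (lower peak value), the free-fall minimum reached
shortly before the impact peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cwt import CWTGrid, dilated_bank, half_support
from .signals import (
    Recording,
    SumVectorSeries,
    compute_sv,
)
from .wavelet import MotherWavelet

__all__ = [
    "FeatureConfig",
    "wavelet_feature",
    "upv_feature",
    "lpv_feature",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("id", "label", "wavelet", "upv_g", "lpv_g")


@dataclass
class FeatureConfig:
    """Knobs of the wavelet-feature scan and of the LPV search.

    trigger_threshold_g : SV level that starts wavelet analysis (1.5 g —
        deliberately low so that no falls are missed).
    window_duration_s : candidate window length (2 s, the prototype's span).
    scan_stride : scan step in samples; 1 reproduces the reference behavior
        of re-running the analysis at every supra-threshold sample.
    lpv_search_s : how far before the global peak the LPV minimum is sought.
    """

    trigger_threshold_g: float = 1.5
    window_duration_s: float = 2.0
    scan_stride: int = 1
    lpv_search_s: float = 1.0
    edge_policy: Literal["skip", "reflect"] = "skip"
    cwt_norm: Literal["inverse_scale", "inverse_sqrt_scale"] = "inverse_scale"
    scale_step: int = 1
    translation_step: int = 1

    def __post_init__(self) -> None:
        if self.trigger_threshold_g <= 0:
            raise ValueError("trigger_threshold_g must be positive")
        if self.scan_stride < 1:
            raise ValueError("scan_stride must be >= 1")

    def grid(self, fs: int) -> CWTGrid:
        return CWTGrid(fs=fs, scale_step=self.scale_step,
                       translation_step=self.translation_step)


def wavelet_feature(
    sv: SumVectorSeries,
    wavelet: MotherWavelet,
    cfg: FeatureConfig | None = None,
) -> float:
    """Maximum CWT similarity of any triggered candidate window; >= 0.

    Zero when no SV sample exceeds the trigger threshold, when no triggered
    sample admits a full centered window (skip edge policy), or when every
    candidate's best coefficient is negative (anti-correlated).
    """
    if cfg is None:
        cfg = FeatureConfig()
    values = sv.values
    n = len(values)
    length = int(round(cfg.window_duration_s * sv.fs))
    half = length // 2

    candidates = np.flatnonzero(values > cfg.trigger_threshold_g)
    if cfg.scan_stride > 1 and len(candidates):
        # stride applies to the scan itself: only every stride-th sample is
        # inspected, so a triggered sample must sit on the stride lattice
        candidates = candidates[candidates % cfg.scan_stride == 0]
    if len(candidates) == 0:
        return 0.0
    if cfg.edge_policy == "skip":
        candidates = candidates[(candidates >= half)
                                & (candidates + length - half <= n)]
        if len(candidates) == 0:
            return 0.0

    grid = cfg.grid(sv.fs)
    bank = dilated_bank(wavelet, grid, norm=cfg.cwt_norm)
    K = half_support(grid)
    b = grid.translations
    offsets = b[:, None] + np.arange(2 * K + 1)[None, :]

    best = 0.0
    for c in candidates:
        start = c - half
        if start < 0 or start + length > n:
            # reflect policy: materialize the padded window explicitly
            from .signals import extract_window
            win = extract_window(sv, int(c), cfg.window_duration_s,
                                 edge_policy=cfg.edge_policy)
            if win is None:
                continue
            w = win.values
        else:
            w = values[start:start + length]
        # nearest-value edge extension, matching the transform's boundary rule
        S = np.concatenate([np.full(K, w[0]), w,
                            np.full(K + 1, w[-1])])[offsets]
        m = float((bank @ S.T).max())
        if m > best:
            best = m
    return best


def upv_feature(sv: SumVectorSeries) -> float:
    """Upper peak value: global maximum of SV, in g."""
    return float(sv.values.max())


def lpv_feature(sv: SumVectorSeries, cfg: FeatureConfig | None = None) -> float:
    """Lower peak value: SV minimum in the window preceding the global peak.

    The minimum is searched within ``lpv_search_s`` seconds up to and
    including the (first) global maximum; a peak at index 0 degrades to the
    peak sample itself.
    """
    if cfg is None:
        cfg = FeatureConfig()
    peak = int(np.argmax(sv.values))
    start = max(0, peak - int(round(cfg.lpv_search_s * sv.fs)))
    return float(sv.values[start:peak + 1].min())


def build_feature_table(
    recordings: Sequence[Recording],
    wavelet: MotherWavelet,
    cfg: FeatureConfig | None = None,
    sv_cache: Optional[dict] = None,
) -> pd.DataFrame:
    """Score every recording with all three features.

    Returns a DataFrame with columns ``id,label,wavelet,upv_g,lpv_g``, one
    row per readable recording (unscorable recordings are skipped with a
    logged warning).  ``sv_cache`` maps recording id -> SumVectorSeries to
    avoid recomputation across cross-validation folds.
    """
    if cfg is None:
        cfg = FeatureConfig()
    rows = []
    for rec in recordings:
        try:
            if sv_cache is not None and rec.id in sv_cache:
                sv = sv_cache[rec.id]
            else:
                sv = compute_sv(rec)
                if sv_cache is not None:
                    sv_cache[rec.id] = sv
            rows.append(
                {
                    "id": rec.id,
                    "label": rec.label,
                    "wavelet": wavelet_feature(sv, wavelet, cfg),
                    "upv_g": upv_feature(sv),
                    "lpv_g": lpv_feature(sv, cfg),
                }
            )
        except Exception:   # noqa: BLE001 — skip-and-log is the contract
            logger.warning("recording %s could not be scored; skipped", rec.id,
                           exc_info=True)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
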