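"""Model/Results interface tying the pipeline together.

`FallDetectionModel` holds a labeled dataset of recordings and the feature
configuration; `fit()` runs stratified cross-validation with per-fold
prototype-wavelet retraining and returns a `FallDetectionResults` carrying
held-out feature values, vertically averaged ROC curves for the wavelet,
UPV and LPV features, their AUC / maximum-Youden-index estimates with
fold-based confidence intervals, and paired Wilcoxon comparisons.

Example
-------
>>> from fallwave import FallDetectionModel
>>> model = FallDetectionModel.from_simulation(n_falls=29, n_adls=200, seed=7)
>>> res = model.fit(n_folds=10, seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import (
    ROCResult,
    bonferroni,
    cross_validated_scores,
    false_alarm_rate,
    roc_vertical_average,
    stratified_kfold,
    wilcoxon_signed_rank_paired,
)
from .features import FeatureConfig, build_feature_table
from .signals import InvalidInputError, Recording, compute_sv, load_dataset
from .wavelet import MotherWavelet, average_fall_pattern, pattern_to_wavelet

__all__ = ["FallDetectionModel", "FallDetectionResults", "FEATURES"]

#: evaluated features: column name -> (display name, higher values mean fall)
FEATURES = {
    "wavelet": ("Wavelet", True),
    "upv_g": ("UPV", True),
    "lpv_g": ("LPV", False),
}


class FallDetectionModel:
    """Prototype-wavelet fall detector over a labeled set of recordings.

    Parameters
    ----------
    recordings : sequence of Recording
        Labeled one-minute recordings ("fall" / "adl").
    config : FeatureConfig, optional
        Trigger threshold, window duration and CWT grid settings.
    poly_degree : int
        Degree of the constrained polynomial used when converting the
        averaged fall pattern into the mother wavelet.
    wavelet_method : {"polynomial", "direct"}
    """

    def __init__(
        self,
        recordings: Sequence[Recording],
        config: Optional[FeatureConfig] = None,
        poly_degree: int = 40,
        wavelet_method: str = "direct",
    ) -> None:
        self.recordings = list(recordings)
        if not self.recordings:
            raise InvalidInputError("empty dataset")
        self.config = config or FeatureConfig()
        self.poly_degree = poly_degree
        self.wavelet_method = wavelet_method
        self.labels = np.array([r.label for r in self.recordings])

    @classmethod
    def from_manifest(cls, manifest: str | Path, **kwargs) -> "FallDetectionModel":
        """Build from a dataset manifest CSV (``id,path,label``)."""
        return cls(load_dataset(manifest), **kwargs)

    @classmethod
    def from_simulation(cls, seed: Optional[int] = None,
                        config: Optional[FeatureConfig] = None,
                        **sim_kwargs) -> "FallDetectionModel":
        """Build from the synthetic generator (kwargs go to SimConfig)."""
        from .synthetic import SimConfig, simulate_dataset

        sim_cfg = SimConfig(seed=seed, **sim_kwargs)
        _, recs = simulate_dataset(sim_cfg)
        return cls(recs, config=config)

    def build_wavelet(self) -> MotherWavelet:
        """Prototype wavelet from *all* fall recordings (no held-out data;
        use :meth:`fit` for honest performance estimates)."""
        falls = [compute_sv(r) for r in self.recordings if r.label == "fall"]
        pattern = average_fall_pattern(falls, self.config.window_duration_s)
        return pattern_to_wavelet(pattern, poly_degree=self.poly_degree,
                                  method=self.wavelet_method)

    def score(self, wavelet: Optional[MotherWavelet] = None) -> pd.DataFrame:
        """Feature table for every recording with a fixed wavelet."""
        wavelet = wavelet or self.build_wavelet()
        return build_feature_table(self.recordings, wavelet, self.config)

    def fit(self, n_folds: int = 10, seed: Optional[int] = None
            ) -> "FallDetectionResults":
        """Cross-validated evaluation of all three features."""
        split = stratified_kfold(self.labels, n_folds=n_folds, seed=seed)
        scores = cross_validated_scores(
            self.recordings, self.config, split,
            poly_degree=self.poly_degree, wavelet_method=self.wavelet_method,
        )
        rocs = {
            name: roc_vertical_average(scores, name, higher_is_fall=up)
            for name, (_, up) in FEATURES.items()
        }
        return FallDetectionResults(self, scores, rocs, split)


class FallDetectionResults:
    """Cross-validated performance of the wavelet, UPV and LPV features."""

    def __init__(self, model, scores: pd.DataFrame,
                 rocs: dict[str, ROCResult], split) -> None:
        self.model = model
        self.feature_table = scores
        self.roc = rocs
        self.split = split
        self.n_falls = int((model.labels == "fall").sum())
        self.n_adls = int((model.labels == "adl").sum())
        self.pvalues = self._compare_features()

    def _compare_features(self) -> pd.DataFrame:
        """Paired per-fold Wilcoxon tests of the wavelet feature against each
        baseline, on AUC and on max YI, Bonferroni-corrected (m = 2).

        The signed-rank test needs at least 5 folds; with fewer, p-values
        are reported as None and nothing is called significant.
        """
        rows = []
        wav = self.roc["wavelet"]
        for baseline in ("upv_g", "lpv_g"):
            other = self.roc[baseline]
            for metric, a, b in (
                ("auc", wav.fold_auc, other.fold_auc),
                ("max_yi", wav.fold_yi, other.fold_yi),
            ):
                try:
                    p = wilcoxon_signed_rank_paired(a, b)
                except InvalidInputError:
                    p = None
                rows.append({
                    "comparison": f"wavelet vs {FEATURES[baseline][0]}",
                    "metric": metric,
                    "p_value": p,
                })
        df = pd.DataFrame(rows)
        # two comparisons per metric
        df["significant"] = [
            bool(p is not None and bonferroni([p], 2)[0])
            for p in df["p_value"]
        ]
        return df

    # -- derived quantities -------------------------------------------------

    @property
    def auc(self) -> dict[str, float]:
        return {k: r.auc for k, r in self.roc.items()}

    @property
    def max_yi(self) -> dict[str, float]:
        return {k: r.max_yi for k, r in self.roc.items()}

    def false_alarms(self, feature: str = "wavelet",
                     total_hours: float = 168.0) -> tuple[float, float]:
        """False-alarm count and hourly rate at the feature's best operating
        point, given the monitoring time the ADLs were drawn from."""
        _, spec, _ = self.roc[feature].best_point
        return false_alarm_rate(spec, self.n_adls, total_hours)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = []
        w = 78
        lines.append("Fall detection: cross-validated discriminative ability".center(w))
        lines.append("=" * w)
        lines.append(
            f"Recordings: {self.n_falls} falls, {self.n_adls} ADLs    "
            f"folds: {self.split.n_folds}    seed: {self.split.seed}"
        )
        lines.append("-" * w)
        head = (f"{'Feature':<9}{'AUC':>7}{'[95% CI]':>17}"
                f"{'max YI':>8}{'[95% CI]':>17}{'Sens':>7}{'Spec':>7}")
        lines.append(head)
        for name, (disp, _) in FEATURES.items():
            r = self.roc[name]
            lo, hi = r.auc_ci
            ylo, yhi = r.yi_ci
            sens, spec, _thr = r.best_point
            lines.append(
                f"{disp:<9}{r.auc:>7.3f}{f'[{lo:.3f} {hi:.3f}]':>17}"
                f"{r.max_yi:>8.3f}{f'[{ylo:.3f} {yhi:.3f}]':>17}"
                f"{sens:>7.1%}{spec:>7.1%}"
            )
        lines.append("-" * w)
        lines.append("Paired Wilcoxon signed-rank on per-fold values "
                     "(Bonferroni, m = 2):")
        for row in self.pvalues.itertuples(index=False):
            star = " *" if row.significant else ""
            p_txt = "n/a" if row.p_value is None else f"{row.p_value:.4g}"
            lines.append(f"  {row.comparison:<22}{row.metric:<8}"
                         f"p = {p_txt}{star}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Averaged ROC curves of the three features (1 - specificity on x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for name, (disp, _) in FEATURES.items():
            r = self.roc[name]
            ax.plot(1.0 - r.specificity, r.sensitivity,
                    label=f"{disp} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    def report(self) -> dict:
        """JSON-serializable evaluation report."""
        out = {}
        for name, (disp, _) in FEATURES.items():
            r = self.roc[name]
            sens, spec, thr = r.best_point
            out[name] = {
                "auc": r.auc,
                "auc_ci": list(r.auc_ci),
                "max_yi": r.max_yi,
                "yi_ci": list(r.yi_ci),
                "best_point": {"sensitivity": sens, "specificity": spec,
                               "threshold": thr},
                "per_fold": {"auc": r.fold_auc.tolist(),
                             "max_yi": r.fold_yi.tolist()},
            }
        out["comparisons"] = self.pvalues.to_dict(orient="records")
        return out
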