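"""Continuous wavelet transform against the adapted prototype wavelet.

The transform correlates a candidate SV window with dilated, translated
copies of the mother wavelet:

    C(a, b) = (1/a) * sum_t SV(t) * psi((t - b)/a + 1/2)

with t, a, b in samples and unit sample step.  The 1/a weight (the L1
normalization) softly favors compact, sharply peaked matches; the L2
variant 1/sqrt(a) — under which a signal with exactly the prototype's shape
maximizes at the matched scale — is available as
``norm="inverse_sqrt_scale"``.  The translation b marks the
*center* of the dilated wavelet's support [b - a/2, b + a/2]: the prototype
is defined on [0,1] with its impact peak at the midpoint, so a candidate
window centered on a peak matches best when the wavelet is centered there
too.  Because the prototype came from a 2-second pattern, a matched signal
peaks at scale a = 2*Fs; the search box is restricted to scales within half
an Fs of 2*Fs and translations b in [0.5*Fs, 1.5*Fs] (away from the window
edges, to avoid border effects).  Where the dilated wavelet overhangs the
window, the window is extended by replicating its edge samples, so locally
constant signal levels are annihilated by admissibility instead of leaking
border steps into the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signals import InvalidInputError, Window
from .wavelet import MotherWavelet

__all__ = ["CWTGrid", "CWTCoefficients", "cwt_coefficients", "max_coefficient",
           "dilated_bank", "half_support"]


@dataclass
class CWTGrid:
    """Integer (scale, translation) search box, in samples.

    Defaults reproduce the restriction used with a 2-second prototype:
    scales in [1.5*fs, 2.5*fs], translations in [0.5*fs, 1.5*fs], step 1.
    """

    fs: int = 100
    scale_step: int = 1
    translation_step: int = 1
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]
    translations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scales is None:
            lo = int(round(1.5 * self.fs))
            hi = int(round(2.5 * self.fs))
            self.scales = np.arange(lo, hi + 1, self.scale_step)
        if self.translations is None:
            lo = int(round(0.5 * self.fs))
            hi = int(round(1.5 * self.fs))
            self.translations = np.arange(lo, hi + 1, self.translation_step)
        self.scales = np.asarray(self.scales, dtype=int)
        self.translations = np.asarray(self.translations, dtype=int)
        if len(self.scales) == 0 or len(self.translations) == 0:
            raise InvalidInputError("CWT grid must be non-empty")


@dataclass
class CWTCoefficients:
    """Coefficient matrix indexed by (scale, translation)."""

    scales: np.ndarray
    translations: np.ndarray
    matrix: np.ndarray          # shape (n_scales, n_translations)


def half_support(grid: CWTGrid) -> int:
    """Half-width (in samples) of the widest dilated wavelet in the grid."""
    return int(np.ceil(grid.scales.max() / 2.0))


def dilated_bank(
    wavelet: MotherWavelet,
    grid: CWTGrid,
    norm: Literal["inverse_scale", "inverse_sqrt_scale"] = "inverse_scale",
) -> np.ndarray:
    """Precompute the centered dilated wavelet rows for every scale.

    Returns an (n_scales, 2*K+1) array G over lags k in [-K, K] with
    ``K = half_support(grid)`` and ``G[i, K + k]`` the normalized
    ``psi(k/a_i + 1/2)`` (zero where the argument falls outside [0,1]), so
    that ``C(a_i, b) = sum_k SV(b + k) * G[i, K + k]``.
    """
    K = half_support(grid)
    k = np.arange(-K, K + 1, dtype=float)
    G = np.empty((len(grid.scales), 2 * K + 1))
    for i, a in enumerate(grid.scales):
        x = k / a + 0.5
        psi_vals = wavelet(x)
        # discrete admissibility: resampling psi at the dilated lattice
        # leaves a small nonzero sum; recenter over the support so constant
        # signal levels cancel exactly
        support = (x >= 0.0) & (x <= 1.0)
        psi_vals[support] -= psi_vals[support].mean()
        if norm == "inverse_scale":
            G[i] = psi_vals / a
        elif norm == "inverse_sqrt_scale":
            G[i] = psi_vals / np.sqrt(a)
        else:
            raise InvalidInputError(f"unknown norm {norm!r}")
    return G


def _lagged_window_matrix(values: np.ndarray, translations: np.ndarray,
                          K: int) -> np.ndarray:
    """S[j, m] = values[b_j - K + m], with nearest-value edge extension.

    Scales above the window length always overhang the window; replicating
    the edge samples (rather than padding with zeros) means a locally
    constant signal meets the full dilated support and is annihilated by
    admissibility, instead of leaking a border step into the coefficients.
    """
    padded = np.concatenate([np.full(K, values[0]), values,
                             np.full(K + 1, values[-1])])
    idx = translations[:, None] + np.arange(2 * K + 1)[None, :]
    return padded[idx]


def cwt_coefficients(
    window: Window,
    wavelet: MotherWavelet,
    grid: CWTGrid | None = None,
    norm: Literal["inverse_scale", "inverse_sqrt_scale"] = "inverse_scale",
    bank: np.ndarray | None = None,
) -> CWTCoefficients:
    """CWT coefficients of a candidate window over the restricted (a,b) box.

    ``bank`` may carry a precomputed :func:`dilated_bank` for the same
    (wavelet, grid, window length) to amortize repeated evaluation during
    signal scanning.
    """
    if grid is None:
        grid = CWTGrid(fs=window.fs)
    values = np.asarray(window.values, dtype=float)
    if bank is None:
        bank = dilated_bank(wavelet, grid, norm=norm)
    S = _lagged_window_matrix(values, grid.translations, half_support(grid))
    matrix = bank @ S.T                      # (n_scales, n_translations)
    if not np.all(np.isfinite(matrix)):
        raise InvalidInputError("non-finite CWT coefficients")
    return CWTCoefficients(scales=grid.scales, translations=grid.translations,
                           matrix=matrix)


def max_coefficient(coeffs: CWTCoefficients) -> tuple[float, int, int]:
    """Signed maximum coefficient and its (scale, translation) location.

    First occurrence wins on ties (row-major scan: scales, then translations).
    """
    flat = int(np.argmax(coeffs.matrix))
    i, j = np.unravel_index(flat, coeffs.matrix.shape)
    return (float(coeffs.matrix[i, j]), int(coeffs.scales[i]),
            int(coeffs.translations[j]))
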