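"""Build the prototype-fall mother wavelet from peak-centered fall windows.

The prototype ("average fall pattern") is the per-sample mean of the 2-second
SV windows centered on each training fall's impact peak.  That pattern is then
converted into an admissible mother wavelet Psi_fall on the unit interval:
a zero-integral, unit-L2-norm waveform whose inner products with candidate
signal windows quantify fall-likeness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.linalg import lstsq, null_space

from .signals import InvalidInputError, SumVectorSeries, Window, extract_window

__all__ = [
    "FallPattern",
    "MotherWavelet",
    "average_fall_pattern",
    "pattern_to_wavelet",
    "save_wavelet",
    "load_wavelet",
    "DegeneratePatternError",
]

logger = logging.getLogger(__name__)

#: fraction of the grid tapered to zero at each end of the wavelet
TAPER_FRACTION = 0.02
ADMISSIBILITY_TOL = 1e-6


class DegeneratePatternError(InvalidInputError):
    """The pattern is constant and cannot yield an admissible wavelet."""


@dataclass
class FallPattern:
    """Averaged peak-centered SV window: the empirical prototype of a fall."""

    fs: int
    values: np.ndarray          # mean SV, in g, length round(duration_s * fs)
    sd: Optional[np.ndarray] = None     # per-sample standard deviation, in g
    duration_s: float = 2.0
    n_falls: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MotherWavelet:
    """Admissible prototype wavelet sampled on N equispaced points of [0,1].

    Invariants (enforced at construction): the Riemann sum of ``psi`` is zero
    to within 1e-6 and its discrete L2 norm is one, with the grid spacing
    ``dx = 1/(N-1)`` as the integration measure.
    """

    grid: np.ndarray
    psi: np.ndarray
    source_duration_s: float = 2.0
    fs_source: int = 100
    poly_degree: Optional[int] = None
    n_falls: Optional[int] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.grid.shape != self.psi.shape:
            raise InvalidInputError("grid and psi must have the same shape")
        dx = self.dx
        if abs(float(np.sum(self.psi)) * dx) > ADMISSIBILITY_TOL:
            raise InvalidInputError("wavelet is not admissible (nonzero integral)")
        norm2 = float(np.sum(self.psi**2)) * dx
        if abs(norm2 - 1.0) > ADMISSIBILITY_TOL:
            raise InvalidInputError("wavelet does not have unit L2 norm")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate psi by linear interpolation; zero outside [0, 1]."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid, self.psi, left=0.0, right=0.0)


def average_fall_pattern(
    falls: Sequence[SumVectorSeries],
    duration_s: float = 2.0,
) -> FallPattern:
    """Average the peak-centered windows of the training falls.

    Each fall contributes the window of ``duration_s`` seconds centered on the
    first global maximum of its SV (the impact peak).  Falls whose peak sits
    too close to an edge for a full window are excluded with a warning; if all
    are excluded this is an error.
    """
    if len(falls) == 0:
        raise InvalidInputError("need at least one fall to build a pattern")
    fs = falls[0].fs
    windows: list[Window] = []
    for i, sv in enumerate(falls):
        if sv.fs != fs:
            raise InvalidInputError("all falls must share one sampling rate")
        peak = int(np.argmax(sv.values))        # first occurrence on ties
        win = extract_window(sv, peak, duration_s=duration_s, edge_policy="skip")
        if win is None:
            logger.warning(
                "fall %d: peak window overruns the recording; excluded", i
            )
            continue
        windows.append(win)
    if not windows:
        raise InvalidInputError("every fall's peak window overran its recording")
    stack = np.stack([w.values for w in windows])
    return FallPattern(
        fs=fs,
        values=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1) if len(windows) > 1 else None,
        duration_s=duration_s,
        n_falls=len(windows),
    )


def _constrained_poly_fit(y: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial fit of y s.t. the fit sums to zero.

    Uses a Chebyshev basis (well conditioned at the degrees needed to
    resolve a sharp impact spike); the zero-sum admissibility constraint is
    handled by restricting the coefficient search to the null space of the
    column-summed design row.  The basis is nested in the degree, so the
    residual sum of squares is non-increasing in ``degree``.
    """
    n = len(y)
    x = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.chebyshev.chebvander(x, degree)
    a = V.sum(axis=0, keepdims=True)            # 1 x (degree+1)
    Z = null_space(a)                           # (degree+1) x degree
    coef_reduced, *_ = lstsq(V @ Z, y)
    return V @ (Z @ coef_reduced)


def pattern_to_wavelet(
    pattern: FallPattern,
    poly_degree: int = 40,
    method: Literal["polynomial", "direct"] = "direct",
) -> MotherWavelet:
    """Convert the averaged fall pattern into an admissible mother wavelet.

    The pattern is mean-subtracted and rescaled onto [0,1]; a least-squares
    polynomial approximation of configurable degree is taken under the linear
    constraint that the fit integrates to zero (the wavelet admissibility
    condition); the ends are tapered to zero over 2% of the grid on each side
    for continuity, zero integral is restored exactly, and the result is
    scaled to unit L2 norm.  ``method="direct"`` skips the polynomial stage
    and uses the mean-subtracted pattern itself.
    """
    y = np.asarray(pattern.values, dtype=float)
    if np.ptp(y) == 0.0:
        raise DegeneratePatternError(
            "constant pattern: the zero wavelet is not admissible"
        )
    if method == "polynomial" and poly_degree < 2:
        raise InvalidInputError(f"poly_degree must be >= 2, got {poly_degree}")

    n = len(y)
    centered = y - y.mean()
    if method == "polynomial":
        psi = _constrained_poly_fit(centered, poly_degree)
    elif method == "direct":
        psi = centered.copy()
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    # cosine taper to zero at the interval ends, then re-project onto the
    # zero-integral subspace in a way that keeps the endpoints at zero
    m = max(2, int(round(TAPER_FRACTION * n)))
    window = np.ones(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(m) / m))
    window[:m] = ramp
    window[-m:] = ramp[::-1]
    psi = psi * window
    psi = psi - (psi.sum() / window.sum()) * window

    dx = 1.0 / (n - 1)
    norm = np.sqrt(np.sum(psi**2) * dx)
    if norm == 0.0:
        raise DegeneratePatternError("pattern collapsed to zero after projection")
    psi = psi / norm

    return MotherWavelet(
        grid=np.linspace(0.0, 1.0, n),
        psi=psi,
        source_duration_s=pattern.duration_s,
        fs_source=pattern.fs,
        poly_degree=poly_degree if method == "polynomial" else None,
        n_falls=pattern.n_falls,
    )


def save_wavelet(wavelet: MotherWavelet, path: str | Path) -> None:
    """Write psi as CSV ``x,psi`` plus a JSON sidecar with provenance."""
    path = Path(path)
    lines = ["x,psi"] + [
        f"{x:.12g},{p:.12g}" for x, p in zip(wavelet.grid, wavelet.psi)
    ]
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "fs_source": wavelet.fs_source,
        "source_duration_s": wavelet.source_duration_s,
        "poly_degree": wavelet.poly_degree,
        "n_falls": wavelet.n_falls,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def load_wavelet(path: str | Path) -> MotherWavelet:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MotherWavelet(
        grid=data[:, 0],
        psi=data[:, 1],
        source_duration_s=meta.get("source_duration_s", 2.0),
        fs_source=meta.get("fs_source", 100),
        poly_degree=meta.get("poly_degree"),
        n_falls=meta.get("n_falls"),
    )
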