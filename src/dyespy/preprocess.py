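"""Spectral preprocessing chain.

Every spectrum entering a model passes through the same four stages, in
this order:

1. trim to the 450-1650 cm^-1 analysis window (edge-noise removal);
2. baseline subtraction with asymmetric least squares (ASLS),
   lambda = 1e5, p = 0.01;
3. Savitzky-Golay smoothing, window 7, polynomial order 1 (for this pair
   the interior result is the centered 7-point mean);
4. area normalization (negatives clipped to zero, then divide by the sum).

Finally the spectrum is linearly resampled onto the canonical 1 cm^-1
grid so every model sees a fixed 1201-dimensional feature vector, and the
unit-area constraint is re-asserted after interpolation.

The ASLS baseline ``z`` minimizes

    sum_i w_i (y_i - z_i)^2  +  lambda * sum_i (Delta^2 z_i)^2

with asymmetric weights w_i = p where y_i > z_i and w_i = 1 - p otherwise.
Weights start at 1 and the weighted system is re-solved until the weight
vector stops changing (or ``max_iter`` is hit).  The solve uses the
symmetric pentadiagonal structure of ``W + lambda D'D`` via a banded
Cholesky factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .exceptions import CoverageError, DataError, NormalizationError
from .spectra import CANONICAL_GRID, Spectrum, resample_to_grid


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (see module docstring)."""

    trim_low: float = 450.0
    trim_high: float = 1650.0
    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 50
    asls_tol: float = 0.0
    sg_window: int = 7
    sg_polyorder: int = 1
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.asls_p < 1.0:
            raise ValueError("asls_p must be in (0, 1)")
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be positive")
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if self.trim_low >= self.trim_high:
            raise ValueError("trim_low must be below trim_high")
        if self.asls_max_iter < 1:
            raise ValueError("asls_max_iter must be >= 1")


DEFAULT_CONFIG = PreprocessConfig()


def trim(s: Spectrum, low: float | None = None, high: float | None = None) -> Spectrum:
    """Keep only points with ``low <= wavenumber <= high``."""
    low = DEFAULT_CONFIG.trim_low if low is None else low
    high = DEFAULT_CONFIG.trim_high if high is None else high
    mask = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if not mask.any():
        raise CoverageError(
            f"no points of {s.spectrum_id!r} fall inside [{low:g}, {high:g}] cm^-1"
        )
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], s.spectrum_id, s.sample_id)


def _trim_with_guard(s: Spectrum, low: float, high: float) -> Spectrum:
    """Trim, but keep one sample beyond each bound when available.

    The guard points make the later interpolation onto grid points at
    exactly ``low``/``high`` well defined when the acquisition grid does
    not sample those wavenumbers; they are discarded by the resampling.
    """
    mask = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if not mask.any():
        raise CoverageError(
            f"no points of {s.spectrum_id!r} fall inside [{low:g}, {high:g}] cm^-1"
        )
    idx = np.flatnonzero(mask)
    lo = max(idx[0] - 1, 0)
    hi = min(idx[-1] + 1, s.wavenumbers.size - 1)
    return Spectrum(
        s.wavenumbers[lo : hi + 1], s.intensities[lo : hi + 1],
        s.spectrum_id, s.sample_id,
    )


def _second_difference_penalty(n: int, lam: float) -> np.ndarray:
    """Upper-banded form of ``lam * D'D`` for the second-difference matrix D."""
    D = sp.diags_array(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
    )
    A = (lam * (D.T @ D)).todia()
    # solveh_banded expects rows ordered from the outermost upper diagonal
    # down to the main diagonal, right-aligned.
    ab = np.zeros((3, n))
    offsets = {int(o): i for i, o in enumerate(A.offsets)}
    for band, row in ((2, 0), (1, 1), (0, 2)):
        if band in offsets:
            diag = A.data[offsets[band]]
            ab[row, :] = diag  # dia_array stores right-aligned upper diagonals
    return ab


def asls_baseline(
    y: np.ndarray,
    cfg: PreprocessConfig | None = None,
    *,
    lam: float | None = None,
    p: float | None = None,
    max_iter: int | None = None,
) -> np.ndarray:
    """Asymmetric least-squares baseline of an intensity vector."""
    cfg = cfg or DEFAULT_CONFIG
    lam = cfg.asls_lambda if lam is None else lam
    p = cfg.asls_p if p is None else p
    max_iter = cfg.asls_max_iter if max_iter is None else max_iter

    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise DataError("asls_baseline needs a 1-D vector of length >= 5")
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite intensity passed to asls_baseline")

    n = y.size
    penalty = _second_difference_penalty(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def savgol(y: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial).

    Edge points are handled by fitting the polynomial over the nearest full
    window and evaluating it at the edge positions (length-preserving).
    """
    cfg = cfg or DEFAULT_CONFIG
    y = np.asarray(y, dtype=float)
    if y.size < cfg.sg_window:
        raise DataError(
            f"vector of length {y.size} shorter than the "
            f"{cfg.sg_window}-point smoothing window"
        )
    return savgol_filter(y, cfg.sg_window, cfg.sg_polyorder, mode="interp")


def area_normalize(y: np.ndarray, clip_negative: bool = True) -> np.ndarray:
    """Scale intensities to unit sum (negatives clipped to zero first)."""
    y = np.asarray(y, dtype=float)
    if clip_negative:
        y = np.clip(y, 0.0, None)
    total = y.sum()
    if total <= 0:
        raise NormalizationError("cannot area-normalize a non-positive vector")
    return y / total


def preprocess(
    s: Spectrum,
    cfg: PreprocessConfig | None = None,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Full chain: trim -> ASLS subtract -> smooth -> normalize -> resample."""
    cfg = cfg or DEFAULT_CONFIG
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    t = _trim_with_guard(s, cfg.trim_low, cfg.trim_high)
    corrected = t.intensities - asls_baseline(t.intensities, cfg)
    smoothed = savgol(corrected, cfg)
    normalized = area_normalize(smoothed, cfg.clip_negative)
    out = Spectrum(t.wavenumbers, normalized, s.spectrum_id, s.sample_id)
    out = resample_to_grid(out, grid)
    # Interpolation onto a different grid perturbs the discrete sum; the
    # unit-area contract is re-asserted on the final vector.
    return Spectrum(
        out.wavenumbers,
        area_normalize(out.intensities, cfg.clip_negative),
        s.spectrum_id,
        s.sample_id,
    )


def preprocess_table(table, cfg: PreprocessConfig | None = None, grid=None):
    """Preprocess every spectrum of a table onto one shared grid."""
    from .spectra import SpectrumTable

    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    spectra = [preprocess(s, cfg, grid) for s in table]
    return SpectrumTable(spectra, grid=grid)


class SpectrumPreprocessor:
    """sklearn-style transformer wrapping :func:`preprocess_table`.

    ``transform`` accepts a :class:`~dyespy.spectra.SpectrumTable` (or any
    iterable of spectra) and returns the preprocessed table on the canonical
    grid.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, config: PreprocessConfig | None = None, grid=None):
        self.config = config
        self.grid = grid

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "grid": self.grid}

    def set_params(self, **params) -> "SpectrumPreprocessor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "SpectrumPreprocessor":
        self.config_ = self.config or DEFAULT_CONFIG
        return self

    def transform(self, X):
        from .spectra import SpectrumTable

        if not hasattr(self, "config_"):
            self.fit()
        if not isinstance(X, SpectrumTable):
            X = SpectrumTable(list(X))
        return preprocess_table(X, self.config_, self.grid)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
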