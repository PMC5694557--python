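"""Population receptive field (pRF) forward model and per-voxel fitting.

Each voxel's frequency tuning is a Gaussian over log2 frequency with center
``f0`` (Hz), spread ``sigma`` (octaves), and a static compressive power-law
exponent ``n`` in [0, 1] applied to the hemodynamically blurred model drive.
The predicted BOLD time course for a stimulus is::

    p(t) = ( sum_bins  (stim_bin * hdr)(t) * g(bin_freq) ) ** n
    g(f) = exp( -(log2 f - log2 f0)**2 / (2 sigma**2) )

where ``hdr`` is a gamma-density hemodynamic response kernel.  Fitting
maximizes the Pearson correlation between prediction and data, which is
invariant to affine rescaling of the data, so the model carries no gain or
baseline parameters; per-voxel gain/baseline can be recovered afterwards by
least squares (`estimate_gain`) for analyses that need absolute units.

Tuning widths are reported as FWHM bandwidths in octaves
(FWHM = 2 sqrt(2 ln 2) sigma).  Fitted sigma is constrained above 0.015
octaves and ``n`` to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import gamma as gamma_dist
from sklearn.base import BaseEstimator, RegressorMixin

from .stimulus import ParameterError, AlignmentError, StimulusMatrix

__all__ = [
    "HDRParams", "hdr_kernel", "gaussian_weight", "fwhm_octaves",
    "sigma_from_fwhm", "predict_timecourse", "fit_prf", "fit_population",
    "estimate_gain", "select_voxels", "PRFParams", "PRFEncoder",
]

LN2 = np.log(2.0)
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
SIGMA_FLOOR = 0.015          # octaves; resolution of the presented frequencies
DEFAULT_F0_BOUNDS = (44.0, 16000.0)  # one octave beyond the stimulus range
DEFAULT_SIGMA_MAX = 8.0      # octaves


@dataclass(frozen=True)
class HDRParams:
    """Gamma-density hemodynamic response: shape ``k``, scale ``tau`` (s),
    onset ``delay`` (s).  Mode at ``delay + (k - 1) * tau``."""

    shape_k: int = 3
    tau: float = 1.5
    delay: float = 2.0

    def __post_init__(self) -> None:
        if self.shape_k < 1 or self.tau <= 0 or self.delay < 0:
            raise ParameterError("need shape_k >= 1, tau > 0, delay >= 0")


@dataclass(frozen=True)
class PRFParams:
    """One voxel's fitted tuning."""

    f0: float        # Hz
    sigma: float     # octaves
    n_exp: float     # [0, 1]
    fit_r: float = np.nan

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ParameterError("f0 must be positive")
        if self.sigma < SIGMA_FLOOR:
            raise ParameterError(f"sigma must be >= {SIGMA_FLOOR} octaves")
        if not 0.0 <= self.n_exp <= 1.0:
            raise ParameterError("n_exp must lie in [0, 1]")


def hdr_kernel(params: HDRParams, tr: float = 2.0, length: float = 32.0
               ) -> np.ndarray:
    """Gamma-density HDR sampled at t = 0, tr, 2*tr, ... < length (seconds).

    The kernel is a probability density of time, so ``sum(kernel) * tr``
    approaches 1 once ``length`` covers the density mass.
    """
    t = np.arange(0.0, length, tr)
    mass = gamma_dist.cdf(length - params.delay, a=params.shape_k,
                          scale=params.tau)
    if mass < 0.99:
        warnings.warn(f"HDR kernel length {length}s covers only "
                      f"{100 * mass:.1f}% of the density mass", stacklevel=2)
    return gamma_dist.pdf(t - params.delay, a=params.shape_k, scale=params.tau)


def gaussian_weight(f, f0: float, sigma: float):
    """Gaussian tuning weight in log2-frequency space; 1 at ``f == f0``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or f0 <= 0:
        raise ParameterError("frequencies must be positive")
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    z = (np.log2(f) - np.log2(f0)) / sigma
    return np.exp(-0.5 * z * z)


def fwhm_octaves(sigma: float) -> float:
    """Full width at half maximum of the tuning Gaussian, in octaves."""
    if np.any(np.asarray(sigma) <= 0):
        raise ParameterError("sigma must be positive")
    return FWHM_FACTOR * sigma


def sigma_from_fwhm(fwhm: float) -> float:
    """Inverse of `fwhm_octaves`."""
    if np.any(np.asarray(fwhm) <= 0):
        raise ParameterError("fwhm must be positive")
    return fwhm / FWHM_FACTOR


def _as_stim_list(stim) -> list[StimulusMatrix]:
    return list(stim) if isinstance(stim, (list, tuple)) else [stim]


def blurred_design(stim, hdr: HDRParams) -> np.ndarray:
    """HDR-convolved stimulus design: each frequency-bin row convolved
    (causal, same length) with the HDR kernel; multiple scans are
    concatenated along time with convolution confined to each scan."""
    stims = _as_stim_list(stim)
    freqs = stims[0].bin_frequencies
    parts = []
    for s in stims:
        if s.tr != stims[0].tr:
            raise AlignmentError("stimulus matrices have mismatched tr")
        if s.bin_frequencies.shape != freqs.shape or not np.allclose(
                s.bin_frequencies, freqs):
            raise AlignmentError("stimulus matrices have mismatched bins")
        kern = hdr_kernel(hdr, tr=s.tr)
        # direct (not FFT) convolution: FFT round-off (~1e-15) below the
        # exponent n < 1 would blow up into ~1e-5 artifacts on silent TRs
        blurred = np.apply_along_axis(
            lambda row: np.convolve(row, kern)[:s.n_trs], 1, s.values)
        parts.append(blurred)
    return np.concatenate(parts, axis=1)


def predict_timecourse(stim, prf: PRFParams, hdr: HDRParams) -> np.ndarray:
    """Predicted BOLD time course (one value per TR) for one voxel."""
    design = blurred_design(stim, hdr)
    freqs = _as_stim_list(stim)[0].bin_frequencies
    w = gaussian_weight(freqs, prf.f0, prf.sigma)
    drive = w @ design
    return np.maximum(drive, 0.0) ** prf.n_exp if prf.n_exp != 1.0 else drive


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for `fit_prf`.

    Stage 1 is a coarse grid over f0 (<= 1/4-octave steps spanning the
    stimulus frequency range) x sigma (log-spaced) at n = 1; stage 2 refines
    (log2 f0, sigma, n) with a bounded local optimizer from the best cell.
    """

    f0_step_octaves: float = 0.25
    sigma_grid: tuple[float, float, int] = (0.05, 8.0, 12)  # lo, hi, n (log-spaced)
    f0_bounds: tuple[float, float] = DEFAULT_F0_BOUNDS
    sigma_bounds: tuple[float, float] = (SIGMA_FLOOR, DEFAULT_SIGMA_MAX)
    n_bounds: tuple[float, float] = (0.0, 1.0)
    tol: float = 1e-6


def _grid_axes(freqs: np.ndarray, config: FitConfig):
    lo, hi = np.log2(freqs[0]), np.log2(freqs[-1])
    n_f0 = int(np.ceil((hi - lo) / config.f0_step_octaves)) + 1
    f0s = np.logspace(lo, hi, n_f0, base=2.0)
    s_lo, s_hi, s_n = config.sigma_grid
    sigmas = np.geomspace(s_lo, s_hi, s_n)
    return f0s, sigmas


def _stage1_predictions(freqs: np.ndarray, design: np.ndarray,
                        config: FitConfig):
    """Standardized linear (n=1) predictions for every grid cell.

    Returns (cells, P) where ``cells[i] = (f0, sigma)`` and ``P[i]`` is the
    z-scored predicted time course, ordered by (f0, sigma) ascending so that
    ties resolve toward the lowest f0 then lowest sigma.
    """
    f0s, sigmas = _grid_axes(freqs, config)
    cells, rows = [], []
    for f0 in f0s:
        for sig in sigmas:
            w = gaussian_weight(freqs, f0, sig)
            rows.append(w @ design)
            cells.append((float(f0), float(sig)))
    P = np.asarray(rows)
    P = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    norms[norms == 0] = np.inf
    return cells, P / norms


def _refine(voxel_tc: np.ndarray, freqs: np.ndarray, design: np.ndarray,
            start: tuple[float, float, float], config: FitConfig) -> PRFParams:
    y = voxel_tc - voxel_tc.mean()
    y_norm = np.linalg.norm(y)

    def neg_r(theta):
        log2f0, sigma, n = theta
        w = gaussian_weight(freqs, 2.0 ** log2f0, sigma)
        p = np.maximum(w @ design, 0.0) ** n
        p = p - p.mean()
        denom = np.linalg.norm(p) * y_norm
        return -(p @ y) / denom if denom > 0 else 0.0

    x0 = np.array([np.log2(start[0]), start[1], start[2]])
    bounds = [tuple(np.log2(config.f0_bounds)), config.sigma_bounds,
              config.n_bounds]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(neg_r, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": config.tol})
    cand = [(float(-res.fun), res.x), (float(-neg_r(x0)), x0)]
    r_best, x_best = max(cand, key=lambda c: c[0])
    return PRFParams(f0=float(2.0 ** x_best[0]), sigma=float(x_best[1]),
                     n_exp=float(x_best[2]), fit_r=r_best)


def fit_prf(voxel_tc: np.ndarray, stim, hdr: HDRParams,
            fit_config: FitConfig | None = None) -> PRFParams:
    """Fit one voxel's pRF by correlation maximization (grid then refine)."""
    config = fit_config or FitConfig()
    design = blurred_design(stim, hdr)
    freqs = _as_stim_list(stim)[0].bin_frequencies
    cells, P = _stage1_predictions(freqs, design, config)
    return _fit_one(np.asarray(voxel_tc, dtype=float), freqs, design,
                    cells, P, config)


def _fit_one(voxel_tc, freqs, design, cells, P, config) -> PRFParams:
    if voxel_tc.size != design.shape[1]:
        raise AlignmentError("voxel time course length != stimulus TR count")
    if np.std(voxel_tc) == 0:
        return PRFParams(f0=float(freqs[0]), sigma=config.sigma_grid[0],
                         n_exp=1.0, fit_r=0.0)
    y = voxel_tc - voxel_tc.mean()
    y /= np.linalg.norm(y)
    rs = P @ y
    f0_0, sig_0 = cells[int(np.argmax(rs))]
    return _refine(voxel_tc, freqs, design, (f0_0, sig_0, 1.0), config)


def fit_population(bold: np.ndarray, stim, hdr: HDRParams,
                   fit_config: FitConfig | None = None,
                   voxel_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Fit every row of a voxel x TR matrix; returns the pRF table.

    Columns: voxel_id, f0_hz, sigma_oct, fwhm_oct, n_exp, fit_r, amp, base.
    Unfittable voxels (zero variance) keep their row with fit_r = 0.
    """
    config = fit_config or FitConfig()
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    design = blurred_design(stim, hdr)
    freqs = _as_stim_list(stim)[0].bin_frequencies
    cells, P = _stage1_predictions(freqs, design, config)
    rows = []
    for i in range(bold.shape[0]):
        prf = _fit_one(bold[i], freqs, design, cells, P, config)
        pred = np.maximum(
            gaussian_weight(freqs, prf.f0, prf.sigma) @ design, 0.0
        ) ** prf.n_exp
        amp, base = estimate_gain(bold[i], pred)
        rows.append((prf.f0, prf.sigma, fwhm_octaves(prf.sigma), prf.n_exp,
                     prf.fit_r, amp, base))
    ids = list(voxel_ids) if voxel_ids is not None else [
        f"v{i:04d}" for i in range(bold.shape[0])]
    table = pd.DataFrame(rows, columns=["f0_hz", "sigma_oct", "fwhm_oct",
                                        "n_exp", "fit_r", "amp", "base"])
    table.insert(0, "voxel_id", ids)
    return table


def estimate_gain(voxel_tc: np.ndarray, pred: np.ndarray
                  ) -> tuple[float, float]:
    """Least-squares per-voxel gain and baseline: tc ~ amp * pred + base.

    The correlation objective is affine-invariant, so these factors are not
    part of the pRF fit; they put voxels back on a common response scale for
    cross-voxel pattern comparison.
    """
    p = pred - pred.mean()
    var = p @ p
    if var == 0:
        return 0.0, float(np.mean(voxel_tc))
    amp = float(p @ (voxel_tc - voxel_tc.mean()) / var)
    base = float(np.mean(voxel_tc) - amp * np.mean(pred))
    return amp, base


def select_voxels(params_table: pd.DataFrame, threshold: float = 0.15
                  ) -> np.ndarray:
    """Indices of voxels with fit_r strictly above ``threshold``; no other
    selection criterion is applied."""
    if len(params_table) == 0:
        raise ParameterError("empty pRF table")
    return np.flatnonzero(params_table["fit_r"].to_numpy() > threshold)


class PRFEncoder(BaseEstimator, RegressorMixin):
    """Per-voxel auditory pRF model with an sklearn fit/predict surface.

    Parameters
    ----------
    hdr : tuple (shape_k, tau_s, delay_s)
        Gamma-density HDR kernel parameters.
    f0_step_octaves, sigma_grid, f0_bounds, sigma_max, tol
        Search configuration (see `FitConfig`).
    threshold : float
        Goodness-of-fit retention cut; voxels with ``fit_r > threshold``
        populate `retained_`.

    Attributes (after `fit`)
    ----------
    prf_params_ : DataFrame with one row per voxel.
    retained_ : boolean mask of retained voxels.
    """

    def __init__(self, hdr=(3, 1.5, 2.0), f0_step_octaves=0.25,
                 sigma_grid=(0.05, 8.0, 12), f0_bounds=DEFAULT_F0_BOUNDS,
                 sigma_max=DEFAULT_SIGMA_MAX, threshold=0.15, tol=1e-6):
        self.hdr = hdr
        self.f0_step_octaves = f0_step_octaves
        self.sigma_grid = sigma_grid
        self.f0_bounds = f0_bounds
        self.sigma_max = sigma_max
        self.threshold = threshold
        self.tol = tol

    def _hdr(self) -> HDRParams:
        return self.hdr if isinstance(self.hdr, HDRParams) else HDRParams(*self.hdr)

    def _config(self) -> FitConfig:
        return FitConfig(f0_step_octaves=self.f0_step_octaves,
                         sigma_grid=tuple(self.sigma_grid),
                         f0_bounds=tuple(self.f0_bounds),
                         sigma_bounds=(SIGMA_FLOOR, self.sigma_max),
                         tol=self.tol)

    def fit(self, X, y):
        """Fit per-voxel pRFs.

        X : StimulusMatrix or list of StimulusMatrix (scans are concatenated)
        y : array (n_trs_total, n_voxels) of BOLD responses
        """
        y = np.atleast_2d(np.asarray(y, dtype=float))
        self.prf_params_ = fit_population(y.T, X, self._hdr(), self._config())
        self.retained_ = self.prf_params_["fit_r"].to_numpy() > self.threshold
        self.n_voxels_ = len(self.prf_params_)
        return self

    def predict(self, X):
        """Predicted time courses, shape (n_trs, n_voxels), unit gain."""
        design = blurred_design(X, self._hdr())
        freqs = _as_stim_list(X)[0].bin_frequencies
        out = np.empty((design.shape[1], self.n_voxels_))
        for i, row in enumerate(self.prf_params_.itertuples()):
            drive = gaussian_weight(freqs, row.f0_hz, row.sigma_oct) @ design
            out[:, i] = np.maximum(drive, 0.0) ** row.n_exp
        return out

    def score(self, X, y):
        """Mean per-voxel Pearson correlation between prediction and data."""
        pred = self.predict(X)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return float(np.mean([_pearson(pred[:, i], y[:, i])
                              for i in range(pred.shape[1])]))
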