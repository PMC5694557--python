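"""Block-wise tone-sequence reconstruction from voxel activity patterns.

For each 2-s block of a song scan, the decoder takes the measured spatial
pattern of voxel responses at a fixed 6-s hemodynamic lag after block onset
(cyclic within the presentation-averaged time course), and finds the pure
tone frequency whose predicted pattern best correlates with it.  Predicted
patterns are the per-voxel steady-state tuning amplitudes
``g_i(f) ** n_i``; a candidate grid of half-octave steps from 88 Hz seeds a
bounded 1-D refinement over log2 frequency.

The decoder depends only on each voxel's fitted tuning (f0, sigma, n), never
on voxel locations.  Because the pRF fit is affine-invariant per voxel,
measured patterns are by default mapped back to model units using the
per-voxel gain/baseline recovered from the training fit
(``normalization="calibrated"``); ``"none"`` and ``"zscore"`` are available
as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .encoding import gaussian_weight, PRFEncoder, select_voxels
from .stimulus import ParameterError, AlignmentError, StimulusSequence

__all__ = ["make_candidate_grid", "extract_block_pattern", "predict_pattern",
           "decode_block", "reconstruct_sequence", "normalize_timecourses",
           "ReconstructionResult", "SequenceDecoder"]

DEFAULT_BOUNDS = (88.0, 8000.0)


@dataclass
class ReconstructionResult:
    """Per-block decoded frequencies and their pattern correlations."""

    block_frequencies_hz: list  # float or None (undecodable block)
    block_onsets_s: list
    pattern_correlations: list
    lag_s: float = 6.0

    def __len__(self) -> int:
        return len(self.block_frequencies_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block_index": np.arange(len(self)),
            "onset_s": self.block_onsets_s,
            "decoded_hz": [np.nan if f is None else f
                           for f in self.block_frequencies_hz],
            "pattern_r": self.pattern_correlations,
        })


def make_candidate_grid(f_min: float = 88.0, f_max: float = 8000.0,
                        step_octaves: float = 0.5) -> np.ndarray:
    """Geometric candidate grid: f_min * 2**(k*step) for k = 0, 1, ...
    while <= f_max.  Defaults give 14 frequencies from 88 to ~7964.6 Hz."""
    if f_min <= 0 or f_min > f_max or step_octaves <= 0:
        raise ParameterError("need 0 < f_min <= f_max and step > 0")
    n = int(np.floor(np.log2(f_max / f_min) / step_octaves + 1e-12)) + 1
    return f_min * 2.0 ** (step_octaves * np.arange(n))


def extract_block_pattern(avg_tc: np.ndarray, block_onset_s: float,
                          lag_s: float = 6.0, tr: float = 2.0) -> np.ndarray:
    """Voxel pattern at the TR nearest ``onset + lag``, cyclic within the
    averaged presentation (presentations repeat, so the lag wraps)."""
    if abs(lag_s / tr - round(lag_s / tr)) > 1e-9:
        raise AlignmentError("lag must be a whole number of TRs")
    avg_tc = np.atleast_2d(avg_tc)
    idx = int(round((block_onset_s + lag_s) / tr)) % avg_tc.shape[1]
    return avg_tc[:, idx]


def predict_pattern(f: float, prf_table: pd.DataFrame) -> np.ndarray:
    """Predicted steady-state voxel pattern for one tone frequency."""
    if len(prf_table) == 0:
        raise ParameterError("empty pRF table")
    if f <= 0:
        raise ParameterError("frequency must be positive")
    f0 = prf_table["f0_hz"].to_numpy()
    sigma = prf_table["sigma_oct"].to_numpy()
    n = prf_table["n_exp"].to_numpy()
    z = (np.log2(f) - np.log2(f0)) / sigma
    return np.exp(-0.5 * z * z) ** n


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def decode_block(measured: np.ndarray, prf_table: pd.DataFrame,
                 grid: np.ndarray | None = None,
                 bounds: tuple[float, float] = DEFAULT_BOUNDS,
                 tol: float = 1e-8):
    """Decode one block: (frequency_hz, pattern_r), or (None, 0.0) if the
    measured pattern has zero variance.

    Evaluates the pattern correlation at every grid frequency (ties broken
    toward the lower frequency), then refines with a bounded optimization
    over log2 frequency; the refined answer never scores below the best grid
    point.
    """
    measured = np.asarray(measured, dtype=float)
    if len(prf_table) < 3:
        raise ParameterError("need at least 3 retained voxels to decode")
    if np.std(measured) == 0:
        return None, 0.0
    if grid is None:
        grid = make_candidate_grid(*bounds)
    rs = np.array([_pearson(measured, predict_pattern(f, prf_table))
                   for f in grid])
    best = int(np.argmax(rs))  # argmax returns the first (lowest-f) maximum

    def neg_r(log2f):
        return -_pearson(measured, predict_pattern(2.0 ** float(log2f[0]),
                                                   prf_table))

    res = optimize.minimize(neg_r, [np.log2(grid[best])], method="L-BFGS-B",
                            bounds=[tuple(np.log2(bounds))],
                            options={"ftol": tol})
    if -res.fun >= rs[best]:
        return float(2.0 ** res.x[0]), float(-res.fun)
    return float(grid[best]), float(rs[best])


def normalize_timecourses(avg_tc: np.ndarray, prf_table: pd.DataFrame,
                          mode: str = "calibrated") -> np.ndarray:
    """Put the averaged voxel x TR matrix on a common cross-voxel scale.

    ``"calibrated"``: (tc - base_i) / amp_i using the training-fit gain and
    baseline columns; ``"zscore"``: per-voxel temporal z-score; ``"none"``:
    raw values.
    """
    avg_tc = np.atleast_2d(np.asarray(avg_tc, dtype=float))
    if mode == "none":
        return avg_tc
    if mode == "zscore":
        sd = avg_tc.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (avg_tc - avg_tc.mean(axis=1, keepdims=True)) / sd
    if mode == "calibrated":
        if not {"amp", "base"}.issubset(prf_table.columns):
            raise ParameterError(
                "calibrated normalization needs 'amp'/'base' columns in the "
                "pRF table (produced by fit_population)")
        amp = prf_table["amp"].to_numpy(dtype=float).copy()
        base = prf_table["base"].to_numpy(dtype=float)
        amp[amp == 0] = 1.0
        return (avg_tc - base[:, None]) / amp[:, None]
    raise ParameterError(f"unknown normalization mode {mode!r}")


def reconstruct_sequence(avg_tc: np.ndarray, prf_table: pd.DataFrame,
                         seq: StimulusSequence,
                         grid: np.ndarray | None = None,
                         lag_s: float = 6.0, tr: float = 2.0,
                         bounds: tuple[float, float] = DEFAULT_BOUNDS,
                         normalization: str = "calibrated"
                         ) -> ReconstructionResult:
    """Decode every block of one presentation, in order.

    ``avg_tc`` is the presentation-averaged voxel x TR matrix (from
    `average_presentations`); ``seq`` supplies the block onsets.  Per-block
    failures are recorded as missing entries without aborting.
    """
    avg_tc = np.atleast_2d(np.asarray(avg_tc, dtype=float))
    if avg_tc.shape[0] != len(prf_table):
        raise AlignmentError("avg_tc rows must match pRF table rows")
    tc = normalize_timecourses(avg_tc, prf_table, normalization)
    if grid is None:
        grid = make_candidate_grid(*bounds)
    freqs, onsets, corrs = [], [], []
    for block in seq.presentation_blocks():
        pattern = extract_block_pattern(tc, block.onset, lag_s, tr)
        f, r = decode_block(pattern, prf_table, grid, bounds)
        freqs.append(f)
        onsets.append(block.onset)
        corrs.append(r)
    return ReconstructionResult(freqs, onsets, corrs, lag_s=lag_s)


class SequenceDecoder(BaseEstimator):
    """Tone-sequence decoder with an sklearn-style surface.

    ``fit`` consumes a pRF table (or fitted `PRFEncoder`), keeping voxels
    with ``fit_r > threshold``; ``predict`` decodes a presentation-averaged
    time course given the block onsets.
    """

    def __init__(self, lag_s=6.0, tr=2.0, f_min=88.0, f_max=8000.0,
                 step_octaves=0.5, normalization="calibrated", threshold=0.15):
        self.lag_s = lag_s
        self.tr = tr
        self.f_min = f_min
        self.f_max = f_max
        self.step_octaves = step_octaves
        self.normalization = normalization
        self.threshold = threshold

    def fit(self, X, y=None):
        """X: pRF table DataFrame or fitted PRFEncoder."""
        table = X.prf_params_ if isinstance(X, PRFEncoder) else X
        keep = select_voxels(table, self.threshold)
        if keep.size == 0:
            raise ParameterError("no voxels retained; decoding refuses to run")
        self.prf_table_ = table.iloc[keep].reset_index(drop=True)
        self.retained_index_ = keep
        self.grid_ = make_candidate_grid(self.f_min, self.f_max,
                                         self.step_octaves)
        return self

    def predict(self, X, block_onsets_s=None):
        """Decode blocks from an averaged time course.

        X : array (n_trs, n_voxels_retained), presentation-averaged.
        block_onsets_s : onsets of the blocks to decode (default: every TR
            up to the presentation length).
        Returns the decoded frequencies as an array (NaN = undecodable).
        """
        avg = np.atleast_2d(np.asarray(X, dtype=float)).T  # -> voxels x TRs
        if block_onsets_s is None:
            block_onsets_s = np.arange(avg.shape[1]) * self.tr
        tc = normalize_timecourses(avg, self.prf_table_, self.normalization)
        out = []
        for onset in block_onsets_s:
            pattern = extract_block_pattern(tc, float(onset), self.lag_s,
                                            self.tr)
            f, _ = decode_block(pattern, self.prf_table_, self.grid_,
                                (self.f_min, self.f_max))
            out.append(np.nan if f is None else f)
        return np.asarray(out)

    def reconstruct(self, avg_tc: np.ndarray, seq: StimulusSequence
                    ) -> ReconstructionResult:
        """Decode one presentation of ``seq`` from a voxel x TR matrix."""
        return reconstruct_sequence(avg_tc, self.prf_table_, seq,
                                    self.grid_, self.lag_s, self.tr,
                                    (self.f_min, self.f_max),
                                    self.normalization)
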