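"""Evaluation of reconstructed tone sequences.

Three procedures:

* **Identification** — the reconstruction is correlated (Pearson, on log2
  frequency by default) with the actual sequence and with foil sequences
  generated by a first-order Markov chain matched to the song's note
  inventory and note-to-note transition probabilities.  A foil is beaten
  when its correlation is strictly below the actual sequence's; ties count
  against correct identification.

* **Reconstruction accuracy** — signed per-note residuals in cents
  (1200 cents per octave); a two-tailed one-sample t-test of the mean
  residual against zero probes systematic over/underestimation, with
  Bonferroni or Holm adjustment across subjects x songs.

* **Model reliability** — relative RMSE per voxel:
  ``rRMSE = (RMSE(pred, scan1) + RMSE(pred, scan2)) / (2 RMSE(scan1, scan2))``.
  1 means the model predicts a scan no better than the other scan does
  (test-retest parity); with IID zero-mean noise a perfect model gives
  1/sqrt(2) ~ 0.707.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .stimulus import ParameterError

__all__ = ["cents_error", "generate_foils", "identification",
           "residual_bias_test", "adjust_pvalues", "rrmse", "rrmse_report",
           "FoilSet", "EvalReport", "RRMSE_PERFECT", "evaluate_reconstruction"]

RRMSE_PERFECT = 1.0 / np.sqrt(2.0)  # ~0.707, perfect model under IID noise


def cents_error(f_est: float, f_true: float):
    """Signed pitch error in cents; positive = overestimate.  1200/octave."""
    f_est = np.asarray(f_est, dtype=float)
    f_true = np.asarray(f_true, dtype=float)
    if np.any(f_est <= 0) or np.any(f_true <= 0):
        raise ParameterError("frequencies must be positive")
    out = 1200.0 * np.log2(f_est / f_true)
    return float(out) if out.ndim == 0 else out


@dataclass
class FoilSet:
    """Markov-chain foil sequences sharing a song's note statistics."""

    sequences: list[list[float]]
    source_song: list[float]
    seed: int

    def __len__(self) -> int:
        return len(self.sequences)


def generate_foils(song: Sequence[float], n_foils: int = 1000,
                   rng_seed: int = 0) -> FoilSet:
    """Simulate song-like foils from a first-order Markov chain.

    Transition probabilities are the empirical note-to-note frequencies of
    consecutive song pairs (no smoothing: unseen transitions stay at zero);
    the first note is drawn from the song's empirical note distribution.
    Every foil has the song's length and draws from its note set.
    """
    song = [float(f) for f in song]
    if len(song) < 2:
        raise ParameterError("song must have at least 2 notes")
    rng = np.random.default_rng(rng_seed)
    states = sorted(set(song))
    index = {f: i for i, f in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for a, b in zip(song[:-1], song[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    # notes that never lead anywhere (only the final note can be such a
    # state) restart from the marginal note distribution
    marginal = np.bincount([index[f] for f in song],
                           minlength=len(states)).astype(float)
    marginal /= marginal.sum()
    trans = np.where(row_sums > 0, counts / np.where(row_sums, row_sums, 1),
                     marginal)
    sequences = []
    for _ in range(n_foils):
        seq = [states[rng.choice(len(states), p=marginal)]]
        for _ in range(len(song) - 1):
            row = trans[index[seq[-1]]]
            seq.append(states[rng.choice(len(states), p=row)])
        sequences.append(seq)
    return FoilSet(sequences, song, rng_seed)


def _seq_corr(a, b, scale: str) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if scale == "log2":
        a, b = np.log2(a), np.log2(b)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


def identification(reconstructed: Sequence[float], actual: Sequence[float],
                   foils: FoilSet, scale: str = "log2"
                   ) -> tuple[int, float]:
    """(correct_count, actual_r): number of foils whose correlation with the
    reconstruction falls strictly below the actual sequence's.

    A zero-variance reconstruction makes the correlation undefined; this is
    reported as 0 correct with actual_r = nan.
    """
    reconstructed = np.asarray(reconstructed, dtype=float)
    if len(reconstructed) != len(actual):
        raise ParameterError("sequences must have equal length")
    actual_r = _seq_corr(reconstructed, actual, scale)
    if np.isnan(actual_r):
        return 0, float("nan")
    correct = 0
    for foil in foils.sequences:
        r = _seq_corr(reconstructed, foil, scale)
        if np.isnan(r) or r < actual_r:  # ties count against identification
            correct += 1
    return correct, actual_r


def residual_bias_test(residuals_cents: Sequence[float]
                       ) -> tuple[float, float, float, float]:
    """(mean, sd, t, p): two-tailed one-sample t-test of the mean residual
    against zero, df = N - 1.  Zero-variance residuals give t = p = nan."""
    res = np.asarray(residuals_cents, dtype=float)
    if res.size < 2:
        raise ParameterError("need at least 2 residuals")
    mean, sd = float(res.mean()), float(res.std(ddof=1))
    if sd == 0:
        return mean, sd, float("nan"), float("nan")
    t, p = stats.ttest_1samp(res, 0.0)
    return mean, sd, float(t), float(p)


def adjust_pvalues(p_list: Sequence[float], method: str = "bonferroni",
                   m: int | None = None) -> list[float]:
    """Multiple-comparison adjustment over ``m`` tests (default: list length).

    ``bonferroni``: min(1, m*p).  ``holm``: step-down sequentially rejective
    adjustment with monotonicity enforcement.
    """
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ParameterError("m must be >= number of p values")
    if method == "bonferroni":
        return np.minimum(1.0, m * p).tolist()
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ParameterError(f"unknown method {method!r}")


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(d * d)))


def rrmse(tc_pred, tc_scan1, tc_scan2) -> float:
    """Relative RMSE of a prediction against two repeats of the same scan.

    Returns nan (flagged) when the two scans are identical (zero
    test-retest denominator).
    """
    tc_pred, tc_scan1, tc_scan2 = (np.asarray(x, dtype=float)
                                   for x in (tc_pred, tc_scan1, tc_scan2))
    if not tc_pred.shape == tc_scan1.shape == tc_scan2.shape:
        raise ParameterError("time courses must have equal length")
    denom = _rmse(tc_scan1, tc_scan2)
    if denom == 0:
        return float("nan")
    return (_rmse(tc_pred, tc_scan1) + _rmse(tc_pred, tc_scan2)) / (2 * denom)


def rrmse_report(pred_matrix, scan1_matrix, scan2_matrix
                 ) -> tuple[np.ndarray, float, float]:
    """Per-voxel rRMSE over matrix rows: (values, median, fraction > 1).

    Flagged voxels (identical scan rows) propagate as nan and are excluded
    from the summaries.
    """
    pred, s1, s2 = (np.atleast_2d(np.asarray(x, dtype=float))
                    for x in (pred_matrix, scan1_matrix, scan2_matrix))
    if not pred.shape == s1.shape == s2.shape:
        raise ParameterError("matrices must have matching shapes")
    values = np.array([rrmse(pred[i], s1[i], s2[i])
                       for i in range(pred.shape[0])])
    ok = values[~np.isnan(values)]
    if ok.size == 0:
        return values, float("nan"), float("nan")
    return values, float(np.median(ok)), float(np.mean(ok > 1.0))


def plot_rrmse_hist(values, ax=None, bins=30):
    """Histogram of per-voxel rRMSE with the test-retest parity line (1.0)
    and the perfect-model line (1/sqrt 2) marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    ax.hist(vals, bins=bins, color="0.6", edgecolor="0.3")
    ax.axvline(1.0, color="tab:blue", label="test-retest (1.0)")
    ax.axvline(RRMSE_PERFECT, color="tab:red", label="perfect model (0.707)")
    ax.set_xlabel("rRMSE")
    ax.set_ylabel("voxels")
    ax.legend(frameon=False)
    return ax


@dataclass
class EvalReport:
    """Aggregate evaluation statistics for one reconstructed sequence."""

    identification_correct: int
    n_foils: int
    actual_r: float
    residuals_cents: list[float]
    mean_cents: float
    sd_cents: float
    t_stat: float
    p_value: float
    rrmse_per_voxel: list[float] = field(default_factory=list)
    rrmse_median: float = float("nan")
    rrmse_frac_gt_1: float = float("nan")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_reconstruction(reconstructed, actual, foils: FoilSet,
                            pred_matrix=None, scan1_matrix=None,
                            scan2_matrix=None, scale: str = "log2"
                            ) -> EvalReport:
    """Run all three evaluation procedures and bundle the results."""
    rec = np.asarray(reconstructed, dtype=float)
    act = np.asarray(actual, dtype=float)
    ok = ~np.isnan(rec)
    if not ok.any():
        raise ParameterError("no decodable blocks in the reconstruction")
    # undecodable blocks are imputed with the median decoded frequency for
    # the sequence-level correlation; residuals skip them
    filled = np.where(ok, rec, np.nanmedian(rec))
    correct, actual_r = identification(filled, act, foils, scale)
    residuals = cents_error(rec[ok], act[ok])
    mean, sd, t, p = residual_bias_test(residuals)
    report = EvalReport(correct, len(foils), actual_r,
                        np.asarray(residuals).tolist(), mean, sd, t, p)
    if pred_matrix is not None:
        values, med, frac = rrmse_report(pred_matrix, scan1_matrix,
                                         scan2_matrix)
        report.rrmse_per_voxel = values.tolist()
        report.rrmse_median = med
        report.rrmse_frac_gt_1 = frac
    return report
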