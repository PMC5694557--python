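"""Synthetic voxel populations and BOLD datasets.

The study's fMRI scans are not public, so this module generates ground-truth
voxel populations and noisy multi-scan datasets with the statistical
structure the analysis assumes: Gaussian log-frequency tuning with centers
log-uniform over the mapped range, FWHM bandwidths and compressive exponents
drawn from truncated normals matched to reported per-subject statistics, a
per-voxel response gain and constant baseline, and IID Gaussian TR noise
(optionally AR(1) for stress-testing).

``make_study`` mirrors one subject's session structure: 6 randomized-tone
mapping scans (fresh shuffles of the same 240 frequencies) and 2 scans per
song of 8 presentations each.  All randomness flows from one master seed via
named substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .stimulus import (ParameterError, StimulusSequence, build_random_sequence,
                       build_song_sequence, rasterize, MELODIES)
from .encoding import HDRParams, sigma_from_fwhm, blurred_design, gaussian_weight
from .io import BoldDataset, write_bold

__all__ = ["PopulationConfig", "sample_population", "simulate_scan",
           "make_study", "StudyBundle", "noise_sd_for_mean_r"]


@dataclass(frozen=True)
class PopulationConfig:
    """Generative parameters for one synthetic subject.

    Defaults follow the reported per-subject statistics of the modeled
    study: a few hundred auditory voxels, bandwidths ~3.4 +- 2.8 octaves and
    exponents ~0.59 +- 0.31; response gain and baseline are in arbitrary
    scanner units, with noise_sd on the same scale as the unit-gain
    response.
    """

    n_voxels: int = 400
    f0_range: tuple[float, float] = (88.0, 8000.0)  # log-uniform
    bandwidth_mean: float = 3.385   # FWHM octaves
    bandwidth_sd: float = 2.807
    bandwidth_floor: float = 0.05
    n_exp_mean: float = 0.587
    n_exp_sd: float = 0.310
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.25
    amplitude_floor: float = 0.05
    baseline_mean: float = 100.0
    baseline_sd: float = 10.0
    noise_sd: float = 0.5
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ParameterError("n_voxels must be >= 1")
        for name in ("bandwidth_sd", "n_exp_sd", "amplitude_sd",
                     "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        if not lo <= mean <= hi:
            raise ParameterError("degenerate mean outside truncation bounds")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if a >= 8 or b <= -8:
        raise ParameterError("infeasible truncation: mean far outside bounds")
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_population(config: PopulationConfig) -> pd.DataFrame:
    """Seed-deterministic ground-truth table: one row per voxel with
    f0_hz, sigma_oct, n_exp, amplitude, baseline."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(0,)))
    lo, hi = config.f0_range
    if not 0 < lo < hi:
        raise ParameterError("invalid f0_range")
    f0 = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_voxels))
    fwhm = _truncated_normal(rng, config.bandwidth_mean, config.bandwidth_sd,
                             config.bandwidth_floor, np.inf, config.n_voxels)
    n_exp = _truncated_normal(rng, config.n_exp_mean, config.n_exp_sd,
                              0.0, 1.0, config.n_voxels)
    amp = _truncated_normal(rng, config.amplitude_mean, config.amplitude_sd,
                            config.amplitude_floor, np.inf, config.n_voxels)
    base = rng.normal(config.baseline_mean, config.baseline_sd,
                      config.n_voxels)
    return pd.DataFrame({
        "voxel_id": [f"v{i:04d}" for i in range(config.n_voxels)],
        "f0_hz": f0,
        "sigma_oct": sigma_from_fwhm(fwhm),
        "n_exp": n_exp,
        "amplitude": amp,
        "baseline": base,
    })


def _noiseless_responses(stim, truth: pd.DataFrame, hdr: HDRParams
                         ) -> np.ndarray:
    """Unit-gain noiseless voxel x TR responses for one scan."""
    design = blurred_design(stim, hdr)
    freqs = stim.bin_frequencies
    resp = np.empty((len(truth), design.shape[1]))
    for i, row in enumerate(truth.itertuples()):
        drive = gaussian_weight(freqs, row.f0_hz, row.sigma_oct) @ design
        resp[i] = np.maximum(drive, 0.0) ** row.n_exp
    return resp


def simulate_scan(stim, truth: pd.DataFrame, hdr: HDRParams,
                  noise_sd: float = 0.0, rng_seed: int = 0,
                  ar1_rho: float = 0.0, scan_id: str = "") -> BoldDataset:
    """One simulated scan: baseline + amplitude * response + noise per voxel."""
    resp = _noiseless_responses(stim, truth, hdr)
    amp = truth["amplitude"].to_numpy()[:, None]
    base = truth["baseline"].to_numpy()[:, None]
    values = base + amp * resp
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        noise = rng.standard_normal(values.shape)
        if ar1_rho:
            for k in range(1, noise.shape[1]):
                noise[:, k] = (ar1_rho * noise[:, k - 1]
                               + np.sqrt(1 - ar1_rho ** 2) * noise[:, k])
        values = values + noise_sd * noise
    return BoldDataset(values, tr=stim.tr, scan_id=scan_id,
                       voxel_ids=truth["voxel_id"].tolist())


def noise_sd_for_mean_r(stim, truth: pd.DataFrame, hdr: HDRParams,
                        target_r: float = 0.5) -> float:
    """Noise SD giving an expected data-model correlation near ``target_r``.

    For a noiseless unit response with temporal SD s and amplitude a, IID
    noise of SD sigma yields r = 1 / sqrt(1 + sigma^2 / (a s)^2); solving at
    the population mean signal SD gives sigma = mean(a s) sqrt(1/r^2 - 1).
    """
    if not 0 < target_r < 1:
        raise ParameterError("target_r must be in (0, 1)")
    resp = _noiseless_responses(stim, truth, hdr)
    signal_sd = (truth["amplitude"].to_numpy() * resp.std(axis=1)).mean()
    return float(signal_sd * np.sqrt(1.0 / target_r ** 2 - 1.0))


@dataclass
class StudyBundle:
    """In-memory equivalent of one subject's simulated session pair."""

    config: PopulationConfig
    hdr: HDRParams
    truth: pd.DataFrame
    random_seqs: list[StimulusSequence]
    random_scans: list[BoldDataset]
    song_seqs: dict[str, StimulusSequence]
    song_scans: dict[str, list[BoldDataset]]  # two scans per song

    @property
    def n_scans(self) -> int:
        return len(self.random_scans) + sum(len(v) for v in
                                            self.song_scans.values())


def make_study(config: PopulationConfig | None = None,
               hdr: HDRParams | None = None, melodies: dict | None = None,
               n_random_scans: int = 6, n_song_scans: int = 2,
               tr: float = 2.0, out_dir=None) -> StudyBundle:
    """Simulate a full subject: mapping scans, song scans, and ground truth.

    With ``out_dir`` set, every scan matrix, the truth table, and the
    stimulus parameters are also written as delimited text/JSON.
    """
    config = config or PopulationConfig()
    hdr = hdr or HDRParams()
    melodies = melodies if melodies is not None else dict(MELODIES)
    truth = sample_population(config)
    # named substreams off the master seed: population (0,), scan orders (1,),
    # per-scan noise (2,)
    order_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    noise_seeds = np.random.SeedSequence(config.seed, spawn_key=(2,)).spawn(
        n_random_scans + n_song_scans * len(melodies))

    random_seqs, random_scans = [], []
    k = 0
    for s in range(n_random_scans):
        seq = build_random_sequence(rng_seed=int(order_rng.integers(2 ** 31)))
        stim = rasterize(seq, tr)
        random_scans.append(simulate_scan(stim, truth, hdr, config.noise_sd,
                                          rng_seed=noise_seeds[k],
                                          ar1_rho=config.ar1_rho,
                                          scan_id=f"random{s + 1}"))
        random_seqs.append(seq)
        k += 1

    song_seqs, song_scans = {}, {}
    for name, melody in melodies.items():
        seq = build_song_sequence(melody)
        stim = rasterize(seq, tr)
        scans = []
        for s in range(n_song_scans):
            scans.append(simulate_scan(stim, truth, hdr, config.noise_sd,
                                       rng_seed=noise_seeds[k],
                                       ar1_rho=config.ar1_rho,
                                       scan_id=f"{name}{s + 1}"))
            k += 1
        song_seqs[name] = seq
        song_scans[name] = scans

    bundle = StudyBundle(config, hdr, truth, random_seqs, random_scans,
                         song_seqs, song_scans)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: StudyBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    meta = {"config": asdict(bundle.config), "hdr": asdict(bundle.hdr),
            "melodies": {k: list(map(float, v.block_frequencies[
                :len(v.presentation_blocks())]))
                for k, v in bundle.song_seqs.items()}}
    with open(out / "study.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for ds in bundle.random_scans:
        write_bold(out / f"{ds.scan_id}.tsv", ds)
    for scans in bundle.song_scans.values():
        for ds in scans:
            write_bold(out / f"{ds.scan_id}.tsv", ds)
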