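"""Stimulus timelines for tonotopic mapping and song decoding.

Two protocols are supported:

``random_tones``
    240 two-second pure-tone blocks, one per frequency of a geometric grid
    spanning 88-8000 Hz, in a freshly shuffled order per scan, with a 12-s
    silent pause after every 60 blocks.  The silences let the receptive-field
    fit see baseline periods.

``song``
    A melody of 2-s frequency blocks (notes restricted to 880-2349 Hz,
    i.e. A5-D7) followed by 8 s of silence; the presentation is repeated
    8 times per scan.

Timelines use 0-based seconds; TR index ``k`` covers ``[k*tr, (k+1)*tr)``
and block onsets are aligned to TR boundaries.  Within-block burst fine
structure (the "Morse code" pattern of 50/200-ms bursts, or the 13x75-ms
vibrato bursts of song blocks) is recorded for audio rendering but ignored
when rasterizing: at TR resolution each block is one full-TR stimulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ToneBlock",
    "StimulusSequence",
    "StimulusMatrix",
    "build_random_sequence",
    "build_song_sequence",
    "rasterize",
    "average_presentations",
    "note_to_hz",
    "RAINBOW_STANDIN",
    "WISH_STANDIN",
    "MELODIES",
    "load_stimulus_spec",
    "save_stimulus_spec",
    "sequence_from_spec",
]

RANDOM_FREQ_RANGE = (88.0, 8000.0)
SONG_FREQ_RANGE = (880.0, 2349.4)  # A5 .. D7 (equal temperament, A4 = 440)


class ParameterError(ValueError):
    """Invalid stimulus/model parameter."""


class AlignmentError(ValueError):
    """Timeline does not tile onto the TR sampling grid."""


def note_to_hz(name: str) -> float:
    """Equal-tempered frequency (A4 = 440 Hz) of a note name like ``'F#6'``."""
    pitch_class = {"C": -9, "C#": -8, "Db": -8, "D": -7, "D#": -6, "Eb": -6,
                   "E": -5, "F": -4, "F#": -3, "Gb": -3, "G": -2, "G#": -1,
                   "Ab": -1, "A": 0, "A#": 1, "Bb": 1, "B": 2}
    head, octave = name[:-1], int(name[-1])
    if head not in pitch_class:
        raise ParameterError(f"unknown note name {name!r}")
    semis = pitch_class[head] + 12 * (octave - 4)
    return 440.0 * 2.0 ** (semis / 12.0)


# Stand-in melodies.  The study's songs ("Somewhere Over the Rainbow",
# "When You Wish Upon a Star") are published only as notation images, so the
# package ships synthetic stand-ins written from the general contour of those
# tunes (octave-leap opening, stepwise motion, repeated notes), in A5-D7.
# All downstream code is melody-agnostic.
RAINBOW_STANDIN = ("A5 A6 G#6 E6 F#6 G#6 A6 A6 F#6 E6 "
                   "F#6 F#6 F#6 E6 D6 E6 F#6 E6 D6 C#6 B5 B5 A5").split()
WISH_STANDIN = ("A5 B5 C#6 D6 C#6 B5 A5 A5 C#6 E6 E6 D6 C#6 B5 "
                "B5 C#6 D6 F#6 E6 D6 C#6 B5 A5 A5 A5").split()
MELODIES = {
    "rainbow": [note_to_hz(n) for n in RAINBOW_STANDIN],  # 23 notes
    "wish": [note_to_hz(n) for n in WISH_STANDIN],        # 25 notes
}


@dataclass(frozen=True)
class ToneBlock:
    """One pure-tone block: a single frequency played for ``duration`` s."""

    frequency: float
    onset: float
    duration: float = 2.0
    burst_pattern: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ParameterError("block frequency must be positive")
        if self.duration <= 0:
            raise ParameterError("block duration must be positive")
        used = sum(b + isi for b, isi in self.burst_pattern)
        if used > self.duration + 1e-9:
            raise ParameterError("burst pattern exceeds block duration")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusSequence:
    """Ordered timeline of tone blocks and silences for one scan."""

    blocks: list[ToneBlock]
    silences: list[tuple[float, float]]  # (onset_s, duration_s)
    total_duration: float
    protocol: str  # "random_tones" | "song"
    frequency_grid: list[float]
    n_repeats: int = 1  # presentations per scan (song protocol)

    def __post_init__(self) -> None:
        events = [(b.onset, b.duration) for b in self.blocks] + list(self.silences)
        events.sort()
        t = 0.0
        for onset, dur in events:
            if abs(onset - t) > 1e-6:
                raise AlignmentError(
                    f"timeline gap/overlap at t={t:.3f}s (next event at {onset:.3f}s)")
            t = onset + dur
        if abs(t - self.total_duration) > 1e-6:
            raise AlignmentError("events do not tile [0, total_duration]")

    @property
    def block_onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.blocks])

    @property
    def block_frequencies(self) -> np.ndarray:
        return np.array([b.frequency for b in self.blocks])

    @property
    def presentation_duration(self) -> float:
        """Duration of one presentation (= total for non-repeated protocols)."""
        return self.total_duration / self.n_repeats

    def presentation_blocks(self) -> list[ToneBlock]:
        """Blocks of the first presentation."""
        limit = self.presentation_duration
        return [b for b in self.blocks if b.onset < limit - 1e-9]


@dataclass
class StimulusMatrix:
    """Binary frequency-bin x TR indicator matrix for a stimulus sequence."""

    values: np.ndarray  # (n_bins, n_trs), entries in {0, 1}
    tr: float
    bin_frequencies: np.ndarray  # Hz, ascending

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_frequencies = np.asarray(self.bin_frequencies, dtype=float)
        if self.values.shape[0] != self.bin_frequencies.size:
            raise ParameterError("row count must match number of frequency bins")
        if np.any(np.diff(self.bin_frequencies) <= 0):
            raise ParameterError("bin frequencies must be strictly increasing")

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


def _random_burst_pattern(rng: np.random.Generator, n_bursts: int = 8,
                          durations: Sequence[float] = (0.05, 0.2),
                          isi: float = 0.05, limit: float = 2.0
                          ) -> tuple[tuple[float, float], ...]:
    # seed-determined mix of short/long bursts; 8 long bursts + ISIs fill
    # exactly 2 s, so any mix fits
    picks = rng.choice(durations, size=n_bursts)
    pattern = tuple((float(d), isi) for d in picks)
    assert sum(d + i for d, i in pattern) <= limit + 1e-9
    return pattern


def build_random_sequence(n_freqs: int = 240, f_min: float = 88.0,
                          f_max: float = 8000.0, rng_seed: int = 0,
                          block_s: float = 2.0, pause_s: float = 12.0,
                          blocks_per_pause: int = 60) -> StimulusSequence:
    """Build one randomized pure-tone mapping scan.

    Frequencies are geometrically spaced from ``f_min`` to ``f_max``
    inclusive, each presented exactly once per scan in a seed-shuffled
    order, with a ``pause_s`` silence after every ``blocks_per_pause``
    blocks.
    """
    if n_freqs < 2 or f_min <= 0 or f_min >= f_max:
        raise ParameterError("need n_freqs >= 2 and 0 < f_min < f_max")
    rng = np.random.default_rng(rng_seed)
    grid = np.geomspace(f_min, f_max, n_freqs)
    order = rng.permutation(n_freqs)
    blocks: list[ToneBlock] = []
    silences: list[tuple[float, float]] = []
    t = 0.0
    for i, j in enumerate(order):
        blocks.append(ToneBlock(float(grid[j]), t, block_s,
                                _random_burst_pattern(rng, limit=block_s)))
        t += block_s
        if (i + 1) % blocks_per_pause == 0:
            silences.append((t, pause_s))
            t += pause_s
    return StimulusSequence(blocks, silences, t, "random_tones",
                            list(grid), n_repeats=1)


def build_song_sequence(melody: Sequence[float], tempo_block_s: float = 2.0,
                        silence_s: float = 8.0, n_repeats: int = 8
                        ) -> StimulusSequence:
    """Build one song scan: the melody blocks + silence, repeated ``n_repeats``
    times.  Each block carries 13 bursts of 75 ms (75-ms ISI), a vibrato-like
    pattern that is only metadata at TR resolution."""
    melody = [float(f) for f in melody]
    lo, hi = SONG_FREQ_RANGE
    for f in melody:
        if not (lo - 1e-6 <= f <= hi + 1e-6):
            raise ParameterError(f"song note {f:.2f} Hz outside [{lo}, {hi}] Hz")
    bursts = tuple((0.075, 0.075) for _ in range(13))
    blocks: list[ToneBlock] = []
    silences: list[tuple[float, float]] = []
    t = 0.0
    for _ in range(n_repeats):
        for f in melody:
            blocks.append(ToneBlock(f, t, tempo_block_s, bursts))
            t += tempo_block_s
        silences.append((t, silence_s))
        t += silence_s
    grid = sorted(set(melody))
    return StimulusSequence(blocks, silences, t, "song", grid,
                            n_repeats=n_repeats)


def rasterize(seq: StimulusSequence, tr: float = 2.0) -> StimulusMatrix:
    """Rasterize a sequence into a binary frequency-bin x TR matrix.

    The bin for a block's frequency is 1 during that block's TRs; silence
    columns are all zero.  ``tr`` must tile every block and silence.
    """
    n_trs_f = seq.total_duration / tr
    if abs(n_trs_f - round(n_trs_f)) > 1e-9:
        raise AlignmentError("tr does not tile the total duration")
    n_trs = int(round(n_trs_f))
    freqs = np.asarray(sorted(set(seq.frequency_grid)))
    values = np.zeros((freqs.size, n_trs))
    for b in seq.blocks:
        start, span = b.onset / tr, b.duration / tr
        if abs(start - round(start)) > 1e-9 or abs(span - round(span)) > 1e-9:
            raise AlignmentError("block onset/duration not aligned to tr grid")
        row = int(np.searchsorted(freqs, b.frequency))
        if row >= freqs.size or abs(freqs[row] - b.frequency) > 1e-6 * b.frequency:
            raise ParameterError("block frequency missing from frequency grid")
        values[row, int(round(start)):int(round(start + span))] = 1.0
    return StimulusMatrix(values, tr, freqs)


def average_presentations(scan_tcs: Sequence[np.ndarray], presentation_trs: int,
                          n_reps: int) -> np.ndarray:
    """Average voxel x TR matrices over within-scan repetitions and scans.

    Each scan's first ``n_reps * presentation_trs`` columns are folded into
    ``n_reps`` segments and averaged, then results are averaged across scans.
    """
    if presentation_trs < 1 or n_reps < 1:
        raise ParameterError("presentation_trs and n_reps must be >= 1")
    mats = [np.asarray(m, dtype=float) for m in scan_tcs]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise AlignmentError("scan matrices have mismatched shapes")
    (n_vox, n_trs), = shapes
    need = n_reps * presentation_trs
    if n_trs < need:
        raise AlignmentError(
            f"scans have {n_trs} TRs; need >= {need} for {n_reps} presentations")
    out = np.zeros((n_vox, presentation_trs))
    for m in mats:
        out += m[:, :need].reshape(n_vox, n_reps, presentation_trs).mean(axis=1)
    return out / len(mats)


# -- stimulus spec files ------------------------------------------------------

def save_stimulus_spec(path, protocol: str, **params) -> None:
    """Write a stimulus spec (protocol + parameters) as JSON or YAML by suffix."""
    spec = {"protocol": protocol, **params}
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(spec, fh)
        else:
            json.dump(spec, fh, indent=1)


def load_stimulus_spec(path) -> dict:
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            return yaml.safe_load(fh)
        return json.load(fh)


def sequence_from_spec(spec: dict) -> StimulusSequence:
    """Instantiate a StimulusSequence from a loaded stimulus spec dict."""
    spec = dict(spec)
    protocol = spec.pop("protocol")
    if protocol == "random_tones":
        return build_random_sequence(**spec)
    if protocol == "song":
        melody = spec.pop("melody")
        if isinstance(melody, str):
            melody = MELODIES[melody]
        return build_song_sequence(melody, **spec)
    raise ParameterError(f"unknown protocol {protocol!r}")
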