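"""Delimited-text I/O: BOLD matrices, pRF parameter tables, stimulus matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BoldDataset", "read_bold", "write_bold",
           "read_prf_table", "write_prf_table", "write_stimulus_matrix"]

PRF_COLUMNS = ["voxel_id", "f0_hz", "sigma_oct", "fwhm_oct", "n_exp", "fit_r"]


@dataclass
class BoldDataset:
    """Voxel x TR response matrix for one scan, in arbitrary BOLD units."""

    values: np.ndarray  # (n_voxels, n_trs)
    tr: float = 2.0
    scan_id: str = ""
    voxel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.voxel_ids:
            self.voxel_ids = [f"v{i:04d}" for i in range(self.values.shape[0])]
        if len(self.voxel_ids) != self.values.shape[0]:
            raise ValueError("voxel_ids length must match row count")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


def write_bold(path, ds: BoldDataset) -> None:
    """Write a BOLD matrix as TSV: voxel_id column + one column per TR."""
    df = pd.DataFrame(ds.values, columns=[f"tr{k}" for k in range(ds.n_trs)])
    df.insert(0, "voxel_id", ds.voxel_ids)
    df.to_csv(path, sep="\t", index=False)


def read_bold(path, tr: float = 2.0, scan_id: str = "") -> BoldDataset:
    df = pd.read_csv(path, sep="\t")
    voxel_ids = df["voxel_id"].astype(str).tolist()
    values = df.drop(columns=["voxel_id"]).to_numpy(dtype=float)
    return BoldDataset(values, tr=tr, scan_id=scan_id or str(path),
                       voxel_ids=voxel_ids)


def write_prf_table(path, table: pd.DataFrame) -> None:
    cols = [c for c in PRF_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_prf_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stimulus_matrix(path, stim) -> None:
    """Export a binary stimulus matrix with a header row of bin frequencies."""
    df = pd.DataFrame(stim.values.T,
                      columns=[f"{f:.4f}" for f in stim.bin_frequencies])
    df.to_csv(path, sep="\t", index=False)
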