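"""Containers and file formats for sets of absorbance spectra.

A :class:`SpectrumSet` holds a shared wavenumber grid (cm^-1, stored
high-to-low by instrument convention), an ``n_samples x n_points``
absorbance matrix and a per-sample metadata table.  The grid is explicit
metadata everywhere: no stage assumes a particular orientation or spacing.

On disk a set is a pair of CSV files: a wide spectra table whose first
column is ``wavenumber_cm-1`` and whose remaining columns are one sample
each, plus a metadata table with columns ``sample_id, patient_id,
component, group``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

WAVENUMBER_COLUMN = "wavenumber_cm-1"
METADATA_COLUMNS = ("sample_id", "patient_id", "component", "group")


@dataclasses.dataclass
class Spectrum:
    """A single absorbance spectrum on an explicit wavenumber grid."""

    grid: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    patient_id: str = ""
    component: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.grid.shape != self.absorbance.shape or self.grid.ndim != 1:
            raise ValueError(
                "grid and absorbance must be 1-D arrays of equal length; "
                f"got {self.grid.shape} and {self.absorbance.shape}"
            )
        d = np.diff(self.grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.grid.copy(),
            self.absorbance.copy(),
            self.sample_id,
            self.patient_id,
            self.component,
            self.group,
        )


class SpectrumSet:
    """A cohort of spectra sharing one wavenumber grid.

    Parameters
    ----------
    grid:
        Shared wavenumber vector in cm^-1, strictly monotone.
    absorbance:
        ``n_samples x n_points`` matrix, one row per sample.
    metadata:
        DataFrame with at least the columns in :data:`METADATA_COLUMNS`;
        one row per sample, aligned with ``absorbance`` rows.
    """

    def __init__(self, grid: np.ndarray, absorbance: np.ndarray, metadata: pd.DataFrame):
        grid = np.asarray(grid, dtype=float)
        absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
        if absorbance.shape[1] != grid.size:
            raise ValueError(
                f"absorbance has {absorbance.shape[1]} columns but grid has {grid.size} points"
            )
        d = np.diff(grid)
        if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        metadata = metadata.reset_index(drop=True)
        missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(metadata) != absorbance.shape[0]:
            raise ValueError("metadata rows must match absorbance rows")
        if metadata["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        self.grid = grid
        self.absorbance = absorbance
        self.metadata = metadata

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.metadata.iloc[i]
        return Spectrum(
            self.grid,
            self.absorbance[i],
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            component=str(row["component"]),
            group=str(row["group"]),
        )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.metadata["sample_id"]]

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask, dtype=bool)
        return SpectrumSet(self.grid, self.absorbance[mask], self.metadata.loc[mask])

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("empty spectrum list")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
                raise ValueError("all spectra must share one grid")
        absorb = np.vstack([s.absorbance for s in spectra])
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "patient_id": [s.patient_id for s in spectra],
                "component": [s.component for s in spectra],
                "group": [s.group for s in spectra],
            }
        )
        return cls(grid, absorb, meta)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, spectra_path: str | Path, metadata_path: str | Path) -> None:
        """Write the wide spectra CSV and the metadata CSV."""
        wide = pd.DataFrame(self.absorbance.T, columns=self.sample_ids)
        wide.insert(0, WAVENUMBER_COLUMN, self.grid)
        wide.to_csv(spectra_path, index=False)
        self.metadata.to_csv(metadata_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path: str | Path, metadata_path: str | Path) -> "SpectrumSet":
        wide = pd.read_csv(spectra_path)
        if wide.columns[0] != WAVENUMBER_COLUMN:
            raise ValueError(f"first column must be {WAVENUMBER_COLUMN!r}")
        meta = pd.read_csv(metadata_path, dtype=str).fillna("")
        grid = wide[WAVENUMBER_COLUMN].to_numpy(dtype=float)
        sample_ids = [str(s) for s in meta["sample_id"]]
        absorb = wide[sample_ids].to_numpy(dtype=float).T
        return cls(grid, absorb, meta)

    def to_jcamp(self, directory: str | Path) -> list[Path]:
        """Export one JCAMP-DX (XYDATA table) file per spectrum."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in self:
            path = directory / f"{s.sample_id}.jdx"
            lines = [
                f"##TITLE={s.sample_id}",
                "##JCAMP-DX=4.24",
                "##DATA TYPE=INFRARED SPECTRUM",
                "##XUNITS=1/CM",
                "##YUNITS=ABSORBANCE",
                f"##FIRSTX={s.grid[0]:.6g}",
                f"##LASTX={s.grid[-1]:.6g}",
                f"##NPOINTS={s.grid.size}",
                "##XYDATA=(XY..XY)",
            ]
            lines += [f"{x:.6g}, {y:.8g}" for x, y in zip(s.grid, s.absorbance)]
            lines.append("##END=")
            path.write_text("\n".join(lines) + "\n")
            paths.append(path)
        return paths
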