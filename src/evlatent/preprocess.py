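"""Spectral preprocessing: baseline correction, 0-1 normalization, binning.

The pipeline order is fixed: (1) subtract a straight line fitted by
ordinary least squares to the flat 3900-4000 cm^-1 region, (2) min-max
normalize each spectrum to [0, 1] over the full range, (3) bin to a
fixed length by averaging consecutive groups of points.  Because real
instrument exports do not always contain an exact multiple of the bin
width, spectra are first resampled by linear interpolation onto a
uniform grid of ``bin_width * target_length`` points spanning
4000 -> 1000 cm^-1, so the output length is exactly ``target_length``
(375 by default) regardless of the input grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet


@dataclasses.dataclass
class PreprocessConfig:
    baseline_window: tuple[float, float] = (3900.0, 4000.0)  # cm^-1
    bin_width: int = 8  # points per bin
    target_length: int = 375  # bins emitted
    span: tuple[float, float] = (4000.0, 1000.0)  # cm^-1, high -> low

    def __post_init__(self) -> None:
        if self.bin_width < 1 or self.target_length < 1:
            raise ValueError("bin_width and target_length must be >= 1")
        lo, hi = self.baseline_window
        if lo >= hi:
            raise ValueError("baseline_window must be (low, high)")


@dataclasses.dataclass
class ProcessedSpectrum:
    """A binned spectrum plus the provenance of the steps that made it."""

    binned_grid: np.ndarray  # bin-center wavenumbers, high -> low
    values: np.ndarray
    sample_id: str = ""
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.binned_grid.shape != self.values.shape:
            raise ValueError("binned grid and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("processed values must be finite")


def baseline_correct(
    spectrum: Spectrum, window: tuple[float, float] = (3900.0, 4000.0)
) -> Spectrum:
    """Subtract the OLS line fitted to the points inside ``window``.

    The fitted line a + b*wavenumber uses only in-window points, so band
    regions contribute nothing to the fit; in-window residuals average
    to zero by the normal equations.
    """
    lo, hi = window
    mask = (spectrum.grid >= lo) & (spectrum.grid <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"baseline window ({lo}, {hi}) cm^-1 contains {int(mask.sum())} grid "
            "points; need at least 2"
        )
    b, a = np.polyfit(spectrum.grid[mask], spectrum.absorbance[mask], deg=1)
    out = spectrum.copy()
    out.absorbance = spectrum.absorbance - (a + b * spectrum.grid)
    return out


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Map the spectrum linearly onto [0, 1]; errors on constant input."""
    lo = float(spectrum.absorbance.min())
    hi = float(spectrum.absorbance.max())
    # tolerance guards against spectra that are constant up to float
    # residue (e.g. a pure baseline after correction)
    if hi - lo <= 1e-8 * max(1.0, abs(hi), abs(lo)):
        raise ValueError(
            f"degenerate spectrum {spectrum.sample_id!r}: constant absorbance, "
            "min-max normalization undefined"
        )
    out = spectrum.copy()
    out.absorbance = (spectrum.absorbance - lo) / (hi - lo)
    return out


def _resample(spectrum: Spectrum, config: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate onto bin_width*target_length uniform points, high->low."""
    n = config.bin_width * config.target_length
    hi, lo = config.span
    grid = np.linspace(hi, lo, n)
    # np.interp needs ascending x
    order = np.argsort(spectrum.grid)
    values = np.interp(grid[::-1], spectrum.grid[order], spectrum.absorbance[order])[::-1]
    return grid, values


def bin_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None) -> ProcessedSpectrum:
    """Average consecutive non-overlapping groups of ``bin_width`` points.

    Emits exactly ``target_length`` bins with the mean wavenumber of each
    group as the bin center.  Inputs whose point count is not
    bin_width * target_length are first resampled (see module docstring).
    """
    config = config or PreprocessConfig()
    if spectrum.grid.size < config.target_length:
        raise ValueError(
            f"spectrum has {spectrum.grid.size} points; cannot form "
            f"{config.target_length} bins"
        )
    n = config.bin_width * config.target_length
    if spectrum.grid.size == n:
        grid, values = spectrum.grid, spectrum.absorbance
        resampled = False
    else:
        grid, values = _resample(spectrum, config)
        resampled = True
    binned_grid = grid.reshape(config.target_length, config.bin_width).mean(axis=1)
    binned = values.reshape(config.target_length, config.bin_width).mean(axis=1)
    return ProcessedSpectrum(
        binned_grid=binned_grid,
        values=binned,
        sample_id=spectrum.sample_id,
        provenance={
            "bin_width": config.bin_width,
            "target_length": config.target_length,
            "resampled": resampled,
        },
    )


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None) -> ProcessedSpectrum:
    """baseline -> normalize -> bin for a single spectrum."""
    config = config or PreprocessConfig()
    corrected = baseline_correct(spectrum, config.baseline_window)
    normalized = minmax_normalize(corrected)
    processed = bin_spectrum(normalized, config)
    processed.provenance["steps"] = [
        {"step": "baseline_correct", "window": list(config.baseline_window)},
        {"step": "minmax_normalize", "range": [0.0, 1.0]},
        {"step": "bin_spectrum", "bin_width": config.bin_width,
         "target_length": config.target_length},
    ]
    return processed


def preprocess_set(
    raw_set: SpectrumSet, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline over a cohort.

    Returns an ``n_samples x target_length`` DataFrame (index sample_id,
    columns bin-center wavenumbers, high-to-low) plus a provenance dict.
    """
    config = config or PreprocessConfig()
    rows, ids, grid = [], [], None
    for spec in raw_set:
        processed = preprocess_spectrum(spec, config)
        rows.append(processed.values)
        ids.append(spec.sample_id)
        grid = processed.binned_grid
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                          columns=np.round(grid, 4))
    provenance = {
        "n_samples": len(ids),
        "config": dataclasses.asdict(config),
        "steps": ["baseline_correct", "minmax_normalize", "bin_spectrum"],
    }
    return matrix, provenance
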