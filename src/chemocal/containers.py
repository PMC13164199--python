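"""In-memory containers for NIR spectra and GC-IMS peak tables.

Two tabular objects flow through the whole pipeline:

``SpectraSet``
    a wavelength grid, an (n_spectra, n_wavelengths) absorbance matrix and a
    per-spectrum metadata frame (sample id, processed flag, storage months,
    subsample, scan).

``PeakTable``
    a long-format table of GC-IMS peak volumes: one row per
    (compound, sample, replicate), carrying compound metadata (CAS number,
    monomer/dimer form, compound class) plus the internal-standard row used
    for injection normalization.

Both round-trip through plain UTF-8 CSV ("." decimal separator, single
header line) so every intermediate artifact of a run is inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

META_COLUMNS = ["sample", "processed", "months", "subsample", "scan"]
PEAK_COLUMNS = ["compound", "cas", "form", "compound_class", "sample", "replicate", "volume"]

INTERNAL_STANDARD = "2-octanol-D"


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavelength grid with per-spectrum metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelength grid must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} points"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("metadata length does not match the number of spectra")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite entries")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def grid_spacing(self) -> float:
        """Mean grid spacing in nm (grids are generated equally spaced)."""
        return float(np.mean(np.diff(self.wavelengths)))

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same grid and metadata, new data matrix (used by preprocessing)."""
        return SpectraSet(self.wavelengths, absorbance, self.meta.copy())

    def subset(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            self.wavelengths,
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        """Wide CSV: metadata columns followed by one column per wavelength."""
        frame = self.meta.copy()
        wide = pd.DataFrame(
            self.absorbance, columns=[f"{w:.4f}" for w in self.wavelengths]
        )
        pd.concat([frame, wide], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        frame = pd.read_csv(path)
        meta = frame[META_COLUMNS].copy()
        spectral = frame.drop(columns=META_COLUMNS)
        wavelengths = np.array([float(c) for c in spectral.columns])
        return cls(wavelengths, spectral.to_numpy(dtype=float), meta)


@dataclass
class PeakTable:
    """Long-format GC-IMS peak-volume table.

    ``data`` columns: compound, cas, form (M/D), compound_class, sample,
    replicate, volume. One compound may be present as both a monomer (M) and
    a dimer (D) row sharing the same CAS number; the internal standard is a
    single M row per replicate.
    """

    data: pd.DataFrame
    internal_standard: str = INTERNAL_STANDARD

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table is missing columns: {missing}")
        if (self.data["volume"] <= 0).any():
            bad = self.data.loc[self.data["volume"] <= 0].iloc[0]
            raise ValueError(
                f"non-positive peak volume for compound {bad['compound']!r} "
                f"in sample {bad['sample']!r} replicate {bad['replicate']}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def compounds(self) -> pd.DataFrame:
        """Deduplicated compound metadata (name, cas, form, class)."""
        return (
            self.data[["compound", "cas", "form", "compound_class"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    @property
    def samples(self) -> list:
        return list(pd.unique(self.data["sample"]))

    @property
    def analytes(self) -> "PeakTable":
        """Table without the internal-standard rows."""
        return replace(self, data=self.data[self.data["compound"] != self.internal_standard])

    def replicate_matrix(self) -> pd.DataFrame:
        """(sample, replicate) x compound volume matrix."""
        return self.data.pivot_table(
            index=["sample", "replicate"], columns="compound", values="volume"
        )

    def sample_means(self) -> pd.DataFrame:
        """sample x compound matrix of replicate-mean volumes."""
        return self.data.pivot_table(index="sample", columns="compound", values="volume")

    def to_csv(self, path) -> None:
        self.data[PEAK_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, internal_standard: str = INTERNAL_STANDARD) -> "PeakTable":
        return cls(pd.read_csv(path), internal_standard=internal_standard)
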