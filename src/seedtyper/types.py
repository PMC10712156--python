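"""Core containers shared across the biotyping pipeline.

The pipeline moves data through three representations:

``Spectrum``
    a raw (or preprocessed) profile trace over the 2-20 kDa acquisition
    window, with intensities in arbitrary units;
``PeakList``
    discrete picked peaks for one spectral reading of one technical
    replicate, optionally carrying signal-to-noise ratios;
``MainSpectrum``
    a consensus fingerprint ("MSP") of up to 70 reproducible peaks built
    from 20-30 replicate readings of one seed, with per-peak replicate
    frequencies.

All m/z values are treated as neutral masses of singly-protonated ions, the
usual convention for linear-mode protein biotyping; no charge deconvolution
is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: Default acquisition window in Da.
ACQUISITION_RANGE: tuple[float, float] = (2000.0, 20000.0)

#: Canonical-name substitutions applied before any species comparison or
#: vote.  A. rudis and A. tuberculatus are treated as the same species
#: (waterhemp); the second entry normalizes a common orthographic variant.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Amaranthus rudis": "Amaranthus tuberculatus",
    "Amaranthus powelli": "Amaranthus powellii",
}


@dataclass(frozen=True)
class MassTolerance:
    """Mass-dependent matching window: ``max(ppm * 1e-6 * mz, min_da)``.

    The default (500 ppm, floor 1 Da) is intentionally wider than the
    ±300 ppm calibration window because library and query spectra come from
    independent acquisitions.
    """

    ppm: float = 500.0
    min_da: float = 1.0

    def window(self, mz: float) -> float:
        return max(self.ppm * 1e-6 * mz, self.min_da)


DEFAULT_TOLERANCE = MassTolerance()


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one spectral reading.

    ``(accession_id, seed_index, tech_replicate, reading)`` uniquely
    identifies a reading; ``species`` may be ``"unknown"`` for blind samples.
    """

    genus: str = ""
    species: str = "unknown"
    accession_id: str = ""
    seed_index: int = 1
    tech_replicate: int = 1
    reading: int = 1
    role: str = "library"  # library | blind | standard

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.accession_id, self.seed_index, self.tech_replicate, self.reading)

    @property
    def seed_id(self) -> str:
        return f"{self.accession_id}.s{self.seed_index}"

    @property
    def reading_id(self) -> str:
        return f"{self.accession_id}.s{self.seed_index}.t{self.tech_replicate}.r{self.reading}"


@dataclass
class Spectrum:
    """Profile trace: parallel ``mz`` / ``intensity`` arrays."""

    mz: np.ndarray
    intensity: np.ndarray
    meta: Optional[SampleMeta] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"mz and intensity lengths differ ({len(self.mz)} vs {len(self.intensity)})"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    def replace_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.mz.copy(), intensity, self.meta)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: Optional[float] = None


@dataclass
class PeakList:
    """Picked peaks for one spectral reading, sorted by m/z.

    ``flatline`` marks an acquisition that produced no usable protein
    spectrum (fewer picked peaks than the flatline threshold).
    """

    peaks: list[Peak]
    meta: Optional[SampleMeta] = None
    flatline: bool = False

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            self.peaks = sorted(self.peaks, key=lambda p: p.mz)
            mzs = [p.mz for p in self.peaks]
            if any(b <= a for a, b in zip(mzs, mzs[1:])):
                raise ValueError("peak m/z values must be distinct")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class MspPeak:
    mz: float
    mean_intensity: float
    frequency: float


@dataclass(frozen=True)
class Taxonomy:
    genus: str
    species: str
    accession_id: str
    seed_index: int


@dataclass
class MainSpectrum:
    """Consensus fingerprint of one seed: ≤70 peaks with replicate frequencies."""

    peaks: list[MspPeak]
    n_source: int
    taxonomy: Taxonomy
    label: str

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.mean_intensity for p in self.peaks], dtype=float)

    def as_peaklist(self) -> PeakList:
        """View the consensus peaks as a query peak list (for self-validation)."""
        meta = SampleMeta(
            genus=self.taxonomy.genus,
            species=self.taxonomy.species,
            accession_id=self.taxonomy.accession_id,
            seed_index=self.taxonomy.seed_index,
        )
        return PeakList(
            [Peak(p.mz, p.mean_intensity) for p in self.peaks], meta=meta
        )


@dataclass
class Library:
    """Collection of MSPs plus the species synonym map.

    ``extra`` holds unknown top-level fields from a JSON round-trip so that
    forward-compatible metadata is preserved.
    """

    msps: list[MainSpectrum] = field(default_factory=list)
    synonym_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [m.label for m in self.msps]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate MSP labels: {dupes}")
        for target in self.synonym_map.values():
            if target in self.synonym_map and self.synonym_map[target] != target:
                raise ValueError(f"synonym target {target!r} is not canonical")

    def __len__(self) -> int:
        return len(self.msps)

    def __iter__(self) -> Iterable[MainSpectrum]:
        return iter(self.msps)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.msps]

    @property
    def species(self) -> list[str]:
        return sorted({m.taxonomy.species for m in self.msps})

    def taxonomy_tree(self) -> dict:
        """Nested genus → species → accession → [seed_index] mapping."""
        tree: dict = {}
        for m in self.msps:
            t = m.taxonomy
            tree.setdefault(t.genus, {}).setdefault(t.species, {}).setdefault(
                t.accession_id, []
            ).append(t.seed_index)
        return tree
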