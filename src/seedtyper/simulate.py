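"""Synthetic single-seed protein spectra with the full variance structure
the pipeline assumes.

The generator emulates what the instrument study design produces without
modelling the physics: each species owns a template of discrete protein
peaks in the 2-20 kDa window; accessions within a species modulate peak
presence and intensity; technical replicates add m/z jitter, multiplicative
intensity noise, dropout, spurious peaks and occasional flatline failures.
Raw profile traces can be rendered from any peak list (Gaussian peaks on an
exponentially decaying baseline plus white noise) to exercise the
preprocessing chain end-to-end.

All randomness flows from a single master seed through named sub-streams,
so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ACQUISITION_RANGE,
    Peak,
    PeakList,
    SampleMeta,
    Spectrum,
)


@dataclass(frozen=True)
class SpeciesTemplate:
    """Ground-truth peak set of one species."""

    species: str
    mz: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class NoiseModel:
    """Variance structure of replicate acquisitions.

    Intensity noise is log-normal (multiplicative), the standard model for
    MALDI peak intensities.  ``peak_presence_beta`` draws each accession's
    per-peak detection probability; ``dropout_prob`` is the additional
    per-reading loss.  Defaults keep within-species matches inside the
    500 ppm matching window (jitter 200 ppm) while making the documented
    failure phenomena (flatlines, divergent replicates) occur at realistic
    but low rates.
    """

    accession_intensity_sd: float = 0.3
    peak_presence_beta: tuple[float, float] = (8.0, 1.0)
    dropout_prob: float = 0.10
    mz_jitter_ppm: float = 200.0
    intensity_sd_tech: float = 0.4
    n_spurious_peaks: float = 3.0
    flatline_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "flatline_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz_jitter_ppm must be >= 0")


LOW_NOISE = NoiseModel(
    accession_intensity_sd=0.05,
    peak_presence_beta=(50.0, 1.0),
    dropout_prob=0.02,
    mz_jitter_ppm=50.0,
    intensity_sd_tech=0.1,
    n_spurious_peaks=0.5,
    flatline_prob=0.0,
)


@dataclass(frozen=True)
class AccessionEffect:
    """Per-accession modulation of a species template."""

    presence_prob: np.ndarray      # per template peak, in [0, 1]
    intensity_factor: np.ndarray   # per template peak, multiplicative


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tags))


# ---------------------------------------------------------------------------
# species templates
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, mz_range, min_gap_cap: float = 25.0) -> np.ndarray:
    lo, hi = mz_range[0] + 100.0, mz_range[1] - 100.0
    step = min(min_gap_cap, (hi - lo) / (2.0 * max(n, 1)))
    slots = np.arange(lo, hi, step)
    chosen = rng.choice(len(slots), size=n, replace=False)
    return np.sort(slots[chosen] + rng.uniform(0.0, 0.2 * step, size=n))


def make_genus(
    n_species: int,
    peaks_per_species: int = 100,
    sharing: Union[float, dict] = 0.0,
    seed: int = 0,
    mz_range: tuple[float, float] = ACQUISITION_RANGE,
    species_names: Optional[Sequence[str]] = None,
) -> list[SpeciesTemplate]:
    """Generate species templates with a controllable shared-peak structure.

    ``sharing`` as a float places a pool of ``round(f × P)`` peaks common to
    *all* species (so every pairwise shared fraction equals ``f``); as a
    ``{(i, j): f}`` dict it allocates a dedicated pool per species pair,
    which models phylogenetically sister taxa sharing most of their peaks
    while remaining unrelated to everyone else.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if species_names is None:
        species_names = [f"Species {chr(65 + i)}" for i in range(n_species)]
    rng = _substream(seed, 0)
    P = peaks_per_species

    if isinstance(sharing, dict):
        pair_pools = {tuple(sorted(k)): round(v * P) for k, v in sharing.items()}
    else:
        pair_pools = None
        n_common = round(float(sharing) * P)

    if pair_pools is None:
        total = n_common + n_species * (P - n_common)
    else:
        total = sum(pair_pools.values()) + sum(
            P - sum(n for (i, j), n in pair_pools.items() if s in (i, j))
            for s in range(n_species)
        )
    positions = _draw_positions(rng, total, mz_range)
    # base intensity belongs to the peak (protein), so species sharing a
    # peak also share its typical abundance
    base_intensity = rng.lognormal(mean=np.log(50.0), sigma=0.8, size=total)
    order = rng.permutation(total)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = order[cursor : cursor + n]
        cursor += n
        return out

    species_idx: list[list[int]] = [[] for _ in range(n_species)]
    if pair_pools is None:
        common = take(n_common)
        for s in range(n_species):
            species_idx[s].extend(common)
            species_idx[s].extend(take(P - n_common))
    else:
        for (i, j), n in pair_pools.items():
            pool = take(n)
            species_idx[i].extend(pool)
            species_idx[j].extend(pool)
        for s in range(n_species):
            deficit = P - len(species_idx[s])
            if deficit < 0:
                raise ValueError(f"pairwise sharing for species {s} exceeds the peak budget")
            species_idx[s].extend(take(deficit))

    templates = []
    for s, name in zip(range(n_species), species_names):
        idx = np.asarray(species_idx[s], dtype=int)
        mz_order = np.argsort(positions[idx])
        templates.append(
            SpeciesTemplate(
                name, positions[idx][mz_order], base_intensity[idx][mz_order]
            )
        )
    return templates


def shared_fraction(a: SpeciesTemplate, b: SpeciesTemplate, tol_da: float = 0.5) -> float:
    """Realized fraction of a's peaks with a counterpart in b."""
    hits = sum(1 for m in a.mz if np.min(np.abs(b.mz - m)) <= tol_da)
    return hits / len(a.mz)


# ---------------------------------------------------------------------------
# replicate peak lists
# ---------------------------------------------------------------------------

def make_accession_effect(
    template: SpeciesTemplate, noise: NoiseModel, seed: int
) -> AccessionEffect:
    rng = _substream(seed, 1)
    a, b = noise.peak_presence_beta
    return AccessionEffect(
        presence_prob=rng.beta(a, b, size=len(template)),
        intensity_factor=rng.lognormal(0.0, noise.accession_intensity_sd, size=len(template)),
    )


def simulate_peaklist(
    template: SpeciesTemplate,
    accession_effect: Optional[AccessionEffect],
    noise: NoiseModel,
    seed: int,
    meta: Optional[SampleMeta] = None,
    mz_range: tuple[float, float] = ACQUISITION_RANGE,
) -> PeakList:
    """One technical reading: presence thinning, jitter, noise, spurious peaks.

    With probability ``flatline_prob`` the reading is a flatline (empty peak
    list).  Deterministic given the seed.
    """
    rng = _substream(seed, 2)
    if rng.uniform() < noise.flatline_prob:
        return PeakList([], meta=meta, flatline=True)

    presence = np.ones(len(template)) if accession_effect is None else accession_effect.presence_prob
    factor = np.ones(len(template)) if accession_effect is None else accession_effect.intensity_factor
    keep = rng.uniform(size=len(template)) < presence * (1.0 - noise.dropout_prob)

    mz = template.mz[keep]
    mz = mz + rng.normal(0.0, 1.0, size=len(mz)) * (noise.mz_jitter_ppm * 1e-6 * mz)
    inten = (
        template.intensity[keep]
        * factor[keep]
        * rng.lognormal(0.0, noise.intensity_sd_tech, size=int(keep.sum()))
    )

    n_spurious = rng.poisson(noise.n_spurious_peaks)
    if n_spurious:
        smz = rng.uniform(mz_range[0], mz_range[1], size=n_spurious)
        sint = rng.lognormal(np.log(5.0), 0.5, size=n_spurious)
        mz = np.concatenate([mz, smz])
        inten = np.concatenate([inten, sint])

    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    # collapse jitter collisions so the peak list stays strictly increasing
    keep_idx = np.concatenate([[True], np.diff(mz) > 1e-9])
    mz, inten = mz[keep_idx], inten[keep_idx]
    peaks = [Peak(float(m), float(i)) for m, i in zip(mz, inten)]
    return PeakList(peaks, meta=meta, flatline=False)


# ---------------------------------------------------------------------------
# raw profile rendering
# ---------------------------------------------------------------------------

def simulate_spectrum(
    peaklist: PeakList,
    resolution: float = 700.0,
    grid_step: float = 1.0,
    baseline_amplitude: float = 0.0,
    baseline_decay: float = 3000.0,
    noise_sd: float = 0.0,
    mz_range: tuple[float, float] = ACQUISITION_RANGE,
    seed: int = 0,
) -> Spectrum:
    """Render a peak list as a profile trace.

    Each peak becomes a Gaussian with FWHM = m/z / resolution; an
    exponential-decay chemical baseline and white noise are added on top.
    """
    if peaklist.flatline:
        raise ValueError("cannot render a flatline peak list")
    rng = _substream(seed, 3)
    grid = np.arange(mz_range[0], mz_range[1] + grid_step / 2, grid_step)
    y = np.zeros_like(grid)
    for p in peaklist.peaks:
        sigma = (p.mz / resolution) / 2.3548200450309493  # FWHM -> sigma
        lo = np.searchsorted(grid, p.mz - 6 * sigma)
        hi = np.searchsorted(grid, p.mz + 6 * sigma)
        y[lo:hi] += p.intensity * np.exp(-0.5 * ((grid[lo:hi] - p.mz) / sigma) ** 2)
    if baseline_amplitude:
        y = y + baseline_amplitude * np.exp(-(grid - mz_range[0]) / baseline_decay)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=len(grid))
    return Spectrum(grid, np.clip(y, 0.0, None), meta=peaklist.meta)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything a simulated study emits, in pipeline-ready structures."""

    templates: list[SpeciesTemplate]
    #: (species, accession_id, seed_index) -> replicate readings (tech × readings)
    library_peaklists: dict[tuple[str, str, int], list[PeakList]] = field(default_factory=dict)
    #: blind sample id -> technical replicate peak lists
    blind_peaklists: dict[str, list[PeakList]] = field(default_factory=dict)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_study(
    n_species: int = 16,
    accessions_per_species: int = 3,
    seeds_per_accession: int = 3,
    tech_replicates: int = 10,
    readings_per_replicate: int = 3,
    blind_seeds_per_accession: int = 1,
    blind_replicates: int = 3,
    blind_from_new_accessions: bool = False,
    blind_noise: Optional[NoiseModel] = None,
    peaks_per_species: int = 100,
    sharing: Union[float, dict] = 0.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    genus: str = "Genus",
) -> StudyData:
    """Simulate a full biotyping study: library seeds plus blind seeds.

    Defaults mirror the reference study design: a database built from 10
    technical replicates × 3 readings per seed (30 readings), three seeds
    per accession and three accessions per species; blind seeds are queried
    with 3 technical replicates each and their identities are shuffled with
    a seeded permutation.

    ``blind_noise`` lets blind material be noisier than the curated library
    acquisitions (external samples of unknown provenance); it defaults to
    ``noise``.  ``blind_from_new_accessions`` draws each blind seed from an
    accession the library has never seen.
    """
    if blind_noise is None:
        blind_noise = noise
    templates = make_genus(
        n_species, peaks_per_species, sharing=sharing, seed=seed
    )
    study = StudyData(templates=templates)

    def subseed(*tags: int) -> int:
        return int(
            np.random.SeedSequence(entropy=seed, spawn_key=tags).generate_state(1)[0]
            % (2**31)
        )

    blind_entries = []  # (species, accession_id, peaklists)
    for si, template in enumerate(templates):
        for ai in range(accessions_per_species):
            accession_id = f"ACC{si:02d}-{ai:02d}"
            effect = make_accession_effect(template, noise, seed=subseed(4, si, ai))
            for sdi in range(1, seeds_per_accession + 1):
                readings: list[PeakList] = []
                for tr in range(1, tech_replicates + 1):
                    for rd in range(1, readings_per_replicate + 1):
                        meta = SampleMeta(
                            genus=genus,
                            species=template.species,
                            accession_id=accession_id,
                            seed_index=sdi,
                            tech_replicate=tr,
                            reading=rd,
                            role="library",
                        )
                        readings.append(
                            simulate_peaklist(
                                template,
                                effect,
                                noise,
                                seed=subseed(6, si, ai, sdi, tr, rd),
                                meta=meta,
                            )
                        )
                study.library_peaklists[(template.species, accession_id, sdi)] = readings
            for bsi in range(1, blind_seeds_per_accession + 1):
                if blind_from_new_accessions:
                    # blind material from an independent source: its own
                    # accession-level effect, never seen by the library
                    blind_acc = f"BLD{si:02d}-{ai:02d}-{bsi:02d}"
                    blind_effect = make_accession_effect(
                        template, blind_noise, seed=subseed(8, si, ai, bsi)
                    )
                else:
                    blind_acc = accession_id
                    blind_effect = effect
                reps: list[PeakList] = []
                for tr in range(1, blind_replicates + 1):
                    meta = SampleMeta(
                        genus=genus,
                        species="unknown",
                        accession_id=blind_acc,
                        seed_index=100 + bsi,
                        tech_replicate=tr,
                        reading=1,
                        role="blind",
                    )
                    reps.append(
                        simulate_peaklist(
                            template,
                            blind_effect,
                            blind_noise,
                            seed=subseed(7, si, ai, bsi, tr),
                            meta=meta,
                        )
                    )
                blind_entries.append((template.species, blind_acc, reps))

    # shuffled blind numbering, mirroring randomized sample submission
    rng = _substream(seed, 5)
    order = rng.permutation(len(blind_entries))
    truth_rows = []
    for rank, idx in enumerate(order, start=1):
        species, accession_id, reps = blind_entries[idx]
        sample_id = f"blind-{rank:03d}"
        study.blind_peaklists[sample_id] = reps
        truth_rows.append(
            {"sample_id": sample_id, "species": species, "accession_id": accession_id}
        )
    study.truth = pd.DataFrame(truth_rows)
    return study


def write_study(study: StudyData, outdir) -> None:
    """Write a simulated study in the formats the pipeline consumes.

    ``library/`` and ``blind/`` hold per-reading peak-list CSVs, each
    directory with a ``metadata.csv`` mapping readings to files;
    ``truth.csv`` carries the blind identities.
    """
    from pathlib import Path

    from .io import write_metadata_table, write_peaklist

    outdir = Path(outdir)
    for sub in ("library", "blind"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    metas, paths = [], []
    for (species, accession_id, seed_index), readings in study.library_peaklists.items():
        for pl in readings:
            m = pl.meta
            name = f"{accession_id}_s{seed_index}_t{m.tech_replicate}_r{m.reading}.csv"
            write_peaklist(pl, outdir / "library" / name)
            metas.append(m)
            paths.append(f"library/{name}")
    write_metadata_table(metas, outdir / "library" / "metadata.csv", paths=paths)

    metas, paths = [], []
    for sample_id, reps in study.blind_peaklists.items():
        for i, pl in enumerate(reps, start=1):
            name = f"{sample_id}_rep{i}.csv"
            write_peaklist(pl, outdir / "blind" / name)
            metas.append(
                SampleMeta(
                    species="unknown",
                    accession_id=sample_id,
                    seed_index=1,
                    tech_replicate=i,
                    reading=1,
                    role="blind",
                )
            )
            paths.append(f"blind/{name}")
    write_metadata_table(metas, outdir / "blind" / "metadata.csv", paths=paths)
    study.truth.to_csv(outdir / "truth.csv", index=False)
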