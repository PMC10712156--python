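"""Readers and writers for every on-disk representation.

Two-column text is the canonical raw-spectrum format (one ``mz<sep>intensity``
pair per line, comma/tab/whitespace separated); mzML is supported as an
optional read-only dialect through :mod:`pyteomics`.  Libraries round-trip
through a versioned JSON schema or a NIST-MSP-style text export; peak lists
and metadata tables are plain CSV/TSV.
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ACQUISITION_RANGE,
    DEFAULT_SYNONYMS,
    Library,
    MainSpectrum,
    MspPeak,
    Peak,
    PeakList,
    SampleMeta,
    Spectrum,
    Taxonomy,
)

logger = logging.getLogger(__name__)

LIBRARY_SCHEMA_VERSION = "1"

_META_COLUMNS = ("species", "accession_id", "seed_index", "tech_replicate", "reading")


# ---------------------------------------------------------------------------
# raw spectra
# ---------------------------------------------------------------------------

def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 2:
                continue
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header or junk row
            mz.append(m)
            inten.append(i)
    return np.asarray(mz), np.asarray(inten)


def _parse_mzml(path: Path) -> tuple[np.ndarray, np.ndarray]:
    from pyteomics import mzml  # optional dependency

    with mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level", 1) == 1:
                return (
                    np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float),
                )
    raise ValueError(f"{path}: no MS1 spectrum found")


def read_spectrum(
    path,
    dialect: str = "two_column",
    mz_range: tuple[float, float] = ACQUISITION_RANGE,
    meta: Optional[SampleMeta] = None,
) -> Spectrum:
    """Read a raw spectrum, sort it, and clip it to the acquisition range.

    Out-of-range points are dropped with a logged count; unsorted input is
    sorted; exact duplicate m/z values are merged by averaging intensity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "two_column":
        mz, inten = _parse_two_column(path)
    elif dialect == "mzml":
        mz, inten = _parse_mzml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(mz) == 0:
        raise ValueError(f"{path}: no numeric rows")

    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    keep = (mz >= mz_range[0]) & (mz <= mz_range[1])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d point(s) outside %s Da", path, n_dropped, mz_range)
    mz, inten = mz[keep], inten[keep]
    if len(mz) == 0:
        raise ValueError(f"{path}: all data points outside acquisition range {mz_range}")
    # merge exact duplicates (averaging) so mz stays strictly increasing
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if len(uniq) != len(mz):
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed / counts
    return Spectrum(mz, np.clip(inten, 0.0, None), meta=meta)


def write_spectrum(spectrum: Spectrum, path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r}{sep}{float(i)!r}\n")


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

def write_peaklist(peaklist: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# flatline={int(peaklist.flatline)}\n")
        fh.write("mz,intensity,snr\n")
        for p in peaklist.peaks:
            snr = "" if p.snr is None else repr(float(p.snr))
            fh.write(f"{float(p.mz)!r},{float(p.intensity)!r},{snr}\n")


def read_peaklist(path, meta: Optional[SampleMeta] = None) -> PeakList:
    path = Path(path)
    flatline = False
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                m = re.search(r"flatline\s*=\s*(\d)", line)
                if m:
                    flatline = bool(int(m.group(1)))
                continue
            if not line or line.lower().startswith("mz"):
                continue
            parts = line.split(",")
            snr = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
            peaks.append(Peak(float(parts[0]), float(parts[1]), snr))
    return PeakList(peaks, meta=meta, flatline=flatline)


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------

def read_metadata_table(path) -> list[SampleMeta]:
    """Read a CSV/TSV metadata table into :class:`SampleMeta` records.

    Requires columns ``species, accession_id, seed_index, tech_replicate,
    reading``; ``genus`` and ``role`` are optional.  Duplicate identifier
    tuples are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[SampleMeta] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        meta = SampleMeta(
            genus=str(row.get("genus", "")) if "genus" in df.columns else "",
            species=str(row["species"]),
            accession_id=str(row["accession_id"]),
            seed_index=int(row["seed_index"]),
            tech_replicate=int(row["tech_replicate"]),
            reading=int(row["reading"]),
            role=str(row.get("role", "library")) if "role" in df.columns else "library",
        )
        if meta.key in seen:
            raise ValueError(f"{path}: duplicate identifier tuple {meta.key}")
        seen.add(meta.key)
        records.append(meta)
    return records


def write_metadata_table(metas: Sequence[SampleMeta], path, paths=None) -> None:
    rows = []
    for i, m in enumerate(metas):
        row = {
            "genus": m.genus,
            "species": m.species,
            "accession_id": m.accession_id,
            "seed_index": m.seed_index,
            "tech_replicate": m.tech_replicate,
            "reading": m.reading,
            "role": m.role,
        }
        if paths is not None:
            row["path"] = str(paths[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# libraries: JSON and MSP-text
# ---------------------------------------------------------------------------

def _msp_to_dict(m: MainSpectrum) -> dict:
    return {
        "label": m.label,
        "genus": m.taxonomy.genus,
        "species": m.taxonomy.species,
        "accession_id": m.taxonomy.accession_id,
        "seed_index": m.taxonomy.seed_index,
        "n_source": m.n_source,
        "peaks": [[p.mz, p.mean_intensity, p.frequency] for p in m.peaks],
    }


def _msp_from_dict(d: dict) -> MainSpectrum:
    return MainSpectrum(
        peaks=[MspPeak(*row) for row in d["peaks"]],
        n_source=int(d["n_source"]),
        taxonomy=Taxonomy(
            d.get("genus", ""), d["species"], d["accession_id"], int(d["seed_index"])
        ),
        label=d["label"],
    )


def write_library(library: Library, path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        doc = dict(library.extra)
        doc["schema_version"] = LIBRARY_SCHEMA_VERSION
        doc["synonyms"] = library.synonym_map
        doc["msps"] = [_msp_to_dict(m) for m in library.msps]
        path.write_text(json.dumps(doc, indent=1))
    elif format == "msp_text":
        with open(path, "w") as fh:
            for src, dst in library.synonym_map.items():
                fh.write(f"# Synonym: {src} -> {dst}\n")
            for m in library.msps:
                fh.write(f"Name: {m.label}\n")
                fh.write(f"Genus: {m.taxonomy.genus}\n")
                fh.write(f"Species: {m.taxonomy.species}\n")
                fh.write(f"Accession: {m.taxonomy.accession_id}\n")
                fh.write(f"Seed: {m.taxonomy.seed_index}\n")
                fh.write(f"NSource: {m.n_source}\n")
                fh.write(f"Num Peaks: {len(m.peaks)}\n")
                for p in m.peaks:
                    fh.write(
                        f"{float(p.mz)!r} {float(p.mean_intensity)!r} {float(p.frequency)!r}\n"
                    )
                fh.write("\n")
    else:
        raise ValueError(f"unknown library format {format!r}")


def read_library(path, format: str = "json") -> Library:
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        version = doc.pop("schema_version", None)
        if version != LIBRARY_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: library schema version {version!r} is not supported "
                f"(expected {LIBRARY_SCHEMA_VERSION!r})"
            )
        synonyms = doc.pop("synonyms", dict(DEFAULT_SYNONYMS))
        msps = [_msp_from_dict(d) for d in doc.pop("msps")]
        return Library(msps=msps, synonym_map=synonyms, extra=doc)
    if format == "msp_text":
        return _read_msp_text(path)
    raise ValueError(f"unknown library format {format!r}")


def _read_msp_text(path: Path) -> Library:
    msps: list[MainSpectrum] = []
    synonyms: dict[str, str] = {}
    fields: dict = {}
    peaks: list[MspPeak] = []
    n_expected = 0

    def flush():
        nonlocal fields, peaks, n_expected
        if fields:
            if len(peaks) != n_expected:
                raise ValueError(
                    f"{path}: record {fields.get('Name')!r} declares "
                    f"{n_expected} peaks but has {len(peaks)}"
                )
            msps.append(
                MainSpectrum(
                    peaks=list(peaks),
                    n_source=int(fields.get("NSource", 0)),
                    taxonomy=Taxonomy(
                        fields.get("Genus", ""),
                        fields.get("Species", ""),
                        fields.get("Accession", ""),
                        int(fields.get("Seed", 1)),
                    ),
                    label=fields["Name"],
                )
            )
        fields, peaks, n_expected = {}, [], 0

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# Synonym:"):
                src, dst = line[len("# Synonym:"):].split("->")
                synonyms[src.strip()] = dst.strip()
                continue
            if not line.strip():
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, value = line.split(":", 1)
                fields[key.strip()] = value.strip()
                if key.strip() == "Num Peaks":
                    n_expected = int(value)
                continue
            parts = line.split()
            peaks.append(MspPeak(float(parts[0]), float(parts[1]), float(parts[2])))
    flush()
    return Library(msps=msps, synonym_map=synonyms or dict(DEFAULT_SYNONYMS))


def round_trip_equal(a: Library, b: Library, mz_tol: float = 1e-6, rel_tol: float = 1e-9) -> bool:
    """True when two libraries agree to the stated round-trip tolerances."""
    if a.labels != b.labels or a.synonym_map != b.synonym_map:
        return False
    for ma, mb in zip(a.msps, b.msps):
        if ma.taxonomy != mb.taxonomy or ma.n_source != mb.n_source:
            return False
        if len(ma.peaks) != len(mb.peaks):
            return False
        for pa, pb in zip(ma.peaks, mb.peaks):
            if abs(pa.mz - pb.mz) > mz_tol:
                return False
            if not math.isclose(pa.mean_intensity, pb.mean_intensity, rel_tol=rel_tol, abs_tol=1e-12):
                return False
            if not math.isclose(pa.frequency, pb.frequency, rel_tol=rel_tol, abs_tol=1e-12):
                return False
    return True
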