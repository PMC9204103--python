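"""Readers and writers: FASTA, peak lists (MGF / two-column text), fixture
tables and TSV/JSON reports.

FASTA goes through Biopython, MGF through pyteomics; the two-column text
dialect (whitespace-separated m/z and intensity, ``#`` comments) matches
common MALDI peak-list exports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .digest import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_MZ_RANGE = (500.0, 3500.0)


@dataclass(frozen=True)
class PeakList:
    """Sorted (m/z, intensity) pairs with acquisition metadata.

    ``level`` is ``"MS1"`` for survey scans or ``"MS2"`` for fragment
    spectra (which then carry ``precursor_mz``).  When ``mz_range`` is
    declared, all peaks must fall inside it — mirroring a MALDI-TOF
    acquisition window such as m/z 500–3,500.
    """

    peaks: tuple[tuple[float, float], ...]
    label: str = ""
    level: str = "MS1"
    mz_range: tuple[float, float] | None = None
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.level not in ("MS1", "MS2"):
            raise ValueError(f"level must be MS1 or MS2, got {self.level!r}")
        peaks = [(float(mz), float(inten)) for mz, inten in self.peaks]
        for mz, inten in peaks:
            if inten < 0:
                raise ValueError(f"negative intensity {inten} at m/z {mz}")
            if not (mz == mz and abs(inten) < float("inf")):
                raise ValueError("non-finite peak values")
        if any(peaks[i][0] > peaks[i + 1][0] for i in range(len(peaks) - 1)):
            warnings.warn("peak list was not sorted by m/z; sorting", stacklevel=2)
            peaks.sort()
        if self.mz_range is not None:
            lo, hi = self.mz_range
            for mz, _ in peaks:
                if not lo <= mz <= hi:
                    raise ValueError(
                        f"peak m/z {mz} outside declared range [{lo}, {hi}]"
                    )
        object.__setattr__(self, "peaks", tuple(peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)

    @property
    def intensity(self) -> tuple[float, ...]:
        return tuple(inten for _, inten in self.peaks)


# ---------------------------------------------------------------------------
# peak lists


def read_peaklist(path: str | Path, format: str = "tsv") -> list[PeakList]:
    """Read one (tsv) or many (mgf) peak lists from ``path``."""
    path = Path(path)
    if format == "tsv":
        return [_read_tsv_peaklist(path)]
    if format == "mgf":
        return _read_mgf(path)
    raise ValueError(f"unknown peak-list format {format!r}")


def _read_tsv_peaklist(path: Path) -> PeakList:
    peaks = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (m/z intensity), "
                    f"got {len(fields)}"
                )
            try:
                mz, inten = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append((mz, inten))
    if not peaks:
        logger.warning("peak list %s is empty", path)
    return PeakList(peaks=tuple(peaks), label=path.stem)


def _read_mgf(path: Path) -> list[PeakList]:
    out = []
    with _mgf.read(str(path)) as reader:
        for spectrum in reader:
            params = spectrum.get("params", {})
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            peaks = tuple(
                zip(
                    (float(x) for x in spectrum["m/z array"]),
                    (float(x) for x in spectrum["intensity array"]),
                )
            )
            out.append(
                PeakList(
                    peaks=peaks,
                    label=str(params.get("title", path.stem)),
                    level="MS2" if precursor is not None else "MS1",
                    precursor_mz=precursor,
                )
            )
    if not out:
        logger.warning("MGF file %s contains no spectra", path)
    return out


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list as two-column text."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"# {peaklist.label} level={peaklist.level}\n")
        for mz, inten in peaklist.peaks:
            handle.write(f"{mz:.6f} {inten:.6f}\n")


def write_mgf(peaklists: Sequence[PeakList], path: str | Path) -> None:
    """Write MS2 peak lists as an MGF file (PEPMASS from precursor m/z)."""
    spectra = []
    for pl in peaklists:
        params = {"title": pl.label}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        spectra.append(
            {
                "params": params,
                "m/z array": list(pl.mz),
                "intensity array": list(pl.intensity),
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; an ``offset=N`` token in the header sets the
    numbering of the first residue."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        offset = 1
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        try:
            records.append(
                ProteinRecord(
                    id=rec.id, sequence=str(rec.seq).upper(),
                    numbering_offset=offset,
                )
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence), id=p.id,
            description=f"offset={p.numbering_offset}",
        )
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# fixture tables (printed peptide lists, domain tables)


@dataclass(frozen=True)
class PrintedPeptide:
    """A peptide as printed in a published table: lowercase letters mark
    modified residues (k = biotinylated lysine, c = carbamidomethyl
    cysteine); the printed residue range is kept as an opaque label."""

    isoform: str
    sequence: str
    range_label: str = ""


def read_printed_peptides(path: str | Path) -> list[PrintedPeptide]:
    """Read a fixture TSV with columns isoform, sequence, range_label."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"isoform", "sequence"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        PrintedPeptide(
            isoform=row["isoform"],
            sequence=row["sequence"],
            range_label=row.get("range_label", ""),
        )
        for _, row in frame.iterrows()
    ]


def read_domain_table(path: str | Path):
    """Read a domain-annotation TSV (name, start, end) into a DomainTable."""
    from .footprint_compare import DomainTable

    frame = pd.read_csv(path, sep="\t")
    entries = [
        (str(row["name"]), int(row["start"]), int(row["end"]))
        for _, row in frame.iterrows()
    ]
    return DomainTable(entries=tuple(entries))


# ---------------------------------------------------------------------------
# reports


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialize a report object (anything with ``to_records``/``to_dict``)."""
    path = Path(path)
    if format == "tsv":
        records = report.to_records()
        frame = pd.DataFrame.from_records(records)
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as handle:
            json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)
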