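"""Readers and writers for identification tables, the canonical dataset CSV
and percolator PIN files.

Search-engine outputs (MaxQuant evidence-style TSV, PEAKS-style CSV) are
mapped onto :class:`IonRecord`, with raw sequences converted to the canonical
token string by :mod:`ccspred.chem`. Rows whose sequence or charge cannot be
parsed are skipped and counted, never silently dropped.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

from . import chem

CANONICAL_COLUMNS = (
    "sequence",
    "charge",
    "mz",
    "inv_k0",
    "ccs",
    "intensity",
    "occurrence",
    "source_id",
)


class FormatError(ValueError):
    """Malformed input table (missing column, ragged row ...)."""


@dataclass(frozen=True)
class IonRecord:
    """One identified peptide ion observation."""

    sequence: str  # canonical token string
    charge: int
    mz: float
    inv_k0: float | None = None
    ccs: float | None = None
    intensity: float | None = None
    occurrence: int = 1
    source_id: str = ""
    raw_sequence: str = ""

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.ccs is not None and self.ccs <= 0:
            raise ValueError(f"ccs must be positive, got {self.ccs}")
        if self.inv_k0 is None and self.ccs is None:
            raise ValueError("at least one of inv_k0/ccs must be present")
        if self.occurrence < 1:
            raise ValueError(f"occurrence must be >= 1, got {self.occurrence}")


@dataclass
class Dataset:
    """Ordered collection of ion records sharing acquisition metadata."""

    records: list = field(default_factory=list)
    source_id: str = ""
    drift_gas: str = "N2"
    temperature: float = 305.0
    alignment_shift: float = 0.0
    skipped: int = 0  # unparseable input rows

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class PinTable:
    """Percolator input table: header + PSM feature rows.

    An optional second "DefaultDirection" line is preserved verbatim.
    """

    header: list[str]
    rows: list[list[str]]
    direction_row: list[str] | None = None

    def __post_init__(self):
        ncol = len(self.header)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise FormatError(f"row {i + 1} has {len(row)} fields, expected {ncol}")
        if self.rows and "Label" in self.header:
            li = self.header.index("Label")
            labels = {r[li] for r in self.rows}
            if not labels <= {"1", "-1", "+1"}:
                raise FormatError(
                    f"Label column contains values outside ±1: {sorted(labels)}"
                )


# ---------------------------------------------------------------------------
# search-result readers

_MANDATORY = {
    "maxquant": ["Modified sequence", "Charge", "m/z"],
    "peaks": ["Peptide", "Z", "m/z"],
    "canonical": ["sequence", "charge", "mz"],
}

# default column maps per dialect; the PEAKS export layout varies, so the
# mobility/CCS column names are configurable through column_map
_DEFAULT_MAP = {
    "maxquant": {
        "sequence": "Modified sequence",
        "charge": "Charge",
        "mz": "m/z",
        "ccs": "CCS",
        "inv_k0": "1/K0",
        "intensity": "Intensity",
    },
    "peaks": {
        "sequence": "Peptide",
        "charge": "Z",
        "mz": "m/z",
        "ccs": "CCS",
        "inv_k0": "1/K0",
        "intensity": "Intensity",
    },
    "canonical": {c: c for c in CANONICAL_COLUMNS},
}


def _parse_float(text: str | None) -> float | None:
    if text is None or text.strip() == "":
        return None
    value = float(text)
    return value if math.isfinite(value) else None


def read_search_results(path, dialect: str, column_map: dict | None = None) -> Dataset:
    """Read an identification table into a :class:`Dataset` of IonRecords.

    Rows with unparseable sequence or charge, or without any mobility/CCS
    information, are skipped and counted in ``Dataset.skipped``.
    """
    if dialect not in _MANDATORY:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = dict(_DEFAULT_MAP[dialect])
    if column_map:
        colmap.update(column_map)
    delim = "\t" if dialect == "maxquant" else ","

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file", stacklevel=2)
            return Dataset(source_id=str(path))
        for col in _MANDATORY[dialect]:
            mapped = colmap[{"Modified sequence": "sequence", "Peptide": "sequence",
                             "Charge": "charge", "Z": "charge", "m/z": "mz",
                             "sequence": "sequence", "charge": "charge",
                             "mz": "mz"}[col]]
            if mapped not in reader.fieldnames:
                raise FormatError(f"missing mandatory column: {mapped}")
        has_ccs = colmap["ccs"] in reader.fieldnames
        has_k0 = colmap["inv_k0"] in reader.fieldnames
        if not (has_ccs or has_k0):
            raise FormatError(
                f"missing mobility information: need column {colmap['ccs']} or {colmap['inv_k0']}"
            )

        ds = Dataset(source_id=str(path))
        for row in reader:
            try:
                raw = row[colmap["sequence"]]
                sequence = chem.tokenize(raw, dialect)
                charge = int(row[colmap["charge"]])
                mz = _parse_float(row.get(colmap["mz"]))
                ccs = _parse_float(row.get(colmap["ccs"])) if has_ccs else None
                inv_k0 = _parse_float(row.get(colmap["inv_k0"])) if has_k0 else None
                if mz is None:
                    mz = chem.mz(chem.monoisotopic_mass(sequence), charge)
                intensity = _parse_float(row.get(colmap.get("intensity", ""), ""))
                occ_text = row.get(colmap.get("occurrence", "occurrence"), "")
                occurrence = int(occ_text) if occ_text and occ_text.strip() else 1
                src = row.get(colmap.get("source_id", "source_id"), "") or ds.source_id
                ds.records.append(
                    IonRecord(
                        sequence=sequence,
                        charge=charge,
                        mz=mz,
                        inv_k0=inv_k0,
                        ccs=ccs,
                        intensity=intensity,
                        occurrence=occurrence,
                        source_id=src,
                        raw_sequence=raw,
                    )
                )
            except (chem.TokenizationError, ValueError, KeyError):
                ds.skipped += 1
        return ds


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_dataset(ds: Dataset, path) -> None:
    """Write a Dataset as canonical CSV (UTF-8, '.' decimal, empty = missing).

    Reals are written with 6 decimals; ``read_search_results(path,
    "canonical")`` round-trips all fields.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in ds.records:
            writer.writerow(
                [
                    chem.detokenize(rec.sequence),
                    rec.charge,
                    _fmt(rec.mz),
                    _fmt(getattr(rec, "inv_k0", None)),
                    _fmt(rec.ccs),
                    _fmt(getattr(rec, "intensity", None)),
                    rec.occurrence,
                    getattr(rec, "source_id", ds.source_id),
                ]
            )


# ---------------------------------------------------------------------------
# percolator PIN


def read_pin(path) -> PinTable:
    """Read a percolator input file (TSV; header, optional direction line)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty PIN file")
    header = lines[0].split("\t")
    rows, direction = [], None
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"line {lineno}: {len(fields)} fields, expected {len(header)}"
            )
        if lineno == 2 and fields[0] == "DefaultDirection":
            direction = fields
            continue
        rows.append(fields)
    return PinTable(header=header, rows=rows, direction_row=direction)


def write_pin(pin: PinTable, path) -> None:
    """Write a PinTable back to TSV; untouched fields are byte-stable."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(pin.header) + "\n")
        if pin.direction_row is not None:
            fh.write("\t".join(pin.direction_row) + "\n")
        for row in pin.rows:
            fh.write("\t".join(row) + "\n")
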