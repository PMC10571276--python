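"""Compound records: reading, structure normalization, and deduplication.

The canonical in-memory unit of the package is :class:`CompoundRecord`, one
curated molecule together with its provenance (which database-derived set it
came from), biospecimen detection flags (gut / serum), the two reported pKa
values (strongest acidic and strongest basic group), a chemical-class
annotation, and the derived set labels filled in later by
:mod:`gutperm.set_assembly`.

Structures are normalized to a canonical parent form before any comparison:
the largest organic fragment is kept (salts and solvents stripped), charges
are neutralized where chemically valid, and the canonical SMILES is emitted.
The normalizer is built on RDKit's ``rdMolStandardize`` (cleanup, fragment
parent, uncharge) and is idempotent.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class Source(str, Enum):
    """Provenance of a record: gut metabolome, serum metabolome, or drug set."""

    HMDB_GUT = "hmdb_gut"
    HMDB_SERUM = "hmdb_serum"
    DRUGBANK = "drugbank"


class QuantStatus(str, Enum):
    QUANTIFIED = "quantified"
    DETECTED_NOT_QUANTIFIED = "detected_not_quantified"


#: Quantification statuses retained by default at read time.
ALLOWED_QUANT_STATUSES = frozenset(QuantStatus)


@dataclass
class CompoundRecord:
    """One curated molecule.

    ``compartment_set``, ``fl_flag`` and ``permanence_label`` are derived
    labels; they are ``None`` until :mod:`gutperm.set_assembly` runs.
    """

    id: str
    smiles: str
    source: Source
    in_gut: bool = False
    in_serum: bool = False
    pka_strongest_acidic: Optional[float] = None
    pka_strongest_basic: Optional[float] = None
    chem_class: str = "Other"
    quant_status: Optional[QuantStatus] = None
    compartment_set: Optional[str] = None
    fl_flag: Optional[bool] = None
    permanence_label: Optional[str] = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.source = Source(self.source)
        for attr in ("pka_strongest_acidic", "pka_strongest_basic"):
            v = getattr(self, attr)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{attr} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Structure normalization
# ---------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()


def normalize_structure(smiles: str) -> str:
    """Return the canonical neutral parent structure of ``smiles``.

    Cleanup (valence/aromaticity fixes), largest-organic-fragment selection
    (strips counterions and solvents), charge neutralization where valid,
    then canonical SMILES. Idempotent: ``normalize(normalize(s)) ==
    normalize(s)``.

    Raises
    ------
    ValueError
        If the input does not parse to a molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Reading delimited compound tables
# ---------------------------------------------------------------------------

#: Default header-name mapping: canonical field -> accepted column names.
DEFAULT_COLUMN_MAP = {
    "id": ("id", "identifier", "accession", "hmdb_id", "drugbank_id"),
    "smiles": ("smiles", "SMILES", "canonical_smiles"),
    "source": ("source",),
    "in_gut": ("in_gut", "gut", "feces"),
    "in_serum": ("in_serum", "serum", "blood"),
    "pka_strongest_acidic": ("pka_strongest_acidic", "pka_acid", "acidic_pka"),
    "pka_strongest_basic": ("pka_strongest_basic", "pka_base", "basic_pka"),
    "chem_class": ("chem_class", "class", "classyfire_class", "chemical_class"),
    "quant_status": ("quant_status", "status", "quantification_status"),
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _parse_pka(value: str) -> Optional[float]:
    v = value.strip()
    if v == "" or v.lower() in {"na", "nan", "none"}:
        return None
    x = float(v)
    if not math.isfinite(x):
        raise ValueError(f"non-finite pKa: {value!r}")
    return x


def _resolve_columns(header: Sequence[str], column_map: dict) -> dict:
    resolved = {}
    lower = {h.lower(): h for h in header}
    for canonical, aliases in column_map.items():
        for alias in aliases:
            if alias.lower() in lower:
                resolved[canonical] = lower[alias.lower()]
                break
    return resolved


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_compound_table`."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped_structure: int = 0
    n_skipped_status: int = 0
    skipped: list = field(default_factory=list)  # (row id, reason)


def read_compound_table(
    path: str | Path,
    source: Source | str,
    *,
    column_map: dict | None = None,
    normalize: bool = True,
    allowed_statuses: Iterable[QuantStatus] | None = ALLOWED_QUANT_STATUSES,
    report: ReadReport | None = None,
) -> list[CompoundRecord]:
    """Read a delimited compound table into records, in file order.

    Rows whose SMILES does not parse are skipped with a logged warning and
    counted in ``report``. Rows whose quantification status is outside
    ``allowed_statuses`` are dropped (pass ``allowed_statuses=None`` to keep
    everything). Duplicate ids are kept at read time but flagged
    ``"duplicate_id"`` for the dedup stage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source = Source(source)
    column_map = column_map or DEFAULT_COLUMN_MAP
    allowed = None if allowed_statuses is None else {QuantStatus(s) for s in allowed_statuses}
    if report is None:
        report = ReadReport()

    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"empty table: {path}")
        cols = _resolve_columns(reader.fieldnames, column_map)
        if "smiles" not in cols:
            raise ValueError(f"no SMILES column found in {path} (header: {reader.fieldnames})")

        records: list[CompoundRecord] = []
        seen_ids: set[str] = set()
        for i, row in enumerate(reader):
            report.n_rows += 1
            rid = row.get(cols.get("id", ""), "") or f"row{i}"
            raw_smiles = row[cols["smiles"]]

            # a per-row source column (e.g. in the package's own outputs)
            # overrides the table-level default
            row_source = source
            if "source" in cols and row.get(cols["source"], "").strip():
                try:
                    row_source = Source(row[cols["source"]].strip().lower())
                except ValueError:
                    pass

            status = None
            if "quant_status" in cols and row.get(cols["quant_status"], "").strip():
                try:
                    status = QuantStatus(row[cols["quant_status"]].strip().lower())
                except ValueError:
                    status = None
            if allowed is not None and row_source is not Source.DRUGBANK:
                if status not in allowed:
                    report.n_skipped_status += 1
                    report.skipped.append((rid, "quantification status"))
                    continue

            try:
                smiles = normalize_structure(raw_smiles) if normalize else raw_smiles
                if not normalize and Chem.MolFromSmiles(raw_smiles) is None:
                    raise ValueError(f"unparseable SMILES: {raw_smiles!r}")
            except ValueError:
                logger.warning("skipping %s: unparseable SMILES %r", rid, raw_smiles)
                report.n_skipped_structure += 1
                report.skipped.append((rid, "unparseable structure"))
                continue

            rec = CompoundRecord(
                id=rid,
                smiles=smiles,
                source=row_source,
                in_gut=(
                    _parse_bool(row[cols["in_gut"]])
                    if "in_gut" in cols
                    else row_source is Source.HMDB_GUT
                ),
                in_serum=(
                    _parse_bool(row[cols["in_serum"]])
                    if "in_serum" in cols
                    else row_source is Source.HMDB_SERUM
                ),
                pka_strongest_acidic=(
                    _parse_pka(row[cols["pka_strongest_acidic"]])
                    if "pka_strongest_acidic" in cols
                    else None
                ),
                pka_strongest_basic=(
                    _parse_pka(row[cols["pka_strongest_basic"]])
                    if "pka_strongest_basic" in cols
                    else None
                ),
                chem_class=(row.get(cols.get("chem_class", ""), "") or "Other").strip() or "Other",
                quant_status=status,
            )
            if row_source is not Source.DRUGBANK and not (rec.in_gut or rec.in_serum):
                # metabolite records must be detected somewhere
                report.skipped.append((rid, "no biospecimen flag"))
                continue
            if rid in seen_ids:
                rec.flags.add("duplicate_id")
            seen_ids.add(rid)
            records.append(rec)
            report.n_kept += 1
    return records


CSV_COLUMNS = [
    "id",
    "smiles",
    "source",
    "in_gut",
    "in_serum",
    "pka_strongest_acidic",
    "pka_strongest_basic",
    "chem_class",
    "quant_status",
    "compartment_set",
    "fl_flag",
    "permanence_label",
]


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records to CSV with a fixed column order (round-trips the reader)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.id,
                    r.smiles,
                    r.source.value,
                    int(r.in_gut),
                    int(r.in_serum),
                    "" if r.pka_strongest_acidic is None else repr(r.pka_strongest_acidic),
                    "" if r.pka_strongest_basic is None else repr(r.pka_strongest_basic),
                    r.chem_class,
                    "" if r.quant_status is None else r.quant_status.value,
                    r.compartment_set or "",
                    "" if r.fl_flag is None else int(r.fl_flag),
                    r.permanence_label or "",
                ]
            )


def write_skip_log(report: ReadReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"rows={report.n_rows} kept={report.n_kept} ")
        fh.write(f"skipped_structure={report.n_skipped_structure} ")
        fh.write(f"skipped_status={report.n_skipped_status}\n")
        for rid, reason in report.skipped:
            fh.write(f"{rid}\t{reason}\n")


def read_master_table(path: str | Path) -> list[CompoundRecord]:
    """Read back a CSV written by :func:`write_compound_table`, including the
    derived set labels; exact inverse of the writer for valid rows."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rec = CompoundRecord(
                id=row["id"],
                smiles=row["smiles"],
                source=Source(row["source"]),
                in_gut=bool(int(row["in_gut"])),
                in_serum=bool(int(row["in_serum"])),
                pka_strongest_acidic=_parse_pka(row["pka_strongest_acidic"]),
                pka_strongest_basic=_parse_pka(row["pka_strongest_basic"]),
                chem_class=row["chem_class"],
                quant_status=QuantStatus(row["quant_status"]) if row["quant_status"] else None,
            )
            rec.compartment_set = row["compartment_set"] or None
            rec.fl_flag = bool(int(row["fl_flag"])) if row["fl_flag"] != "" else None
            rec.permanence_label = row["permanence_label"] or None
            records.append(rec)
    return records


def read_compound_sdf(
    path: str | Path,
    source: Source | str,
    *,
    normalize: bool = True,
    report: ReadReport | None = None,
) -> list[CompoundRecord]:
    """Read an SDF whose property fields carry the non-structural columns.

    Property names follow the same aliases as the CSV reader
    (``DEFAULT_COLUMN_MAP``); the structure comes from the mol block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source = Source(source)
    if report is None:
        report = ReadReport()
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        report.n_rows += 1
        if mol is None:
            report.n_skipped_structure += 1
            report.skipped.append((f"sdf_record_{i}", "unparseable structure"))
            continue
        props = {k.lower(): mol.GetProp(k) for k in mol.GetPropNames()}

        def get(canonical: str) -> Optional[str]:
            for alias in DEFAULT_COLUMN_MAP[canonical]:
                if alias.lower() in props:
                    return props[alias.lower()]
            return None

        smiles = Chem.MolToSmiles(mol)
        if normalize:
            smiles = normalize_structure(smiles)
        status_raw = get("quant_status")
        try:
            status = QuantStatus(status_raw.strip().lower()) if status_raw else None
        except ValueError:
            status = None
        rec = CompoundRecord(
            id=get("id") or (mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"),
            smiles=smiles,
            source=source,
            in_gut=_parse_bool(get("in_gut") or "") if get("in_gut") else source is Source.HMDB_GUT,
            in_serum=(
                _parse_bool(get("in_serum") or "")
                if get("in_serum")
                else source is Source.HMDB_SERUM
            ),
            pka_strongest_acidic=_parse_pka(get("pka_strongest_acidic") or ""),
            pka_strongest_basic=_parse_pka(get("pka_strongest_basic") or ""),
            chem_class=(get("chem_class") or "Other").strip() or "Other",
            quant_status=status,
        )
        records.append(rec)
        report.n_kept += 1
    return records


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

_SOURCE_PRIORITY = {Source.DRUGBANK: 0, Source.HMDB_GUT: 1, Source.HMDB_SERUM: 2}


def deduplicate_across_sets(
    records: Sequence[CompoundRecord], *, strip_stereo: bool = False
) -> list[CompoundRecord]:
    """Collapse records sharing a normalized structure.

    A molecule present in both the drug set and a metabolite set survives as
    the drug record. Duplicates within metabolite sources collapse to one
    record whose gut/serum flags are the union of the duplicates'. Output
    order follows first appearance of each structure.

    ``strip_stereo=True`` compares structures with stereochemistry removed;
    the default retains it.
    """

    def key(r: CompoundRecord) -> str:
        if not strip_stereo:
            return r.smiles
        mol = Chem.MolFromSmiles(r.smiles)
        Chem.RemoveStereochemistry(mol)
        return Chem.MolToSmiles(mol)

    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in records:
        k = key(r)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)

    out: list[CompoundRecord] = []
    for k in order:
        group = groups[k]
        winner = min(group, key=lambda r: _SOURCE_PRIORITY[r.source])
        if winner.source is Source.DRUGBANK:
            merged = replace(winner, in_gut=False, in_serum=False, flags=set(winner.flags))
        else:
            merged = replace(
                winner,
                in_gut=any(r.in_gut for r in group),
                in_serum=any(r.in_serum for r in group),
                flags=set(winner.flags),
            )
            # keep the first reported pKa pair when the winner lacks one
            for r in group:
                if merged.pka_strongest_acidic is None:
                    merged.pka_strongest_acidic = r.pka_strongest_acidic
                if merged.pka_strongest_basic is None:
                    merged.pka_strongest_basic = r.pka_strongest_basic
        out.append(merged)
    return out
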