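"""Read user PTM regulation tables and dose-response (CurveCurator) outputs.

Two ingestion paths feed the projection and enrichment machinery:

* a generic regulation CSV/TSV — one modified peptide per row with a
  regulation category (up/down/not) and optional quantitative columns, and
* the ``curves.txt`` table written by a dose-response curve-fitting run
  together with its TOML parameter file, from which potency (pEC50) and
  curve fold change are taken.

Also implements the dose-pair deduplication used when an inhibitor was
profiled at a low and a high dose: duplicates within one experiment resolve
to the most significant entry, then per peptide the high-dose entry wins
unless only the low-dose one was significant.
"""

from __future__ import annotations

import csv
import math
import tomllib
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Sequence, Union

import pandas as pd

from .projection import PTMRecord, parse_site

#: default column names; every entry can be overridden through ``column_map``.
DEFAULT_COLUMNS = {
    "peptide": "Peptide",
    "experiment": "Experiment",
    "regulation": "Regulation",
    "accession": "Uniprot Accession",
    "gene": "Gene Name",
    "site": "Site",
    "fold_change": "Fold Change",
    "p_adj": "Adjusted p-Value",
    "pec50": "pEC50",
}

#: CurveCurator-style defaults for the curves table.
CURVES_COLUMNS = {
    "peptide": "Modified sequence",
    "regulation": "Curve Regulation",
    "accession": "Proteins",
    "gene": "Genes",
    "site": "Site",
    "fold_change": "Curve Fold Change",
    "pec50": "pEC50",
    "experiment": "Experiment",
}

_REGULATIONS = {"up", "down", "not"}


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


class MissingColumnError(KeyError):
    pass


def _sniff_delimiter(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    return max(counts, key=counts.get) if any(counts.values()) else ","


def _read_table(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    sep = _sniff_delimiter(text)
    return pd.read_csv(StringIO(text), sep=sep, dtype=str, keep_default_na=False)


def _split_multi(value: str) -> tuple[str, ...]:
    return tuple(v.strip() for v in value.replace(";", ",").split(",") if v.strip())


def _parse_sites(value: str) -> tuple[tuple[str, int], ...]:
    tokens = [t for t in value.replace("&", ";").replace(",", ";").split(";") if t.strip()]
    return tuple(parse_site(t) for t in tokens)


def _opt_float(value: str) -> float | None:
    value = value.strip()
    if not value or value.lower() in ("na", "nan", "none"):
        return None
    return float(value)


def read_ptm_csv(
    source: Union[str, Path, IO[str]], column_map: dict[str, str] | None = None
) -> tuple[list[PTMRecord], list[RowError]]:
    """Parse a PTM regulation table into records plus a row-error report.

    Required columns: peptide key, regulation, and at least one of
    accession / gene name.  Regulation is case-insensitive and must
    normalize to up/down/not; site strings like "S1134" (multi-site:
    "S236&S240") split into residue + 1-based position.  Malformed rows are
    collected with their line numbers instead of aborting the whole file;
    a missing required column is a hard error naming it.
    """
    columns = {**DEFAULT_COLUMNS, **(column_map or {})}
    frame = _read_table(source)

    for required in ("peptide", "regulation"):
        if columns[required] not in frame.columns:
            raise MissingColumnError(f"required column {columns[required]!r} not found")
    if columns["accession"] not in frame.columns and columns["gene"] not in frame.columns:
        raise MissingColumnError(
            f"need at least one of {columns['accession']!r} or {columns['gene']!r}"
        )

    def cell(row, key: str) -> str:
        name = columns[key]
        return str(row[name]).strip() if name in frame.columns else ""

    records: list[PTMRecord] = []
    errors: list[RowError] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            regulation = cell(row, "regulation").lower()
            if regulation not in _REGULATIONS:
                raise ValueError(
                    f"regulation {cell(row, 'regulation')!r} not in {{up, down, not}}"
                )
            sites = _parse_sites(cell(row, "site")) if cell(row, "site") else ()
            records.append(
                PTMRecord(
                    experiment=cell(row, "experiment") or "default",
                    peptide_key=cell(row, "peptide"),
                    regulation=regulation,
                    uniprot_accessions=_split_multi(cell(row, "accession")),
                    gene_names=_split_multi(cell(row, "gene")),
                    residue=sites[0][0] if sites else None,
                    position=sites[0][1] if sites else None,
                    sites=sites,
                    fold_change=_opt_float(cell(row, "fold_change")),
                    p_adj=_opt_float(cell(row, "p_adj")),
                    pec50=_opt_float(cell(row, "pec50")),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line, str(exc)))
    return records, errors


def write_ptm_csv(records: Sequence[PTMRecord], destination: Union[str, Path, IO[str]]) -> None:
    """Inverse of :func:`read_ptm_csv` for the documented columns."""
    rows = []
    for r in records:
        rows.append(
            {
                DEFAULT_COLUMNS["peptide"]: r.peptide_key,
                DEFAULT_COLUMNS["experiment"]: r.experiment,
                DEFAULT_COLUMNS["regulation"]: r.regulation,
                DEFAULT_COLUMNS["accession"]: ";".join(r.uniprot_accessions),
                DEFAULT_COLUMNS["gene"]: ";".join(r.gene_names),
                DEFAULT_COLUMNS["site"]: "&".join(f"{res}{pos}" for res, pos in r.sites),
                DEFAULT_COLUMNS["fold_change"]: "" if r.fold_change is None else repr(r.fold_change),
                DEFAULT_COLUMNS["p_adj"]: "" if r.p_adj is None else repr(r.p_adj),
                DEFAULT_COLUMNS["pec50"]: "" if r.pec50 is None else repr(r.pec50),
            }
        )
    frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))
    if isinstance(destination, (str, Path)):
        frame.to_csv(destination, index=False, quoting=csv.QUOTE_MINIMAL)
    else:
        frame.to_csv(destination, index=False, quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# CurveCurator / dose-response ingestion


@dataclass(frozen=True)
class DoseExperiment:
    """Parameters of one dose-response experiment (from the TOML file)."""

    drug: str
    doses_molar: tuple[float, ...]

    @property
    def pec50_window(self) -> tuple[float, float]:
        """pEC50 equivalents of the dose range, high-potency end first
        (1 nM .. 10 uM -> (9.0, 5.0))."""
        return (-math.log10(min(self.doses_molar)), -math.log10(max(self.doses_molar)))


def read_toml_params(source: Union[str, Path, IO[bytes]]) -> DoseExperiment:
    """Parse the minimal experiment parameter TOML.

    Documented schema::

        [experiment]
        name = "Lapatinib"
        doses_nM = [1, 3, 10, ...]     # or: doses = [...] in molar

    """
    if isinstance(source, (str, Path)):
        doc = tomllib.loads(Path(source).read_text())
    else:
        doc = tomllib.load(source)
    exp = doc.get("experiment", doc)
    name = exp.get("name") or exp.get("drug")
    if not name:
        raise ValueError("TOML parameter file: missing experiment name/drug")
    if "doses_nM" in exp:
        doses = tuple(float(d) * 1e-9 for d in exp["doses_nM"])
    elif "doses" in exp:
        doses = tuple(float(d) for d in exp["doses"])
    else:
        raise ValueError("TOML parameter file: missing doses / doses_nM")
    if not doses or any(d <= 0 for d in doses):
        raise ValueError("TOML parameter file: doses must be positive")
    return DoseExperiment(drug=str(name), doses_molar=doses)


def read_curvecurator(
    curves: Union[str, Path, IO[str]],
    params: Union[str, Path, IO[bytes], DoseExperiment],
    column_map: dict[str, str] | None = None,
) -> list[PTMRecord]:
    """Read a fitted dose-response curves table plus its TOML parameters.

    Curves classified up/down become regulated records carrying pEC50 and
    curve fold change; unclassified curves become "not" records without a
    potency.  A pEC50 outside the dosed concentration window is kept but
    flagged in the record details.  If the curves table names its
    experiment, it must match the TOML drug name (hard error otherwise).
    """
    experiment = params if isinstance(params, DoseExperiment) else read_toml_params(params)
    columns = {**CURVES_COLUMNS, **(column_map or {})}
    frame = _read_table(curves)
    for required in ("peptide", "regulation"):
        if columns[required] not in frame.columns:
            raise MissingColumnError(f"required column {columns[required]!r} not found")

    if columns["experiment"] in frame.columns:
        names = {str(v).strip() for v in frame[columns["experiment"]] if str(v).strip()}
        if names and names != {experiment.drug}:
            raise ValueError(
                f"curves/TOML drug-name mismatch: curves say {sorted(names)}, "
                f"TOML says {experiment.drug!r}"
            )

    hi, lo = experiment.pec50_window
    records: list[PTMRecord] = []
    for _, row in frame.iterrows():
        def cell(key: str) -> str:
            name = columns[key]
            return str(row[name]).strip() if name in frame.columns else ""

        regulation = cell("regulation").lower()
        if regulation not in _REGULATIONS:
            regulation = "not"
        regulated = regulation in ("up", "down")
        pec50 = _opt_float(cell("pec50")) if regulated else None
        details: list[tuple[str, str]] = [("drug", experiment.drug)]
        if pec50 is not None and not (lo <= pec50 <= hi):
            details.append(("pec50_out_of_range", f"{pec50} outside [{lo}, {hi}]"))
        sites = _parse_sites(cell("site")) if cell("site") else ()
        records.append(
            PTMRecord(
                experiment=experiment.drug,
                peptide_key=cell("peptide"),
                regulation=regulation,
                uniprot_accessions=_split_multi(cell("accession")),
                gene_names=_split_multi(cell("gene")),
                residue=sites[0][0] if sites else None,
                position=sites[0][1] if sites else None,
                sites=sites,
                fold_change=_opt_float(cell("fold_change")) if regulated else None,
                pec50=pec50,
                details=tuple(details),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Dose-pair deduplication


@dataclass(frozen=True)
class DoseEntry:
    peptide_key: str
    dose: str  # "low" | "high"
    significant: bool
    p_adj: float
    fold_change: float = 0.0
    regulation: str = "not"

    def __post_init__(self):
        if self.dose not in ("low", "high"):
            raise ValueError(f"dose must be low/high, got {self.dose!r}")


@dataclass(frozen=True)
class DedupResult:
    entry: DoseEntry
    rule: str  # "I+II" etc. records which selection rule fired


def dedup_dose_pairs(entries: Sequence[DoseEntry]) -> dict[str, DedupResult]:
    """Collapse low/high-dose duplicates to exactly one entry per peptide.

    Rule I resolves duplicates *within* one dose experiment by minimum
    adjusted p-value; then, per peptide: the high-dose entry is kept when it
    is significant (rule III) or when neither dose is (rule II); only a
    significant low-dose entry next to a non-significant high dose survives
    instead (rule IV).  The rules are mutually exclusive and exhaustive, and
    the firing rule is recorded for provenance.
    """
    per_peptide: dict[str, dict[str, DoseEntry]] = {}
    for entry in entries:
        slot = per_peptide.setdefault(entry.peptide_key, {})
        incumbent = slot.get(entry.dose)
        # rule I: most significant entry within the same experiment
        if incumbent is None or entry.p_adj < incumbent.p_adj:
            slot[entry.dose] = entry

    chosen: dict[str, DedupResult] = {}
    for peptide, slot in per_peptide.items():
        low, high = slot.get("low"), slot.get("high")
        if high is not None and high.significant:
            chosen[peptide] = DedupResult(high, "III")
        elif low is not None and low.significant:
            chosen[peptide] = DedupResult(low, "IV")
        elif high is not None:
            chosen[peptide] = DedupResult(high, "II")
        else:
            chosen[peptide] = DedupResult(low, "II")
    return chosen
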