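"""Readers and writers for the external formats of the pipeline.

Handles the peptide-level quantification table (CSV/TSV), the sample
design table, proteome FASTA, and all result tables. The peptide table
dialect is ``protein_accession, peptide_sequence, modifications, charge,
<sample_1>, ..., <sample_n>`` with a modification string of the form
``"Phospho (S5); Oxidation (M3)"`` (1-based in-peptide positions). A
pluggable parser hook (`mod_parser=`) accommodates other vendor dialects.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("protein_accession", "peptide_sequence", "modifications", "charge")

PHOSPHO_RESIDUES = frozenset("STY")
VALID_CHARGES = frozenset({2, 3, 4})


class FormatError(ValueError):
    """Input file does not conform to the expected table layout."""


class DesignMismatchError(ValueError):
    """Table columns do not match the sample design."""


class RowValidationError(ValueError):
    """A data row fails a consistency check (reports the offending rows)."""


@dataclass(frozen=True)
class SampleDesign:
    """One quantified sample: its column name, group, and replicate index."""

    sample_id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be positive, got {self.replicate}")


def validate_design(design: Sequence[SampleDesign]) -> None:
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise DesignMismatchError("duplicate sample_ids in design")


def group_samples(design: Sequence[SampleDesign]) -> dict[str, list[str]]:
    """Map group name -> ordered list of its sample_ids."""
    out: dict[str, list[str]] = {}
    for d in design:
        out.setdefault(d.group, []).append(d.sample_id)
    return out


@dataclass
class PeptideRecord:
    """One quantified peptide ion variant.

    ``phospho_positions`` are 1-based positions within ``peptide_sequence``
    and must index S, T or Y. ``other_mods`` keeps the non-phospho
    modification tags verbatim (e.g. ``"Oxidation (M3)"``) so tables
    round-trip exactly.
    """

    protein_accession: str
    peptide_sequence: str
    phospho_positions: tuple[int, ...]
    other_mods: frozenset[str]
    charge: int
    intensities: dict[str, float]

    @property
    def is_phospho(self) -> bool:
        return len(self.phospho_positions) > 0

    def modification_string(self) -> str:
        tags = [f"Phospho ({self.peptide_sequence[p - 1]}{p})" for p in self.phospho_positions]
        tags.extend(sorted(self.other_mods))
        return "; ".join(tags)


_MOD_RE = re.compile(r"^(?P<name>[A-Za-z][\w\- ]*?)\s*\((?P<args>[^)]*)\)$")
_PHOSPHO_ARG_RE = re.compile(r"^(?P<res>[A-Z])(?P<pos>\d+)$")


def parse_modifications(mods: str) -> tuple[tuple[int, ...], frozenset[str]]:
    """Parse ``"Phospho (S5); Oxidation (M3)"`` -> ((5,), {"Oxidation (M3)"}).

    Phospho entries are split out into sorted 1-based positions; every other
    tag is kept verbatim.
    """
    if not mods or not mods.strip():
        return (), frozenset()
    positions: list[int] = []
    others: list[str] = []
    for raw in mods.split(";"):
        tag = raw.strip()
        if not tag:
            continue
        m = _MOD_RE.match(tag)
        if m is None:
            raise FormatError(f"unparseable modification tag: {tag!r}")
        if m.group("name").strip().lower() == "phospho":
            pm = _PHOSPHO_ARG_RE.match(m.group("args").strip())
            if pm is None:
                raise FormatError(f"unparseable phospho tag: {tag!r}")
            positions.append(int(pm.group("pos")))
        else:
            others.append(tag)
    return tuple(sorted(positions)), frozenset(others)


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a sample design CSV with columns sample_id, group, replicate."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8-sig")
    missing = {"sample_id", "group", "replicate"} - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    design = [
        SampleDesign(str(r.sample_id), str(r.group), int(r.replicate))
        for r in df.itertuples(index=False)
    ]
    validate_design(design)
    return design


def read_peptide_table(
    path: str | Path,
    design: Sequence[SampleDesign],
    *,
    mod_parser: Callable[[str], tuple[tuple[int, ...], frozenset[str]]] = parse_modifications,
    strict_missing: bool = False,
) -> list[PeptideRecord]:
    """Read a peptide quantification table against a sample design.

    Accepts comma- or tab-delimited files (delimiter sniffed) with an
    optional UTF-8 BOM. Missing intensity cells are read as 0.0 unless
    ``strict_missing``. Rows with zero phosphosites are kept (flagged via
    ``is_phospho``) for the protein-level arm.
    """
    validate_design(design)
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8-sig")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"peptide table missing required columns: {sorted(missing)}")
    sample_ids = [d.sample_id for d in design]
    absent = set(sample_ids) - set(df.columns)
    if absent:
        raise DesignMismatchError(f"design samples absent from table: {sorted(absent)}")
    unknown = set(df.columns) - set(REQUIRED_COLUMNS) - set(sample_ids)
    if unknown:
        raise DesignMismatchError(f"unknown sample columns in table: {sorted(unknown)}")

    records: list[PeptideRecord] = []
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        seq = str(rowd["peptide_sequence"]).strip().upper()
        mods = rowd["modifications"]
        mods = "" if pd.isna(mods) else str(mods)
        positions, others = mod_parser(mods)
        for p in positions:
            if not (1 <= p <= len(seq)) or seq[p - 1] not in PHOSPHO_RESIDUES:
                bad_rows.append(f"row {i + 2}: phospho position {p} not on S/T/Y in {seq}")
        charge = int(rowd["charge"])
        if charge not in VALID_CHARGES:
            bad_rows.append(f"row {i + 2}: charge {charge} not in {sorted(VALID_CHARGES)}")
        intens: dict[str, float] = {}
        for s in sample_ids:
            v = rowd[s]
            if pd.isna(v):
                if strict_missing:
                    bad_rows.append(f"row {i + 2}: missing intensity for sample {s}")
                v = 0.0
            v = float(v)
            if v < 0:
                bad_rows.append(f"row {i + 2}: negative intensity {v} for sample {s}")
            intens[s] = v
        records.append(
            PeptideRecord(
                protein_accession=str(rowd["protein_accession"]).strip(),
                peptide_sequence=seq,
                phospho_positions=positions,
                other_mods=others,
                charge=charge,
                intensities=intens,
            )
        )
    if bad_rows:
        raise RowValidationError("; ".join(bad_rows))
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord],
    design: Sequence[SampleDesign],
    path: str | Path,
    *,
    sep: str = ",",
) -> None:
    """Write records in the canonical table dialect (round-trips exactly)."""
    sample_ids = [d.sample_id for d in design]
    rows = []
    for r in records:
        row = {
            "protein_accession": r.protein_accession,
            "peptide_sequence": r.peptide_sequence,
            "modifications": r.modification_string(),
            "charge": r.charge,
        }
        row.update({s: r.intensities[s] for s in sample_ids})
        rows.append(row)
    cols = list(REQUIRED_COLUMNS) + sample_ids
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": d.sample_id, "group": d.group, "replicate": d.replicate} for d in design]
    ).to_csv(path, index=False)


class Proteome(dict):
    """Mapping accession -> uppercase amino-acid sequence."""

    def __setitem__(self, key: str, value: str) -> None:
        if not value:
            raise FormatError(f"empty sequence for accession {key!r}")
        super().__setitem__(key, value.upper())


def read_fasta(path: str | Path) -> Proteome:
    """Read a proteome FASTA; accession = first whitespace token of header."""
    proteome = Proteome()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in proteome:
            raise FormatError(f"duplicate accession in FASTA: {acc!r}")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for accession {acc!r}")
        proteome[acc] = seq
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc in proteome:
            fh.write(f">{acc}\n")
            seq = proteome[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV, 12 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8-sig")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
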