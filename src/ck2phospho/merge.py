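"""Collapse peptide ion variants into unique phosphopeptide motifs.

A phosphopeptide motif is the pair (protein, set of phosphorylated
protein positions). Charge states, missed-cleavage peptides and oxidised
variants of the same motif all localize to the same protein positions, so
keying on protein coordinates merges them all; their per-sample
intensities are summed into a single abundance vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

from .io import PeptideRecord
from .motifs import extract_window

logger = logging.getLogger(__name__)


class LocalizationError(ValueError):
    """Peptide sequence not found in its protein."""


class AmbiguousPeptideError(ValueError):
    """Peptide sequence occurs more than once in its protein."""


class MotifKey(NamedTuple):
    """Identity of a phosphopeptide motif.

    ``sites`` are 1-based protein coordinates. When the protein sequence is
    unavailable, ``peptide`` carries the bare peptide sequence and ``sites``
    fall back to in-peptide coordinates (charge/oxidation variants still
    merge; missed-cleavage variants cannot).
    """

    accession: str
    sites: tuple[int, ...]
    peptide: Optional[str] = None

    def __str__(self) -> str:
        s = "+".join(str(p) for p in self.sites)
        return f"{self.accession}:{s}" if self.peptide is None else f"{self.accession}:{self.peptide}:{s}"

    @classmethod
    def parse(cls, text: str) -> "MotifKey":
        parts = text.split(":")
        sites = tuple(int(p) for p in parts[-1].split("+"))
        if len(parts) == 2:
            return cls(parts[0], sites)
        return cls(parts[0], sites, parts[1])


@dataclass
class PhosphoMotif:
    """A unique motif with merged per-sample abundances and site windows."""

    key: MotifKey
    abundances: dict[str, float]
    n_variants: int
    windows: list[str] = field(default_factory=list)


@dataclass
class MergeReport:
    """Bookkeeping for records excluded during merging."""

    n_records: int = 0
    n_merged: int = 0
    n_not_found: int = 0
    n_ambiguous: int = 0
    n_fallback_key: int = 0
    excluded: list[str] = field(default_factory=list)


def localize_sites(record: PeptideRecord, proteome: Mapping[str, str]) -> MotifKey:
    """Map in-peptide phospho positions to 1-based protein coordinates.

    Raises ``LocalizationError`` if the peptide is absent from the protein
    and ``AmbiguousPeptideError`` if it occurs more than once (the site
    cannot be placed unambiguously).
    """
    seq = proteome[record.protein_accession]
    first = seq.find(record.peptide_sequence)
    if first < 0:
        raise LocalizationError(
            f"peptide {record.peptide_sequence!r} not found in {record.protein_accession}"
        )
    if seq.find(record.peptide_sequence, first + 1) >= 0:
        raise AmbiguousPeptideError(
            f"peptide {record.peptide_sequence!r} occurs more than once in {record.protein_accession}"
        )
    sites = tuple(sorted(first + p for p in record.phospho_positions))
    return MotifKey(record.protein_accession, sites)


def merge_variants(
    records: Sequence[PeptideRecord],
    proteome: Mapping[str, str],
) -> tuple[list[PhosphoMotif], MergeReport]:
    """Merge phosphopeptide records into unique motifs.

    Per-sample abundances of all variants sharing a motif key are summed.
    Records whose accession lacks a proteome sequence fall back to a
    peptide-sequence key (logged); unlocalizable records are excluded and
    counted in the report. Output is sorted by key, so the result is
    independent of input order.
    """
    report = MergeReport(n_records=len(records))
    merged: dict[MotifKey, dict] = {}
    for rec in records:
        if not rec.is_phospho:
            raise ValueError("merge_variants expects phosphorylated records only")
        if rec.protein_accession in proteome:
            try:
                key = localize_sites(rec, proteome)
            except LocalizationError as e:
                report.n_not_found += 1
                report.excluded.append(str(e))
                continue
            except AmbiguousPeptideError as e:
                report.n_ambiguous += 1
                report.excluded.append(str(e))
                continue
        else:
            key = MotifKey(rec.protein_accession, rec.phospho_positions, rec.peptide_sequence)
            report.n_fallback_key += 1
        slot = merged.setdefault(key, {"abundances": {}, "n": 0})
        for s, v in rec.intensities.items():
            slot["abundances"][s] = slot["abundances"].get(s, 0.0) + v
        slot["n"] += 1
        report.n_merged += 1
    if report.n_fallback_key:
        logger.warning(
            "%d records lacked a proteome sequence; merged on peptide-sequence keys",
            report.n_fallback_key,
        )
    if report.n_not_found or report.n_ambiguous:
        logger.warning(
            "excluded %d unlocalizable and %d ambiguous records",
            report.n_not_found,
            report.n_ambiguous,
        )
    motifs: list[PhosphoMotif] = []
    for key in sorted(merged, key=lambda k: (k.accession, k.sites, k.peptide or "")):
        windows = []
        if key.peptide is None and key.accession in proteome:
            windows = [extract_window(proteome, key.accession, site) for site in key.sites]
        motifs.append(
            PhosphoMotif(
                key=key,
                abundances=dict(merged[key]["abundances"]),
                n_variants=merged[key]["n"],
                windows=windows,
            )
        )
    return motifs, report


def motifs_to_frame(motifs: Sequence[PhosphoMotif], sample_ids: Sequence[str]):
    """Tabulate motifs: key, n_variants, windows, per-sample abundances."""
    import pandas as pd

    rows = []
    for m in motifs:
        row = {
            "key": str(m.key),
            "protein_accession": m.key.accession,
            "phosphosites": "+".join(str(s) for s in m.key.sites),
            "n_variants": m.n_variants,
            "windows": ";".join(m.windows),
        }
        row.update({s: m.abundances.get(s, 0.0) for s in sample_ids})
        rows.append(row)
    cols = ["key", "protein_accession", "phosphosites", "n_variants", "windows"] + list(sample_ids)
    return pd.DataFrame(rows, columns=cols)
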