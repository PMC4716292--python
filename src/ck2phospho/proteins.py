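"""Protein-level arm: aggregation, differential testing, venn classes.

Protein abundance is the per-sample sum of all peptide-ion intensities
assigned to the protein (all charges, modification states and variants).
The same normalise -> arcsinh -> pooled-t -> fold-change machinery as the
motif pipeline classifies proteins between groups; venn membership across
the four line/timepoint comparisons is restricted to proteins quantified
with at least two distinct peptide sequences.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import PeptideRecord, SampleDesign
from .stats import (
    ClassificationThresholds,
    LABEL_DOWN,
    LABEL_UP,
    differential_analysis,
)


def aggregate_proteins(
    records: Sequence[PeptideRecord], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Sum peptide intensities per protein per sample.

    Returns a table with accession, n_peptides (distinct peptide
    sequences) and one abundance column per sample. Includes phospho and
    non-phospho records alike.
    """
    acc_order: list[str] = []
    sums: dict[str, dict[str, float]] = {}
    peptides: dict[str, set[str]] = {}
    for rec in records:
        acc = rec.protein_accession
        if acc not in sums:
            acc_order.append(acc)
            sums[acc] = {s: 0.0 for s in sample_ids}
            peptides[acc] = set()
        peptides[acc].add(rec.peptide_sequence)
        for s in sample_ids:
            sums[acc][s] += rec.intensities.get(s, 0.0)
    rows = []
    for acc in sorted(acc_order):
        row = {"accession": acc, "n_peptides": len(peptides[acc])}
        row.update(sums[acc])
        rows.append(row)
    cols = ["accession", "n_peptides"] + list(sample_ids)
    return pd.DataFrame(rows, columns=cols)


def protein_differential(
    proteins: pd.DataFrame,
    design: Sequence[SampleDesign],
    group_a: str,
    group_b: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Two-group differential table over protein abundances."""
    sample_ids = [d.sample_id for d in design]
    matrix = proteins.set_index("accession")[sample_ids]
    out = differential_analysis(matrix, design, group_a, group_b, thresholds)
    n_pep = dict(zip(proteins["accession"], proteins["n_peptides"]))
    out.insert(1, "n_peptides", out["key"].map(n_pep))
    return out


def venn_classes(
    comparisons: Mapping[str, pd.DataFrame],
    *,
    direction: str = LABEL_UP,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Venn membership of proteins across named comparisons.

    ``comparisons`` maps a comparison name to its differential table (with
    ``n_peptides``). A protein is a member for a comparison when labelled
    in the requested direction there; proteins below ``min_peptides`` in
    any table are excluded. Returns one row per protein in >=1 set, with
    one boolean column per comparison and the membership count ``n_sets``.
    """
    if direction not in (LABEL_UP, LABEL_DOWN):
        raise ValueError("direction must be UP or DOWN")
    names = list(comparisons)
    member: dict[str, dict[str, bool]] = {}
    too_few: set[str] = set()
    for name, table in comparisons.items():
        for row in table.itertuples(index=False):
            if int(row.n_peptides) < min_peptides:
                too_few.add(row.key)
                continue
            if row.label == direction:
                member.setdefault(row.key, {n: False for n in names})[name] = True
    rows = []
    for acc in sorted(set(member) - too_few):
        row = {"accession": acc}
        row.update(member[acc])
        row["n_sets"] = sum(member[acc].values())
        rows.append(row)
    return pd.DataFrame(rows, columns=["accession"] + names + ["n_sets"])


def venn_region_counts(membership: pd.DataFrame, names: Optional[Sequence[str]] = None) -> dict:
    """Count proteins per exact venn region (frozenset of comparison names)."""
    if membership.empty:
        return {}
    if names is None:
        names = [c for c in membership.columns if c not in ("accession", "n_sets")]
    counts: dict[frozenset, int] = {}
    for row in membership.itertuples(index=False):
        region = frozenset(n for n in names if getattr(row, n))
        if region:
            counts[region] = counts.get(region, 0) + 1
    return counts
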