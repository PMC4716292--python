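"""Cross-treatment overlap of three-class labellings and chord export.

Two differential tables (e.g. overexpression-vs-parent and
inhibitor-vs-control) are intersected by motif key; confidently labelled
motifs feed a 3x3 overlap matrix (the flows of a chord diagram), while
UNCLASSIFIED or absent motifs are reported as unshared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io import write_json, read_json
from .stats import LABEL_DOWN, LABEL_UNCHANGED, LABEL_UP, LABEL_UNCLASSIFIED

CONFIDENT_LABELS = (LABEL_UP, LABEL_DOWN, LABEL_UNCHANGED)
#: chord-diagram colour convention: up green, down red, unchanged grey
LABEL_COLOURS = {LABEL_UP: "green", LABEL_DOWN: "red", LABEL_UNCHANGED: "grey"}


@dataclass
class OverlapCounts:
    """3x3 label-overlap matrix plus marginals and unshared tallies.

    ``unshared_a[label]`` counts motifs confidently labelled in comparison
    A that are UNCLASSIFIED (``*_unclassified``) or not quantified
    (``*_absent``) in B, and symmetrically for B.
    """

    counts: pd.DataFrame
    marginals_a: dict[str, int]
    marginals_b: dict[str, int]
    unshared_a_unclassified: dict[str, int]
    unshared_a_absent: dict[str, int]
    unshared_b_unclassified: dict[str, int]
    unshared_b_absent: dict[str, int]

    def total_unshared(self) -> int:
        return sum(
            sum(d.values())
            for d in (
                self.unshared_a_unclassified,
                self.unshared_a_absent,
                self.unshared_b_unclassified,
                self.unshared_b_absent,
            )
        )


def _label_map(results: pd.DataFrame) -> dict[str, str]:
    if results["key"].duplicated().any():
        dups = results.loc[results["key"].duplicated(), "key"].tolist()
        raise ValueError(f"duplicate keys in differential table: {dups[:5]}")
    return dict(zip(results["key"].astype(str), results["label"]))


def overlap_counts(a: pd.DataFrame, b: pd.DataFrame) -> OverlapCounts:
    """Intersect two differential tables by key into chord counts."""
    la, lb = _label_map(a), _label_map(b)
    counts = pd.DataFrame(0, index=list(CONFIDENT_LABELS), columns=list(CONFIDENT_LABELS))
    un_a_uncl = {lab: 0 for lab in CONFIDENT_LABELS}
    un_a_abs = {lab: 0 for lab in CONFIDENT_LABELS}
    un_b_uncl = {lab: 0 for lab in CONFIDENT_LABELS}
    un_b_abs = {lab: 0 for lab in CONFIDENT_LABELS}
    for key, lab_a in la.items():
        if lab_a not in CONFIDENT_LABELS:
            continue
        if key not in lb:
            un_a_abs[lab_a] += 1
        elif lb[key] not in CONFIDENT_LABELS:
            un_a_uncl[lab_a] += 1
        else:
            counts.loc[lab_a, lb[key]] += 1
    for key, lab_b in lb.items():
        if lab_b not in CONFIDENT_LABELS:
            continue
        if key not in la:
            un_b_abs[lab_b] += 1
        elif la[key] not in CONFIDENT_LABELS:
            un_b_uncl[lab_b] += 1
    marg_a = {lab: sum(1 for v in la.values() if v == lab) for lab in CONFIDENT_LABELS}
    marg_b = {lab: sum(1 for v in lb.values() if v == lab) for lab in CONFIDENT_LABELS}
    return OverlapCounts(
        counts=counts,
        marginals_a=marg_a,
        marginals_b=marg_b,
        unshared_a_unclassified=un_a_uncl,
        unshared_a_absent=un_a_abs,
        unshared_b_unclassified=un_b_uncl,
        unshared_b_absent=un_b_abs,
    )


def responsive_union(a: pd.DataFrame, b: pd.DataFrame) -> set[str]:
    """Keys labelled UP or DOWN in at least one comparison (the
    treatment-responsive motif catalogue)."""
    la, lb = _label_map(a), _label_map(b)
    diff = {LABEL_UP, LABEL_DOWN}
    return {k for k, v in la.items() if v in diff} | {k for k, v in lb.items() if v in diff}


def chord_dict(
    overlap: OverlapCounts, name_a: str = "A", name_b: str = "B"
) -> dict:
    """Chord-diagram JSON structure: 6 coloured nodes and weighted flows."""
    nodes = [
        {"id": f"{lab}_{side}", "comparison": name, "label": lab, "colour": LABEL_COLOURS[lab]}
        for side, name in (("A", name_a), ("B", name_b))
        for lab in CONFIDENT_LABELS
    ]
    flows = [
        {
            "source": f"{la}_A",
            "target": f"{lb}_B",
            "weight": int(overlap.counts.loc[la, lb]),
        }
        for la in CONFIDENT_LABELS
        for lb in CONFIDENT_LABELS
        if int(overlap.counts.loc[la, lb]) > 0
    ]
    return {
        "nodes": nodes,
        "flows": flows,
        "unshared": {
            "A_unclassified_in_B": overlap.unshared_a_unclassified,
            "A_absent_in_B": overlap.unshared_a_absent,
            "B_unclassified_in_A": overlap.unshared_b_unclassified,
            "B_absent_in_A": overlap.unshared_b_absent,
        },
    }


def export_chord(
    overlap: OverlapCounts, path, name_a: str = "A", name_b: str = "B"
) -> None:
    write_json(chord_dict(overlap, name_a, name_b), path)


def read_chord(path) -> pd.DataFrame:
    """Parse a chord JSON back into the 3x3 count matrix."""
    d = read_json(path)
    counts = pd.DataFrame(0, index=list(CONFIDENT_LABELS), columns=list(CONFIDENT_LABELS))
    for flow in d["flows"]:
        la = flow["source"].rsplit("_", 1)[0]
        lb = flow["target"].rsplit("_", 1)[0]
        counts.loc[la, lb] = flow["weight"]
    return counts


def overlap_table(overlap: OverlapCounts) -> pd.DataFrame:
    """Long-format overlap TSV content (label_a, label_b, count)."""
    rows = [
        {"label_a": la, "label_b": lb, "count": int(overlap.counts.loc[la, lb])}
        for la in CONFIDENT_LABELS
        for lb in CONFIDENT_LABELS
    ]
    return pd.DataFrame(rows)
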