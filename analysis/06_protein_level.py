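#!/usr/bin/env python
"""Protein-level arm: aggregate peptides, test, venn membership.

Sums all peptide-ion intensities per protein, runs the same differential
machinery between groups, and tabulates venn membership (>=2 peptides)
of up- and downregulated proteins across the comparisons.
"""

from pathlib import Path

from ck2phospho import io, proteins

BASE = Path(__file__).resolve().parent.parent / "results"
COMPARISONS = [("parent", "ck2ox"), ("parent", "tbb")]


def main() -> None:
    design = io.read_design(BASE / "data" / "design.csv")
    records = io.read_peptide_table(BASE / "data" / "peptides.csv", design)
    sample_ids = [d.sample_id for d in design]
    prot = proteins.aggregate_proteins(records, sample_ids)
    io.write_table(prot, BASE / "proteins.tsv")
    print(f"{len(records)} peptide rows aggregated into {len(prot)} proteins")

    tables = {}
    for a, b in COMPARISONS:
        name = f"{b}_vs_{a}"
        res = proteins.protein_differential(prot, design, a, b)
        tables[name] = res
        io.write_table(res, BASE / f"protein_differential_{name}.tsv")
        n_diff = int(res["label"].isin(["UP", "DOWN"]).sum())
        print(f"{name}: {n_diff} proteins with differential abundance")

    for direction in ("UP", "DOWN"):
        membership = proteins.venn_classes(tables, direction=direction, min_peptides=2)
        io.write_table(membership, BASE / f"venn_{direction.lower()}.tsv")
        both = membership[membership["n_sets"] == len(tables)] if len(membership) else membership
        print(
            f"{direction}: {len(membership)} proteins in >=1 comparison, "
            f"{len(both)} in both"
        )


if __name__ == "__main__":
    main()
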