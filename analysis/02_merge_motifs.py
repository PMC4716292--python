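#!/usr/bin/env python
"""Merge peptide ion variants into unique phosphopeptide motifs.

Charge states, missed-cleavage peptides and oxidised variants of the same
(protein, phosphosite) identity are collapsed by summing their per-sample
intensities. Writes results/motifs.tsv and prints the merge summary.
"""

from pathlib import Path

from ck2phospho import io, merge

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = io.read_design(BASE / "data" / "design.csv")
    proteome = io.read_fasta(BASE / "data" / "proteome.fasta")
    records = [
        r for r in io.read_peptide_table(BASE / "data" / "peptides.csv", design) if r.is_phospho
    ]
    motif_list, report = merge.merge_variants(records, proteome)
    table = merge.motifs_to_frame(motif_list, [d.sample_id for d in design])
    io.write_table(table, BASE / "motifs.tsv")
    print(
        f"{report.n_merged} phosphopeptides merged into {len(motif_list)} unique motifs "
        f"({report.n_not_found} unlocalizable, {report.n_ambiguous} ambiguous)"
    )
    multi = sum(1 for m in motif_list if m.n_variants > 1)
    print(f"{multi} motifs were observed as more than one ion variant")


if __name__ == "__main__":
    main()
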