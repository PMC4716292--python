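#!/usr/bin/env python
"""CK2 consensus percentages and binomial log-odds logos per class.

For each label class of the overexpression comparison, reports the
percentage of motifs matching the combined CK2 consensus (S/T with D/E at
+1..+3) and writes the position-specific binomial log-odds matrix scored
against the S/T/Y-centred proteome background.
"""

from pathlib import Path

from ck2phospho import io, motifs

BASE = Path(__file__).resolve().parent.parent / "results"
COMPARISON = "ck2ox_vs_parent"


def main() -> None:
    proteome = io.read_fasta(BASE / "data" / "proteome.fasta")
    motif_table = io.read_table(BASE / "motifs.tsv")
    diff = io.read_table(BASE / f"differential_{COMPARISON}.tsv")
    windows_by_key = {
        str(k): str(w).split(";")
        for k, w in zip(motif_table["key"], motif_table["windows"])
        if isinstance(w, str) and w
    }
    background = motifs.background_frequencies(proteome)
    percentages = {}
    for label in ("UP", "DOWN", "UNCHANGED"):
        keys = diff.loc[diff["label"] == label, "key"].astype(str)
        groups = [windows_by_key[k] for k in keys if k in windows_by_key]
        if not groups:
            continue
        pct = motifs.ck2_percentage(groups)
        percentages[label] = pct
        logo = motifs.plogo_scores([w for ws in groups for w in ws], background)
        io.write_json(logo.to_dict(), BASE / f"logo_{COMPARISON}_{label}.json")
        n_sig = int(logo.significant.sum())
        print(
            f"{label}: {len(groups)} motifs, {pct}% CK2 consensus, "
            f"{n_sig} residue-positions over the Bonferroni line"
        )
    io.write_json(percentages, BASE / f"ck2_percent_{COMPARISON}.json")


if __name__ == "__main__":
    main()
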