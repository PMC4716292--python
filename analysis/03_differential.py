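#!/usr/bin/env python
"""Three-class differential analysis of both treatment comparisons.

Motif abundances are mean-normalised and arcsinh-transformed; each motif
is classified UP / DOWN (pooled t, p < 0.05, |FC| > 1.5), UNCHANGED
(TOST, p < 0.05, |FC| < 1.5) or UNCLASSIFIED, for overexpression-vs-
parent and inhibitor-vs-parent. Writes per-comparison tables under
results/.
"""

from pathlib import Path

from ck2phospho import io, stats

BASE = Path(__file__).resolve().parent.parent / "results"
COMPARISONS = [("parent", "ck2ox"), ("parent", "tbb")]


def main() -> None:
    design = io.read_design(BASE / "data" / "design.csv")
    table = io.read_table(BASE / "motifs.tsv")
    sample_ids = [d.sample_id for d in design]
    matrix = table.set_index("key")[sample_ids]
    for a, b in COMPARISONS:
        res = stats.differential_analysis(matrix, design, a, b)
        name = f"{b}_vs_{a}"
        io.write_table(res, BASE / f"differential_{name}.tsv")
        counts = res["label"].value_counts().to_dict()
        print(f"{name}: {counts}")


if __name__ == "__main__":
    main()
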