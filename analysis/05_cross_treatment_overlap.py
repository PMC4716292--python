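#!/usr/bin/env python
"""Overlap of the three-class labellings across the two treatments.

Intersects the overexpression and inhibition comparisons by motif key,
writes the 3x3 chord counts and reports the union of motifs responsive
(UP or DOWN) to at least one treatment — the CK2-responsive catalogue.
"""

from pathlib import Path

from ck2phospho import io, overlap

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    a = io.read_table(BASE / "differential_ck2ox_vs_parent.tsv")
    b = io.read_table(BASE / "differential_tbb_vs_parent.tsv")
    ov = overlap.overlap_counts(a, b)
    io.write_table(overlap.overlap_table(ov), BASE / "overlap.tsv")
    overlap.export_chord(ov, BASE / "chord.json", "ck2ox_vs_parent", "tbb_vs_parent")
    union = overlap.responsive_union(a, b)
    print("3x3 overlap (rows: overexpression, cols: inhibition):")
    print(ov.counts.to_string())
    print(f"unshared (unclassified or absent in the other arm): {ov.total_unshared()}")
    print(f"CK2-responsive union (UP or DOWN in either arm): {len(union)} motifs")


if __name__ == "__main__":
    main()
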