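#!/usr/bin/env python
"""Generate the study-condition synthetic dataset.

Emulates the dusk-phase design: a parent line, a CK2-overexpression line
and an inhibitor (TBB) treatment, five replicates each; 1520 phospho-
peptide motifs observed as 1-4 charge/missed-cleavage/oxidation variants;
CK2-like acidic contexts planted class-dependently (more frequent among
upregulated sites, rarer among downregulated ones). Writes FASTA, peptide
CSV, design CSV and ground truth under results/data/.
"""

import sys
from pathlib import Path

from ck2phospho import simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = simulate.SyntheticConfig(
        seed=SEED,
        ck2_fraction_by_class={"UP": 0.622, "DOWN": 0.364, "UNCHANGED": 0.5},
    )
    records, design, truth, proteome = simulate.generate_dataset(cfg)
    paths = simulate.write_dataset(OUT, records, design, truth, proteome)
    n_motifs = truth["key"].nunique()
    print(f"seed {SEED}: {len(records)} peptide-ion rows covering {n_motifs} motifs")
    print(f"{len(proteome)} proteins, {len(design)} samples in 3 groups")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
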