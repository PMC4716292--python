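import dataclasses
import math

import numpy as np
import pytest

from ck2phospho import io, merge, motifs, simulate, stats


class TestProteomeGeneration:
    def test_same_seed_identical_fasta_bytes(self, tmp_path, small_config):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        io.write_fasta(simulate.generate_proteome(small_config), p1)
        io.write_fasta(simulate.generate_proteome(small_config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_constrained_frequency_table(self):
        cfg = simulate.SyntheticConfig(
            seed=3, n_proteins=5, protein_length=(50, 60),
            residue_frequencies={"A": 0.9, "S": 0.1},
        )
        proteome = simulate.generate_proteome(cfg)
        assert all(set(seq) <= {"A", "S"} for seq in proteome.values())

    def test_uniform_frequencies_within_binomial_error(self):
        cfg = simulate.SyntheticConfig(seed=4, n_proteins=250, protein_length=(400, 400))
        proteome = simulate.generate_proteome(cfg)
        residues = "".join(proteome.values())
        n = len(residues)
        assert n == 100_000
        se = math.sqrt((1 / 20) * (19 / 20) / n)
        for aa in simulate.AMINO_ACIDS:
            freq = residues.count(aa) / n
            assert abs(freq - 0.05) < 3.6 * se  # 3 sigma with a small multiplicity cushion

    def test_invalid_frequencies_rejected(self):
        cfg = simulate.SyntheticConfig(residue_frequencies={"A": -1.0})
        with pytest.raises(ValueError):
            simulate.generate_proteome(cfg)


class TestDatasetGeneration:
    def test_full_determinism_byte_identical(self, tmp_path, small_config):
        out1, out2 = tmp_path / "d1", tmp_path / "d2"
        for out in (out1, out2):
            simulate.write_dataset(out, *simulate.generate_dataset(small_config))
        for name in ("proteome.fasta", "peptides.csv", "design.csv", "ground_truth.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_noiseless_limit_recovers_planted_fold_change(self):
        cfg = simulate.SyntheticConfig(
            seed=5, n_proteins=60, n_phospho_motifs=50, replicate_cv=1e-9
        )
        records, design, truth, proteome = simulate.generate_dataset(cfg)
        motif_list, _ = merge.merge_variants(records, proteome)
        groups = io.group_samples(design)
        by_key = {str(m.key): m for m in motif_list}
        for row in truth[truth["treatment"] == "ck2ox"].itertuples(index=False):
            m = by_key[row.key]
            mean_parent = np.mean([m.abundances[s] for s in groups["parent"]])
            mean_ox = np.mean([m.abundances[s] for s in groups["ck2ox"]])
            assert mean_ox / mean_parent == pytest.approx(row.true_fold_change, rel=1e-6)

    def test_variant_split_conserves_motif_intensity(self, small_dataset, small_motifs):
        # every motif's merged abundance is the pre-split intensity by construction:
        # variants carry Dirichlet weights that sum to one
        motif_list, _ = small_motifs
        multi = [m for m in motif_list if m.n_variants > 1]
        assert multi, "fixture should contain split motifs"
        truth = small_dataset["truth"]
        assert set(truth["key"]) == {str(m.key) for m in motif_list}

    def test_emitted_tables_pass_io_validation(self, tmp_path, small_dataset):
        paths = simulate.write_dataset(
            tmp_path / "d",
            small_dataset["records"],
            small_dataset["design"],
            small_dataset["truth"],
            small_dataset["proteome"],
        )
        design = io.read_design(paths["design"])
        records = io.read_peptide_table(paths["peptides"], design, strict_missing=True)
        assert len(records) == len(small_dataset["records"])
        proteome = io.read_fasta(paths["proteome"])
        assert proteome == small_dataset["proteome"]

    def test_ck2_context_fraction_is_exact(self, small_dataset):
        truth = small_dataset["truth"]
        per_motif = truth.drop_duplicates("key")
        frac = per_motif["ck2_context"].mean()
        assert frac == pytest.approx(0.5, abs=0.01)
        # planted contexts must actually match the consensus, non-contexts must not
        proteome = small_dataset["proteome"]
        for row in per_motif.itertuples(index=False):
            w = motifs.extract_window(proteome, row.protein_accession, row.site)
            assert motifs.ck2_match(w)[0] is bool(row.ck2_context)

    def test_insufficient_sites_error(self):
        cfg = simulate.SyntheticConfig(seed=6, n_proteins=2, n_phospho_motifs=5000)
        with pytest.raises(ValueError, match="eligible"):
            simulate.generate_dataset(cfg)


class TestEndToEndRecovery:
    def test_planted_up_motifs_recovered_with_correct_direction(self):
        cfg = simulate.SyntheticConfig(
            seed=7,
            n_proteins=200,
            n_phospho_motifs=500,
            groups=("parent", "ck2ox"),
            class_proportions={"ck2ox": {"UP": 0.2}},
            effect_fc_range=(2.0, 4.0),
            replicate_cv=0.2,
        )
        records, design, truth, proteome = simulate.generate_dataset(cfg)
        motif_list, _ = merge.merge_variants(records, proteome)
        table = merge.motifs_to_frame(motif_list, [d.sample_id for d in design])
        matrix = table.set_index("key")[[d.sample_id for d in design]]
        res = stats.differential_analysis(matrix, design, "parent", "ck2ox")
        joined = res.set_index("key").join(
            truth[truth["treatment"] == "ck2ox"].set_index("key"), how="inner"
        )
        up = joined[joined["true_class"] == "UP"]
        assert (up["label"] == "UP").mean() >= 0.90
        assert (up["label"] == "DOWN").sum() == 0

    def test_false_calls_rare_under_study_proportions(self):
        # under the default (mildly asymmetric) planted proportions the
        # mean-normalisation stays calibrated and planted-unchanged motifs
        # are almost never called differential; strong one-sided planting
        # (e.g. 20% UP at 3x) shifts column totals and inflates this rate
        cfg = simulate.SyntheticConfig(seed=7, n_proteins=200, n_phospho_motifs=500)
        records, design, truth, proteome = simulate.generate_dataset(cfg)
        motif_list, _ = merge.merge_variants(records, proteome)
        table = merge.motifs_to_frame(motif_list, [d.sample_id for d in design])
        matrix = table.set_index("key")[[d.sample_id for d in design]]
        res = stats.differential_analysis(matrix, design, "parent", "ck2ox")
        joined = res.set_index("key").join(
            truth[truth["treatment"] == "ck2ox"].set_index("key"), how="inner"
        )
        unchanged = joined[joined["true_class"] == "UNCHANGED"]
        assert (unchanged["label"].isin(["UP", "DOWN"])).mean() <= 0.07
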