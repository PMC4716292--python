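"""End-to-end orchestration with config, logging and run manifests.

``run_phospho_pipeline`` executes read -> merge -> normalise/test/classify
per comparison -> windows/CK2/logo per class -> cross-comparison overlap,
writing every result table plus a manifest (config, package versions, row
counts and output-file hashes) so identical manifests imply identical
results. ``run_proteome_pipeline`` runs the protein-level arm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__, io, merge, motifs, overlap, proteins, stats

logger = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_DATA = 3


class ValidationError(ValueError):
    """Configuration inconsistent with the data; raised before computation."""


@dataclass
class RunConfig:
    """Inputs, comparisons and options for a pipeline run."""

    peptide_table: Path
    fasta: Path
    design: Path
    outdir: Path
    comparisons: list[tuple[str, str]]
    thresholds: stats.ClassificationThresholds = field(
        default_factory=stats.ClassificationThresholds
    )
    min_peptides: int = 2
    bonferroni: bool = True
    background_centers: str = "STY"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = stats.ClassificationThresholds(**raw.get("thresholds", {}))
        return cls(
            peptide_table=Path(raw["peptide_table"]),
            fasta=Path(raw["fasta"]),
            design=Path(raw["design"]),
            outdir=Path(raw["outdir"]),
            comparisons=[tuple(c) for c in raw["comparisons"]],
            thresholds=thr,
            min_peptides=int(raw.get("min_peptides", 2)),
            bonferroni=bool(raw.get("bonferroni", True)),
            background_centers=str(raw.get("background_centers", "STY")),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    design = io.read_design(config.design)
    groups = io.group_samples(design)
    for a, b in config.comparisons:
        for g in (a, b):
            if g not in groups:
                raise ValidationError(f"comparison group {g!r} absent from design")
            if len(groups[g]) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 replicates")
    proteome = io.read_fasta(config.fasta)
    records = io.read_peptide_table(config.peptide_table, design)
    return design, proteome, records


def run_phospho_pipeline(config: RunConfig) -> dict:
    """Run the phosphoproteomic arm; returns the result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, proteome, records = _load_inputs(config)
    sample_ids = [d.sample_id for d in design]
    phospho = [r for r in records if r.is_phospho]
    logger.info("read %d records (%d phosphopeptides)", len(records), len(phospho))

    motif_list, report = merge.merge_variants(phospho, proteome)
    logger.info(
        "merged %d phosphopeptides into %d unique motifs (%d excluded)",
        report.n_merged,
        len(motif_list),
        report.n_not_found + report.n_ambiguous,
    )
    motif_table = merge.motifs_to_frame(motif_list, sample_ids)
    io.write_table(motif_table, outdir / "motifs.tsv")

    matrix = motif_table.set_index("key")[sample_ids]
    windows_by_key = {
        str(m.key): list(m.windows) for m in motif_list
    }
    background = motifs.background_frequencies(
        proteome, centers=frozenset(config.background_centers)
    )

    manifest_counts = {
        "records": len(records),
        "phosphopeptides": len(phospho),
        "motifs": len(motif_list),
        "merge_excluded": report.n_not_found + report.n_ambiguous,
    }
    differentials: dict[str, pd.DataFrame] = {}
    logos: dict[str, dict] = {}
    ck2_percent: dict[str, dict[str, float]] = {}
    for a, b in config.comparisons:
        name = f"{b}_vs_{a}"
        table = stats.differential_analysis(matrix, design, a, b, config.thresholds)
        differentials[name] = table
        io.write_table(table, outdir / f"differential_{name}.tsv")
        counts = table["label"].value_counts().to_dict()
        manifest_counts[f"classes_{name}"] = counts
        logger.info("%s: %s", name, counts)
        logos[name] = {}
        ck2_percent[name] = {}
        for label in overlap.CONFIDENT_LABELS:
            keys = table.loc[table["label"] == label, "key"]
            group_windows = [windows_by_key[k] for k in keys if windows_by_key.get(k)]
            if not group_windows:
                continue
            flat = [w for ws in group_windows for w in ws]
            logo = motifs.plogo_scores(flat, background, bonferroni=config.bonferroni)
            logos[name][label] = logo
            io.write_json(logo.to_dict(), outdir / f"logo_{name}_{label}.json")
            ck2_percent[name][label] = motifs.ck2_percentage(group_windows)
        io.write_json(ck2_percent[name], outdir / f"ck2_percent_{name}.json")

    bundle: dict = {
        "design": design,
        "report": report,
        "motifs": motif_list,
        "motif_table": motif_table,
        "differentials": differentials,
        "logos": logos,
        "ck2_percent": ck2_percent,
    }
    if len(config.comparisons) >= 2:
        name_a = f"{config.comparisons[0][1]}_vs_{config.comparisons[0][0]}"
        name_b = f"{config.comparisons[1][1]}_vs_{config.comparisons[1][0]}"
        ov = overlap.overlap_counts(differentials[name_a], differentials[name_b])
        union = overlap.responsive_union(differentials[name_a], differentials[name_b])
        io.write_table(overlap.overlap_table(ov), outdir / "overlap.tsv")
        overlap.export_chord(ov, outdir / "chord.json", name_a, name_b)
        manifest_counts["responsive_union"] = len(union)
        bundle["overlap"] = ov
        bundle["responsive_union"] = union

    manifest = {
        "tool": "ck2phospho",
        "version": __version__,
        "config": _config_dict(config),
        "versions": _lib_versions(),
        "counts": manifest_counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.yaml"
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def run_proteome_pipeline(config: RunConfig) -> dict:
    """Run the protein-level arm: aggregate, test, venn membership."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, _proteome, records = _load_inputs(config)
    sample_ids = [d.sample_id for d in design]
    prot = proteins.aggregate_proteins(records, sample_ids)
    logger.info("aggregated %d records into %d proteins", len(records), len(prot))
    io.write_table(prot, outdir / "proteins.tsv")

    differentials: dict[str, pd.DataFrame] = {}
    manifest_counts: dict = {"records": len(records), "proteins": len(prot)}
    for a, b in config.comparisons:
        name = f"{b}_vs_{a}"
        table = proteins.protein_differential(prot, design, a, b, config.thresholds)
        differentials[name] = table
        io.write_table(table, outdir / f"protein_differential_{name}.tsv")
        manifest_counts[f"classes_{name}"] = table["label"].value_counts().to_dict()
    memberships = {}
    for direction in (stats.LABEL_UP, stats.LABEL_DOWN):
        membership = proteins.venn_classes(
            differentials, direction=direction, min_peptides=config.min_peptides
        )
        memberships[direction] = membership
        io.write_table(membership, outdir / f"venn_{direction.lower()}.tsv")
        manifest_counts[f"venn_{direction.lower()}"] = len(membership)

    manifest = {
        "tool": "ck2phospho-proteins",
        "version": __version__,
        "config": _config_dict(config),
        "versions": _lib_versions(),
        "counts": manifest_counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.yaml"
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {
        "design": design,
        "proteins": prot,
        "differentials": differentials,
        "venn": memberships,
        "manifest": manifest,
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    d["comparisons"] = [list(c) for c in d["comparisons"]]
    return d


def _lib_versions() -> dict:
    import numpy, scipy, pandas  # noqa: PLC0415

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
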