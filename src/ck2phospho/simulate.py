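"""Ground-truth synthetic data for the whole pipeline.

Generates a random proteome, a multi-group label-free phosphopeptide
quantification table and the matching ground truth, with the statistical
structure the analysis assumes: per-motif intensities split across charge
(2+/3+/4+), missed-cleavage and oxidation variants; multiplicative
log-normal replicate noise; planted fold-change effects per treatment;
and CK2-like acidic +1..+3 contexts planted at an exact controllable
fraction of sites. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    PeptideRecord,
    Proteome,
    SampleDesign,
    write_design,
    write_fasta,
    write_peptide_table,
    write_table,
)
from .merge import MotifKey

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ACIDIC = "DE"
#: replacement alphabet for de-acidified contexts: no D/E (would create a
#: CK2 context) and no K/R (would alter the tryptic digest)
NON_ACIDIC_NON_CLEAVING = "ACFGHILMNPQSTVWY"

CLASS_UP = "UP"
CLASS_DOWN = "DOWN"
CLASS_UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Defaults emulate the scale and design of a dusk-phase CK2 perturbation
    experiment: a parent/control line, a kinase-overexpression line and an
    inhibitor treatment, five replicates each; ~1520 phosphopeptide motifs
    over ~400 proteins observed as 1-4 ion variants apiece; log-normal
    base intensities around e^14 ion counts with 20% replicate CV;
    planted effects of 1.5-4 fold. Class proportions are per treatment
    (remainder = unchanged); overexpression skews towards upregulation,
    inhibition mirrors it.
    """

    seed: int = 0
    n_proteins: int = 400
    protein_length: tuple[int, int] = (200, 600)
    residue_frequencies: Optional[Mapping[str, float]] = None  # default uniform
    n_phospho_motifs: int = 1520
    fraction_ck2_context: float = 0.5
    ck2_fraction_by_class: Optional[Mapping[str, float]] = None
    groups: tuple[str, ...] = ("parent", "ck2ox", "tbb")
    class_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ck2ox": {CLASS_UP: 0.113, CLASS_DOWN: 0.022},
            "tbb": {CLASS_UP: 0.022, CLASS_DOWN: 0.113},
        }
    )
    effect_fc_range: tuple[float, float] = (1.5, 4.0)
    base_log_mean: float = 14.0
    base_log_sd: float = 1.5
    replicate_cv: float = 0.2
    n_replicates: int = 5
    max_variants: int = 4
    p_missed_cleavage: float = 0.3
    p_oxidation: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_ck2_context <= 1.0):
            raise ValueError("fraction_ck2_context must be in [0, 1]")
        if self.replicate_cv <= 0:
            raise ValueError("replicate CV must be positive")
        for g, props in self.class_proportions.items():
            if g not in self.groups:
                raise ValueError(f"class proportions name unknown group {g!r}")
            if sum(props.values()) > 1.0 + 1e-12:
                raise ValueError(f"class proportions for {g!r} exceed 1")
        for p in (self.p_missed_cleavage, self.p_oxidation):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


def _frequency_arrays(config: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    freqs = config.residue_frequencies
    if freqs is None:
        return list(AMINO_ACIDS), np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    letters = list(freqs)
    probs = np.array([freqs[a] for a in letters], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0 or not set(letters) <= set(AMINO_ACIDS):
        raise ValueError("invalid residue frequency table")
    return letters, probs / probs.sum()


def generate_proteome(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> Proteome:
    """Random proteome: i.i.d. residues from the frequency table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    letters, probs = _frequency_arrays(config)
    lo, hi = config.protein_length
    proteome = Proteome()
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteome[f"SYN{i + 1:04d}"] = seq
    return proteome


def _tryptic_peptides(seq: str) -> list[tuple[int, int]]:
    """(start, end) 0-based half-open spans cut after every K/R."""
    spans, start = [], 0
    for i, res in enumerate(seq):
        if res in "KR":
            spans.append((start, i + 1))
            start = i + 1
    if start < len(seq):
        spans.append((start, len(seq)))
    return spans


@dataclass
class _Site:
    accession: str
    protein_site: int  # 1-based
    pep_span: tuple[int, int]
    prev_span: Optional[tuple[int, int]]  # preceding tryptic peptide, for missed cleavage
    ck2_context: bool = False


def _eligible_sites(proteome: Mapping[str, str]) -> list[_Site]:
    """Sites usable for planting: S/T inside a 7-35 aa tryptic peptide with
    the +1..+3 context strictly inside the peptide (before its K/R end)."""
    sites = []
    for acc in sorted(proteome):
        seq = proteome[acc]
        spans = _tryptic_peptides(seq)
        for si, (start, end) in enumerate(spans):
            if not (7 <= end - start <= 35):
                continue
            prev = spans[si - 1] if si > 0 else None
            for i in range(start, end):
                # +3 must stay before the terminal K/R so context planting
                # cannot alter the digest
                if seq[i] in "ST" and i + 3 < end - 1:
                    sites.append(_Site(acc, i + 1, (start, end), prev))
    return sites


def _plant_contexts(
    proteome: Proteome,
    sites: Sequence[_Site],
    context_flags: Sequence[bool],
    rng: np.random.Generator,
) -> Proteome:
    """Rewrite +1..+3 of every selected site: acidic for CK2-context sites,
    de-acidified otherwise, so the planted context fraction is exact."""
    seqs = {acc: list(proteome[acc]) for acc in proteome}
    for site, is_ctx in zip(sites, context_flags):
        seq = seqs[site.accession]
        idx = site.protein_site - 1
        for off in (1, 2, 3):
            if is_ctx:
                seq[idx + off] = str(rng.choice(list(ACIDIC)))
            elif seq[idx + off] in ACIDIC:
                seq[idx + off] = str(rng.choice(list(NON_ACIDIC_NON_CLEAVING)))
        site.ck2_context = is_ctx
    out = Proteome()
    for acc in proteome:
        out[acc] = "".join(seqs[acc])
    return out


def make_design(config: SyntheticConfig) -> list[SampleDesign]:
    return [
        SampleDesign(f"{g}_{r}", g, r)
        for g in config.groups
        for r in range(1, config.n_replicates + 1)
    ]


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    s2 = math.log(1.0 + cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size))


def generate_dataset(
    config: SyntheticConfig, proteome: Optional[Proteome] = None
) -> tuple[list[PeptideRecord], list[SampleDesign], pd.DataFrame, Proteome]:
    """Generate (records, design, ground truth, context-planted proteome).

    One motif per selected tryptic peptide; per-treatment classes and fold
    changes are drawn independently per motif. Ground truth has one row
    per motif x treatment with the planted class, fold change and context
    flag; a noiseless run (cv -> 0) recovers the planted mean ratios
    exactly after merging because variant splits are conserved sums.
    """
    rng = np.random.default_rng(config.seed)
    if proteome is None:
        proteome = generate_proteome(config, rng)
    candidates = _eligible_sites(proteome)
    if len(candidates) < config.n_phospho_motifs:
        raise ValueError(
            f"proteome offers {len(candidates)} eligible sites, "
            f"need {config.n_phospho_motifs}"
        )
    # one site per tryptic peptide so motifs never share a peptide
    by_pep: dict[tuple[str, tuple[int, int]], list[_Site]] = {}
    for s in candidates:
        by_pep.setdefault((s.accession, s.pep_span), []).append(s)
    pep_keys = sorted(by_pep)
    chosen_peps = rng.choice(len(pep_keys), size=config.n_phospho_motifs, replace=False)
    sites = [by_pep[pep_keys[i]][rng.integers(len(by_pep[pep_keys[i]]))] for i in chosen_peps]

    fractions = _context_fractions(config)
    treatments = [g for g in config.groups[1:]]
    classes, fcs = _plant_classes(config, rng, len(sites), treatments)
    context_flags = _draw_context_flags(rng, len(sites), classes, treatments, fractions)
    proteome = _plant_contexts(proteome, sites, context_flags, rng)

    design = make_design(config)
    sample_ids = [d.sample_id for d in design]
    records: list[PeptideRecord] = []
    truth_rows = []
    for mi, site in enumerate(sites):
        seq = proteome[site.accession]
        start, end = site.pep_span
        peptide = seq[start:end]
        base = math.exp(rng.normal(config.base_log_mean, config.base_log_sd))
        group_means = {config.groups[0]: base}
        for t in treatments:
            group_means[t] = base * fcs[t][mi]
        intensities: dict[str, float] = {}
        for d in design:
            noise = _mean_one_lognormal(rng, config.replicate_cv, 1)[0]
            intensities[d.sample_id] = group_means[d.group] * noise
        n_var = int(rng.integers(1, config.max_variants + 1))
        weights = rng.dirichlet(np.ones(n_var))
        key = MotifKey(site.accession, (site.protein_site,))
        variant_desc = []
        for v in range(n_var):
            missed = site.prev_span is not None and rng.random() < config.p_missed_cleavage
            if missed:
                vstart = site.prev_span[0]
                vpep = seq[vstart:end]
            else:
                vstart, vpep = start, peptide
            # variants must stay uniquely localizable
            if seq.count(vpep) != 1:
                vstart, vpep, missed = start, peptide, False
            pos_in_pep = site.protein_site - vstart
            mods: set[str] = set()
            m_positions = [i + 1 for i, r in enumerate(vpep) if r == "M"]
            if m_positions and rng.random() < config.p_oxidation:
                mods.add(f"Oxidation (M{m_positions[0]})")
            charge = int(rng.choice([2, 3, 4]))
            records.append(
                PeptideRecord(
                    protein_accession=site.accession,
                    peptide_sequence=vpep,
                    phospho_positions=(pos_in_pep,),
                    other_mods=frozenset(mods),
                    charge=charge,
                    intensities={s: weights[v] * intensities[s] for s in sample_ids},
                )
            )
            variant_desc.append(
                f"z{charge}" + ("+mc" if missed else "") + ("+ox" if mods else "")
            )
        for t in treatments:
            truth_rows.append(
                {
                    "key": str(key),
                    "protein_accession": site.accession,
                    "site": site.protein_site,
                    "treatment": t,
                    "true_class": classes[t][mi],
                    "true_fold_change": fcs[t][mi],
                    "ck2_context": site.ck2_context,
                    "n_variants": n_var,
                    "variants": ";".join(variant_desc),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, design, truth, proteome


def _context_fractions(config: SyntheticConfig) -> dict[str, float]:
    base = config.fraction_ck2_context
    out = {CLASS_UP: base, CLASS_DOWN: base, CLASS_UNCHANGED: base}
    if config.ck2_fraction_by_class:
        out.update(config.ck2_fraction_by_class)
    return out


def _plant_classes(
    config: SyntheticConfig,
    rng: np.random.Generator,
    n: int,
    treatments: Sequence[str],
) -> tuple[dict[str, list[str]], dict[str, np.ndarray]]:
    lo, hi = config.effect_fc_range
    classes: dict[str, list[str]] = {}
    fcs: dict[str, np.ndarray] = {}
    for t in treatments:
        props = config.class_proportions.get(t, {})
        p_up = props.get(CLASS_UP, 0.0)
        p_down = props.get(CLASS_DOWN, 0.0)
        u = rng.random(n)
        labels = np.where(u < p_up, CLASS_UP, np.where(u < p_up + p_down, CLASS_DOWN, CLASS_UNCHANGED))
        effect = rng.uniform(lo, hi, n)
        fc = np.where(labels == CLASS_UP, effect, np.where(labels == CLASS_DOWN, 1.0 / effect, 1.0))
        classes[t] = labels.tolist()
        fcs[t] = fc
    return classes, fcs


def _draw_context_flags(
    rng: np.random.Generator,
    n: int,
    classes: Mapping[str, list[str]],
    treatments: Sequence[str],
    fractions: Mapping[str, float],
) -> list[bool]:
    """Context fraction is exact per planted class of the first treatment
    (rounded count); the remaining treatments inherit the site contexts."""
    primary = treatments[0] if treatments else None
    if primary is None:
        k = round(fractions[CLASS_UNCHANGED] * n)
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags.tolist()
    flags = np.zeros(n, dtype=bool)
    labels = np.array(classes[primary])
    for cls in (CLASS_UP, CLASS_DOWN, CLASS_UNCHANGED):
        idx = np.flatnonzero(labels == cls)
        k = round(fractions[cls] * len(idx))
        flags[rng.permutation(idx)[:k]] = True
    return flags.tolist()


def write_dataset(
    outdir: str | Path,
    records: Sequence[PeptideRecord],
    design: Sequence[SampleDesign],
    truth: pd.DataFrame,
    proteome: Proteome,
) -> dict[str, Path]:
    """Write FASTA + peptide CSV + design CSV + truth TSV into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "peptides": outdir / "peptides.csv",
        "design": outdir / "design.csv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_fasta(proteome, paths["proteome"])
    write_peptide_table(records, design, paths["peptides"])
    write_design(design, paths["design"])
    write_table(truth, paths["truth"])
    return paths
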