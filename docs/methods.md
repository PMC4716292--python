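# Methods

## Statistical model

Label-free peptide ion intensities are treated as positive,
heavy-tailed quantities with approximately multiplicative replicate
error. Two transformations make them testable with *t* statistics:

- **Mean normalisation.** Every sample column is scaled by
  (mean column total) / (its own total), so all column totals equal the
  pre-scaling mean. This removes loading/injection differences under the
  assumption that most of the signal is unchanged between samples (see
  *Limitations*).
- **arcsinh transform.** `arcsinh(x) = ln(x + √(x²+1))` is defined at
  zero and behaves as `ln(2x)` for typical intensities, so multiplicative
  noise becomes approximately additive and Gaussian.

Differential calls use the equal-variance (pooled) two-sample *t*-test
with `df = n_a + n_b − 2`; for two groups this is the test a one-way
ANOVA on the transformed data reduces to. Equivalence calls use the two
one-sided tests (TOST): with Δ the transformed-scale mean difference and
margin δ, `p = max{ P(T ≥ (Δ+δ)/se), P(T ≤ (Δ−δ)/se) }`; small *p*
rejects both "Δ ≤ −δ" and "Δ ≥ +δ". Degenerate zero-variance rows use
the limit conventions p = 1 (equal means) / p = 0 (unequal) for the
*t*-test, and p = 0 / p = 1 for TOST according to whether |Δ| clears the
margin.

The three-class rule is:

| class | rule |
| --- | --- |
| UP / DOWN | t-test p < 0.05 **and** abs. fold change > 1.5, sign of the ratio |
| UNCHANGED | TOST p < 0.05 **and** abs. fold change < 1.5 |
| UNCLASSIFIED | neither (including |FC| exactly 1.5 under the strict inequalities) |

Fold changes are ratios of within-group means on the **normalised raw**
scale (treatment/control), floored at half the smallest positive value
in the matrix to guard all-zero groups; tests run on the transformed
scale. No multiple-testing correction is applied by default (the rules
are raw-p thresholds); a Benjamini-Hochberg helper is available.

### Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `alpha_diff`, `alpha_tost` | 0.05 | p-value thresholds for the differential and equivalence tests |
| `fc_min_diff`, `fc_max_equiv` | 1.5 | absolute fold-change bounds (dimensionless ratio) |
| `tost_margin` | ln 1.5 ≈ 0.405 | equivalence margin on the arcsinh scale; since arcsinh ≈ ln(2x), it mirrors the 1.5-fold bound. The margin is not uniquely determined by the classification rules alone, so it is configurable; class counts (especially UNCHANGED) are sensitive to it. |

## Motif identity and merging

A motif key is (protein accession, sorted tuple of 1-based protein
positions of the phosphosites). This is the only identity under which
charge, oxidation **and** missed-cleavage variants all collapse;
peptide-string identity would fail to merge missed cleavages. Sites are
localized by finding the peptide in the protein: peptides occurring more
than once are ambiguous and excluded (counted and logged), peptides of
accessions absent from the FASTA fall back to a peptide-sequence key
that merges charge/oxidation but not missed-cleavage variants.
Abundances are summed per sample; summation conserves per-sample totals
up to floating-point associativity (verified at 1e−12 relative).

## Sequence windows and CK2 matching

Windows are site ± 7 residues (15 long), positions beyond the termini
padded with `X`. The six combined CK2 patterns' union is exactly "centre
S or T and ≥ 1 of D/E at +1..+3" (the pattern `S/T-D/E-X/D/E` is read as
D/E at +1 with a free +2, hence subsumed by `S/T-D/E`); patterns are
retained individually so matches can be reported per pattern. `X`
padding never counts as acidic. Centre-Y windows never match (CK2 is an
S/T kinase).

## Probability-logo statistics

The background is the set of 15-mers centred on **every S, T and Y** in
the proteome — conditioning the background on phosphorylatable centres
matches the construction of the foreground; a whole-proteome residue
composition is available by flag. Per residue × offset the score is the
signed log₁₀ of the exact binomial tail (`scipy.stats.binom`), positive
above the axis for overrepresentation. `X` positions are excluded from
both foreground counts and background probabilities, so terminal padding
can never reach significance; the fixed centre (offset 0) is not scored.
The default significance line is Bonferroni over the 20 × 14
residue-position tests, `−log₁₀(0.05/280) ≈ 3.75`; this bounds the
family-wise error at 5% **per direction** (over- or under-representation
each form 280 one-tailed tests). A residue observed in the foreground
with background probability zero receives a `+∞` sentinel and a flag.

## Synthetic data: what it emulates, what it does not

The generator emulates the study conditions: three groups (parent,
overexpression, inhibitor) × 5 replicates; 1520 single-site motifs over
400 random proteins (uniform residue usage, 200–600 aa); each motif
observed as 1–4 variants with Dirichlet(1,…,1) intensity split, charge
drawn from {2,3,4}, missed cleavage extending across the preceding K/R
with probability 0.3, methionine oxidation tagging with probability 0.2.
Base abundances are log-normal (μ = 14, σ = 1.5 on the natural-log
scale, i.e. median ≈ 1.2 × 10⁶ ion counts); replicates multiply the
group mean by mean-one log-normal noise at 20% CV. Planted classes per
treatment default to 11.3% UP / 2.2% DOWN (overexpression) and the
mirror (inhibition) with fold changes Uniform[1.5, 4] — the classified
fractions of the motivating experiment. CK2 contexts are planted by
rewriting +1..+3 to D/E for the configured fraction of sites and
de-acidifying +1..+3 elsewhere (replacement residues avoid K/R so the
tryptic digest is unchanged), making the planted fraction exact; an
optional per-class fraction map lets enrichment studies plant contexts
class-dependently. Everything derives from one `numpy` Generator seed,
so outputs are byte-identical across runs.

Not emulated: multi-site motifs, missing intensities, identification
error, site-localization ambiguity, protein-level abundance structure
independent of the phosphopeptides, correlated effects between
treatments, and non-uniform residue usage. Passing recovery tests
therefore show the statistics behave as designed under the model's
assumptions — not that those assumptions hold for any particular real
dataset.

## Calibration results the tests compute

- Null (no effects, 5% CV, n = 5, 1000 motifs): ≥ 95% of motifs
  UNCHANGED; raw *t*-test rejections at the nominal 5% within binomial
  tolerance. The compound UP/DOWN rule fires far below 5% because the
  fold-change gate almost never passes at 5% CV.
- Planted effects (20% UP at 2–4 fold, 20% CV): ≥ 90% of planted UP
  motifs recovered as UP, none flipped to DOWN.
- Logo null (foreground drawn from the background, 200 windows, 100
  replicates): overrepresentation crossings of the Bonferroni line in
  ≤ 5% of replicates.

## Numerical choices

- Binomial tails switch to `logsf`/`logcdf` when the direct tail
  underflows double precision.
- Result tables are written with `%.12g` (12 significant digits) and
  round-trip within half an ulp of the 12th digit.
- Table parsing sniffs comma/tab delimiters and tolerates a UTF-8 BOM;
  missing intensity cells read as 0.0 (label-free exports are dense),
  with a strict mode to reject them.
- Problem sizes in tests (hundreds of motifs, 100-replicate logo nulls)
  were chosen so the full suite runs in seconds while keeping binomial
  tolerances meaningful.

## Known limitations

- **Totals-based normalisation drifts under asymmetric perturbation.**
  When a large one-sided fraction of signal moves (e.g. 20% of motifs up
  3-fold), equalising column totals scales the treatment down ~1.2-fold,
  shifting unchanged motifs toward DOWN and inflating their false-call
  rate above the nominal level (measured ~12% in that regime vs ~1%
  under the default mildly asymmetric proportions). This is a property
  of the published normalisation scheme, reproduced faithfully; a
  reference-feature or median-ratio normalisation would mitigate it but
  is deliberately not the default.
- The TOST margin is a modelling choice (see above); published
  UNCHANGED counts cannot be reproduced exactly without knowing it.
- Peptides mapping to repeated regions or shared between proteins are
  excluded/keyed conservatively rather than apportioned.
- The equal-variance t-test assumes homoscedasticity on the transformed
  scale; no moderation (empirical Bayes) is applied.
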