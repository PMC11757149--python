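# Methods

## The analysis in brief

`motifcons` quantifies whether the sequence flanking a transcription-factor
binding site is under stronger constraint in species that carry the site than
in species that lack it. The motivating system is the hexamer CTGTCA — the
recognition sequence of the SHOOTMERISTEMLESS (STM) homeodomain protein —
found in the promoters of *STM* orthologues of Brassicaceae species whose
fruits undergo a gynoecium-to-fruit shape change, and absent in species whose
fruits do not. The analysis proceeds in four steps:

1. **Scanning and window extraction.** Promoters are scanned for exact
   consensus matches (forward strand by default; the element is defined in a
   fixed promoter orientation). From an aligned panel, the six alignment
   columns covering a reference motif plus a flank on each side are
   extracted, and rows are partitioned into a *with-site* and a
   *without-site* group by exact consensus match of the window centre. The
   20-column window (7-column flanks) is used for sequence logos; the
   entropy profiles use 12-column flanks by default (18 is supported).
2. **Conservation profiling.** For each group and each flank, the mean
   Shannon entropy H = −Σ p_b log₂ p_b (bits) of every 6-bp window is
   computed. 0 bits means an invariant window; 2 bits a window uniform over
   the four bases.
3. **Neutral reference.** From a codon alignment of orthologous coding
   sequences, all third codon positions belonging to a fourfold-degenerate
   family in every sequence are collected. Each null replicate draws six
   distinct such columns, averages their entropies, and this is repeated
   1,000 times; the resulting ensemble approximates the entropy of
   neutrally evolving sequence at matched sample size (six columns, the
   same number a 6-bp window contains).
4. **Comparison.** Two-sided Mann–Whitney U tests are run among the three
   samples (with-site windows, without-site windows, null replicates), and
   the group medians are reported.

The package also implements the study's phenotype quantifications: the
shoulder index θ = arctan((L1 − L2)/W) scoring valve-shoulder protrusion of
the heart-shaped *Capsella* fruit, relative expression by the 2^−ΔCT method
against an internal reference gene, one-sided Student's t-tests with
*/**/*** star coding at 0.05/0.01/0.001, and the cross-species 2×2
association between motif presence and shape change (concordance fraction
plus two-sided Fisher exact test, no phylogenetic correction).

## Model objects

The core is exposed statsmodels-style: `FlankConservation` is constructed
from the two window sets (or via `from_panel` from an aligned panel and an
anchor hit) plus an optional CDS alignment; `fit(seed=...)` returns a
`FlankConservationResults` holding the profiles, the null ensemble, the
tests and a `summary()` table. The spec-level operations
(`find_motif`, `extract_windows`, `window_scan`, `build_null`,
`compare_groups`, `logo_matrix`, …) remain importable functions; the model
simply composes them.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| consensus | `CTGTCA` | binding-site hexamer (exact matching; N never matches) |
| flank_len | 12 bp | flank profiled on each side of the hexamer (12 or 18 in the source protocol) |
| width | 6 bp | scan window width |
| display_step | 1 bp | step of the descriptive sliding profile |
| test_step | = width | step of the windows pooled into the test samples |
| n_null / k | 1000 / 6 | null replicates; distinct fourfold sites per replicate |
| exact_bound | 400 | largest n1·n2 for the exact tie-free U distribution |

### Overlapping profiles, tiled tests

"Every 6 bp in a sliding-window mode" can be read as overlapping (step 1)
or tiled (step 6) windows; both are implemented and the step is recorded in
all outputs. The *descriptive* profile defaults to step 1 because it is the
more informative picture. The *test* samples default to tiled windows
because overlapping window means share columns: adjacent step-1 windows
overlap in five of six columns, so treating them as independent
observations in a rank test would understate the null variance of U and
inflate the false-positive rate. With tiled windows the window means within
a group are functions of disjoint column sets and — columns being
independent under the generator — genuinely independent observations. The
calibration test in the suite verifies that the comparison then holds its
nominal 5% level.

Window means pooled across the 5′ and 3′ flanks form one sample per group
(the pooling convention is echoed into the run metadata). Entropies use
log₂ (bits), matching the sequence-logo convention; gaps and N are excluded
from counts, and a column with fewer than two informative rows is flagged
missing and excluded from window means (with the effective column count
recorded) rather than scored 0.

### Rank-test method selection

Tie-free samples with n1·n2 ≤ 400 use the exact U distribution. Small tied
samples (C(n1+n2, n1) ≤ 20,000 labelings) use an exact midrank
label-permutation enumeration, so that e.g. two identical samples report
p = 1 exactly. Larger samples use the normal approximation with tie and
continuity corrections. The method actually used is recorded in every
`TestResult`.

## The synthetic-data generator

No sequence panel ships with the package (the study panel was obtained by
TAIL-PCR and is not machine-readable), so `motifcons.simulate` generates
panels with the statistical structure the analysis assumes, plus a truth
sidecar (motif coordinates, group labels, fourfold columns) consumed only
by tests and QC.

* **Promoter panel.** A single ancestral 200-bp scaffold is drawn uniformly
  over {A,C,G,T} with the consensus planted at position 100 (leaving the
  ATG imagined at the scaffold end, so upstream-distance reporting is
  exercised). Each species mutates every non-centre position independently
  at its group's per-column substitution probability, substituting to one
  of the other three bases uniformly — the simplest neutral model, with no
  tree structure and no indels. With-site sequences are rejection-sampled
  to contain exactly one consensus match; without-site sequences receive a
  diverged centre (≥ 1 mismatch, or the canned non-functional variant
  ATATAA) and are rejection-sampled to contain none, with a bounded retry
  count so an unsatisfiable `center_mut_prob` fails loudly.
* **Defaults are the study conditions**: group sizes 21/28, substitution
  probabilities 0.01 (with-site) versus 0.30 (without-site), 12-bp flanks.
* **CDS alignment.** An ancestral gene is assembled with an exact share
  (`fourfold_fraction`, default 0.5) of codons from the eight
  fourfold-degenerate families and non-fourfold sense codons elsewhere;
  rows substitute only the third base of fourfold codons
  (`third_pos_sub_prob`, default 0.1 — a field the generator needs so the
  null is non-degenerate), keeping every substitution synonymous and the
  truth columns exactly the ancestral fourfold positions.
* **Phenotypes.** Fruit measurements are Gaussian around per-genotype means
  (defaults sketch a heart-shaped wild type, L1 > L2, against a
  reduced-shoulder allele at a plausible µm scale), truncated so W stays
  positive; CT tables put the noise on the ΔCT scale against a fixed
  reference CT.

Because columns are independent and groups share one ancestor, the
generator realises exactly the exchangeability the rank test assumes under
the null and a clean monotone effect-size dial
(|sub_prob_without − sub_prob_with|) for power checks. What it does *not*
emulate: phylogenetic correlation among species, indels and alignment
error, base-composition bias, and heterogeneous rates along the flank. A
passing suite therefore validates the machinery and its calibration under
idealised sampling, not robustness to tree-structured non-independence —
on real panels the rank test shares the usual caveat of treating species
as independent observations.

## Numerical and edge-case choices

* Coordinates 0-based half-open internally; human-readable upstream
  distances are 1-based and measured to the motif's 3′-most base by default
  (a `start` convention is available and the choice is echoed in outputs).
* An all-gap column raises rather than scoring 0; window means skip missing
  columns and record the effective count.
* Null sampling is without replacement within a replicate; fewer usable
  fourfold sites than k is an error, never silent replacement sampling.
* Logo information content is IC = 2 − H, optionally minus the small-sample
  correction e(n) = 3/(2·ln 2·n), floored at 0.
* θ is reported in degrees by default (radians behind a flag); technical
  qPCR replicates are averaged on the CT scale before ΔCT.
* Internal stop codons and gapped codons abort fourfold extraction with the
  offending row named; a terminal stop is tolerated.
* Type-I calibration in the test suite uses identical substitution
  probability (0.1) for both groups with the study group sizes (21/28);
  problem sizes throughout the suite (e.g. 200 calibration panels, 100
  recovery panels, 100 oracle draws) were chosen as the smallest giving
  stable verdicts for the binomial bounds being checked.

## Known limitations

* Exact consensus matching only — no position-weight-matrix scores, no
  degenerate matching; this mirrors the presence/absence logic of the
  source analysis.
* The pipeline consumes pre-aligned input; it never runs an aligner.
* The without-site "counterpart region" is defined by alignment column
  (not by flanking-anchor homology), and this convention is recorded in
  the window outputs.
* The association between motif presence and phenotype is descriptive;
  species are not independent samples and no phylogenetic comparative
  correction is attempted.
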