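# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of the package. Nothing here states an empirical result
that the test suite or the acceptance script does not itself compute.

## 1. Differential selection

**Per-cohort rule.** Each cohort contributes one pooled metastatic (M)
and one pooled metastasis-free (non-M) plasma sample, quantified at the
peptide level. For proteins with ≥ 2 peptides, the paired unit is the
peptide: a paired *t*-test on log2 peptide abundances (M vs non-M), kept
at *p* < 0.05. Single-peptide proteins are kept only when the peptide
maps to a unique protein and its identification score (natural-log
likelihood of the peptide-spectrum match) is ≥ 6.0; they are then
selected on fold change alone. Every candidate additionally needs a fold
change strictly beyond 1.25 in either direction (a value of exactly 1.25
is excluded).

**Protein-level fold change** is the ratio of peptide-abundance *means*
(configurable to medians): pooled peptide signal is additive, so the
mean mirrors how a protein-level quantity would accumulate. All
log-scale work uses log2.

**Loess normalization.** Protein-level log2 abundances are normalized
per sample against the row-wise median reference profile: the sample's
deviation from the reference (M-vs-A style) is smoothed against
reference abundance with lowess (default span 0.3) and subtracted, then
the sample is re-centred so its median equals the reference median. A
constant offset between samples is removed exactly; samples that already
match the reference are returned unchanged.

**Four-cohort concordance.** On the normalized protein table, a protein
is concordantly up when (i) FC > 1.25 in ≥ 3 of 4 cohorts, (ii) no
cohort has FC < 1/1.25 (opposite-direction veto), and (iii) a paired
*t*-test across the four cohort-level (M, non-M) log2 pairs gives
*p* < 0.1 (symmetric rule for down). The concordance stage runs on the
*full* protein table, not only on per-cohort candidates: the two stages
are separate analyses. Chaining them (requiring per-cohort candidacy in
the concordant cohorts) roughly halves sensitivity on synthetic data
with 2–5 peptides per protein, because a 3-peptide paired *t*-test at
*p* < 0.05 is underpowered; the tests quantify this trade-off.

**Degenerate tests.** A paired *t*-test with all differences exactly
zero returns (t = 0, p = 1). Zero variance with a nonzero mean
difference (the zero-noise planted case: every cohort shows the same
fold change) is flagged degenerate and reported at the smallest
representable p — the evidence against the null is unbounded, so
degenerate results count as significant at any threshold. Variance below
1e-10 relative to the mean difference is treated as zero to absorb
floating-point noise in log ratios.

**Multiple testing.** No correction is applied by default; a
Benjamini–Hochberg option (`adjust="bh"`) is available.

## 2. Interaction network

Scored edges use the 0–1000 STRING combined-score convention and are
kept only when strictly greater than 500; curated edges carry confidence
1000 and bypass the threshold. Duplicate undirected edges keep the
highest confidence; self-loops are dropped. Hub candidates are ranked by
the number of distinct seed proteins they touch, ties broken
alphabetically; exclusion-listed symbols (default: ALB, which dominates
plasma interaction counts) are skipped and reported with their counts.

Topology conventions: local clustering of degree-0/1 nodes is 0 (so the
mean is defined on every graph); the characteristic path length averages
over ordered *connected* pairs only, since progression-protein seed
networks typically contain isolated nodes; mean degree is 2E/N. Layers
are minimum BFS distance to any upstream-regulator node (layer 0),
unreachable nodes one layer below the deepest reachable one. The
topology report is computed both for the bare seed network and after hub
and regulator augmentation, since the two variants answer different
questions. Published topology values for the original study's network
(clustering 0.145, mean degree 2.444, path length 2.920) depend on the
interaction-database version and are not reproduction targets.

Gene-set enrichment is an upper-tail hypergeometric test per term
against a user-supplied annotation (GMT-style), BH-corrected across
terms.

## 3. Cross-species refinement

Mouse prediagnostic fold changes F10/F20 (fast group) and S10/S20 (slow
group) are ratios of prediagnostic-1/-2 abundance to baseline. Selection
uses F20 strictly greater than 1.3; F10/S10/S20 are reported but not
filtered on. Human–mouse matching is case-insensitive symbol equality —
no orthology database. "Tumor-intrinsic" means spectral count ≥ 1 in
≥ 1 cell line of the panel (both thresholds configurable). Secretome
concordance uses metastatic/non-metastatic conditioned-media ratios from
two independent cell-line pairs: ≥ 1.5 in both (up) or ≤ 0.67 in both
(down), boundaries *inclusive* — note the asymmetry with the strict
plasma and mouse cutoffs, which follows the stated rules. The refined
signature is the alphabetically ordered set of proteins up in the human
metastatic contrast, present in the mouse F20 set, and tumor-intrinsic;
it is rule-derived, never a hard-coded gene list.

## 4. Survival evaluation

The risk score is the per-patient mean of the signature genes'
expression. Genes are z-scored across patients before averaging
(default): an unweighted mean of raw expression is dominated by the
highest-expressed gene when scales differ; the literal unstandardized
mean is available with `standardize=False`. The top quartile
(`high_fraction=0.25`, exactly ⌈0.25·N⌉ patients, ties broken by cohort
order) is High Risk. Note the original study reports n = 40/170 of 210,
which is not an exact quarter; the fraction is configurable.

Groups are compared by Kaplan–Meier product-limit curves, the two-group
log-rank test (chi-square, 1 df), and Cox proportional-hazards models
(lifelines, Efron tie handling; Breslow is not implemented). Univariate
mode fits each covariate alone; multivariate mode fits the risk group
together with the configured clinical covariates. Clinical dichotomies:
stage 0–1 vs 2–4, pre vs post menopause, grade 1–2 vs 3, size < 31 mm vs
≥ 31 mm. Confidence intervals are 95% Wald. Pearson correlation with a
reference regulator (default TGFB1) uses the two-sided *t*
approximation; zero-variance genes are flagged, not errored.

## 5. Synthetic study generator

The generator emulates the study's five inputs with one seeded RNG
(`numpy` PCG64 via `SeedSequence`; every sub-table draws from a
deterministically derived child stream, so identical (config, seed)
yields byte-identical outputs).

Stated scale anchors: 1618 quantified plasma proteins, 4 cohorts
(menopause × stage), 210-patient survival cohort, 17 TNBC cell lines,
planted fold change 1.6, planted hazard ratio 1.8.

Free parameters chosen once (neither the paper nor any stated condition
fixes them), with rationale:

| parameter | default | rationale |
|---|---|---|
| `noise_cv` | 0.2 | peptide-level lognormal measurement noise; plausible for label-based pooled MS |
| `fraction_single_peptide` | 0.30 | share of proteins identified by one peptide in deep plasma profiling |
| `mean_extra_peptides` | 2.0 | multi-peptide proteins have 2 + Poisson(2) peptides |
| `fraction_low_score` | 0.15 | single-peptide identifications with score < 6.0 |
| `fraction_multi_mapped` | 0.05 | peptides mapping to several proteins |
| `mouse_noise_cv` | 0.1 | pooled longitudinal samples from an inbred strain vary less than cross-patient pools |
| `mouse_effect_f20` | 1.6 | planted mouse rise; gives an expected F20 > 1.3 pass rate ≈ 0.93 at cv 0.1 |
| `censor_rate` | 0.30 | independent exponential censoring fraction in the low-risk group |
| `baseline_hazard` | ln2/5 per year | median ~5-year survival in the low-risk group |
| `tgfb_correlation` | 0.45 | signature–TGFB1 correlation via a shared latent factor |
| secretome planted sets | 60 up / 50 down | scaled-down from the original media proteome to the shared 1618-protein namespace |

Noise is multiplicative lognormal with unit mean
(σ² = ln(1 + cv²)), so linear-scale expectations equal the planted
effects and log fold changes are normal with zero bias. At cv = 0 every
threshold decision is exactly predictable from the planted truth, which
is what the end-to-end planted-truth tests exploit.

Structural conventions of the planted truth: progression proteins are
always multi-peptide (a planted effect hidden behind an unreliable
single-peptide identification would be unfalsifiable); the human∩mouse
common set, the cell-line-undetected subset and the signature are nested
so the refinement chain has one exact expected outcome; the survival
cohort assigns the hazard multiplier to the top-quartile group defined
by the same scoring rule the analysis uses.

**What the generator does not emulate:** per-patient plasma variation
(pools are simulated directly), peptide-level missingness, shared
peptides between proteins affecting quantification (mapping multiplicity
is metadata only), batch effects, real orthology, correlated clinical
covariates, and non-proportional hazards. A green planted-truth test
therefore establishes rule correctness and statistical calibration under
this model — not robustness to the artefacts of real MS data.

**Known sensitivity:** with peptide cv 0.2, single-peptide null proteins
have per-cohort log2-FC standard deviation ≈ 0.405, so ≈ 5% of them
cross the 1.25 concordance rule in ≥ 3/4 cohorts by chance; the
false-discovery proportion of the differential stage then sits near 0.2
at the default 30% single-peptide fraction (the acceptance test reports
the exact per-seed values). This reflects the method's real weakness —
fold-change-only selection of single-peptide proteins — rather than an
implementation artefact.

## 6. Pipeline

Stages run in order (simulate or load → differential → network →
integrate → survival → report) with thresholds echoed at start and a
plain-text + JSON report; wall-clock timestamps go only to the log file
so fixed-seed runs are byte-identical. Config files are INI
(`[run]`, `[simulation]`, `[inputs]` sections). When the refined
signature contains genes absent from the survival cohort's expression
table, the available subset is evaluated and the missing genes are
reported (mirroring how validation cohorts lack some genes).

## 7. Open choices made here

- The cross-cohort "paired" unit is the cohort-level (M, non-M) protein
  pair; within a cohort it is the peptide. Both thresholds (*p* < 0.05
  per cohort, *p* < 0.1 combined) are exposed as configuration.
- The opposite-direction veto interprets "concordant": a protein up in
  3 cohorts but crossing the down threshold in the 4th is excluded.
- Hub pools: pool 1 is proteins quantified in all 4 cohorts; pool 2 is
  proteins with |FC| beyond 1.25 in ≥ 3/4 cohorts regardless of
  direction concordance (the direction requirement is left to the
  concordance stage).
- Whether the original analysis z-scored genes before averaging is
  unstated; standardization defaults on here, with the literal mode
  available.
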