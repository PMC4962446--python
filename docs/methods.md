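# Methods

`panelsim` studies a practical question in clinical cancer genomics: when a
tumor is sequenced **without** a patient-matched normal sample, how many of
the reported "somatic" mutations are actually inherited germline variants,
how does that error rate depend on the patient's ancestry and on the
germline databases used for filtering, and how well do targeted gene panels
recover exome-wide mutational and neoantigen load? The package implements
the full analysis pipeline (filtering, downsampling, performance metrics,
ancestry comparison, load statistics) together with a synthetic cohort
generator so every stage is testable end-to-end without access to protected
patient data.

## The filtering model

A tumor-only call set is filtered in four fixed steps:

1. **Allelic-fraction gate.** Calls with allelic fraction below a floor
   (default 0.05, i.e. the conventional ≥5 % gate for high-confidence
   calls) are dropped. The same gate applies to matched-truth construction,
   keeping the two arms comparable.
2. **Database membership.** A surviving call is a *hit* if its variant key
   `(chrom, pos, ref, alt)` is a member of **any** database named by the
   strategy (union semantics). Union is the only reading under which adding
   databases to a strategy is meaningful: filtering is strictly destructive.
3. **Hotspot rescue.** A hit is kept anyway when rescue is enabled and the
   somatic catalog (COSMIC-like recurrence counts) records the key at least
   `rescue_threshold` times. Thresholds take the graded stringencies
   1/3/5/10; 0 disables rescue. Rescue applies only to database hits —
   a non-hit needs no rescue and a high catalog count confers no other
   special handling.
4. **Scoring.** With truth available, retained calls are classified by key
   against the patient's true somatic and germline sets:
   sensitivity = TP/(TP+FN), PPV = TP/retained, fp_rate = FP/retained, so
   PPV + fp_rate = 1 under complete truth. Undefined ratios are reported
   as absent, never as zero. The strategy sweep pools counts over patients
   (never averaging per-patient ratios) and selects the optimum by
   maximizing sensitivity × PPV, ties broken toward sensitivity; the
   selection objective is a package choice, since only the identity of the
   optimum — the largest database plus rescue at the n ≥ 10 stringency —
   is given in the source material.

The PPV denominator is all **retained** calls (the standard definition).
The alternative reading, all pre-filter calls, would make PPV independent
of filtering stringency and inconsistent with a 14 % false-positive rate
among reported variants; this interpretation is deliberate and documented
here.

## The synthetic cohort generator

The generator's defaults are the study conditions: 157 patients (82 lung /
75 colon adenocarcinoma, ~12 % self-reported non-European ancestry).

**Somatic burden.** Per-patient exome-wide somatic counts are hierarchical
Poisson–lognormal, `N_i ~ Poisson(Lognormal(μ, σ))`, with
μ = ln 75 and σ = 0.66 (matching a median of 75 and IQR of roughly
55–134 mutations per matched exome), plus a cancer-type shift of ±0.15 on
the log scale (lung above colon). The Poisson layer matters: when σ → 0
the burden degenerates to pure Poisson, under which the pooled ancestry
contingency cells become independent Poissons with multiplicative means and
Fisher's conditional test is *exactly* calibrated — the property the null
configuration (`null_config`) exploits for type-I-error checks.

**Germline contamination.** Unmatched calling admits a Poisson number of
residual germline variants per exome (mean 370, the gap between the
unmatched and matched median counts, 445 − 75). Variants are drawn without
replacement from three disjoint pools:

| pool | size | European mix | non-European mix |
|---|---|---|---|
| common-shared | 30 000 | 0.85 | 0.60 |
| ancestry-specific | 8 000 | 0 | 0.25 |
| private-rare | 60 000 | 0.15 | 0.15 |

Each database is an independent Bernoulli thinning of each pool:

| database | common | ancestry-specific | private-rare | hotspot |
|---|---|---|---|---|
| dbsnp | 0.965 | 0.15 | 0.30 | 0.50 |
| thousand_genomes | 0.93 | 0.35 | 0.25 | 0.30 |
| exac | 0.96 | 0.86 | 0.40 | 0.45 |

The three-pool structure is the minimal mechanism that produces the
ancestry disparity: small databases cover the ancestry-specific pool
poorly, so non-European germline variants survive filtering more often.
Under these coverages the expected variant-level odds ratios
(non-European vs European odds of a retained variant being a germline
false positive) are ≈ 2.5 / 1.8 / 1.2 for dbSNP / 1000 Genomes / ExAC
filtering, chosen analytically to reproduce the published disparity
pattern; with ExAC the two ancestries' in-database fractions differ by
less than five percentage points, so the disparity collapses.

**Hotspots and the somatic catalog.** A fraction (0.10) of somatic
mutations recur from a shared 400-variant hotspot pool whose catalog counts
are lognormal (median 25, log-sd 0.9), so most hotspots clear the n ≥ 10
rescue bar. A thin layer (5 %) of germline pool variants also appears in
the catalog at low geometric counts (annotation noise, mean < 3). This is
precisely what graded rescue trades off: low thresholds rescue germline
noise back into the report; the top threshold rescues essentially only
true hotspots, which is why the full-database + rescue-10 recipe maximizes
sensitivity × PPV at exome scale.

**Genes and panels.** Gene assignment uses capture probabilities, not real
coordinates: somatic mutations land in large/medium/small panel genes with
probabilities 0.053 / 0.027 / 0.013 (calibrated from matched per-patient
medians of 4/2/1 over a median burden of 75 — cancer panels are strongly
enriched for mutated genes), while germline variants land uniformly over an
18 000-gene universe (so panel capture of contaminants is proportional to
panel size). The shipped placeholder panels have the correct sizes
(300/48/15), are disjoint rather than nested, and are drop-in replaceable
by real gene lists. Territories default to 1.5 kb of coding sequence per
gene (0.45 / 0.072 / 0.0225 Mb) and 30 Mb for WES; all are
config-overridable because true panel territories are assay-specific.

**Allelic fractions.** Somatic AF ~ Uniform(0.05, 1); germline
AF ~ Normal(0.5, 0.1) truncated to [0, 1]. This keeps the ≥5 % gate
exercisable without a tumor-purity model.

**Neoantigens.** Each somatic mutation yields a Poisson(2) number of
candidate 9/10-mer peptides with lognormal affinities
(log-mean ln 2000, log-sd 2), giving a binder fraction
P(affinity < 500 nM) ≈ 0.24 and a median of ≈ 38 predicted binders per
exome. A binder is *recovered* by a panel iff its source mutation survives
in the panel data (source-mutation level; identical peptides from
different mutations are not deduplicated).

**Determinism.** All draws flow from the single config seed through one
generator in a fixed order (pools → hotspots → catalog → databases →
patients in index order); neoantigen streams derive from
(seed, patient-id) so they are order-independent. Identical configs give
bitwise-identical cohorts and byte-identical report bundles.

## Statistics

**Fisher's exact test.** The ancestry comparison builds a variant-level
2×2 table — rows ancestry, columns (retained germline FP, retained true
somatic), pooled over patients — because patient-level threshold counts
cannot reproduce odds ratios of the published magnitude; the per-patient
burden table is emitted alongside for transparency. The two-sided p-value
follows the classical probability-mass rule (sum of hypergeometric
probabilities of all margin-preserving tables no more probable than the
observed one). For table totals ≤ 2000 it is evaluated in exact integer
arithmetic, so ties are resolved without floating-point ambiguity; above
that, the identical sum is evaluated from vectorized log-pmf values with a
1e-12 tie tolerance. The odds ratio is the sample (a·d)/(b·c) with
zero-cell convention ∞ / 0 / NaN; a Haldane–Anscombe-corrected value is
emitted as a labeled secondary quantity, never substituted.

**Other statistics.** Pearson correlation (and its t-transform p-value)
comes from `scipy.stats.pearsonr`; r² is reported with the signed r kept
alongside. Quantiles use linear interpolation between order statistics
(the numpy default) — the convention is declared here because the source
material does not state one. Printed percentages round half-away-from-zero
at the requested number of decimals, with the exact fraction always
returned alongside.

## Numerical and degenerate-input choices

* Zero-denominator ratios (empty retained set, no truth somatic, no exome
  binders) are absent (`None`), never zero.
* A zero row or column margin makes Fisher's test undefined: the operation
  raises, and the study runner records the entry as undefined (this is the
  expected outcome of a zero-contamination cohort).
* Only SNVs are modeled; indel-like rows are rejected at parse time with
  the offending row number.
* The AF gate is `>=` (a call exactly at the floor is kept).
* The binder threshold is strict (`< 500 nM`).

## Problem sizes used in the shipped checks

The test suite exercises the default 157-patient cohort for the
seed-fixed qualitative reproductions (disparity pattern, load-correlation
ordering, sweep optimum), a 500-patient cohort for parameter recovery, and
1000 scaled-down null cohorts (40 patients, ancestry-independent coverage,
near-Poisson burden) for the type-I calibration of the Fisher
implementation. The acceptance script runs the default study once and
additionally measures the database odds ratios on a 1000-patient
simulation, where the coverage-driven odds ratio is estimated precisely;
at 157 patients the odds measurement carries ~16 % noise dominated by the
small non-European group's somatic-burden total.

## What the generator does and does not emulate

It reproduces: heavy-tailed per-patient burdens in two cancer-type strata,
hundreds of residual germline variants per unmatched exome,
ancestry-dependent database coverage, hotspot recurrence with graded
catalog counts, panel capture fractions, and affinity-thresholded
neoantigen candidates. It does **not** simulate reads, sequencing error,
FFPE/oxidative artifacts, tumor purity or clonality, sample contamination,
real gene coordinates, linkage between germline variants, or HLA-specific
binding. Consequently, passing tests demonstrate the correctness and the
qualitative behavior of the analysis pipeline under the modeled
mechanisms — not the exact error rates of any real assay. Two visible
consequences: the synthetic matched large-panel load correlation reaches
r² ≈ 0.74 rather than the near-perfect value seen in real cohorts (the
real dynamic range includes hypermutators far beyond a lognormal
calibrated to the median/IQR), and per-patient false-positive burdens are
Poisson-thin, so the tail fraction of patients with many false positives
is smaller than in real data.

## Known limitations

* Ancestry is a binary label (European / non-European), mirroring the
  modeled analysis; finer strata would require per-stratum pools.
* The placeholder panel gene lists are size-correct but arbitrary; real
  panel analyses must supply the true lists as files.
* The variant-level contingency table treats variants as independent;
  shared pool variants across patients induce a small positive dependence
  at default pool sizes (negligible in the shipped checks, quantified by
  the type-I calibration).
* `rescue_threshold` is restricted to the graded set {0, 1, 3, 5, 10}.
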