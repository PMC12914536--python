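# Methods

This note records the statistical model behind each operation, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Normalization and layers

Counts are library-size scaled to a target sum of 10,000 per cell and
transformed with the natural `log1p` — the de facto single-cell standard.
The normalized layer is always recomputed from counts plus the recorded
`NormalizationConfig`, so normalization is idempotent and auditable.
Cells with zero total counts are refused rather than silently dropped.
Scores are computed on the normalized layer by default; the counts layer
is available for sensitivity analysis, since sum-scores on CPM-log data
and on raw counts can disagree when library sizes vary strongly.

## Signature scores

The per-cell score is the **sum** of the chosen layer over the
signature's genes (mean available as an option). Sum-scores keep the
group-level "total score" readable and are linear, which the tests
exploit (disjoint signatures add). Missing genes never fail silently:
coverage and the gene count used are part of every `ScoreVector`.

No background/control-gene correction is applied (bin-matched control
scoring à la the common "module score" is deliberately out of scope).
Consequence: sum-scores inherit compositional effects of CPM
normalization — a cell that up-regulates one scored program slightly
deflates the normalized values of all other genes. With realistic gene
abundance distributions the effect on rank correlations is below 0.01
(measured on the generator's null), but it is a known limitation for
small transcriptomes or very large signatures.

## Gene-symbol harmonization

Two deterministic steps: the target species' case convention (mouse
Title-case; human/pig/macaque upper-case), then a packaged alias table
(`Tmem173→Sting1`, `Mb21d1→Cgas`, `Figf→Vegfd`, `Pigf→Pgf`). Signature
files are parsed verbatim; aliasing happens only when a signature is
matched against a matrix, so published gene lists survive round-trips
unchanged. Unknown symbols pass through with a log line — cross-species
alias tables are incomplete by nature and a hard failure would be worse.
The case rule mangles the rare symbol whose official form deviates
(e.g. MHC locus genes); such genes need explicit alias entries.

## Annotation and angiogenic-EC calling

Cells are labeled by marker argmax: the panel cell type with the highest
mean normalized marker expression. Exact ties abstain (`unassigned`), as
does any cell whose best-vs-second margin falls below `min_margin`
(default 0). This is a per-cell, deterministic replacement for
cluster-level annotation; a cluster labeling is recovered by majority
vote over any clustering column supplied in `cell_meta`. The packaged
retinal panel is a literature-standard assembly (marked `synthetic` in
its filename — it is an editable default, not a transcription of any
single published panel).

Angiogenic ECs are called from the additive score of the activation
program (Mki67, Cxcr4, Dll4, Aplnr, Esm1). Default mode is quantile
q = 0.75 — the top quartile of EC activation scores — because no absolute
cutoff generalizes across datasets; a fixed-threshold mode exists for
calibrated settings. By construction the called fraction is 1 − q up to
ties.

## Correlation testing

Spearman ρ uses midrank ties (Pearson on ranks). p-values:

- `exact` (n ≤ 9): full enumeration of all n! rank permutations;
  two-sided by |ρ| with a 1e-12 tolerance at the boundary. Constant
  vectors are an error, not a NaN.
- `permutation`: seeded Monte-Carlo with the add-one estimator
  (p ≥ 1/(B+1)); default B = 10,000 for publication-grade runs.
- `t`: the usual t-approximation (scipy), default above n = 9.

The exact route is verified in the tests against an independent
enumeration oracle that computes ρ through the 6Σd²/(n(n²−1)) formula.

## Enrichment

`ks_enrichment` wraps the two-sample KS test: the exact small-sample
distribution is used when `n_a·n_b ≤ 10,000` **and** the pooled sample is
tie-free; with ties the continuous-case exact distribution is not the
conditional permutation law, so the asymptotic form is used instead.

`gsea_es` implements the weighted running sum: hits increment by
|score|^p normalized to one in total (p ∈ {0, 1}; p = 0 is the classic
KS-style statistic), misses decrement by 1/(N − N_h); the ES is the
signed maximum deviation, first occurrence on ties. Ranking ties are
broken by stable input order. The null permutes gene labels (random hit
positions) with a mandatory seed; the nominal p and NES are computed
within the observed sign class, add-one estimator. If every hit weight
is zero under p = 1, the statistic falls back to unweighted hits to stay
defined.

## Stratification and contrasts

Tertile (general k-quantile) stratification sorts scores with a stable
sort and chunks the order into k nearly equal groups — boundary ties go
to the lower stratum first, so group sizes always differ by ≤ 1 and the
partition depends only on ranks. Pairwise stratum contrasts use
two-sided Mann-Whitney tests (p = 1 returned for degenerate all-equal
comparisons, where the asymptotic variance vanishes). The ordered-trend
statistic is Jonckheere-Terpstra with pair-ties counted ½, normal
approximation with the no-tie variance (conservative under heavy ties; a
fully constant input reports the null mean). High-vs-low single-gene
contrasts use median halves or tertile extremes; log₂ fold change is
computed on group means of the normalized layer with pseudocount
ε = 1e-9, recorded in the result.

## The synthetic generator

What it emulates: several cell types with distinct marker programs; an
EC subset whose cells carry a bivariate-normal latent pair
(innate-immune activity, angiogenesis activity) with configurable
correlation ρ, optionally per developmental stage; an angiogenic EC
subpopulation (top `angiogenic_fraction` of ECs by angiogenesis latent)
carrying the activation program; negative-binomial counts with
log-linear loadings; optional per-batch gene offsets. Identical configs
are bit-identical across runs.

Defaults and rationale (all on the log-mean scale):

| parameter | default | why |
|---|---|---|
| `n_cells` / `n_genes` | 5000 / 1000 | 2000 ECs at 40% — large enough for stable rank correlations, small enough to simulate in ~1 s |
| `base_mean` | 0.5 | typical per-gene mean of a moderately sequenced cell |
| `nb_dispersion` | 0.5 | Var = μ + 0.5μ², mid-range single-cell overdispersion |
| `loading` | 1.0 | graded latent → e^±1 dynamic range on signature genes |
| `marker_loading`, `activation_loading` | 3.0 | discrete cell-state programs; ≈20× enrichment, conservative against real canonical markers (Rho, Esm1 are 100–1000×) |
| `noise_sd` | 0.25 | per cell×gene lognormal wobble uncoupled from the latents |
| `gene_mean_sd` | 2.0 | lognormal background abundance spread; real transcriptomes span 3–4 decades, and the resulting housekeeping tail keeps signature genes < 1% of each library, which the null calibration of score correlations requires |
| `angiogenic_fraction` | 0.25 | matches the default q = 0.75 quantile call |
| `rho` | 0.6 | the strongest co-activation regime studied |

Signature genes reuse the canonical mouse symbols of the packaged
signatures, so packaged GMTs score synthetic data at coverage 1.0; the
two scored programs are disjoint by default, with a `signature_overlap`
option to share genes (shared genes inflate score correlations — real
signature pairs do overlap, and the option makes that visible rather
than hidden).

What it does **not** emulate: real gene-level moments, library-size
distributions, ambient RNA, zero-inflation beyond NB (dropout is
implicit in the dispersion), doublets, or batch effects on cell
composition. Passing recovery tests therefore validates the statistics
of the pipeline, not biological fidelity.

### Attenuation and the frozen recovery band

Score-level rank correlation underestimates the latent ρ because NB
sampling noise blurs per-cell scores. Measured at defaults
(n_EC = 2000, eight calibration seeds): ρ = 0.6 recovers
ρ̂ = 0.508 ± 0.014; ρ = 1 with `noise_sd = 0` reaches a ceiling of
≈ 0.86–0.88. The recovery tests assert the frozen bands
ρ̂(0.6) ∈ [0.46, 0.56] and ρ̂(1, noise 0) ≥ 0.83, and strict
monotonicity of the mean estimate over
ρ ∈ {0, 0.15, 0.3, 0.45, 0.6, 0.75}. Null calibration: at ρ = 0 the
t-approximation test on 200-cell EC subsets rejects at 5.2% (1000-run
measurement; the acceptance test re-measures with 2000 runs and requires
[3%, 7%]).

## Pipeline and provenance

`run_pipeline` executes stages fail-fast (an error names the stage and
aborts before any result file is written for that analysis), serializes
the verbatim config into the output directory, and emits a manifest with
package version, per-stage log records, wall time, and SHA-256 checksums
of every output file. Re-running an identical config reproduces every
statistical output exactly; all stochastic analyses carry their seed.
Presets package the four study-level analyses (FVM co-activation,
developmental stages, cross-species, P6 stratification) as filled
config templates.

## Problem sizes in tests

The test suite and acceptance script run entirely on simulated data at
the sizes above: oracle checks enumerate up to 9! permutations and
C(16,8) group assignments; calibration uses 2000 null subsets of 200 ECs;
recovery uses 6 grid values × 10 seeds at 2000 ECs. These sizes were
chosen so the whole suite completes in a few minutes on one CPU while
keeping binomial/seed noise far from every asserted band.

## Known limitations

- Sum-scores without control-gene matching inherit mild compositional
  coupling under CPM normalization (quantified above).
- The KS exact path is disabled under ties; heavily tied score
  distributions fall back to the asymptotic approximation.
- The Jonckheere-Terpstra variance ignores tie corrections
  (conservative).
- Mouse Title-casing is a heuristic; nonstandard symbols need alias
  entries.
- Cluster-level annotation is emulated by per-cell argmax plus majority
  vote, not by re-implementing graph clustering.
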