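# coactivate

Gene-signature scoring and pathway **co-activation** analysis for
single-cell and bulk transcriptomics, built around one recurring question
in vascular biology: do an innate-immune program (cGAS-STING signaling)
and an angiogenesis program rise and fall together across individual
endothelial cells (ECs)?

The package is aimed at computational biologists analyzing retinal or
other vascular scRNA-seq data who want the full chain — marker-based cell
selection, additive signature scoring, rank-correlation testing,
stratification contrasts — as small, deterministic, testable functions
rather than a notebook of ad hoc steps. A negative-binomial simulator
with a known latent correlation ships alongside, so every stage can be
validated by parameter recovery before touching real data.

## The statistics

**Signature score.** For cell *c* and gene signature *G* (an ordered gene
list such as the packaged 20-gene cGAS-STING set), the score is additive
over the log-normalized layer:

    s_c(G) = Σ_{g ∈ G ∩ genes} x_{c,g},   x_{c,g} = log(1 + 10⁴ · n_{c,g} / N_c)

with raw count *n*, cell total *N_c*. Coverage (the fraction of signature
genes present) is always reported.

**Co-activation.** For two score vectors on a cell subset, Spearman's
rank correlation ρ with a p-value from full permutation enumeration
(n ≤ 9), seeded Monte-Carlo permutation, or the t-approximation.

**Enrichment.** Two-sample Kolmogorov–Smirnov D between score
distributions of cell groups (exact small-sample p when tie-free), and a
GSEA weighted running-sum enrichment score over a ranked gene list with a
gene-label permutation null (NES = ES divided by the mean same-sign null
magnitude).

**Stratification.** Cells split into low/mid/high tertiles of one score
(stable rank order at ties); a second score is contrasted via pairwise
rank-sum tests and a Jonckheere–Terpstra ordered-trend test; single-gene
high-vs-low contrasts report log₂ fold change with a rank-sum p.

**Simulator.** Multi-type tissue with per-type marker programs; ECs carry
a bivariate-normal latent pair with correlation ρ entering NB log-means
(`count ~ NB(base_mean · e^η, dispersion)`). See `docs/methods.md`.

## Worked example

```python
import coactivate as ca

matrix, truth = ca.simulate_dataset(ca.SyntheticConfig(seed=1, rho=0.6))
matrix = ca.normalize(matrix)
ec = ca.select_endothelial(matrix, ca.annotate_cells(matrix, ca.default_marker_panel()))
sx = ca.score_signature(ec, ca.default_signature("cGAS-STING"))
sy = ca.score_signature(ec, ca.default_signature("Angiogenesis"))
print(ca.spearman_coactivation(sx, sy, p_method="t", subset="EC"))
```

prints (see `examples/02_coactivation.py`):

```
ECs selected: 2000 of 5000 cells
latent correlation (truth): 0.6
Spearman R = 0.479, p = 2.5e-115 (n = 2000)
Sting1 vs Kdr: R = 0.138, p = 5e-10
```

The recovered R = 0.479 is the latent ρ = 0.6 attenuated by counting
noise (quantified in `docs/methods.md`); the single-gene Sting1–Kdr
correlation is much weaker than the signature-level one, which is why
scoring aggregates a program rather than reading one gene. The
`examples/` directory has one short script per capability (scoring and
group summaries, co-activation, stratification with Kdr/Flt1 contrasts,
annotation and angiogenic-EC calling, configured pipeline runs), and the
`coactivate` CLI exposes the same operations from a shell
(`coactivate simulate|ingest|annotate|score|correlate|stratify|run`).

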