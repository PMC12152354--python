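# placmed

Single-nucleus analysis of how maternal obesity may program offspring
neurobehavior through placental hypoxia — as a tested, reusable pipeline.

Maternal obesity (MO, pre-pregnancy BMI > 35) is associated with
neurobehavioral impairment (NBI) in children, and the placenta — in
particular the extravillous trophoblast (EVT), the fetal cell type that
invades maternal tissue — is a suspected intermediary. The analysis this
package implements links three quantities at single-nucleus resolution:

* **HGS** — a hypoxia gene score: the activity of a signed hypoxia gene
  program in a nucleus's expression profile;
* **NBIGS** — a neurobehavioral-impairment gene score whose weights are
  per-gene association statistics between placental expression and child
  outcome questionnaires (SDQ/ASEBA analogues) in a bulk birth cohort;
* **maternal BMI**, treated as a continuous exposure.

The causal question — *how much of the BMI → NBI-gene-expression association
in EVTs runs through hypoxia?* — is answered by linear mediation analysis.

## What is inside

| module | contents |
| --- | --- |
| `placmed.io` | 10x-style Matrix Market triplets, long weight TSVs, sample/phenotype CSVs, bulk TSVs — validated, bit-faithful round trips |
| `placmed.simulate` | synthetic cohort generator with a known BMI → hypoxia → NBI structural model (`SimConfig`, `generate_cohort`, ground truth for recovery tests) |
| `placmed.qc` | nucleus filters (>200 genes, >500 UMIs, <5% mito, strict), per-stratum gene filter (≥10 counts), log1p-CP10K normalization, pseudobulk sums |
| `placmed.diffexp` | per-gene negative-binomial GLM association engine (pseudobulk DE by BMI; transcriptome-wide phenotype scan on bulk), method-of-moments dispersion, BH-FDR |
| `placmed.footprint` | ulm/mlm linear-model footprint scorers (score = t-value of the weight coefficient), signature derivation (top-500 genes by p, signed statistic as weight), `FootprintScorer` sklearn-style estimator |
| `placmed.mediation` | Shapiro–Wilk normality gate, tie-aware Spearman tests, product-of-coefficients mediation with seeded nonparametric bootstrap (`LinearMediation` estimator) |
| `placmed.pipeline` / `placmed.cli` | one-config orchestration with a hashed manifest; `placmed` command with `simulate/qc/pseudobulk/de/weights/score/correlate/mediate/pipeline/report` subcommands |

### The model at the core

For each nucleus *j* of cell type *k* in sample *s* (standardized BMI `z_s`),
the generator draws latent activities

    h_j = h0_k + a_k z_s + ε_h          (hypoxia)
    m_j = m0_k + b h_j + c′ z_s + ε_m   (NBI)

so the true proportion mediated in type *k* is `a_k b / (a_k b + c′)` — 0.44
for the EVT-like type at the defaults (a = 0.8, b = 0.55, c′ = 0.56). Gene
counts are negative binomial with log-mean
`baseline_g + s_h w_h(g) h_j + s_n w_n(g) m_j` plus library-size scaling.

Scoring regresses a profile **x** on program weights **w** over their gene
intersection; the activity is the t-value of the slope (`ulm`), or of each
program's coefficient in the joint regression on all programs (`mlm`).
Mediation fits `m ~ 1 + t` and `y ~ 1 + t + m` by OLS: ACME = a·b (indirect),
ADE = c′ (direct), total = ACME + ADE, with percentile bootstrap intervals.

## Worked example

```python
from placmed import (SimConfig, generate_cohort, filter_nuclei,
                     normalize_log1p_cp10k, score_matrix, mediate,
                     true_mediation_proportion)
from placmed.qc import mito_gene_ids_by_prefix
from placmed.mediation import spearman_test

cm, samples, bulk, phen, weights, truth = generate_cohort(SimConfig(seed=1))
print(f"cohort: {cm.n_nuclei} nuclei x {cm.n_genes} genes, {len(samples)} samples")
kept = filter_nuclei(cm, mito_gene_ids=mito_gene_ids_by_prefix(cm))
print(f"QC: {kept.n_nuclei} nuclei pass (>200 genes, >500 UMIs, <5% mito)")
scores = score_matrix(normalize_log1p_cp10k(kept), weights,
                      gene_ids=kept.gene_ids, obs_ids=kept.barcodes).scores

evt = ((kept.nucleus_meta["cell_type"] == "EVT")
       & (kept.nucleus_meta["side"] == "maternal")).to_numpy()
hgs, nbigs = scores.loc[evt, "hypoxia"], scores.loc[evt, "nbi_true"]
rho = spearman_test(hgs.to_numpy(), nbigs.to_numpy())
print(f"EVT HGS-NBIGS Spearman rho = {rho.rho:.2f} (n = {rho.n}, p = {rho.p:.2g})")

bmi = samples.loc[kept.nucleus_meta.loc[evt, "sample_id"], "bmi"].to_numpy()
res = mediate(bmi, hgs.to_numpy(), nbigs.to_numpy(), n_boot=1000, seed=0)
print(f"ACME = {res.acme:.3f} (95% CI {res.ci['acme'][0]:.3f}-{res.ci['acme'][1]:.3f}), "
      f"ADE = {res.ade:.3f}, proportion mediated = {res.prop_mediated:.2f}")
print(f"constructed truth: {true_mediation_proportion(truth, 'EVT'):.2f}")
```

prints:

```
cohort: 10000 nuclei x 2000 genes, 20 samples
QC: 9498 nuclei pass (>200 genes, >500 UMIs, <5% mito)
EVT HGS-NBIGS Spearman rho = 0.59 (n = 911, p = 2.4e-85)
ACME = 0.089 (95% CI 0.074-0.106), ADE = 0.156, proportion mediated = 0.36
constructed truth: 0.44
```

The hypoxia and NBI scores correlate strongly in EVT nuclei; mediation
attributes roughly forty percent of the BMI → NBIGS association to the
hypoxia path (the single-cohort estimate sits a little below the constructed
0.44 because the scored mediator is a noisy measurement of the latent
activity — see `docs/methods.md`).

The same run from a shell:

```bash
placmed pipeline --config examples/pipeline.yaml
placmed report --run-dir placmed_out
```

## Documentation

`docs/methods.md` describes the statistical model, every tunable parameter
with its default and rationale, what the synthetic cohort does and does not
emulate, and known limitations (pseudoreplication, measurement-error
attenuation, signature contamination).
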