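# cernet

Inference of lncRNA-mediated competing-endogenous-RNA (ceRNA) networks and
survival-based prognostic modules.

Long non-coding RNAs can act as miRNA sponges: a lncRNA and an mRNA that
share many miRNA binding partners compete for the same miRNA pool, so their
expression tends to rise and fall together. `cernet` turns this hypothesis
into a testable pipeline for cancer cohorts with matched expression and
clinical follow-up, aimed at computational biologists looking for prognostic
lncRNA biomarkers. Because real cohorts have no ground truth, the package
ships a first-class synthetic-cohort generator with planted ceRNA pairs,
planted competing modules and planted risk genes, so every stage can be
validated against a known answer key.

## The method

1. **Shared-miRNA test.** For each lncRNA–mRNA pair, with N miRNAs in the
   universe, K interacting with the lncRNA, M with the mRNA and x shared,
   the overlap is referred to a hypergeometric null:

   P = P(X ≥ x),  X ~ Hypergeom(N, K, M)

   (the complement-of-CDF variant P(X > x) is also available). p-values are
   Benjamini–Hochberg adjusted; pairs with FDR < 0.01 are candidates.
   miRNA–lncRNA interactions can first be filtered to experimentally
   supported records (AGO-CLIP-style evidence labels).
2. **Co-expression filter.** Candidates are kept as network edges when
   Pearson ρ_{X,Y} = cov(X,Y)/(σ_X σ_Y) is positive and significant
   (FDR < 0.01, exact t reference with n−2 df). Edges with r > 0.5 form the
   high-competition sub-network.
3. **Topology.** The resulting bipartite graph is annotated with degree and
   betweenness centrality (both the Brandes pair-fraction sum and the
   global paths-through-node / total-paths ratio); degree distributions are
   fitted with log–log least squares; lncRNAs in the top 5% by *both*
   degree and betweenness are hub–bottleneck candidates.
4. **Modules.** Maximal bicliques of the sub-network (every lncRNA linked
   to every mRNA, extendable by no vertex) are enumerated and ranked by
   size and mean edge correlation — these are synergistic competing
   modules.
5. **Survival.** Candidate genes are screened with univariate Cox
   regression on a random half of the cohort; significant genes form a risk
   score RiskScore = Σᵢ rᵢ·Exp(i) with rᵢ the training Cox coefficient.
   The training median splits patients into high/low risk; the same
   coefficients and cutoff are applied verbatim to the held-out half and to
   external cohorts, compared by Kaplan–Meier curves and log-rank tests.
6. **Function by association.** A focal lncRNA is characterized through its
   network neighbors: two-way hierarchical clustering (1 − r distance,
   average linkage) and hypergeometric gene-set enrichment against a
   user-supplied GMT collection.

## Worked example

Run the whole pipeline on a synthetic cohort of 150 patients with a planted
2×3 competing module (miRNA sharing 0.8, pair correlation 0.9) and a planted
risk gene (log hazard ratio 0.7 per SD):

```python
from cernet import PipelineConfig, SimulationConfig, run_pipeline
import pandas as pd

sim = SimulationConfig(n_mirnas=120, n_lncrnas=12, n_mrnas=40, n_samples=150,
                       n_true_pairs=8, planted_biclique=(2, 3), seed=7)
run_dir = run_pipeline(PipelineConfig(outdir="demo", seed=7, simulation=sim))
print(pd.read_csv(run_dir / "modules.tsv", sep="\t").to_string(index=False))
print(pd.read_csv(run_dir / "survival_report.tsv", sep="\t").to_string(index=False))
```

prints

```
module_id      lncrna_ids                   mrna_ids  n_edges   mean_r
 module_1 LNC0001,LNC0002 MRNA0001,MRNA0002,MRNA0003        6 0.895244

  cohort  n_high  n_low  chi_square      p_value
   train      37     38   23.340528 1.357101e-06
    test      49     26    7.426544 6.426864e-03
     all      86     64   31.312325 2.196806e-08
external     104     46   14.834817 1.173489e-04
```

The enumerated module is exactly the planted 2×3 biclique (mean edge
correlation 0.90, matching the planted 0.9), and the risk score built from
its five genes separates high- from low-risk patients significantly
(log-rank p < 0.05) in the training half, the untouched test half, the
combined cohort, and an independently simulated external cohort — the
hallmark of a prognostic signature rather than an overfit split. Every
stage also leaves a TSV (`pair_tests.tsv`, `coexpression.tsv`, `nodes.tsv`,
`km_curves.tsv`, …) and `manifest.json` records parameters, record counts
and content checksums.

The same stages are available from the shell:

```sh
cernet run-all --outdir demo --seed 7
cernet survival --outdir demo --seed 7     # rerun one stage, resuming from TSVs
```

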