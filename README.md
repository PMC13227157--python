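# elocodon

Codon-centric analysis of Elongator-dependent translational regulation.

The Elongator complex modifies the wobble uridine (U34) of eleven tRNA
species, and the A-ending codons they decode — TTA, GTA, TCA, ACA, GCA,
CCA (ncm⁵U34), GGA, AGA (mcm⁵U34), CAA, GAA, AAA (mcm⁵s²U34) — are
translated inefficiently when the modification is lost. Transcripts rich
in these "Elongator-targeted" codons are then preferentially degraded,
so in an Elongator mutant their mRNA abundance drops. `elocodon` tests
for that signature in bulk differential-expression data: it scores every
coding sequence for its target-codon load, stratifies genes by that load,
and asks whether codon-loaded genes are shifted toward downregulation.

## What it computes

For each coding sequence six parameters are computed:

- **F_T** — frequency of target codons among all codons;
- **F_S** — frequency of target codons among the codons encoding the same
  eleven amino-acid families (controls for amino-acid usage);
- **F_2, F_3, F_4** — fraction of codons inside runs of ≥ 2, 3, 4
  consecutive target codons (codon clustering);
- **D** — mean distance, in codons, between consecutive target codons.

Downstream analyses:

- **DEG filtering** (padj ≤ 0.05, |LFC| ≥ 0.5, mean count ≥ 100) and the
  partition of two organs' DEG sets into organ-specific and shared
  (same- or opposite-direction) classes;
- **DM_LFC curves** — genes are ranked in ascending order of one
  parameter; for each percentage class p = 1..50 the p% of genes at the
  two extremes are compared by their log₂ fold changes:
  `DM_LFC = Me(LFC_HF) − Me(LFC_LF)` (high vs. low frequency; for D,
  shortest vs. longest distances). A negative DM_LFC means codon-loaded
  genes are downregulated;
- **cross-organ DM_LFC** — cotyledon-minus-hypocotyl median LFC within
  matched percentage classes of one joint ranking;
- **candidate selection** — significantly downregulated genes (LFC ≤ −1)
  with at least one frequency parameter above its 95th percentile or D
  below its 5th percentile;
- a **statistics toolkit**: Shapiro–Wilk (n ≤ 5000) or Anderson–Darling
  (n > 5000) normality dispatch to Welch's *t* or Wilcoxon–Mann–Whitney,
  Benjamini–Hochberg adjustment, interpolated percentiles, and the
  phenotype percent-difference statistic
  `D = 100% · (F_a − F̄_c) / F̄_c`;
- a **synthetic-data generator**: Markov-chain coding sequences with
  tunable target-codon propensity θ and clustering κ, plus expression
  tables with a planted slope β of LFC on standardized F_T — so the whole
  pipeline is testable without any sequencing data.

## Worked example

```python
from elocodon import (SimulationConfig, simulate_two_organ_study,
                      filter_degs, dm_lfc_curve, compute_codon_profile)

p = compute_codon_profile(["ATG", "GAA", "GAA", "TTA", "AGC"], "toy")
print("F_T=%.2f F_S=%.2f F_2=%.2f F_3=%.2f F_4=%.2f D=%.1f"
      % (p.f_t, p.f_s, p.f_2, p.f_3, p.f_4, p.d))

config = SimulationConfig(n_genes=2000, organs=2, beta_effect=(0.2, -0.5), seed=1)
study = simulate_two_organ_study(config)
deg_cot = filter_degs(study.cotyledon)
print(f"{len(deg_cot)} cotyledon DEGs "
      f"({(deg_cot['direction'] == 'down').sum()} down, "
      f"{(deg_cot['direction'] == 'up').sum()} up)")

lfc = dict(zip(study.cotyledon["gene_id"], study.cotyledon["lfc"]))
curve = dm_lfc_curve(study.profiles, lfc, "F_T", pcts=[1, 5, 10, 25, 50])
print(curve[["pct", "n_per_subset", "median_high", "median_low",
             "dm_lfc", "padj", "significant"]].to_string(index=False))
```

prints

```
F_T=0.60 F_S=0.75 F_2=0.60 F_3=0.60 F_4=0.00 D=1.0
517 cotyledon DEGs (240 down, 277 up)
 pct  n_per_subset  median_high  median_low    dm_lfc          padj  significant
   1            20    -1.693505    1.077451 -2.770955  1.872962e-17         True
   5           100    -1.214075    0.852714 -2.066789  4.765127e-71         True
  10           200    -1.008623    0.788111 -1.796733 1.794825e-117         True
  25           500    -0.625302    0.589409 -1.214710 3.112446e-172         True
  50          1000    -0.322682    0.379708 -0.702390 4.684492e-134         True
```

The toy gene has 3 target codons among 5 (F_T = 0.6), all in one run of
three (F_2 = F_3 = 0.6, F_4 = 0), adjacent to each other (D = 1). In the
simulated cotyledon (planted β = −0.5) the genes with the highest F_T
have strongly negative median LFCs, the genes with the lowest F_T
positive ones, and the DM_LFC curve is negative and significant at every
class — steepest at the ranking extremes, exactly the behaviour the
stratification is designed to detect.

The same analyses are available from the shell via the `elocodon` CLI
(`simulate`, `profile`, `deg-filter`, `partition`, `stratify`,
`cross-organ`, `compare-groups`, `select-candidates`, `pheno-diff`);
see `elocodon --help`.

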