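# tgct

Somatic mutational-landscape analysis for testicular germ cell tumour
(TGCT) whole-exome cohorts.

TGCTs are the most common cancer of young men and a genomic outlier among
solid tumours: a very low point-mutation burden (~0.5 non-synonymous
mutations per Mb, consistent with an embryonic origin) combined with heavy
aneuploidy — near-universal 12p gain, frequently as an isochromosome
i(12p), plus recurrent gains of chromosomes 7, 21, 22 and X and loss of Y.
This package implements the full analysis a matched tumour/normal WES
study of such a cohort needs, as a tested, reusable library with a CLI:

* **Variant filtering** — an oxidation-artifact (OxoG) filter (strand
  support on both strands, base quality > 26, mapping quality ≥ 50,
  alignability = 1.0) and removal of common germline SNPs (population
  MAF > 25%).
* **Landscape statistics** — per-sample and cohort mutation rates, the
  strand-collapsed six-class SNV spectrum, gene-level recurrence with
  histology stratification, and the age–mutation-rate association.
* **Driver statistics** — exact binomial recurrence tests against a
  compounded background rate `p_bg = 1 − (1 − μ·10⁻⁶)^L`, a binomial
  cohort power model (smallest genome-wide-significant count `k_min`,
  power = upper tail of Binom(n, f) at `k_min`), and Fisher's
  combined-probability meta-analysis.
* **CNV engine** — tumour/normal log2 depth ratios per exon, a
  permutation-tested circular-binary-segmentation variant, gain/loss
  calls (ratio > 1.3 / < 0.7) gated by a specificity confidence score,
  and BAF-based LOH calling at germline heterozygous sites.
* **CNV landscape** — focal (< 3 Mb) vs large-scale classification,
  arm/chromosome aneuploidy summaries with isochromosome-12p detection,
  chromothripsis flagging (> 20 CNVs on one arm), genome CNV fraction,
  unstable-sample exclusion, focal-event-to-gene mapping with
  coverage-artifact removal, recurrence ranking and binomial
  significance.
* **Synthetic cohorts** — a generator for matched tumour/normal exome
  cohorts with all of the structure above (spiked drivers, aneuploidies,
  focal amplifications, chromothriptic outliers, oxidation artifacts,
  common SNPs), plus a deterministic *paper fixture* encoding a published
  42-tumour cohort's printed summaries for end-to-end verification.

The deposited patient data of the underlying study are access-controlled;
everything here runs on the synthetic cohorts, whose generator is
first-class, tested code. See `docs/methods.md` for the models,
assumptions and design decisions.

## Worked example

Reproduce the fixture cohort analysis in one command:

```
tgct run --fixture --out runs/fixture --seed 1
```

This writes the simulated inputs (42 VCFs, coverage/het-site/sample
tables, gene BED) under `runs/fixture/inputs/`, every stage's output
table under `runs/fixture/results/`, and prints the cohort report. Key
lines of that report and what they mean:

```
 "mean_nonsyn_rate_per_mb": 0.5116,      # 795 calls / (42 x 37 Mb)
 "spectrum": {"C>A": 0.3099, "C>T": 0.2697, "T>C": 0.2303, ...},
 "genes": {"KIT": {"percent_samples": 14.3,
                   "percent_by_histology": {"seminoma": 31.3, ...}},
           "CDC27": {"percent_samples": 11.9, ...}},
 "n_12p_gain": 30,  "pct_12p_gain": 71.4,   # 30/42 tumours, 25 of them
 "n_isochromosome_12p": 25,                 # isochromosome-pattern
 "n_chrX_gain": 16, "n_chr7_gain": 15,      # whole-chromosome gains
 "n_chr21_gain": 12, "n_chr22_gain": 11,
 "n_chrY_loss": 10,
 "n_large_scale_samples": 35,
 "excluded_samples": ["T32", "T33", "T34"], # chromothriptic outliers
 "fsip2": {"losses": 2, "gains": 7, "total": 9,
           "n_gain_samples": 6, "pct_retained": 15.4},
 "n_common_snps_removed": 33
```

The FSIP2 row (2 losses, 7 gains, 9 total events across 6 amplified
tumours of the 39 retained) is the top-ranked focal recurrence; the Xq28
row collapses 18 genes sharing one amplified 0.4 Mb footprint.

Library use mirrors the CLI:

```python
from tgct import paper_fixture
from tgct.pipeline import analyze_cohort

report = analyze_cohort(paper_fixture(), seed=1)
print(report.summary()["pct_12p_gain"])   # 71.4
```

Other verbs: `tgct simulate` (cohort from a YAML config), `tgct fixture`
(write fixture inputs only), `tgct filter`, `tgct landscape`,
`tgct driver-test`, `tgct power`, `tgct cnv-call`, `tgct cnv-landscape`.
For example, the cohort power model at the study's scale:

```
$ tgct power --n 42 --mu 0.51 --freqs 0.05,0.10,0.15
n       frequency       k_min   power
42      0.05    4       0.1569
42      0.1     4       0.6164
42      0.15    4       0.8933
```

i.e. with 42 tumours the study design has high power only for drivers
mutated in more than ~15% of cases.

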