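# chimkin

Chimerism quantification and kinetic relapse prediction after allogeneic
hematopoietic cell transplantation (HCT).

## The problem

After an allogeneic transplant, the fraction of recipient-derived DNA in
blood or marrow ("chimerism") is monitored serially: a rising recipient
fraction is often the first measurable sign of impending relapse. Two assay
families dominate clinical practice:

* **STR-PCR** — capillary electrophoresis of short-tandem-repeat markers,
  quantified from informative peak areas; limit of detection about **0.8 %**
  recipient DNA.
* **SNP-panel NGS** — deep sequencing of a panel of ~200 biallelic SNPs
  (mean per-marker coverage near 1900×), quantified from allele read counts;
  limit of quantification about **0.36 %**.

This package implements both quantification models, the method-comparison
statistics used to assess their concordance on paired clinical samples, and
the kinetic predictors (change, rate, ratio, and increment-per-day of the
recipient fraction between consecutive tests) used to discriminate relapsing
from non-relapsing courses. A seeded synthetic-data generator reproduces the
statistical structure of the assays so every estimator can be validated
against known truth.

## Core model

At a biallelic SNP locus, each contributor `s` carries an alternate-allele
dosage `g_s ∈ {0, 1, 2}`. In a mixture with fractions `f_s` (summing to 1),
the expected alternate-read fraction is

```
p = Σ_s f_s · g_s / 2,    p_eff = p·(1−e) + (1−p)·e
```

with per-base error rate `e`. Alternate read counts at depth `d` are modeled
as Binomial(`d`, `p_eff`). Depending on which genotypes are known, the model
runs in four modes:

* **double-targeted** (recipient and donor genotyped): per-locus fraction
  estimates at informative loci (one contributor heterozygous and the others
  identically homozygous, scale 2; or opposite homozygotes, scale 1),
  aggregated by the median. With three or more contributors and one
  ungenotyped, the known fractions are fit by joint maximum likelihood with
  the unknown genotype marginalized under Hardy–Weinberg priors, and the
  unknown receives the remainder to 100 %.
* **recipient-** or **donor-targeted** (one genotype known): profile
  likelihood over the unknown fraction with the known dosages fixed and the
  other genotype marginalized.
* **blind** (no genotypes): one-dimensional profile likelihood of the minor
  fraction `f ∈ [0, 0.5]`, marginalizing both genotypes per locus under
  Hardy–Weinberg priors.

Estimates below the assay floor are reported censored at the floor
(0.36 % SNP-NGS, 0.8 % STR). STR quantification uses recipient-unique and
donor-unique peak areas with zygosity scaling and optional stutter
correction. Full derivations and parameter rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a 202-locus SNP panel read-count table for a 2 % recipient / 98 %
donor mixture at study-like coverage, then quantify it with both genotypes
known:

```python
from chimkin.simulate import (SimulationConfig, simulate_panel,
                              simulate_genotypes, simulate_mixture_counts)
from chimkin.snp import SNPChimerismModel

cfg = SimulationConfig(seed=7, true_fractions={"recipient": 2.0, "donor": 98.0})
panel = simulate_panel(cfg)
genotypes = simulate_genotypes(cfg, panel)
counts = simulate_mixture_counts(cfg, genotypes)

res = SNPChimerismModel(counts, genotypes, panel=panel).fit()
print(res.summary())
```

Output:

```
SNP chimerism estimate
==============================================
mode                        double_targeted
informative markers         119
mean marker coverage        1818.9
QC status                   pass
----------------------------------------------
recipient                         2.01 %
donor                            97.99 %
----------------------------------------------
reported recipient                2.01 %
```

The same analyses are available from the command line. `chimkin compare`
runs the method-comparison statistics on the bundled clinical pair table
(36 consecutive test pairs, 68 unique post-HCT samples):

```console
$ chimkin compare
{
  "n_samples": 68,
  "spearman_rho_all": 0.808245579274893,
  "spearman_rho_str_mc": 0.9774436090225563,
  "bland_altman": {
    "mean_diff": 0.26250000000000023,
    "lower_limit": -1.8381704686624332,
    "upper_limit": 2.3631704686624335,
    "prop_within_limits": 0.9411764705882353
  },
  "n_str_cc": 48,
  "n_str_mc": 20,
  "n_cc_with_detectable_mc": 26,
  "detectable_mean": 0.7657692307692308,
  "detectable_min": 0.41,
  "detectable_max": 2.7
}
```

and `chimkin roc` evaluates a kinetic predictor for relapse prediction:

```console
$ chimkin roc --method str --predictor delta_c
{
  "method": "str",
  "predictor": "delta_c",
  "auc": 0.9114583333333334,
  "ci95": [
    0.7913887421427767,
    1.0
  ],
  "youden_cutoff": 5.4,
  "metrics_cutoff": 2.36,
  "sensitivity_pct": 91.66666666666667,
  "specificity_pct": 79.16666666666667,
  "ppv_pct": 68.75,
  "npv_pct": 95.0
}
```

Other subcommands: `chimkin simulate` (write a synthetic dataset),
`chimkin quantify-snp` / `chimkin quantify-str` (quantify one sample from a
counts or peak table), `chimkin kinetics` (per-pair predictors and
increasing/non-increasing classification). Run `chimkin --help` for options;
analysis thresholds can be overridden with a YAML file via `--config`.

## Layout

```
src/chimkin/        library (io, snp, str_analysis, kinetics,
                    concordance, roc, simulate, fixture, config, cli)
src/chimkin/data/   bundled clinical pair table (TSV, checksummed)
tests/              pytest suite, including end-to-end acceptance tests
scripts/            acceptance.py
docs/methods.md     methods note: models, parameters, limitations
```
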