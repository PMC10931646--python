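# Methods

This note records the statistical models implemented in `chimkin`, the
assumptions behind them, the default parameter values and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices made along the way. No empirical claim here goes beyond
what the package itself computes.

## 1. SNP-panel chimerism model (`chimkin.snp`)

### Read model

At a biallelic autosomal locus, contributor `s` carries an alternate-allele
dosage `g_s ∈ {0, 1, 2}`. A DNA mixture with contributor fractions `f_s`
(`Σ f_s = 1`) has expected alternate-read fraction

```
p = Σ_s f_s g_s / 2
```

Sequencing error flips a base ref↔alt symmetrically with probability `e`,
so the effective alternate fraction is `p_eff = p(1−e) + (1−p)e`. Given
locus depth `d`, the alternate read count is modeled Binomial(`d`, `p_eff`).
Loci are treated as independent (the panel loci are spread across the 22
autosomes, far apart relative to linkage).

### Informative loci and targeted estimation

With all contributor genotypes known, a locus is *informative* when exactly
one contributor carries a signal allele the others lack:

* **het-vs-hom**: one contributor heterozygous, all others identically
  homozygous. The signal allele's read fraction equals `f_s / 2`, so the
  per-locus estimate is scaled by 2.
* **opposite homozygotes** (two contributors): each subject's allele is
  fully private; scale 1.

Per-locus fraction estimates are `scale × (signal-allele fraction − e)`,
clipped at 0. The per-contributor estimate is the **median** over that
contributor's informative loci. The median (rather than the mean or a
depth-weighted mean) is robust to the occasional aberrant locus — allele
dropout, mis-genotyped reference, or a mapping artifact — at a negligible
efficiency cost when ~100 loci are available. Contributors with no
informative loci of their own receive the remainder to 100 % when only one
is missing, or a non-negative least-squares fit of the full dosage matrix
otherwise.

When three or more contributors are expected but only some are genotyped
(e.g. recipient and one of two donors), the known contributors' fractions
are estimated by joint maximum likelihood over all loci: the known dosages
enter the mean directly, the ungenotyped contributor's dosage is
marginalized per locus under Hardy–Weinberg (HWE) priors, and the fractions
are optimized on the simplex (SLSQP, initialized from the per-locus private
allele medians). The ungenotyped contributor is then reported as
`100 − Σ known`. Per-locus private-allele estimates alone are biased in
this setting because the unknown contributor can share the signal allele;
the joint likelihood removes that bias.

### Blind and single-genotype modes

With **no genotypes**, the model profiles a one-dimensional likelihood of
the minor fraction `f ∈ [0, 0.5]`. At each locus the pair of contributor
dosages is unknown, so the likelihood marginalizes all nine dosage
combinations with HWE priors — `(1−q)², 2q(1−q), q²` at panel alternate
frequency `q`, or uniform (1/3 each) when no panel is supplied — combined
with `logsumexp`. Marginalizing rather than maximizing over genotype
configurations matters: assigning each locus its best-fitting genotype pair
overfits binomial noise and produces spurious nonzero minor fractions in
pure (100 % donor) samples, whereas the marginal likelihood correctly
concentrates at `f = 0` and the estimate censors at the quantification
floor. Blind mode reports the *minor/major* split only; it cannot say which
contributor is the recipient, and near `f = 0.5` the labeling becomes
unidentifiable (a warning is attached above 0.45).

With **one genotype known**, the same profile likelihood is used with the
known dosages fixed and the other contributor's dosage marginalized; the
estimated fraction is assigned to the ungenotyped side.

The profile likelihood is evaluated on a 201-point grid and refined with
bounded scalar minimization around the grid optimum — the function is
smooth and effectively unimodal after marginalization, so this is cheap and
reliable. A flat profile (log-likelihood range < 2 across the grid) attaches
a warning.

### Censoring and QC

Estimates below the limit of quantification are reported *at* the floor and
flagged `censored` (strictly-below comparison, so a value exactly at the
floor is reported uncensored). QC fails when fewer than `min_informative`
loci remain or coverage collapses; low mean coverage attaches a warning.
Loci under `min_locus_depth` reads are dropped with a warning.

## 2. STR chimerism model (`chimkin.str_analysis`)

Reference profiles for recipient and donor define, per shared marker, the
recipient-unique and donor-unique allele sets (alleles present in one
profile and absent from the other). A marker is informative when the
recipient has at least one private allele. The recipient fraction at a
marker is

```
r = area(recipient-unique) × 2 / (unique copies)
d = area(donor-unique)     × 2 / (unique copies)
pct = 100 · r / (r + d)
```

The ×2/copies factor rescales a partial allele set to the full genome
share: a heterozygote with one private allele shows only half its genome in
unique peaks, a homozygote (single peak, two copies) shows all of it.
Shared alleles are excluded entirely rather than apportioned. Markers where
the donor has no unique allele are skipped (the donor share cannot be
formed). The sample estimate is the unweighted **mean** over informative
markers, as peak areas on a capillary run are on a common scale. Estimates
below the 0.8 % limit of detection are censored at the floor.

Optional stutter correction subtracts `ratio × parent area` from the peak
one repeat unit below each observed allele (floored at 0) before
quantification; the allowed ratio range is 0–0.2, covering typical
tetranucleotide stutter.

## 3. Kinetic predictors (`chimkin.kinetics`)

For a pair of consecutive tests with recipient fractions `Ct1`, `Ct2`
(percent) separated by `Δt` days:

| predictor | definition |
|---|---|
| `delta_c` | `Ct2 − Ct1` (percentage points) |
| `rate`    | `delta_c / Δt` (points/day) |
| `ratio`   | `Ct2 / Ct1` |
| `icf`     | `(Ct2 / Ct1)^(1/Δt)` — increment per day as the Δt-th root of the ratio |

`Ct1 = 0` is rejected with guidance to substitute the assay floor, since the
ratio-based predictors are undefined at zero. Pairs are classified
**CH** (chimerism increase: start at/below the STR floor, end above it),
**NC** (no change: both at/below the floor), or excluded (decreasing, or
already above the floor at the first test). The fixed decision cut-off
`delta_c > 2.36` (strict) is the package default for relapse calling.

## 4. Method comparison (`chimkin.concordance`)

* **Spearman rank correlation** via `scipy.stats.spearmanr` (average ranks
  for ties). Censored floor values are used verbatim, so samples at the
  floor form genuine ties — this is deliberate: the assays report the floor,
  and the rank statistic handles the resulting ties exactly.
* **Bland–Altman**: differences `x − y`, limits of agreement mean ± 2·SD.
  The sample SD (ddof = 1) is the default; a population-SD option exists.
  2 rather than 1.96 is used for the limits multiplier, matching common
  clinical-laboratory practice; the difference is immaterial at these n.
* **Censoring cross-tabulation**: among samples the STR assay calls
  complete chimerism (at/below 0.8 %), count those where the SNP assay
  still quantifies recipient DNA above its 0.36 % floor, with
  mean/min/max of those values.

## 5. ROC analysis (`chimkin.roc`)

AUC is the tie-corrected Mann–Whitney statistic computed from midranks;
the ROC curve itself comes from `sklearn.metrics.roc_curve`, and the
trapezoidal area under it equals the rank statistic identically (this
equivalence is property-tested). The 95 % CI uses DeLong's method via
placement values by default, with a seeded, class-stratified bootstrap as
an alternative. The Youden-optimal cutoff maximizes `J = sensitivity −
(1 − specificity)` over midpoint candidates between adjacent distinct
scores (plus open ends); ties in `J` break toward higher specificity.
Confusion metrics use a strict `score > cutoff` rule, matching the
`delta_c > 2.36` decision rule; PPV/NPV are NaN when no sample is predicted
in the corresponding class.

## 6. Synthetic-data generator (`chimkin.simulate`)

Defaults mirror the assay conditions the estimators are meant for:

| parameter | default | rationale |
|---|---|---|
| `n_loci` | 202 | size of the SNP quantification panel |
| `maf_range` | (0.2, 0.5) | panels select common variants for informativeness |
| `depth_mean` | 1871 | mean per-marker coverage of the deep-sequencing assay |
| `depth_dispersion` | 8 | negative-binomial size; reproduces strong inter-locus depth variation typical of amplicon panels |
| `error_rate` | 0.001 | per-base error of a quality-filtered short-read run |
| `true_fractions` | 5 % / 95 % | a clinically relevant low-level mixed chimerism |
| `n_str_markers` | 10 | typical informative-marker count of a commercial STR kit |
| `stutter_ratio` | 0 | stutter is opt-in so exact-recovery tests stay exact |

The generator emulates: HWE genotypes with optional full-sibling or
parent–child relatedness (Mendelian transmission from simulated parents —
related donors share alleles identical by descent, shrinking the informative
locus count); overdispersed per-locus depth; binomial allele sampling with
symmetric error; STR profiles with areas proportional to genome share ×
allele copies/2 and optional stutter one repeat below each allele; and
longitudinal trajectories in which non-relapsing patients hold a flat
sub-floor recipient fraction while relapsing patients grow geometrically
per day from a sub-floor baseline, with inter-test intervals ~Normal(28, 8)
days clipped to 3–48.

It does **not** emulate: locus-specific amplification bias, PCR duplicates,
index hopping, mapping error, copy-number alterations in the malignant
clone (which distort dosage at affected loci), degraded-sample allele
dropout, STR electrophoresis artifacts beyond single-step stutter, or
clinical interventions (donor lymphocyte infusion, second transplant) that
make real trajectories non-monotone. Relapse onset is always placed between
the last two tests, which makes trajectory labels cleanly learnable by
construction — useful for pipeline validation, not for estimating
real-world classifier performance.

All outputs are reproducible from the configured seed via
`numpy.random.default_rng`.

## 7. Numerical choices

* Log-space likelihoods throughout, combined with `scipy.special.logsumexp`;
  binomial coefficients omitted where they cancel in profile comparisons.
* Grid-then-refine (201 points, `minimize_scalar` bounded) for 1-D
  profiles; SLSQP with simplex constraint for the multi-contributor joint
  fit.
* `scipy.optimize.nnls` for the fallback dosage-matrix fit.
* Censoring uses strict `<` against floors so values exactly at a floor
  pass through unflagged.
* The bundled clinical table is verified against a SHA-256 checksum and
  structural invariants at load time.

## 8. Limitations

* The binomial read model ignores overdispersion from amplification
  jitter; at very high depth the reported uncertainty of SNP estimates is
  optimistic.
* Blind mode assumes exactly two contributors and cannot label them;
  fractions near 50 % are unidentifiable up to label swap.
* The withheld-contributor fit assumes HWE for the unknown genotype; a
  related unknown contributor violates this prior.
* STR quantification assumes peak area is proportional to template amount
  within a marker; inter-marker amplification efficiency differences are
  absorbed only by the per-marker ratio construction.
* DeLong CIs are asymptotic and can exceed [0, 1] only after clipping; at
  n = 36 pairs they are wide and the bootstrap alternative is preferable
  for skewed score distributions.
* The clinical pair table is a small single-cohort dataset; statistics
  computed from it describe that cohort, not assay performance in general.
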