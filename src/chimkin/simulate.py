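"""Synthetic genotypes, read counts, STR profiles and chimerism trajectories.

Everything the analysis consumes can be generated here with the statistical
structure the estimators assume, so the whole pipeline is testable without
patient data:

* contributor genotypes under Hardy-Weinberg equilibrium at each panel
  locus, with optional Mendelian relatedness (full siblings or
  parent-child share alleles identical by descent, which shrinks the
  number of informative loci — the situation of related transplant
  donors);
* post-transplant read counts: per-locus depth drawn from an overdispersed
  (negative-binomial) distribution around the assay's mean coverage, and
  alternate-allele reads binomial around the dosage-weighted mixture
  fraction with a per-base error rate;
* STR profiles on a small multiallelic marker panel with peak areas
  proportional to genome share and optional stutter;
* longitudinal chimerism trajectories: flat sub-floor courses for
  non-relapsing patients and per-day geometric growth for relapsing ones,
  with realistic inter-test intervals.

All outputs are fully determined by the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import METHOD_FLOORS, SNPPanel

__all__ = [
    "SimulationConfig",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_mixture_counts",
    "simulate_str_profiles",
    "simulate_trajectories",
]

_RELATEDNESS = ("unrelated", "sibling", "parent_child")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Defaults mirror the assays being emulated: a 202-locus autosomal SNP
    panel at ~1871x mean per-marker coverage, a 10-marker STR panel, common
    panel variants (minor-allele frequencies uniform on [0.2, 0.5]), a
    0.1% per-base error rate, and a 5% recipient / 95% donor mixture.
    ``depth_dispersion`` is the negative-binomial size parameter (smaller =
    more inter-locus depth variation).
    """

    seed: int = 0
    n_loci: int = 202
    maf_range: tuple[float, float] = (0.2, 0.5)
    relatedness: str = "unrelated"
    depth_mean: float = 1871.0
    depth_dispersion: float = 8.0
    error_rate: float = 0.001
    true_fractions: dict = field(
        default_factory=lambda: {"recipient": 5.0, "donor": 95.0}
    )
    n_str_markers: int = 10
    stutter_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.relatedness not in _RELATEDNESS:
            raise ValueError(
                f"relatedness must be one of {_RELATEDNESS}, got {self.relatedness!r}"
            )
        total = sum(self.true_fractions.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"true fractions must sum to 100, got {total}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_panel(config: SimulationConfig, rng=None) -> SNPPanel:
    """A synthetic biallelic SNP panel spread over the 22 autosomes."""
    rng = config.rng() if rng is None else rng
    n = config.n_loci
    lo, hi = config.maf_range
    df = pd.DataFrame(
        {
            "locus_id": [f"rs{i + 1:04d}" for i in range(n)],
            "chromosome": (np.arange(n) % 22) + 1,
            "position": rng.integers(1, 2_000_000, size=n) * 100 + 1,
            "allele_ref": rng.choice(list("ACGT"), size=n),
            "pop_alt_freq": rng.uniform(lo, hi, size=n),
        }
    )
    alt = []
    for ref in df["allele_ref"]:
        options = [b for b in "ACGT" if b != ref]
        alt.append(options[rng.integers(0, 3)])
    df["allele_alt"] = alt
    return SNPPanel(df[["locus_id", "chromosome", "position", "allele_ref",
                        "allele_alt", "pop_alt_freq"]])


def _hwe_alleles(rng, freqs: np.ndarray, size: int) -> np.ndarray:
    return (rng.random((size, len(freqs))) < freqs).astype(int)


def simulate_genotypes(
    config: SimulationConfig,
    panel: SNPPanel,
    subjects: tuple[str, ...] = ("recipient", "donor"),
    rng=None,
) -> dict[str, dict[str, int | None]]:
    """Diploid alt-allele dosages per subject under the configured relatedness.

    ``unrelated`` draws each subject independently under Hardy-Weinberg at
    the panel allele frequencies. ``sibling`` makes all subjects full
    siblings (children of one simulated parent pair, each inheriting one
    allele per parent per locus). ``parent_child`` makes the first subject a
    parent of each of the others.
    """
    rng = config.rng() if rng is None else rng
    freqs = panel.loci["pop_alt_freq"].to_numpy()
    loci = panel.locus_ids
    n = len(loci)

    def profile(dosages: np.ndarray) -> dict[str, int | None]:
        return {loc: int(d) for loc, d in zip(loci, dosages)}

    if config.relatedness == "unrelated":
        return {
            s: profile(_hwe_alleles(rng, freqs, 2).sum(axis=0)) for s in subjects
        }
    if config.relatedness == "sibling":
        # one parental pair; every subject is a full sibling
        parents = [_hwe_alleles(rng, freqs, 2) for _ in range(2)]
        out = {}
        for s in subjects:
            picks = [p[rng.integers(0, 2, size=n), np.arange(n)] for p in parents]
            out[s] = profile(picks[0] + picks[1])
        return out
    # parent_child: first subject is a parent of each subsequent one
    parent = _hwe_alleles(rng, freqs, 2)
    out = {subjects[0]: profile(parent.sum(axis=0))}
    for s in subjects[1:]:
        transmitted = parent[rng.integers(0, 2, size=n), np.arange(n)]
        other = _hwe_alleles(rng, freqs, 1)[0]
        out[s] = profile(transmitted + other)
    return out


def simulate_mixture_counts(
    config: SimulationConfig,
    genotypes: dict[str, dict[str, int | None]],
    rng=None,
) -> pd.DataFrame:
    """Per-locus ref/alt read counts of the configured DNA mixture.

    Depth per locus is negative-binomial with mean ``depth_mean``; the
    alternate-allele read count is binomial around the dosage-weighted
    mixture fraction perturbed by the per-base error rate. Returns the same
    frame layout as :func:`chimkin.io.read_allele_counts`.
    """
    rng = config.rng() if rng is None else rng
    subjects = list(genotypes)
    missing = set(config.true_fractions) - set(subjects)
    if missing:
        raise ValueError(f"fractions given for absent subjects: {sorted(missing)}")
    loci = list(next(iter(genotypes.values())))
    fracs = np.array([config.true_fractions[s] / 100.0 for s in subjects])
    dosage = np.array(
        [[genotypes[s][loc] for s in subjects] for loc in loci], dtype=float
    )
    p = dosage @ fracs / 2.0
    e = config.error_rate
    p_eff = p * (1 - e) + (1 - p) * e

    r = config.depth_dispersion
    nb_p = r / (r + config.depth_mean)
    depth = rng.negative_binomial(r, nb_p, size=len(loci))
    alt = rng.binomial(depth, p_eff)
    return pd.DataFrame(
        {"ref_count": depth - alt, "alt_count": alt, "depth": depth},
        index=pd.Index(loci, name="locus_id"),
    )


# ---------------------------------------------------------------------------
# STR


def simulate_str_profiles(config: SimulationConfig, rng=None):
    """Recipient/donor reference profiles plus the mixed-sample profile.

    Each marker has a six-allele ladder; subjects draw two alleles from a
    symmetric frequency ladder, and the mixture's peak areas are
    proportional to genome share (fraction x allele copies / 2), with
    optional stutter added one repeat unit below each true allele.
    Returns ``(profiles, mixed)`` where ``profiles`` maps subject name to
    its reference :class:`~chimkin.str_analysis.STRProfile`.
    """
    from .str_analysis import STRProfile

    rng = config.rng() if rng is None else rng
    subjects = list(config.true_fractions)
    markers = [f"STR{i + 1:02d}" for i in range(config.n_str_markers)]
    ladder = np.arange(8, 14)  # repeat numbers

    genotypes = {s: {} for s in subjects}
    for marker in markers:
        for s in subjects:
            pair = tuple(sorted(rng.choice(ladder, size=2, replace=True)))
            genotypes[s][marker] = pair

    reference = {}
    for s in subjects:
        peaks = {}
        for marker in markers:
            areas: dict[int, float] = {}
            for allele in genotypes[s][marker]:
                areas[allele] = areas.get(allele, 0.0) + 5000.0
            peaks[marker] = areas
        reference[s] = STRProfile(peaks, genotypes=dict(genotypes[s]))

    total_area = 10000.0
    mixed_peaks = {}
    for marker in markers:
        areas: dict[int, float] = {}
        for s in subjects:
            share = config.true_fractions[s] / 100.0
            for allele in genotypes[s][marker]:
                areas[allele] = areas.get(allele, 0.0) + total_area * share / 2.0
        if config.stutter_ratio > 0:
            stutter: dict[int, float] = {}
            for allele, area in areas.items():
                stutter[allele - 1] = stutter.get(allele - 1, 0.0) \
                    + config.stutter_ratio * area
            for allele, extra in stutter.items():
                areas[allele] = areas.get(allele, 0.0) + extra
        mixed_peaks[marker] = areas
    return reference, STRProfile(mixed_peaks)


# ---------------------------------------------------------------------------
# longitudinal trajectories


def simulate_trajectories(
    config: SimulationConfig,
    n_patients: int = 20,
    n_tests: int = 4,
    relapse_fraction: float = 0.4,
    baseline_pct: float = 0.1,
    growth_per_day: float = 1.2,
    rng=None,
) -> pd.DataFrame:
    """Longitudinal two-assay chimerism tables with relapse labels.

    Non-relapsing patients hold a flat sub-floor recipient fraction;
    relapsing patients grow geometrically at ``growth_per_day`` from a
    sub-LOQ baseline starting before their final test. Inter-test
    intervals are drawn to match clinical practice (median about 28 days,
    clamped to 3-48). Columns: ``patient_id, sample_id, days_post_hct,
    true_pct, str_pct, str_censored, allo_pct, allo_censored, relapse``.
    """
    if n_patients < 2:
        raise ValueError("need at least two patients")
    rng = config.rng() if rng is None else rng
    rows = []
    n_relapse = max(1, round(relapse_fraction * n_patients))
    for i in range(n_patients):
        patient = f"sim{i + 1:03d}"
        relapse = i < n_relapse
        intervals = np.clip(np.rint(rng.normal(28, 8, size=n_tests - 1)), 3, 48)
        days = np.concatenate([[30], 30 + np.cumsum(intervals)]).astype(int)
        onset = days[-2] + rng.integers(1, max(2, int(intervals[-1])))
        for j, day in enumerate(days):
            if relapse and day >= onset:
                true = min(95.0, baseline_pct * growth_per_day ** (day - onset + 14))
            else:
                true = baseline_pct * float(rng.uniform(0.5, 1.5))
            str_val, str_cens = _censor(true, METHOD_FLOORS["STR"])
            allo_val, allo_cens = _censor(true, METHOD_FLOORS["SNP-NGS"])
            rows.append(
                (patient, f"{patient}_post{j + 1}", int(day), true,
                 str_val, str_cens, allo_val, allo_cens, relapse)
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample_id", "days_post_hct", "true_pct",
                 "str_pct", "str_censored", "allo_pct", "allo_censored",
                 "relapse"],
    )


def _censor(value: float, floor: float) -> tuple[float, bool]:
    if value < floor:
        return floor, True
    return float(value), False
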