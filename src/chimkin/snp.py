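"""Contributor-fraction estimation from SNP-panel allele read counts.

A post-transplant blood or marrow sample is a DNA mixture of the recipient
and one or two donors. At a biallelic SNP the expected alternate-allele read
fraction is the dosage-weighted mixture

    p = sum_k  f_k * d_k / 2

where ``f_k`` is contributor *k*'s genome fraction and ``d_k`` its
alternate-allele dosage (0, 1 or 2). Two genotype configurations make a
locus *informative* for a single contributor:

* **het-vs-hom** — one contributor heterozygous, all others identically
  homozygous: the heterozygote's private allele appears on half of its
  chromosomes, so its fraction is twice the private-allele read fraction;
* **opposite homozygotes** — one contributor homozygous, all others
  homozygous for the other allele: the private-allele read fraction *is*
  the contributor's fraction.

Estimation runs in two regimes:

* **targeted** (pre-transplant genotypes available for at least two
  contributors): per-locus private-allele arithmetic, robustly aggregated
  per contributor; a single withheld contributor is recovered as
  100 minus the sum of the estimated ones;
* **blind / single-genotype** (no, or only one, genotype available): a
  one-dimensional profile-likelihood fit of the mixture fraction, where
  each locus's unknown genotype configuration is profiled out by taking
  the best-fitting dosage assignment under a binomial read model.

Use :class:`SNPChimerismModel` and its :meth:`~SNPChimerismModel.fit`; it
returns an :class:`SNPChimerismResults` carrying the estimates, QC and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io import SNPPanel

__all__ = [
    "InfoClass",
    "InformativeLocus",
    "SNPChimerismModel",
    "SNPChimerismResults",
    "classify_informative",
    "apply_loq",
]

logger = logging.getLogger(__name__)

_DOSAGES = (0, 1, 2)


class InfoClass(str, Enum):
    HET_VS_HOM = "het_vs_hom"
    OPP_HOM = "opp_hom"


@dataclass(frozen=True)
class InformativeLocus:
    """A locus whose genotype configuration exposes one contributor.

    ``signal_subject``'s private allele (``signal_allele``, ``"ref"`` or
    ``"alt"``) is absent from every other contributor; multiplying its read
    fraction by ``scale`` (2 for a heterozygous signal subject, 1 for
    opposite homozygotes) yields that contributor's genome fraction.
    """

    locus_id: str
    info_class: InfoClass
    signal_subject: str
    signal_allele: str
    scale: int

    def __post_init__(self) -> None:
        if self.scale not in (1, 2):
            raise ValueError("scale must be 1 or 2")
        expected = 2 if self.info_class is InfoClass.HET_VS_HOM else 1
        if self.scale != expected:
            raise ValueError(f"scale {self.scale} inconsistent with {self.info_class}")
        if self.signal_allele not in ("ref", "alt"):
            raise ValueError("signal_allele must be 'ref' or 'alt'")


def classify_informative(
    genotypes: Mapping[str, int | None],
    locus_id: str = "",
) -> InformativeLocus | None:
    """Classify one locus given alt-allele dosages of the known contributors.

    Returns ``None`` when the locus is not informative (including any
    missing genotype). When both opposite homozygotes of a two-subject
    locus qualify as the exposed contributor, the recipient is preferred
    (its fraction is the clinically reported quantity), else the first
    subject in input order.
    """
    if len(genotypes) < 2:
        raise ValueError("need genotypes of at least two contributors")
    if any(d is None for d in genotypes.values()):
        return None
    subjects = list(genotypes)
    dosages = [genotypes[s] for s in subjects]
    if any(d not in _DOSAGES for d in dosages):
        raise ValueError(f"invalid dosage among {dosages}")

    hets = [s for s, d in zip(subjects, dosages) if d == 1]
    if len(hets) == 1:
        others = [genotypes[s] for s in subjects if s not in hets]
        if len(set(others)) == 1 and others[0] in (0, 2):
            # het subject's private allele is the one the homozygotes lack
            allele = "alt" if others[0] == 0 else "ref"
            return InformativeLocus(locus_id, InfoClass.HET_VS_HOM, hets[0], allele, 2)
        return None
    if hets:
        return None

    # all homozygous; informative iff exactly one subject opposes the rest
    groups: dict[int, list[str]] = {0: [], 2: []}
    for s, d in zip(subjects, dosages):
        groups[d].append(s)
    if not groups[0] or not groups[2]:
        return None
    singletons = [d for d in (0, 2) if len(groups[d]) == 1]
    if not singletons:
        return None
    if len(singletons) == 2:  # two subjects, opposite homozygotes
        if "recipient" in (groups[0][0], groups[2][0]):
            chosen = 0 if groups[0][0] == "recipient" else 2
        else:
            chosen = 0 if subjects.index(groups[0][0]) < subjects.index(groups[2][0]) else 2
    else:
        chosen = singletons[0]
    subject = groups[chosen][0]
    allele = "alt" if chosen == 2 else "ref"
    return InformativeLocus(locus_id, InfoClass.OPP_HOM, subject, allele, 1)


def apply_loq(value_pct: float, floor: float = 0.36) -> tuple[float, bool]:
    """Censor a chimerism percentage at the assay's reporting floor.

    Values strictly below *floor* are reported at the floor with
    ``censored=True`` (complete chimerism); values at or above it pass
    through unchanged.
    """
    if value_pct < 0:
        raise ValueError("chimerism percentage cannot be negative")
    if value_pct < floor:
        return floor, True
    return float(value_pct), False


# ---------------------------------------------------------------------------
# profile-likelihood machinery for blind / single-genotype estimation


def _error_adjust(p: np.ndarray, error_rate: float) -> np.ndarray:
    # a read is miscalled to the other allele with probability error_rate
    return p * (1.0 - error_rate) + (1.0 - p) * error_rate


def _hwe_dosage_probs(alt_freq: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities, shape (n_loci, 3)."""
    q = np.asarray(alt_freq, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)


def _mixture_loglik(
    f: float,
    alt: np.ndarray,
    depth: np.ndarray,
    fixed: np.ndarray | None,
    error_rate: float,
    priors: np.ndarray,
) -> float:
    """Log-likelihood of mixture fraction *f* with genotypes marginalized.

    Unknown genotype configurations are summed out with per-locus
    Hardy-Weinberg prior weights (``priors``, shape ``(n, 3)``) rather than
    maximized over: a hard per-locus arg-max assignment lets *f* absorb
    binomial read noise around the heterozygote fraction 0.5 and biases a
    pure single-contributor sample upward by several times the reporting
    floor. ``fixed`` holds the known contributor's per-locus dosage (the
    unknown contributes fraction *f*); ``None`` means both genotypes are
    unknown (blind mode, *f* the minor fraction).
    """
    if fixed is None:
        # p and combo weight for all 9 (known-free) dosage pairs
        p_locus = np.empty((len(alt), 9))
        w = np.empty((len(alt), 9))
        k = 0
        for a in _DOSAGES:
            for b in _DOSAGES:
                p_locus[:, k] = f * b / 2 + (1 - f) * a / 2
                w[:, k] = priors[:, a] * priors[:, b]
                k += 1
    else:
        p_locus = np.stack(
            [f * b / 2 + (1 - f) * fixed / 2 for b in _DOSAGES], axis=1
        )
        w = priors
    p_eff = _error_adjust(p_locus, error_rate)
    ll = stats.binom.logpmf(alt[:, None], depth[:, None], p_eff)
    ll = ll + np.log(w)
    m = ll.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))).sum())


def _withheld_loglik(
    f_known: np.ndarray,
    alt: np.ndarray,
    depth: np.ndarray,
    dosage: np.ndarray,
    error_rate: float,
    priors: np.ndarray,
) -> float:
    """Log-likelihood of the known contributors' fractions when one
    contributor's genotype is withheld.

    ``dosage`` is the (n_loci, k) matrix of known alt dosages; the withheld
    contributor carries fraction ``1 - sum(f_known)`` and its per-locus
    dosage is marginalized with Hardy-Weinberg priors. Without this, reads
    from the withheld contributor's private alleles masquerade as signal at
    loci that look informative among the known genotypes.
    """
    f_rest = max(0.0, 1.0 - float(f_known.sum()))
    base = dosage @ f_known / 2.0
    p_locus = np.stack([base + f_rest * b / 2.0 for b in _DOSAGES], axis=1)
    p_eff = _error_adjust(np.clip(p_locus, 0.0, 1.0), error_rate)
    ll = stats.binom.logpmf(alt[:, None], depth[:, None], p_eff) + np.log(priors)
    m = ll.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))).sum())


def _fit_fraction(
    alt: np.ndarray,
    depth: np.ndarray,
    fixed: np.ndarray | None,
    error_rate: float,
    f_max: float,
    priors: np.ndarray | None = None,
    n_grid: int = 201,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid search plus bounded refinement of the mixture fraction."""
    if priors is None:
        priors = np.full((len(alt), 3), 1.0 / 3.0)
    grid = np.linspace(0.0, f_max, n_grid)
    lls = np.array(
        [_mixture_loglik(f, alt, depth, fixed, error_rate, priors) for f in grid]
    )
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda f: -_mixture_loglik(f, alt, depth, fixed, error_rate, priors),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        f_hat = float(res.x)
        if -res.fun < lls[i]:
            f_hat = float(grid[i])
    else:
        f_hat = float(grid[i])
    return f_hat, grid, lls


# ---------------------------------------------------------------------------
# model / results


@dataclass
class SNPChimerismResults:
    """Estimated contributor fractions of one post-transplant sample.

    Attributes
    ----------
    fractions_pct : dict
        Raw per-contributor percentages summing to 100 (before censoring).
        Blind fits label the contributors ``minor``/``major`` since their
        identities are not determined by the data.
    recipient_pct : float
        The reported recipient chimerism: the recipient's raw fraction
        censored at the assay's limit of quantitation.
    censored : bool
        True when the raw recipient fraction fell below the floor.
    qc_status : str
        ``pass`` / ``warning`` / ``fail``; see ``qc_reasons``.
    per_locus : pandas.DataFrame or None
        Targeted fits: one row per informative locus with its class, scale
        and fraction estimate. Blind fits: None (see ``profile``).
    profile : pandas.DataFrame or None
        Blind/single-genotype fits: the likelihood profile over the grid.
    """

    fractions_pct: dict[str, float]
    recipient_pct: float
    censored: bool
    n_informative: int
    mean_marker_coverage: float
    qc_status: str
    qc_reasons: list[str]
    mode: str
    loq_pct: float
    per_locus: pd.DataFrame | None = None
    profile: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "SNP chimerism estimate",
            "=" * 46,
            f"{'mode':<28}{self.mode}",
            f"{'informative markers':<28}{self.n_informative}",
            f"{'mean marker coverage':<28}{self.mean_marker_coverage:.1f}",
            f"{'QC status':<28}{self.qc_status}"
            + (f" ({'; '.join(self.qc_reasons)})" if self.qc_reasons else ""),
            "-" * 46,
        ]
        for subject, pct in self.fractions_pct.items():
            lines.append(f"{subject:<28}{pct:10.2f} %")
        lines.append("-" * 46)
        flag = " (censored at LOQ)" if self.censored else ""
        lines.append(f"{'reported recipient':<28}{self.recipient_pct:10.2f} %{flag}")
        return "\n".join(lines)


class SNPChimerismModel:
    """Mixture-fraction model for SNP-panel read counts of one sample.

    Parameters
    ----------
    counts : pandas.DataFrame
        Per-locus read counts indexed by ``locus_id`` with columns
        ``ref_count`` and ``alt_count`` (as returned by
        :func:`chimkin.io.read_allele_counts`).
    genotypes : mapping, optional
        ``subject -> {locus_id: alt dosage or None}`` for the contributors
        with pre-transplant genotypes. Omit entirely for blind analysis.
        The recipient's profile must be keyed ``"recipient"``.
    n_contributors : int, optional
        Total number of genetic contributors in the sample (recipient plus
        donors). Defaults to ``max(2, len(genotypes))``; when it exceeds the
        number of supplied genotypes by one, the missing contributor's
        fraction is recovered by difference.
    panel : SNPPanel, optional
        When given, counts are validated against the panel.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        genotypes: Mapping[str, Mapping[str, int | None]] | None = None,
        n_contributors: int | None = None,
        panel: SNPPanel | None = None,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ) -> None:
        counts = counts.copy()
        if "depth" not in counts.columns:
            counts["depth"] = counts["ref_count"] + counts["alt_count"]
        if (counts[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        if panel is not None:
            unknown = [loc for loc in counts.index if loc not in panel]
            if unknown:
                raise ValueError(f"loci absent from panel: {unknown[:5]}")
        zero = counts.index[counts["depth"] == 0]
        if len(zero):
            logger.warning("omitting %d zero-depth loci from estimation", len(zero))
        shallow = counts.index[
            (counts["depth"] > 0) & (counts["depth"] < config.min_locus_depth)
        ]
        if len(shallow):
            logger.warning(
                "omitting %d loci below minimum depth %d",
                len(shallow), config.min_locus_depth,
            )
        self.counts = counts[counts["depth"] >= config.min_locus_depth]
        self.genotypes = dict(genotypes) if genotypes else {}
        if n_contributors is None:
            n_contributors = max(2, len(self.genotypes))
        if n_contributors < 2:
            raise ValueError("a chimeric sample has at least two contributors")
        if n_contributors - len(self.genotypes) > 1 and self.genotypes:
            raise ValueError("at most one contributor's genotype may be withheld")
        self.n_contributors = n_contributors
        self.panel = panel
        self.config = config

    # -- public API --------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        counts_path,
        genotypes_path=None,
        dialect: str = "tsv",
        **kwargs,
    ) -> "SNPChimerismModel":
        """Build a model straight from a counts file and a genotype table."""
        from .io import read_allele_counts, read_genotype_table

        counts = read_allele_counts(counts_path, dialect=dialect)
        genotypes = (
            read_genotype_table(genotypes_path) if genotypes_path else None
        )
        return cls(counts, genotypes=genotypes, **kwargs)

    @property
    def mode(self) -> str:
        """Analysis mode implied by the available genotypes."""
        known = set(self.genotypes)
        if not known:
            return "blind"
        if known == {"recipient"}:
            return "recipient_targeted"
        if "recipient" not in known:
            return "donor_targeted"
        return "double_targeted"

    def fit(self) -> SNPChimerismResults:
        if self.mode == "blind":
            return self._fit_blind()
        if len(self.genotypes) == 1:
            return self._fit_single_genotype()
        return self._fit_targeted()

    # -- targeted (>=2 known genotypes) ------------------------------------

    def _aggregate(self, values: np.ndarray) -> float:
        if self.config.aggregator == "mean":
            return float(np.mean(values))
        return float(np.median(values))

    def _fit_targeted(self) -> SNPChimerismResults:
        cfg = self.config
        subjects = list(self.genotypes)
        rows = []
        for locus_id, row in self.counts.iterrows():
            calls = {s: self.genotypes[s].get(locus_id) for s in subjects}
            info = classify_informative(calls, locus_id)
            if info is None:
                continue
            signal = row["alt_count"] if info.signal_allele == "alt" else row["ref_count"]
            raw = signal / row["depth"]
            frac = min(1.0, info.scale * max(0.0, raw - cfg.error_rate))
            rows.append(
                (locus_id, info.signal_subject, info.info_class.value,
                 info.scale, int(signal), int(row["depth"]), frac)
            )
        per_locus = pd.DataFrame(
            rows,
            columns=["locus_id", "signal_subject", "info_class", "scale",
                     "signal_count", "depth", "fraction"],
        )
        n_informative = len(per_locus)
        coverage = float(per_locus["depth"].mean()) if n_informative else 0.0

        qc_reasons: list[str] = []
        if n_informative < cfg.min_informative:
            return self._qc_fail_result(
                "insufficient informative markers", n_informative, coverage,
                per_locus=per_locus,
            )
        if coverage < cfg.min_mean_coverage:
            qc_reasons.append("low mean marker coverage")

        estimates: dict[str, float] = {}
        for subject in subjects:
            sub = per_locus[per_locus["signal_subject"] == subject]
            if len(sub):
                estimates[subject] = self._aggregate(sub["fraction"].to_numpy())
        missing_direct = [s for s in subjects if s not in estimates]

        if missing_direct:
            if len(missing_direct) == 1 and self.n_contributors == len(subjects):
                estimates[missing_direct[0]] = max(
                    0.0, 1.0 - sum(estimates.values())
                )
                qc_reasons.append(
                    f"no private markers for {missing_direct[0]}; "
                    "fraction recovered by difference"
                )
            else:
                # nonnegative least squares on expected allele-dosage fractions
                nnls = self._nnls_fractions(subjects)
                if nnls is None:
                    return self._qc_fail_result(
                        "insufficient informative markers",
                        n_informative, coverage, per_locus=per_locus,
                    )
                estimates = nnls
                qc_reasons.append("fractions solved by nonnegative least squares")

        if self.n_contributors == len(subjects):
            total = sum(estimates.values())
            if total > 0:
                estimates = {s: v / total for s, v in estimates.items()}

        fractions = {s: float(np.clip(v, 0.0, 1.0)) for s, v in estimates.items()}
        if self.n_contributors > len(subjects):
            # "all participants minus one": refine the known fractions under
            # the joint likelihood (the withheld contributor's genotype is
            # marginalized, so its private alleles stop polluting the
            # known contributors' signal loci), then assign it the remainder
            fractions = self._refine_withheld(subjects, fractions)
            fractions["unknown"] = max(0.0, 1.0 - sum(fractions.values()))
        total = sum(fractions.values())
        if total > 0:
            fractions = {s: v / total for s, v in fractions.items()}
        return self._build_result(
            fractions, n_informative, coverage, qc_reasons, per_locus=per_locus
        )

    def _refine_withheld(
        self, subjects: list[str], init: dict[str, float]
    ) -> dict[str, float]:
        usable = [
            loc for loc in self.counts.index
            if all(self.genotypes[s].get(loc) is not None for s in subjects)
        ]
        counts = self.counts.loc[usable]
        alt = counts["alt_count"].to_numpy(dtype=float)
        depth = counts["depth"].to_numpy(dtype=float)
        dosage = np.array(
            [[self.genotypes[s][loc] for s in subjects] for loc in usable],
            dtype=float,
        )
        priors = self._genotype_priors(usable)
        x0 = np.clip([init.get(s, 1.0 / self.n_contributors) for s in subjects],
                     0.0, 1.0)
        if x0.sum() > 1.0:
            x0 = x0 / x0.sum()
        res = optimize.minimize(
            lambda x: -_withheld_loglik(
                np.asarray(x), alt, depth, dosage, self.config.error_rate, priors
            ),
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(subjects),
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - np.sum(x)}],
            options={"ftol": 1e-10, "maxiter": 200},
        )
        x = res.x if res.success else x0
        return {s: float(np.clip(v, 0.0, 1.0)) for s, v in zip(subjects, x)}

    def _nnls_fractions(self, subjects: list[str]) -> dict[str, float] | None:
        rows, y = [], []
        for locus_id, row in self.counts.iterrows():
            dosages = [self.genotypes[s].get(locus_id) for s in subjects]
            if any(d is None for d in dosages):
                continue
            if len(set(dosages)) == 1:
                continue  # no contrast between contributors
            rows.append([d / 2 for d in dosages])
            y.append(row["alt_count"] / row["depth"])
        if len(rows) < self.config.min_informative:
            return None
        coef, _ = optimize.nnls(np.asarray(rows), np.asarray(y))
        if coef.sum() <= 0:
            return None
        return {s: float(min(c, 1.0)) for s, c in zip(subjects, coef)}

    # -- blind & single-genotype likelihood fits ----------------------------

    def _prepare_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        alt = self.counts["alt_count"].to_numpy(dtype=float)
        depth = self.counts["depth"].to_numpy(dtype=float)
        if len(alt) < self.config.min_informative:
            raise ValueError("too few usable loci for likelihood fitting")
        return alt, depth

    def _genotype_priors(self, loci) -> np.ndarray:
        """Per-locus genotype prior: Hardy-Weinberg at the panel allele
        frequency when a panel is available, else uniform."""
        if self.panel is not None:
            freq = (
                self.panel.loci.set_index("locus_id")["pop_alt_freq"]
                .reindex(loci)
                .to_numpy()
            )
            if not np.isnan(freq).any():
                return _hwe_dosage_probs(freq)
        return np.full((len(loci), 3), 1.0 / 3.0)

    def _fit_blind(self) -> SNPChimerismResults:
        cfg = self.config
        alt, depth = self._prepare_arrays()
        priors = self._genotype_priors(self.counts.index)
        f_hat, grid, lls = _fit_fraction(
            alt, depth, None, cfg.error_rate, 0.5, priors
        )
        profile = pd.DataFrame({"fraction": grid, "loglik": lls})
        qc_reasons = []
        if f_hat > 0.45:
            qc_reasons.append(
                "near-equal mixture: minor/major contributor identity ambiguous"
            )
        if float(lls.max() - np.median(lls)) < 2.0:
            qc_reasons.append("flat likelihood profile")
        fractions = {"minor": f_hat, "major": 1.0 - f_hat}
        # the minor contributor is the quantity reported against the LOQ
        value, censored = apply_loq(f_hat * 100.0, cfg.snp_loq_pct)
        coverage = float(depth.mean())
        if coverage < cfg.min_mean_coverage:
            qc_reasons.append("low mean marker coverage")
        return SNPChimerismResults(
            fractions_pct={s: v * 100.0 for s, v in fractions.items()},
            recipient_pct=value,
            censored=censored,
            n_informative=len(alt),
            mean_marker_coverage=coverage,
            qc_status="warning" if qc_reasons else "pass",
            qc_reasons=qc_reasons,
            mode="blind",
            loq_pct=cfg.snp_loq_pct,
            profile=profile,
        )

    def _fit_single_genotype(self) -> SNPChimerismResults:
        cfg = self.config
        known = next(iter(self.genotypes))
        profile_map = self.genotypes[known]
        usable = [loc for loc in self.counts.index if profile_map.get(loc) is not None]
        counts = self.counts.loc[usable]
        alt = counts["alt_count"].to_numpy(dtype=float)
        depth = counts["depth"].to_numpy(dtype=float)
        if len(alt) < cfg.min_informative:
            return self._qc_fail_result(
                "insufficient informative markers", len(alt),
                float(depth.mean()) if len(depth) else 0.0,
            )
        fixed = np.array([profile_map[loc] for loc in usable], dtype=float)
        priors = self._genotype_priors(counts.index)
        f_hat, grid, lls = _fit_fraction(
            alt, depth, fixed, cfg.error_rate, 1.0, priors
        )
        rest = "rest" if known != "recipient" else "donor"
        fractions = {known: 1.0 - f_hat, rest: f_hat}
        qc_reasons = []
        if float(lls.max() - np.median(lls)) < 2.0:
            qc_reasons.append("flat likelihood profile")
        coverage = float(depth.mean())
        if coverage < cfg.min_mean_coverage:
            qc_reasons.append("low mean marker coverage")
        profile = pd.DataFrame({"fraction": grid, "loglik": lls})
        return self._finalize_likelihood_result(
            fractions, len(alt), coverage, qc_reasons, profile
        )

    def _finalize_likelihood_result(
        self, fractions, n_informative, coverage, qc_reasons, profile
    ) -> SNPChimerismResults:
        cfg = self.config
        if "recipient" in fractions:
            raw_recipient = fractions["recipient"]
        else:
            raw_recipient = fractions.get("rest", 0.0)
        value, censored = apply_loq(raw_recipient * 100.0, cfg.snp_loq_pct)
        return SNPChimerismResults(
            fractions_pct={s: v * 100.0 for s, v in fractions.items()},
            recipient_pct=value,
            censored=censored,
            n_informative=n_informative,
            mean_marker_coverage=coverage,
            qc_status="warning" if qc_reasons else "pass",
            qc_reasons=qc_reasons,
            mode=self.mode,
            loq_pct=cfg.snp_loq_pct,
            profile=profile,
        )

    # -- shared result assembly ---------------------------------------------

    def _build_result(
        self, fractions, n_informative, coverage, qc_reasons, per_locus=None
    ) -> SNPChimerismResults:
        cfg = self.config
        raw_recipient = fractions.get("recipient")
        if raw_recipient is None:
            # donor-targeted: recipient is the unknown remainder
            raw_recipient = fractions.get("unknown", 0.0)
        value, censored = apply_loq(raw_recipient * 100.0, cfg.snp_loq_pct)
        return SNPChimerismResults(
            fractions_pct={s: v * 100.0 for s, v in fractions.items()},
            recipient_pct=value,
            censored=censored,
            n_informative=n_informative,
            mean_marker_coverage=coverage,
            qc_status="warning" if qc_reasons else "pass",
            qc_reasons=qc_reasons,
            mode=self.mode,
            loq_pct=cfg.snp_loq_pct,
            per_locus=per_locus,
        )

    def _qc_fail_result(
        self, reason: str, n_informative: int, coverage: float, per_locus=None
    ) -> SNPChimerismResults:
        return SNPChimerismResults(
            fractions_pct={},
            recipient_pct=float("nan"),
            censored=False,
            n_informative=n_informative,
            mean_marker_coverage=coverage,
            qc_status="fail",
            qc_reasons=[reason],
            mode=self.mode,
            loq_pct=self.config.snp_loq_pct,
            per_locus=per_locus,
        )
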