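"""Recipient chimerism from STR fragment peak areas.

A capillary-electrophoresis STR profile gives, per marker, a peak area for
each allele (repeat number). When the recipient carries alleles the donor
lacks, the recipient's share of the mixed sample is the proportion of
recipient-unique peak area relative to the total distinguishable signal at
that marker. Shared alleles are uninterpretable without deconvolution and
are excluded; zygosity scaling puts a one-unique-allele subject (the other
allele shared or homozygous-unique) on the same genome-share footing as a
two-unique-allele subject.

The estimate is the mean of per-marker proportions over informative
markers, censored at the assay's 0.8% limit of detection. A stutter
correction (PCR artifact one repeat unit below a true allele) is available
but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig

__all__ = [
    "STRProfile",
    "InformativeSTRMarker",
    "STRChimerismModel",
    "STRChimerismResults",
    "select_informative_str",
    "correct_stutter",
]


@dataclass(frozen=True)
class STRProfile:
    """Peak areas per marker: ``{marker: {allele repeat number: area}}``.

    A single subject's profile has one or two alleles per marker (a
    homozygote shows one peak carrying both copies); a mixed sample may
    show more. Areas are arbitrary fluorescence units and must be
    nonnegative.
    """

    peaks: Mapping[str, Mapping[int, float]]
    genotypes: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        for marker, alleles in self.peaks.items():
            if any(area < 0 for area in alleles.values()):
                raise ValueError(f"negative peak area at marker {marker}")

    @property
    def markers(self) -> set[str]:
        return set(self.peaks)

    def alleles(self, marker: str) -> set[int]:
        return set(self.peaks.get(marker, {}))

    def genotype(self, marker: str) -> tuple[int, ...]:
        """Allele pair with multiplicity (homozygotes count twice)."""
        if self.genotypes is not None and marker in self.genotypes:
            return tuple(self.genotypes[marker])
        alleles = sorted(self.peaks.get(marker, {}))
        if len(alleles) == 1:  # single peak: assume homozygous
            return (alleles[0], alleles[0])
        return tuple(alleles)

    def area(self, marker: str, alleles: set[int]) -> float:
        return float(sum(self.peaks.get(marker, {}).get(a, 0.0) for a in alleles))


@dataclass(frozen=True)
class InformativeSTRMarker:
    """A marker where the recipient shows at least one allele the donor lacks."""

    marker: str
    recipient_unique: frozenset[int]
    donor_unique: frozenset[int]
    recipient_unique_copies: int  # allele copies (homozygous-unique = 2)
    donor_unique_copies: int


def select_informative_str(
    recipient: STRProfile, donor: STRProfile
) -> list[InformativeSTRMarker]:
    """Markers usable for quantification: recipient has a private allele.

    The unique-allele *copy* counts drive the zygosity scaling: a
    heterozygote with one shared allele exposes half its genome, a
    homozygote or fully distinct heterozygote exposes all of it.
    """
    shared_markers = recipient.markers & donor.markers
    if not shared_markers:
        raise ValueError("recipient and donor profiles share no markers")
    informative = []
    for marker in sorted(shared_markers):
        r_alleles, d_alleles = recipient.alleles(marker), donor.alleles(marker)
        r_unique = r_alleles - d_alleles
        if not r_unique:
            continue
        d_unique = d_alleles - r_alleles
        r_copies = sum(1 for a in recipient.genotype(marker) if a in r_unique)
        d_copies = sum(1 for a in donor.genotype(marker) if a in d_unique)
        informative.append(
            InformativeSTRMarker(
                marker, frozenset(r_unique), frozenset(d_unique),
                r_copies, d_copies,
            )
        )
    return informative


def correct_stutter(profile: STRProfile, stutter_ratio: float) -> STRProfile:
    """Remove expected stutter: subtract ``ratio x parent area`` at repeat n-1.

    Areas floor at zero. ``stutter_ratio`` must lie in [0, 0.2]; 0 is the
    identity.
    """
    if not 0 <= stutter_ratio <= 0.2:
        raise ValueError("stutter_ratio must be in [0, 0.2]")
    if stutter_ratio == 0:
        return profile
    corrected = {}
    for marker, alleles in profile.peaks.items():
        new = dict(alleles)
        for allele, area in alleles.items():
            target = allele - 1
            if target in new:
                new[target] = max(0.0, new[target] - stutter_ratio * area)
        corrected[marker] = new
    return STRProfile(corrected, genotypes=profile.genotypes)


@dataclass
class STRChimerismResults:
    """Recipient chimerism of one mixed sample from STR peak areas."""

    value_pct: float
    censored: bool
    n_informative: int
    qc_status: str
    qc_reasons: list[str]
    per_marker: pd.DataFrame
    lod_pct: float

    def summary(self) -> str:
        lines = [
            "STR chimerism estimate",
            "=" * 46,
            f"{'informative markers':<28}{self.n_informative}",
            f"{'QC status':<28}{self.qc_status}"
            + (f" ({'; '.join(self.qc_reasons)})" if self.qc_reasons else ""),
            "-" * 46,
        ]
        for r in self.per_marker.itertuples():
            lines.append(f"{r.marker:<28}{r.recipient_pct:10.2f} %")
        lines.append("-" * 46)
        flag = " (censored at LOD)" if self.censored else ""
        lines.append(f"{'recipient chimerism':<28}{self.value_pct:10.2f} %{flag}")
        return "\n".join(lines)


class STRChimerismModel:
    """Peak-area mixture model for one post-transplant STR run.

    Parameters
    ----------
    mixed : STRProfile
        Peak areas observed in the post-transplant sample.
    recipient, donor : STRProfile
        Pre-transplant reference profiles used to pick informative markers.
    stutter_ratio : float
        If nonzero, the mixed profile is stutter-corrected before
        quantification.
    """

    def __init__(
        self,
        mixed: STRProfile,
        recipient: STRProfile,
        donor: STRProfile,
        stutter_ratio: float = 0.0,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ) -> None:
        self.mixed = correct_stutter(mixed, stutter_ratio)
        self.recipient = recipient
        self.donor = donor
        self.config = config
        self.informative = select_informative_str(recipient, donor)

    def fit(self) -> STRChimerismResults:
        cfg = self.config
        rows = []
        for info in self.informative:
            r_area = self.mixed.area(info.marker, set(info.recipient_unique))
            d_area = self.mixed.area(info.marker, set(info.donor_unique))
            if info.donor_unique_copies == 0:
                continue  # donor fully masked by recipient alleles: no contrast
            # scale each side's unique-allele area to a full genome share
            r_scaled = r_area * 2.0 / info.recipient_unique_copies
            d_scaled = d_area * 2.0 / info.donor_unique_copies
            total = r_scaled + d_scaled
            if total <= 0:
                continue
            rows.append((info.marker, r_area, d_area, 100.0 * r_scaled / total))
        per_marker = pd.DataFrame(
            rows, columns=["marker", "recipient_area", "donor_area", "recipient_pct"]
        )
        n = len(per_marker)
        qc_reasons: list[str] = []
        if n < cfg.min_informative:
            qc_reasons.append("insufficient informative markers")
            status = "fail"
        else:
            status = "pass"
        value = float(per_marker["recipient_pct"].mean()) if n else 0.0
        censored = value < cfg.str_lod_pct
        if censored:
            value = cfg.str_lod_pct
        return STRChimerismResults(
            value_pct=value,
            censored=censored,
            n_informative=n,
            qc_status=status,
            qc_reasons=qc_reasons,
            per_marker=per_marker,
            lod_pct=cfg.str_lod_pct,
        )
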