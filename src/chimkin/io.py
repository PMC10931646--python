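"""Readers and writers for the tabular formats used in chimerism monitoring.

Formats
-------
* genotype tables: TSV with a ``locus_id`` column and one column per subject
  (``recipient``, ``donor``, ``donor2``, ...) holding diploid calls
  ``0/0``, ``0/1``, ``1/1`` or ``./.``;
* per-locus allele read counts: either a plain TSV
  (``locus_id  ref_count  alt_count``) or the per-sample AD (allelic depth)
  field of a standard VCF;
* STR peak tables: TSV/CSV with columns ``subject, marker, allele, area``;
* longitudinal chimerism tables: one row per (patient, sample, method)
  measurement with censoring flags.

Genotypes are returned as alt-allele dosages (0, 1, 2, or ``None`` for a
missing call) keyed by locus, the representation every downstream
computation works in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SNPPanel",
    "LongitudinalRecord",
    "read_genotype_table",
    "read_allele_counts",
    "read_str_peaks",
    "read_longitudinal",
    "write_longitudinal",
]

logger = logging.getLogger(__name__)

_GT_TOKENS = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": None}

#: method name -> reporting floor (percent); SNP-NGS floor is a limit of
#: quantitation, the STR floor a limit of detection.
METHOD_FLOORS = {"STR": 0.8, "SNP-NGS": 0.36}


@dataclass(frozen=True)
class SNPPanel:
    """A biallelic SNP marker panel on the autosomes.

    Parameters
    ----------
    loci : pandas.DataFrame
        Columns ``locus_id`` (unique), ``chromosome`` (1-22), ``position``
        (1-based), ``allele_ref``, ``allele_alt`` (single bases) and
        ``pop_alt_freq`` (population alternate-allele frequency in (0, 1)).
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.loci
        required = {"locus_id", "chromosome", "position", "allele_ref",
                    "allele_alt", "pop_alt_freq"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if df["locus_id"].duplicated().any():
            dup = df.loc[df["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus_id in panel: {dup}")
        chrom = pd.to_numeric(df["chromosome"], errors="coerce")
        if chrom.isna().any() or not chrom.between(1, 22).all():
            raise ValueError("panel chromosomes must be autosomes 1-22")
        freq = df["pop_alt_freq"]
        if not ((freq > 0) & (freq < 1)).all():
            raise ValueError("pop_alt_freq must lie strictly in (0, 1)")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci["locus_id"])

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in set(self.loci["locus_id"])


@dataclass(frozen=True)
class LongitudinalRecord:
    """One chimerism measurement of one post-transplant sample.

    ``censored`` means the value sits at the method's reporting floor
    (0.8% for STR, 0.36% for SNP-NGS): the true recipient fraction is only
    known to be at or below it.
    """

    patient_id: str
    sample_id: str
    days_post_hct: int
    method: str  # "STR" | "SNP-NGS"
    value_pct: float
    censored: bool

    def __post_init__(self) -> None:
        if self.method not in METHOD_FLOORS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.days_post_hct < 0:
            raise ValueError("days_post_hct must be nonnegative")
        if not 0 <= self.value_pct <= 100:
            raise ValueError("value_pct must be in [0, 100]")
        if self.censored and self.value_pct != METHOD_FLOORS[self.method]:
            raise ValueError(
                "censored records must sit exactly at the method floor "
                f"({METHOD_FLOORS[self.method]} for {self.method})"
            )


def read_genotype_table(
    path: str | Path,
    panel: SNPPanel | None = None,
) -> dict[str, dict[str, int | None]]:
    """Read a TSV of diploid genotype calls, one subject per column.

    Returns a mapping ``subject -> {locus_id: alt dosage or None}``.
    Missing calls (``./.``) are kept as ``None`` and logged, never dropped
    silently. If *panel* is given, every locus must belong to it.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "locus_id":
            raise ValueError(f"{path}: first column must be 'locus_id'")
        subjects = header[1:]
        if not subjects:
            raise ValueError(f"{path}: no subject columns")
        profiles: dict[str, dict[str, int | None]] = {s: {} for s in subjects}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
            locus = fields[0]
            if panel is not None and locus not in panel:
                raise ValueError(f"{path}:{lineno}: locus {locus!r} not in panel")
            for subject, token in zip(subjects, fields[1:]):
                if token not in _GT_TOKENS:
                    raise ValueError(
                        f"{path}:{lineno}: malformed genotype token {token!r} "
                        f"for subject {subject!r}"
                    )
                dosage = _GT_TOKENS[token]
                if dosage is None:
                    logger.warning(
                        "%s: missing genotype for %s at %s", path, subject, locus
                    )
                profiles[subject][locus] = dosage
    return profiles


def read_allele_counts(
    path: str | Path,
    dialect: str = "tsv",
    sample: str | None = None,
    panel: SNPPanel | None = None,
) -> pd.DataFrame:
    """Read per-locus ref/alt read counts of one post-transplant sample.

    Parameters
    ----------
    dialect : {"tsv", "vcf_ad"}
        ``tsv`` expects columns ``locus_id, ref_count, alt_count``;
        ``vcf_ad`` reads the AD field of a VCF (first sample unless *sample*
        names one, locus ids taken from the ID column).

    Returns
    -------
    pandas.DataFrame
        Indexed by ``locus_id`` with integer columns ``ref_count``,
        ``alt_count`` and ``depth``.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
        required = {"locus_id", "ref_count", "alt_count"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: need columns {sorted(required)}")
        df = df.set_index("locus_id")[["ref_count", "alt_count"]]
    elif dialect == "vcf_ad":
        df = _read_vcf_ad(path, sample)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        bad = df[(df["ref_count"] < 0) | (df["alt_count"] < 0)].index[0]
        raise ValueError(f"negative read count at locus {bad!r}")
    if panel is not None:
        unknown = [loc for loc in df.index if loc not in panel]
        if unknown:
            raise ValueError(f"loci absent from panel: {unknown[:5]}")
    df = df.astype(int)
    df["depth"] = df["ref_count"] + df["alt_count"]
    return df


def _read_vcf_ad(path: str | Path, sample: str | None) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        target = sample or samples[0]
        if target not in samples:
            raise ValueError(f"{path}: sample {target!r} not found")
        for rec in vcf:
            ad = rec.samples[target].get("AD")
            if ad is None or ad[0] is None:
                continue
            locus = rec.id or f"{rec.chrom}:{rec.pos}"
            rows.append((locus, int(ad[0]), int(ad[1])))
    return pd.DataFrame(
        rows, columns=["locus_id", "ref_count", "alt_count"]
    ).set_index("locus_id")


def read_str_peaks(path: str | Path, sep: str | None = None):
    """Read an STR peak table into one profile per subject/sample.

    Expects columns ``subject, marker, allele, area`` (TSV or CSV; the
    delimiter is sniffed from the extension when *sep* is None). Returns
    ``{subject: STRProfile}``.
    """
    from .str_analysis import STRProfile

    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"subject", "marker", "allele", "area"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    profiles = {}
    for subject, sub in df.groupby("subject"):
        peaks = {
            marker: {int(r.allele): float(r.area) for r in grp.itertuples()}
            for marker, grp in sub.groupby("marker")
        }
        profiles[str(subject)] = STRProfile(peaks)
    return profiles


_DOSAGE_TOKENS = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_genotype_table(
    profiles: Mapping[str, Mapping[str, int | None]], path: str | Path
) -> None:
    """Write genotype profiles in the TSV layout `read_genotype_table` reads."""
    subjects = list(profiles)
    loci = list(profiles[subjects[0]])
    with Path(path).open("w") as fh:
        fh.write("\t".join(["locus_id", *subjects]) + "\n")
        for locus in loci:
            tokens = [_DOSAGE_TOKENS[profiles[s].get(locus)] for s in subjects]
            fh.write("\t".join([locus, *tokens]) + "\n")


def write_allele_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a per-locus count table readable by the ``tsv`` dialect."""
    counts[["ref_count", "alt_count"]].rename_axis("locus_id").to_csv(
        path, sep="\t"
    )


_LONG_COLUMNS = ["patient_id", "sample_id", "days_post_hct", "method",
                 "value_pct", "censored"]


def write_longitudinal(records: Sequence[LongitudinalRecord], path: str | Path) -> None:
    """Write longitudinal chimerism records as a TSV (round-trips exactly)."""
    df = pd.DataFrame([vars(r) for r in records], columns=_LONG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_longitudinal(path: str | Path) -> list[LongitudinalRecord]:
    """Read a longitudinal chimerism TSV written by :func:`write_longitudinal`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = [
        LongitudinalRecord(
            patient_id=str(r.patient_id),
            sample_id=str(r.sample_id),
            days_post_hct=int(r.days_post_hct),
            method=str(r.method),
            value_pct=float(r.value_pct),
            censored=bool(r.censored),
        )
        for r in df.itertuples()
    ]
    keys = [(r.patient_id, r.sample_id, r.method) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (patient, sample, method) rows")
    return records
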