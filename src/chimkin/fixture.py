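"""Bundled clinical dataset: consecutive post-transplant chimerism pairs.

The package ships the complete pair-level dataset of a published 29-patient
transplant cohort: 36 consecutive-measurement pairs over 68 unique
post-transplant samples, each measured by both the STR assay and the
SNP-NGS assay, with relapse labels. Consecutive pairs of the same patient
share the middle sample (e.g. patient 4's post2 is the second sample of one
pair and the first of the next), which is why 36 pairs cover 68 rather than
72 samples.

Values printed at the assay floors (0.8 for STR, 0.36 for SNP-NGS) are
complete-chimerism calls: the recipient fraction is below the floor, so the
longitudinal view marks them censored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import METHOD_FLOORS, LongitudinalRecord

__all__ = ["RelapsePairs", "load_relapse_pairs"]

_FIXTURE_NAME = "relapse_pairs.tsv"
_FIXTURE_SHA256 = "11da2f346f81aabd0497c704f5639cc878e0dc75a8480797a611eeaa01d71c36"

N_PAIRS = 36
N_RELAPSED = 12
N_UNIQUE_SAMPLES = 68


@dataclass(frozen=True)
class RelapsePairs:
    """The bundled pair table plus derived per-sample views.

    Attributes
    ----------
    pairs : pandas.DataFrame
        One row per consecutive pair: ``patient_id, sample_t1, sample_t2,
        str_ct1, str_ct2, allo_ct1, allo_ct2, days_hct_to_t1,
        interval_days, relapsed, relapse_diagnosed_days_after_t2``.
    """

    pairs: pd.DataFrame

    def unique_samples(self) -> pd.DataFrame:
        """Deduplicated per-sample table (one row per post-HCT sample).

        Columns ``patient_id, sample_id, days_post_hct, str_pct, allo_pct``.
        Samples shared between consecutive pairs appear once.
        """
        rows = []
        for r in self.pairs.itertuples():
            t1 = r.days_hct_to_t1
            rows.append((r.patient_id, r.sample_t1, t1, r.str_ct1, r.allo_ct1))
            rows.append((r.patient_id, r.sample_t2, t1 + r.interval_days,
                         r.str_ct2, r.allo_ct2))
        df = pd.DataFrame(
            rows,
            columns=["patient_id", "sample_id", "days_post_hct",
                     "str_pct", "allo_pct"],
        )
        return (
            df.drop_duplicates(subset=["patient_id", "sample_id"])
            .reset_index(drop=True)
        )

    def to_longitudinal(self) -> list[LongitudinalRecord]:
        """Expand into per-measurement records (both methods per sample)."""
        records = []
        for r in self.unique_samples().itertuples():
            for method, value in (("STR", r.str_pct), ("SNP-NGS", r.allo_pct)):
                floor = METHOD_FLOORS[method]
                records.append(
                    LongitudinalRecord(
                        patient_id=str(r.patient_id),
                        sample_id=str(r.sample_id),
                        days_post_hct=int(r.days_post_hct),
                        method=method,
                        value_pct=float(value),
                        censored=bool(value == floor),
                    )
                )
        return records


def load_relapse_pairs() -> RelapsePairs:
    """Load the bundled pair table, verifying its checksum and invariants."""
    data = (
        resources.files("chimkin").joinpath("data", _FIXTURE_NAME).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"bundled dataset {_FIXTURE_NAME} is corrupted "
            f"(sha256 {digest}, expected {_FIXTURE_SHA256})"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(data), sep="\t")
    df["relapsed"] = df["relapsed"].map({"yes": True, "no": False})
    fixture = RelapsePairs(df)
    if len(df) != N_PAIRS:
        raise RuntimeError(f"expected {N_PAIRS} pairs, found {len(df)}")
    if int(df["relapsed"].sum()) != N_RELAPSED:
        raise RuntimeError("relapse-label count does not match the source data")
    if len(fixture.unique_samples()) != N_UNIQUE_SAMPLES:
        raise RuntimeError("unique-sample count does not match the source data")
    return fixture
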