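"""Analysis configuration: reporting floors, marker requirements, error model.

All thresholds used across the package live here so a laboratory can override
them from a single YAML file. Defaults follow the validated assay settings:
a 0.36% limit of quantitation for the SNP-NGS assay, a 0.8% limit of
detection for the STR assay, a minimum of three informative markers, and the
relapse-prediction cut-off of 2.36 percentage points on the chimerism change
between consecutive tests.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and numerical settings shared by all analysis stages.

    Attributes
    ----------
    snp_loq_pct : float
        Limit of quantitation of the SNP-NGS assay in percent. Recipient
        fractions below it are reported at the floor with ``censored=True``
        (complete chimerism).
    str_lod_pct : float
        Limit of detection of the STR assay in percent; same censoring rule.
    min_informative : int
        Minimum number of informative markers required for a quantification
        to pass QC (both assays).
    min_mean_coverage : float
        Mean per-marker read depth below which the SNP quantification is
        flagged with a QC warning.
    min_locus_depth : int
        Loci with fewer reads than this are dropped from estimation.
    error_rate : float
        Per-base sequencing/genotyping error rate subtracted in expectation
        from signal-allele fractions.
    delta_c_cutoff : float
        Chimerism-change (percentage points) above which a consecutive pair
        is called test-positive for impending relapse (strict ``>``).
    aggregator : str
        How per-locus fraction estimates are combined: ``"median"``
        (default, robust to sporadic genotype errors) or ``"mean"``.
    bland_altman_population_sd : bool
        Use the population (ddof=0) instead of sample (ddof=1) standard
        deviation for the limits of agreement.
    """

    snp_loq_pct: float = 0.36
    str_lod_pct: float = 0.8
    min_informative: int = 3
    min_mean_coverage: float = 100.0
    min_locus_depth: int = 20
    error_rate: float = 0.001
    delta_c_cutoff: float = 2.36
    aggregator: str = "median"
    bland_altman_population_sd: bool = False

    def __post_init__(self) -> None:
        if self.aggregator not in ("median", "mean"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for name in ("snp_loq_pct", "str_lod_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = AnalysisConfig()


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file.

    The file holds flat ``key: value`` entries and/or nested sections whose
    leaves are merged; unknown keys raise so typos do not silently fall back
    to defaults. ``None`` returns the defaults.
    """
    if path is None:
        return DEFAULT_CONFIG
    raw = yaml.safe_load(Path(path).read_text()) or {}
    flat: dict = {}

    def _walk(d: dict) -> None:
        for k, v in d.items():
            if isinstance(v, dict):
                _walk(v)
            else:
                flat[k] = v

    _walk(raw)
    valid = {f.name for f in fields(AnalysisConfig)}
    unknown = set(flat) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**flat)
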