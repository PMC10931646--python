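"""Method-comparison statistics between two chimerism assays.

Chimerism values are heavily tied at the assay reporting floors (every
complete-chimerism sample prints the floor verbatim), so rank correlation
must use average ranks for ties, and the floors are treated as real data
points rather than excluded. Bland-Altman limits of agreement summarize the
paired differences on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, AnalysisConfig

__all__ = ["BlandAltman", "spearman_rho", "bland_altman", "summarize_cc_mc"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Equivalent to the Pearson correlation of the two rank vectors; raises
    on length mismatch, fewer than three pairs, or a constant vector
    (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltman:
    """Limits of agreement for paired differences ``d = x - y``."""

    mean_diff: float
    lower_limit: float
    upper_limit: float
    sd_diff: float
    prop_within_limits: float
    n: int


def bland_altman(
    x, y, config: AnalysisConfig = DEFAULT_CONFIG
) -> BlandAltman:
    """Bland-Altman agreement analysis of two paired measurement series.

    Limits are ``mean(d) -/+ 2 sd(d)`` with the sample SD by default
    (population SD via config). Degenerate zero-variance differences give
    limits collapsed onto the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    d = x - y
    ddof = 0 if config.bland_altman_population_sd else 1
    sd = float(np.std(d, ddof=ddof))
    mean = float(np.mean(d))
    lower, upper = mean - 2 * sd, mean + 2 * sd
    within = float(np.mean((d >= lower) & (d <= upper)))
    return BlandAltman(mean, lower, upper, sd, within, len(d))


def summarize_cc_mc(
    samples: pd.DataFrame,
    str_col: str = "str_pct",
    snp_col: str = "allo_pct",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Cross-assay censoring summary over deduplicated samples.

    Counts the samples the STR assay calls complete chimerism (value at or
    below its floor) and, among those, the ones where the more sensitive
    SNP-NGS assay still quantifies mixed chimerism (value above its LOQ),
    with the level summary of that subset.

    Requires unique ``(patient_id, sample_id)`` rows: shared samples of
    consecutive pairs must already be deduplicated.
    """
    if samples.empty:
        raise ValueError("no samples supplied")
    key_cols = [c for c in ("patient_id", "sample_id") if c in samples.columns]
    if key_cols and samples.duplicated(subset=key_cols).any():
        raise ValueError("duplicate sample ids; deduplicate before summarizing")
    str_cc = samples[samples[str_col] <= config.str_lod_pct]
    detectable = str_cc[str_cc[snp_col] > config.snp_loq_pct]
    levels = detectable[snp_col]
    return {
        "n_samples": int(len(samples)),
        "n_str_cc": int(len(str_cc)),
        "n_str_mc": int(len(samples) - len(str_cc)),
        "n_cc_with_detectable_mc": int(len(detectable)),
        "detectable_mean": float(levels.mean()) if len(levels) else float("nan"),
        "detectable_min": float(levels.min()) if len(levels) else float("nan"),
        "detectable_max": float(levels.max()) if len(levels) else float("nan"),
    }
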