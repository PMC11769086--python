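"""Chemical-biological composite health index.

Five chemistry indicators (TN, TP, NH3-N, CODMn in the "lower is better"
direction; DO in the "higher is better" direction) are standardized against
the class I-V envelope of the surface-water quality standard, and three
biological metrics (richness T, diversity H, dominance D) against the 5th
and 95th percentiles of the study's pooled biological data.  Equal-weight
means form a nutrient score i_N, an oxygen-balance score i_O, a chemical
layer i_C and a biological layer i_B; the composite index is
I = a * (i_C + i_B) with correction multiplier a = 0.5 for the two
criterion layers, graded on five lower-inclusive bands.

Note on the chemical layer: combining i_N and i_O by their *sum* would push
I past 1 for pristine water, off the top of the grade scale; the default
therefore combines them by their mean, which maps all-perfect indicator
scores to exactly I = 1.0.  The additive form remains available via
``chemical_combine='sum'`` for sensitivity experiments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import (
    BIO_METRICS,
    DEFAULT_COMPOSITE_GRADE_CUTS,
    WQ_INDICATORS,
    AnalysisConfig,
    BioPercentiles,
    StandardBounds,
)
from .errors import ConfigError, ParameterError, ValidationError

logger = logging.getLogger(__name__)


def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def standardize_decreasing(C: float, bounds: tuple[float, float]) -> float:
    """S1 = (Cmax - C)/(Cmax - Cmin), clamped to [0, 1].

    For indicators where a lower concentration is better (TN, TP, NH3-N,
    CODMn): the score is 1 at the class-I bound and 0 at the class-V bound.
    """
    cmin, cmax = bounds
    if cmax == cmin:
        raise ConfigError("degenerate bounds: Cmax equals Cmin")
    return _clamp01((cmax - C) / (cmax - cmin))


def standardize_increasing(C: float, bounds: tuple[float, float]) -> float:
    """S2 = (C - Cmin)/(Cmax - Cmin), clamped; for DO, where more is better."""
    cmin, cmax = bounds
    if cmax == cmin:
        raise ConfigError("degenerate bounds: Cmax equals Cmin")
    return _clamp01((C - cmin) / (cmax - cmin))


def standardize_dominance(M: float, pct: tuple[float, float],
                          metric: str = "D") -> float:
    """S3 = (Q95 - M)/(Q95 - Q5), clamped; high dominance scores low."""
    q5, q95 = pct
    if q95 == q5:
        raise ValidationError(f"degenerate percentiles for {metric}: Q95 equals Q5")
    return _clamp01((q95 - M) / (q95 - q5))


def standardize_richness(M: float, pct: tuple[float, float],
                         metric: str = "T") -> float:
    """S4 = (M - Q5)/(Q95 - Q5), clamped; for T and H, where more is better."""
    q5, q95 = pct
    if q95 == q5:
        raise ValidationError(f"degenerate percentiles for {metric}: Q95 equals Q5")
    return _clamp01((M - q5) / (q95 - q5))


def nutrient_score(S_TN: float, S_TP: float) -> float:
    """i_N: equal-weight mean of the standardized nutrient scores."""
    return (S_TN + S_TP) / 2.0


def oxygen_score(S_DO: float, S_NH3N: float, S_CODMn: float) -> float:
    """i_O: equal-weight mean of the oxygen-balance scores."""
    return (S_DO + S_NH3N + S_CODMn) / 3.0


def biology_score(S_T: float, S_H: float, S_D: float) -> float:
    """i_B: equal-weight mean of the standardized biological scores."""
    return (S_T + S_H + S_D) / 3.0


def chemical_score(i_N: float, i_O: float, combine: str = "mean") -> float:
    """i_C: the chemical criterion layer.

    ``mean`` (default) keeps the composite on [0, 1]; ``sum`` is the
    additive alternative (see module docstring).
    """
    if combine == "mean":
        return (i_N + i_O) / 2.0
    if combine == "sum":
        return i_N + i_O
    raise ConfigError(f"unknown chemical_combine: {combine!r}")


def composite_index(i_C: float, i_B: float, a: float = 0.5, n: int = 2) -> float:
    """I = a * (i_C + i_B): corrected equal-weight sum of the n = 2 layers."""
    if n != 2:
        raise ParameterError("the composite index is defined for n = 2 criterion layers")
    return a * (i_C + i_B)


def grade_composite(I: float,
                    cuts: tuple[float, ...] = DEFAULT_COMPOSITE_GRADE_CUTS) -> str:
    """Five-band grade, lower-inclusive: [0.8,1] healthy ... [0,0.2) very poor."""
    if not 0 <= I <= 1:
        raise ParameterError(f"composite index must lie in [0, 1], got {I}")
    c1, c2, c3, c4 = cuts
    if I >= c1:
        return "healthy"
    if I >= c2:
        return "sub-healthy"
    if I >= c3:
        return "general"
    if I >= c4:
        return "poor"
    return "very poor"


def standardized_scores(sample: pd.Series, metrics: pd.Series,
                        bounds: StandardBounds,
                        percentiles: BioPercentiles) -> dict[str, float]:
    """All eight S-scores for one site x period record."""
    s = {
        "S_TN": standardize_decreasing(sample["TN"], bounds["TN"]),
        "S_TP": standardize_decreasing(sample["TP"], bounds["TP"]),
        "S_NH3N": standardize_decreasing(sample["NH3N"], bounds["NH3N"]),
        "S_CODMn": standardize_decreasing(sample["CODMn"], bounds["CODMn"]),
        "S_DO": standardize_increasing(sample["DO"], bounds["DO"]),
        "S_T": standardize_richness(metrics["T"], percentiles["T"], "T"),
        "S_H": standardize_richness(metrics["H"], percentiles["H"], "H"),
        "S_D": standardize_dominance(metrics["D"], percentiles["D"], "D"),
    }
    return s


def assess_composite(samples: pd.DataFrame, bio_metrics: pd.DataFrame,
                     config: AnalysisConfig | None = None,
                     bounds: StandardBounds | None = None,
                     percentiles: BioPercentiles | None = None) -> pd.DataFrame:
    """Composite index per site x (year, quarter).

    ``samples`` holds the chemistry records, ``bio_metrics`` the matching
    T/H/D rows.  Percentiles default to the 5%/95% quantiles pooled over
    all rows of ``bio_metrics`` — they must span the whole study, not a
    single site.  Records missing an indicator (or without a chemistry /
    biology counterpart) are skipped with a log entry, never imputed.
    """
    config = config or AnalysisConfig()
    bounds = bounds or config.bounds
    if percentiles is None:
        percentiles = BioPercentiles.from_metrics(bio_metrics)
    key = ["site_id", "year", "quarter"]
    bio = bio_metrics.set_index(key)
    rows = []
    for _, sample in samples.iterrows():
        k = (sample["site_id"], sample["year"], sample["quarter"])
        if k not in bio.index:
            logger.info("no biological metrics for %s %sQ%s: record skipped", *k)
            continue
        metrics = bio.loc[k]
        if sample[list(WQ_INDICATORS)].isna().any() or metrics[list(BIO_METRICS)].isna().any():
            logger.info("missing indicator at %s %sQ%s: record skipped", *k)
            continue
        s = standardized_scores(sample, metrics, bounds, percentiles)
        i_N = nutrient_score(s["S_TN"], s["S_TP"])
        i_O = oxygen_score(s["S_DO"], s["S_NH3N"], s["S_CODMn"])
        i_C = chemical_score(i_N, i_O, config.chemical_combine)
        i_B = biology_score(s["S_T"], s["S_H"], s["S_D"])
        I = composite_index(i_C, i_B, a=config.a, n=config.n_layers)
        row = {"site_id": k[0], "year": int(k[1]), "quarter": int(k[2]), **s,
               "i_N": i_N, "i_O": i_O, "i_C": i_C, "i_B": i_B, "I": I}
        row["grade"] = (grade_composite(I, config.composite_grade_cuts)
                        if 0 <= I <= 1 else "off-scale")
        rows.append(row)
    return pd.DataFrame(rows)


def quarter_means(results: pd.DataFrame) -> pd.Series:
    """Mean composite index per quarter, indexed 1..4."""
    return results.groupby("quarter")["I"].mean()
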