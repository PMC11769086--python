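"""Biological metrics and community-composition summaries.

Provides the three metrics feeding the biological layer of the composite
index — taxonomic-unit richness T, a diversity index H (Shannon-Wiener,
natural log by default) and a dominance index D (Simpson concentration
sum(p^2) by default) — plus phylum / subgroup / per-site percentage
breakdowns of the community.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import OccurrenceMatrix
from .errors import ParameterError, ValidationError


def taxon_richness(row: pd.Series | np.ndarray) -> int:
    """T: number of taxa present (presence 1) at a site."""
    vals = np.asarray(row, dtype=float)
    return int((vals > 0).sum())


def shannon_diversity(counts: pd.Series | np.ndarray, base: str = "e") -> float:
    """H = -sum(p_i * log p_i) over taxa with positive abundance.

    ``base`` selects the logarithm: natural (default) or base 2.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("diversity undefined: no individuals counted")
    p = c[c > 0] / total
    H = float(-(p * np.log(p)).sum())
    if base == "2":
        H /= np.log(2.0)
    elif base != "e":
        raise ParameterError(f"unknown log base {base!r}")
    return H


def dominance_index(counts: pd.Series | np.ndarray,
                    metric: str = "simpson") -> float:
    """D: community dominance.

    ``simpson`` (default) is the Simpson concentration sum(p_i^2);
    ``berger_parker`` is the largest single relative abundance max(p_i).
    Either way D is 1 for a monoculture and small for even communities.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("dominance undefined: no individuals counted")
    p = c[c > 0] / total
    if metric == "simpson":
        return float((p ** 2).sum())
    if metric == "berger_parker":
        return float(p.max())
    raise ParameterError(f"unknown dominance metric {metric!r}")


def site_bio_metrics(matrix: OccurrenceMatrix, base: str = "e",
                     dominance: str = "simpson") -> pd.DataFrame:
    """T, H, D per site; H and D need abundance data (fall back to presence
    counts, i.e. a uniform community over the observed taxa, when absent)."""
    table = matrix.abundance if matrix.abundance is not None else matrix.presence
    rows = []
    for sid in matrix.site_ids:
        counts = table.loc[sid]
        T = taxon_richness(matrix.presence.loc[sid])
        if T == 0:
            rows.append({"site_id": sid, "T": 0, "H": 0.0, "D": float("nan")})
            continue
        rows.append({
            "site_id": sid,
            "T": T,
            "H": shannon_diversity(counts, base),
            "D": dominance_index(counts, dominance),
        })
    return pd.DataFrame(rows)


def complement_share(named_shares: dict[str, float],
                     label: str = "other") -> dict[str, float]:
    """Close a set of percentage shares with a residual category.

    The residual absorbs 100 minus the named shares so the totals are
    exactly 100 (e.g. shares of 84.3 and 8.9 leave 6.8 for "other").
    """
    total = sum(named_shares.values())
    if total > 100 + 1e-9:
        raise ParameterError(f"named shares already exceed 100: {total}")
    out = dict(named_shares)
    out[label] = round(100.0 - total, 10)
    return out


def composition_breakdown(matrix: OccurrenceMatrix, level: str = "phylum",
                          phylum: str | None = None) -> pd.DataFrame:
    """Percentage composition of the community.

    level='phylum': share of taxonomic units per phylum, over all taxa in
    the matrix.  level='within_phylum': subgroup shares inside one phylum
    (taxa with a blank subgroup pool into "other").  level='per_site':
    share of *individuals* per phylum at each site; requires abundance.
    Percentages always total 100 (up to rounding).
    """
    tax = matrix.taxonomy.loc[matrix.taxon_ids]
    if level == "phylum":
        counts = tax["phylum"].value_counts()
        pct = 100.0 * counts / counts.sum()
        return pct.rename("percentage").rename_axis("phylum").reset_index()
    if level == "within_phylum":
        if phylum is None:
            raise ParameterError("within_phylum breakdown needs a phylum argument")
        block = tax[tax["phylum"] == phylum]
        if len(block) == 0:
            raise ParameterError(f"no taxa recorded for phylum {phylum!r}")
        sub = block["subgroup"].fillna("other").replace("", "other")
        counts = sub.value_counts()
        pct = 100.0 * counts / counts.sum()
        return pct.rename("percentage").rename_axis("subgroup").reset_index()
    if level == "per_site":
        if matrix.abundance is None:
            raise ParameterError("per-site composition needs abundance data")
        phyla = tax["phylum"]
        totals = matrix.abundance.T.groupby(phyla).sum().T   # sites x phyla
        pct = totals.div(totals.sum(axis=1), axis=0) * 100.0
        return pct.rename_axis(index="site_id", columns="phylum")
    raise ParameterError(f"unknown breakdown level {level!r}")


def plot_per_site_composition(matrix: OccurrenceMatrix, path: str) -> None:
    """Stacked-bar chart of per-site individual shares by phylum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = composition_breakdown(matrix, level="per_site")
    ax = pct.plot.bar(stacked=True, figsize=(8, 4))
    ax.set_ylabel("share of individuals (%)")
    ax.legend(title="phylum", bbox_to_anchor=(1.02, 1), loc="upper left")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
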