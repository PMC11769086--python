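"""Domain types, tabular I/O, configuration and validation.

All tabular exchange formats are comma-separated UTF-8 text with a header
row: an occurrence table (sites x taxa), a taxonomy sidecar
(taxon -> phylum, subgroup), a site table (role + natural predictors) and a
water-quality table (site x period concentrations in mg/L).
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

#: Chemistry indicators entering the composite index, in canonical order.
WQ_INDICATORS = ("TN", "TP", "NH3N", "CODMn", "DO")

#: Biological metrics entering the composite index, in canonical order.
BIO_METRICS = ("T", "H", "D")

#: Natural predictors used to classify sites into reference groups.
PREDICTOR_NAMES = (
    "lake_area",
    "shoreline_length",
    "mean_depth",
    "retention_time",
    "mean_temperature",
    "mean_rainfall",
)

SITE_ROLES = ("reference", "damaged", "severely_damaged", "test")

#: Class I-V envelope (Cmin, Cmax) per indicator of the Chinese surface-water
#: quality standard GB3838-2002, lake/reservoir column for TP.  These are
#: editable configuration defaults, not constants of the method.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "TN": (0.2, 2.0),
    "TP": (0.01, 0.2),
    "NH3N": (0.15, 2.0),
    "CODMn": (2.0, 15.0),
    "DO": (2.0, 7.5),
}

#: Lower cut points of the O/E grade bands (top band lower-inclusive,
#: the bottom cut itself belongs to "Poor").
DEFAULT_OE_GRADE_CUTS = (0.79, 0.59, 0.39, 0.19)
OE_GRADE_LABELS = ("Excellent", "Healthy", "Sub-healthy", "General", "Poor")

#: Lower cut points of the composite-index grade bands (lower-inclusive).
DEFAULT_COMPOSITE_GRADE_CUTS = (0.8, 0.6, 0.4, 0.2)
COMPOSITE_GRADE_LABELS = ("healthy", "sub-healthy", "general", "poor", "very poor")


# ---------------------------------------------------------------------------
# quarters


def quarter_of_month(month: int) -> int:
    """Map a calendar month to its quarter: Jan-Mar -> 1, ..., Oct-Dec -> 4."""
    if not 1 <= int(month) <= 12:
        raise ValidationError(f"month out of range: {month!r}")
    return (int(month) - 1) // 3 + 1


def quarter_of_date(date: _dt.date | str) -> int:
    """Quarter of a date or ISO date string."""
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date.strip())
        except ValueError as exc:
            raise FormatError(f"unparseable date: {date!r}") from exc
    return quarter_of_month(date.month)


# ---------------------------------------------------------------------------
# occurrence matrix


@dataclass
class OccurrenceMatrix:
    """Sites x taxa community table with a taxonomy sidecar.

    ``presence`` is a strictly 0/1 integer frame.  ``abundance`` (optional)
    holds the raw counts the presence frame was binarized from; where given
    it must satisfy presence == (abundance > 0).  ``taxonomy`` maps each
    taxon id to a (phylum, subgroup) pair.
    """

    presence: pd.DataFrame
    taxonomy: pd.DataFrame
    abundance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.presence = self.presence.rename_axis(index="site_id", columns=None)
        if self.abundance is not None:
            self.abundance = self.abundance.rename_axis(index="site_id", columns=None)
        self.taxonomy = self.taxonomy.rename_axis(index="taxon_id")
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        pres = self.presence
        if pres.index.duplicated().any():
            raise ValidationError("duplicate site identifiers in occurrence matrix")
        if pres.columns.duplicated().any():
            raise ValidationError("duplicate taxon identifiers in occurrence matrix")
        vals = pres.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence matrix must contain only 0/1 values")
        missing = [t for t in pres.columns if t not in self.taxonomy.index]
        if missing:
            raise ValidationError(
                "taxa missing from taxonomy sidecar: " + ", ".join(map(str, missing))
            )
        if self.abundance is not None:
            ab = self.abundance
            if not ab.index.equals(pres.index) or not ab.columns.equals(pres.columns):
                raise ValidationError("abundance table not aligned with presence table")
            a = ab.to_numpy(dtype=float)
            if (a < 0).any():
                raise ValidationError("negative abundance values")
            if not np.array_equal((a > 0).astype(int), vals.astype(int)):
                raise ValidationError("presence != (abundance > 0)")

    # -- conveniences ------------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.presence.columns)

    def subset_sites(self, site_ids: Sequence[str]) -> "OccurrenceMatrix":
        ab = self.abundance.loc[list(site_ids)] if self.abundance is not None else None
        return OccurrenceMatrix(self.presence.loc[list(site_ids)], self.taxonomy, ab)

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "OccurrenceMatrix":
        cols = list(taxon_ids)
        ab = self.abundance[cols] if self.abundance is not None else None
        return OccurrenceMatrix(self.presence[cols], self.taxonomy, ab)


def read_occurrence_table(path: str | Path, taxonomy_path: str | Path) -> OccurrenceMatrix:
    """Read a sites x taxa table plus its taxonomy sidecar.

    Cell values may be counts; they are binarized into the presence frame
    and, when any cell exceeds 1, retained as the abundance frame.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    taxa = header[1:]
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"duplicate taxon columns in {path.name}")
    raw = pd.read_csv(path, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = [str(c) for c in taxa]
    if raw.index.duplicated().any():
        raise FormatError(f"duplicate site rows in {path.name}")
    vals = raw.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError(f"negative cell values in {path.name}")
    taxonomy = read_taxonomy_table(taxonomy_path)
    presence = (raw > 0).astype(int)
    abundance = raw.astype(float) if (vals > 1).any() else None
    return OccurrenceMatrix(presence, taxonomy, abundance)


def write_occurrence_table(matrix: OccurrenceMatrix, path: str | Path,
                           taxonomy_path: str | Path | None = None) -> None:
    table = matrix.abundance if matrix.abundance is not None else matrix.presence
    table.to_csv(path, index_label="site_id")
    if taxonomy_path is not None:
        write_taxonomy_table(matrix.taxonomy, taxonomy_path)


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path)
    required = {"taxon_id", "phylum", "subgroup"}
    if not required.issubset(tax.columns):
        raise FormatError(f"taxonomy table needs columns {sorted(required)}")
    tax["taxon_id"] = tax["taxon_id"].astype(str)
    if tax["taxon_id"].duplicated().any():
        raise FormatError("duplicate taxon ids in taxonomy table")
    return tax.set_index("taxon_id")[["phylum", "subgroup"]]


def write_taxonomy_table(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, index_label="taxon_id")


# ---------------------------------------------------------------------------
# site records


@dataclass
class SiteRecord:
    """A monitoring site: identifier, disturbance role and natural predictors."""

    site_id: str
    role: str
    predictors: dict[str, float]

    def __post_init__(self) -> None:
        if self.role not in SITE_ROLES:
            raise ValidationError(
                f"site {self.site_id}: unknown role {self.role!r} (expected one of {SITE_ROLES})"
            )
        bad = [k for k, v in self.predictors.items() if v is None or not np.isfinite(v)]
        if bad:
            raise ValidationError(f"site {self.site_id}: missing predictor values {bad}")


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table: columns ``site_id``, ``role``, then predictors.

    Returns a frame indexed by site_id; every row is validated as a
    :class:`SiteRecord`.
    """
    df = pd.read_csv(path)
    if "site_id" not in df.columns or "role" not in df.columns:
        raise FormatError("site table needs 'site_id' and 'role' columns")
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        raise FormatError("duplicate site ids in site table")
    df = df.set_index("site_id")
    pred_cols = [c for c in df.columns if c != "role"]
    for sid, row in df.iterrows():
        SiteRecord(sid, row["role"], {c: row[c] for c in pred_cols})
    return df


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, index_label="site_id")


def predictor_frame(sites: pd.DataFrame) -> pd.DataFrame:
    """The numeric predictor block of a site table, role column dropped."""
    return sites.drop(columns=["role"]).astype(float)


# ---------------------------------------------------------------------------
# water quality


@dataclass
class WaterQualitySample:
    """One site x period set of chemistry measurements (mg/L)."""

    site_id: str
    year: int
    quarter: int
    TN: float
    TP: float
    NH3N: float
    CODMn: float
    DO: float

    def __post_init__(self) -> None:
        if self.quarter not in (1, 2, 3, 4):
            raise ValidationError(f"site {self.site_id}: quarter must be 1-4")
        for name in WQ_INDICATORS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"site {self.site_id} {self.year}Q{self.quarter}: "
                    f"{name} must be a non-negative number, got {v!r}"
                )
        if self.DO <= 0:
            raise ValidationError(
                f"site {self.site_id} {self.year}Q{self.quarter}: DO must be > 0"
            )


def read_waterquality_table(path: str | Path) -> pd.DataFrame:
    """Read water-quality records into a validated frame.

    Accepts either a ``date`` column (ISO dates; year and quarter are
    derived) or explicit ``year`` and ``quarter`` columns.  Returns columns
    site_id, year, quarter, TN, TP, NH3N, CODMn, DO.
    """
    df = pd.read_csv(path)
    needed = {"site_id", *WQ_INDICATORS}
    if not needed.issubset(df.columns):
        raise FormatError(f"water-quality table needs columns {sorted(needed)}")
    df["site_id"] = df["site_id"].astype(str)
    if "date" in df.columns:
        dates = [str(d) for d in df["date"]]
        df["quarter"] = [quarter_of_date(d) for d in dates]
        df["year"] = [_dt.date.fromisoformat(d.strip()).year for d in dates]
    elif {"year", "quarter"}.issubset(df.columns):
        df["year"] = df["year"].astype(int)
        df["quarter"] = df["quarter"].astype(int)
    else:
        raise FormatError("water-quality table needs a 'date' or 'year'+'quarter' column")
    out = df[["site_id", "year", "quarter", *WQ_INDICATORS]].copy()
    for _, row in out.iterrows():
        WaterQualitySample(row["site_id"], int(row["year"]), int(row["quarter"]),
                           *(float(row[k]) for k in WQ_INDICATORS))
    return out


def write_waterquality_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


def read_biometrics_table(path: str | Path) -> pd.DataFrame:
    """Read per site x period biological metrics (columns T, H, D)."""
    df = pd.read_csv(path)
    needed = {"site_id", "year", "quarter", *BIO_METRICS}
    if not needed.issubset(df.columns):
        raise FormatError(f"bio-metrics table needs columns {sorted(needed)}")
    df["site_id"] = df["site_id"].astype(str)
    return df[["site_id", "year", "quarter", *BIO_METRICS]].copy()


# ---------------------------------------------------------------------------
# standardization envelopes


@dataclass(frozen=True)
class StandardBounds:
    """Per-indicator (Cmin, Cmax) envelope used by chemistry standardization."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise ConfigError(f"bounds for {name}: Cmax ({hi}) must exceed Cmin ({lo})")

    def __getitem__(self, indicator: str) -> tuple[float, float]:
        try:
            return tuple(self.bounds[indicator])
        except KeyError:
            raise ConfigError(f"no standard bounds configured for {indicator!r}") from None


@dataclass(frozen=True)
class BioPercentiles:
    """Per-metric (Q5, Q95) percentiles of the biological data, all sites pooled."""

    percentiles: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (q5, q95) in self.percentiles.items():
            if q95 < q5:
                raise ValidationError(f"percentiles for {name}: Q95 < Q5")

    def __getitem__(self, metric: str) -> tuple[float, float]:
        try:
            return tuple(self.percentiles[metric])
        except KeyError:
            raise ConfigError(f"no percentiles available for {metric!r}") from None

    def is_degenerate(self, metric: str) -> bool:
        q5, q95 = self[metric]
        return q95 == q5

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame,
                     columns: Sequence[str] = BIO_METRICS) -> "BioPercentiles":
        """Linear-interpolation 5th/95th percentiles pooled over all records."""
        pct = {}
        for col in columns:
            vals = metrics[col].to_numpy(dtype=float)
            q5, q95 = np.percentile(vals, [5, 95])
            pct[col] = (float(q5), float(q95))
        return cls(pct)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Resolved run configuration; every field has a documented default."""

    seed: int = 42
    # O/E model
    pc_threshold: float = 0.5
    rare_taxon_max_freq: float = 0.05
    beta: float = -0.5
    n_groups: int | None = None            # None -> silhouette selection
    group_candidates: tuple[int, int] = (2, 8)
    n_trees: int = 100
    max_depth: int | None = None
    cv_folds: int = 5
    # composite index
    a: float = 0.5
    n_layers: int = 2
    chemical_combine: str = "mean"         # "mean" (default) or "sum" (printed form)
    diversity_log_base: str = "e"          # "e" or "2"
    dominance_metric: str = "simpson"      # "simpson" or "berger_parker"
    bounds: StandardBounds = field(default_factory=StandardBounds)
    oe_grade_cuts: tuple[float, ...] = DEFAULT_OE_GRADE_CUTS
    composite_grade_cuts: tuple[float, ...] = DEFAULT_COMPOSITE_GRADE_CUTS

    def __post_init__(self) -> None:
        if not 0 <= self.pc_threshold < 1:
            raise ConfigError(f"pc_threshold must be in [0, 1), got {self.pc_threshold}")
        if not 0 <= self.rare_taxon_max_freq < 1:
            raise ConfigError(
                f"rare_taxon_max_freq must be in [0, 1), got {self.rare_taxon_max_freq}"
            )
        if not self.beta < 1:
            raise ConfigError(f"clustering beta must be < 1, got {self.beta}")
        if self.n_trees < 1:
            raise ConfigError("forest size must be positive")
        if self.chemical_combine not in ("mean", "sum"):
            raise ConfigError("chemical_combine must be 'mean' or 'sum'")
        if self.diversity_log_base not in ("e", "2"):
            raise ConfigError("diversity_log_base must be 'e' or '2'")
        if self.dominance_metric not in ("simpson", "berger_parker"):
            raise ConfigError("dominance_metric must be 'simpson' or 'berger_parker'")
        if self.a <= 0:
            raise ConfigError("correction multiplier a must be positive")

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, StandardBounds):
                v = {k: list(b) for k, b in v.bounds.items()}
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML config file, filling unspecified keys with defaults.

    An empty or missing file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            data = loaded
    kwargs: dict = {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if key == "bounds":
            merged = dict(DEFAULT_BOUNDS)
            for ind, pair in value.items():
                if ind not in DEFAULT_BOUNDS:
                    raise ConfigError(f"unknown indicator in bounds: {ind!r}")
                merged[ind] = (float(pair[0]), float(pair[1]))
            kwargs["bounds"] = StandardBounds(merged)
        elif key in ("group_candidates", "oe_grade_cuts", "composite_grade_cuts"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return AnalysisConfig(**kwargs)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False),
                          encoding="utf-8")
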