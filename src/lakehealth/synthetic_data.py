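"""Synthetic survey generator with known ground truth.

Emulates the three inputs of a lake bioassessment campaign — a benthic
occurrence matrix with taxonomy, a site table with natural predictors, and
seasonal water-quality series — with planted structure that every pipeline
stage can be checked against:

* reference sites fall into distinct community groups (group-specific taxa
  occur with high probability within the group, rarely elsewhere) whose
  predictor centroids are separable, so clustering and the group classifier
  have a recoverable target;
* impaired sites are reference draws whose high-occurrence ("expected")
  taxa are preferentially suppressed, so the O/E score has a planted
  monotone response to the impairment fraction;
* water chemistry and biology follow quarterly quality levels ordered
  Q1 > Q4 > Q2 > Q3 (spring best, autumn worst), so the composite index has
  a planted seasonal ordering.

Everything is drawn from a single seeded generator: the same seed
reproduces the identical world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    PREDICTOR_NAMES,
    WQ_INDICATORS,
    OccurrenceMatrix,
    StandardBounds,
)
from .errors import ValidationError

#: Typical magnitudes for a large shallow floodplain lake, used as predictor
#: baselines (km^2, km, m, days, deg C, mm/yr).
_PRED_BASE = (3000.0, 1200.0, 8.0, 30.0, 17.0, 1600.0)
_PRED_SCALE = (400.0, 150.0, 1.5, 5.0, 1.5, 120.0)

_PHYLA = (
    ("Mollusca", ("Gastropoda", "Valvularia")),
    ("Annelida", ("Oligochaeta", "Polychaeta")),
    ("Arthropoda", ("Insecta", "Crustacea")),
)


@dataclass
class WorldSpec:
    """Parameters of the synthetic study system.

    Quarter quality levels are target standardized scores (0 = worst bound,
    1 = best bound) encoding the planted seasonal ordering; noise scales are
    in the same standardized units.
    """

    n_groups: int = 3
    n_ref_per_group: int = 5
    n_taxa: int = 40
    n_shared_taxa: int = 4
    high_prob: float = 0.9          # group-specific taxon, within its group
    low_prob: float = 0.05          # group-specific taxon, elsewhere
    shared_prob: float = 0.7        # ubiquitous taxa, everywhere
    centroid_separation: float = 6.0  # predictor centroid offset, in noise SDs
    predictor_noise: float = 1.0
    quarter_quality: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.85, 4: 0.65, 2: 0.55, 3: 0.40}
    )
    wq_noise: float = 0.1
    severity_gain: float = 0.5      # quality drop per unit site severity
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("high_prob", "low_prob", "shared_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if sorted(self.quarter_quality) != [1, 2, 3, 4]:
            raise ValidationError("quarter_quality must cover quarters 1-4")
        if not all(0 < q < 1 for q in self.quarter_quality.values()):
            raise ValidationError("quarter quality levels must lie in (0, 1)")
        if self.n_taxa <= self.n_shared_taxa:
            raise ValidationError("need more taxa than shared taxa")


def make_taxonomy(spec: WorldSpec) -> pd.DataFrame:
    rows = []
    for t in range(spec.n_taxa):
        phylum, subgroups = _PHYLA[t % len(_PHYLA)]
        rows.append({"taxon_id": f"t{t + 1:03d}", "phylum": phylum,
                     "subgroup": subgroups[(t // len(_PHYLA)) % len(subgroups)]})
    return pd.DataFrame(rows).set_index("taxon_id")


def group_profiles(spec: WorldSpec) -> pd.DataFrame:
    """Per-group taxon occurrence probabilities (groups x taxa).

    The first ``n_taxa - n_shared_taxa`` taxa are split evenly into
    group-specific blocks; the tail is shared at ``shared_prob``.
    """
    taxa = [f"t{t + 1:03d}" for t in range(spec.n_taxa)]
    n_specific = spec.n_taxa - spec.n_shared_taxa
    per_group = n_specific // spec.n_groups
    P = np.full((spec.n_groups, spec.n_taxa), spec.low_prob)
    for g in range(spec.n_groups):
        lo = g * per_group
        hi = n_specific if g == spec.n_groups - 1 else lo + per_group
        P[g, lo:hi] = spec.high_prob
    P[:, n_specific:] = spec.shared_prob
    return pd.DataFrame(P, index=range(spec.n_groups), columns=taxa)


def _draw_predictors(spec: WorldSpec, groups: Sequence[int],
                     rng: np.random.Generator) -> np.ndarray:
    n_pred = len(PREDICTOR_NAMES)
    out = np.empty((len(groups), n_pred))
    for i, g in enumerate(groups):
        z = np.array([spec.centroid_separation if d % spec.n_groups == g else 0.0
                      for d in range(n_pred)])
        z = z + spec.predictor_noise * rng.standard_normal(n_pred)
        out[i] = np.array(_PRED_BASE) + np.array(_PRED_SCALE) * z
    return out


def _draw_occurrence(profiles: pd.DataFrame, groups: Sequence[int],
                     ids: Sequence[str], rng: np.random.Generator,
                     impairment: float = 0.0) -> pd.DataFrame:
    """Bernoulli presence per taxon; impairment suppresses high-prob taxa."""
    P = profiles.to_numpy()
    rows = np.empty((len(groups), P.shape[1]), dtype=int)
    for i, g in enumerate(groups):
        pres = rng.random(P.shape[1]) < P[g]
        if impairment > 0:
            high = P[g] >= 0.5
            suppressed = rng.random(P.shape[1]) < impairment
            pres = pres & ~(high & suppressed)
        rows[i] = pres.astype(int)
    return pd.DataFrame(rows, index=list(ids), columns=profiles.columns)


def _with_abundance(presence: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    counts = rng.poisson(5, size=presence.shape) + 1
    return pd.DataFrame(counts * presence.to_numpy(), index=presence.index,
                        columns=presence.columns).astype(float)


def _site_frame(ids: Sequence[str], roles: Sequence[str],
                predictors: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(predictors, index=list(ids), columns=list(PREDICTOR_NAMES))
    df.insert(0, "role", list(roles))
    return df.rename_axis(index="site_id")


def generate_reference_world(
    spec: WorldSpec, seed: int | None = None, n_per_group: int | None = None,
    role: str = "reference", prefix: str = "R",
) -> tuple[OccurrenceMatrix, pd.DataFrame, pd.Series]:
    """Reference sites with known group labels.

    Returns the occurrence matrix (with abundance), the site table and the
    ground-truth group label per site.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    npg = spec.n_ref_per_group if n_per_group is None else n_per_group
    groups = [g for g in range(spec.n_groups) for _ in range(npg)]
    ids = [f"{prefix}{i + 1:02d}" for i in range(len(groups))]
    profiles = group_profiles(spec)
    presence = _draw_occurrence(profiles, groups, ids, rng)
    matrix = OccurrenceMatrix(presence, make_taxonomy(spec),
                              _with_abundance(presence, rng))
    sites = _site_frame(ids, [role] * len(ids), _draw_predictors(spec, groups, rng))
    return matrix, sites, pd.Series(groups, index=ids, name="group")


def generate_impaired_sites(
    spec: WorldSpec, impairment: float, n_sites: int, seed: int,
    groups: Sequence[int] | None = None, role: str | None = None,
    prefix: str = "D",
) -> tuple[OccurrenceMatrix, pd.DataFrame, pd.Series]:
    """Sites drawn from reference profiles with expected taxa suppressed.

    Each high-occurrence taxon of the site's source group is independently
    deleted with probability ``impairment``.  Role defaults to ``damaged``,
    escalating to ``severely_damaged`` at impairment >= 0.75 and relaxing
    to ``test`` at impairment 0.
    """
    if not 0 <= impairment <= 1:
        raise ValidationError(f"impairment must lie in [0, 1], got {impairment}")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = list(rng.integers(0, spec.n_groups, size=n_sites))
    if role is None:
        role = ("severely_damaged" if impairment >= 0.75
                else "damaged" if impairment > 0 else "test")
    ids = [f"{prefix}{i + 1:02d}" for i in range(n_sites)]
    profiles = group_profiles(spec)
    presence = _draw_occurrence(profiles, groups, ids, rng, impairment)
    matrix = OccurrenceMatrix(presence, make_taxonomy(spec),
                              _with_abundance(presence, rng))
    sites = _site_frame(ids, [role] * n_sites, _draw_predictors(spec, groups, rng))
    return matrix, sites, pd.Series(list(groups), index=ids, name="group")


def generate_waterquality_series(
    spec: WorldSpec, site_ids: Sequence[str], years: Sequence[int], seed: int,
    site_severity: Mapping[str, float] | None = None,
    bounds: StandardBounds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seasonal chemistry and paired biological metrics per site x period.

    Each record's latent quality level is the quarter's planted level minus
    ``severity_gain`` times the site's severity, plus Gaussian noise in
    standardized units; concentrations are mapped through the standard
    bounds (inverted for the "lower is better" indicators) and truncated at
    zero, and the biological metrics degrade with the same latent quality.
    """
    rng = np.random.default_rng(seed)
    bounds = bounds or StandardBounds()
    severity = dict(site_severity or {})
    wq_rows, bio_rows = [], []
    for sid in site_ids:
        sev = severity.get(sid, 0.0)
        for year in years:
            for quarter in (1, 2, 3, 4):
                q0 = spec.quarter_quality[quarter] - spec.severity_gain * sev
                rec = {"site_id": sid, "year": int(year), "quarter": quarter}
                for ind in WQ_INDICATORS:
                    cmin, cmax = bounds[ind]
                    q = np.clip(q0 + spec.wq_noise * rng.standard_normal(), 0.0, 1.0)
                    if ind == "DO":                       # higher is better
                        c = cmin + q * (cmax - cmin)
                        rec[ind] = max(c, 0.05)
                    else:                                 # lower is better
                        rec[ind] = max(cmax - q * (cmax - cmin), 0.0)
                wq_rows.append(rec)
                bT, bH, bD = np.clip(
                    q0 + spec.wq_noise * rng.standard_normal(3), 0.0, 1.0)
                bio_rows.append({
                    "site_id": sid, "year": int(year), "quarter": quarter,
                    "T": int(2 + round(18 * bT)),
                    "H": float(0.2 + 2.3 * bH),
                    "D": float(1.0 - 0.85 * bD),
                })
    return pd.DataFrame(wq_rows), pd.DataFrame(bio_rows)


@dataclass
class SurveyBundle:
    """A complete simulated campaign ready for the dual evaluation."""

    spec: WorldSpec
    matrix: OccurrenceMatrix           # all sites stacked
    sites: pd.DataFrame                # roles + predictors for all sites
    true_groups: pd.Series
    severity: pd.Series                # latent severity per non-reference site
    waterquality: pd.DataFrame
    bio_metrics: pd.DataFrame


def _stack(matrices: Sequence[OccurrenceMatrix]) -> OccurrenceMatrix:
    presence = pd.concat([m.presence for m in matrices])
    abundance = pd.concat([m.abundance for m in matrices])
    return OccurrenceMatrix(presence, matrices[0].taxonomy, abundance)


def simulate_survey(spec: WorldSpec | None = None, seed: int = 42,
                    n_test: int = 11, n_severe: int = 4,
                    years: Sequence[int] | None = None) -> SurveyBundle:
    """Simulate a full campaign with one latent severity driving both
    community impairment and chemistry degradation.

    Test sites receive severities spread over [0, 0.8]; severely damaged
    sites sit at 0.85.  The shared driver makes the O/E score and the
    composite index positively coupled across sites by construction.
    """
    spec = spec or WorldSpec()
    years = list(years) if years is not None else list(range(2018, 2023))
    root = np.random.default_rng(seed)
    s_ref, s_test, s_sev, s_wq = root.integers(0, 2**31 - 1, size=4)

    ref_matrix, ref_sites, ref_groups = generate_reference_world(spec, seed=int(s_ref))
    severities = np.linspace(0.0, 0.8, n_test)
    test_parts, test_sites, test_groups, sev_map = [], [], [], {}
    test_rng = np.random.default_rng(int(s_test))
    for i, sev in enumerate(severities):
        sid_seed = int(test_rng.integers(0, 2**31 - 1))
        m, s, g = generate_impaired_sites(spec, float(sev), 1, sid_seed,
                                          role="test", prefix=f"T{i + 1:02d}_")
        m.presence.index = s.index = g.index = [f"T{i + 1:02d}"]
        m.abundance.index = m.presence.index
        test_parts.append(m)
        test_sites.append(s)
        test_groups.append(g)
        sev_map[f"T{i + 1:02d}"] = float(sev)
    sev_matrix, sev_sites, sev_groups = generate_impaired_sites(
        spec, 0.85, n_severe, int(s_sev), prefix="S")
    for sid in sev_sites.index:
        sev_map[sid] = 0.85

    matrix = _stack([ref_matrix] + test_parts + [sev_matrix])
    sites = pd.concat([ref_sites] + test_sites + [sev_sites])
    groups = pd.concat([ref_groups] + test_groups + [sev_groups])
    wq, bio = generate_waterquality_series(
        spec, list(sites.index), years, int(s_wq), site_severity=sev_map)
    return SurveyBundle(spec, matrix, sites, groups,
                        pd.Series(sev_map, name="severity"), wq, bio)
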