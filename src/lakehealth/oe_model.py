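"""RIVPACS-style O/E predictive model for benthic community integrity.

The model is built from minimally disturbed (reference) sites only:

1. taxa occurring at <= 5% of reference sites are excluded;
2. reference sites are clustered on Sørensen dissimilarity of their
   presence/absence profiles with flexible-beta agglomeration (beta = -0.5);
3. per-group taxon occurrence frequencies f(t|g) are tabulated;
4. a random forest maps natural predictors (geomorphology, climate) to
   group-membership probabilities p_g for any site;
5. each taxon's probability of capture pc(t) = sum_g p_g * f(t|g);
6. E is the sum of pc over taxa passing the pc threshold, O the count of
   observed taxa passing it, and the O/E ratio is graded on five bands.

Sites with intact communities score near 1; taxon loss pulls the score
toward 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .data_model import (
    DEFAULT_OE_GRADE_CUTS,
    AnalysisConfig,
    OccurrenceMatrix,
    predictor_frame,
)
from .errors import (
    ModelBuildError,
    ParameterError,
    UndefinedScoreError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# dissimilarity


def sorensen_dissimilarity(matrix: OccurrenceMatrix,
                           site_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity D = 1 - 2a/(2a + b + c).

    ``a`` counts shared taxa, ``b`` and ``c`` taxa unique to either site.
    Two empty sites are defined as identical (D = 0, with a warning); an
    empty site against a non-empty one is maximally dissimilar (D = 1).
    """
    pres = matrix.presence
    if site_subset is not None:
        pres = pres.loc[list(site_subset)]
    if len(pres) < 2:
        raise ParameterError("Sørensen dissimilarity needs at least two sites")
    X = pres.to_numpy(dtype=float)
    shared = X @ X.T                      # a
    richness = X.sum(axis=1)              # a + b per site
    denom = richness[:, None] + richness[None, :]   # 2a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - 2.0 * shared / denom
    both_empty = denom == 0
    if both_empty.any():
        warnings.warn("sites with no taxa: dissimilarity of two empty sites set to 0")
        D[both_empty] = 0.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0                   # enforce exact symmetry
    return pd.DataFrame(D, index=pres.index, columns=pres.index)


# ---------------------------------------------------------------------------
# rare-taxon exclusion


def filter_rare_taxa(matrix: OccurrenceMatrix, max_freq: float) -> OccurrenceMatrix:
    """Drop taxa whose occurrence frequency across the given sites is <= max_freq.

    The exclusion is boundary-inclusive: a taxon at exactly the cutoff
    frequency is removed.
    """
    if not 0 <= max_freq < 1:
        raise ParameterError(f"max_freq must be in [0, 1), got {max_freq}")
    freq = matrix.presence.mean(axis=0)
    retained = list(freq.index[freq > max_freq])
    if not retained:
        raise ModelBuildError("rare-taxon exclusion removed every taxon")
    return matrix.subset_taxa(retained)


# ---------------------------------------------------------------------------
# flexible-beta agglomerative clustering


def flexible_beta_linkage(D: np.ndarray, beta: float) -> list[tuple[int, int, float]]:
    """Full agglomerative merge sequence under the Lance-Williams recurrence.

    Flexible beta: alpha_i = alpha_j = (1 - beta)/2, gamma = 0, so after
    merging clusters i and j the distance to any k is

        d(k, i+j) = alpha * (d(k, i) + d(k, j)) + beta * d(i, j).

    Returns merges as (rep_i, rep_j, height) with rep indices referring to
    the representative (smallest original index) of each merged cluster.
    Ties are broken toward the lexicographically smallest index pair, which
    makes the sequence deterministic.
    """
    if not beta < 1:
        raise ParameterError(f"beta must be < 1, got {beta}")
    n = D.shape[0]
    alpha = (1.0 - beta) / 2.0
    d = D.astype(float).copy()
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        best: tuple[float, int, int] | None = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                cand = (d[i, j], i, j)
                if best is None or cand < best:
                    best = cand
        height, i, j = best
        for k in active:
            if k in (i, j):
                continue
            dnew = alpha * (d[i, k] + d[j, k]) + beta * height
            d[i, k] = d[k, i] = dnew
        active.remove(j)
        merges.append((i, j, height))
    return merges


def flexible_beta_cluster(D: pd.DataFrame | np.ndarray, beta: float,
                          n_groups: int) -> np.ndarray:
    """Cut the flexible-beta merge tree at ``n_groups`` clusters.

    Returns integer labels 0..n_groups-1 ordered by each group's smallest
    site index; deterministic for a fixed input.
    """
    Dv = D.to_numpy() if isinstance(D, pd.DataFrame) else np.asarray(D, dtype=float)
    n = Dv.shape[0]
    if not 1 <= n_groups <= n:
        raise ParameterError(f"n_groups must be in [1, {n}], got {n_groups}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, j, _ in flexible_beta_linkage(Dv, beta)[: n - n_groups]:
        members[i].extend(members.pop(j))
    labels = np.empty(n, dtype=int)
    for g, rep in enumerate(sorted(members, key=lambda r: min(members[r]))):
        labels[members[rep]] = g
    return labels


def select_n_groups(D: pd.DataFrame | np.ndarray,
                    candidates: Iterable[int] | None = None,
                    beta: float = -0.5) -> int:
    """Pick the group count maximizing mean silhouette width over ``D``.

    Candidates default to 2..min(8, n-1); ties resolve toward the smaller
    count so that uninformative dissimilarities give the simplest grouping.
    """
    Dv = D.to_numpy() if isinstance(D, pd.DataFrame) else np.asarray(D, dtype=float)
    n = Dv.shape[0]
    if n < 3:
        raise ModelBuildError("group selection needs at least 3 reference sites")
    if candidates is None:
        candidates = range(2, min(8, n - 1) + 1)
    cands = sorted(set(int(k) for k in candidates))
    if any(k < 2 or k > n - 1 for k in cands):
        raise ParameterError(f"candidate group counts must lie in [2, {n - 1}]")
    best_k, best_s = None, -np.inf
    for k in cands:
        labels = flexible_beta_cluster(Dv, beta, k)
        s = silhouette_score(Dv, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


# ---------------------------------------------------------------------------
# group frequencies and membership


def group_frequencies(matrix: OccurrenceMatrix,
                      labels: Sequence[int]) -> pd.DataFrame:
    """Occurrence frequency f(t|g) of each retained taxon within each group."""
    labels = np.asarray(labels)
    if len(labels) != len(matrix.site_ids):
        raise ValidationError("labels must cover every reference site")
    rows = {}
    for g in np.unique(labels):
        block = matrix.presence.iloc[labels == g]
        if len(block) == 0:
            raise ModelBuildError(f"reference group {g} is empty")
        rows[int(g)] = block.mean(axis=0)
    return pd.DataFrame(rows).T.rename_axis(index="group")


def fit_group_classifier(predictors: pd.DataFrame, labels: Sequence[int],
                         config: AnalysisConfig) -> tuple[RandomForestClassifier, float]:
    """Random-forest group classifier with cross-validated accuracy.

    The forest uses ``config.n_trees`` fully grown trees (no depth cap by
    default) and a fixed seed.  The fold count drops to the smallest group
    size when a group has fewer sites than the configured folds.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ModelBuildError("classifier needs at least two reference groups")
    counts = pd.Series(y).value_counts()
    folds = int(config.cv_folds)
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        warnings.warn(
            f"smallest group has {counts.min()} sites; reducing CV folds to {folds}"
        )
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
    )
    if counts.min() >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
        cv_accuracy = float(cross_val_score(clf, predictors, y, cv=cv).mean())
    else:
        warnings.warn("a reference group has a single site; CV accuracy unavailable")
        cv_accuracy = float("nan")
    clf.fit(predictors, y)
    return clf, cv_accuracy


def capture_probabilities(membership: pd.DataFrame,
                          freqs: pd.DataFrame) -> pd.DataFrame:
    """pc(t) = sum_g p_g * f(t|g) for every site (rows) and taxon (columns)."""
    if set(membership.columns) != set(freqs.index):
        raise ValidationError("membership and frequency tables use different groups")
    aligned = membership[list(freqs.index)]
    pc = aligned.to_numpy() @ freqs.to_numpy()
    return pd.DataFrame(pc, index=membership.index, columns=freqs.columns)


# ---------------------------------------------------------------------------
# O, E, O/E and grading


def _passing_mask(pc: np.ndarray, threshold: float) -> np.ndarray:
    # pc >= threshold for a positive threshold; strictly > 0 at threshold 0,
    # since a taxon with pc = 0 carries no expectation.
    if not 0 <= threshold < 1:
        raise ParameterError(f"pc threshold must be in [0, 1), got {threshold}")
    return pc >= threshold if threshold > 0 else pc > 0


def expected_richness(profile: pd.Series | np.ndarray, threshold: float) -> float:
    """E: sum of capture probabilities over taxa passing the threshold."""
    pc = np.asarray(profile, dtype=float)
    E = float(pc[_passing_mask(pc, threshold)].sum())
    if E == 0.0:
        warnings.warn("expected richness is 0: no taxon passes the pc threshold")
    return E


def observed_richness(observed: Iterable[str], profile: pd.Series,
                      threshold: float) -> int:
    """O: count of observed taxa whose capture probability passes the threshold."""
    observed = set(observed)
    unknown = observed - set(profile.index)
    if unknown:
        raise ValidationError(f"observed taxa outside the modelled pool: {sorted(unknown)}")
    passing = profile.index[_passing_mask(profile.to_numpy(dtype=float), threshold)]
    return int(len(observed & set(passing)))


def oe_score(O: float, E: float, site_id: str = "?") -> float:
    """The O/E ratio, unclamped (scores above 1 are possible and kept)."""
    if E <= 0:
        raise UndefinedScoreError(f"site {site_id}: O/E undefined because E = {E}")
    return float(O) / float(E)


def grade_oe(score: float, cuts: Sequence[float] = DEFAULT_OE_GRADE_CUTS) -> str:
    """Five-band O/E grade.

    Bands are lower-inclusive except the bottom cut, which itself belongs to
    Poor: >= cuts[0] Excellent, >= cuts[1] Healthy, >= cuts[2] Sub-healthy,
    > cuts[3] General, otherwise Poor.
    """
    if score < 0:
        raise ParameterError(f"O/E score must be non-negative, got {score}")
    c1, c2, c3, c4 = cuts
    if score >= c1:
        return "Excellent"
    if score >= c2:
        return "Healthy"
    if score >= c3:
        return "Sub-healthy"
    if score > c4:
        return "General"
    return "Poor"


# ---------------------------------------------------------------------------
# end-to-end model


@dataclass
class OEModel:
    """Fitted predictive-model artifact."""

    retained_taxa: list[str]
    group_labels: pd.Series              # reference site -> group id
    freqs: pd.DataFrame                  # group x taxon occurrence frequency
    classifier: RandomForestClassifier
    cv_accuracy: float
    pc_threshold: float
    beta: float
    n_groups: int
    seed: int
    reference_predictors: pd.DataFrame = field(repr=False)

    def membership(self, predictors: pd.DataFrame) -> pd.DataFrame:
        """Group-membership probability vectors p_g for the given sites."""
        predictors = predictors[list(self.reference_predictors.columns)]
        proba = self.classifier.predict_proba(predictors)
        return pd.DataFrame(proba, index=predictors.index,
                            columns=[int(c) for c in self.classifier.classes_])

    def capture_profiles(self, predictors: pd.DataFrame) -> pd.DataFrame:
        return capture_probabilities(self.membership(predictors), self.freqs)


def fit_oe_model(matrix: OccurrenceMatrix, sites: pd.DataFrame,
                 config: AnalysisConfig) -> OEModel:
    """Build the O/E model from the reference sites of a survey.

    ``sites`` is a site table (role + predictors); only rows with role
    ``reference`` that also appear in ``matrix`` are used.
    """
    # canonicalize site/taxon order so the fit is invariant to input ordering
    ref_ids = sorted(s for s in sites.index[sites["role"] == "reference"]
                     if s in matrix.presence.index)
    if len(ref_ids) < 3:
        raise ModelBuildError(f"need at least 3 reference sites, found {len(ref_ids)}")
    ref = matrix.subset_sites(ref_ids).subset_taxa(sorted(matrix.taxon_ids))
    ref = filter_rare_taxa(ref, config.rare_taxon_max_freq)
    D = sorensen_dissimilarity(ref)
    if config.n_groups is not None:
        k = int(config.n_groups)
    else:
        lo, hi = config.group_candidates
        hi = min(hi, len(ref_ids) - 1)
        k = select_n_groups(D, range(lo, hi + 1), beta=config.beta)
    labels = flexible_beta_cluster(D, config.beta, k)
    freqs = group_frequencies(ref, labels)
    preds = predictor_frame(sites.loc[ref_ids])
    preds = preds[sorted(preds.columns)]
    clf, cv_acc = fit_group_classifier(preds, labels, config)
    return OEModel(
        retained_taxa=ref.taxon_ids,
        group_labels=pd.Series(labels, index=ref_ids, name="group"),
        freqs=freqs,
        classifier=clf,
        cv_accuracy=cv_acc,
        pc_threshold=config.pc_threshold,
        beta=config.beta,
        n_groups=k,
        seed=config.seed,
        reference_predictors=preds,
    )


def assess_sites(model: OEModel, matrix: OccurrenceMatrix,
                 sites: pd.DataFrame, threshold: float | None = None) -> pd.DataFrame:
    """Score every site of ``matrix``: O, E, O/E and grade.

    ``sites`` may be a full site table (its role column is ignored) or a
    bare predictor frame.  Raises :class:`UndefinedScoreError`, naming the
    site, if any expected richness is zero.
    """
    thr = model.pc_threshold if threshold is None else float(threshold)
    preds = predictor_frame(sites) if "role" in sites.columns else sites.astype(float)
    preds = preds.loc[matrix.site_ids]
    profiles = model.capture_profiles(preds)
    pres = matrix.presence
    rows = []
    for sid in matrix.site_ids:
        profile = profiles.loc[sid]
        observed = [t for t in model.retained_taxa
                    if t in pres.columns and pres.at[sid, t] == 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            E = expected_richness(profile, thr)
        O = observed_richness(observed, profile, thr)
        score = oe_score(O, E, site_id=sid)
        rows.append({"site_id": sid, "threshold": thr, "O": O, "E": E,
                     "OE": score, "grade": grade_oe(score)})
    return pd.DataFrame(rows)


def performance_test(reference_scores: Sequence[float],
                     severely_damaged_scores: Sequence[float]) -> dict:
    """Compare O/E between validation-reference and severely damaged sites.

    Reports per-set mean and SD, their difference, and whether the
    reference mean exceeds the severely damaged mean (the separation the
    index must achieve to be informative).
    """
    ref = np.asarray(list(reference_scores), dtype=float)
    dam = np.asarray(list(severely_damaged_scores), dtype=float)
    if ref.size == 0 or dam.size == 0:
        raise ParameterError("both site sets must be non-empty")

    def _sd(x: np.ndarray) -> float:
        if x.size < 2:
            warnings.warn("single-site set: SD reported as 0")
            return 0.0
        return float(np.std(x, ddof=1))

    report = {
        "mean_reference": float(ref.mean()),
        "sd_reference": _sd(ref),
        "mean_severely_damaged": float(dam.mean()),
        "sd_severely_damaged": _sd(dam),
    }
    report["difference"] = report["mean_reference"] - report["mean_severely_damaged"]
    report["separation"] = report["difference"] > 0
    return report


# ---------------------------------------------------------------------------
# model serialization


def save_model(model: OEModel, path: str | Path) -> None:
    """Serialize the model as a structured YAML document.

    The forest itself is not pickled; its parameters, seed and training data
    are stored so that :func:`load_model` refits it bit-identically.
    """
    doc = {
        "retained_taxa": list(model.retained_taxa),
        "group_labels": {str(k): int(v) for k, v in model.group_labels.items()},
        "freqs": {str(g): {str(t): float(v) for t, v in row.items()}
                  for g, row in model.freqs.iterrows()},
        "forest": {"n_trees": int(model.classifier.n_estimators),
                   "max_depth": model.classifier.max_depth,
                   "seed": int(model.seed)},
        "cv_accuracy": float(model.cv_accuracy),
        "pc_threshold": float(model.pc_threshold),
        "beta": float(model.beta),
        "n_groups": int(model.n_groups),
        "reference_predictors": {
            str(s): {str(c): float(v) for c, v in row.items()}
            for s, row in model.reference_predictors.iterrows()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_model(path: str | Path) -> OEModel:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    labels = pd.Series(doc["group_labels"], name="group")
    freqs = pd.DataFrame.from_dict(doc["freqs"], orient="index")
    freqs.index = freqs.index.astype(int)
    freqs = freqs.rename_axis(index="group")
    preds = pd.DataFrame.from_dict(doc["reference_predictors"], orient="index")
    preds = preds.loc[list(labels.index)]
    clf = RandomForestClassifier(
        n_estimators=doc["forest"]["n_trees"],
        max_depth=doc["forest"]["max_depth"],
        random_state=doc["forest"]["seed"],
    )
    clf.fit(preds, labels.to_numpy())
    return OEModel(
        retained_taxa=list(doc["retained_taxa"]),
        group_labels=labels,
        freqs=freqs,
        classifier=clf,
        cv_accuracy=float(doc["cv_accuracy"]),
        pc_threshold=float(doc["pc_threshold"]),
        beta=float(doc["beta"]),
        n_groups=int(doc["n_groups"]),
        seed=int(doc["forest"]["seed"]),
        reference_predictors=preds,
    )
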