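import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakehealth.data_model import AnalysisConfig
from lakehealth.errors import (
    ModelBuildError,
    ParameterError,
    UndefinedScoreError,
)
from lakehealth.oe_model import (
    assess_sites,
    capture_probabilities,
    expected_richness,
    filter_rare_taxa,
    fit_group_classifier,
    fit_oe_model,
    flexible_beta_cluster,
    flexible_beta_linkage,
    grade_oe,
    group_frequencies,
    load_model,
    observed_richness,
    oe_score,
    performance_test,
    save_model,
    select_n_groups,
    sorensen_dissimilarity,
)

from conftest import make_matrix, random_dissimilarity
from _oracles import brute_force_flexible_beta, same_partition


# ---------------------------------------------------------------------------
# Sørensen dissimilarity


def test_sorensen_hand_values():
    # rows: identical; sharing a=2 with b=c=1; disjoint from the rest
    presence = np.array([[1, 1, 1, 0, 0],
                         [1, 1, 1, 0, 0],
                         [1, 1, 0, 1, 0],
                         [0, 0, 0, 0, 1]])
    D = sorensen_dissimilarity(make_matrix(presence))
    assert D.iloc[0, 1] == 0.0
    assert D.iloc[0, 2] == pytest.approx(1 - 4 / 6)   # a=2, b=1, c=1
    assert D.iloc[0, 3] == 1.0


def test_sorensen_empty_site_conventions():
    presence = np.array([[0, 0], [0, 0], [1, 0]])
    with pytest.warns(UserWarning, match="empty"):
        D = sorensen_dissimilarity(make_matrix(presence))
    assert D.iloc[0, 1] == 0.0          # both empty -> identical by convention
    assert D.iloc[0, 2] == 1.0          # empty vs non-empty -> maximal


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_sorensen_matrix_invariants(seed):
    rng = np.random.default_rng(seed)
    presence = (rng.random((rng.integers(2, 8), rng.integers(1, 10))) < 0.5)
    m = make_matrix(presence.astype(int))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = sorensen_dissimilarity(m).to_numpy()
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0)
    assert ((D >= 0) & (D <= 1)).all()


# ---------------------------------------------------------------------------
# rare-taxon exclusion


def test_rare_taxa_excluded_at_and_below_cutoff():
    presence = np.zeros((30, 3), dtype=int)
    presence[:, 0] = 1          # everywhere: retained
    presence[0, 1] = 1          # 1/30 ~ 3.3% <= 5%: removed
    presence[:2, 2] = 1         # 2/30 ~ 6.7%: retained
    filtered = filter_rare_taxa(make_matrix(presence), 0.05)
    assert filtered.taxon_ids == ["t1", "t3"]


def test_rare_taxa_boundary_is_inclusive():
    presence = np.zeros((20, 2), dtype=int)
    presence[:, 0] = 1
    presence[0, 1] = 1          # exactly 5% of 20 sites: removed
    filtered = filter_rare_taxa(make_matrix(presence), 0.05)
    assert filtered.taxon_ids == ["t1"]


def test_all_taxa_removed_is_a_build_error():
    presence = np.zeros((30, 2), dtype=int)
    presence[0, :] = 1
    with pytest.raises(ModelBuildError):
        filter_rare_taxa(make_matrix(presence), 0.05)


# ---------------------------------------------------------------------------
# flexible-beta clustering


def test_lance_williams_update_hand_value():
    # merging singletons i, j with d(ik)=0.4, d(jk)=0.6, d(ij)=0.2 at
    # beta=-0.5 gives d(k, i+j) = 0.75*0.4 + 0.75*0.6 - 0.5*0.2 = 0.65
    D = np.array([[0.0, 0.2, 0.4],
                  [0.2, 0.0, 0.6],
                  [0.4, 0.6, 0.0]])
    merges = flexible_beta_linkage(D, -0.5)
    assert merges[0] == (0, 1, 0.2)
    assert merges[1][2] == pytest.approx(0.65)


def test_every_site_its_own_group_at_full_cut():
    rng = np.random.default_rng(3)
    D = random_dissimilarity(rng, 5)
    labels = flexible_beta_cluster(D, -0.5, 5)
    assert sorted(labels) == [0, 1, 2, 3, 4]
    with pytest.raises(ParameterError):
        flexible_beta_cluster(D, -0.5, 6)


def test_well_separated_blocks_are_recovered():
    rng = np.random.default_rng(4)
    n1, n2 = 4, 4
    D = np.full((n1 + n2, n1 + n2), 0.9) + 0.05 * rng.random((8, 8))
    D[:n1, :n1] = 0.05 * rng.random((n1, n1))
    D[n1:, n1:] = 0.05 * rng.random((n2, n2))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    labels = flexible_beta_cluster(D, -0.5, 2)
    assert same_partition(labels, [0] * n1 + [1] * n2)


@pytest.mark.parametrize("seed", range(40))
def test_clustering_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    D = random_dissimilarity(rng, n)
    k = int(rng.integers(1, n + 1))
    assert same_partition(flexible_beta_cluster(D, -0.5, k),
                          brute_force_flexible_beta(D, -0.5, k))


def test_clustering_matches_r_agnes_flexible():
    """Independent cross-check against cluster::agnes(method='flexible').

    agnes parameterizes flexible-beta by a single alpha; alpha = 0.75
    corresponds to beta = 1 - 2*alpha = -0.5.
    """
    rng = np.random.default_rng(11)
    D = random_dissimilarity(rng, 8)
    rows = ";".join(",".join(repr(float(v)) for v in row) for row in D)
    rscript = (
        f'D <- do.call(rbind, lapply(strsplit(strsplit("{rows}", ";")[[1]], ","),'
        " as.numeric));"
        "library(cluster);"
        'ag <- agnes(as.dist(D), diss=TRUE, method="flexible", par.method=0.75);'
        'cat(sort(ag$height), sep=","); cat("\\n");'
        'cat(cutree(as.hclust(ag), k=3), sep=",")'
    )
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, check=True)
    lines = out.stdout.strip().splitlines()
    heights_r = np.array([float(x) for x in lines[0].split(",")])
    labels_r = [int(x) for x in lines[1].split(",")]
    heights_py = np.sort([h for _, _, h in flexible_beta_linkage(D, -0.5)])
    np.testing.assert_allclose(heights_py, heights_r, atol=1e-6)
    assert same_partition(flexible_beta_cluster(D, -0.5, 3), labels_r)


def test_group_count_selection_finds_planted_blocks():
    rng = np.random.default_rng(7)
    for n_blocks in (2, 3):
        size = 4
        n = n_blocks * size
        D = np.full((n, n), 0.9) + 0.05 * rng.random((n, n))
        for b in range(n_blocks):
            s = slice(b * size, (b + 1) * size)
            D[s, s] = 0.05 * rng.random((size, size))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        assert select_n_groups(D, range(2, 6)) == n_blocks


def test_group_count_ties_break_toward_fewer_groups():
    D = np.full((6, 6), 0.5)
    np.fill_diagonal(D, 0)
    assert select_n_groups(D, [2, 3, 4]) == 2


# ---------------------------------------------------------------------------
# group frequencies, classifier, capture probabilities


def test_group_frequencies_are_count_ratios():
    presence = np.array([[1, 1, 0],
                         [1, 0, 0],
                         [1, 1, 0],
                         [1, 0, 0],
                         [1, 0, 0]])
    freqs = group_frequencies(make_matrix(presence), [0, 0, 0, 0, 0])
    assert freqs.loc[0, "t1"] == 1.0
    assert freqs.loc[0, "t2"] == pytest.approx(0.4)   # 2 of 5 sites
    assert freqs.loc[0, "t3"] == 0.0


def test_classifier_separable_groups_and_probability_contract():
    preds = pd.DataFrame({"x": [0.0, 1.0, 0.5, 100.0, 101.0, 99.5]},
                         index=[f"s{i}" for i in range(6)])
    labels = [0, 0, 0, 1, 1, 1]
    clf, cv_acc = fit_group_classifier(preds, labels, AnalysisConfig(seed=0, cv_folds=3))
    assert cv_acc == 1.0
    proba = clf.predict_proba(pd.DataFrame({"x": [0.2, 50.0, 99.0]}))
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_classifier_chance_level_on_permuted_labels():
    rng = np.random.default_rng(0)
    preds = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60)})
    labels = rng.permutation([0, 1] * 30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, cv_acc = fit_group_classifier(preds, labels, AnalysisConfig(seed=0))
    # chance is 0.5; allow ~3 SD of binomial noise at n=60
    assert abs(cv_acc - 0.5) < 3 * np.sqrt(0.25 / 60) + 0.05


def test_classifier_reduces_folds_for_small_groups():
    preds = pd.DataFrame({"x": [0, 1, 100, 101]}, dtype=float)
    with pytest.warns(UserWarning, match="folds"):
        _, cv_acc = fit_group_classifier(preds, [0, 0, 1, 1],
                                         AnalysisConfig(seed=0, cv_folds=5))
    assert np.isfinite(cv_acc)


def test_capture_probabilities_are_membership_weighted_frequencies():
    membership = pd.DataFrame([[1.0, 0.0], [0.5, 0.5]], index=["a", "b"],
                              columns=[0, 1])
    freqs = pd.DataFrame({"t1": [0.8, 0.2], "t2": [0.0, 0.0]}, index=[0, 1])
    pc = capture_probabilities(membership, freqs)
    assert pc.loc["a", "t1"] == pytest.approx(0.8)    # degenerate membership
    assert pc.loc["b", "t1"] == pytest.approx(0.5)    # equal-weight mean
    assert pc.loc["a", "t2"] == 0.0                    # absent everywhere


# ---------------------------------------------------------------------------
# O, E, O/E


def test_expected_richness_threshold_conventions():
    pc = pd.Series({"A": 0.8, "B": 0.6, "C": 0.3})
    assert expected_richness(pc, 0.5) == pytest.approx(1.4)
    assert expected_richness(pc, 0.0) == pytest.approx(1.7)
    with pytest.warns(UserWarning, match="0"):
        assert expected_richness(pd.Series(dtype=float), 0.5) == 0.0


def test_observed_richness_counts_passing_taxa():
    pc = pd.Series({"A": 0.8, "B": 0.6, "C": 0.3})
    assert observed_richness({"A", "C"}, pc, 0.5) == 1   # only A passes
    assert observed_richness({"A", "C"}, pc, 0.0) == 2
    assert observed_richness(set(), pc, 0.5) == 0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_expected_richness_decreases_with_threshold(seed):
    rng = np.random.default_rng(seed)
    pc = pd.Series(rng.random(12))
    assert expected_richness(pc, 0.5) <= expected_richness(pc, 0.0)


def test_oe_score_ratio_and_division_guard():
    assert oe_score(7, 10) == pytest.approx(0.7)
    assert oe_score(5, 5) == 1.0
    with pytest.raises(UndefinedScoreError, match="p9"):
        oe_score(3, 0, site_id="p9")


@pytest.mark.parametrize("score,grade", [
    (0.85, "Excellent"),
    (0.79, "Excellent"),     # top band lower-inclusive
    (0.60, "Healthy"),
    (0.59, "Healthy"),
    (0.50, "Sub-healthy"),
    (0.39, "Sub-healthy"),
    (0.20, "General"),
    (0.19, "Poor"),          # the bottom cut itself is Poor
    (0.05, "Poor"),
    (1.30, "Excellent"),     # scores above 1 are kept, not clamped
])
def test_oe_grade_bands(score, grade):
    assert grade_oe(score) == grade


def test_negative_oe_score_rejected():
    with pytest.raises(ParameterError):
        grade_oe(-0.1)


# ---------------------------------------------------------------------------
# end-to-end model behaviour


def _config(seed=1234):
    return AnalysisConfig(seed=seed)


def test_self_assessment_scores_near_one(reference_world):
    spec, matrix, sites, labels = reference_world
    model = fit_oe_model(matrix, sites, _config())
    # a test site identical in taxa and predictors to a reference site
    probe = matrix.subset_sites([matrix.site_ids[0]])
    res = assess_sites(model, probe, sites)
    assert 0.9 <= res["OE"].iloc[0] <= 1.1


def test_oe_is_invariant_to_taxon_and_site_reordering(reference_world):
    spec, matrix, sites, labels = reference_world
    cfg = _config()
    model = fit_oe_model(matrix, sites, cfg)
    base = assess_sites(model, matrix, sites).set_index("site_id")["OE"]

    rng = np.random.default_rng(0)
    taxa = list(rng.permutation(matrix.taxon_ids))
    site_order = list(rng.permutation(matrix.site_ids))
    shuffled = matrix.subset_taxa(taxa).subset_sites(site_order)
    model2 = fit_oe_model(shuffled, sites.loc[site_order], cfg)
    res2 = assess_sites(model2, shuffled, sites.loc[site_order])
    scores2 = res2.set_index("site_id")["OE"]
    for sid in base.index:
        assert scores2[sid] == pytest.approx(base[sid], abs=1e-9)


def test_model_round_trips_through_serialization(reference_world, tmp_path):
    spec, matrix, sites, labels = reference_world
    model = fit_oe_model(matrix, sites, _config())
    save_model(model, tmp_path / "model.yaml")
    back = load_model(tmp_path / "model.yaml")
    a = assess_sites(model, matrix, sites)
    b = assess_sites(back, matrix, sites)
    pd.testing.assert_frame_equal(a, b)


def test_recovered_groups_match_planted_labels(reference_world):
    spec, matrix, sites, labels = reference_world
    model = fit_oe_model(matrix, sites, _config())
    assert model.n_groups == spec.n_groups
    assert same_partition(model.group_labels.loc[labels.index].to_numpy(),
                          labels.to_numpy())


# ---------------------------------------------------------------------------
# performance test


def test_performance_report_separates_constructed_sets():
    report = performance_test([0.95, 1.0, 1.05], [0.1, 0.2, 0.15])
    assert report["separation"] is True
    assert report["difference"] == pytest.approx(1.0 - 0.15)


def test_performance_identical_sets_have_zero_difference():
    report = performance_test([0.8, 0.9], [0.8, 0.9])
    assert report["difference"] == 0.0
    assert report["separation"] is False


def test_performance_single_site_sd_is_zero_with_warning():
    with pytest.warns(UserWarning, match="single-site"):
        report = performance_test([1.0], [0.2])
    assert report["sd_reference"] == 0.0
    assert report["sd_severely_damaged"] == 0.0
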