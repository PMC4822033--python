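"""CCF model, clone clustering, trajectories, sampling-loss analysis and the
evolution classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clonalshift.clonal_dynamics import (
    ClusterParams,
    EvolutionThresholds,
    ccf_from_vaf,
    classify_evolution,
    classify_trajectory,
    cluster_clones,
    detect_polyclonality,
    expected_vaf,
    sampling_loss_probability,
    select_for_clustering,
    spatial_concordance,
    vaf_cv,
)


# ------------------------------------------------------------- CCF algebra

def test_clonal_heterozygous_diploid_identity():
    assert ccf_from_vaf(0.5, 1.0, 2, 1) == pytest.approx(1.0, abs=1e-12)


def test_half_purity_identity():
    assert ccf_from_vaf(0.25, 0.5, 2, 1) == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(
    ccf=st.floats(0.01, 1.0),
    purity=st.floats(0.05, 1.0),
    cn=st.integers(1, 6),
    mult=st.integers(1, 3),
)
def test_ccf_inverts_expected_vaf(ccf, purity, cn, mult):
    mult = min(mult, cn)
    v = expected_vaf(ccf, purity, cn, mult)
    back = ccf_from_vaf(float(v), purity, cn, mult)
    assert back == pytest.approx(ccf, abs=1e-12)


def test_zero_purity_rejected():
    with pytest.raises(ValueError):
        ccf_from_vaf(0.5, 0.0)


def test_implausible_ccf_is_clipped_and_flagged():
    ccf, clipped = ccf_from_vaf(np.array([0.9]), 0.5, 2, 1)
    assert ccf[0] == 1.5 and clipped[0]


# ------------------------------------------------------------- selection

def _rec(pre_depth, post_depth, pre_alt, post_alt, gene="."):
    return {
        "gene": gene,
        "pre_depth": pre_depth, "post_depth": post_depth,
        "pre_alt": pre_alt, "post_alt": post_alt,
        "pre_vaf": pre_alt / pre_depth, "post_vaf": post_alt / post_depth,
    }


def test_shared_variant_with_sixty_x_in_one_sample_is_included():
    df = pd.DataFrame([_rec(59, 61, 12, 12)])
    out = select_for_clustering(df)
    assert out["inclusion_reason"].iloc[0] == "coverage60"


def test_low_vaf_in_one_sample_is_rescued():
    df = pd.DataFrame([_rec(30, 30, 6, 0)])  # VAFs 0.20 / 0.00
    out = select_for_clustering(df)
    assert out["inclusion_reason"].iloc[0] == "low_vaf_rescue"


def test_shared_low_coverage_variant_is_not_included():
    df = pd.DataFrame([_rec(30, 30, 6, 6)])
    out = select_for_clustering(df)
    assert not out["included_in_clustering"].iloc[0]


def test_drivers_kept_regardless_of_coverage_and_subsampling():
    rng = np.random.default_rng(0)
    rows = [_rec(100, 100, 30, 30) for _ in range(2000)]
    for i in range(3):
        rows[i] = _rec(10, 10, 3, 3, gene="TP53")
    df = pd.DataFrame(rows)
    out = select_for_clustering(df, drivers={"TP53"}, subsample_cap=500, seed=1)
    included = out[out["included_in_clustering"]]
    assert len(included) == 500
    assert (included["gene"] == "TP53").sum() == 3
    del rng


def test_subsampling_is_seeded():
    rows = [_rec(100, 100, 30, 30) for _ in range(800)]
    df = pd.DataFrame(rows)
    a = select_for_clustering(df, subsample_cap=100, seed=3)
    b = select_for_clustering(df, subsample_cap=100, seed=3)
    assert a["included_in_clustering"].equals(b["included_in_clustering"])


# ------------------------------------------------------------- clustering

def _two_clone_records(rng, n_per=200, depth=100, purity=1.0):
    rows = []
    for ccf_pre, ccf_post in [(1.0, 1.0), (0.6, 0.05)]:
        vp = expected_vaf(ccf_pre, purity)
        vq = expected_vaf(ccf_post, purity)
        for _ in range(n_per):
            dp, dq = rng.poisson(depth), rng.poisson(depth)
            dp, dq = max(dp, 60), max(dq, 60)
            ap, aq = rng.binomial(dp, vp), rng.binomial(dq, vq)
            rows.append({
                "pre_depth": dp, "post_depth": dq, "pre_alt": ap, "post_alt": aq,
                "pre_vaf": ap / dp, "post_vaf": aq / dq, "gene": ".",
                "included_in_clustering": True,
            })
    return pd.DataFrame(rows)


def test_identical_records_collapse_to_one_cluster():
    df = pd.DataFrame([
        dict(pre_depth=100, post_depth=100, pre_alt=50, post_alt=50,
             pre_vaf=0.5, post_vaf=0.5, gene=".", included_in_clustering=True)
    ] * 30)
    clusters = cluster_clones(df, ClusterParams(seed=0))
    assert len(clusters) == 1
    assert clusters[0].center_pre == pytest.approx(1.0, abs=0.05)


def test_two_planted_clones_are_recovered():
    df = _two_clone_records(np.random.default_rng(4))
    clusters = cluster_clones(df, ClusterParams(seed=0))
    centers = sorted((c.center_pre, c.center_post) for c in clusters)
    assert len(clusters) == 2
    assert centers[0][0] == pytest.approx(0.6, abs=0.1)
    assert centers[0][1] == pytest.approx(0.05, abs=0.1)
    assert centers[1][0] == pytest.approx(1.0, abs=0.1)
    # >= 95% correct assignment: members of each cluster share the same truth
    truth = np.repeat([0, 1], 200)
    assign = np.empty(400, dtype=int)
    for k, c in enumerate(clusters):
        assign[np.asarray(c.member_index)] = k
    acc = max((assign == truth).mean(), (assign != truth).mean())
    assert acc >= 0.95


def test_cluster_count_is_stable_across_seeds():
    df = _two_clone_records(np.random.default_rng(10))
    a = cluster_clones(df, ClusterParams(seed=1))
    b = cluster_clones(df, ClusterParams(seed=99))
    assert len(a) == len(b) == 2
    assign = lambda cl: tuple(sorted(tuple(sorted(c.member_index)) for c in cl))
    assert assign(a) == assign(b)


def test_too_few_records_is_not_clusterable():
    df = _two_clone_records(np.random.default_rng(1)).head(3)
    with pytest.raises(ValueError):
        cluster_clones(df)


# ------------------------------------------------------------- trajectories

@pytest.mark.parametrize(
    "pre,post,want",
    [(0.30, 0.00, "pre_only"), (0.30, 0.25, "shared"), (0.00, 0.10, "post_only"),
     (0.019, 0.019, "shared")],
)
def test_trajectory_classification(pre, post, want):
    assert classify_trajectory(pre, post, 0.02) == want


def test_sampling_loss_probability_matches_exact_binomial_sum():
    grid = [(0.05, 40, 2), (0.20, 75, 4), (0.50, 100, 4), (0.01, 1000, 4)]
    for vaf, depth, min_alt in grid:
        brute = sum(stats.binom.pmf(k, depth, vaf) for k in range(min_alt))
        assert sampling_loss_probability(vaf, depth, min_alt) == pytest.approx(
            brute, abs=1e-12
        )


def test_high_vaf_loss_is_never_explainable_by_sampling():
    assert sampling_loss_probability(0.5, 100, 4) < 1e-20


def test_zero_vaf_is_always_explainable():
    assert sampling_loss_probability(0.0, 100, 4) == 1.0


def test_sampling_loss_probability_is_monotone():
    vafs = np.linspace(0.01, 0.5, 20)
    p = sampling_loss_probability(vafs, 80, 4)
    assert np.all(np.diff(p) <= 1e-15)
    depths = np.arange(10, 400, 10)
    p2 = sampling_loss_probability(0.1, depths, 4)
    assert np.all(np.diff(p2) <= 1e-15)


# ------------------------------------------------------------- polyclonality

def _driver_df(trajectories, gene="TP53"):
    return pd.DataFrame({"gene": gene, "trajectory": trajectories})


def test_discordant_triple_driver_set_detected():
    assert detect_polyclonality(_driver_df(["pre_only", "shared", "shared"])) == 1


def test_concordant_triple_is_not_discordant():
    assert detect_polyclonality(_driver_df(["shared", "shared", "shared"])) == 0


def test_two_mutations_are_below_the_threshold():
    assert detect_polyclonality(_driver_df(["pre_only", "shared"])) == 0


def test_gained_mutation_counts_as_discordance_partner():
    assert detect_polyclonality(_driver_df(["pre_only", "post_only", "shared"])) == 1


# ------------------------------------------------------------- classifier

def _metrics(**kw):
    m = {
        "lost_high_vaf_fraction": 0.0, "shared_count": 300,
        "expanding_minor_clone": False, "discordant_same_gene_drivers": 0,
        "pre_burden": 350, "post_burden": 300,
        "high_vaf_losses": 0, "high_vaf_gains": 0,
    }
    m.update(kw)
    return m


def test_qc_failure_dominates():
    call = classify_evolution(_metrics(), qc_excluded=True)
    assert call.category == "excluded"


def test_quiet_genome_is_stable():
    assert classify_evolution(_metrics()).category == "stable"


def test_bottleneck_requires_all_three_features():
    full = _metrics(lost_high_vaf_fraction=0.4, expanding_minor_clone=True)
    assert classify_evolution(full).category == "bottleneck"
    for missing in (
        dict(lost_high_vaf_fraction=0.1),
        dict(shared_count=5),
        dict(expanding_minor_clone=False),
    ):
        assert classify_evolution({**full, **missing}).category == "stable"


def test_discordant_drivers_force_polyclonal():
    m = _metrics(discordant_same_gene_drivers=1, lost_high_vaf_fraction=0.5,
                 expanding_minor_clone=True)
    assert classify_evolution(m).category == "polyclonal"


def test_hypermutator_with_cross_spectrum_loss_and_gain_is_polyclonal():
    m = _metrics(pre_burden=7000, high_vaf_losses=50, high_vaf_gains=40)
    assert classify_evolution(m).category == "polyclonal"
    # the same pattern at normal burden without MSI is not called polyclonal
    m2 = _metrics(pre_burden=350, high_vaf_losses=50, high_vaf_gains=40)
    assert classify_evolution(m2).category == "stable"
    assert classify_evolution(m2, msi=True).category == "polyclonal"


def test_thresholds_are_reported_with_every_call():
    call = classify_evolution(_metrics())
    assert call.thresholds["lost_fraction_min"] == EvolutionThresholds().lost_fraction_min


# ------------------------------------------------------------- diversity

def test_cv_of_equal_vafs_is_zero():
    assert vaf_cv([0.2, 0.2, 0.2]) == pytest.approx(0.0, abs=1e-12)


def test_cv_hand_computed_example():
    assert vaf_cv([0.1, 0.3]) == pytest.approx(np.sqrt(0.02) / 0.2, abs=1e-12)


def test_cv_is_scale_invariant():
    v = np.array([0.05, 0.1, 0.2, 0.4])
    assert vaf_cv(v) == pytest.approx(vaf_cv(3 * v), abs=1e-12)


def test_cv_needs_two_values():
    with pytest.raises(ValueError):
        vaf_cv([0.3])


# ------------------------------------------------------------- concordance

def test_identical_mutation_sets_are_fully_concordant():
    assert spatial_concordance({1, 2, 3}, {1, 2, 3}) == 1.0


def test_disjoint_sets_have_zero_concordance():
    assert spatial_concordance({1, 2}, {3, 4}) == 0.0


def test_55_of_66_assessed_sites():
    universe = set(range(66))
    a = set(range(60))
    b = set(range(55)) | set(range(60, 66))  # 55 shared present, 6 discordant extra
    frac = spatial_concordance(a, b, universe=universe)
    assert frac == pytest.approx(55 / 66, abs=1e-12)


def test_gene_exclusion_removes_sites_from_the_universe():
    gene_of = {1: "NOTCH1", 2: "TP53", 3: "TP53"}.get
    frac = spatial_concordance({1, 2}, {2, 3}, universe={1, 2, 3},
                               exclude_genes={"NOTCH1"}, gene_of=gene_of)
    assert frac == pytest.approx(0.5)


def test_empty_universe_not_computable():
    with pytest.raises(ValueError):
        spatial_concordance(set(), set())
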