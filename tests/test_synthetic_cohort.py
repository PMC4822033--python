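"""Generator invariants: tree consistency, bottleneck renormalization,
signature sampling, binomial sequencing noise, and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonalshift.synthetic_cohort import (
    CloneNode,
    CompleteResponseError,
    SimConfig,
    apply_bottleneck,
    assign_mutation_spectra,
    cell_fractions,
    default_arm_table,
    planted_signatures,
    read_cohort_dir,
    sequence_sample,
    simulate_clone_tree,
    simulate_cohort,
    simulate_patient,
    write_cohort,
)
from clonalshift.variant_filtering import read_variants


# ---------------------------------------------------------------- clone trees

def test_single_clone_tree_is_the_full_tumour():
    tree = simulate_clone_tree(1, seed=0)
    assert len(tree) == 1
    assert tree[0].parent_id is None
    assert tree[0].fraction_pre == 1.0


def test_tree_generation_is_deterministic():
    t1 = simulate_clone_tree(3, seed=7)
    t2 = simulate_clone_tree(3, seed=7)
    assert [(n.clone_id, n.parent_id, n.fraction_pre) for n in t1] == [
        (n.clone_id, n.parent_id, n.fraction_pre) for n in t2
    ]


@pytest.mark.parametrize("n_clones,seed", [(5, 1), (6, 3), (2, 9)])
def test_child_fractions_never_exceed_parents(n_clones, seed):
    tree = simulate_clone_tree(n_clones, seed)
    by_id = {n.clone_id: n for n in tree}
    for n in tree:
        if n.parent_id is not None:
            assert n.fraction_pre <= by_id[n.parent_id].fraction_pre + 1e-9
    # sibling sums bounded by the parent as well
    for n in tree:
        kids = [c for c in tree if c.parent_id == n.clone_id]
        assert sum(k.fraction_pre for k in kids) <= n.fraction_pre + 1e-9


def test_invalid_clone_count_rejected():
    with pytest.raises(ValueError):
        simulate_clone_tree(0)


# ---------------------------------------------------------------- bottleneck

def _chain_tree(fracs):
    return [CloneNode(i, None if i == 0 else i - 1, fraction_pre=f)
            for i, f in enumerate(fracs)]


def test_uniform_survival_leaves_fractions_unchanged():
    tree = simulate_clone_tree(4, seed=2)
    pre = [n.fraction_pre for n in tree]
    apply_bottleneck(tree, {n.clone_id: 1.0 for n in tree})
    assert [n.fraction_post for n in tree] == pytest.approx(pre, abs=1e-12)


def test_killed_sibling_share_is_absorbed_by_survivor():
    # root carries no private cells: its two children partition the tumour
    tree = [CloneNode(0, None, fraction_pre=1.0),
            CloneNode(1, 0, fraction_pre=0.6),
            CloneNode(2, 0, fraction_pre=0.4)]
    apply_bottleneck(tree, {0: 1.0, 1: 1.0, 2: 0.0})
    assert tree[1].fraction_post == pytest.approx(1.0, abs=1e-12)
    assert tree[2].fraction_post == 0.0


def test_renormalization_matches_closed_form():
    """Three-clone chain with survival (1, 0.1, 0.01) against hand arithmetic."""
    tree = _chain_tree([1.0, 0.5, 0.2])
    surv = {0: 1.0, 1: 0.1, 2: 0.01}
    # private cell fractions: 0.5, 0.3, 0.2 -> survive 0.5, 0.03, 0.002
    total = 0.5 + 0.03 + 0.002
    expect = {2: 0.002 / total, 1: (0.03 + 0.002) / total, 0: 1.0}
    apply_bottleneck(tree, surv)
    for n in tree:
        assert n.fraction_post == pytest.approx(expect[n.clone_id], abs=1e-12)


def test_complete_kill_raises_complete_response():
    tree = _chain_tree([1.0, 0.5])
    with pytest.raises(CompleteResponseError):
        apply_bottleneck(tree, {0: 0.0, 1: 0.0})


def test_extinct_clones_are_zeroed():
    tree = _chain_tree([1.0, 0.5])
    apply_bottleneck(tree, {0: 1.0, 1: 1e-7})
    assert tree[1].fraction_post == 0.0


def test_cell_fractions_sum_to_one():
    tree = simulate_clone_tree(5, seed=4)
    assert sum(cell_fractions(tree, "pre").values()) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- spectra

def test_pure_signature_draws_converge_to_the_signature():
    sigs = planted_signatures()
    ch = assign_mutation_spectra(10_000, (1, 0, 0), seed=3)
    emp = np.bincount(ch, minlength=96) / 10_000
    tv = 0.5 * np.abs(emp - sigs[:, 0]).sum()
    assert tv < 0.05


def test_spectrum_assignment_is_deterministic():
    a = assign_mutation_spectra(500, (0.5, 0.5, 0), seed=11)
    b = assign_mutation_spectra(500, (0.5, 0.5, 0), seed=11)
    assert np.array_equal(a, b)


def test_point_mass_signature_yields_single_channel():
    point = np.zeros((96, 1))
    point[42, 0] = 1.0
    ch = assign_mutation_spectra(200, [1.0], seed=0, signatures=point)
    assert np.all(ch == 42)


def test_zero_weights_rejected():
    with pytest.raises(ValueError):
        assign_mutation_spectra(10, (0, 0, 0))


# ---------------------------------------------------------------- sequencing

def test_expected_vaf_identities_via_sequencing_mean():
    rng = np.random.default_rng(5)
    d, a = sequence_sample(np.ones(10_000), 2.0, purity=1.0, depth=100, seed=rng)
    vaf = a[d > 0] / d[d > 0]
    se = np.sqrt(0.25 / 100) / np.sqrt(len(vaf))
    assert abs(vaf.mean() - 0.5) < 3 * se


def test_half_purity_halves_the_clonal_vaf():
    rng = np.random.default_rng(6)
    d, a = sequence_sample(np.ones(20_000), 2.0, purity=0.5, depth=200, seed=rng)
    assert abs((a.sum() / d.sum()) - 0.25) < 0.005


def test_alt_counts_follow_the_binomial_model():
    """Chi-square goodness of fit of alt counts at fixed depth and VAF."""
    rng = np.random.default_rng(7)
    n, depth, vaf = 20_000, 40, 0.25
    alt = rng.binomial(depth, vaf, size=n)  # reference draw
    d = np.full(n, depth)
    _, sim = sequence_sample(np.full(n, 2 * vaf), 2.0, 1.0, depth, seed=8)
    # compare simulated alt|depth==depth against exact binomial pmf
    sim_d, sim_a = sequence_sample(np.full(n, 2 * vaf), 2.0, 1.0, depth, seed=9)
    mask = sim_d == depth
    obs = np.bincount(sim_a[mask], minlength=depth + 1)
    exp = stats.binom.pmf(np.arange(depth + 1), depth, vaf) * mask.sum()
    keep = exp >= 5
    chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
    chi2 += (obs[~keep].sum() - exp[~keep].sum()) ** 2 / max(exp[~keep].sum(), 1e-9)
    dof = keep.sum()  # pooled tail contributes one cell
    assert stats.chi2.sf(chi2, dof) > 0.01
    del alt, d, sim


def test_sequencing_rejects_bad_arguments():
    with pytest.raises(ValueError):
        sequence_sample(np.ones(5), 2.0, purity=0.0, depth=100)
    with pytest.raises(ValueError):
        sequence_sample(np.ones(5), 2.0, purity=0.5, depth=0.1)


# ---------------------------------------------------------------- cohort I/O

def test_patient_truth_covers_every_variant(bottleneck_patient):
    assert len(bottleneck_patient.truth) == len(bottleneck_patient.variants)


def test_equal_conditions_give_equal_pre_post_expected_vafs(study_config):
    p = simulate_patient(3, "stable", study_config)
    t = p.truth[~p.truth["germline"] & (p.truth["ccf_pre"] > 0)]
    assert np.allclose(t["ccf_pre"], t["ccf_post"])
    assert len(t) > 100


def test_write_then_read_round_trip(tmp_path, small_cohort):
    out = write_cohort(small_cohort, tmp_path / "cohort")
    back = read_cohort_dir(out)
    assert len(back.patients) == len(small_cohort.patients)
    p0 = small_cohort.patients[0]
    b0 = back.patients[0]
    a = p0.variants.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
    assert len(b0.variants) == len(a)
    assert np.array_equal(b0.variants["pre_alt"].to_numpy(), a["pre_alt"].to_numpy())


def test_vcf_and_tsv_mirrors_agree(tmp_path, small_cohort):
    out = write_cohort(small_cohort, tmp_path / "cohort")
    pid = small_cohort.patients[0].patient_id
    tsv = read_variants(out / f"{pid}.variants.tsv", "tsv")
    vcf = read_variants(out / f"{pid}.vcf", "vcf")
    assert len(tsv) == len(vcf)
    for col in ("pos", "pre_depth", "pre_alt", "post_depth", "post_alt",
                "normal_depth", "normal_alt", "context96"):
        assert np.array_equal(tsv[col].to_numpy(), vcf[col].to_numpy()), col
    assert np.allclose(tsv["pre_vaf"], vcf["pre_vaf"])


def test_cohort_writes_are_byte_identical_for_same_seed(tmp_path):
    cfg = SimConfig(n_patients=2, seed=33)
    d1 = write_cohort(simulate_cohort(cfg), tmp_path / "a")
    d2 = write_cohort(simulate_cohort(cfg), tmp_path / "b")
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_default_cohort_size_and_files(tmp_path):
    cfg = SimConfig(n_patients=30, seed=44, mean_burden=60, post_only_mean=5,
                    hypermutator_factor=3, probes_per_arm=20)
    out = write_cohort(simulate_cohort(cfg), tmp_path / "c")
    assert len(list(out.glob("*.vcf"))) == 30
    assert len(list(out.glob("*.truth.tsv"))) == 30
    clin = pd.read_csv(out / "clinical.tsv", sep="\t")
    assert list(clin.columns) == ["Case", "Age", "Sex", "T", "N", "PathR", "Mandard"]
    assert len(clin) == 30


def test_arm_table_is_contiguous():
    t = default_arm_table()
    assert len(t) == 44
    for _, grp in t.groupby("chrom"):
        grp = grp.sort_values("start")
        assert grp.iloc[0]["start"] == 1
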