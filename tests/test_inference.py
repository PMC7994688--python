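import numpy as np
import pytest

from tractstats import (
    ClusterConfig,
    CohortConfig,
    GlmDesign,
    VertexDataset,
    extract_clusters,
    generate_cohort,
    permutation_fwer,
    vertexwise_tstat,
    vertex_area_weights,
)
from tractstats.errors import ConfigError, DesignError

from conftest import flat_grid_mesh, flood_fill_oracle


def two_group_design(n_a, n_b, covariates=None, direction="both"):
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    return GlmDesign("A", "B", labels, covariates,
                     contrast_direction=direction)


# ---------------------------------------------------------------------------
# Vertex-wise t

def test_textbook_two_sample_t():
    design = two_group_design(3, 3)
    y = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
    t, _ = vertexwise_tstat(y, design)
    assert abs(t[0]) == pytest.approx(1.2247, abs=1e-3)


def test_identical_groups_t_zero():
    design = two_group_design(4, 4)
    block = np.random.default_rng(0).uniform(size=(4, 7))
    t, _ = vertexwise_tstat(np.vstack([block, block]), design)
    assert np.allclose(t, 0.0, atol=1e-10)


def test_covariate_absorbs_matching_offset():
    # group offset exactly equal to age_slope * (age difference); with age
    # in the model the group coefficient vanishes on noise-free data
    ages = np.array([20.0, 25.0, 30.0, 35.0, 30.0, 35.0, 40.0, 45.0])
    design = two_group_design(4, 4, covariates=ages[:, None])
    slope = 0.002
    y = (0.4 + slope * ages)[:, None] * np.ones((1, 5))
    # independent residualization oracle: after removing the age fit, the
    # two groups are identical, so t must be ~0
    t, flags = vertexwise_tstat(y, design)
    assert np.all(np.abs(t) < 0.05)


def test_zero_variance_vertex_flagged():
    design = two_group_design(3, 3)
    y = np.column_stack([np.full(6, 0.5), [1, 2, 3, 2, 3, 4.0]])
    t, flags = vertexwise_tstat(y, design)
    assert flags[0] and not flags[1]
    assert t[0] == 0.0


def test_rank_deficient_design_rejected():
    labels = np.array(["A", "A", "B", "B"])
    cov = np.array([[0.0], [0.0], [1.0], [1.0]])  # duplicates the indicator
    with pytest.raises(DesignError):
        GlmDesign("A", "B", labels, cov)


def test_small_group_rejected():
    with pytest.raises(DesignError):
        two_group_design(1, 4)


# ---------------------------------------------------------------------------
# Cluster extraction

@pytest.fixture
def grid6():
    return flat_grid_mesh(6, spacing=1.0)


def test_no_suprathreshold_empty(grid6):
    t = np.zeros(grid6.n_vertices)
    assert extract_clusters(t, grid6, t0=2.0) == []


def test_full_sheet_single_cluster(grid6):
    t = np.full(grid6.n_vertices, 5.0)
    clusters = extract_clusters(t, grid6, t0=2.0)
    assert len(clusters) == 1
    assert clusters[0].mass == pytest.approx(
        vertex_area_weights(grid6).sum(), rel=1e-12)
    assert len(clusters[0].vertices) == grid6.n_vertices


def test_toy_sheet_matches_flood_fill_oracle():
    mesh = flat_grid_mesh(3)  # vertices 0..8
    t = np.zeros(9)
    t[[0, 1]] = 3.0  # adjacent pair
    t[8] = 3.0  # isolated corner
    clusters = extract_clusters(t, mesh, t0=2.0, direction="group1_lower")
    got = sorted(c.vertices.tolist() for c in clusters)
    oracle = flood_fill_oracle(t >= 2.0, mesh.edges())
    assert got == oracle


def test_random_maps_match_flood_fill_oracle(cc_mesh):
    rng = np.random.default_rng(5)
    for _ in range(10):
        t = rng.normal(size=cc_mesh.n_vertices)
        for direction, mask in [("group1_lower", t >= 1.0),
                                ("group2_lower", t <= -1.0)]:
            clusters = extract_clusters(t, cc_mesh, 1.0, direction)
            got = sorted(c.vertices.tolist() for c in clusters)
            assert got == flood_fill_oracle(mask, cc_mesh.edges())


def test_clusters_sorted_by_mass_then_index(grid6):
    t = np.zeros(grid6.n_vertices)
    t[[0, 1, 2]] = 3.0
    t[35] = 3.0
    clusters = extract_clusters(t, grid6, t0=2.0)
    masses = [c.mass for c in clusters]
    assert masses == sorted(masses, reverse=True)


def test_direction_separates_signs(grid6):
    t = np.zeros(grid6.n_vertices)
    t[0], t[1] = 4.0, -4.0  # adjacent but opposite tails
    both = extract_clusters(t, grid6, t0=2.0, direction="both")
    assert len(both) == 2
    assert {c.direction for c in both} == {"group1_lower", "group2_lower"}


# ---------------------------------------------------------------------------
# Permutation FWER

def planted_datasets(mesh, n_a=4, n_b=4, delta=0.3, sd=0.05, seed=0,
                     tract="CC"):
    rng = np.random.default_rng(seed)
    y = 0.5 + rng.normal(0, sd, (n_a + n_b, mesh.n_vertices))
    y[n_a:, :9] -= delta  # group B lower on a corner patch
    ids = [f"s{i}" for i in range(n_a + n_b)]
    return {tract: VertexDataset(tract, ids, y)}


def test_extreme_rank_p_bound(grid6):
    # with 10v10 subjects a random relabelling essentially never recreates
    # the planted split, so the observed mass beats every permutation
    datasets = planted_datasets(grid6, n_a=10, n_b=10, delta=0.5, sd=0.01)
    design = two_group_design(10, 10)
    config = ClusterConfig(n_permutations=100, seed=6)
    results, null_max = permutation_fwer(
        datasets, {"CC": grid6}, design, config, method="monte_carlo",
        return_null=True)
    assert min(r.p_fwer for r in results) >= 1.0 / 101.0
    big = max(results, key=lambda r: r.mass)
    assert np.all(null_max < big.mass)
    assert big.p_fwer == pytest.approx(1.0 / 101.0)
    assert big.direction == "group2_lower"
    # p-value formula against the returned null distribution
    for r in results:
        expected = (1 + np.count_nonzero(null_max >= r.mass)) / 101.0
        assert r.p_fwer == pytest.approx(expected)


def test_exhaustive_vs_monte_carlo_agreement(grid6):
    datasets = planted_datasets(grid6, delta=0.15, sd=0.08)
    design = two_group_design(4, 4)
    exact = permutation_fwer(datasets, {"CC": grid6}, design,
                             ClusterConfig(n_permutations=10_000, seed=0),
                             method="auto")  # 70 splits -> exhaustive
    mc = permutation_fwer(datasets, {"CC": grid6}, design,
                          ClusterConfig(n_permutations=10_000, seed=3),
                          method="monte_carlo")
    assert len(exact) == len(mc)
    for a, b in zip(exact, mc):
        assert a.mass == pytest.approx(b.mass)
        assert abs(a.p_fwer - b.p_fwer) < 0.02


def test_p_monotone_in_mass(grid6):
    datasets = planted_datasets(grid6, delta=0.2, sd=0.1, seed=4)
    design = two_group_design(4, 4)
    results = permutation_fwer(datasets, {"CC": grid6}, design,
                               ClusterConfig(n_permutations=200, seed=0),
                               method="monte_carlo")
    by_mass = sorted(results, key=lambda r: -r.mass)
    ps = [r.p_fwer for r in by_mass]
    assert ps == sorted(ps)


def test_pooling_inflates_null_tract_p(grid6):
    other = flat_grid_mesh(6, name="SLF_R")
    rng = np.random.default_rng(8)
    noise = 0.5 + rng.normal(0, 0.05, (8, other.n_vertices))
    ids = [f"s{i}" for i in range(8)]
    strong = planted_datasets(grid6, delta=0.4, sd=0.03, seed=2)["CC"]
    b_only = {"SLF_R": VertexDataset("SLF_R", ids, noise)}
    pooled = {"CC": strong, "SLF_R": b_only["SLF_R"]}
    design = two_group_design(4, 4)
    cfg = ClusterConfig(n_permutations=300, seed=0)
    res_single = permutation_fwer(b_only, {"SLF_R": other}, design, cfg,
                                  method="monte_carlo")
    res_pooled = permutation_fwer(pooled, {"CC": grid6, "SLF_R": other},
                                  design, cfg, method="monte_carlo")
    p_single = {tuple(r.vertices): r.p_fwer for r in res_single}
    for r in res_pooled:
        if r.tract == "SLF_R":
            # same permutation stream: pooled maxima dominate, p never smaller
            assert r.p_fwer >= p_single[tuple(r.vertices)] - 1e-12


def test_subject_order_invariance(skeletons_small):
    cfg = CohortConfig(seed=1, effect_delta=0.08)
    records, datasets = generate_cohort(cfg, skeletons_small)
    design = GlmDesign.from_records(records, "CTL", "SCD")
    ids = design.subject_subset(records)
    sub = {t: d.subset(ids) for t, d in datasets.items()}

    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ids))
    ids_p = [ids[i] for i in perm]
    rec_by_id = {r.subject_id: r for r in records}
    design_p = GlmDesign.from_records([rec_by_id[s] for s in ids_p],
                                      "CTL", "SCD")
    sub_p = {t: d.subset(ids_p) for t, d in sub.items()}

    cc = ClusterConfig(n_permutations=100, seed=5)
    res_a = permutation_fwer(sub, skeletons_small, design, cc)
    res_b = permutation_fwer(sub_p, skeletons_small, design_p, cc)
    key = lambda rs: sorted((r.tract, r.direction, tuple(r.vertices),
                             round(r.mass, 9)) for r in rs)
    assert key(res_a) == key(res_b)


def test_determinism_given_seed(grid6):
    datasets = planted_datasets(grid6, delta=0.2, sd=0.1)
    design = two_group_design(4, 4)
    cfg = ClusterConfig(n_permutations=150, seed=9)
    a = permutation_fwer(datasets, {"CC": grid6}, design, cfg,
                         method="monte_carlo")
    b = permutation_fwer(datasets, {"CC": grid6}, design, cfg,
                         method="monte_carlo")
    assert [(r.p_fwer, r.mass) for r in a] == [(r.p_fwer, r.mass) for r in b]


def test_mismatched_subject_order_rejected(grid6):
    datasets = planted_datasets(grid6)
    other = planted_datasets(flat_grid_mesh(6, name="SLF_R"), tract="SLF_R")
    other["SLF_R"].subject_ids[0] = "zz"
    with pytest.raises(ConfigError):
        permutation_fwer({**datasets, **other},
                         {"CC": grid6, "SLF_R": flat_grid_mesh(6, name="SLF_R")},
                         two_group_design(4, 4),
                         ClusterConfig(n_permutations=100, seed=0))


def test_cluster_config_validation():
    with pytest.raises(ConfigError):
        ClusterConfig(n_permutations=0)
    with pytest.raises(ConfigError):
        ClusterConfig(cluster_forming_p=0.0)
    with pytest.raises(ConfigError):
        ClusterConfig(fwer_alpha=1.5)
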