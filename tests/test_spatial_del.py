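"""Unit and oracle tests for the spatial DEL stage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from delatlas.errors import (
    EmptyOutputError,
    InvalidArgumentError,
    InvalidPartitionError,
)
from delatlas.spatial_del import (
    DomainPartition,
    _lloyd_spherical,
    _unit_rows,
    bic_skmeans,
    bic_spherical,
    combine_dels,
    DELCall,
    final_domains,
    jackstraw,
    pairwise_del,
    pc_loading_genes,
    preliminary_domains,
    run_pca,
    select_hvg,
    spherical_kmeans,
    zscore_rows,
)
from delatlas.synthetic_data import generate_embryo, preset_e65

from conftest import make_matrix


# ---------------------------------------------------------------------------
# HVGs and z-scoring
# ---------------------------------------------------------------------------

def test_select_hvg_single_variable_gene():
    vals = np.zeros((4, 4))
    vals[2] = [0, 2, 4, 6]  # the only variable gene
    m = make_matrix(vals)
    assert select_hvg(m, 1) == ["g002"]


def test_select_hvg_tie_break_lexicographic():
    m = make_matrix(np.ones((8, 3)))
    assert select_hvg(m, 5) == [f"g{i:03d}" for i in range(5)]


def test_select_hvg_matches_variance_sort(rng):
    m = make_matrix(rng.normal(size=(50, 10)))
    got = select_hvg(m, 10)
    var = m.values.var(axis=1, ddof=1)
    expected = list(var.sort_values(ascending=False).index[:10])
    assert got == expected


def test_select_hvg_rejects_bad_n():
    m = make_matrix(np.ones((3, 3)))
    with pytest.raises(InvalidArgumentError):
        select_hvg(m, 0)
    with pytest.raises(InvalidArgumentError):
        select_hvg(m, 4)


def test_zscore_three_point_row():
    m = make_matrix(np.array([[1.0, 2.0, 3.0]]))
    z = zscore_rows(m)
    assert np.allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])


def test_zscore_drops_constant_rows_and_has_unit_moments(rng):
    vals = rng.normal(size=(6, 12))
    vals[3] = 7.0
    z = zscore_rows(make_matrix(vals))
    assert "g003" not in z.gene_ids
    assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
    assert np.allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-10)


def test_zscore_all_constant_raises():
    with pytest.raises(EmptyOutputError):
        zscore_rows(make_matrix(np.ones((4, 5))))


# ---------------------------------------------------------------------------
# preliminary domains
# ---------------------------------------------------------------------------

def test_preliminary_domains_recovers_identical_blocks(two_block_matrix, rng):
    matrix, block_a = two_block_matrix
    noisy = make_matrix(
        matrix.values.to_numpy() + rng.normal(0, 1e-6, size=matrix.values.shape)
    )
    part = preliminary_domains(zscore_rows(noisy), 2)
    labels = part.assignment
    assert labels[block_a].nunique() == 1
    assert labels.drop(block_a).nunique() == 1
    assert labels[block_a].iloc[0] != labels.drop(block_a).iloc[0]


def test_preliminary_domains_k_equals_samples(rng):
    z = zscore_rows(make_matrix(rng.normal(size=(20, 6))))
    part = preliminary_domains(z, 6)
    assert part.K == 6


def test_preliminary_domains_matches_planted_split_at_low_noise():
    preset = preset_e65(seed=0, noise_sigma=1e-6)
    matrix, truth, _ = generate_embryo(preset)
    z = zscore_rows(matrix.to_log2(1.0))
    part = preliminary_domains(z, 2)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth.assignment, part.assignment) == 1.0


def test_preliminary_domains_rejects_k_above_samples(rng):
    z = zscore_rows(make_matrix(rng.normal(size=(10, 4))))
    with pytest.raises(InvalidArgumentError):
        preliminary_domains(z, 5)


# ---------------------------------------------------------------------------
# pairwise t/FC calls
# ---------------------------------------------------------------------------

def _welch_oracle(a, b):
    """Hand-rolled Welch t-test (two-sided)."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


def _partition(samples_a, samples_b):
    return DomainPartition(
        pd.Series(
            ["A"] * len(samples_a) + ["B"] * len(samples_b),
            index=list(samples_a) + list(samples_b),
        ),
        kind="preliminary",
    )


def test_pairwise_del_matches_brute_force(rng):
    lin = np.exp2(rng.normal(3, 1, size=(20, 8)))
    m = make_matrix(lin, scale_tag="linear")
    part = _partition(m.sample_ids[:4], m.sample_ids[4:])
    calls = pairwise_del(m, part, pseudocount=1e-6, log_pseudocount=1.0)
    called = {c.gene_id for c in calls}
    expected = set()
    log2 = np.log2(lin + 1.0)
    for i, g in enumerate(m.gene_ids):
        p = _welch_oracle(log2[i, :4], log2[i, 4:])
        fc = (lin[i, :4].mean() + 1e-6) / (lin[i, 4:].mean() + 1e-6)
        if p < 0.05 and max(fc, 1 / fc) >= 1.5:
            expected.add(g)
    assert called == expected


def test_identical_gene_not_called():
    lin = np.tile([4.0, 4.0, 4.0, 4.0], (1, 2)).reshape(1, 8)
    m = make_matrix(lin, scale_tag="linear")
    part = _partition(m.sample_ids[:4], m.sample_ids[4:])
    assert pairwise_del(m, part) == []


def test_clear_fourfold_difference_called(rng):
    lin = np.array([[4, 4, 4, 4, 1, 1, 1, 1]], dtype=float)
    lin += rng.normal(0, 1e-6, size=lin.shape)
    m = make_matrix(np.abs(lin), scale_tag="linear")
    part = _partition(m.sample_ids[:4], m.sample_ids[4:])
    calls = pairwise_del(m, part, pseudocount=0.0)
    assert len(calls) == 1
    assert calls[0].fold_change == pytest.approx(4.0, rel=1e-4)
    assert calls[0].p_value < 0.05


def test_fold_change_gate_blocks_significant_but_small_effects(rng):
    # FC = 1.4 with tiny within-group noise: p is minuscule, gate must hold
    lin = np.concatenate([np.full(6, 1.4), np.full(6, 1.0)]).reshape(1, 12)
    lin = lin + rng.normal(0, 1e-9, size=lin.shape)
    m = make_matrix(lin, scale_tag="linear")
    part = _partition(m.sample_ids[:6], m.sample_ids[6:])
    calls = pairwise_del(m, part, pseudocount=0.0, log_pseudocount=0.0)
    assert calls == []
    # sanity: it is the FC gate, not the p-value, that blocks the call
    assert pairwise_del(m, part, fc_thresh=1.3, pseudocount=0.0,
                        log_pseudocount=0.0)


def test_pairwise_del_rejects_singleton_domain():
    m = make_matrix(np.ones((3, 4)) + 1, scale_tag="linear")
    part = _partition(m.sample_ids[:1], m.sample_ids[1:])
    with pytest.raises(InvalidPartitionError):
        pairwise_del(m, part)


# ---------------------------------------------------------------------------
# PCA / jackstraw / loading calls
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix():
    base = np.array([1.0, -1.0, 2.0, 0.0, 3.0])
    vals = np.outer([1, 2, 3, 4], base)
    z = zscore_rows(make_matrix(vals))
    _, _, var = run_pca(z)
    assert var.iloc[0] == pytest.approx(1.0)
    assert np.all(var.iloc[1:] < 1e-20)


def test_pca_two_by_two_closed_form():
    # loadings of X = [[1, 0], [0, -1]] for 2 genes over 2 samples:
    # z-scored rows become +-1/sqrt(2) patterns; hand eigenvectors are
    # (1, -1)/sqrt(2) for the leading PC of the gene-gene covariance.
    z = zscore_rows(make_matrix(np.array([[1.0, 0.0], [0.0, 1.0]])))
    loadings, _, var = run_pca(z)
    assert np.allclose(np.abs(loadings["PC1"]), 1 / np.sqrt(2), atol=1e-12)
    assert np.sign(loadings["PC1"]["g000"]) != np.sign(loadings["PC1"]["g001"])
    assert var.iloc[0] == pytest.approx(1.0)


def test_pca_loadings_orthonormal(rng):
    z = zscore_rows(make_matrix(rng.normal(size=(30, 8))))
    loadings, _, _ = run_pca(z)
    L = loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)


def test_jackstraw_seed_determinism(rng):
    z = zscore_rows(make_matrix(rng.normal(size=(60, 10))))
    a = jackstraw(z, n_pcs=3, B=20, seed=5)
    b = jackstraw(z, n_pcs=3, B=20, seed=5)
    pd.testing.assert_frame_equal(a.per_gene_p, b.per_gene_p)
    assert a.significant_pcs == b.significant_pcs


def test_jackstraw_rejects_vanishing_permutation_fraction(rng):
    z = zscore_rows(make_matrix(rng.normal(size=(6, 10))))
    with pytest.raises(InvalidArgumentError):
        jackstraw(z, n_pcs=2, s=0.01, B=5)


def test_jackstraw_flags_planted_structure(rng):
    base = rng.normal(size=(2, 20)) * 2
    X = np.vstack(
        [
            base[0] + rng.normal(0, 0.3, size=(50, 20)),
            base[1] + rng.normal(0, 0.3, size=(50, 20)),
            rng.normal(size=(60, 20)),
        ]
    )
    z = zscore_rows(make_matrix(X))
    js = jackstraw(z, n_pcs=5, B=50, seed=0)
    assert js.significant_pcs[:2] == [1, 2]


def test_pc_loading_call_counts_and_top_selection(rng):
    loadings = pd.DataFrame(
        rng.normal(size=(40, 4)),
        index=[f"g{i:03d}" for i in range(40)],
        columns=["PC1", "PC2", "PC3", "PC4"],
    )
    calls = pc_loading_genes(loadings, [1, 2, 3, 4], top_n=10)
    assert len(calls) == 40
    # per-PC selection equals a brute-force sort
    for pc in (1, 2, 3, 4):
        chosen = {c.gene_id for c in calls if c.pc == pc}
        col = loadings[f"PC{pc}"].sort_values()
        assert chosen == set(col.index[:5]) | set(col.index[-5:])


def test_pc_loading_two_gene_example():
    loadings = pd.DataFrame(
        {"PC1": [0.9, -0.8, 0.1, 0.05]}, index=["g1", "g2", "g3", "g4"]
    )
    calls = pc_loading_genes(loadings, [1], top_n=2)
    assert {c.gene_id for c in calls} == {"g1", "g2"}


def test_pc_loading_clips_with_warning(caplog):
    loadings = pd.DataFrame({"PC1": [0.5, -0.5, 0.1]}, index=["a", "b", "c"])
    calls = pc_loading_genes(loadings, [1], top_n=10)
    assert len(calls) == 2
    with pytest.raises(InvalidArgumentError):
        pc_loading_genes(loadings, [1], top_n=3)  # odd top_n


def test_combine_modes():
    t = [DELCall("A", "ttest_fc", domain_pair=("x", "y")),
         DELCall("B", "ttest_fc", domain_pair=("x", "y"))]
    p = [DELCall("B", "pc_loading", pc=1), DELCall("C", "pc_loading", pc=2)]
    assert combine_dels(t, p, "union").genes == ["A", "B", "C"]
    assert combine_dels(t, p, "intersection").genes == ["B"]
    assert combine_dels(t, [], "union").genes == ["A", "B"]


# ---------------------------------------------------------------------------
# final domains and BIC spherical K-means
# ---------------------------------------------------------------------------

def test_final_domains_recovers_separated_blocks(rng):
    profiles = np.zeros((30, 12))
    profiles[:, :6] = 5.0
    z = zscore_rows(make_matrix(profiles + rng.normal(0, 0.1, size=profiles.shape)))
    part = final_domains(z, 2, seed=0)
    labels = part.assignment
    assert labels.iloc[:6].nunique() == 1
    assert labels.iloc[6:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]
    again = final_domains(z, 2, seed=0)
    pd.testing.assert_series_equal(part.assignment, again.assignment)


def test_lloyd_rss_is_non_increasing(rng):
    X = _unit_rows(rng.normal(size=(40, 10)))
    C0 = X[:4].copy()
    trace: list = []
    _lloyd_spherical(X, C0.copy(), max_iter=100, trace=trace)
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_bic_skmeans_single_k():
    m = zscore_rows(make_matrix(np.random.default_rng(0).normal(size=(10, 6))))
    gg = bic_skmeans(m, k_range=[1], min_group_size=1, min_group_coherence=0)
    assert gg.K_selected == 1
    assert gg.assignment.nunique() == 1


def _exhaustive_skmeans_oracle(Xu, k_values):
    """Global-optimum spherical K-means + BIC by set-partition enumeration."""
    n, d = Xu.shape

    def partitions(k):
        # restricted growth strings with exactly k blocks
        def rec(i, groups, used):
            if i == n:
                if used == k:
                    yield list(groups)
                return
            for g in range(min(used + 1, k)):
                groups.append(g)
                yield from rec(i + 1, groups, max(used, g + 1))
                groups.pop()

        yield from rec(0, [], 0)

    best = {}
    for k in k_values:
        best_rss, best_labels = np.inf, None
        for labels in partitions(k):
            labels = np.asarray(labels)
            rss = 0.0
            for g in range(k):
                block = Xu[labels == g]
                mean = block.sum(axis=0)
                norm = np.linalg.norm(mean)
                c = mean / norm if norm > 0 else block[0]
                rss += float(np.sum(2.0 - 2.0 * block @ c))
            if rss < best_rss - 1e-12:
                best_rss, best_labels = rss, labels
        bic = (
            -np.inf
            if best_rss <= 0
            else n * d * np.log(best_rss / (n * d)) + (k * d + 1) * np.log(n * d)
        )
        best[k] = (best_rss, bic, best_labels)
    return best


def test_bic_skmeans_matches_exhaustive_oracle_on_planted_pair(rng):
    from sklearn.metrics import adjusted_rand_score

    a = np.array([1.0, 1, 1, 0, 0, 0])
    b = np.array([0.0, 0, 0, 1, 1, 1])
    X = np.vstack(
        [a + rng.normal(0, 0.3, size=(5, 6)), b + rng.normal(0, 0.3, size=(5, 6))]
    )
    z = zscore_rows(make_matrix(X))
    gg = bic_skmeans(z, k_range=[1, 2, 3], seed=0)  # default size floor (5)
    oracle = _exhaustive_skmeans_oracle(
        _unit_rows(z.values.to_numpy()), [1, 2, 3]
    )
    # the whole BIC curve equals the global-optimum enumeration
    for k in (1, 2, 3):
        assert gg.bic_curve[k] == pytest.approx(oracle[k][1], rel=1e-9)
    # selection replicating the size floor: clusters below 5 genes are noise
    admissible = [
        k for k, (_, _, labels) in oracle.items()
        if k == 1 or np.bincount(labels, minlength=k).min() >= 5
    ]
    oracle_k = min(admissible, key=lambda k: (oracle[k][1], k))
    assert gg.K_selected == oracle_k == 2
    codes = pd.Categorical(gg.assignment).codes
    assert adjusted_rand_score(codes, oracle[2][2]) == 1.0


def test_bic_skmeans_size_floor_suppresses_outlier_clusters(rng):
    """A couple of isotropic outlier genes must not open an extra group."""
    a = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
    b = 1 - a
    X = np.vstack(
        [
            a + rng.normal(0, 0.1, size=(30, 8)),
            b + rng.normal(0, 0.1, size=(30, 8)),
            rng.normal(size=(2, 8)),  # outliers
        ]
    )
    z = zscore_rows(make_matrix(X))
    constrained = bic_skmeans(z, k_range=[2, 3, 4], seed=0)
    assert constrained.K_selected == 2
    free = bic_skmeans(z, k_range=[2, 3, 4], seed=0, min_group_size=1, min_group_coherence=0)
    assert free.K_selected > 2  # the BIC alone chases the outliers


def test_spherical_kmeans_seed_determinism(rng):
    X = rng.normal(size=(25, 7))
    l1, c1, r1 = spherical_kmeans(X, 3, seed=2, n_init=10)
    l2, c2, r2 = spherical_kmeans(X, 3, seed=2, n_init=10)
    assert np.array_equal(l1, l2) and r1 == r2


def test_bic_spherical_perfect_fit_is_minus_infinity():
    assert bic_spherical(0.0, 10, 4, 2) == -np.inf
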