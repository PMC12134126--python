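"""Unit and oracle tests for the co-expression network stage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from delatlas.coexpression import (
    CoexpressionModule,
    NetworkParams,
    categorize_modules,
    compute_tom,
    default_power,
    detect_modules,
    module_eigengene,
    module_trait,
    pick_soft_power,
    run_coexpression_pipeline,
    scale_free_fit,
)
from delatlas.errors import InvalidArgumentError
from delatlas.synthetic_data import TimecoursePreset, generate_timecourse

from conftest import make_matrix


# ---------------------------------------------------------------------------
# scale-free fit and soft power
# ---------------------------------------------------------------------------

def test_scale_free_fit_perfect_power_law():
    # k = 2^b with frequency 2^(10-b): log-frequency is exactly linear in
    # log-k with negative slope, so the binned fit must be perfect
    k = np.concatenate([np.full(2 ** (10 - b), float(2**b)) for b in range(1, 11)])
    r2, slope = scale_free_fit(k, n_bins=10)
    assert r2 == pytest.approx(1.0, abs=1e-9)
    assert slope < 0


def test_scale_free_fit_rejects_increasing_distribution():
    k = np.concatenate([np.full(2**b, float(2**b)) for b in range(1, 11)])
    r2, _ = scale_free_fit(k, n_bins=10)
    assert r2 == 0.0


def test_pick_soft_power_zero_target_accepts_beta_one(rng):
    m = make_matrix(rng.normal(size=(20, 8)))
    params = pick_soft_power(m, r2_target=0.0)
    assert params.beta == 1


def test_pick_soft_power_requires_samples(rng):
    with pytest.raises(InvalidArgumentError):
        pick_soft_power(make_matrix(rng.normal(size=(5, 3))))


def test_default_power_convention():
    assert default_power(16) == 9
    assert default_power(32) == 7
    assert default_power(50) == 6
    assert default_power(50, signed=True) == 12


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def test_tom_perfectly_correlated_pair():
    profile = np.array([1.0, 2.0, 3.0, 4.0])
    m = make_matrix(np.vstack([profile, 2 * profile + 1]))
    tom = compute_tom(m, NetworkParams(1, 1.0))
    assert tom.values.iloc[0, 1] == pytest.approx(1.0)


def test_tom_matches_elementwise_formula(rng):
    m = make_matrix(rng.normal(size=(7, 10)))
    beta = 3
    tom = compute_tom(m, NetworkParams(beta, 0.0)).values.to_numpy()
    corr = np.corrcoef(m.values.to_numpy())
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    n = len(a)
    expected = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                expected[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            expected[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    assert np.allclose(tom, expected, atol=1e-10)


def test_tom_uncorrelated_genes_have_zero_overlap():
    # orthogonal two-gene network: adjacency ~0 off-diagonal
    m = make_matrix(np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]]))
    tom = compute_tom(m, NetworkParams(1, 0.0)).values.to_numpy()
    assert abs(tom[0, 1]) < 1e-12


def test_tom_symmetric_bounded(rng):
    tom = compute_tom(make_matrix(rng.normal(size=(15, 8))), NetworkParams(6, 0.0))
    v = tom.values.to_numpy()
    assert np.allclose(v, v.T)
    assert (v >= 0).all() and (v <= 1 + 1e-12).all()
    assert np.allclose(np.diag(v), 1.0)


# ---------------------------------------------------------------------------
# module detection / eigengenes
# ---------------------------------------------------------------------------

def _block_matrix(rng, n_blocks=4, block=40, d=20, sep=3.0, noise=0.3):
    profiles = rng.normal(size=(n_blocks, d)) * sep
    X = np.vstack(
        [profiles[b] + rng.normal(0, noise, size=(block, d)) for b in range(n_blocks)]
    )
    return make_matrix(X)


def test_detect_modules_recovers_planted_blocks(rng):
    m = _block_matrix(rng)
    tom = compute_tom(m, NetworkParams(6, 0.0))
    modules = detect_modules(m, tom, min_size=30)
    assert len(modules) == 4
    blocks = [set(f"g{i:03d}" for i in range(b * 40, (b + 1) * 40)) for b in range(4)]
    got = [set(mod.member_genes) for mod in modules]
    assert all(any(gb == b for gb in got) for b in blocks)


def test_detect_modules_min_size_floor(rng):
    m = make_matrix(rng.normal(size=(20, 8)))
    tom = compute_tom(m, NetworkParams(6, 0.0))
    assert detect_modules(m, tom, min_size=30) == []


def test_detect_modules_eigengene_merge_step(rng):
    # two blocks whose profiles correlate ~0.8: they separate in TOM space
    # at a strict cut, but their eigengene dissimilarity (~0.2) is below
    # the default merge threshold of 0.25, so they fuse afterwards
    p = rng.normal(size=24)
    q = rng.normal(size=24)
    p = (p - p.mean()) / p.std()
    q = (q - q.mean()) / q.std()
    q = q - np.dot(q, p) / np.dot(p, p) * p
    q = q / q.std()
    pb = 0.8 * p + 0.6 * q
    X = np.vstack(
        [
            3 * p + rng.normal(0, 0.2, size=(35, 24)),
            3 * pb + rng.normal(0, 0.2, size=(35, 24)),
            rng.normal(size=(20, 24)),  # grey background
        ]
    )
    m = make_matrix(X)
    tom = compute_tom(m, NetworkParams(12, 0.0))
    separate = detect_modules(m, tom, min_size=30, merge_cut=0.05,
                              cut_height_frac=0.5)
    assert len(separate) == 2
    merged = detect_modules(m, tom, min_size=30, merge_cut=0.25,
                            cut_height_frac=0.5)
    assert len(merged) == 1 and len(merged[0].member_genes) == 70


def test_module_eigengene_of_identical_genes(rng):
    profile = rng.normal(size=10)
    m = make_matrix(np.tile(profile, (5, 1)))
    e = module_eigengene(m, list(m.gene_ids))
    z = (profile - profile.mean()) / profile.std(ddof=1)
    assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)
    assert np.linalg.norm(e) == pytest.approx(1.0)
    # sign convention: non-negative correlation with the member average
    assert np.corrcoef(e, z)[0, 1] > 0


def test_module_eigengene_matches_svd(rng):
    m = make_matrix(rng.normal(size=(3, 9)))
    e = module_eigengene(m, list(m.gene_ids))
    z = stats.zscore(m.values.to_numpy(), axis=1, ddof=1)
    _, _, vt = np.linalg.svd(z)
    assert abs(np.corrcoef(e, vt[0])[0, 1]) == pytest.approx(1.0)


def test_module_eigengene_member_order_invariant(rng):
    m = make_matrix(rng.normal(size=(6, 8)))
    genes = list(m.gene_ids)
    a = module_eigengene(m, genes)
    b = module_eigengene(m, genes[::-1])
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# trait correlation and categories
# ---------------------------------------------------------------------------

def _toy_module(e, samples):
    return CoexpressionModule(
        "M1", ["g1"], pd.Series(e / np.linalg.norm(e), index=samples)
    )


def test_module_trait_exact_linearity():
    samples = [f"s{i}" for i in range(4)]
    mod = _toy_module(np.array([1.0, 2.0, 3.0, 4.0]), samples)
    [out] = module_trait([mod], {"t": pd.Series([2.0, 4.0, 6.0, 8.0], index=samples)})
    r, p = out.trait_correlations["t"]
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_module_trait_matches_textbook_formula(rng):
    samples = [f"s{i}" for i in range(10)]
    e = rng.normal(size=10)
    t = rng.normal(size=10)
    mod = _toy_module(e, samples)
    [out] = module_trait([mod], {"t": pd.Series(t, index=samples)})
    r, p = out.trait_correlations["t"]
    n = 10
    ex = e / np.linalg.norm(e)
    r_hand = np.corrcoef(ex, t)[0, 1]
    t_stat = abs(r_hand) * np.sqrt((n - 2) / (1 - r_hand**2))
    p_hand = 2 * stats.t.sf(t_stat, n - 2)
    assert r == pytest.approx(r_hand, rel=1e-12)
    assert p == pytest.approx(p_hand, rel=1e-6)


def test_module_trait_constant_trait_is_missing():
    samples = [f"s{i}" for i in range(5)]
    mod = _toy_module(np.arange(5.0) + 1, samples)
    [out] = module_trait([mod], {"c": pd.Series(1.0, index=samples)})
    assert np.isnan(out.trait_correlations["c"][0])


def _wt_gko_frame(n_days=8, reps=2):
    samples, day, gt = [], [], []
    for g in ("WT", "GKO"):
        for d in range(n_days):
            for r in range(reps):
                samples.append(f"{g}_D{d}_R{r}")
                day.append(float(d))
                gt.append(g)
    return samples, pd.Series(day, index=samples), pd.Series(gt, index=samples)


def test_categorize_gko_constant_by_construction():
    samples, day, gt = _wt_gko_frame()
    e = np.where(gt == "GKO", 1.0, 0.0) + np.random.default_rng(0).normal(0, 0.01, len(samples))
    [mod] = categorize_modules([_toy_module(e, samples)], day=day, genotype=gt)
    assert mod.category == "GKO-constant"


def test_categorize_wt_late_by_construction():
    samples, day, gt = _wt_gko_frame()
    e = np.where(gt == "WT", day / 7.0, 0.0)
    [mod] = categorize_modules([_toy_module(e, samples)], day=day, genotype=gt)
    assert mod.category == "WT-Late"


def test_categorize_strict_threshold_unassigns_everything():
    samples, day, gt = _wt_gko_frame()
    e = np.where(gt == "GKO", 1.0, 0.0)
    [mod] = categorize_modules(
        [_toy_module(e, samples)], day=day, genotype=gt, r_min=1.0
    )
    assert mod.category == "unassigned"


def test_pipeline_recovers_planted_program_categories():
    matrix, truth = generate_timecourse(TimecoursePreset(seed=1))
    result = run_coexpression_pipeline(matrix)
    recovered = {m.category for m in result.modules} - {"unassigned"}
    assert recovered == {"WT-Early", "WT-Late", "GKO-Early", "GKO-constant"}
    # modules partition their genes (no overlap after merging)
    all_members = [g for m in result.modules for g in m.member_genes]
    assert len(all_members) == len(set(all_members))
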