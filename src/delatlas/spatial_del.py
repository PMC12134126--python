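"""Spatial DEL identification and domain/gene-group clustering.

Implements the four-step procedure used to call differentially expressed
lncRNAs (DELs) across laser-microdissected gastrula positions:

1. rank genes by expression variance and keep the top *n* highly variable
   genes (HVGs);
2. hierarchically cluster samples on correlation distance of z-scored HVG
   expression to obtain preliminary spatial domains;
3. call genes differential between every pair of preliminary domains with a
   Welch t-test (P < 0.05) and a linear fold-change gate (FC >= 1.5);
4. add the top positive and top negative principal-component loading genes
   of the jackstraw-significant PCs.

The combined DEL set then drives K-means assignment of the final spatial
domains and BIC-guided spherical K-means (``bic_skmeans``) grouping of the
DEL genes themselves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import (
    EmptyOutputError,
    InvalidArgumentError,
    InvalidPartitionError,
)
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class DomainPartition:
    """Assignment of spatial samples to domain labels."""

    assignment: pd.Series  # sample_id -> domain label
    kind: str = "final"    # "preliminary", "final" or "true" (generator truth)

    def __post_init__(self) -> None:
        if self.assignment.index.duplicated().any():
            raise InvalidPartitionError("a sample is assigned more than once")
        if len(self.assignment) == 0:
            raise InvalidPartitionError("empty partition")

    @property
    def K(self) -> int:
        return self.assignment.nunique()

    @property
    def labels(self) -> list:
        """Domain labels ordered by first occurrence."""
        return list(dict.fromkeys(self.assignment))

    def samples_of(self, label) -> pd.Index:
        return self.assignment.index[self.assignment == label]


@dataclass
class DELCall:
    """A single piece of evidence that a gene is spatially differential."""

    gene_id: str
    source: str                     # "ttest_fc" or "pc_loading"
    p_value: float | None = None
    fold_change: float | None = None  # direction-agnostic linear ratio, >= 1
    domain_pair: tuple | None = None
    pc: int | None = None           # 1-based PC index
    loading: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("ttest_fc", "pc_loading"):
            raise InvalidArgumentError(f"unknown DEL source {self.source!r}")
        if self.source == "ttest_fc" and self.domain_pair is None:
            raise InvalidArgumentError("ttest_fc call requires a domain pair")
        if self.source == "pc_loading" and self.pc is None:
            raise InvalidArgumentError("pc_loading call requires a PC index")


@dataclass
class DELSet:
    """Deduplicated DEL gene set with per-call provenance."""

    calls: list

    @property
    def genes(self) -> list:
        return sorted({c.gene_id for c in self.calls})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "source": c.source,
                "p_value": c.p_value,
                "fold_change": c.fold_change,
                "domain_a": c.domain_pair[0] if c.domain_pair else None,
                "domain_b": c.domain_pair[1] if c.domain_pair else None,
                "pc": c.pc,
                "loading": c.loading,
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "source", "p_value", "fold_change",
                "domain_a", "domain_b", "pc", "loading",
            ],
        )


@dataclass
class JackstrawResult:
    s: float
    B: int
    alpha: float
    per_gene_p: pd.DataFrame      # genes x PC empirical p-values
    pc_p_values: pd.Series        # binomial-excess p per PC
    significant_pcs: list         # 1-based indices, ascending


@dataclass
class GeneGroupClustering:
    """Gene -> group assignment with the BIC curve that selected K."""

    assignment: pd.Series            # gene_id -> group label ("G1"...)
    K_selected: int
    bic_curve: dict                  # K -> BIC (np.inf where infeasible)
    centroids: pd.DataFrame | None = None  # group x sample, unit L2 norm

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.assignment))


# ---------------------------------------------------------------------------
# step 1-2: HVGs, z-scoring, preliminary domains
# ---------------------------------------------------------------------------

def select_hvg(matrix: ExpressionMatrix, n: int = 1000) -> list:
    """Top-``n`` genes by expression variance (sample variance, ddof=1).

    Ties are broken by gene_id ascending so the selection is deterministic.
    """
    matrix.require_scale("log2")
    if n <= 0:
        raise InvalidArgumentError(f"n must be positive, got {n}")
    if n > matrix.n_genes:
        raise InvalidArgumentError(
            f"n={n} exceeds the {matrix.n_genes} genes available"
        )
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(matrix.gene_ids, key=lambda g: (-var[g], str(g)))
    return order[:n]


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (sample sd, ddof=1).

    Constant rows (sd == 0) are dropped with a warning; a fully constant
    matrix raises :class:`EmptyOutputError`.
    """
    matrix.require_scale("log2")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise EmptyOutputError("all gene rows are constant; nothing to z-score")
    if (~keep).any():
        dropped = list(vals.index[~keep])
        logger.warning(
            "zscore_rows dropped %d constant gene row(s): %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    sub = vals.loc[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(z, scale_tag="zscore", sample_meta=matrix.sample_meta)


def preliminary_domains(matrix: ExpressionMatrix, k_prelim: int) -> DomainPartition:
    """Average-linkage clustering of samples on 1 - Pearson, cut at ``k_prelim``."""
    matrix.require_scale("zscore")
    n = matrix.n_samples
    if not (1 <= k_prelim <= n):
        raise InvalidArgumentError(
            f"k_prelim={k_prelim} out of range for {n} samples"
        )
    X = matrix.values.to_numpy(dtype=float)
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=k_prelim, criterion="maxclust")
    # relabel by first occurrence for determinism
    remap: dict = {}
    labels = []
    for c in flat:
        if c not in remap:
            remap[c] = f"P{len(remap) + 1}"
        labels.append(remap[c])
    assignment = pd.Series(labels, index=matrix.sample_ids, name="domain")
    part = DomainPartition(assignment, kind="preliminary")
    if part.K != k_prelim:
        logger.warning(
            "dendrogram cut yielded %d clusters instead of %d (tied heights)",
            part.K, k_prelim,
        )
    return part


# ---------------------------------------------------------------------------
# step 3: pairwise t-test / fold-change calls
# ---------------------------------------------------------------------------

def pairwise_del(
    matrix: ExpressionMatrix,
    partition: DomainPartition,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    pseudocount: float = 1e-6,
    log_pseudocount: float = 1.0,
    fdr: bool = False,
) -> list:
    """Welch t + fold-change DEL calls for every unordered domain pair.

    The t-test runs on ``log2(x + log_pseudocount)``; the fold change is the
    ratio of linear domain means with pseudocount ``pseudocount`` and is
    gated direction-agnostically: ``max(FC, 1/FC) >= fc_thresh``.  Raw
    p-values are used by default; ``fdr=True`` applies Benjamini-Hochberg
    within each domain pair.
    """
    matrix.require_scale("linear")
    for lab in partition.labels:
        if len(partition.samples_of(lab)) < 2:
            raise InvalidPartitionError(
                f"domain {lab!r} has fewer than 2 samples"
            )
    lin = matrix.values
    logm = np.log2(lin.to_numpy(dtype=float) + log_pseudocount)
    logm = pd.DataFrame(logm, index=lin.index, columns=lin.columns)

    calls: list = []
    labels = sorted(map(str, partition.labels))
    for lab_a, lab_b in itertools.combinations(labels, 2):
        cols_a = partition.samples_of(lab_a)
        cols_b = partition.samples_of(lab_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(
                logm[cols_a], logm[cols_b], axis=1, equal_var=False
            )
        if fdr:
            ok = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            if ok.any():
                adj[ok] = stats.false_discovery_control(pvals[ok], method="bh")
            pvals = adj
        mean_a = lin[cols_a].mean(axis=1).to_numpy()
        mean_b = lin[cols_b].mean(axis=1).to_numpy()
        fc = (mean_a + pseudocount) / (mean_b + pseudocount)
        with np.errstate(divide="ignore"):
            fc_max = np.maximum(fc, 1.0 / fc)
        called = (
            np.isfinite(pvals)
            & (pvals < p_thresh)
            & np.isfinite(fc_max)
            & (fc_max >= fc_thresh)
        )
        for gi in np.flatnonzero(called):
            calls.append(
                DELCall(
                    gene_id=lin.index[gi],
                    source="ttest_fc",
                    p_value=float(pvals[gi]),
                    fold_change=float(fc_max[gi]),
                    domain_pair=(lab_a, lab_b),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# step 4: PCA, jackstraw and PC-loading calls
# ---------------------------------------------------------------------------

def run_pca(matrix: ExpressionMatrix):
    """PCA of samples in gene-standardized space.

    Returns ``(loadings, scores, variance_explained)`` where loadings is a
    genes x PC frame with orthonormal columns (sign fixed so the
    largest-magnitude entry of each loading vector is positive), scores is
    samples x PC, and variance_explained is the per-PC fraction.
    """
    matrix.require_scale("zscore")
    if matrix.n_samples < 2:
        raise InvalidArgumentError("PCA requires at least 2 samples")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes, cols ~ mean 0
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(S > 0):
        raise InvalidArgumentError("degenerate (rank-0) input")
    # deterministic sign: largest |entry| of each loading vector positive
    V = Vt.T
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    cols = [f"PC{j + 1}" for j in range(len(S))]
    loadings = pd.DataFrame(V, index=matrix.gene_ids, columns=cols)
    scores = pd.DataFrame(U * S, index=matrix.sample_ids, columns=cols)
    var_explained = pd.Series(S**2 / np.sum(S**2), index=cols)
    return loadings, scores, var_explained


def _svd_loadings(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Absolute gene loadings of the first ``n_pcs`` PCs of genes x samples X."""
    _, _, Vt = np.linalg.svd(X.T, full_matrices=False)
    return np.abs(Vt.T[:, :n_pcs])


def jackstraw(
    matrix: ExpressionMatrix,
    n_pcs: int,
    s: float = 0.1,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    gene_p_thresh: float = 0.05,
    multiple_correction: str = "bonferroni",
) -> JackstrawResult:
    """Permutation (jackstraw) significance of PCs.

    Each of ``B`` iterations permutes a random fraction ``s`` of gene rows
    across samples, recomputes the PCA, and pools the permuted genes'
    absolute loadings as the per-PC null.  Per-gene empirical p-values use
    the add-one estimator ``(1 + #null >= |obs|) / (1 + #null)``.  A PC is
    declared significant when the number of genes with p < ``gene_p_thresh``
    exceeds the binomial expectation by a one-sided test at level ``alpha``
    (Bonferroni-corrected across the tested PCs by default).
    """
    matrix.require_scale("zscore")
    G, n = matrix.n_genes, matrix.n_samples
    if n_pcs > min(G, n) - 1:
        raise InvalidArgumentError(
            f"n_pcs={n_pcs} exceeds min(genes, samples) - 1 = {min(G, n) - 1}"
        )
    if not 0 < s < 1:
        raise InvalidArgumentError("s must lie in (0, 1)")
    m = int(round(s * G))
    if m < 1:
        raise InvalidArgumentError("s * genes < 1: no rows to permute")
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    if multiple_correction not in ("bonferroni", "none"):
        raise InvalidArgumentError(
            f"unknown multiple_correction {multiple_correction!r}"
        )

    X = matrix.values.to_numpy(dtype=float)
    obs = _svd_loadings(X, n_pcs)

    rng = np.random.default_rng(seed)
    null = [[] for _ in range(n_pcs)]
    for _ in range(B):
        idx = rng.choice(G, size=m, replace=False)
        Xp = X.copy()
        for i in idx:
            Xp[i] = Xp[i][rng.permutation(n)]
        lp = _svd_loadings(Xp, n_pcs)
        for j in range(n_pcs):
            null[j].append(lp[idx, j])

    per_gene_p = np.empty((G, n_pcs))
    for j in range(n_pcs):
        pooled = np.sort(np.concatenate(null[j]))
        N = len(pooled)
        n_ge = N - np.searchsorted(pooled, obs[:, j], side="left")
        per_gene_p[:, j] = (1.0 + n_ge) / (1.0 + N)

    counts = (per_gene_p < gene_p_thresh).sum(axis=0)
    pc_p = stats.binom.sf(counts - 1, G, gene_p_thresh)
    level = alpha / n_pcs if multiple_correction == "bonferroni" else alpha
    significant = [j + 1 for j in range(n_pcs) if pc_p[j] < level]

    cols = [f"PC{j + 1}" for j in range(n_pcs)]
    return JackstrawResult(
        s=s,
        B=B,
        alpha=alpha,
        per_gene_p=pd.DataFrame(per_gene_p, index=matrix.gene_ids, columns=cols),
        pc_p_values=pd.Series(pc_p, index=cols),
        significant_pcs=significant,
    )


def pc_loading_genes(
    loadings: pd.DataFrame,
    pcs: list,
    top_n: int = 300,
    by_abs: bool = False,
) -> list:
    """DEL calls for the top positive and top negative loading genes per PC.

    ``top_n // 2`` most-positive plus ``top_n // 2`` most-negative loadings
    are taken for each requested PC (``by_abs=True`` instead takes the
    ``top_n`` largest absolute loadings).  ``top_n`` larger than the gene
    count is clipped (with a warning) to the largest feasible even value.
    Duplicate genes across PCs are retained as separate calls.
    """
    if top_n <= 0:
        raise InvalidArgumentError("top_n must be positive")
    if not by_abs and top_n % 2:
        raise InvalidArgumentError("top_n must be even for a symmetric split")
    G = len(loadings)
    if top_n > G:
        clipped = G if by_abs else G - (G % 2)
        logger.warning("top_n=%d exceeds %d genes; clipping to %d", top_n, G, clipped)
        top_n = clipped
    calls: list = []
    for pc in pcs:
        col = f"PC{pc}"
        if col not in loadings.columns:
            raise InvalidArgumentError(f"{col} not among computed PCs")
        vals = loadings[col]
        if by_abs:
            chosen = sorted(
                loadings.index, key=lambda g: (-abs(vals[g]), str(g))
            )[:top_n]
        else:
            pos = sorted(loadings.index, key=lambda g: (-vals[g], str(g)))
            neg = sorted(loadings.index, key=lambda g: (vals[g], str(g)))
            chosen = pos[: top_n // 2] + neg[: top_n // 2]
        calls.extend(
            DELCall(
                gene_id=g, source="pc_loading", pc=int(pc),
                loading=float(vals[g]),
            )
            for g in chosen
        )
    return calls


def combine_dels(ttest_calls: list, pc_calls: list, mode: str = "union") -> DELSet:
    """Merge step-3 and step-4 evidence into one DEL set.

    ``union`` keeps every gene supported by either source; ``intersection``
    keeps genes supported by both, retaining all their calls.
    """
    if mode not in ("union", "intersection"):
        raise InvalidArgumentError(f"unknown combine mode {mode!r}")
    if mode == "union":
        return DELSet(list(ttest_calls) + list(pc_calls))
    t_genes = {c.gene_id for c in ttest_calls}
    p_genes = {c.gene_id for c in pc_calls}
    shared = t_genes & p_genes
    return DELSet([c for c in list(ttest_calls) + list(pc_calls) if c.gene_id in shared])


# ---------------------------------------------------------------------------
# final domains (K-means) and gene groups (BIC spherical K-means)
# ---------------------------------------------------------------------------

def final_domains(
    matrix: ExpressionMatrix,
    k_final: int,
    seed: int = 0,
    n_init: int = 50,
) -> DomainPartition:
    """K-means of samples on z-scored DEL-gene profiles (best of ``n_init``)."""
    matrix.require_scale("zscore")
    if k_final <= 0:
        raise InvalidArgumentError("k_final must be positive")
    if k_final > matrix.n_samples:
        raise InvalidArgumentError(
            f"k_final={k_final} exceeds {matrix.n_samples} samples"
        )
    X = matrix.values.to_numpy(dtype=float).T
    km = KMeans(n_clusters=k_final, n_init=n_init, random_state=seed)
    flat = km.fit_predict(X)
    remap: dict = {}
    labels = []
    for c in flat:
        if c not in remap:
            remap[c] = f"F{len(remap) + 1}"
        labels.append(remap[c])
    return DomainPartition(
        pd.Series(labels, index=matrix.sample_ids, name="domain"), kind="final"
    )


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidArgumentError("zero-norm gene row cannot be unit-scaled")
    return X / norms


def _plusplus_init(Xu: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style farthest-point seeding under cosine distance."""
    n = Xu.shape[0]
    centroids = [Xu[rng.integers(n)]]
    for _ in range(1, K):
        sim = Xu @ np.asarray(centroids).T
        d2 = np.maximum(2.0 - 2.0 * sim.max(axis=1), 0.0) ** 2
        total = d2.sum()
        if total <= 0:
            centroids.append(Xu[rng.integers(n)])
            continue
        centroids.append(Xu[rng.choice(n, p=d2 / total)])
    return np.asarray(centroids)


def _lloyd_spherical(
    Xu: np.ndarray,
    C: np.ndarray,
    max_iter: int = 300,
    trace: list | None = None,
):
    """Lloyd iterations for spherical K-means; returns (labels, C, rss, ok)."""
    n, K = Xu.shape[0], C.shape[0]
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sim = Xu @ C.T
        new_labels = np.argmax(sim, axis=1)
        # repair empty clusters with the worst-fit points
        for k in range(K):
            if not np.any(new_labels == k):
                far = np.argsort(sim[np.arange(n), new_labels])
                for cand in far:
                    if np.sum(new_labels == new_labels[cand]) > 1:
                        new_labels[cand] = k
                        C[k] = Xu[cand]
                        break
                else:
                    return labels, C, np.inf, False
        rss = float(np.sum(2.0 - 2.0 * (Xu @ C.T)[np.arange(n), new_labels]))
        if trace is not None:
            trace.append(rss)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            mean = Xu[labels == k].sum(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                C[k] = mean / norm
    sim = Xu @ C.T
    rss = float(np.sum(2.0 - 2.0 * sim[np.arange(n), labels]))
    return labels, C, rss, True


def _refine_moves(Xu: np.ndarray, labels: np.ndarray, K: int, max_sweeps: int = 50):
    """Hartigan-style single-point relocation to escape Lloyd fixed points.

    For unit rows the objective obeys ``RSS = 2n - 2 * sum_c ||S_c||``
    with ``S_c`` the resultant vector of cluster c, so the exact gain of
    moving one point is computable in O(d).  Moves are applied greedily
    until no single relocation improves the objective.
    """
    labels = labels.copy()
    n = Xu.shape[0]
    sums = np.zeros((K, Xu.shape[1]))
    counts = np.zeros(K, dtype=int)
    for i, lab in enumerate(labels):
        sums[lab] += Xu[i]
        counts[lab] += 1
    for _ in range(max_sweeps * max(n, 10)):
        norms = np.linalg.norm(sums, axis=1)
        dots = Xu @ sums.T                                    # n x K
        # ||S_a - x_i|| for the current cluster of each point
        own = norms[labels] ** 2 - 2 * dots[np.arange(n), labels] + 1.0
        loss = norms[labels] - np.sqrt(np.maximum(own, 0.0))
        # ||S_b + x_i|| - ||S_b|| for every candidate target
        gain_to = np.sqrt(norms[None, :] ** 2 + 2 * dots + 1.0) - norms[None, :]
        gains = gain_to - loss[:, None]
        gains[np.arange(n), labels] = -np.inf
        gains[counts[labels] <= 1, :] = -np.inf  # never empty a cluster
        i, b = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[i, b] <= 1e-10:
            break
        a = labels[i]
        sums[a] -= Xu[i]
        sums[b] += Xu[i]
        counts[a] -= 1
        counts[b] += 1
        labels[i] = b
    norms = np.linalg.norm(sums, axis=1)
    C = sums / np.maximum(norms, 1e-300)[:, None]
    rss = float(2 * n - 2 * norms.sum())
    return labels, C, rss


def spherical_kmeans(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
):
    """Best-of-``n_init`` spherical K-means of the rows of ``X``.

    Rows are scaled to unit norm; assignment is by maximal cosine
    similarity and centroids are normalized member means.  Each restart
    runs Lloyd iterations to convergence followed by a Hartigan-style
    relocation refinement (Lloyd fixed points are not always local optima
    of the partition objective).  Returns ``(labels, centroids, rss)``;
    ``rss`` is the summed squared Euclidean distance of unit rows to their
    assigned centroid.
    """
    if K < 1 or K > X.shape[0]:
        raise InvalidArgumentError(f"K={K} infeasible for {X.shape[0]} rows")
    Xu = _unit_rows(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        C0 = _plusplus_init(Xu, K, rng)
        labels, C, rss, ok = _lloyd_spherical(Xu, C0.copy(), max_iter)
        if not ok:
            continue
        if K > 1:
            labels, C, rss = _refine_moves(Xu, labels, K)
        if best is None or rss < best[2] - 1e-12:
            best = (labels, C, rss)
    if best is None:
        raise InvalidArgumentError(f"K={K} produced persistent empty clusters")
    return best


def bic_spherical(rss: float, n: int, d: int, K: int) -> float:
    """Spherical-Gaussian BIC of a K-cluster fit: smaller is better.

    ``BIC(K) = n*d*ln(RSS/(n*d)) + (K*d + 1)*ln(n*d)`` with ``n`` genes,
    ``d`` samples, ``K*d`` free centroid parameters and one shared
    variance parameter.  The Gaussian likelihood is over the ``n*d``
    scalar residuals, so ``n*d`` is also the BIC sample-size term; a
    perfect fit (RSS = 0) maps to ``-inf``.
    """
    if rss <= 0:
        return -np.inf
    return n * d * np.log(rss / (n * d)) + (K * d + 1) * np.log(n * d)


def bic_skmeans(
    matrix: ExpressionMatrix,
    k_range=range(2, 13),
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
    min_group_size: int | None = None,
    min_group_coherence: float = 0.6,
) -> GeneGroupClustering:
    """Spherical K-means over genes with K selected by minimal BIC.

    Gene rows of the z-scored matrix are unit-normalized; for every K in
    ``k_range`` the best of ``n_init`` seeded restarts is kept and scored
    with :func:`bic_spherical`.  Ties in the BIC curve resolve to the
    smaller K.  K values that cannot sustain non-empty clusters are marked
    infeasible (BIC = +inf).

    Because a likelihood-based BIC rewards sweeping stray noise genes into
    a cluster of their own, K values whose best fit contains a group that
    is not a credible expression program are excluded from selection: a
    group smaller than ``min_group_size`` (default ``max(5, round(0.02
    n))``) or one whose members' mean cosine to their centroid falls below
    ``min_group_coherence``.  A bundle of isotropic noise genes aligns
    with its own resultant only weakly (~1/sqrt(m), and at most ~0.5 even
    when the optimizer cherry-picks the best-aligned subset of a larger
    noise pool), while a shared expression program keeps its members
    tightly around the centroid (0.8+ in z-score space); the default floor
    of 0.6 sits between those regimes, and the two guards together cover
    small and large noise bundles.
    Pass ``min_group_size=1, min_group_coherence=0`` for the unconstrained
    argmin.  The full BIC curve is reported for every K either way; when
    every K violates the guards the unconstrained argmin is used with a
    warning.
    """
    matrix.require_scale("zscore")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > matrix.n_genes:
        raise InvalidArgumentError(
            f"k_range must lie within [1, {matrix.n_genes}]"
        )
    X = matrix.values.to_numpy(dtype=float)
    n, d = X.shape
    if min_group_size is None:
        min_group_size = max(5, round(0.02 * n))
    bic_curve: dict = {}
    fits: dict = {}
    for K in ks:
        try:
            labels, C, rss = spherical_kmeans(
                X, K, seed=np.random.SeedSequence([seed, K]).generate_state(1)[0],
                n_init=n_init, max_iter=max_iter,
            )
        except InvalidArgumentError:
            bic_curve[K] = np.inf
            continue
        bic_curve[K] = bic_spherical(rss, n, d, K)
        fits[K] = (labels, C)
    if not fits:
        raise InvalidArgumentError("no feasible K in k_range")
    Xu = _unit_rows(X)

    def _credible(k: int) -> bool:
        if k == 1:
            return True
        labels, C = fits[k]
        if np.bincount(labels, minlength=k).min() < min_group_size:
            return False
        cos = (Xu * C[labels]).sum(axis=1)
        mean_cos = np.array([cos[labels == g].mean() for g in range(k)])
        return bool((mean_cos >= min_group_coherence).all())

    candidates = [k for k in fits if _credible(k)]
    if not candidates:
        logger.warning(
            "every K violates the group credibility guards (size >= %d, "
            "coherence >= %.2f); selecting unconstrained",
            min_group_size, min_group_coherence,
        )
        candidates = list(fits)
    K_sel = min(candidates, key=lambda k: (bic_curve[k], k))
    labels, C = fits[K_sel]
    remap: dict = {}
    named = []
    for c in labels:
        if c not in remap:
            remap[c] = f"G{len(remap) + 1}"
        named.append(remap[c])
    order = [c for c, _ in sorted(remap.items(), key=lambda kv: kv[1])]
    centroids = pd.DataFrame(
        C[order], index=[remap[c] for c in order], columns=matrix.sample_ids
    )
    return GeneGroupClustering(
        assignment=pd.Series(named, index=matrix.gene_ids, name="group"),
        K_selected=K_sel,
        bic_curve=bic_curve,
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# end-to-end stage pipeline
# ---------------------------------------------------------------------------

@dataclass
class SpatialDELResult:
    hvg: list
    preliminary: DomainPartition
    ttest_calls: list
    jackstraw_result: JackstrawResult | None
    pc_calls: list
    del_set: DELSet
    final: DomainPartition
    groups: GeneGroupClustering
    variance_explained: pd.Series = field(default_factory=pd.Series)


def run_spatial_pipeline(
    matrix: ExpressionMatrix,
    k_prelim: int | None = None,
    k_final: int | None = None,
    hvg_n: int = 1000,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    top_n: int | None = None,
    n_pcs: int | None = None,
    jackstraw_B: int = 100,
    jackstraw_s: float = 0.1,
    combine: str = "intersection",
    k_range=range(2, 13),
    seed: int = 0,
    n_init: int = 50,
) -> SpatialDELResult:
    """Full DEL pipeline from a linear-scale expression matrix.

    ``k_prelim`` defaults to the number of distinct zipcodes in the sample
    metadata; ``k_final`` defaults to ``k_prelim``.  The step-3 and step-4
    call lists are combined by intersection by default (step 4 read as a
    refinement of step 3; pass ``combine="union"`` for the permissive rule).
    PCs for the loading step are the jackstraw-significant ones, falling
    back to PC1-4 when none reach significance.  ``top_n`` defaults to 30%
    of the gene panel (capped at 300): a fixed "top 300" is meaningful for
    a ~1000-gene HVG panel but covers everything on a smaller one, and the
    loading filter would then do no filtering at all.
    """
    matrix.require_scale("linear")
    logm = matrix.to_log2(1.0)
    hvg = select_hvg(logm, min(hvg_n, matrix.n_genes))
    z = zscore_rows(logm.subset_genes(hvg))

    if k_prelim is None:
        if "zipcode" not in matrix.sample_meta.columns:
            raise InvalidArgumentError(
                "k_prelim not given and no zipcode metadata to derive it from"
            )
        k_prelim = int(matrix.sample_meta["zipcode"].nunique())
    prelim = preliminary_domains(z, k_prelim)

    ttest_calls = pairwise_del(
        matrix.subset_genes(z.gene_ids), prelim,
        p_thresh=p_thresh, fc_thresh=fc_thresh,
    )

    loadings, _, var_explained = run_pca(z)
    max_pcs = min(z.n_genes, z.n_samples) - 1
    n_pcs_eff = min(n_pcs if n_pcs is not None else 10, max_pcs)
    js = jackstraw(
        z, n_pcs_eff, s=jackstraw_s, B=jackstraw_B, seed=seed,
    )
    pcs = js.significant_pcs or list(range(1, min(4, max_pcs) + 1))
    eff_top = top_n if top_n is not None else min(300, round(0.3 * z.n_genes))
    eff_top = min(eff_top, z.n_genes)
    eff_top -= eff_top % 2
    pc_calls = pc_loading_genes(loadings, pcs, top_n=eff_top)

    del_set = combine_dels(ttest_calls, pc_calls, mode=combine)
    del_genes = [g for g in z.gene_ids if g in set(del_set.genes)]
    if not del_genes:
        raise EmptyOutputError("no DELs identified; cannot cluster")
    zdel = z.subset_genes(del_genes)

    final = final_domains(zdel, k_final or k_prelim, seed=seed, n_init=n_init)
    groups = bic_skmeans(zdel, k_range=k_range, seed=seed, n_init=n_init)
    return SpatialDELResult(
        hvg=hvg,
        preliminary=prelim,
        ttest_calls=ttest_calls,
        jackstraw_result=js,
        pc_calls=pc_calls,
        del_set=del_set,
        final=final,
        groups=groups,
        variance_explained=var_explained,
    )
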