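"""Weighted co-expression network stage: soft power, TOM, modules, traits.

The network is built the WGCNA way: a soft-thresholding power chosen by
the scale-free topology criterion turns the gene-gene correlation matrix
into an adjacency, the adjacency into a topological overlap matrix (TOM),
and average-linkage clustering of TOM dissimilarity into gene modules
(minimum size 30, similar modules merged on eigengene correlation).  Module
eigengenes are correlated against sample traits, and modules of a WT/GKO
differentiation course are sorted into the four temporal categories
(WT-Early, WT-Late, GKO-Early, GKO-constant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InvalidArgumentError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

CATEGORY_LABELS = ("WT-Early", "WT-Late", "GKO-Early", "GKO-constant")


@dataclass
class NetworkParams:
    """Soft-thresholding power and the scale-free fit that selected it."""

    beta: int
    r2: float
    r2_target: float = 0.8
    signed: bool = False

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise InvalidArgumentError("beta must be >= 1")


@dataclass
class TOMatrix:
    """Symmetric gene x gene topological overlap, entries in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("TOM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InvalidArgumentError("TOM must be symmetric")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class CoexpressionModule:
    module_id: str
    member_genes: list
    eigengene: pd.Series                 # per-sample, unit L2 norm
    trait_correlations: dict = field(default_factory=dict)  # trait -> (r, p)
    category: str = "unassigned"


# ---------------------------------------------------------------------------
# adjacency / scale-free fit / TOM
# ---------------------------------------------------------------------------

def _gene_correlation(matrix: ExpressionMatrix) -> tuple[np.ndarray, pd.Index]:
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "dropping %d constant gene row(s) before network construction",
            int((~keep).sum()),
        )
    vals = vals.loc[keep]
    if vals.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 non-constant genes")
    corr = np.corrcoef(vals.to_numpy(dtype=float))
    return np.clip(corr, -1.0, 1.0), vals.index


def _adjacency(corr: np.ndarray, beta: int, signed: bool) -> np.ndarray:
    a = ((1.0 + corr) / 2.0) ** beta if signed else np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Connectivities are pooled into ``n_bins`` logarithmic bins; the fit is
    the squared Pearson correlation of (log10 mean-k, log10 frequency).
    Returns ``(r2, slope)``; a non-negative slope or a degenerate binning
    yields ``r2 = 0`` because a scale-free network requires a *decreasing*
    log-log degree distribution.
    """
    k = connectivity[connectivity > 0]
    if len(k) < 2 or np.allclose(k.min(), k.max()):
        return 0.0, 0.0
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    total = len(k)
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / total))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    if res.slope >= 0:
        return 0.0, float(res.slope)
    return float(res.rvalue**2), float(res.slope)


def default_power(n_samples: int, signed: bool = False) -> int:
    """Conventional soft power by sample count (doubled for signed nets)."""
    if n_samples < 20:
        beta = 9
    elif n_samples < 30:
        beta = 8
    elif n_samples < 40:
        beta = 7
    else:
        beta = 6
    return 2 * beta if signed else beta


def pick_soft_power(
    matrix: ExpressionMatrix,
    powers=range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
    n_bins: int = 10,
) -> NetworkParams:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    When no power reaches the target, the power of maximal fit is used
    (with a warning); when the whole scan is uninformative (best R^2 below
    0.3, as happens for strongly modular networks whose degree
    distribution is lumpy rather than scale-free) the conventional
    sample-count default of :func:`default_power` is used instead.
    """
    if matrix.n_samples < 4:
        raise InvalidArgumentError("need at least 4 samples for the power scan")
    corr, _ = _gene_correlation(matrix)
    fits = []
    for beta in powers:
        a = _adjacency(corr, int(beta), signed)
        r2, _ = scale_free_fit(a.sum(axis=1), n_bins=n_bins)
        fits.append((int(beta), r2))
        if r2 >= r2_target:
            return NetworkParams(int(beta), r2, r2_target, signed)
    best_beta, best_r2 = max(fits, key=lambda t: (t[1], -t[0]))
    if best_r2 < 0.3:
        best_beta = default_power(matrix.n_samples, signed)
        logger.warning(
            "scale-free scan uninformative (best R^2=%.3f); using the "
            "sample-count default beta=%d", best_r2, best_beta,
        )
    else:
        logger.warning(
            "no power reached scale-free R^2 >= %.2f; using beta=%d (R^2=%.3f)",
            r2_target, best_beta, best_r2,
        )
    return NetworkParams(best_beta, best_r2, r2_target, signed)


def compute_tom(matrix: ExpressionMatrix, params: NetworkParams) -> TOMatrix:
    """Topological overlap of the soft-thresholded correlation network.

    ``TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with unit diagonal; entries lie in [0, 1].
    """
    corr, genes = _gene_correlation(matrix)
    a = _adjacency(corr, params.beta, params.signed)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(pd.DataFrame(tom, index=genes, columns=genes))


# ---------------------------------------------------------------------------
# module detection, eigengenes, traits, categories
# ---------------------------------------------------------------------------

def module_eigengene(matrix: ExpressionMatrix, member_genes) -> pd.Series:
    """First-PC summary profile of a module across samples (unit norm).

    Computed from the z-scored member submatrix; the sign is fixed so the
    eigengene correlates non-negatively with the average member profile.
    Falls back to the normalized average profile (with a warning) when the
    submatrix is singular or fully constant.
    """
    members = list(member_genes)
    if not members:
        raise InvalidArgumentError("module has no member genes")
    sub = matrix.values.loc[members]
    sd = sub.std(axis=1, ddof=1)
    live = sd > 0
    if not live.any():
        logger.warning("module submatrix is constant; using flat profile")
        flat = np.ones(matrix.n_samples) / np.sqrt(matrix.n_samples)
        return pd.Series(flat, index=matrix.sample_ids)
    z = sub.loc[live].sub(sub.loc[live].mean(axis=1), axis=0).div(sd[live], axis=0)
    zv = z.to_numpy(dtype=float)
    try:
        _, _, vt = np.linalg.svd(zv, full_matrices=False)
        e = vt[0]
    except np.linalg.LinAlgError:
        logger.warning("SVD failed for module; falling back to average profile")
        e = zv.mean(axis=0)
        norm = np.linalg.norm(e)
        e = e / norm if norm > 0 else np.ones_like(e) / np.sqrt(len(e))
    mean_profile = zv.mean(axis=0)
    if np.std(mean_profile) > 0 and np.std(e) > 0:
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
    return pd.Series(e, index=matrix.sample_ids)


def detect_modules(
    matrix: ExpressionMatrix,
    tom: TOMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    cut_height_frac: float = 0.8,
) -> list:
    """Gene modules from average-linkage clustering of 1 - TOM.

    A simplified dynamic cut: the dendrogram is cut at
    ``cut_height_frac * max merge height`` and only branches of at least
    ``min_size`` genes become modules (the rest stay unassigned, the
    "grey" genes of WGCNA).  Merges between unrelated branches concentrate
    near the top of a TOM dendrogram, so the cut sits well below the
    ceiling (default 0.8) and the size floor discards the fragments this
    leaves behind.  Modules whose eigengenes are closer than ``merge_cut``
    in correlation dissimilarity are then merged iteratively.
    """
    genes = list(tom.gene_ids)
    if len(genes) < 2:
        raise InvalidArgumentError("need at least 2 genes")
    dissim = 1.0 - tom.values.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    max_h = Z[:, 2].max()
    flat = hierarchy.fcluster(Z, t=cut_height_frac * max_h, criterion="distance")
    clusters: dict = {}
    for g, c in zip(genes, flat):
        clusters.setdefault(c, []).append(g)
    member_lists = [m for m in clusters.values() if len(m) >= min_size]
    if not member_lists:
        logger.warning(
            "no dendrogram branch reached min_size=%d; zero modules", min_size
        )
        return []

    # iterative eigengene merge
    member_lists = sorted(member_lists, key=lambda m: (-len(m), str(m[0])))
    eigs = [module_eigengene(matrix, m) for m in member_lists]
    while len(member_lists) > 1:
        best = None
        for i in range(len(member_lists)):
            for j in range(i + 1, len(member_lists)):
                r = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if np.isnan(r):
                    continue
                if best is None or r > best[0]:
                    best = (r, i, j)
        if best is None or 1.0 - best[0] >= merge_cut:
            break
        _, i, j = best
        merged = member_lists[i] + member_lists[j]
        member_lists = [
            m for k, m in enumerate(member_lists) if k not in (i, j)
        ] + [merged]
        member_lists = sorted(member_lists, key=lambda m: (-len(m), str(m[0])))
        eigs = [module_eigengene(matrix, m) for m in member_lists]

    return [
        CoexpressionModule(
            module_id=f"M{i + 1}",
            member_genes=sorted(m),
            eigengene=e,
        )
        for i, (m, e) in enumerate(zip(member_lists, eigs))
    ]


def module_trait(modules: list, traits: dict) -> list:
    """Pearson r and two-sided p of each eigengene against each trait.

    Constant traits are reported as missing ``(nan, nan)``.  The p-value is
    the Student-t approximation ``2 P(T_{n-2} > |r| sqrt((n-2)/(1-r^2)))``.
    """
    for module in modules:
        e = module.eigengene
        for name, vec in traits.items():
            v = pd.Series(vec).reindex(e.index).astype(float)
            if v.isna().any():
                raise InvalidArgumentError(
                    f"trait {name!r} missing values for some samples"
                )
            if v.nunique() <= 1 or np.std(e) == 0:
                logger.warning("trait %r is constant; correlation undefined", name)
                module.trait_correlations[name] = (np.nan, np.nan)
                continue
            r, p = stats.pearsonr(e.to_numpy(), v.to_numpy())
            module.trait_correlations[name] = (float(r), float(p))
    return modules


def _pearson_rp(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0 or len(x) < 3:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def categorize_modules(
    modules: list,
    day: pd.Series,
    genotype: pd.Series,
    r_min: float = 0.3,
    alpha: float = 0.05,
    knockout_label: str = "GKO",
) -> list:
    """Assign temporal categories from eigengene-trait correlations.

    A module is WT-flavored when its eigengene correlates below ``-r_min``
    (significantly at level ``alpha``) with the knockout indicator and
    GKO-flavored above ``+r_min``.  Within the flavored genotype's samples,
    a significant correlation with day below ``-r_min`` means Early, above
    ``+r_min`` Late, and anything weaker or non-significant constant — a
    trend that does not reach significance over the genotype's samples is
    no trend.  Composite labels outside the four canonical categories stay
    unassigned.
    """
    if day is None or genotype is None:
        raise InvalidArgumentError("day and genotype traits are required")
    for module in modules:
        e = module.eigengene
        d = pd.Series(day).reindex(e.index).astype(float)
        g = pd.Series(genotype).reindex(e.index)
        if d.isna().any() or g.isna().any():
            raise InvalidArgumentError("day/genotype metadata incomplete")
        ko = (g == knockout_label).astype(float).to_numpy()
        r_g, p_g = _pearson_rp(e.to_numpy(), ko)
        if np.isnan(r_g) or p_g >= alpha:
            module.category = "unassigned"
            continue
        if r_g < -r_min:
            flavor, mask = "WT", ko == 0
        elif r_g > r_min:
            flavor, mask = knockout_label, ko == 1
        else:
            module.category = "unassigned"
            continue
        r_d, p_d = _pearson_rp(e.to_numpy()[mask], d.to_numpy()[mask])
        if np.isnan(r_d):
            tempo = "constant"
        elif r_d < -r_min and p_d < alpha:
            tempo = "Early"
        elif r_d > r_min and p_d < alpha:
            tempo = "Late"
        else:
            tempo = "constant"
        label = f"{flavor}-{tempo}"
        module.category = label if label in CATEGORY_LABELS else "unassigned"
    return modules


@dataclass
class CoexpressionResult:
    params: NetworkParams
    modules: list
    tom: TOMatrix | None = None


def run_coexpression_pipeline(
    matrix: ExpressionMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    r2_target: float = 0.8,
    signed: bool = False,
    r_min: float = 0.3,
    keep_tom: bool = False,
) -> CoexpressionResult:
    """Network construction through category assignment in one call.

    Expects a linear-scale matrix with ``day`` and ``genotype`` sample
    metadata; works on ``log2(x + 1)`` values internally.
    """
    for col in ("day", "genotype"):
        if col not in matrix.sample_meta.columns:
            raise InvalidArgumentError(f"sample metadata lacks {col!r}")
    logm = matrix.to_log2(1.0) if matrix.scale_tag == "linear" else matrix
    params = pick_soft_power(logm, r2_target=r2_target, signed=signed)
    tom = compute_tom(logm, params)
    sub = logm.subset_genes(tom.gene_ids)
    modules = detect_modules(sub, tom, min_size=min_size, merge_cut=merge_cut)
    traits = {
        "day": matrix.sample_meta["day"],
        "genotype_ko": (matrix.sample_meta["genotype"] == "GKO").astype(float),
    }
    modules = module_trait(modules, traits)
    modules = categorize_modules(
        modules,
        day=matrix.sample_meta["day"],
        genotype=matrix.sample_meta["genotype"],
        r_min=r_min,
    )
    return CoexpressionResult(params, modules, tom if keep_tom else None)
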