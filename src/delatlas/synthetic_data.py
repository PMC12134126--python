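"""Synthetic gastrula, time-course and genomic-interval generators.

Every downstream stage of the package is exercised against data with known
ground truth produced here:

* :func:`generate_embryo` emits a corn-plot-structured spatial expression
  matrix for a stage preset (E6.5 / E7.0 / E7.5) with planted
  domain-specific gene groups on a log-normal noise model;
* :func:`generate_timecourse` emits WT/GKO embryoid-body differentiation
  time courses with four planted temporal co-expression programs;
* :func:`generate_fixtures` emits gene models, per-replicate interaction
  intervals around a declared viewpoint, a DEG table and histone-mark peak
  sets with planted nearest-gene / overlap / classification truth.

All generators are pure functions of their configuration (including the
seed): the same preset always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .expression import ExpressionMatrix
from .intervals import GeneModel, GenomicInterval
from .spatial_del import DomainPartition, GeneGroupClustering

#: zipcode labels of the corn-plot legend (germ-layer sampling positions)
ZIPCODES = (
    "End", "Mes", "Ect", "PS",
    "A", "P", "L1", "R1", "L2", "R2",
    "EA", "EP", "MA", "MP",
)

#: germ-layer domain of each zipcode (spatial ground truth)
ZIPCODE_DOMAIN = {
    "End": "End", "EA": "End", "EP": "End",
    "Mes": "Mes", "MA": "Mes", "MP": "Mes",
    "Ect": "Ect", "A": "Ect", "P": "Ect",
    "L1": "Ect", "R1": "Ect", "L2": "Ect", "R2": "Ect",
    "PS": "PS",
}


# ---------------------------------------------------------------------------
# spatial embryo generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """A planted domain-specific gene group.

    ``on_zipcodes`` are the positions where the group is elevated by
    ``effect_log2`` above baseline.  ``gradient`` (0 <= g < 1) linearly
    attenuates the effect across section_index: sections are ordered
    posterior (streak end, full effect) to anterior (effect scaled by
    ``1 - gradient``), modelling groups that are strongest in the primitive
    streak and decay into mesoderm.
    """

    group_id: str
    n_genes: int
    on_zipcodes: tuple
    effect_log2: float
    gradient: float = 0.0

    def validate(self, zipcodes: set) -> None:
        if self.n_genes < 1:
            raise InvalidConfigurationError(
                f"group {self.group_id}: n_genes must be >= 1"
            )
        if self.effect_log2 <= 0:
            raise InvalidConfigurationError(
                f"group {self.group_id}: effect_log2 must be > 0"
            )
        if not 0 <= self.gradient < 1:
            raise InvalidConfigurationError(
                f"group {self.group_id}: gradient must lie in [0, 1)"
            )
        unknown = set(self.on_zipcodes) - zipcodes
        if unknown:
            raise InvalidConfigurationError(
                f"group {self.group_id}: zipcodes {sorted(unknown)} not in layout"
            )


@dataclass(frozen=True)
class EmbryoPreset:
    """Stage-specific corn-plot geometry and planted gene-group structure."""

    stage: str
    zipcode_layout: tuple            # ordered (section_index, zipcode) pairs
    planted_groups: tuple            # GroupSpec, pairwise-disjoint gene sets
    n_background_genes: int = 300
    noise_sigma: float = 0.5         # sd of Gaussian noise on log2 scale
    baseline_log2: float = 3.0
    seed: int = 0
    n_domains: int | None = None     # true germ-layer domain count

    def validate(self) -> None:
        if not self.zipcode_layout:
            raise InvalidConfigurationError("zipcode_layout is empty")
        if self.noise_sigma <= 0:
            raise InvalidConfigurationError("noise_sigma must be > 0")
        zips = {z for _, z in self.zipcode_layout}
        bad = zips - set(ZIPCODES)
        if bad:
            raise InvalidConfigurationError(f"unknown zipcodes: {sorted(bad)}")
        total = 0
        for g in self.planted_groups:
            g.validate(zips)
            total += g.n_genes
        if total + self.n_background_genes == 0:
            raise InvalidConfigurationError("preset has zero genes")

    @property
    def sections(self) -> tuple:
        return tuple(sorted({s for s, _ in self.zipcode_layout}))


def _grid_layout(sections, zipcodes) -> tuple:
    return tuple((s, z) for s in sections for z in zipcodes)


def preset_e65(**overrides) -> EmbryoPreset:
    """Early-streak stage: 3 planted groups (2 endoderm, 1 epiblast)."""
    base = EmbryoPreset(
        stage="E6.5",
        zipcode_layout=_grid_layout(range(1, 6), ("EA", "EP", "A", "P")),
        planted_groups=(
            GroupSpec("G1", 40, ("EA", "EP"), 3.0),
            GroupSpec("G2", 40, ("EP",), 2.5),
            GroupSpec("G3", 40, ("A", "P"), 3.0),
        ),
        n_domains=2,
    )
    return replace(base, **overrides)


def preset_e70(**overrides) -> EmbryoPreset:
    """Mid-streak stage: E6.5 groups carried forward + 2 mesoderm groups.

    No streak-specific group is planted yet (that signature emerges at
    E7.5), so the layout carries no PS zipcode: every spatial domain is
    defined by an expression signature and therefore recoverable.
    """
    base = EmbryoPreset(
        stage="E7.0",
        zipcode_layout=_grid_layout(
            range(1, 6), ("EA", "EP", "MA", "MP", "A", "P")
        ),
        planted_groups=(
            GroupSpec("G1", 40, ("EA", "EP"), 3.0),
            GroupSpec("G2", 40, ("EP",), 2.5),
            GroupSpec("G3", 40, ("A", "P"), 3.0),
            GroupSpec("G4", 40, ("MA", "MP"), 3.0),
            GroupSpec("G5", 40, ("MP",), 2.5),
        ),
        n_domains=3,
    )
    return replace(base, **overrides)


def preset_e75(**overrides) -> EmbryoPreset:
    """Late-streak stage: 6 planted groups including a primitive-streak
    group that decays into posterior mesoderm."""
    base = EmbryoPreset(
        stage="E7.5",
        zipcode_layout=_grid_layout(
            range(1, 7),
            ("EA", "EP", "MA", "MP", "A", "P", "L1", "R1", "L2", "R2", "PS"),
        ),
        planted_groups=(
            GroupSpec("G1", 40, ("EA", "EP"), 3.0),
            GroupSpec("G2", 40, ("EP",), 2.5),
            GroupSpec("G3", 40, ("A", "P", "L1", "R1", "L2", "R2"), 3.0),
            GroupSpec("G4", 40, ("MA", "MP"), 3.0),
            GroupSpec("G5", 40, ("MP",), 2.5),
            GroupSpec("G6", 40, ("PS", "MP"), 3.0, gradient=0.4),
        ),
        n_domains=4,
    )
    return replace(base, **overrides)


STAGE_PRESETS = {"E6.5": preset_e65, "E7.0": preset_e70, "E7.5": preset_e75}


def gradient_multiplier(preset: EmbryoPreset, group: GroupSpec, section: int) -> float:
    """Linear decay of a group's effect across the section axis."""
    if group.gradient == 0:
        return 1.0
    secs = preset.sections
    if len(secs) == 1:
        return 1.0
    frac = (section - secs[0]) / (secs[-1] - secs[0])
    return max(0.0, 1.0 - group.gradient * frac)


def expected_log2(preset: EmbryoPreset) -> pd.DataFrame:
    """Noise-free log2 expression implied by a preset (planted genes only
    carry structure; background rows sit at baseline)."""
    preset.validate()
    sample_ids = [
        f"{preset.stage}_S{s}_{z}" for s, z in preset.zipcode_layout
    ]
    gene_ids, rows = [], []
    for g in preset.planted_groups:
        profile = np.array(
            [
                preset.baseline_log2
                + (
                    g.effect_log2 * gradient_multiplier(preset, g, s)
                    if z in g.on_zipcodes
                    else 0.0
                )
                for s, z in preset.zipcode_layout
            ]
        )
        for i in range(g.n_genes):
            gene_ids.append(f"{g.group_id}_{i:03d}")
            rows.append(profile)
    for i in range(preset.n_background_genes):
        gene_ids.append(f"BG_{i:04d}")
        rows.append(np.full(len(sample_ids), preset.baseline_log2))
    if len(set(gene_ids)) != len(gene_ids):
        raise InvalidConfigurationError("planted group gene sets overlap")
    return pd.DataFrame(rows, index=gene_ids, columns=sample_ids)


def generate_embryo(preset: EmbryoPreset):
    """Simulate a corn-plot spatial expression matrix from a stage preset.

    Returns ``(matrix, true_partition, true_groups)``: a linear-scale
    (FPKM-like) :class:`ExpressionMatrix` with zipcode metadata, the
    germ-layer domain truth for every sample, and the planted gene-group
    truth (background genes are left out of the group assignment).
    """
    mean_log2 = expected_log2(preset)
    rng = np.random.default_rng(preset.seed)
    noisy = mean_log2 + rng.normal(
        0.0, preset.noise_sigma, size=mean_log2.shape
    )
    values = np.exp2(noisy)
    meta = pd.DataFrame(
        {
            "stage": preset.stage,
            "section_index": [s for s, _ in preset.zipcode_layout],
            "zipcode": [z for _, z in preset.zipcode_layout],
        },
        index=mean_log2.columns,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=mean_log2.index, columns=mean_log2.columns),
        scale_tag="linear",
        sample_meta=meta,
    )
    domains = pd.Series(
        [ZIPCODE_DOMAIN[z] for _, z in preset.zipcode_layout],
        index=mean_log2.columns,
        name="domain",
    )
    true_partition = DomainPartition(domains, kind="true")
    assignment = pd.Series(
        {
            f"{g.group_id}_{i:03d}": g.group_id
            for g in preset.planted_groups
            for i in range(g.n_genes)
        },
        name="group",
    )
    true_groups = GeneGroupClustering(
        assignment=assignment,
        K_selected=len(preset.planted_groups),
        bic_curve={},
    )
    return matrix, true_partition, true_groups


# ---------------------------------------------------------------------------
# WT/GKO differentiation time-course generator
# ---------------------------------------------------------------------------

PROGRAM_LABELS = ("WT-Early", "WT-Late", "GKO-Early", "GKO-constant")


@dataclass(frozen=True)
class ProgramSpec:
    """A planted temporal co-expression program restricted to one genotype."""

    label: str
    n_genes: int
    genotype: str          # "WT" or "GKO"
    shape: str             # "early", "late" or "constant"
    amplitude_log2: float = 3.0

    def profile(self, days: np.ndarray) -> np.ndarray:
        t = (days - days.min()) / max(days.max() - days.min(), 1)
        if self.shape == "early":
            return 1.0 - t
        if self.shape == "late":
            return t
        if self.shape == "constant":
            return np.ones_like(t)
        raise InvalidConfigurationError(f"unknown program shape {self.shape!r}")


@dataclass(frozen=True)
class TimecoursePreset:
    """WT/GKO embryoid-body differentiation course with planted programs."""

    genotypes: tuple = ("WT", "GKO")
    days: tuple = tuple(range(8))
    planted_programs: tuple = (
        ProgramSpec("WT-Early", 40, "WT", "early"),
        ProgramSpec("WT-Late", 40, "WT", "late"),
        ProgramSpec("GKO-Early", 40, "GKO", "early"),
        ProgramSpec("GKO-constant", 40, "GKO", "constant"),
    )
    n_background_genes: int = 80
    n_replicates: int = 2
    noise_sigma: float = 0.4
    latent_sigma: float = 0.3       # shared per-program per-sample wiggle
    baseline_log2: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.days) < 2:
            raise InvalidConfigurationError("need at least 2 time points")
        if self.noise_sigma <= 0:
            raise InvalidConfigurationError("noise_sigma must be > 0")
        labels = [p.label for p in self.planted_programs]
        if len(set(labels)) != len(labels):
            raise InvalidConfigurationError("duplicate program labels")
        for p in self.planted_programs:
            if p.genotype not in self.genotypes:
                raise InvalidConfigurationError(
                    f"program {p.label}: genotype {p.genotype!r} not in preset"
                )
            if p.n_genes < 1:
                raise InvalidConfigurationError(
                    f"program {p.label}: n_genes must be >= 1"
                )


def generate_timecourse(preset: TimecoursePreset):
    """Simulate the WT/GKO time course.

    Returns ``(matrix, true_programs)``: a linear-scale matrix with ``day``
    and ``genotype`` metadata, and a gene -> program-label Series for the
    planted genes.  Program genes share a latent temporal profile (plus a
    per-sample program-level wiggle of sd ``latent_sigma``) with iid
    gene-level noise on top, so they co-vary within the program.
    """
    preset.validate()
    rng = np.random.default_rng(preset.seed)
    days = np.asarray(preset.days, dtype=float)
    samples = [
        (gt, d, r)
        for gt in preset.genotypes
        for d in preset.days
        for r in range(1, preset.n_replicates + 1)
    ]
    sample_ids = [f"{gt}_D{d}_R{r}" for gt, d, r in samples]
    n_s = len(samples)

    gene_ids, rows = [], []
    truth = {}
    for p in preset.planted_programs:
        prof_by_day = dict(zip(preset.days, p.profile(days)))
        base_profile = np.array(
            [
                p.amplitude_log2 * prof_by_day[d] if gt == p.genotype else 0.0
                for gt, d, r in samples
            ]
        )
        latent = rng.normal(0.0, preset.latent_sigma, size=n_s)
        profile = preset.baseline_log2 + base_profile + latent
        for i in range(p.n_genes):
            gid = f"{p.label}_{i:03d}"
            gene_ids.append(gid)
            truth[gid] = p.label
            rows.append(profile)
    for i in range(preset.n_background_genes):
        gene_ids.append(f"BG_{i:04d}")
        rows.append(np.full(n_s, preset.baseline_log2))
    mean_log2 = np.asarray(rows)
    noisy = mean_log2 + rng.normal(0.0, preset.noise_sigma, size=mean_log2.shape)
    meta = pd.DataFrame(
        {
            "day": [d for _, d, _ in samples],
            "genotype": [gt for gt, _, _ in samples],
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(noisy), index=gene_ids, columns=sample_ids),
        scale_tag="linear",
        sample_meta=meta,
    )
    return matrix, pd.Series(truth, name="program")


# ---------------------------------------------------------------------------
# genomic fixture generator (4C screen + histone-mark classification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Configuration of the interval/DEG/peak fixture bundle.

    Defaults mirror the screen's study conditions: 1919 interaction targets
    of which 601 fall on a gene-free chromosome (leaving 1318 with an
    assignable nearest gene), and 21 up- / 18 down-regulated significant
    DEGs among the assigned genes.
    """

    genome: tuple = (
        ("chr7", 20_000_000),   # viewpoint chromosome
        ("chr2", 20_000_000),
        ("chr1", 20_000_000),
        ("chr3", 20_000_000),
        ("chrUn", 20_000_000),  # gene-free: intervals here stay unassigned
    )
    genes_per_chrom: tuple = (("chr7", 400), ("chr2", 400), ("chr1", 300), ("chr3", 300))
    viewpoint: tuple = ("chr7", 3_000_000, 3_002_000)
    n_assigned_targets: int = 1318
    n_unassignable_targets: int = 601
    n_extra_per_replicate: int = 40
    n_replicates: int = 3
    n_deg_up: int = 21
    n_deg_down: int = 18
    n_deg_null: int = 150          # target genes without significant change
    n_deg_offtarget: int = 40      # significant DEGs that are not targets
    gene_span: int = 5_000
    gene_spacing: int = 15_000
    n_up_regions: int = 300
    k4_pos_fraction: float = 0.5
    region_width: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        chroms = {c for c, _ in self.genome}
        if self.viewpoint[0] not in chroms:
            raise InvalidConfigurationError("viewpoint chromosome not in genome")
        lengths = dict(self.genome)
        for chrom, n in self.genes_per_chrom:
            if chrom not in chroms:
                raise InvalidConfigurationError(f"gene chromosome {chrom} not in genome")
            needed = n * self.gene_spacing + self.gene_span
            if needed > lengths[chrom]:
                raise InvalidConfigurationError(
                    f"{n} genes do not fit on {chrom} ({needed} > {lengths[chrom]} bp)"
                )
        n_genes = sum(n for _, n in self.genes_per_chrom)
        if self.n_assigned_targets > n_genes:
            raise InvalidConfigurationError(
                "more assigned targets than genes available"
            )
        if not 0 <= self.k4_pos_fraction <= 1:
            raise InvalidConfigurationError("k4_pos_fraction must lie in [0, 1]")
        if self.gene_span < 5_000:
            raise InvalidConfigurationError(
                "gene_span must be >= 5000 bp to carry the two-exon model"
            )
        if self.gene_spacing < self.gene_span + 8_000:
            raise InvalidConfigurationError(
                "gene_spacing too small for unambiguous nearest-gene truth"
            )


@dataclass
class FixtureBundle:
    """In-memory fixture bundle with planted ground truth."""

    genes: list                      # GeneModel
    replicates: list                 # list of lists of GenomicInterval
    viewpoint: GenomicInterval
    deg_table: pd.DataFrame          # gene_id, log2FC, padj
    k27_up_regions: list             # GenomicInterval
    k4_peaks: list                   # GenomicInterval
    truth_targets: pd.DataFrame      # interval -> nearest gene/distance/class
    truth_candidates: pd.DataFrame   # planted screen outcome per DEG gene
    truth_regions: pd.DataFrame      # planted class + annotation per region


_ANNOTATION_CYCLE = ("promoter", "exon", "intron", "intergenic")


def _make_genes(spec: FixtureSpec, rng: np.random.Generator) -> list:
    genes = []
    gi = 0
    for chrom, n in spec.genes_per_chrom:
        for k in range(n):
            start = 100_000 + k * spec.gene_spacing + int(rng.integers(0, 2_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + spec.gene_span,
                    strand=strand,
                    exons=(
                        (start, start + 1_000),
                        (start + 4_000, start + spec.gene_span),
                    ),
                )
            )
            gi += 1
    return genes


def generate_fixtures(spec: FixtureSpec) -> FixtureBundle:
    """Build the interval/DEG/peak fixture bundle with planted truth.

    Target intervals are placed within 2 kb of their designated gene's TSS
    while genes are spaced ``gene_spacing`` bp apart, so the designated
    gene is provably the nearest TSS.  Replicate lists contain jittered
    copies of every consensus interval plus replicate-private decoys placed
    in disjoint zones, so an all-replicate consensus recovers exactly the
    planted targets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.genome)
    genes = _make_genes(spec, rng)
    viewpoint = GenomicInterval(*spec.viewpoint)

    # --- consensus interaction intervals around designated gene TSSs ------
    order = rng.permutation(len(genes))[: spec.n_assigned_targets]
    consensus: list = []
    truth_rows = []
    for idx in order:
        g = genes[int(idx)]
        width = int(rng.integers(400, 1_500))
        offset = int(rng.integers(-2_000, 2_001 - width))
        start = max(0, g.tss + offset)
        iv = GenomicInterval(g.chrom, start, start + width)
        consensus.append(iv)
        truth_rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "nearest_gene": g.gene_id,
                "distance": iv.distance_to(g.tss),
                "chromosomal_class": "intra" if iv.chrom == viewpoint.chrom else "inter",
            }
        )
    # unassignable targets on the gene-free chromosome
    free_chroms = sorted(
        set(lengths) - {c for c, _ in spec.genes_per_chrom}
    )
    for k in range(spec.n_unassignable_targets):
        chrom = free_chroms[k % len(free_chroms)] if free_chroms else spec.genome[0][0]
        start = 50_000 + k * 9_000
        if start + 1_000 > lengths[chrom]:
            raise InvalidConfigurationError(
                "unassignable targets do not fit on the gene-free chromosome"
            )
        iv = GenomicInterval(chrom, start, start + 800)
        consensus.append(iv)
        truth_rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "nearest_gene": None, "distance": None,
                "chromosomal_class": "intra" if iv.chrom == viewpoint.chrom else "inter",
            }
        )
    consensus.sort()
    truth_targets = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "nearest_gene", "distance", "chromosomal_class"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # --- replicates: jittered consensus + replicate-private decoys --------
    decoy_chrom = free_chroms[0] if free_chroms else spec.genome[0][0]
    zone_base = lengths[decoy_chrom] - 2_000_000
    replicates = []
    for r in range(spec.n_replicates):
        rep = []
        for iv in consensus:
            jitter = int(rng.integers(-150, 151)) if r > 0 else 0
            start = max(0, iv.start + jitter)
            rep.append(GenomicInterval(iv.chrom, start, start + (iv.end - iv.start)))
        for k in range(spec.n_extra_per_replicate):
            start = zone_base + r * 600_000 + k * 5_000
            rep.append(GenomicInterval(decoy_chrom, start, start + 700))
        rep.sort()
        replicates.append(rep)

    # --- DEG table with planted screen outcome ----------------------------
    assigned_ids = [row["nearest_gene"] for row in truth_rows if row["nearest_gene"]]
    assigned_ids = list(rng.permutation(assigned_ids))
    n_sig = spec.n_deg_up + spec.n_deg_down
    if n_sig + spec.n_deg_null > len(assigned_ids):
        raise InvalidConfigurationError("not enough assigned genes for the DEG plan")
    deg_rows = []
    cand_rows = []
    for i, gid in enumerate(assigned_ids[: spec.n_deg_up]):
        lfc = float(1.0 + 3.0 * rng.random())
        deg_rows.append({"gene_id": gid, "log2FC": lfc, "padj": float(10 ** -rng.uniform(3, 10))})
        cand_rows.append({"gene_id": gid, "direction": "up", "log2FC": lfc})
    for gid in assigned_ids[spec.n_deg_up: n_sig]:
        lfc = float(-(1.0 + 3.0 * rng.random()))
        deg_rows.append({"gene_id": gid, "log2FC": lfc, "padj": float(10 ** -rng.uniform(3, 10))})
        cand_rows.append({"gene_id": gid, "direction": "down", "log2FC": lfc})
    for gid in assigned_ids[n_sig: n_sig + spec.n_deg_null]:
        # either tiny effect or non-significant p: never passes the screen
        if rng.random() < 0.5:
            deg_rows.append({"gene_id": gid, "log2FC": float(rng.uniform(-0.4, 0.4)), "padj": float(rng.uniform(0, 0.04))})
        else:
            deg_rows.append({"gene_id": gid, "log2FC": float(rng.uniform(-3, 3)), "padj": float(rng.uniform(0.2, 1.0))})
    unassigned_genes = sorted(set(g.gene_id for g in genes) - set(assigned_ids))
    for gid in unassigned_genes[: spec.n_deg_offtarget]:
        deg_rows.append({"gene_id": gid, "log2FC": float(rng.uniform(1, 4)), "padj": 1e-6})
    deg_table = pd.DataFrame(deg_rows, columns=["gene_id", "log2FC", "padj"])
    truth_candidates = pd.DataFrame(cand_rows, columns=["gene_id", "direction", "log2FC"])

    # --- histone-mark regions with planted class and annotation -----------
    # one region per distinct gene so planted peaks cannot collide
    if spec.n_up_regions > len(genes):
        raise InvalidConfigurationError("n_up_regions exceeds the gene count")
    region_gene_idx = rng.choice(len(genes), size=spec.n_up_regions, replace=False)
    k27, k4, region_rows = [], [], []
    half = spec.region_width // 2
    for i, gidx in enumerate(region_gene_idx):
        anno = _ANNOTATION_CYCLE[i % 4]
        g = genes[int(gidx)]
        sign = 1 if g.strand == "+" else -1
        if anno == "promoter":
            mid = g.tss - sign * 800            # inside the (-2000, +500) window
        elif anno == "exon":
            mid = g.start + 700                 # inside the 5' exon block,
            #                                     outside any promoter window
        elif anno == "intron":
            mid = g.start + 2_500               # between the two exon blocks
        else:  # intergenic: clear of this gene, the next gene and promoters
            mid = g.end + 3_000
        start = max(0, mid - half)
        region = GenomicInterval(g.chrom, start, start + spec.region_width)
        planted_pos = bool(rng.random() < spec.k4_pos_fraction)
        if planted_pos:
            pk_start = max(0, mid - 300)
            k4.append(GenomicInterval(g.chrom, pk_start, pk_start + 600))
        k27.append(region)
        region_rows.append(
            {
                "chrom": region.chrom, "start": region.start, "end": region.end,
                "class_label": "H3K27ac_up_K4pos" if planted_pos else "H3K27ac_up_K4neg",
                "annotation": anno,
            }
        )
    k27_sorted = sorted(k27)
    truth_regions = (
        pd.DataFrame(region_rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    k4.sort()

    return FixtureBundle(
        genes=genes,
        replicates=replicates,
        viewpoint=viewpoint,
        deg_table=deg_table,
        k27_up_regions=k27_sorted,
        k4_peaks=k4,
        truth_targets=truth_targets,
        truth_candidates=truth_candidates,
        truth_regions=truth_regions,
    )
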