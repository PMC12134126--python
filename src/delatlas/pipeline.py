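"""Umbrella pipeline: configuration, stage orchestration, run manifest.

A run directory is reproducible from its manifest: the manifest records
the package version, the full parameter set (defaults included), the seed,
and SHA-256 checksums of every input and output file.  Nothing
time-dependent is written, so identical configurations produce
byte-identical run directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import run_coexpression_pipeline
from .cornplot import render_cornplot
from .epigenome_classes import annotate_regions, class_summary, split_by_h3k4me3
from .errors import InvalidConfigurationError
from .expression import ExpressionMatrix
from .intervals import GenomicInterval
from .io import (
    parse_viewpoint,
    read_bed,
    read_deg_table,
    read_expression,
    read_gff_genes,
    write_bed,
    write_expression,
    write_gff_genes,
    write_table,
)
from .multiomic_screen import degs_from_frame, run_screen
from .spatial_del import run_spatial_pipeline
from .synthetic_data import (
    STAGE_PRESETS,
    FixtureSpec,
    TimecoursePreset,
    generate_embryo,
    generate_fixtures,
    generate_timecourse,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "spatial_del", "coexpr", "screen", "epiclass")


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable).

    Unknown top-level or per-stage keys are rejected so typos cannot
    silently fall back to defaults.
    """

    stages: list = field(default_factory=lambda: list(KNOWN_STAGES))
    seed: int = 0
    outdir: str = "delatlas_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    spatial_del: dict = field(default_factory=dict)
    coexpr: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    epiclass: dict = field(default_factory=dict)

    _STAGE_KEYS = {
        "simulate": {"embryo_stages", "timecourse", "fixtures"},
        "spatial_del": {
            "expr", "meta", "k_prelim", "k_final", "hvg_n", "p_thresh",
            "fc_thresh", "top_n", "combine", "k_min", "k_max",
        },
        "coexpr": {"expr", "meta", "min_size", "merge_cut", "r2_target", "r_min", "signed"},
        "screen": {
            "replicates", "genes", "deg", "viewpoint", "min_support",
            "padj_thresh", "lfc_thresh",
        },
        "epiclass": {"up", "k4", "genes", "min_overlap_bp"},
    }

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise InvalidConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        for stage, allowed in self._STAGE_KEYS.items():
            params = getattr(self, stage)
            bad = set(params) - allowed
            if bad:
                raise InvalidConfigurationError(
                    f"unknown key(s) for stage {stage}: {sorted(bad)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        bad = set(raw) - known
        if bad:
            raise InvalidConfigurationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "outdir": str(self.outdir),
            "log_level": self.log_level,
            "simulate": dict(self.simulate),
            "spatial_del": dict(self.spatial_del),
            "coexpr": dict(self.coexpr),
            "screen": dict(self.screen),
            "epiclass": dict(self.epiclass),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    params = cfg.simulate
    stages = params.get("embryo_stages", ["E7.5"])
    for stage in stages:
        if stage not in STAGE_PRESETS:
            raise InvalidConfigurationError(f"unknown embryo stage {stage!r}")
        preset = STAGE_PRESETS[stage](seed=cfg.seed)
        matrix, partition, groups = generate_embryo(preset)
        tag = stage.replace(".", "")
        write_expression(
            matrix, outdir / f"expr_{tag}.tsv", outdir / f"meta_{tag}.tsv"
        )
        write_table(
            partition.assignment.rename("domain").rename_axis("sample_id").reset_index(),
            outdir / f"truth_domains_{tag}.tsv",
        )
        write_table(
            groups.assignment.rename("group").rename_axis("gene_id").reset_index(),
            outdir / f"truth_groups_{tag}.tsv",
        )
    if params.get("timecourse", True):
        matrix, truth = generate_timecourse(TimecoursePreset(seed=cfg.seed))
        write_expression(
            matrix, outdir / "expr_timecourse.tsv", outdir / "meta_timecourse.tsv"
        )
        write_table(
            truth.rename("program").rename_axis("gene_id").reset_index(),
            outdir / "truth_programs.tsv",
        )
    if params.get("fixtures", True):
        bundle = generate_fixtures(FixtureSpec(seed=cfg.seed))
        for i, rep in enumerate(bundle.replicates, start=1):
            write_bed(rep, outdir / f"4c_rep{i}.bed")
        write_gff_genes(bundle.genes, outdir / "genes.gff3")
        write_table(bundle.deg_table, outdir / "deg.tsv")
        write_bed(bundle.k27_up_regions, outdir / "k27ac_up.bed")
        write_bed(bundle.k4_peaks, outdir / "k4me3.bed")
        write_table(bundle.truth_targets, outdir / "truth_targets.tsv")
        write_table(bundle.truth_candidates, outdir / "truth_candidates.tsv")
        write_table(bundle.truth_regions, outdir / "truth_regions.tsv")
        vp = bundle.viewpoint
        (outdir / "viewpoint.txt").write_text(
            f"{vp.chrom}:{vp.start}-{vp.end}\n", encoding="utf-8"
        )


def _load_matrix(params: dict, outdir: Path, default_expr: str, default_meta: str) -> ExpressionMatrix:
    expr = Path(params.get("expr", outdir / default_expr))
    meta = Path(params.get("meta", outdir / default_meta))
    if not expr.exists():
        raise InvalidConfigurationError(
            f"missing upstream output {expr}; run the simulate stage or pass expr="
        )
    return read_expression(expr, meta)


def _stage_spatial_del(cfg: RunConfig, outdir: Path) -> None:
    params = cfg.spatial_del
    matrix = _load_matrix(params, outdir, "expr_E75.tsv", "meta_E75.tsv")
    result = run_spatial_pipeline(
        matrix,
        k_prelim=params.get("k_prelim"),
        k_final=params.get("k_final"),
        hvg_n=params.get("hvg_n", 1000),
        p_thresh=params.get("p_thresh", 0.05),
        fc_thresh=params.get("fc_thresh", 1.5),
        top_n=params.get("top_n", 300),
        combine=params.get("combine", "intersection"),
        k_range=range(params.get("k_min", 2), params.get("k_max", 12) + 1),
        seed=cfg.seed,
    )
    write_table(result.del_set.to_frame(), outdir / "del_calls.tsv")
    write_table(
        pd.DataFrame({"gene_id": result.del_set.genes}), outdir / "del_genes.tsv"
    )
    write_table(
        result.preliminary.assignment.rename("domain").rename_axis("sample_id").reset_index(),
        outdir / "domains_preliminary.tsv",
    )
    write_table(
        result.final.assignment.rename("domain").rename_axis("sample_id").reset_index(),
        outdir / "domains_final.tsv",
    )
    write_table(
        result.groups.assignment.rename("group").rename_axis("gene_id").reset_index(),
        outdir / "gene_groups.tsv",
    )
    write_table(
        pd.DataFrame(
            {"K": list(result.groups.bic_curve),
             "BIC": list(result.groups.bic_curve.values())}
        ),
        outdir / "bic_curve.tsv",
    )


def _stage_coexpr(cfg: RunConfig, outdir: Path) -> None:
    params = cfg.coexpr
    matrix = _load_matrix(params, outdir, "expr_timecourse.tsv", "meta_timecourse.tsv")
    result = run_coexpression_pipeline(
        matrix,
        min_size=params.get("min_size", 30),
        merge_cut=params.get("merge_cut", 0.25),
        r2_target=params.get("r2_target", 0.8),
        signed=params.get("signed", False),
        r_min=params.get("r_min", 0.3),
    )
    rows = [
        {"gene_id": g, "module_id": m.module_id, "category": m.category}
        for m in result.modules
        for g in m.member_genes
    ]
    write_table(
        pd.DataFrame(rows, columns=["gene_id", "module_id", "category"]),
        outdir / "modules.tsv",
    )
    eig = pd.DataFrame({m.module_id: m.eigengene for m in result.modules})
    eig.index.name = "sample_id"
    write_table(eig.reset_index(), outdir / "eigengenes.tsv")
    trait_rows = [
        {
            "module_id": m.module_id, "trait": t, "r": r, "p": p,
            "category": m.category,
        }
        for m in result.modules
        for t, (r, p) in m.trait_correlations.items()
    ]
    write_table(
        pd.DataFrame(
            trait_rows, columns=["module_id", "trait", "r", "p", "category"]
        ),
        outdir / "module_trait.tsv",
    )


def _stage_screen(cfg: RunConfig, outdir: Path) -> None:
    params = cfg.screen
    rep_paths = params.get(
        "replicates", [outdir / f"4c_rep{i}.bed" for i in (1, 2, 3)]
    )
    replicates = [read_bed(p) for p in rep_paths]
    genes = read_gff_genes(params.get("genes", outdir / "genes.gff3"))
    degs = degs_from_frame(read_deg_table(params.get("deg", outdir / "deg.tsv")))
    vp = params.get("viewpoint")
    if vp is None:
        vp_file = outdir / "viewpoint.txt"
        if not vp_file.exists():
            raise InvalidConfigurationError("no viewpoint given or simulated")
        vp = vp_file.read_text(encoding="utf-8").strip()
    viewpoint = vp if isinstance(vp, GenomicInterval) else parse_viewpoint(vp)
    targets, candidates, summary = run_screen(
        replicates, genes, degs, viewpoint,
        min_support=params.get("min_support"),
        padj_thresh=params.get("padj_thresh", 0.05),
        lfc_thresh=params.get("lfc_thresh", 0.585),
    )
    write_table(
        pd.DataFrame(
            [
                {
                    "chrom": t.interval.chrom,
                    "start": t.interval.start,
                    "end": t.interval.end,
                    "nearest_gene": t.nearest_gene,
                    "distance": t.distance,
                    "chromosomal_class": t.chromosomal_class,
                }
                for t in targets
            ]
        ),
        outdir / "targets.tsv",
    )
    write_table(candidates, outdir / "candidates.tsv")
    write_table(
        pd.DataFrame([summary]), outdir / "screen_summary.tsv"
    )


def _stage_epiclass(cfg: RunConfig, outdir: Path) -> None:
    params = cfg.epiclass
    up = read_bed(params.get("up", outdir / "k27ac_up.bed"))
    k4 = read_bed(params.get("k4", outdir / "k4me3.bed"))
    genes = read_gff_genes(params.get("genes", outdir / "genes.gff3"))
    classified = split_by_h3k4me3(
        up, k4, min_overlap_bp=params.get("min_overlap_bp", 1)
    )
    classified = annotate_regions(classified, genes)
    write_table(
        pd.DataFrame(
            [
                {
                    "chrom": c.region.chrom,
                    "start": c.region.start,
                    "end": c.region.end,
                    "class_label": c.class_label,
                    "annotation": c.annotation,
                    "nearest_gene": c.nearest_gene,
                }
                for c in classified
            ]
        ),
        outdir / "region_classes.tsv",
    )
    write_table(class_summary(classified), outdir / "region_class_summary.tsv")


_RUNNERS = {
    "simulate": _stage_simulate,
    "spatial_del": _stage_spatial_del,
    "coexpr": _stage_coexpr,
    "screen": _stage_screen,
    "epiclass": _stage_epiclass,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order; write a manifest.

    Returns the run directory.  Any stage failure propagates after the log
    records it; the manifest is only written when every stage succeeded.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("delatlas")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        ordered = [s for s in KNOWN_STAGES if s in config.stages]
        inputs: dict = {}
        for stage in ordered:
            for key in ("expr", "meta", "replicates", "genes", "deg", "up", "k4"):
                val = getattr(config, stage, {}).get(key) if stage in KNOWN_STAGES else None
                if isinstance(val, (str, Path)) and Path(val).exists():
                    inputs[str(val)] = _sha256(Path(val))
                elif isinstance(val, list):
                    for v in val:
                        if Path(v).exists():
                            inputs[str(v)] = _sha256(Path(v))
            logger.info("running stage %s", stage)
            _RUNNERS[stage](config, outdir)
        handler.flush()
        outputs = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        manifest = {
            "package": "delatlas",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "input_checksums": inputs,
            "output_checksums": outputs,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
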