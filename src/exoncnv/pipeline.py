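"""End-to-end orchestration: regions -> ratios -> model -> segments -> calls,
plus the independent variant-filter -> summaries branch.

Outputs land in a plain run directory with a JSON manifest recording the
parameters, SHA-256 digests of each stage's inputs and outputs, and stage
status. A completed stage whose inputs and parameters are unchanged is
skipped on re-run (digest-checked), so a run directory is resumable after
a failure without redoing finished work.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import depth_ratio as dr
from . import ploidy_purity as pp
from . import regions as rg
from . import segmentation as sg
from . import somatic_filters as sf
from . import summaries as sm

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("exoncnv")

STAGES = (
    "regions",
    "depth_ratio",
    "cnv_model",
    "segmentation",
    "variant_filter",
    "summaries",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Optional inputs may be None;
    the stages needing them are then skipped or reduced accordingly."""

    capture_bed: str
    fasta: str
    depth_table: str
    variant_table: str | None = None
    cpg_island_bed: str | None = None
    gene_bed: str | None = None
    qpcr_table: str | None = None

    gc_threshold: float = 0.65
    min_normal_depth: float = 10.0
    normalize_libraries: bool = False
    bandwidth: float | None = None
    purity: float = 1.0
    estimate_purity: bool = False
    seg_threshold: float = 5.0
    min_regions: int = 3
    baseline_cn: int = 2
    amp_min: int = 5
    del_max: int = 0
    filter_params: sf.FilterParams = field(default_factory=sf.FilterParams)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        fp = raw.pop("filter_params", None)
        cfg = cls(**raw)
        if fp is not None:
            cfg.filter_params = sf.FilterParams(**fp)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_inputs(paths: list[Path], params: dict) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(p.name.encode())
        h.update(_sha256(p).encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages into ``outdir``; return the run manifest.

    Raises :class:`PipelineError` naming the failing stage; outputs of
    stages completed before the failure are retained (and reused on
    re-run).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"stages": {}, "parameters": config.to_dict()}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
            manifest["parameters"] = config.to_dict()
        except json.JSONDecodeError:
            pass
    manifest.setdefault("stages", {})

    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        _run_stages(config, out, manifest, manifest_path)
    finally:
        log.removeHandler(fh)
        fh.close()
    return manifest


def _stage_guard(stage: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(stage, str(exc)) from exc

        return wrapper

    return deco


def _maybe_skip(
    manifest: dict, stage: str, digest: str, outputs: list[Path]
) -> bool:
    entry = manifest["stages"].get(stage)
    if (
        entry
        and entry.get("status") == "completed"
        and entry.get("input_digest") == digest
        and all(Path(p).exists() for p in entry.get("outputs", []))
    ):
        log.info("stage %s: up to date, skipping", stage)
        return True
    return False


def _record(
    manifest: dict,
    manifest_path: Path,
    stage: str,
    digest: str,
    outputs: list[Path],
    extra: dict | None = None,
) -> None:
    entry = {
        "status": "completed",
        "input_digest": digest,
        "outputs": [str(p) for p in outputs],
        "output_digests": {p.name: _sha256(p) for p in outputs},
    }
    if extra:
        entry.update(extra)
    manifest["stages"][stage] = entry
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _require(path_str: str | None, stage: str, what: str) -> Path:
    if path_str is None:
        raise PipelineError(stage, f"missing required input: {what}")
    p = Path(path_str)
    if not p.exists():
        raise PipelineError(stage, f"{what} not found: {p}")
    return p


def _run_stages(
    config: PipelineConfig, out: Path, manifest: dict, manifest_path: Path
) -> None:
    # -- stage 1: regions ---------------------------------------------------
    stage = "regions"
    capture = _require(config.capture_bed, stage, "capture BED")
    fasta = _require(config.fasta, stage, "reference FASTA")
    inputs = [capture, fasta]
    islands_path = None
    if config.cpg_island_bed:
        islands_path = _require(config.cpg_island_bed, stage, "CpG-island BED")
        inputs.append(islands_path)
    params = {"gc_threshold": config.gc_threshold}
    digest = _digest_inputs(inputs, params)
    regions_out = out / "regions_filtered.bed"
    report_out = out / "exclusion_report.tsv"
    if not _maybe_skip(manifest, stage, digest, [regions_out, report_out]):
        run = _stage_guard(stage)(_stage_regions)
        run(config, capture, fasta, islands_path, regions_out, report_out)
        _record(manifest, manifest_path, stage, digest, [regions_out, report_out])

    # -- stage 2: depth_ratio ----------------------------------------------
    stage = "depth_ratio"
    depths_path = _require(config.depth_table, stage, "depth table")
    params = {
        "min_normal_depth": config.min_normal_depth,
        "normalize_libraries": config.normalize_libraries,
    }
    digest = _digest_inputs([depths_path, regions_out], params)
    ratios_out = out / "ratios.tsv"
    if not _maybe_skip(manifest, stage, digest, [ratios_out]):
        run = _stage_guard(stage)(_stage_ratios)
        run(config, depths_path, regions_out, ratios_out)
        _record(manifest, manifest_path, stage, digest, [ratios_out])

    # -- stage 3: cnv_model ------------------------------------------------
    stage = "cnv_model"
    params = {
        "bandwidth": config.bandwidth,
        "purity": config.purity,
        "estimate_purity": config.estimate_purity,
    }
    digest = _digest_inputs([ratios_out], params)
    model_out = out / "model.json"
    density_out = out / "density.tsv"
    cn_out = out / "copy_number.tsv"
    if not _maybe_skip(manifest, stage, digest, [model_out, density_out, cn_out]):
        run = _stage_guard(stage)(_stage_model)
        run(config, ratios_out, model_out, density_out, cn_out)
        _record(manifest, manifest_path, stage, digest, [model_out, density_out, cn_out])

    # -- stage 4: segmentation ----------------------------------------------
    stage = "segmentation"
    params = {
        "seg_threshold": config.seg_threshold,
        "min_regions": config.min_regions,
        "baseline_cn": config.baseline_cn,
        "amp_min": config.amp_min,
        "del_max": config.del_max,
    }
    inputs = [cn_out]
    genes_path = None
    if config.gene_bed:
        genes_path = _require(config.gene_bed, stage, "gene BED")
        inputs.append(genes_path)
    digest = _digest_inputs(inputs, params)
    seg_out = out / "segments.tsv"
    gene_out = out / "gene_calls.tsv"
    seg_outputs = [seg_out] + ([gene_out] if genes_path else [])
    if not _maybe_skip(manifest, stage, digest, seg_outputs):
        run = _stage_guard(stage)(_stage_segment)
        run(config, cn_out, genes_path, seg_out, gene_out)
        _record(manifest, manifest_path, stage, digest, seg_outputs)

    # -- stage 5: variant_filter --------------------------------------------
    stage = "variant_filter"
    pass_out = out / "variants_pass.tsv"
    filter_report_out = out / "filter_report.tsv"
    if config.variant_table:
        variants_path = _require(config.variant_table, stage, "variant table")
        params = dataclasses.asdict(config.filter_params)
        digest = _digest_inputs([variants_path], params)
        if not _maybe_skip(manifest, stage, digest, [pass_out, filter_report_out]):
            run = _stage_guard(stage)(_stage_filter)
            run(config, variants_path, pass_out, filter_report_out)
            _record(
                manifest, manifest_path, stage, digest, [pass_out, filter_report_out]
            )
    else:
        manifest["stages"][stage] = {"status": "skipped", "reason": "no variant table"}

    # -- stage 6: summaries ---------------------------------------------------
    stage = "summaries"
    summary_out = out / "summary.json"
    qpcr_out = out / "qpcr_folds.tsv"
    inputs = [regions_out, fasta]
    if config.variant_table:
        inputs.append(pass_out)
    if config.qpcr_table:
        inputs.append(_require(config.qpcr_table, stage, "qPCR Ct table"))
    digest = _digest_inputs(inputs, {})
    outputs = [summary_out] + ([qpcr_out] if config.qpcr_table else [])
    if not _maybe_skip(manifest, stage, digest, outputs):
        run = _stage_guard(stage)(_stage_summaries)
        run(config, regions_out, fasta, pass_out, summary_out, qpcr_out)
        _record(manifest, manifest_path, stage, digest, outputs)


def _stage_regions(config, capture, fasta, islands_path, regions_out, report_out):
    log.info("stage regions: merging and GC-filtering capture regions")
    intervals = rg.read_bed(capture)
    merged = rg.merge_capture_regions(intervals)
    ref = rg.ReferenceSequence.from_fasta(fasta)
    islands = rg.read_bed(islands_path) if islands_path else None
    kept, report = rg.exclude_high_gc(merged, ref, config.gc_threshold, islands)
    rg.write_bed(kept, regions_out)
    report.to_tsv(report_out)
    log.info(
        "stage regions: %d regions kept, removed %s", len(kept), report.counts
    )


def _stage_ratios(config, depths_path, regions_out, ratios_out):
    log.info("stage depth_ratio: computing tumor:normal ratios")
    records = dr.read_depth_table(depths_path)
    keep = {(iv.chrom, iv.start, iv.end) for iv in rg.read_bed(regions_out)}
    records = [
        d
        for d in records
        if (d.interval.chrom, d.interval.start, d.interval.end) in keep
    ]
    if not records:
        raise ValueError("no depth records remain after region filtering")
    series = dr.compute_ratios(
        records, config.min_normal_depth, config.normalize_libraries
    )
    dr.write_ratio_table(series, ratios_out)


def _stage_model(config, ratios_out, model_out, density_out, cn_out):
    log.info("stage cnv_model: density, mode, ploidy, purity correction")
    series = dr.read_ratio_table(ratios_out)
    density = pp.estimate_density(series, bandwidth=config.bandwidth)
    mode = pp.find_mode(density)
    ploidy = pp.estimate_ploidy(mode)
    purity = config.purity
    if config.estimate_purity:
        est = pp.estimate_purity_from_peaks(density)
        if est is None:
            raise ValueError(
                "purity estimation failed: fewer than two density peaks"
            )
        purity = est
    model = pp.PloidyPurityModel(mode=mode, ploidy=ploidy, purity=purity)
    model.to_json(model_out, bandwidth=density.bandwidth)
    pp.write_density_table(density, density_out)
    cn = pp.correct_copy_number(series, purity)
    pp.write_copy_number_table(cn, series, cn_out)


def _stage_segment(config, cn_out, genes_path, seg_out, gene_out):
    log.info("stage segmentation: binary segmentation and calling")
    cn = pp.read_copy_number_table(cn_out)
    segs = sg.segment(cn, threshold=config.seg_threshold, min_regions=config.min_regions)
    segs = sg.call_segments(
        segs,
        baseline_cn=config.baseline_cn,
        amp_min=config.amp_min,
        del_max=config.del_max,
    )
    sg.write_segment_table(segs, seg_out)
    if genes_path:
        genes = rg.read_bed(genes_path)
        calls, n_unassigned = sg.annotate_genes(segs, genes)
        sg.write_gene_call_table(calls, gene_out)
        log.info("stage segmentation: %d genes unassigned", n_unassigned)


def _stage_filter(config, variants_path, pass_out, report_out):
    log.info("stage variant_filter: somatic filter cascade")
    variants = sf.read_variant_table(variants_path)
    passing, report = sf.apply_somatic_filters(variants, config.filter_params)
    sf.write_variant_table(passing, pass_out)
    report.to_tsv(report_out)


def _stage_summaries(config, regions_out, fasta, pass_out, summary_out, qpcr_out):
    log.info("stage summaries: mutation rates and qPCR folds")
    kept = rg.read_bed(regions_out)
    region_set = rg.merge_capture_regions(kept)
    ref = rg.ReferenceSequence.from_fasta(fasta)
    summary: dict = {
        "target_bases": region_set.total_bases,
        "target_note": "merged capture target after GC/CpG-island exclusion",
    }
    if config.variant_table and Path(pass_out).exists():
        passing = sf.read_variant_table(pass_out)
        summary["n_passing_variants"] = len(passing)
        summary["mutation_rate_per_mb"] = sm.mutation_rate(
            len(passing), region_set.total_bases
        )
        cpg = sm.cpg_context_rates(passing, ref, region_set)
        summary["cpg_context_bases"] = sm.cpg_context_bases(ref, region_set)
        if cpg is None:
            summary["cpg_ti_rate_per_mb"] = None
            summary["cpg_tv_rate_per_mb"] = None
        else:
            summary["cpg_ti_rate_per_mb"], summary["cpg_tv_rate_per_mb"] = cpg
    if config.qpcr_table:
        measurements = sm.read_qpcr_table(config.qpcr_table)
        folds = sm.qpcr_fold_table(measurements)
        folds.to_csv(qpcr_out, sep="\t", index=False)
        summary["qpcr_samples"] = len(folds)
    with open(summary_out, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
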