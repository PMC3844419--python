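"""End-to-end orchestration: cascade -> spectrum -> SMG -> TDG -> DE ->
enrichment, plus the attrition-table report and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .consequence import (
    ConsequenceAnnotation,
    annotate_all,
    call_tdgs,
    consequence_counts,
    TDGRecord,
)
from .coverage import CoverageTrack
from .enrichment import CategoryMap, enrich, overlap_test, results_to_frame
from .expression import CountMatrix, nb_test
from .gene_models import TranscriptModel, load_transcripts, pick_representative
from .mutation_spectrum import (
    BMRTable,
    CoverageSummary,
    categorize_variants,
    estimate_bmr,
    summarize_coverage,
)
from .smg import (
    RateComparison,
    SMGRecord,
    build_profiles,
    call_smgs,
    compare_mutation_rates,
    results_to_frame as smg_results_to_frame,
    test_genes,
)
from .variant_filters import (
    CascadeThresholds,
    FilterReport,
    SamplePair,
    VariantCall,
    run_cascade,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """The report percentage formatter: 100 * num / den rounded to ``decimals``
    places (to the nearest integer when decimals == 0)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    value = 100.0 * numerator / denominator
    rounded = round(value, decimals)
    return int(rounded) if decimals == 0 else rounded


def make_table2_report(
    report: FilterReport, consequence_by_sample: Mapping[str, Mapping[str, int]] | None = None
) -> pd.DataFrame:
    """Attrition table: one row per stage, one column per sample plus a Sum
    column computed from the per-sample cells."""
    if consequence_by_sample:
        for sid, counts in consequence_by_sample.items():
            for stage in ("coding", "disruptive", "disruptive_genes"):
                if stage in counts:
                    report.set_stage(sid, stage, counts[stage])
    return report.to_frame()


@dataclass
class SampleSpec:
    sample_id: str
    condition: str  # "normal" | "tumor"
    patient: str
    vcf: Path
    depth: Path


@dataclass
class PipelineConfig:
    fasta: Path
    annotation: Path
    samples: list[SampleSpec]
    out_dir: Path
    blacklist: Path | None = None
    counts: Path | None = None
    gmt: Path | None = None
    thresholds: CascadeThresholds = field(default_factory=CascadeThresholds)
    smg_alpha: float = 0.01
    min_covered: int = 100
    min_depth: int = 3
    de_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in [self.fasta, self.annotation, self.blacklist, self.counts, self.gmt] + [
            s.vcf for s in self.samples
        ] + [s.depth for s in self.samples]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        patients: dict[str, dict[str, SampleSpec]] = {}
        for s in self.samples:
            if s.condition not in ("normal", "tumor"):
                raise ValueError(f"{s.sample_id}: condition must be normal or tumor")
            patients.setdefault(s.patient, {})[s.condition] = s
        for patient, conds in patients.items():
            if set(conds) != {"normal", "tumor"}:
                raise ValueError(f"patient {patient} is not a complete normal/tumor pair")
        self._patients = patients

    def pairs(self) -> list[tuple[SampleSpec, SampleSpec]]:
        return [
            (conds["normal"], conds["tumor"]) for _, conds in sorted(self._patients.items())
        ]

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        """Flat key=value config; the ``sample`` key is repeatable with value
        ``id,condition,patient,vcf,depth`` (paths relative to the config)."""
        path = Path(path)
        base = path.parent
        keys: dict[str, str] = {}
        samples: list[SampleSpec] = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key == "sample":
                parts = [x.strip() for x in value.split(",")]
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: sample needs 5 comma-separated fields")
                samples.append(
                    SampleSpec(parts[0], parts[1], parts[2], base / parts[3], base / parts[4])
                )
            else:
                keys[key] = value
        thresholds = CascadeThresholds(
            min_qual=float(keys.get("min_qual", 20)),
            min_support=int(keys.get("min_support", 2)),
            max_depth=int(keys.get("max_depth", 500)),
            min_depth=int(keys.get("min_depth", 3)),
        )
        opt = lambda k: (base / keys[k]) if k in keys else None
        return cls(
            fasta=base / keys["fasta"],
            annotation=base / keys["annotation"],
            samples=samples,
            out_dir=base / keys.get("out", "results"),
            blacklist=opt("blacklist"),
            counts=opt("counts"),
            gmt=opt("gmt"),
            thresholds=thresholds,
            smg_alpha=float(keys.get("smg_alpha", 0.01)),
            min_covered=int(keys.get("min_covered", 100)),
            min_depth=int(keys.get("min_depth", 3)),
            de_alpha=float(keys.get("de_alpha", 0.05)),
            seed=int(keys.get("seed", 0)),
        )


@dataclass
class AnalysisResult:
    report: FilterReport
    somatic: dict[str, list[VariantCall]]
    coverage_summaries: dict[str, CoverageSummary]
    bmr_tables: dict[str, BMRTable]
    smg_records: list[SMGRecord]
    smg_set: set[str]
    annotations: dict[str, list[ConsequenceAnnotation]]
    consequence_by_sample: dict[str, dict[str, int]]
    tdg_records: list[TDGRecord]
    tdg_set: set[str]
    rate_comparison: RateComparison | None
    de: pd.DataFrame | None
    deg_set: set[str] | None
    enrichment: dict[str, list] | None
    overlaps: dict[str, tuple[int, float]] | None
    smg_tdg_intersection: set[str]
    sample_order: list[str]
    tumor_samples: list[str]
    normal_samples: list[str]

    def table2(self) -> pd.DataFrame:
        return make_table2_report(self.report, self.consequence_by_sample)


def analyze(
    models: Sequence[TranscriptModel],
    pairs: Sequence[SamplePair],
    blacklist: set[tuple] = frozenset(),
    thresholds: CascadeThresholds = CascadeThresholds(),
    counts: CountMatrix | None = None,
    gmt: CategoryMap | None = None,
    smg_alpha: float = 0.01,
    min_covered: int = 100,
    min_depth: int = 3,
    de_alpha: float = 0.05,
    tail_model: str = "binomial",
) -> AnalysisResult:
    """Run the full in-memory analysis over loaded inputs."""
    models = list(models)
    models_by_chrom = {m.chrom: m for m in models}
    gene_by_chrom = {m.chrom: m.gene_id for m in models}
    normal_samples = [p.normal_id for p in pairs]
    tumor_samples = [p.tumor_id for p in pairs]
    sample_order = [s for p in pairs for s in (p.normal_id, p.tumor_id)]
    coverage_by_sample = {}
    for p in pairs:
        coverage_by_sample[p.normal_id] = p.normal_cov
        coverage_by_sample[p.tumor_id] = p.tumor_cov

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                log.info("stage %s: done", name)

        return _Ctx()

    with stage("cascade"):
        somatic, report = run_cascade(pairs, thresholds, blacklist)

    with stage("spectrum"):
        summaries, bmrs, sample_results = {}, {}, []
        per_gene_mutations: dict[str, int] = {}
        per_gene_covered: dict[str, int] = {}
        for sid in sample_order:
            summary = summarize_coverage(coverage_by_sample[sid], models, min_depth=min_depth)
            cats = categorize_variants(somatic[sid], models_by_chrom)
            bmr = estimate_bmr(somatic[sid], cats, summary)
            gene_idx, K, N, covered = build_profiles(somatic[sid], cats, summary, gene_by_chrom)
            sample_results.extend(
                test_genes(gene_idx, K, N, covered, bmr,
                           min_covered=min_covered, model=tail_model)
            )
            summaries[sid], bmrs[sid] = summary, bmr
            if sid in tumor_samples:
                for g, kk, cc in zip(gene_idx, K.sum(axis=1), covered):
                    per_gene_mutations[g] = per_gene_mutations.get(g, 0) + int(kk)
                    per_gene_covered[g] = per_gene_covered.get(g, 0) + int(cc)

    with stage("smg"):
        smg_set, smg_records = call_smgs(
            sample_results, tumor_samples, normal_samples, alpha=smg_alpha
        )
        rate_comparison = None
        if smg_set and len(smg_set) < len(per_gene_covered):
            try:
                rate_comparison = compare_mutation_rates(
                    smg_set, per_gene_covered.keys(), per_gene_mutations, per_gene_covered
                )
            except ValueError:
                rate_comparison = None

    with stage("consequence"):
        annotations = {sid: annotate_all(somatic[sid], models_by_chrom) for sid in sample_order}
        cons_by_sample = {sid: consequence_counts(anns) for sid, anns in annotations.items()}
        tdg_records = call_tdgs(annotations, tumor_samples, normal_samples, smg_set)
        tdg_set = {r.gene_id for r in tdg_records if r.is_tdg}
        make_table2_report(report, cons_by_sample)

    de = deg_set = None
    if counts is not None:
        with stage("expression"):
            de = nb_test(counts)
            deg_set = set(de.index[(de["padj"] < de_alpha) & de["tested"]])

    enrichment_results = overlaps = None
    universe = None
    if counts is not None:
        universe = set(counts.counts.index[(counts.counts > 0).all(axis=1)])
    if gmt is not None:
        with stage("enrichment"):
            enrichment_results = {}
            for name, query in (("SMG", smg_set), ("TDG", tdg_set)):
                if query & gmt.universe:
                    enrichment_results[name] = enrich(query, gmt)
    if deg_set is not None and universe:
        with stage("overlap"):
            overlaps = {
                "DEGxSMG": overlap_test(deg_set, smg_set, universe),
                "DEGxTDG": overlap_test(deg_set, tdg_set, universe),
            }

    return AnalysisResult(
        report=report,
        somatic=somatic,
        coverage_summaries=summaries,
        bmr_tables=bmrs,
        smg_records=smg_records,
        smg_set=smg_set,
        annotations=annotations,
        consequence_by_sample=cons_by_sample,
        tdg_records=tdg_records,
        tdg_set=tdg_set,
        rate_comparison=rate_comparison,
        de=de,
        deg_set=deg_set,
        enrichment=enrichment_results,
        overlaps=overlaps,
        smg_tdg_intersection=smg_set & tdg_set,
        sample_order=sample_order,
        tumor_samples=tumor_samples,
        normal_samples=normal_samples,
    )


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Load all inputs per the config, run :func:`analyze` and write reports.

    Any stage failure raises :class:`PipelineError` and removes partial
    outputs from the output directory."""
    from .vcfio import read_blacklist, read_vcf

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    try:
        models = list(pick_representative(
            load_transcripts(config.fasta, config.annotation)
        ).values())
        models.sort(key=lambda m: m.gene_id)
        pairs = []
        for normal_spec, tumor_spec in config.pairs():
            pairs.append(
                SamplePair(
                    normal_id=normal_spec.sample_id,
                    tumor_id=tumor_spec.sample_id,
                    normal_variants=read_vcf(normal_spec.vcf, normal_spec.sample_id),
                    tumor_variants=read_vcf(tumor_spec.vcf, tumor_spec.sample_id),
                    normal_cov=CoverageTrack.from_tsv(normal_spec.depth, normal_spec.sample_id),
                    tumor_cov=CoverageTrack.from_tsv(tumor_spec.depth, tumor_spec.sample_id),
                )
            )
        blacklist = read_blacklist(config.blacklist) if config.blacklist else set()
        counts = None
        if config.counts:
            conditions = {s.sample_id: s.condition for s in config.samples}
            counts = CountMatrix.from_tsv(config.counts, conditions)
        gmt = None
        if config.gmt:
            if counts is not None:
                universe = set(counts.counts.index[(counts.counts > 0).all(axis=1)])
            else:
                universe = {m.gene_id for m in models}
            gmt = CategoryMap.from_gmt(config.gmt, universe)

        result = analyze(
            models,
            pairs,
            blacklist=blacklist,
            thresholds=config.thresholds,
            counts=counts,
            gmt=gmt,
            smg_alpha=config.smg_alpha,
            min_covered=config.min_covered,
            min_depth=config.min_depth,
            de_alpha=config.de_alpha,
        )

        emit("filter_report.tsv", lambda p: result.table2().to_csv(p, sep="\t"))
        emit(
            "filter_report.json",
            lambda p: Path(p).write_text(
                json.dumps(result.report.counts, indent=1, sort_keys=True)
            ),
        )
        for sid, bmr in result.bmr_tables.items():
            emit(f"bmr.{sid}.tsv", bmr.to_tsv)
        for sid, summary in result.coverage_summaries.items():
            emit(f"coverage.{sid}.tsv", summary.to_tsv)
        emit(
            "smg.tsv",
            lambda p: smg_results_to_frame(result.smg_records, result.sample_order).to_csv(
                p, sep="\t", index=False
            ),
        )
        tdg_df = pd.DataFrame(
            [
                {"gene_id": r.gene_id, "is_tdg": r.is_tdg, "also_smg": r.also_smg,
                 **{f"{sid}_disruptive": n for sid, n in r.disruptive_counts.items()}}
                for r in result.tdg_records
            ]
        )
        emit("tdg.tsv", lambda p: tdg_df.to_csv(p, sep="\t", index=False))
        if result.de is not None:
            emit("de.tsv", lambda p: result.de.to_csv(p, sep="\t"))
        if result.enrichment is not None:
            frames = [
                results_to_frame(res, gene_set=name) for name, res in result.enrichment.items()
            ]
            if frames:
                emit(
                    "enrichment.tsv",
                    lambda p: pd.concat(frames).to_csv(p, sep="\t", index=False),
                )
        emit(
            "smg_tdg_intersection.txt",
            lambda p: Path(p).write_text(
                "\n".join(sorted(result.smg_tdg_intersection)) + "\n"
                if result.smg_tdg_intersection
                else ""
            ),
        )

        input_paths = [config.fasta, config.annotation] + [s.vcf for s in config.samples] + [
            s.depth for s in config.samples
        ]
        for p in (config.blacklist, config.counts, config.gmt):
            if p:
                input_paths.append(p)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "thresholds": {
                "min_qual": config.thresholds.min_qual,
                "min_support": config.thresholds.min_support,
                "min_depth": config.thresholds.min_depth,
                "max_depth": config.thresholds.max_depth,
            },
            "smg_alpha": config.smg_alpha,
            "min_covered": config.min_covered,
            "de_alpha": config.de_alpha,
            "inputs": {str(Path(p).name): _sha256_file(p) for p in input_paths},
            "outputs": {p.name: _sha256_file(p) for p in written},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return result
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("io", exc) from exc
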