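"""Paired tumor/normal cohort simulator with planted truth labels.

Generates, per sample: expression-dependent per-base coverage, germline
variants shared within each patient pair, sample-specific somatic variants
(tumor burden elevated over normal), a gene x sample count matrix, and a
known-variant blacklist covering a configurable fraction of germline
alleles.  Planted high-rate genes (SMG truth), tumor-only disruptive genes
(TDG truth) and differentially expressed genes (DEG truth) are recorded in
:class:`TruthLabels` so every downstream stage can be tested without any
external data.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so a given config yields byte-identical fixtures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .expression import CountMatrix
from .gene_models import BaseCategory, TranscriptModel, classify_sequence
from .mutation_spectrum import MutationCategory
from .variant_filters import SamplePair, VariantCall

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# BaseCategory -> (transition MutationCategory, transversion MutationCategory)
_TS_TV_OF_BASECAT = {
    BaseCategory.A: (MutationCategory.AT_TRANSITION, MutationCategory.AT_TRANSVERSION),
    BaseCategory.T: (MutationCategory.AT_TRANSITION, MutationCategory.AT_TRANSVERSION),
    BaseCategory.C_CPG: (MutationCategory.CPG_TRANSITION, MutationCategory.CPG_TRANSVERSION),
    BaseCategory.G_CPG: (MutationCategory.CPG_TRANSITION, MutationCategory.CPG_TRANSVERSION),
    BaseCategory.C_NONCPG: (MutationCategory.CG_TRANSITION, MutationCategory.CG_TRANSVERSION),
    BaseCategory.G_NONCPG: (MutationCategory.CG_TRANSITION, MutationCategory.CG_TRANSVERSION),
}


def default_multipliers() -> dict[MutationCategory, float]:
    # CpG transitions enriched by default; tunable, the real spectrum is unknown
    return {
        MutationCategory.AT_TRANSITION: 1.0,
        MutationCategory.AT_TRANSVERSION: 0.5,
        MutationCategory.CPG_TRANSITION: 8.0,
        MutationCategory.CPG_TRANSVERSION: 1.0,
        MutationCategory.CG_TRANSITION: 1.0,
        MutationCategory.CG_TRANSVERSION: 0.5,
        MutationCategory.INDEL: 1.0,
    }


def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


@dataclass
class CohortConfig:
    n_patients: int = 2
    n_genes: int = 60
    min_cds_codons: int = 60
    max_cds_codons: int = 300
    cds_codons: dict[str, int] = field(default_factory=dict)  # per-gene override
    mean_depth: float = 30.0
    depth_dispersion: float = 0.3  # NB alpha: var = mu + alpha * mu^2
    germline_rate: float = 1e-3
    somatic_rate_normal: float = 2e-4
    somatic_rate_tumor: float = 1e-3
    category_rate_multipliers: dict[MutationCategory, float] = field(
        default_factory=default_multipliers
    )
    indel_fraction: float = 0.1
    smg_genes: list[tuple[str, float]] = field(default_factory=list)
    tdg_genes: list[str] = field(default_factory=list)
    deg_genes: list[tuple[str, float]] = field(default_factory=list)
    blacklist_fraction: float = 0.5
    low_qual_fraction: float = 0.05
    low_support_fraction: float = 0.03
    silenced_gene_fraction: float = 0.02
    expression_sigma: float = 0.5
    counts_mean: float = 200.0
    counts_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "germline_rate",
            "somatic_rate_normal",
            "somatic_rate_tumor",
            "blacklist_fraction",
            "low_qual_fraction",
            "low_support_fraction",
            "silenced_gene_fraction",
            "indel_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("need at least one patient and one gene")
        for gid, fold in self.smg_genes:
            if fold <= 0:
                raise ValueError(f"SMG fold for {gid} must be positive")
        if any(m < 0 for m in self.category_rate_multipliers.values()):
            raise ValueError("category multipliers must be non-negative")


@dataclass
class TruthLabels:
    gene_flags: dict[str, dict[str, bool]]
    # (sample_id, chrom, pos, ref, alt) -> "germline" | "somatic_normal" | "somatic_tumor"
    variant_origin: dict[tuple, str]
    planted_tdg_variants: dict[str, list[tuple]] = field(default_factory=dict)

    def origin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for origin in self.variant_origin.values():
            counts[origin] = counts.get(origin, 0) + 1
        return counts


@dataclass
class SimulatedCohort:
    config: CohortConfig
    models: list[TranscriptModel]
    variants: dict[str, list[VariantCall]]
    coverage: dict[str, CoverageTrack]
    counts: CountMatrix
    blacklist: set[tuple]
    truth: TruthLabels
    pairs: list[tuple[str, str]]  # (normal_id, tumor_id) per patient

    @property
    def normal_samples(self) -> list[str]:
        return [n for n, _ in self.pairs]

    @property
    def tumor_samples(self) -> list[str]:
        return [t for _, t in self.pairs]

    @property
    def models_by_chrom(self) -> dict[str, TranscriptModel]:
        return {m.chrom: m for m in self.models}

    @property
    def gene_by_chrom(self) -> dict[str, str]:
        return {m.chrom: m.gene_id for m in self.models}

    @property
    def contigs(self) -> dict[str, int]:
        return {m.chrom: m.cds_length for m in self.models}

    def sample_pairs(self) -> list[SamplePair]:
        return [
            SamplePair(
                normal_id=n,
                tumor_id=t,
                normal_variants=self.variants[n],
                tumor_variants=self.variants[t],
                normal_cov=self.coverage[n],
                tumor_cov=self.coverage[t],
            )
            for n, t in self.pairs
        ]


def _random_models(config: CohortConfig, rng: np.random.Generator) -> list[TranscriptModel]:
    models = []
    for gid in gene_ids(config.n_genes):
        codons = config.cds_codons.get(
            gid, int(rng.integers(config.min_cds_codons, config.max_cds_codons + 1))
        )
        seq = "".join(rng.choice(_BASES, size=3 * codons))
        tid = f"{gid}.1"
        models.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=tid,
                strand="+",
                cds_intervals=((0, 3 * codons),),
                cds_sequence=seq,
            )
        )
    return models


def _site_weights(models: list[TranscriptModel], mult: dict[MutationCategory, float]) -> np.ndarray:
    """Per-base relative SNV mutability, normalised to mean 1 over the genome."""
    parts = []
    for m in models:
        cats = classify_sequence(m.cds_sequence)
        w = np.empty(len(cats))
        for bc in BaseCategory:
            ts_cat, tv_cat = _TS_TV_OF_BASECAT[bc]
            w[cats == bc] = (mult[ts_cat] + 2.0 * mult[tv_cat]) / 3.0
        parts.append(w)
    flat = np.concatenate(parts)
    mean = flat.mean()
    return flat / mean if mean > 0 else flat


def _draw_alt(ref: str, base_cat: BaseCategory, mult, rng: np.random.Generator) -> str:
    ts_cat, tv_cat = _TS_TV_OF_BASECAT[base_cat]
    m_ts, m_tv = mult[ts_cat], mult[tv_cat]
    denom = m_ts + 2.0 * m_tv
    p_ts = m_ts / denom if denom > 0 else 1.0 / 3.0
    if rng.random() < p_ts:
        return _TRANSITION_OF[ref]
    return _TRANSVERSIONS_OF[ref][int(rng.integers(2))]


def _make_indel(seq: str, pos: int, rng: np.random.Generator) -> tuple[str, str]:
    length = int(rng.integers(1, 4))
    make_insertion = rng.random() < 0.5 or pos + length >= len(seq)
    if make_insertion:
        ins = "".join(rng.choice(_BASES, size=length))
        return seq[pos], seq[pos] + ins
    return seq[pos : pos + length + 1], seq[pos]


class _Event:
    __slots__ = ("chrom", "pos", "ref", "alt", "origin", "planted")

    def __init__(self, chrom, pos, ref, alt, origin, planted=False):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt
        self.origin, self.planted = origin, planted

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


def simulate_cohort(
    config: CohortConfig, models: list[TranscriptModel] | None = None
) -> SimulatedCohort:
    """Simulate a full paired cohort; see the module docstring for structure."""
    rng = np.random.default_rng(config.seed)
    if models is None:
        models = _random_models(config, rng)
    by_gene = {m.gene_id: m for m in models}
    for gid in config.tdg_genes:
        if gid not in by_gene:
            raise ValueError(f"planted TDG gene {gid} has no CDS model")
    for gid, _ in list(config.smg_genes) + list(config.deg_genes):
        if gid not in by_gene:
            raise ValueError(f"planted gene {gid} has no CDS model")

    order = [m.gene_id for m in models]
    lengths = np.array([m.cds_length for m in models], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    L = int(offsets[-1])
    genome = "".join(m.cds_sequence for m in models)
    cats = classify_sequence(genome)
    mult = dict(default_multipliers())
    mult.update(config.category_rate_multipliers)
    weights = _site_weights(models, mult)
    smg_fold = {gid: fold for gid, fold in config.smg_genes}
    deg_fold = {gid: l2 for gid, l2 in config.deg_genes}
    tdg_set = set(config.tdg_genes)

    pairs = [(f"P{p}N", f"P{p}T") for p in range(1, config.n_patients + 1)]
    samples = [s for pair in pairs for s in pair]

    # --- expression weights and coverage -------------------------------------
    expr = (
        np.exp(rng.normal(0.0, config.expression_sigma, size=len(models)))
        if config.expression_sigma > 0
        else np.ones(len(models))
    )
    mu_flat = np.repeat(config.mean_depth * expr, lengths)
    coverage: dict[str, CoverageTrack] = {}
    for sid in samples:
        silenced = rng.random(len(models)) < config.silenced_gene_fraction
        if config.depth_dispersion > 0:
            r = 1.0 / config.depth_dispersion
            depth = rng.negative_binomial(r, r / (r + mu_flat))
        else:
            depth = rng.poisson(mu_flat)
        depth = depth.astype(np.int64)
        for i in np.nonzero(silenced)[0]:
            depth[offsets[i] : offsets[i + 1]] = 0
        coverage[sid] = CoverageTrack(
            sample_id=sid,
            depths={
                models[i].chrom: depth[offsets[i] : offsets[i + 1]].copy()
                for i in range(len(models))
            },
        )

    def locate(flat_idx: int) -> tuple[int, int]:
        gi = int(np.searchsorted(offsets, flat_idx, side="right") - 1)
        return gi, int(flat_idx - offsets[gi])

    def draw_events(rate: float, origin: str, gene_rate_mult: np.ndarray | None,
                    exclude_genes: set[str]) -> dict[tuple[str, int], _Event]:
        """Draw SNV and indel events over the flat genome at the given rate."""
        events: dict[tuple[str, int], _Event] = {}
        p_snv = np.clip(rate * (1.0 - config.indel_fraction) * weights, 0.0, 1.0)
        p_indel = np.full(L, min(rate * config.indel_fraction, 1.0))
        if gene_rate_mult is not None:
            per_base = np.repeat(gene_rate_mult, lengths)
            p_snv = np.clip(p_snv * per_base, 0.0, 1.0)
            p_indel = np.clip(p_indel * per_base, 0.0, 1.0)
        snv_sites = np.nonzero(rng.random(L) < p_snv)[0]
        indel_sites = np.nonzero(rng.random(L) < p_indel)[0]
        for flat_idx in snv_sites:
            gi, pos = locate(int(flat_idx))
            model = models[gi]
            if model.gene_id in exclude_genes:
                continue
            ref = genome[flat_idx]
            alt = _draw_alt(ref, BaseCategory(int(cats[flat_idx])), mult, rng)
            events[(model.chrom, pos)] = _Event(model.chrom, pos, ref, alt, origin)
        for flat_idx in indel_sites:
            gi, pos = locate(int(flat_idx))
            model = models[gi]
            if model.gene_id in exclude_genes or (model.chrom, pos) in events:
                continue
            ref, alt = _make_indel(model.cds_sequence, pos, rng)
            events[(model.chrom, pos)] = _Event(model.chrom, pos, ref, alt, origin)
        return events

    # --- germline and somatic events -----------------------------------------
    germline_by_patient: list[dict[tuple[str, int], _Event]] = []
    somatic_by_sample: dict[str, dict[tuple[str, int], _Event]] = {}
    for p, (normal_id, tumor_id) in enumerate(pairs):
        germ = draw_events(config.germline_rate, "germline", None, set())
        germline_by_patient.append(germ)
        som_n = draw_events(
            config.somatic_rate_normal, "somatic_normal", None, exclude_genes=tdg_set
        )
        tumor_mult = np.array([smg_fold.get(g, 1.0) for g in order])
        som_t = draw_events(config.somatic_rate_tumor, "somatic_tumor", tumor_mult, set())
        # germline takes precedence over somatic at the same site
        somatic_by_sample[normal_id] = {k: e for k, e in som_n.items() if k not in germ}
        somatic_by_sample[tumor_id] = {k: e for k, e in som_t.items() if k not in germ}

    # --- TDG planting ---------------------------------------------------------
    planted: dict[str, list[tuple]] = {t: [] for _, t in pairs}
    for gid in config.tdg_genes:
        model = by_gene[gid]
        for p, (normal_id, tumor_id) in enumerate(pairs):
            taken = (
                set(germline_by_patient[p])
                | set(somatic_by_sample[normal_id])
                | set(somatic_by_sample[tumor_id])
            )
            for _attempt in range(1000):
                pos = int(rng.integers(model.cds_length))
                if (model.chrom, pos) in taken:
                    continue
                if rng.random() < 0.3:
                    ref, alt = _make_indel(model.cds_sequence, pos, rng)
                else:
                    ref = model.cds_sequence[pos]
                    alt = _BASES[int(rng.integers(4))]
                    if alt == ref:
                        continue
                    codon_start = (pos // 3) * 3
                    codon = model.cds_sequence[codon_start : codon_start + 3]
                    alt_codon = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
                    from Bio.Seq import Seq

                    if str(Seq(codon).translate()) == str(Seq(alt_codon).translate()):
                        continue  # synonymous, not disruptive
                event = _Event(model.chrom, pos, ref, str(alt), "somatic_tumor", planted=True)
                somatic_by_sample[tumor_id][(model.chrom, pos)] = event
                planted[tumor_id].append(event.key)
                # guarantee paired coverage so the planted call can survive filter 2
                for sid in (normal_id, tumor_id):
                    arr = coverage[sid].depths[model.chrom]
                    arr[pos] = max(arr[pos], 10)
                break
            else:
                raise RuntimeError(f"could not plant TDG variant in {gid}")

    # --- emit per-sample variant calls ---------------------------------------
    variants: dict[str, list[VariantCall]] = {s: [] for s in samples}
    origin_map: dict[tuple, str] = {}
    # germline calls inside planted TDG genes never get QUAL/support decoys:
    # a decoy on one side of a pair would break pair-shared removal and leave
    # a germline disruptive call looking sample-specific, poisoning TDG truth
    tdg_chroms = {by_gene[g].chrom for g in tdg_set}
    for p, (normal_id, tumor_id) in enumerate(pairs):
        for sid in (normal_id, tumor_id):
            events = dict(germline_by_patient[p])
            events.update(somatic_by_sample[sid])
            track = coverage[sid]
            for (chrom, pos) in sorted(events):
                e = events[(chrom, pos)]
                depth = track.depth(chrom, pos)
                if depth < 2:
                    continue
                af = 0.5 if e.origin == "germline" else 0.4
                support = int(np.clip(rng.binomial(depth, af), 1, depth))
                if e.planted or (e.origin == "germline" and chrom in tdg_chroms):
                    support = max(support, 2)
                    qual = round(float(rng.uniform(40.0, 60.0)), 2)
                else:
                    if rng.random() < config.low_support_fraction:
                        support = 1
                    if rng.random() < config.low_qual_fraction:
                        qual = round(float(rng.uniform(3.0, 19.5)), 2)
                    else:
                        qual = round(float(rng.uniform(25.0, 60.0)), 2)
                variants[sid].append(
                    VariantCall(
                        chrom=chrom,
                        pos=pos,
                        ref=e.ref,
                        alt=e.alt,
                        qual=qual,
                        depth=depth,
                        alt_support=support,
                        sample_id=sid,
                    )
                )
                origin_map[(sid, chrom, pos, e.ref, e.alt)] = e.origin

    # --- blacklist ------------------------------------------------------------
    germline_keys = sorted({e.key for germ in germline_by_patient for e in germ.values()})
    mask = rng.random(len(germline_keys)) < config.blacklist_fraction
    blacklist = {k for k, keep in zip(germline_keys, mask) if keep}

    # --- count matrix ---------------------------------------------------------
    cond = {s: ("tumor" if s.endswith("T") else "normal") for s in samples}
    counts = np.zeros((len(models), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        mu = config.counts_mean * expr
        if cond[sid] == "tumor":
            fold = np.array([2.0 ** deg_fold.get(g, 0.0) for g in order])
            mu = mu * fold
        if config.counts_dispersion > 0:
            r = 1.0 / config.counts_dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, j] = rng.poisson(mu)
    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=order, columns=samples), conditions=cond
    )

    gene_flags = {
        g: {
            "is_smg": g in smg_fold,
            "is_tdg": g in tdg_set,
            "is_deg": g in deg_fold,
        }
        for g in order
    }
    truth = TruthLabels(
        gene_flags=gene_flags, variant_origin=origin_map, planted_tdg_variants=planted
    )
    return SimulatedCohort(
        config=config,
        models=models,
        variants=variants,
        coverage=coverage,
        counts=count_matrix,
        blacklist=blacklist,
        truth=truth,
        pairs=pairs,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_bed12(models: list[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.cds_intervals[0][0]
            end = m.cds_intervals[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.cds_intervals)
            starts = ",".join(str(s - start) for s, _ in m.cds_intervals)
            name = f"{m.gene_id}|{m.transcript_id}"
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{name}\t0\t{m.strand}\t{start}\t{end}\t0\t"
                f"{len(m.cds_intervals)}\t{sizes}\t{starts}\n"
            )


def write_fixture(cohort: SimulatedCohort, out_dir: Path | str) -> dict[str, str]:
    """Write the cohort as plain-text files; returns {filename: sha256}."""
    from .vcfio import write_blacklist, write_vcf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(out_dir)
    written: list[Path] = []

    fasta = out_dir / "transcripts.fa"
    with open(fasta, "w") as fh:
        for m in cohort.models:
            fh.write(f">{m.chrom}\n")
            seq = m.cds_sequence if m.strand == "+" else None
            if seq is None:
                raise ValueError("fixture writing assumes plus-strand transcript space")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    written.append(fasta)

    bed = out_dir / "transcripts.bed"
    _write_bed12(cohort.models, bed)
    written.append(bed)

    contigs = cohort.contigs
    for sid, vs in cohort.variants.items():
        path = out_dir / f"{sid}.vcf"
        write_vcf(path, vs, contigs)
        written.append(path)
        dpath = out_dir / f"{sid}.depth.tsv"
        cohort.coverage[sid].to_tsv(dpath)
        written.append(dpath)

    cpath = out_dir / "counts.tsv"
    cohort.counts.to_tsv(cpath)
    written.append(cpath)

    bpath = out_dir / "blacklist.vcf"
    write_blacklist(bpath, cohort.blacklist, contigs)
    written.append(bpath)

    tpath = out_dir / "truth.json"
    truth_doc = {
        "gene_flags": cohort.truth.gene_flags,
        "variant_origin": {
            "|".join(map(str, k)): v for k, v in sorted(cohort.truth.variant_origin.items())
        },
        "planted_tdg_variants": {
            sid: ["|".join(map(str, k)) for k in keys]
            for sid, keys in cohort.truth.planted_tdg_variants.items()
        },
        "pairs": cohort.pairs,
        "origin_counts": cohort.truth.origin_counts(),
    }
    tpath.write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    written.append(tpath)

    manifest = {p.name: _sha256(p) for p in written}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
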