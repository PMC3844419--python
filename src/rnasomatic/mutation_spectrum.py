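"""Mutation categories, covered-base accounting and background mutation rates.

Seven mutation categories are used: AT transitions/transversions, CpG
transitions/transversions, CG (non-CpG) transitions/transversions and indels.
The SNV denominators pool the two strand-symmetric base categories (the AT
pool is A+T bases, the CpG pool is C-in-CpG + G-in-CpG, the CG pool is the
non-CpG C+G bases); the indel denominator is the total number of covered
bases.  Rates are estimated per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .gene_models import BaseCategory, TranscriptModel, classify_sequence
from .variant_filters import VariantCall

log = logging.getLogger(__name__)


class MutationCategory(IntEnum):
    AT_TRANSITION = 0
    AT_TRANSVERSION = 1
    CPG_TRANSITION = 2
    CPG_TRANSVERSION = 3
    CG_TRANSITION = 4
    CG_TRANSVERSION = 5
    INDEL = 6


SNV_CATEGORIES = tuple(c for c in MutationCategory if c != MutationCategory.INDEL)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_BASE_OF_CATEGORY = {
    BaseCategory.A: "A",
    BaseCategory.T: "T",
    BaseCategory.C_CPG: "C",
    BaseCategory.G_CPG: "G",
    BaseCategory.C_NONCPG: "C",
    BaseCategory.G_NONCPG: "G",
}

# base-category -> (transition category, transversion category)
_ROUTING = {
    BaseCategory.A: (MutationCategory.AT_TRANSITION, MutationCategory.AT_TRANSVERSION),
    BaseCategory.T: (MutationCategory.AT_TRANSITION, MutationCategory.AT_TRANSVERSION),
    BaseCategory.C_CPG: (MutationCategory.CPG_TRANSITION, MutationCategory.CPG_TRANSVERSION),
    BaseCategory.G_CPG: (MutationCategory.CPG_TRANSITION, MutationCategory.CPG_TRANSVERSION),
    BaseCategory.C_NONCPG: (MutationCategory.CG_TRANSITION, MutationCategory.CG_TRANSVERSION),
    BaseCategory.G_NONCPG: (MutationCategory.CG_TRANSITION, MutationCategory.CG_TRANSVERSION),
}


def categorize_mutation(
    ref: str, alt: str, base_cat: BaseCategory | None, is_indel: bool
) -> MutationCategory:
    """Map one variant to its mutation category."""
    if is_indel:
        return MutationCategory.INDEL
    if base_cat is None:
        raise ValueError("SNVs require a base category")
    if _BASE_OF_CATEGORY[base_cat] != ref:
        raise ValueError(f"reference base {ref!r} inconsistent with category {base_cat.name}")
    ts_cat, tv_cat = _ROUTING[base_cat]
    return ts_cat if (ref, alt) in _TRANSITIONS else tv_cat


@dataclass
class CoverageSummary:
    """Per-gene counts of bases covered at >= min_depth, split by base category."""

    sample_id: str
    per_gene: pd.DataFrame  # index: gene_id; columns: BaseCategory names + "covered"
    min_depth: int = 3

    @property
    def totals(self) -> pd.Series:
        return self.per_gene.sum(axis=0)

    def covered(self, gene_id: str) -> int:
        return int(self.per_gene.loc[gene_id, "covered"])

    def pooled_denominators(self, totals: pd.Series | None = None) -> np.ndarray:
        """Available-base denominator for each of the seven mutation categories."""
        t = self.totals if totals is None else totals
        at = int(t[BaseCategory.A.name] + t[BaseCategory.T.name])
        cpg = int(t[BaseCategory.C_CPG.name] + t[BaseCategory.G_CPG.name])
        cg = int(t[BaseCategory.C_NONCPG.name] + t[BaseCategory.G_NONCPG.name])
        return np.array([at, at, cpg, cpg, cg, cg, int(t["covered"])], dtype=np.int64)

    def gene_denominators(self, gene_id: str) -> np.ndarray:
        return self.pooled_denominators(self.per_gene.loc[gene_id])

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index_label="gene_id")


def summarize_coverage(
    track: CoverageTrack,
    models: Sequence[TranscriptModel],
    min_depth: int = 3,
) -> CoverageSummary:
    """Count covered bases per gene and base category for one sample."""
    columns = [c.name for c in BaseCategory] + ["covered"]
    rows = {}
    for model in models:
        if model.chrom not in track.depths:
            log.warning("%s: no coverage for %s; counted as zero-covered",
                        track.sample_id, model.transcript_id)
            rows[model.gene_id] = np.zeros(7, dtype=np.int64)
            continue
        depth = track.profile(model)
        cats = classify_sequence(model.cds_sequence)
        counts = np.bincount(cats[depth >= min_depth], minlength=6).astype(np.int64)
        rows[model.gene_id] = np.concatenate([counts, [counts.sum()]])
    per_gene = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    per_gene.index.name = "gene_id"
    return CoverageSummary(sample_id=track.sample_id, per_gene=per_gene, min_depth=min_depth)


def indel_span(v: VariantCall) -> int:
    """Bases attributed to one indel: deleted ref span, or 1 for insertions."""
    return max(len(v.ref) - len(v.alt), 1)


@dataclass
class BMRTable:
    """Per-sample background mutation rate per mutation category."""

    sample_id: str
    numerators: np.ndarray  # int, length 7 (indel numerator = bases covered by indels)
    denominators: np.ndarray  # int, length 7
    zero_flagged: np.ndarray | None = None  # True where rate is a 0/0 placeholder

    def __post_init__(self) -> None:
        self.numerators = np.asarray(self.numerators, dtype=np.int64)
        self.denominators = np.asarray(self.denominators, dtype=np.int64)
        bad = (self.denominators == 0) & (self.numerators > 0)
        if bad.any():
            names = [MutationCategory(i).name for i in np.nonzero(bad)[0]]
            raise ValueError(f"{self.sample_id}: nonzero count with zero denominator in {names}")
        if self.zero_flagged is None:
            self.zero_flagged = (self.denominators == 0) & (self.numerators == 0)

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.denominators > 0, self.numerators / np.maximum(self.denominators, 1), 0.0)
        return r

    def rate(self, cat: MutationCategory) -> float:
        return float(self.rates[int(cat)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.name for c in MutationCategory],
                "numerator": self.numerators,
                "denominator": self.denominators,
                "rate": self.rates,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def categorize_variants(
    variants: Sequence[VariantCall], models_by_chrom: dict[str, TranscriptModel]
) -> list[MutationCategory]:
    """Category per variant, using the transcript's coding-strand context.

    Variants outside any model's CDS (or on unknown chroms) are categorized by
    indel status only for indels and raise for SNVs, since SNV categories need
    sequence context.
    """
    out = []
    for v in variants:
        if v.is_indel:
            out.append(MutationCategory.INDEL)
            continue
        model = models_by_chrom.get(v.chrom)
        if model is None or not model.contains(v.pos):
            raise ValueError(f"no transcript context for SNV at {v.chrom}:{v.pos}")
        coding = model.genomic_to_coding(v.pos)
        cats = classify_sequence(model.cds_sequence)
        base_cat = BaseCategory(int(cats[coding]))
        ref, alt = v.ref, v.alt
        if model.strand == "-":
            from .gene_models import complement

            ref, alt = complement(ref), complement(alt)
        out.append(categorize_mutation(ref, alt, base_cat, False))
    return out


def estimate_bmr(
    somatic: Sequence[VariantCall],
    categories: Sequence[MutationCategory],
    cov: CoverageSummary,
) -> BMRTable:
    """Estimate the per-category background mutation rate for one sample.

    ``categories`` runs parallel to ``somatic`` (see :func:`categorize_variants`).
    """
    if len(somatic) != len(categories):
        raise ValueError("somatic and categories must be parallel sequences")
    numerators = np.zeros(7, dtype=np.int64)
    for v, c in zip(somatic, categories):
        if c == MutationCategory.INDEL:
            numerators[int(c)] += indel_span(v)
        else:
            numerators[int(c)] += 1
    denominators = cov.pooled_denominators()
    return BMRTable(sample_id=cov.sample_id, numerators=numerators, denominators=denominators)
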