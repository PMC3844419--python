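"""Coding-consequence annotation and tumor-specific disruptive gene calling.

"Disruptive" means a nonsynonymous SNV (stop gain/loss folded in) or any
indel.  A tumor-specific disruptive gene (TDG) carries at least one
disruptive somatic variant in every tumor sample and none in any normal
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .gene_models import TranscriptModel, complement
from .variant_filters import VariantCall

log = logging.getLogger(__name__)


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    INDEL = "indel"
    NON_CODING = "non_coding"


DISRUPTIVE_CLASSES = frozenset({ConsequenceClass.NONSYNONYMOUS, ConsequenceClass.INDEL})


@dataclass(frozen=True)
class ConsequenceAnnotation:
    variant: VariantCall
    gene_id: str
    klass: ConsequenceClass
    ref_aa: str | None = None
    alt_aa: str | None = None
    detail: str | None = None  # e.g. "stop_gained", for downstream inspection

    @property
    def is_disruptive(self) -> bool:
        return self.klass in DISRUPTIVE_CLASSES


@dataclass
class TDGRecord:
    gene_id: str
    disruptive_counts: dict[str, int]  # per sample
    is_tdg: bool
    also_smg: bool = False


def annotate_consequence(v: VariantCall, model: TranscriptModel) -> ConsequenceAnnotation:
    """Annotate one variant against its transcript model.

    Variants outside the CDS are classed non-coding.  SNV class is decided
    purely by codon translation with the ref and alt base substituted.
    """
    if not model.contains(v.pos):
        return ConsequenceAnnotation(variant=v, gene_id=model.gene_id, klass=ConsequenceClass.NON_CODING)
    if v.is_indel:
        return ConsequenceAnnotation(variant=v, gene_id=model.gene_id, klass=ConsequenceClass.INDEL)

    coding = model.genomic_to_coding(v.pos)
    ref, alt = v.ref, v.alt
    if model.strand == "-":
        ref, alt = complement(ref), complement(alt)
    codon_start = (coding // 3) * 3
    offset = coding % 3
    codon = model.cds_sequence[codon_start : codon_start + 3]
    if codon[offset] != ref:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos}: model has {codon[offset]!r}, "
            f"variant claims {ref!r}"
        )
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        klass, detail = ConsequenceClass.SYNONYMOUS, None
    else:
        klass = ConsequenceClass.NONSYNONYMOUS
        if alt_aa == "*":
            detail = "stop_gained"
        elif ref_aa == "*":
            detail = "stop_lost"
        else:
            detail = "missense"
    return ConsequenceAnnotation(
        variant=v, gene_id=model.gene_id, klass=klass, ref_aa=ref_aa, alt_aa=alt_aa, detail=detail
    )


def annotate_all(
    variants: Sequence[VariantCall], models_by_chrom: Mapping[str, TranscriptModel]
) -> list[ConsequenceAnnotation]:
    out = []
    for v in variants:
        model = models_by_chrom.get(v.chrom)
        if model is None:
            log.warning("no transcript model for %s; variant at %d left unannotated", v.chrom, v.pos)
            continue
        out.append(annotate_consequence(v, model))
    return out


def consequence_counts(annotations: Sequence[ConsequenceAnnotation]) -> dict[str, int]:
    """Per-sample attrition-report counts: coding variants, disruptive variants
    and distinct genes with at least one disruptive variant."""
    coding = [a for a in annotations if a.klass != ConsequenceClass.NON_CODING]
    disruptive = [a for a in coding if a.is_disruptive]
    return {
        "coding": len(coding),
        "disruptive": len(disruptive),
        "disruptive_genes": len({a.gene_id for a in disruptive}),
    }


def call_tdgs(
    annotations_by_sample: Mapping[str, Sequence[ConsequenceAnnotation]],
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    smg_set: Iterable[str] = (),
) -> list[TDGRecord]:
    """Call tumor-specific disruptive genes over all four (or 2n) samples."""
    smg_set = set(smg_set)
    counts: dict[str, dict[str, int]] = {}
    for sid, anns in annotations_by_sample.items():
        for a in anns:
            if a.is_disruptive:
                counts.setdefault(a.gene_id, {}).setdefault(sid, 0)
                counts[a.gene_id][sid] += 1
    records = []
    all_samples = list(tumor_samples) + list(normal_samples)
    for gene_id in sorted(counts):
        per_sample = {sid: counts[gene_id].get(sid, 0) for sid in all_samples}
        is_tdg = all(per_sample[s] >= 1 for s in tumor_samples) and all(
            per_sample[s] == 0 for s in normal_samples
        )
        records.append(
            TDGRecord(
                gene_id=gene_id,
                disruptive_counts=per_sample,
                is_tdg=is_tdg,
                also_smg=gene_id in smg_set,
            )
        )
    return records
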