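"""The three-filter somatic variant cascade with per-stage attrition accounting.

Filter 1 keeps calls with QUAL >= 20, at least two supporting reads and read
depth inside the [3, 500] window.  Filter 2 drops calls at positions that are
not covered (depth >= 3) in *both* members of a tumor/normal pair.  Filter 3
subtracts variants shared between the pair and variants present in a
known-variant blacklist; what remains on each side is sample-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .coverage import CoverageTrack

log = logging.getLogger(__name__)

STAGES = (
    "raw",
    "after_filter1",
    "after_filter2",
    "after_filter3",
    "coding",
    "disruptive",
    "disruptive_genes",
)

STAGE_LABELS = {
    "raw": "Raw",
    "after_filter1": "After filter 1",
    "after_filter2": "After filter 2",
    "after_filter3": "After filter 3",
    "coding": "Coding",
    "disruptive": "Disruptive",
    "disruptive_genes": "Disruptive genes",
}

# monotone attrition is only required along the filter cascade itself
_CASCADE_STAGES = ("raw", "after_filter1", "after_filter2", "after_filter3")


@dataclass(frozen=True)
class VariantCall:
    """One parsed, bi-allelic variant call for one sample."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float
    depth: int
    alt_support: int
    sample_id: str
    is_indel: bool | None = None

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError(f"negative QUAL for {self.chrom}:{self.pos}")
        if not 0 <= self.alt_support <= self.depth:
            raise ValueError(
                f"alt support {self.alt_support} outside [0, {self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.is_indel is None:
            object.__setattr__(self, "is_indel", len(self.ref) != len(self.alt))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class CascadeThresholds:
    min_qual: float = 20.0
    min_support: int = 2
    max_depth: int = 500
    min_depth: int = 3

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")


@dataclass
class FilterReport:
    """Per-sample record counts at each cascade stage (attrition table layout)."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    sample_order: list[str] = field(default_factory=list)

    def set_stage(self, sample_id: str, stage: str, n: int) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if sample_id not in self.counts:
            self.counts[sample_id] = {}
            self.sample_order.append(sample_id)
        self.counts[sample_id][stage] = int(n)

    def get(self, sample_id: str, stage: str) -> int:
        return self.counts[sample_id][stage]

    def row_sum(self, stage: str) -> int:
        return sum(self.counts[s][stage] for s in self.sample_order if stage in self.counts[s])

    def validate(self) -> None:
        for sample_id, stages in self.counts.items():
            seq = [stages[s] for s in _CASCADE_STAGES if s in stages]
            if any(a < b for a, b in zip(seq, seq[1:])):
                raise ValueError(f"non-monotone attrition for sample {sample_id}: {seq}")

    def to_frame(self) -> pd.DataFrame:
        stages = [s for s in STAGES if any(s in self.counts[sid] for sid in self.sample_order)]
        data = {
            sid: [self.counts[sid].get(s, 0) for s in stages] for sid in self.sample_order
        }
        df = pd.DataFrame(data, index=[STAGE_LABELS[s] for s in stages])
        df["Sum"] = df.sum(axis=1)
        return df

    @classmethod
    def from_counts(cls, per_sample: dict[str, dict[str, int]]) -> "FilterReport":
        report = cls()
        for sample_id, stages in per_sample.items():
            for stage, n in stages.items():
                report.set_stage(sample_id, stage, n)
        return report


def filter1_quality(
    variants: Sequence[VariantCall], t: CascadeThresholds = CascadeThresholds()
) -> list[VariantCall]:
    """Quality filter: QUAL, supporting reads and the read-depth window."""
    return [
        v
        for v in variants
        if v.qual >= t.min_qual
        and v.alt_support >= t.min_support
        and t.min_depth <= v.depth <= t.max_depth
    ]


def filter2_paired_coverage(
    variants: Sequence[VariantCall],
    own_cov: CoverageTrack,
    mate_cov: CoverageTrack,
    t: CascadeThresholds = CascadeThresholds(),
) -> list[VariantCall]:
    """Keep variants whose position is covered (depth >= min_depth) in both
    members of the sample pair."""
    if own_cov is None or mate_cov is None:
        raise ValueError("both coverage tracks are required for filter 2")
    return [
        v
        for v in variants
        if own_cov.depth(v.chrom, v.pos) >= t.min_depth
        and mate_cov.depth(v.chrom, v.pos) >= t.min_depth
    ]


def _blacklisted(v: VariantCall, blacklist: frozenset | set) -> bool:
    return v.key in blacklist or v.site in blacklist


def filter3_somatic_subtraction(
    normal: Sequence[VariantCall],
    tumor: Sequence[VariantCall],
    blacklist: Iterable[tuple] = (),
    match_alleles: bool = True,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove pair-shared and blacklisted variants; return the sample-specific
    remainder of each side as ``(normal_specific, tumor_specific)``.

    Matching requires allele identity by default; ``match_alleles=False``
    compares positions only.  Blacklist entries may be ``(chrom, pos)`` or
    ``(chrom, pos, ref, alt)`` tuples and are matched accordingly.
    """
    bl = set(blacklist)
    keyfn = (lambda v: v.key) if match_alleles else (lambda v: v.site)
    shared = {keyfn(v) for v in normal} & {keyfn(v) for v in tumor}
    normal_specific = [v for v in normal if keyfn(v) not in shared and not _blacklisted(v, bl)]
    tumor_specific = [v for v in tumor if keyfn(v) not in shared and not _blacklisted(v, bl)]
    return normal_specific, tumor_specific


@dataclass
class SamplePair:
    """Matched normal/tumor inputs for one patient."""

    normal_id: str
    tumor_id: str
    normal_variants: list[VariantCall]
    tumor_variants: list[VariantCall]
    normal_cov: CoverageTrack
    tumor_cov: CoverageTrack

    def __post_init__(self) -> None:
        if self.normal_cov.sample_id != self.normal_id or self.tumor_cov.sample_id != self.tumor_id:
            raise ValueError(
                f"coverage tracks ({self.normal_cov.sample_id}, {self.tumor_cov.sample_id}) "
                f"do not match pair ({self.normal_id}, {self.tumor_id})"
            )
        for v in self.normal_variants:
            if v.sample_id != self.normal_id:
                raise ValueError(f"variant sample {v.sample_id} != pair normal {self.normal_id}")
        for v in self.tumor_variants:
            if v.sample_id != self.tumor_id:
                raise ValueError(f"variant sample {v.sample_id} != pair tumor {self.tumor_id}")


def run_cascade(
    pairs: Sequence[SamplePair],
    t: CascadeThresholds = CascadeThresholds(),
    blacklist: Iterable[tuple] = (),
    match_alleles: bool = True,
) -> tuple[dict[str, list[VariantCall]], FilterReport]:
    """Run filters 1-3 over every pair; return per-sample somatic survivors and
    the per-stage attrition report."""
    report = FilterReport()
    somatic: dict[str, list[VariantCall]] = {}
    bl = set(blacklist)
    for pair in pairs:
        stage: dict[str, list[VariantCall]] = {}
        stage["n_raw"] = list(pair.normal_variants)
        stage["t_raw"] = list(pair.tumor_variants)
        stage["n_f1"] = filter1_quality(stage["n_raw"], t)
        stage["t_f1"] = filter1_quality(stage["t_raw"], t)
        stage["n_f2"] = filter2_paired_coverage(stage["n_f1"], pair.normal_cov, pair.tumor_cov, t)
        stage["t_f2"] = filter2_paired_coverage(stage["t_f1"], pair.tumor_cov, pair.normal_cov, t)
        n_f3, t_f3 = filter3_somatic_subtraction(
            stage["n_f2"], stage["t_f2"], bl, match_alleles=match_alleles
        )
        somatic[pair.normal_id] = n_f3
        somatic[pair.tumor_id] = t_f3
        for sid, raw, f1, f2, f3 in (
            (pair.normal_id, stage["n_raw"], stage["n_f1"], stage["n_f2"], n_f3),
            (pair.tumor_id, stage["t_raw"], stage["t_f1"], stage["t_f2"], t_f3),
        ):
            report.set_stage(sid, "raw", len(raw))
            report.set_stage(sid, "after_filter1", len(f1))
            report.set_stage(sid, "after_filter2", len(f2))
            report.set_stage(sid, "after_filter3", len(f3))
            log.info(
                "%s: raw=%d f1=%d f2=%d f3=%d", sid, len(raw), len(f1), len(f2), len(f3)
            )
    report.validate()
    return somatic, report
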