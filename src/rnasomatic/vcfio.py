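"""VCF input/output. Site-only VCFv4.2 with INFO/DP, INFO/AD and INFO/SOMATIC
class annotations; multi-allelic records are split into bi-allelic calls at
parse time. Positions convert between the package's 0-based convention and
VCF's 1-based one here and nowhere else."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .variant_filters import VariantCall

log = logging.getLogger(__name__)


def _build_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in sorted(contigs):
        header.contigs.add(name, length=contigs[name])
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.info.add("AD", "R", "Integer", "Read depth per allele (ref first)")
    return header


def write_vcf(path: Path | str, variants: Sequence[VariantCall], contigs: dict[str, int]) -> None:
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos,
                alleles=(v.ref, v.alt),
                qual=round(v.qual, 2),
            )
            rec.info["DP"] = v.depth
            rec.info["AD"] = (v.depth - v.alt_support, v.alt_support)
            out.write(rec)


def read_vcf(path: Path | str, sample_id: str) -> list[VariantCall]:
    """Parse a VCF into bi-allelic VariantCalls for one sample.

    Depth is INFO/DP when present; alt support is the matching INFO/AD entry,
    defaulting to the depth (or 1) when AD is absent.
    """
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            dp = rec.info.get("DP")
            ad = rec.info.get("AD")
            for i, alt in enumerate(rec.alts):
                if alt is None or alt in (".", "<NON_REF>"):
                    continue
                depth = int(dp) if dp is not None else None
                support = None
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    support = int(ad[i + 1])
                if depth is None:
                    depth = support if support is not None else 1
                if support is None:
                    support = depth
                out.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=depth,
                        alt_support=min(support, depth),
                        sample_id=sample_id,
                    )
                )
    return out


def read_blacklist(path: Path | str) -> set[tuple]:
    """Read a known-variant blacklist VCF into allele-aware match keys.

    Records with a missing/./ALT contribute positional ``(chrom, pos)`` keys,
    so positional-only blacklists are honoured."""
    keys: set[tuple] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts:
                for alt in rec.alts:
                    if alt in (None, ".", "<NON_REF>"):
                        keys.add((rec.chrom, rec.start))
                    else:
                        keys.add((rec.chrom, rec.start, rec.ref, alt))
            else:
                keys.add((rec.chrom, rec.start))
    return keys


def write_blacklist(path: Path | str, keys: Iterable[tuple], contigs: dict[str, int]) -> None:
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(keys):
            if len(key) == 4:
                chrom, pos, ref, alt = key
                rec = out.new_record(contig=chrom, start=pos, alleles=(ref, alt))
            else:
                chrom, pos = key
                rec = out.new_record(contig=chrom, start=pos, alleles=("N",))
            out.write(rec)
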