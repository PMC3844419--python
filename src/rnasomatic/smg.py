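"""Significantly-mutated-gene test: per-category binomial tails combined by
Fisher's combined P-value test (FCPT), plus consensus calling and the
SMG-vs-other mutation-rate comparison.

The per-category tail is P(X >= k) with X ~ Binomial(n, BMR), which is
coverage-independent in the sense that depth only enters through the number
of available bases n.  All seven categories always enter the combination
(an unobservable category contributes p = 1), so the chi-square degrees of
freedom are fixed at 2 x 7 = 14.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mutation_spectrum import (
    BMRTable,
    CoverageSummary,
    MutationCategory,
    indel_span,
)
from .variant_filters import VariantCall

log = logging.getLogger(__name__)

N_CATEGORIES = len(MutationCategory)


@dataclass
class GeneMutationProfile:
    """Observed mutation counts and available bases for one gene in one sample."""

    gene_id: str
    sample_id: str
    k: np.ndarray  # observed count per MutationCategory, length 7
    n: np.ndarray  # available bases per category (pooled denominators), length 7
    covered: int  # total bases covered at >= min_depth

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.k.shape != (N_CATEGORIES,) or self.n.shape != (N_CATEGORIES,):
            raise ValueError("k and n must have length 7")
        if (self.k < 0).any() or (self.n < 0).any():
            raise ValueError("negative counts")


@dataclass
class SMGSampleResult:
    gene_id: str
    sample_id: str
    statistic: float
    df: int
    pvalue: float
    covered: int
    eligible: bool


@dataclass
class SMGRecord:
    gene_id: str
    per_sample: dict[str, SMGSampleResult]
    is_smg: bool


@dataclass(frozen=True)
class FcptResult:
    statistic: float
    df: int
    pvalue: float


def category_tail_probability(
    k: int,
    n: int,
    p: float,
    model: str = "binomial",
    inclusive: bool = True,
) -> float:
    """Upper-tail probability of observing at least ``k`` mutations among ``n``
    available bases at per-base rate ``p``.

    ``model`` may be "binomial" (default) or "poisson"; ``inclusive=False``
    gives the strict tail P(X > k).
    """
    if k < 0 or n < 0:
        raise ValueError("k and n must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rate {p} outside [0, 1]")
    if n == 0:
        return 1.0
    thresh = k - 1 if inclusive else k
    if thresh < 0:
        return 1.0
    if model == "binomial":
        return float(stats.binom.sf(thresh, n, p))
    if model == "poisson":
        return float(stats.poisson.sf(thresh, n * p))
    raise ValueError(f"unknown tail model {model!r}")


def fcpt_combine(pvals: Sequence[float], eps: float = 1e-300) -> FcptResult:
    """Fisher's combined P-value test: -2 sum(ln p) against chi2(2 * len(pvals))."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    clipped = np.clip(pvals, eps, 1.0)
    statistic = float(-2.0 * np.log(clipped).sum())
    df = 2 * pvals.size
    return FcptResult(statistic=statistic, df=df, pvalue=float(stats.chi2.sf(statistic, df)))


def _tail_matrix(
    K: np.ndarray, N: np.ndarray, rates: np.ndarray, model: str, inclusive: bool
) -> np.ndarray:
    """Vectorised per-category tails for a (G, 7) count/denominator layout."""
    thresh = K - 1 if inclusive else K
    if model == "binomial":
        tails = stats.binom.sf(thresh, N, rates[np.newaxis, :])
    elif model == "poisson":
        tails = stats.poisson.sf(thresh, N * rates[np.newaxis, :])
    else:
        raise ValueError(f"unknown tail model {model!r}")
    tails = np.where(thresh < 0, 1.0, tails)
    tails = np.where(N == 0, 1.0, tails)
    return np.clip(tails, 0.0, 1.0)


def test_genes(
    gene_ids: Sequence[str],
    K: np.ndarray,
    N: np.ndarray,
    covered: np.ndarray,
    bmr: BMRTable,
    min_covered: int = 100,
    model: str = "binomial",
    inclusive: bool = True,
    eps: float = 1e-300,
) -> list[SMGSampleResult]:
    """FCPT over all seven categories for every gene of one sample (vectorised)."""
    K = np.asarray(K, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    rates = bmr.rates
    tails = _tail_matrix(K, N, rates, model, inclusive)
    stat = -2.0 * np.log(np.clip(tails, eps, 1.0)).sum(axis=1)
    df = 2 * N_CATEGORIES
    pvals = stats.chi2.sf(stat, df)
    return [
        SMGSampleResult(
            gene_id=g,
            sample_id=bmr.sample_id,
            statistic=float(stat[i]),
            df=df,
            pvalue=float(pvals[i]),
            covered=int(covered[i]),
            eligible=int(covered[i]) >= min_covered,
        )
        for i, g in enumerate(gene_ids)
    ]


def test_gene(
    profile: GeneMutationProfile,
    bmr: BMRTable,
    min_covered: int = 100,
    model: str = "binomial",
    inclusive: bool = True,
) -> SMGSampleResult:
    """Per-sample SMG test for a single gene profile."""
    if profile.sample_id != bmr.sample_id:
        raise ValueError(
            f"profile sample {profile.sample_id} does not match BMR sample {bmr.sample_id}"
        )
    return test_genes(
        [profile.gene_id],
        profile.k[np.newaxis, :],
        profile.n[np.newaxis, :],
        np.array([profile.covered]),
        bmr,
        min_covered=min_covered,
        model=model,
        inclusive=inclusive,
    )[0]


def build_profiles(
    somatic: Sequence[VariantCall],
    categories: Sequence[MutationCategory],
    cov: CoverageSummary,
    gene_by_chrom: Mapping[str, str],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene count matrix ``K`` (G, 7), denominators ``N`` (G, 7) and covered
    bases, over every gene in the coverage summary."""
    gene_ids = list(cov.per_gene.index)
    index = {g: i for i, g in enumerate(gene_ids)}
    K = np.zeros((len(gene_ids), N_CATEGORIES), dtype=np.int64)
    for v, c in zip(somatic, categories):
        gene = gene_by_chrom.get(v.chrom)
        if gene is None or gene not in index:
            log.warning("variant at %s:%d maps to no known gene; ignored", v.chrom, v.pos)
            continue
        K[index[gene], int(c)] += 1
    pg = cov.per_gene
    at = (pg["A"] + pg["T"]).to_numpy(dtype=np.int64)
    cpg = (pg["C_CPG"] + pg["G_CPG"]).to_numpy(dtype=np.int64)
    cg = (pg["C_NONCPG"] + pg["G_NONCPG"]).to_numpy(dtype=np.int64)
    covered = pg["covered"].to_numpy(dtype=np.int64)
    N = np.stack([at, at, cpg, cpg, cg, cg, covered], axis=1)
    return gene_ids, K, N, covered


def call_smgs(
    sample_results: Iterable[SMGSampleResult],
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    alpha: float = 0.01,
) -> tuple[set[str], list[SMGRecord]]:
    """Consensus SMG call: eligible with P < alpha in every tumor sample and
    P >= alpha (or ineligible) in every normal sample."""
    by_gene: dict[str, dict[str, SMGSampleResult]] = {}
    for r in sample_results:
        by_gene.setdefault(r.gene_id, {})[r.sample_id] = r
    required = set(tumor_samples) | set(normal_samples)
    records = []
    for gene_id in sorted(by_gene):
        per_sample = by_gene[gene_id]
        if not required <= per_sample.keys():
            missing = sorted(required - per_sample.keys())
            log.warning("gene %s skipped: missing sample results %s", gene_id, missing)
            continue
        tumor_hit = all(
            per_sample[s].eligible and per_sample[s].pvalue < alpha for s in tumor_samples
        )
        normal_clean = all(
            (not per_sample[s].eligible) or per_sample[s].pvalue >= alpha
            for s in normal_samples
        )
        records.append(SMGRecord(gene_id=gene_id, per_sample=per_sample, is_smg=tumor_hit and normal_clean))
    return {r.gene_id for r in records if r.is_smg}, records


@dataclass(frozen=True)
class RateComparison:
    rate_smg: float
    rate_other: float
    pvalue: float
    n_smg: int
    n_other: int


def compare_mutation_rates(
    smg_set: set[str],
    all_genes: Iterable[str],
    mutations: Mapping[str, int],
    covered: Mapping[str, int],
    method: str = "ranksums",
) -> RateComparison:
    """Compare per-gene mutation rates (mutations / covered base) between the
    SMG group and all other genes.

    ``method`` is "ranksums" (two-sided Wilcoxon rank-sum, exact for small
    groups) or "welch" (Welch's t-test).
    """
    rates = {
        g: mutations.get(g, 0) / covered[g]
        for g in all_genes
        if covered.get(g, 0) > 0
    }
    grp_smg = np.array([r for g, r in rates.items() if g in smg_set])
    grp_other = np.array([r for g, r in rates.items() if g not in smg_set])
    if grp_smg.size == 0 or grp_other.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "ranksums":
        res = stats.mannwhitneyu(grp_smg, grp_other, alternative="two-sided", method="auto")
    elif method == "welch":
        res = stats.ttest_ind(grp_smg, grp_other, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RateComparison(
        rate_smg=float(grp_smg.mean()),
        rate_other=float(grp_other.mean()),
        pvalue=float(res.pvalue),
        n_smg=grp_smg.size,
        n_other=grp_other.size,
    )


def results_to_frame(records: Sequence[SMGRecord], sample_order: Sequence[str]) -> pd.DataFrame:
    """Flatten SMG records into the results table, with BH-adjusted columns
    (informational only; consensus calling uses raw P)."""
    from .expression import bh_adjust

    rows = []
    for rec in records:
        row: dict = {"gene_id": rec.gene_id, "is_smg": rec.is_smg}
        for sid in sample_order:
            r = rec.per_sample[sid]
            row[f"{sid}_covered"] = r.covered
            row[f"{sid}_stat"] = r.statistic
            row[f"{sid}_df"] = r.df
            row[f"{sid}_p"] = r.pvalue
            row[f"{sid}_eligible"] = r.eligible
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        for sid in sample_order:
            df[f"{sid}_padj"] = bh_adjust(df[f"{sid}_p"].to_numpy())
    return df
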