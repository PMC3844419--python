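"""Simplified negative-binomial differential expression between tumor and
normal groups.

This is a deliberately small stand-in for a full DE package: median-of-ratios
size factors, a per-gene method-of-moments dispersion pooled across the two
conditions, and a conditioned exact test on the group count sums, with
Benjamini-Hochberg correction across tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CONDITIONS = ("normal", "tumor")


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with a sample -> condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        for cond in CONDITIONS:
            if not any(self.conditions[s] == cond for s in self.counts.columns):
                raise ValueError(f"need at least one {cond!r} sample")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @classmethod
    def from_tsv(cls, path, conditions: dict[str, str]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, conditions=conditions)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors against the geometric-mean
    pseudo-reference; genes with any zero count are excluded from the median."""
    counts = m.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene with nonzero counts in every sample")
    sub = counts[nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if (pvals < 0).any() or (pvals > 1).any() or np.isnan(pvals).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _nb_pmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """NB pmf parameterised by mean/variance; Poisson when var <= mu."""
    if var <= mu * (1 + 1e-12) or mu == 0:
        return stats.poisson.pmf(x, mu)
    r = mu * mu / (var - mu)
    return stats.nbinom.pmf(x, r, r / (r + mu))


def _exact_test(kA: int, kB: int, sA: np.ndarray, sB: np.ndarray, alpha: float) -> float:
    """Two-sided conditioned exact test of the group sums under a shared mean.

    Conditions on S = kA + kB and sums the joint probabilities of all splits
    no more likely than the observed one.
    """
    S = kA + kB
    if S == 0:
        return 1.0
    q = S / (sA.sum() + sB.sum())
    muA, muB = q * sA.sum(), q * sB.sum()
    varA = muA + alpha * q * q * np.sum(sA**2)
    varB = muB + alpha * q * q * np.sum(sB**2)
    a = np.arange(S + 1)
    joint = _nb_pmf(a, muA, varA) * _nb_pmf(S - a, muB, varB)
    total = joint.sum()
    if total == 0:
        return 1.0
    p_obs = joint[kA]
    return float(min(1.0, joint[joint <= p_obs * (1 + 1e-7)].sum() / total))


def _mom_dispersion(z: np.ndarray, groups: list[np.ndarray], inv_s_means: list[float]) -> float:
    """Method-of-moments dispersion on normalized counts, pooled over groups."""
    alphas = []
    for idx, m_inv in zip(groups, inv_s_means):
        if idx.size < 2:
            continue
        zg = z[idx]
        mu = zg.mean()
        if mu <= 0:
            continue
        v = zg.var(ddof=1)
        alphas.append((v - mu * m_inv) / (mu * mu))
    if not alphas:
        return np.nan
    return float(np.mean(alphas))


def _pooled_floor(alphas: np.ndarray) -> float:
    """Cross-gene dispersion floor: with 2-per-group designs the per-gene
    moment estimate is far too noisy, so each gene is tested at no less than
    the genome-wide mean of the raw (unfloored, possibly negative) estimates
    — the unbiased pooled dispersion (conservative sharing strategy)."""
    alphas = alphas[np.isfinite(alphas)]
    if alphas.size == 0:
        return 1e-8
    return max(float(np.mean(alphas)), 1e-8)


@dataclass
class DEResult:
    gene_id: str
    base_mean_normal: float
    base_mean_tumor: float
    log2_fold_change: float
    pvalue: float
    padj: float
    tested: bool


def nb_test(
    m: CountMatrix,
    min_total: int = 10,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided NB exact test of tumor vs normal group sums.

    Genes with total count below ``min_total`` (and all-zero genes) get
    P = 1 and are flagged untested; BH adjustment runs across tested genes
    only.  ``dispersion`` overrides the per-gene estimate (useful for the
    Poisson limit).
    """
    s = size_factors(m)
    normals, tumors = m.samples("normal"), m.samples("tumor")
    cols = list(m.counts.columns)
    idxN = np.array([cols.index(x) for x in normals])
    idxT = np.array([cols.index(x) for x in tumors])
    counts = m.counts.to_numpy(dtype=np.int64)
    sf = s.to_numpy()
    z = counts / sf[None, :]
    inv_means = [float(np.mean(1.0 / sf[idxN])), float(np.mean(1.0 / sf[idxT]))]

    gene_alphas = np.array(
        [_mom_dispersion(z[i], [idxN, idxT], inv_means) for i in range(counts.shape[0])]
    )
    alpha_floor = _pooled_floor(gene_alphas[counts.sum(axis=1) >= min_total])

    rows = []
    pvals, tested_idx = [], []
    for i, gene_id in enumerate(m.counts.index):
        meanN = float(z[i, idxN].mean())
        meanT = float(z[i, idxT].mean())
        if meanN > 0 and meanT > 0:
            l2fc = float(np.log2(meanT / meanN))
        elif meanT > 0:
            l2fc = np.inf
        elif meanN > 0:
            l2fc = -np.inf
        else:
            l2fc = 0.0
        total = int(counts[i].sum())
        tested = total >= min_total
        if tested:
            own = float(gene_alphas[i]) if np.isfinite(gene_alphas[i]) else 1e-8
            alpha = dispersion if dispersion is not None else max(own, alpha_floor, 1e-8)
            p = _exact_test(int(counts[i, idxN].sum()), int(counts[i, idxT].sum()),
                            sf[idxN], sf[idxT], alpha)
            pvals.append(p)
            tested_idx.append(len(rows))
        else:
            p = 1.0
        rows.append(
            DEResult(
                gene_id=str(gene_id),
                base_mean_normal=meanN,
                base_mean_tumor=meanT,
                log2_fold_change=l2fc,
                pvalue=p,
                padj=np.nan,
                tested=tested,
            )
        )
    if pvals:
        adj = bh_adjust(np.array(pvals))
        for j, i_row in enumerate(tested_idx):
            rows[i_row].padj = float(adj[j])
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "base_mean_normal": [r.base_mean_normal for r in rows],
            "base_mean_tumor": [r.base_mean_tumor for r in rows],
            "log2_fold_change": [r.log2_fold_change for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "padj": [r.padj for r in rows],
            "tested": [r.tested for r in rows],
        }
    ).set_index("gene_id")
    return df
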