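"""Population differentiation and admixture statistics.

Per-site FST uses the Weir & Cockerham (1984) two-population
variance-component estimator computed from genotypes (observed heterozygosity
included), with the genome-wide value as a ratio of summed components.

The three-population admixture statistic f3(target; A, B) averages the
per-site term (c - a)(c - b) - c(1 - c)/(n_c - 1), where a, b, c are sample
alt-allele frequencies and n_c the target's non-missing allele-copy count;
the correction removes the bias from finite target sample size.  Standard
errors come from a weighted leave-one-block-out jackknife over contiguous
blocks of fixed genetic length, which absorbs linkage disequilibrium.
A significantly negative f3 (Z < -3) indicates the target is admixed between
populations related to the two sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset

Z_ADMIXED = -3.0


@dataclass
class FstSeries:
    """Per-site FST aligned to the dataset's variants; NaN marks undefined sites."""

    fst: np.ndarray
    a: np.ndarray  # between-population variance component
    d: np.ndarray  # total variance a + b + c
    estimator: str = "weir_cockerham_1984"

    @property
    def genome_wide(self) -> float:
        ok = ~np.isnan(self.fst)
        return float(np.sum(self.a[ok]) / np.sum(self.d[ok]))


@dataclass
class F3Result:
    target: str
    sourceA: str
    sourceB: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    @property
    def is_admixed(self) -> bool:
        return self.f3 < 0 and self.z < Z_ADMIXED


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _freq_het_n(genotypes: np.ndarray):
    """Per-site (alt freq, observed het rate, n diploids with data) for one group."""
    ok = genotypes != MISSING
    n = ok.sum(axis=0).astype(float)
    g = np.where(ok, genotypes, 0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = g.sum(axis=0) / (2 * n)
        h = np.where(ok, genotypes == 1, False).sum(axis=0) / n
    return p, h, n


def fst_per_site_matrices(gA: np.ndarray, gB: np.ndarray) -> FstSeries:
    """Weir-Cockerham two-population estimator from two genotype matrices."""
    p1, h1, n1 = _freq_het_n(gA)
    p2, h2, n2 = _freq_het_n(gB)
    r = 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_bar = (n1 + n2) / r
        nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        d = a + b + c
        fst = a / d
    bad = (n1 < 1) | (n2 < 1) | ~np.isfinite(fst)
    fst = np.where(bad, np.nan, fst)
    return FstSeries(fst=fst, a=np.where(bad, 0.0, a), d=np.where(bad, 0.0, d))


def fst_per_site(ds: Dataset, groupA: str, groupB: str) -> FstSeries:
    gA = ds.genotypes[ds.sample_indices(groupA)]
    gB = ds.genotypes[ds.sample_indices(groupB)]
    return fst_per_site_matrices(gA, gB)


# ---------------------------------------------------------------------------
# f3 admixture
# ---------------------------------------------------------------------------

def _block_index(variants: pd.DataFrame, block_cm: float) -> np.ndarray:
    """Contiguous genetic blocks of block_cm per chromosome, numbered genome-wide."""
    chrom_arr = variants["chrom"].to_numpy(object)
    cm = variants["pos_cM"].to_numpy(float)
    blocks = np.empty(len(variants), dtype=np.int64)
    offset = 0
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        local = np.floor((cm[sel] - cm[sel].min()) / block_cm).astype(np.int64)
        blocks[sel] = local + offset
        offset = blocks[sel].max() + 1
    return blocks


def _weighted_block_jackknife(terms: np.ndarray, blocks: np.ndarray):
    """Mean, SE and block count via the weighted delete-one-block jackknife.

    Blocks are weighted by their SNP counts (Busing et al. 1999, the
    convention of the standard three-population-test implementations).
    """
    uniq, inv = np.unique(blocks, return_inverse=True)
    B = uniq.size
    if B < 2:
        raise ValueError(f"need >=2 jackknife blocks, got {B}")
    n = terms.size
    m_b = np.bincount(inv).astype(float)
    sum_b = np.bincount(inv, weights=terms)
    total = terms.sum()
    theta = total / n
    theta_del = (total - sum_b) / (n - m_b)  # leave-one-block-out means
    h = n / m_b
    theta_j = B * theta - np.sum((1 - m_b / n) * theta_del)
    pseudo = h * theta - (h - 1) * theta_del
    var = np.mean((pseudo - theta_j) ** 2 / (h - 1))
    return float(theta), float(np.sqrt(var)), B


def f3_from_freqs(a, b, c, n_c, variants, block_cm: float,
                  labels=("target", "A", "B")) -> F3Result:
    """f3 from per-site frequency arrays (NaN = undefined; dropped complete-case)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    n_c = np.asarray(n_c, float)
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(c)) & (n_c >= 2)
    if ok.sum() == 0:
        raise ValueError("no usable sites for f3")
    term = (c[ok] - a[ok]) * (c[ok] - b[ok]) - c[ok] * (1 - c[ok]) / (n_c[ok] - 1)
    blocks = _block_index(variants, block_cm)[ok]
    f3, se, n_blocks = _weighted_block_jackknife(term, blocks)
    z = f3 / se if se > 0 else np.sign(f3) * np.inf
    return F3Result(target=labels[0], sourceA=labels[1], sourceB=labels[2],
                    f3=f3, se=se, z=float(z), n_snps=int(ok.sum()),
                    n_blocks=n_blocks)


def _group_freq_counts(ds: Dataset, idx: np.ndarray):
    g = ds.genotypes[idx].astype(float)
    miss = g == MISSING
    g[miss] = np.nan
    n_copies = 2 * np.sum(~miss, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(g, axis=0) / n_copies
    p[n_copies == 0] = np.nan
    return p, n_copies


def f3_admixture(ds: Dataset, target: str, sourceA: str, sourceB: str,
                 block_cm: float = 5.0) -> F3Result:
    """f3(target; A, B) with finite-target correction and block-jackknife Z."""
    c, n_c = _group_freq_counts(ds, ds.sample_indices(target))
    a, _ = _group_freq_counts(ds, ds.sample_indices(sourceA))
    b, _ = _group_freq_counts(ds, ds.sample_indices(sourceB))
    return f3_from_freqs(a, b, c, n_c, ds.variants, block_cm,
                         labels=(target, sourceA, sourceB))


def leave_one_out_screen(ds: Dataset, pool: str | list, domestic: str | list,
                         block_cm: float = 5.0) -> list[F3Result]:
    """Per-individual purity screen: f3(individual; pool-minus-individual, domestic).

    Individuals whose f3 is significantly negative (Z < -3) carry domestic
    admixture relative to the rest of the pool and are flagged via
    ``F3Result.is_admixed``.
    """
    pool_labels = [pool] if isinstance(pool, str) else list(pool)
    dom_labels = [domestic] if isinstance(domestic, str) else list(domestic)
    pool_idx = np.concatenate([ds.sample_indices(p) for p in pool_labels])
    pool_idx = np.unique(pool_idx)
    if pool_idx.size < 3:
        raise ValueError("pool must contain >=3 individuals")
    dom_idx = np.unique(np.concatenate([ds.sample_indices(p) for p in dom_labels]))

    b, _ = _group_freq_counts(ds, dom_idx)
    g_pool = ds.genotypes[pool_idx].astype(float)
    miss = g_pool == MISSING
    g_pool[miss] = np.nan
    copies = 2 * (~miss)
    pool_sum = np.nansum(g_pool, axis=0)
    pool_copies = copies.sum(axis=0)

    results = []
    for row, si in enumerate(pool_idx):
        gi = ds.genotypes[si].astype(float)
        ok_i = gi != MISSING
        c = np.where(ok_i, gi / 2.0, np.nan)
        n_c = np.where(ok_i, 2.0, 0.0)
        rest_copies = pool_copies - copies[row]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = (pool_sum - np.nan_to_num(gi * ok_i)) / rest_copies
        a[rest_copies == 0] = np.nan
        res = f3_from_freqs(a, b, c, n_c, ds.variants, block_cm,
                            labels=(ds.samples[si], "+".join(pool_labels) + "-minus",
                                    "+".join(dom_labels)))
        results.append(res)
    return results
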