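"""Selection scans: PBS with a randomization null, and XP-EHH.

PBS (population branch statistic): per-site pairwise FST values are turned
into branch lengths T(i,j) = -log(1 - FST(i,j)) and the target branch is
PBS = (T_AB + T_AC - T_BC)/2 for target A against two related populations
B and C.  Candidate regions are runs of at least ``min_run`` consecutive
SNPs above the 95th percentile of the genome-wide PBS distribution.  Because
the target group is tiny, a randomization null re-runs the scan on
pseudo-targets drawn from the pure pool; real windows that keep reappearing
under the null are artifacts of sample size or shared pool structure and are
flagged unreliable.

XP-EHH compares integrated extended-haplotype homozygosity (iHH) between two
populations per site: ln(iHH_A/iHH_B), standardized genome-wide.  Extreme
positive scores mark recent positive selection in A (here the domestic pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import Dataset
from .popgen_stats import FstSeries, fst_per_site_matrices

FST_CLAMP_MAX = 1.0 - 1e-8


@dataclass
class Window:
    chrom: str
    start_bp: int
    stop_bp: int
    n_snps: int

    def overlaps(self, other) -> bool:
        return (self.chrom == str(other.chrom)
                and self.start_bp <= other.stop_bp
                and self.stop_bp >= other.start_bp)


@dataclass
class PBSResult:
    table: pd.DataFrame  # chrom, pos_bp, T_AB, T_AC, T_BC, PBS (NaN = undefined)
    threshold: float | None = None
    windows: list = field(default_factory=list)

    @property
    def pbs(self) -> np.ndarray:
        return self.table["PBS"].to_numpy()


@dataclass
class XPEHHResult:
    table: pd.DataFrame  # chrom, pos_bp, ihh_a, ihh_b, raw, std
    threshold: float
    windows: list = field(default_factory=list)
    top_marker: tuple | None = None  # (chrom, pos_bp, std score)


@dataclass
class RandomizationReport:
    n_replicates: int
    replicate_window_counts: list
    real_windows: list
    recurrence: list  # fraction of replicates overlapping each real window
    unreliable: list  # bool per real window
    recurrence_max: float

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.replicate_window_counts))


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

def _t_branch(fst: np.ndarray, clamp: bool = True) -> np.ndarray:
    f = np.asarray(fst, float)
    if clamp:
        f = np.clip(f, 0.0, FST_CLAMP_MAX)
    return -np.log1p(-f)


def pbs_per_site(fst_ab: FstSeries, fst_ac: FstSeries, fst_bc: FstSeries,
                 variants: pd.DataFrame, clamp: bool = True) -> PBSResult:
    """Per-site PBS from three aligned FST series (A = target).

    FST is clamped to [0, 1 - 1e-8] before the log transform unless
    ``clamp=False``; sites undefined in any pair get NaN.
    """
    n = len(variants)
    if not (fst_ab.fst.size == fst_ac.fst.size == fst_bc.fst.size == n):
        raise ValueError("FST series are not aligned to the variant table")
    t_ab = _t_branch(fst_ab.fst, clamp)
    t_ac = _t_branch(fst_ac.fst, clamp)
    t_bc = _t_branch(fst_bc.fst, clamp)
    pbs = (t_ab + t_ac - t_bc) / 2.0
    table = pd.DataFrame({
        "chrom": variants["chrom"].to_numpy(object),
        "pos_bp": variants["pos_bp"].to_numpy(np.int64),
        "T_AB": t_ab, "T_AC": t_ac, "T_BC": t_bc, "PBS": pbs,
    })
    return PBSResult(table=table)


def pbs_windows(result: PBSResult, pct: float = 0.95, min_run: int = 5) -> PBSResult:
    """Runs of >= min_run consecutive SNPs strictly above the pct quantile.

    The cutoff is the linear-interpolation empirical quantile of all defined
    PBS values; windows span the first to the last SNP of a run.
    """
    vals = result.pbs
    ok = ~np.isnan(vals)
    result.windows = []
    if ok.sum() < min_run:
        return result
    cutoff = float(np.quantile(vals[ok], pct))
    result.threshold = cutoff
    chrom_arr = result.table["chrom"].to_numpy(object)
    pos = result.table["pos_bp"].to_numpy(np.int64)
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        hit = ok[idx] & (vals[idx] > cutoff)
        run = 0
        for k in range(len(idx) + 1):
            if k < len(idx) and hit[k]:
                run += 1
                continue
            if run >= min_run:
                g = idx[k - run:k]
                result.windows.append(Window(str(chrom), int(pos[g[0]]),
                                             int(pos[g[-1]]), run))
            run = 0
    return result


def pbs_scan(ds: Dataset, target, pure, ref, pct: float = 0.95,
             min_run: int = 5) -> PBSResult:
    """Convenience wrapper: FSTs + PBS + windows for named sample groups.

    Each of target/pure/ref may be a population label or an explicit list of
    sample IDs (so pseudo-target draws can be scanned with the same code)."""
    gi = [_group_matrix(ds, g) for g in (target, pure, ref)]
    res = pbs_per_site(fst_per_site_matrices2(gi[0], gi[1]),
                       fst_per_site_matrices2(gi[0], gi[2]),
                       fst_per_site_matrices2(gi[1], gi[2]), ds.variants)
    return pbs_windows(res, pct=pct, min_run=min_run)


def _group_matrix(ds: Dataset, group) -> np.ndarray:
    if isinstance(group, str):
        return ds.genotypes[ds.sample_indices(group)]
    pos = {s: i for i, s in enumerate(ds.samples)}
    return ds.genotypes[[pos[s] for s in group]]


def fst_per_site_matrices2(gA, gB) -> FstSeries:
    return fst_per_site_matrices(gA, gB)


def pbs_randomization(ds: Dataset, target, pure_pool, ref_wild,
                      n_target: int = 3, R: int = 20,
                      recurrence_max: float = 0.2, pct: float = 0.95,
                      min_run: int = 5, seed: int = 0) -> RandomizationReport:
    """Pseudo-target randomization null for the PBS window scan.

    Each replicate draws ``n_target`` individuals from the pure pool without
    replacement as a pseudo-target and re-runs the full window scan against
    (pure pool minus the draw, ref_wild).  A real window overlapped by
    pseudo-target windows in more than ``recurrence_max`` of replicates is
    flagged unreliable: the signal is reproducible from non-admixed samples,
    so it reflects sample size or pool substructure rather than the target.
    """
    pool = ds.samples_in(pure_pool) if isinstance(pure_pool, str) else list(pure_pool)
    if len(pool) <= n_target:
        raise ValueError("pure pool too small for pseudo-target draws")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    real = pbs_scan(ds, target, pure_pool, ref_wild, pct=pct, min_run=min_run)
    counts, overlap_hits = [], np.zeros(len(real.windows))
    for _ in range(R):
        draw = list(rng.choice(pool, size=n_target, replace=False))
        rest = [s for s in pool if s not in draw]
        rep = pbs_scan(ds, draw, rest, ref_wild, pct=pct, min_run=min_run)
        counts.append(len(rep.windows))
        for i, w in enumerate(real.windows):
            if any(w.overlaps(rw) for rw in rep.windows):
                overlap_hits[i] += 1
    rec = (overlap_hits / R).tolist()
    return RandomizationReport(
        n_replicates=R, replicate_window_counts=counts,
        real_windows=real.windows, recurrence=rec,
        unreliable=[r > recurrence_max for r in rec],
        recurrence_max=recurrence_max)


# ---------------------------------------------------------------------------
# EHH / XP-EHH
# ---------------------------------------------------------------------------

def _group_homozygosity(group_ids: np.ndarray) -> float:
    """Sum of C(n_h, 2)/C(n, 2) over distinct extended haplotypes."""
    _, counts = np.unique(group_ids, return_counts=True)
    n = group_ids.size
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def ehh_at_core(haps: np.ndarray, core_index: int, variants: pd.DataFrame,
                cutoff: float = 0.05):
    """EHH curve around a core marker and its integral iHH (cM units).

    EHH at marker j is the probability that two random haplotypes from the
    population are identical over every SNP from the core out to j
    (inclusive).  The extension proceeds outward in each direction until EHH
    drops below ``cutoff`` (that final point is included in the integral) or
    the chromosome ends.  iHH is the trapezoid integral of EHH over genetic
    distance, both sides summed.

    Returns (curve, ihh): curve is a DataFrame (pos_bp, pos_cM, ehh) in
    genomic order including the core.
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need >=2 haplotypes")
    chrom_arr = variants["chrom"].to_numpy(object)
    cm = variants["pos_cM"].to_numpy(float)
    pos = variants["pos_bp"].to_numpy(np.int64)
    chrom = chrom_arr[core_index]
    cidx = np.flatnonzero(chrom_arr == chrom)
    k0 = int(np.searchsorted(cidx, core_index))

    ehh0 = _group_homozygosity(haps[:, core_index])
    sides = []
    for step in (1, -1):
        pts_cm, pts_ehh = [cm[core_index]], [ehh0]
        gid = np.unique(haps[:, core_index], return_inverse=True)[1]
        ehh = ehh0
        k = k0
        denom = n * (n - 1)
        while ehh >= cutoff:
            k += step
            if k < 0 or k >= len(cidx):
                break
            j = cidx[k]
            _, gid, counts = np.unique(gid * 2 + haps[:, j],
                                       return_inverse=True, return_counts=True)
            ehh = float(np.sum(counts * (counts - 1)) / denom)
            pts_cm.append(cm[j])
            pts_ehh.append(ehh)
        sides.append((np.array(pts_cm), np.array(pts_ehh)))

    ihh = 0.0
    for pts_cm, pts_ehh in sides:
        if pts_cm.size > 1:
            ihh += abs(np.trapezoid(pts_ehh, pts_cm))
    right, left = sides
    span = cidx[k0 - (left[0].size - 1): k0 + right[0].size]
    curve = pd.DataFrame({
        "pos_bp": pos[span],
        "pos_cM": np.concatenate([left[0][::-1], right[0][1:]]),
        "ehh": np.concatenate([left[1][::-1], right[1][1:]]),
    })
    return curve, ihh


def merge_markers(chroms, positions, merge_bp: int) -> list:
    """Merge candidate marker positions (genomic order) into windows when
    successive markers on one chromosome lie within merge_bp."""
    windows: list[Window] = []
    for c, p in zip(chroms, positions):
        if (windows and windows[-1].chrom == c
                and p - windows[-1].stop_bp <= merge_bp):
            windows[-1].stop_bp = int(p)
            windows[-1].n_snps += 1
        else:
            windows.append(Window(c, int(p), int(p), 1))
    return windows


def _ihh_all_sites(haps: np.ndarray, variants: pd.DataFrame,
                   cutoff: float) -> np.ndarray:
    return np.array([ehh_at_core(haps, j, variants, cutoff)[1]
                     for j in range(len(variants))])


def xpehh_scan(haps_a: np.ndarray, haps_b: np.ndarray, variants: pd.DataFrame,
               cutoff: float = 0.05, pct: float = 0.95,
               merge_bp: int = 500_000) -> XPEHHResult:
    """Cross-population EHH scan: positive scores = selection in population A.

    Per site, raw = ln(iHH_A / iHH_B); sites where either iHH is 0 are
    dropped.  Scores are standardized genome-wide; candidate markers are
    those with standardized score at or above the ``pct`` quantile of the
    standardized distribution, merged into windows when within ``merge_bp``.
    """
    ihh_a = _ihh_all_sites(np.asarray(haps_a), variants, cutoff)
    ihh_b = _ihh_all_sites(np.asarray(haps_b), variants, cutoff)
    ok = (ihh_a > 0) & (ihh_b > 0)
    raw = np.full(len(variants), np.nan)
    raw[ok] = np.log(ihh_a[ok] / ihh_b[ok])
    usable = raw[ok]
    if usable.size < 2 or np.std(usable) == 0:
        raise ValueError("cannot standardize: <2 usable sites or zero variance")
    std = np.full_like(raw, np.nan)
    std[ok] = (raw[ok] - usable.mean()) / usable.std()
    thr = float(np.quantile(std[ok], pct))

    chrom_arr = variants["chrom"].to_numpy(object)
    pos = variants["pos_bp"].to_numpy(np.int64)
    cand = np.flatnonzero(ok & (std >= thr))
    windows = merge_markers([str(c) for c in chrom_arr[cand]], pos[cand], merge_bp)
    top = None
    if cand.size:
        jt = cand[np.argmax(std[cand])]
        top = (str(chrom_arr[jt]), int(pos[jt]), float(std[jt]))
    table = pd.DataFrame({"chrom": chrom_arr, "pos_bp": pos,
                          "ihh_a": ihh_a, "ihh_b": ihh_b, "raw": raw, "std": std})
    return XPEHHResult(table=table, threshold=thr, windows=windows, top_marker=top)
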