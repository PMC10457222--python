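"""Two-source local-ancestry inference on phased haplotypes.

A haplotype of an admixed individual is modelled as a 2-state hidden Markov
chain along genetic distance: hidden state wild or domestic, prior domestic
proportion m, and a switch process calibrated to g generations since
admixture - between adjacent SNPs d Morgans apart the ancestry is redrawn
from the prior with probability 1 - exp(-g d).  Emissions are the source
populations' (smoothed) allele frequencies.  Exact posteriors come from the
scaled forward-backward recursion; calls use a hard threshold (default 0.9),
with sites between the thresholds labelled unassigned and excluded from
per-individual summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import Dataset

CALL_WILD, CALL_DOMESTIC, CALL_UNASSIGNED = 0, 1, -1
CALL_NAME = {CALL_WILD: "wild", CALL_DOMESTIC: "domestic", CALL_UNASSIGNED: "unassigned"}


@dataclass
class AncestryModel:
    """HMM parameters: g generations, prior m, smoothed source frequencies."""

    g: float
    m: float
    wild_freqs: np.ndarray
    domestic_freqs: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1)")
        self.wild_freqs = np.asarray(self.wild_freqs, float)
        self.domestic_freqs = np.asarray(self.domestic_freqs, float)
        for name, f in (("wild", self.wild_freqs), ("domestic", self.domestic_freqs)):
            if np.any(f <= 0) or np.any(f >= 1):
                raise ValueError(f"{name} frequencies must lie strictly in (0, 1); "
                                 "smooth them first")

    @classmethod
    def from_frequencies(cls, wild_raw, domestic_raw, n_wild_haps: int,
                         n_dom_haps: int, g: float = 20.0, m: float = 0.2):
        """Build a model from raw panel frequencies with pseudo-count smoothing.

        epsilon = 1/(n_haps + 2) per source: frequency -> (count + 1)/(n + 2),
        so fixed sites never produce zero-likelihood emissions.
        """
        wild_raw = np.asarray(wild_raw, float)
        domestic_raw = np.asarray(domestic_raw, float)
        fw = (wild_raw * n_wild_haps + 1) / (n_wild_haps + 2)
        fd = (domestic_raw * n_dom_haps + 1) / (n_dom_haps + 2)
        eps = 1.0 / (max(n_wild_haps, n_dom_haps) + 2)
        return cls(g=g, m=m, wild_freqs=fw, domestic_freqs=fd, epsilon=eps)

    @classmethod
    def from_dataset(cls, ds: Dataset, wild_pop, domestic_pops,
                     g: float = 20.0, m: float = 0.2):
        """Panel frequencies from phased haplotypes of the named populations;
        the domestic source pools the listed breeds."""
        wild_pops = [wild_pop] if isinstance(wild_pop, str) else list(wild_pop)
        dom_pops = ([domestic_pops] if isinstance(domestic_pops, str)
                    else list(domestic_pops))
        wrows = np.concatenate([ds.haplotype_indices(p) for p in wild_pops])
        drows = np.concatenate([ds.haplotype_indices(p) for p in dom_pops])
        wf = ds.haplotypes[wrows].mean(axis=0)
        df = ds.haplotypes[drows].mean(axis=0)
        return cls.from_frequencies(wf, df, len(wrows), len(drows), g=g, m=m)

    @classmethod
    def from_dataset_samples(cls, ds: Dataset, wild_samples: list,
                             domestic_pops, g: float = 20.0, m: float = 0.2):
        """Like ``from_dataset`` but the wild panel is an explicit sample list
        (e.g. the screen's surviving pure individuals)."""
        pos = {s: i for i, s in enumerate(ds.samples)}
        wrows = np.array([r for s in wild_samples
                          for r in (2 * pos[s], 2 * pos[s] + 1)], dtype=int)
        dom_pops = ([domestic_pops] if isinstance(domestic_pops, str)
                    else list(domestic_pops))
        drows = np.concatenate([ds.haplotype_indices(p) for p in dom_pops])
        wf = ds.haplotypes[wrows].mean(axis=0)
        df = ds.haplotypes[drows].mean(axis=0)
        return cls.from_frequencies(wf, df, len(wrows), len(drows), g=g, m=m)


@dataclass
class AncestryPosterior:
    """Per-haplotype per-site P(domestic) with optional thresholded calls."""

    p_domestic: np.ndarray  # (n_haps, n_sites)
    hap_ids: list
    calls: np.ndarray | None = None  # same shape, values CALL_*
    threshold: float | None = None

    @property
    def n_haps(self) -> int:
        return self.p_domestic.shape[0]


@dataclass
class IndividualAncestrySummary:
    sample: str
    domestic_proportion: float  # NaN if no assigned sites
    per_chromosome: dict
    n_assigned: int


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------

def _emission_loglik(haps: np.ndarray, model: AncestryModel):
    """(H, n_sites, 2) emission likelihoods; missing alleles (<0) contribute 1."""
    fw, fd = model.wild_freqs, model.domestic_freqs
    a = haps.astype(float)
    lw = np.where(a < 0, 1.0, np.where(a == 1, fw, 1 - fw))
    ld = np.where(a < 0, 1.0, np.where(a == 1, fd, 1 - fd))
    return lw, ld


def fit_posteriors(haps: np.ndarray, model: AncestryModel,
                   variants: pd.DataFrame, hap_ids=None) -> AncestryPosterior:
    """Exact posterior P(domestic) per site per haplotype via scaled
    forward-backward, processed per chromosome.

    ``haps``: (H, n_sites) 0/1 alleles aligned to ``variants`` (sorted, with
    pos_cM present).  Numerically stable for arbitrarily many sites.
    """
    haps = np.atleast_2d(np.asarray(haps))
    H, n_sites = haps.shape
    if n_sites != len(variants):
        raise ValueError("haplotype matrix does not match variant table")
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(H)]
    lw_all, ld_all = _emission_loglik(haps, model)
    m, g = model.m, model.g
    prior = np.array([1 - m, m])
    post = np.empty((H, n_sites), dtype=float)

    chrom_arr = variants["chrom"].to_numpy(object)
    cm = variants["pos_cM"].to_numpy(float)
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        T = len(idx)
        lw = lw_all[:, idx]
        ld = ld_all[:, idx]
        d = np.diff(cm[idx]) / 100.0  # Morgans
        stay = np.exp(-g * d)

        alpha = np.empty((T, H, 2))
        scale = np.empty((T, H))
        a0 = np.stack([prior[0] * lw[:, 0], prior[1] * ld[:, 0]], axis=1)
        scale[0] = a0.sum(axis=1)
        alpha[0] = a0 / scale[0][:, None]
        for t in range(1, T):
            r = stay[t - 1]
            # transition: stay with prob r, else redraw from prior
            pw = alpha[t - 1, :, 0] * r + (1 - r) * prior[0]
            pd_ = alpha[t - 1, :, 1] * r + (1 - r) * prior[1]
            at = np.stack([pw * lw[:, t], pd_ * ld[:, t]], axis=1)
            scale[t] = at.sum(axis=1)
            alpha[t] = at / scale[t][:, None]

        beta = np.empty((T, H, 2))
        beta[T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            r = stay[t]
            bw = beta[t + 1, :, 0] * lw[:, t + 1]
            bd = beta[t + 1, :, 1] * ld[:, t + 1]
            mix = (1 - r) * (prior[0] * bw + prior[1] * bd)
            bt = np.stack([r * bw + mix, r * bd + mix], axis=1)
            beta[t] = bt / scale[t + 1][:, None]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        post[:, idx] = gamma[:, :, 1].T
    return AncestryPosterior(p_domestic=post, hap_ids=list(hap_ids))


def call_ancestry(post: AncestryPosterior, threshold: float = 0.9) -> AncestryPosterior:
    """Threshold posteriors into domestic / wild / unassigned calls.

    call = domestic iff P >= threshold, wild iff P <= 1 - threshold, else
    unassigned.  threshold must exceed 0.5 or the two call regions overlap.
    """
    if threshold <= 0.5:
        raise ValueError("threshold must be > 0.5")
    p = post.p_domestic
    eps = 1e-9  # tolerate float representation at the exact boundaries
    calls = np.full(p.shape, CALL_UNASSIGNED, dtype=np.int8)
    calls[p >= threshold - eps] = CALL_DOMESTIC
    calls[p <= (1 - threshold) + eps] = CALL_WILD
    post.calls = calls
    post.threshold = threshold
    return post


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _sample_of(hap_id: str) -> str:
    return hap_id.rsplit("_h", 1)[0]


def global_proportions(post: AncestryPosterior,
                       variants: pd.DataFrame) -> list[IndividualAncestrySummary]:
    """Per-individual domestic proportion over assigned sites, averaged over
    the two haplotypes, with a per-chromosome breakdown."""
    if post.calls is None:
        raise ValueError("call_ancestry must be run first")
    chrom_arr = variants["chrom"].to_numpy(object)
    chroms = list(dict.fromkeys(chrom_arr))
    by_sample: dict[str, list[int]] = {}
    for i, h in enumerate(post.hap_ids):
        by_sample.setdefault(_sample_of(h), []).append(i)
    out = []
    for sample, rows in by_sample.items():
        props, per_chrom = [], {}
        for i in rows:
            c = post.calls[i]
            assigned = c != CALL_UNASSIGNED
            props.append(np.nan if assigned.sum() == 0
                         else (c == CALL_DOMESTIC).sum() / assigned.sum())
        for chrom in chroms:
            sel = chrom_arr == chrom
            vals = []
            for i in rows:
                c = post.calls[i][sel]
                n_as = (c != CALL_UNASSIGNED).sum()
                vals.append(np.nan if n_as == 0 else (c == CALL_DOMESTIC).sum() / n_as)
            per_chrom[chrom] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
        n_assigned = int(sum((post.calls[i] != CALL_UNASSIGNED).sum() for i in rows))
        prop = float(np.nanmean(props)) if not np.all(np.isnan(props)) else np.nan
        out.append(IndividualAncestrySummary(sample=sample, domestic_proportion=prop,
                                             per_chromosome=per_chrom,
                                             n_assigned=n_assigned))
    return out


@dataclass
class CalledTract:
    hap_id: str
    chrom: str
    start_bp: int
    stop_bp: int
    start_cM: float
    stop_cM: float
    ancestry: str
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.stop_bp - self.start_bp + 1

    @property
    def length_morgans(self) -> float:
        return (self.stop_cM - self.start_cM) / 100.0


def extract_tracts(post: AncestryPosterior, variants: pd.DataFrame) -> dict:
    """Maximal runs of identical non-unassigned calls as tracts.

    Interior unassigned sites flanked by the same call do not break a tract
    (they are absorbed into it); an unassigned site between different calls
    terminates the earlier tract.  Tract coordinates span the first to the
    last SNP of the run.
    """
    if post.calls is None:
        raise ValueError("call_ancestry must be run first")
    chrom_arr = variants["chrom"].to_numpy(object)
    pos = variants["pos_bp"].to_numpy(np.int64)
    cm = variants["pos_cM"].to_numpy(float)
    out: dict = {}
    for i, hap in enumerate(post.hap_ids):
        tracts = []
        for chrom in dict.fromkeys(chrom_arr):
            idx = np.flatnonzero(chrom_arr == chrom)
            calls = post.calls[i][idx]
            called = np.flatnonzero(calls != CALL_UNASSIGNED)
            if called.size == 0:
                continue
            run_start = called[0]
            prev = called[0]
            cur = calls[called[0]]
            for k in called[1:]:
                if calls[k] != cur:
                    tracts.append(_mk_tract(hap, chrom, idx, run_start, prev,
                                            calls, pos, cm, cur))
                    run_start = k
                    cur = calls[k]
                prev = k
            tracts.append(_mk_tract(hap, chrom, idx, run_start, prev,
                                    calls, pos, cm, cur))
        out[hap] = tracts
    return out


def _mk_tract(hap, chrom, idx, a, b, calls, pos, cm, call) -> CalledTract:
    gidx = idx[a:b + 1]
    return CalledTract(hap_id=hap, chrom=str(chrom),
                       start_bp=int(pos[gidx[0]]), stop_bp=int(pos[gidx[-1]]),
                       start_cM=float(cm[gidx[0]]), stop_cM=float(cm[gidx[-1]]),
                       ancestry=CALL_NAME[int(call)],
                       n_snps=int(np.sum(calls[a:b + 1] != CALL_UNASSIGNED)))


# ---------------------------------------------------------------------------
# admixture-date utilities
# ---------------------------------------------------------------------------

def estimate_generations_from_tracts(tracts, m: float) -> float:
    """Generations since admixture from the exponential tract-length model.

    Domestic tract lengths are ~ Exp(g (1 - m)) in Morgans, so
    g_hat = 1 / (mean length x (1 - m)).  ``tracts`` is any iterable of
    tract objects with a ``length_morgans`` (or Morgan-valued) attribute,
    or a flat iterable of lengths in Morgans; only domestic tracts should
    be supplied when objects carry no ancestry label.
    """
    lengths = []
    for t in tracts:
        if hasattr(t, "length_morgans"):
            if getattr(t, "ancestry", "domestic") == "domestic":
                lengths.append(t.length_morgans)
        else:
            lengths.append(float(t))
    if len(lengths) < 5:
        raise ValueError(f"need >=5 domestic tracts, got {len(lengths)}")
    mean_len = float(np.mean(lengths))
    if mean_len <= 0:
        raise ValueError("mean tract length must be positive")
    return 1.0 / (mean_len * (1.0 - m))


def expected_backcross_proportion(k: int) -> float:
    """Expected domestic percentage after k backcross generations into the wild.

    The pure domestic founder is generation 0 (100%); the proportion halves
    every backcross generation: 100 x (1/2)^k, e.g. 12.5% at k = 3.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return 100.0 * 0.5**k


GENERATION_TIME_YEARS = 5.0


def generations_to_years(g: float, generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Calendar dating of an admixture event (wild boar generation time 5 y)."""
    return g * generation_time
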