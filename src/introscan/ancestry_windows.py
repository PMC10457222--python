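"""Domestic-ancestry enrichment windows across hybrid haplotypes.

At each SNP the domestic fraction is the number of hybrid haplotypes called
domestic over the total number of hybrid haplotypes (unassigned haplotypes
stay in the denominator).  Maximal runs of consecutive SNPs whose fraction
meets a threshold p become enrichment windows; with 6 hybrid haplotypes the
reported thresholds are p0.67 (>= 4/6) and p0.83 (>= 5/6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .local_ancestry import CALL_DOMESTIC, AncestryPosterior

P067 = 2 / 3 - 1e-9   # >= 4 of 6 haplotypes
P083 = 5 / 6 - 1e-9   # >= 5 of 6 haplotypes


@dataclass
class EnrichmentWindow:
    chrom: str
    start_bp: int
    stop_bp: int
    n_snps: int
    min_fraction: float  # smallest per-site domestic fraction inside the window
    label: str

    @property
    def length_bp(self) -> int:
        return self.stop_bp - self.start_bp + 1


def per_site_domestic_fraction(post: AncestryPosterior) -> np.ndarray:
    """Fraction of hybrid haplotypes called domestic at each site."""
    if post.calls is None:
        raise ValueError("call_ancestry must be run first")
    H = post.n_haps
    if H == 0:
        raise ValueError("no hybrid haplotypes")
    return (post.calls == CALL_DOMESTIC).sum(axis=0) / H


def enrichment_windows(fractions: np.ndarray, variants: pd.DataFrame,
                       p: float, min_snps: int = 2,
                       label: str | None = None) -> list[EnrichmentWindow]:
    """Maximal runs of >= min_snps consecutive SNPs with fraction >= p.

    No gap tolerance: a single below-threshold SNP ends a window.  Windows
    span the first to the last SNP of the run (1-based, closed).
    """
    fractions = np.asarray(fractions, float)
    if fractions.size != len(variants):
        raise ValueError("fractions not aligned to variants")
    if label is None:
        label = f"p{p:.2f}"
    chrom_arr = variants["chrom"].to_numpy(object)
    pos = variants["pos_bp"].to_numpy(np.int64)
    out: list[EnrichmentWindow] = []
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        hit = fractions[idx] >= p
        for a, b in _runs(hit):
            if b - a + 1 >= min_snps:
                g = idx[a:b + 1]
                out.append(EnrichmentWindow(
                    chrom=str(chrom), start_bp=int(pos[g[0]]),
                    stop_bp=int(pos[g[-1]]), n_snps=len(g),
                    min_fraction=float(fractions[g].min()), label=label))
    return out


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size - 1]
    yield from zip(starts, stops)


def window_report(windows: list[EnrichmentWindow],
                  selection_windows=None) -> pd.DataFrame:
    """Tabular report (Chromosome, Start (bp), Stop (bp), ...).

    Windows intersecting any interval in ``selection_windows`` (iterable of
    objects or tuples with chrom/start/stop) are marked - the analogue of
    bolding windows confirmed by a selection scan.
    """
    sel = []
    for w in selection_windows or []:
        if hasattr(w, "chrom"):
            sel.append((str(w.chrom), int(w.start_bp), int(w.stop_bp)))
        else:
            sel.append((str(w[0]), int(w[1]), int(w[2])))
    rows = []
    for w in windows:
        hit = any(c == w.chrom and s <= w.stop_bp and e >= w.start_bp
                  for c, s, e in sel)
        rows.append((w.chrom, w.start_bp, w.stop_bp, w.n_snps, w.label, hit))
    return pd.DataFrame(rows, columns=["Chromosome", "Start (bp)", "Stop (bp)",
                                       "n_snps", "threshold", "intersects_selection"])
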