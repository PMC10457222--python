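#!/usr/bin/env python
"""Selection scans: PBS on the hybrids and XP-EHH on the domestic pool.

PBS contrasts the flagged hybrids (A) against the pure target-island wild
boar (B) and the mainland reference wild boar (C); candidate windows are
runs of >= 5 consecutive SNPs above the 95th percentile, stress-tested by
re-running the scan on pseudo-targets drawn from the pure pool.  XP-EHH
contrasts the pooled domestic breeds against the pure wild sample; extreme
positive standardized scores mark selection in the domestic pool.

Writes results/{pbs_per_site.tsv, pbs_windows.tsv, pbs_randomization.tsv,
xpehh_per_site.tsv, xpehh_windows.tsv, selection_tracks.png}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from introscan import selection_scan as ss
from introscan.genotype_io import read_dataset
from introscan.synthetic_data import DOMESTIC_POPS

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    ds = read_dataset(ROOT / "study" / "study.vcf",
                      popmap_path=ROOT / "study" / "popmap.tsv",
                      genetic_map_path=ROOT / "study" / "genetic_map.tsv")
    hybrids = (ROOT / "hybrids.txt").read_text().split()
    pure = [s for s in ds.samples_in("wild_pure") if s not in hybrids]

    pbs = ss.pbs_scan(ds, hybrids, pure, "wild_ref")
    pbs.table.to_csv(ROOT / "pbs_per_site.tsv", sep="\t", index=False)
    pd.DataFrame([vars(w) for w in pbs.windows]).to_csv(
        ROOT / "pbs_windows.tsv", sep="\t", index=False)
    print(f"PBS: cutoff {pbs.threshold:.4f}, {len(pbs.windows)} windows")

    rand = ss.pbs_randomization(ds, hybrids, pure, "wild_ref",
                                n_target=len(hybrids), R=20, seed=SEED)
    pd.DataFrame({
        "window": [f"{w.chrom}:{w.start_bp}-{w.stop_bp}" for w in rand.real_windows],
        "recurrence": rand.recurrence, "unreliable": rand.unreliable,
    }).to_csv(ROOT / "pbs_randomization.tsv", sep="\t", index=False)
    print(f"randomization: mean pseudo-target window count "
          f"{rand.mean_count:.2f} over {rand.n_replicates} replicates")

    dom = np.concatenate([ds.haplotype_indices(p) for p in DOMESTIC_POPS])
    pure_rows = np.concatenate([[2 * i, 2 * i + 1] for i, s in
                                enumerate(ds.samples) if s in pure])
    xp = ss.xpehh_scan(ds.haplotypes[dom], ds.haplotypes[pure_rows], ds.variants)
    xp.table.to_csv(ROOT / "xpehh_per_site.tsv", sep="\t", index=False)
    pd.DataFrame([vars(w) for w in xp.windows]).to_csv(
        ROOT / "xpehh_windows.tsv", sep="\t", index=False)
    print(f"XP-EHH: {len(xp.windows)} candidate windows; "
          f"top marker {xp.top_marker}")

    plot_tracks(pbs, xp)


def plot_tracks(pbs, xp) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(11, 5), sharex=True)
    for ax, (tab, col, name, thr) in zip(axes, [
            (pbs.table, "PBS", "PBS", pbs.threshold),
            (xp.table, "std", "XP-EHH (sd units)", xp.threshold)]):
        x = np.arange(len(tab))
        ax.scatter(x, tab[col], s=2, c=pd.factorize(tab["chrom"])[0] % 2,
                   cmap="coolwarm")
        if thr is not None:
            ax.axhline(thr, color="k", lw=0.6, ls="--")
        ax.set_ylabel(name)
    axes[1].set_xlabel("SNP index (chromosomes alternate in colour)")
    fig.tight_layout()
    fig.savefig(ROOT / "selection_tracks.png", dpi=120)


if __name__ == "__main__":
    main()
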