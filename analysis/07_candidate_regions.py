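#!/usr/bin/env python
"""Candidate adaptively introgressed regions.

Intersects the domestic-ancestry enrichment windows with the PBS and XP-EHH
selection windows, and looks up genes within +/-100 kb of the top XP-EHH
marker against a small synthetic annotation (generated here; stands in for
a RefSeq table).  Writes results/candidate_regions.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from introscan import annotate as ann
from introscan.selection_scan import Window

ROOT = Path(__file__).resolve().parents[1] / "results"


def synthetic_annotation(rng) -> list:
    """Synthetic gene models: ~12 genes per chromosome, 10-200 kb long."""
    genes = []
    for chrom in [str(c) for c in range(1, 19)]:
        starts = np.sort(rng.integers(1, 124_000_000, size=12))
        for k, s in enumerate(starts):
            genes.append(ann.GeneRecord(chrom, int(s),
                                        int(s + rng.integers(10_000, 200_000)),
                                        f"GENE{chrom}_{k}"))
    return genes


def load_windows(path, label):
    if not path.exists():
        return []
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    cols = {c.lower().split(" ")[0]: c for c in df.columns}
    return [Window(str(r[cols["chromosome"] if "chromosome" in cols else "chrom"]),
                   int(r[cols.get("start", "start_bp")]),
                   int(r[cols.get("stop", "stop_bp")]), 0)
            for _, r in df.iterrows()]


def main() -> None:
    enrich = load_windows(ROOT / "enrichment_windows.tsv", "enrichment")
    pbs = load_windows(ROOT / "pbs_windows.tsv", "PBS")
    xp = load_windows(ROOT / "xpehh_windows.tsv", "XP-EHH")
    regions = (ann.intersect_windows(enrich, pbs, "enrichment", "PBS")
               + ann.intersect_windows(enrich, xp, "enrichment", "XP-EHH"))

    genes = synthetic_annotation(np.random.default_rng(99))
    xp_table = pd.read_csv(ROOT / "xpehh_per_site.tsv", sep="\t",
                           dtype={"chrom": str})
    top = xp_table.loc[xp_table["std"].idxmax()]
    near = ann.genes_near_marker(genes, str(top["chrom"]), int(top["pos_bp"]))
    for r in regions:
        mid = (r.start_bp + r.stop_bp) // 2
        r.genes = ann.genes_near_marker(genes, r.chrom, mid)

    table = ann.candidate_table(regions)
    table.to_csv(ROOT / "candidate_regions.tsv", sep="\t", index=False)
    print(f"{len(regions)} candidate regions "
          f"(enrichment x selection overlaps)")
    print(table.to_string(index=False))
    print(f"\ntop XP-EHH marker {top['chrom']}:{int(top['pos_bp'])} "
          f"(score {top['std']:.2f} sd); genes within 100 kb: "
          f"{[g.name for g in near] or 'none'}")


if __name__ == "__main__":
    main()
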