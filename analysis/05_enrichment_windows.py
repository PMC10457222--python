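#!/usr/bin/env python
"""Domestic-ancestry enrichment windows across the hybrid haplotypes.

Aggregates the thresholded ancestry calls of the 6 hybrid haplotypes into
per-site domestic fractions and reports maximal windows where at least 4/6
(p0.67) or 5/6 (p0.83) haplotypes are domestic - the high-domestic-windows
table of the analysis.  Writes results/enrichment_windows.tsv.
"""

from pathlib import Path

import pandas as pd

from introscan import ancestry_windows as aw
from introscan.genotype_io import read_dataset
from introscan.local_ancestry import CALL_NAME

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_dataset(ROOT / "study" / "study.vcf",
                      popmap_path=ROOT / "study" / "popmap.tsv",
                      genetic_map_path=ROOT / "study" / "genetic_map.tsv")
    hybrids = (ROOT / "hybrids.txt").read_text().split()
    post_table = pd.read_csv(ROOT / "ancestry_posteriors.tsv", sep="\t")
    hyb_haps = [h for h in post_table["haplotype"].unique()
                if h.rsplit("_h", 1)[0] in hybrids]

    code = {v: k for k, v in CALL_NAME.items()}
    import numpy as np

    from introscan.local_ancestry import AncestryPosterior

    calls = np.stack([
        post_table[post_table["haplotype"] == h]["call"].map(code).to_numpy()
        for h in hyb_haps]).astype(np.int8)
    post = AncestryPosterior(p_domestic=(calls == 1).astype(float),
                             hap_ids=hyb_haps, calls=calls, threshold=0.9)

    frac = aw.per_site_domestic_fraction(post)
    w67 = aw.enrichment_windows(frac, ds.variants, aw.P067, 2, "p0.67")
    w83 = aw.enrichment_windows(frac, ds.variants, aw.P083, 2, "p0.83")
    report = aw.window_report(w67 + w83)
    report.to_csv(ROOT / "enrichment_windows.tsv", sep="\t", index=False)
    print(f"{len(w67)} p0.67 windows, {len(w83)} p0.83 windows")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
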