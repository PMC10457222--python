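#!/usr/bin/env python
"""Local-ancestry deconvolution of the flagged hybrids.

Fits the two-source haplotype HMM (g = 20 generations, pooled three-breed
domestic panel, 0.9 assignment threshold) to the hybrid haplotypes plus two
known-pure control animals, then reports per-individual global domestic
proportions, ancestry tracts, and a tract-length admixture date.

Writes results/{ancestry_posteriors.tsv, ancestry_tracts.tsv,
ancestry_summary.tsv}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from introscan import local_ancestry as la
from introscan.genotype_io import read_dataset
from introscan.synthetic_data import DOMESTIC_POPS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_dataset(ROOT / "study" / "study.vcf",
                      popmap_path=ROOT / "study" / "popmap.tsv",
                      genetic_map_path=ROOT / "study" / "genetic_map.tsv")
    hybrids = (ROOT / "hybrids.txt").read_text().split()
    pure = [s for s in ds.samples_in("wild_pure") if s not in hybrids]
    controls = pure[:2]

    model = la.AncestryModel.from_dataset_samples(ds, pure, list(DOMESTIC_POPS),
                                                  g=20, m=0.2)
    pos = {s: i for i, s in enumerate(ds.samples)}
    samples = hybrids + controls
    rows = np.array([r for s in samples for r in (2 * pos[s], 2 * pos[s] + 1)])
    hap_ids = [f"{s}_h{a}" for s in samples for a in (0, 1)]
    post = la.fit_posteriors(ds.haplotypes[rows], model, ds.variants, hap_ids)
    la.call_ancestry(post, 0.9)

    summaries = la.global_proportions(post, ds.variants)
    summary = pd.DataFrame([{
        "sample": s.sample, "role": "control" if s.sample in controls else "hybrid",
        "domestic_proportion": s.domestic_proportion,
        "n_assigned_sites": s.n_assigned,
    } for s in summaries])
    summary.to_csv(ROOT / "ancestry_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    tracts = la.extract_tracts(post, ds.variants)
    tract_rows = [(t.hap_id, t.chrom, t.start_bp, t.stop_bp, t.ancestry, t.n_snps)
                  for trs in tracts.values() for t in trs]
    pd.DataFrame(tract_rows, columns=["haplotype_id", "chrom", "start_bp",
                                      "stop_bp", "ancestry", "n_snps"]).to_csv(
        ROOT / "ancestry_tracts.tsv", sep="\t", index=False)

    dom_tracts = [t for s in hybrids for h in (f"{s}_h0", f"{s}_h1")
                  for t in tracts[h] if t.ancestry == "domestic"]
    m_mean = float(np.mean([s.domestic_proportion for s in summaries
                            if s.sample in hybrids]))
    ghat = la.estimate_generations_from_tracts(dom_tracts, m=m_mean)
    print(f"\ntract-length admixture date: g = {ghat:.1f} generations "
          f"(~{la.generations_to_years(ghat):.0f} years at 5 y/generation)")

    recs = []
    for i, h in enumerate(post.hap_ids):
        recs.append(pd.DataFrame({
            "haplotype": h, "chrom": ds.variants["chrom"],
            "pos_bp": ds.variants["pos_bp"],
            "p_domestic": np.round(post.p_domestic[i], 5),
            "call": [la.CALL_NAME[int(c)] for c in post.calls[i]]}))
    pd.concat(recs).to_csv(ROOT / "ancestry_posteriors.tsv", sep="\t",
                           index=False)


if __name__ == "__main__":
    main()
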