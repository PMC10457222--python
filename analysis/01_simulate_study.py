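#!/usr/bin/env python
"""Emit the synthetic study the rest of the analysis operates on.

Panel-scale design mirroring the merged SNP-array dataset: 18 autosomes,
~54K SNPs, a 96-animal island wild-boar target pool containing 3 hybrids
with 10-27% domestic ancestry from an admixture event ~20 generations ago,
a mainland reference wild population, three commercial-type domestic breeds,
an outgroup, and one planted 10 Mb domestic sweep on chromosome 1.

Writes results/study/{study.vcf, popmap.tsv, genetic_map.tsv,
truth_tracts.tsv, sweep_regions.tsv}.
"""

from pathlib import Path

from introscan.synthetic_data import SimConfig, emit_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 1


def main() -> None:
    cfg = SimConfig.panel_scale(seed=SEED)
    study = emit_study(cfg, OUT)
    ds = study.dataset
    print(f"wrote {ds.n_samples} samples x {ds.n_variants} SNPs to {OUT}")
    print("true hybrids and their domestic proportions:")
    for s, m in study.truth.m_per_sample.items():
        print(f"  {s}: m = {m:.3f}")
    print(f"planted sweep: {study.truth.sweep_regions}")


if __name__ == "__main__":
    main()
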