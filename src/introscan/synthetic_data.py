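"""Synthetic study generator: drifted populations, admixed tracts, planted sweeps.

Emulates the structure of a merged SNP-array study of an island wild-boar
population with domestic introgression: a target wild population, a reference
wild population, three domestic breeds, an outgroup, and a few hybrid
individuals whose genomes are mosaics of wild and domestic tracts dating to
``g`` generations ago.

Allele frequencies drift from a shared ancestral frequency under the
Balding-Nichols model (population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)).
Hybrid haplotypes follow a two-state Markov process in genetic distance:
between adjacent SNPs separated by d Morgans the ancestry is redrawn from the
prior (m domestic) with probability 1 - exp(-g d), which yields exponential
ancestry tracts with mean domestic length 1/(g(1-m)) Morgans - the same
process the local-ancestry HMM assumes, so parameter recovery is a clean
closed loop.  Ground truth (per-haplotype tracts and sweep regions) is
retained for recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import Dataset, write_dataset, write_popmap

WILD, DOMESTIC = 0, 1
_ANCESTRY_NAME = {WILD: "wild", DOMESTIC: "domestic"}

# default populations mirror the study design: a large target wild group, a
# mainland reference wild group, three commercial-type breeds, an outgroup
DEFAULT_SAMPLE_SIZES = {
    "wild_pure": 30,
    "wild_ref": 12,
    "dom_a": 10,
    "dom_b": 10,
    "dom_c": 10,
    "outgroup": 8,
}
# F = 0.18 per branch gives pairwise Weir-Cockerham FST ~ 0.2 between any
# two of these populations (the estimator's expectation under Balding-Nichols
# is ~ F for equal branch lengths), matching wild-vs-commercial-breed
# differentiation on arrays
DEFAULT_DRIFT_F = {
    "wild_pure": 0.18,
    "wild_ref": 0.18,
    "dom_a": 0.18,
    "dom_b": 0.18,
    "dom_c": 0.18,
    "outgroup": 0.35,
}
DOMESTIC_POPS = ("dom_a", "dom_b", "dom_c")
HYBRID_POP = "hybrid"


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    ``admix_m`` is either a single proportion or an (lo, hi) range from which
    each hybrid individual's domestic proportion is drawn uniformly; the
    default range matches introgression proportions of 10-27%.  ``admix_g`` is
    the number of generations since admixture (default 20).  One 10 Mb
    domestic sweep region is planted by default.
    """

    n_chrom: int = 2
    n_snps_per_chrom: int = 5000
    chrom_length_bp: int = 100_000_000
    # mildly ascertained ancestral spectrum, emulating array content where
    # rare variants are under-represented relative to a neutral spectrum
    ancestral_freq_law: tuple[float, float] = (2.0, 2.0)
    drift_F: dict = field(default_factory=lambda: dict(DEFAULT_DRIFT_F))
    sample_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    n_hybrids: int = 3
    admix_g: float = 20.0
    admix_m: tuple[float, float] | float = (0.10, 0.27)
    sweep_regions: list = field(
        default_factory=lambda: [("1", 40_000_001, 50_000_000)]
    )
    # divergence of sweep-carrier haplotypes from the shared core; low enough
    # that EHH from a central core stays > 0.9 across a 10 Mb swept region
    sweep_mut_rate: float = 5e-5
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.admix_g < 1:
            raise ValueError("admix_g must be >= 1")
        lo, hi = self.m_range
        if not (0 < lo <= hi < 1):
            raise ValueError("admix_m must lie in (0, 1)")
        for pop, f in self.drift_F.items():
            if not 0 <= f < 1:
                raise ValueError(f"drift_F[{pop!r}] must be in [0, 1)")

    @classmethod
    def panel_scale(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Study sized like the real merged array panel: 18 autosomes,
        ~54K SNPs, a 96-animal target pool (93 pure + 3 hybrids), 19
        reference wild, three breeds of 10 and an outgroup of 11."""
        fields = dict(
            n_chrom=18, n_snps_per_chrom=3000, chrom_length_bp=125_000_000,
            sample_sizes={"wild_pure": 93, "wild_ref": 19, "dom_a": 10,
                          "dom_b": 10, "dom_c": 10, "outgroup": 11},
            sweep_regions=[("1", 40_000_001, 50_000_000)],
            seed=seed,
        )
        fields.update(overrides)
        return cls(**fields)

    @property
    def m_range(self) -> tuple[float, float]:
        if np.isscalar(self.admix_m):
            return (float(self.admix_m), float(self.admix_m))
        return (float(self.admix_m[0]), float(self.admix_m[1]))


@dataclass
class Tract:
    chrom: str
    start_bp: int
    stop_bp: int
    ancestry: str  # "wild" | "domestic"


@dataclass
class TruthTracts:
    """Ground-truth ancestry: per hybrid haplotype, tracts tiling each chromosome."""

    tracts: dict  # hap_id -> list[Tract]
    sweep_regions: list
    hybrid_samples: list
    site_states: np.ndarray  # (n_hybrid_haps, n_sites), 0 wild / 1 domestic
    hap_ids: list
    m_per_sample: dict

    def domestic_fraction(self, hap_id: str) -> float:
        trs = self.tracts[hap_id]
        dom = sum(t.stop_bp - t.start_bp + 1 for t in trs if t.ancestry == "domestic")
        tot = sum(t.stop_bp - t.start_bp + 1 for t in trs)
        return dom / tot

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (h, t.chrom, t.start_bp, t.stop_bp, t.ancestry)
            for h in self.hap_ids
            for t in self.tracts[h]
        ]
        return pd.DataFrame(
            rows, columns=["haplotype_id", "chrom", "start_bp", "stop_bp", "ancestry"]
        )


@dataclass
class SimulatedStudy:
    dataset: Dataset
    truth: TruthTracts
    source_freqs: dict  # population -> per-site true frequency
    config: SimConfig


# ---------------------------------------------------------------------------
# frequency and haplotype layers
# ---------------------------------------------------------------------------

def _variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for c in range(cfg.n_chrom):
        pos: set[int] = set()
        while len(pos) < cfg.n_snps_per_chrom:
            draw = rng.integers(1, cfg.chrom_length_bp + 1,
                                size=2 * cfg.n_snps_per_chrom)
            pos.update(int(x) for x in draw)
        pos_arr = np.sort(rng.choice(np.fromiter(pos, dtype=np.int64),
                                     size=cfg.n_snps_per_chrom, replace=False))
        chrom = str(c + 1)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos_bp": pos_arr,
            "id": [f"snp{chrom}_{k}" for k in range(cfg.n_snps_per_chrom)],
            "ref_allele": "A",
            "alt_allele": "G",
            "pos_cM": pos_arr / 1e6 * cfg.cm_per_mb,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_source_frequencies(cfg: SimConfig, rng=None, n_sites=None) -> dict:
    """Balding-Nichols frequencies per population around a shared ancestral draw.

    F = 0 reproduces the ancestral frequency exactly.  Returns a dict
    population -> frequency array, plus the ancestral array under key
    ``"_ancestral"``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = n_sites if n_sites is not None else cfg.n_chrom * cfg.n_snps_per_chrom
    a, b = cfg.ancestral_freq_law
    p = rng.beta(a, b, size=n)
    out = {"_ancestral": p}
    for pop, F in cfg.drift_F.items():
        if F == 0:
            out[pop] = p.copy()
            continue
        lam = (1 - F) / F
        alpha = np.maximum(p * lam, 1e-12)
        beta = np.maximum((1 - p) * lam, 1e-12)
        out[pop] = rng.beta(alpha, beta)
    return out


def simulate_haplotypes(freqs: np.ndarray, n_haplotypes: int, rng) -> np.ndarray:
    """Independent Bernoulli(frequency) draws, (n_haplotypes, n_sites) int8."""
    freqs = np.asarray(freqs, dtype=float)
    return (rng.random((n_haplotypes, freqs.size)) < freqs).astype(np.int8)


# ---------------------------------------------------------------------------
# admixed haplotypes
# ---------------------------------------------------------------------------

def simulate_admixed_haplotypes(
    cfg: SimConfig,
    variants: pd.DataFrame,
    wild_freqs: np.ndarray,
    domestic_breed_freqs: list,
    m_per_hap: np.ndarray,
    rng,
    hap_ids: list[str] | None = None,
):
    """Mosaic hybrid haplotypes with Markov ancestry switching in genetic distance.

    Between adjacent SNPs d Morgans apart the ancestry is redrawn from the
    prior (domestic with probability m) with probability 1 - exp(-g d).
    Alleles within a tract are drawn Bernoulli from the active source's
    population frequencies: the wild population's for wild tracts, one
    uniformly chosen breed's for each domestic tract (the breed persists
    within the tract).  Sources thus enter at the frequency level - exactly
    the emission model the downstream ancestry HMM assumes.

    Returns (haplotypes (H, n_sites) int8, states (H, n_sites) int8).
    """
    H = len(m_per_hap)
    n_sites = len(variants)
    haps = np.zeros((H, n_sites), dtype=np.int8)
    states = np.zeros((H, n_sites), dtype=np.int8)
    m = np.asarray(m_per_hap, dtype=float)
    wild_freqs = np.asarray(wild_freqs, float)
    breed_freqs = np.asarray(domestic_breed_freqs, float)  # (n_breeds, n_sites)
    if breed_freqs.ndim == 1:
        breed_freqs = breed_freqs[None, :]
    n_breeds = breed_freqs.shape[0]

    chrom_arr = variants["chrom"].to_numpy(object)
    cm = variants["pos_cM"].to_numpy(float)
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        state = (rng.random(H) < m).astype(np.int8)
        breed = rng.integers(0, n_breeds, size=H)
        for k, j in enumerate(idx):
            if k > 0:
                d = (cm[j] - cm[idx[k - 1]]) / 100.0  # Morgans
                redraw = rng.random(H) < -np.expm1(-cfg.admix_g * d)
                new_state = np.where(redraw, (rng.random(H) < m).astype(np.int8), state)
                to_d = (new_state != state) & (new_state == DOMESTIC)
                if to_d.any():
                    breed[to_d] = rng.integers(0, n_breeds, size=int(to_d.sum()))
                state = new_state
            states[:, j] = state
            q = np.where(state == DOMESTIC, breed_freqs[breed, j], wild_freqs[j])
            haps[:, j] = rng.random(H) < q
    return haps, states


def _tracts_from_states(
    states: np.ndarray, variants: pd.DataFrame, chrom_length_bp: int,
    hap_ids: list[str],
) -> dict:
    """Convert per-site ancestry states into bp tracts tiling each chromosome.

    Boundaries between tracts fall at the midpoint between the two SNPs
    flanking a switch; the first/last tract extend to the chromosome ends.
    """
    chrom_arr = variants["chrom"].to_numpy(object)
    pos = variants["pos_bp"].to_numpy(np.int64)
    out: dict = {h: [] for h in hap_ids}
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        cpos = pos[idx]
        for hi, h in enumerate(hap_ids):
            s = states[hi, idx]
            change = np.flatnonzero(np.diff(s)) + 1  # index into idx of new tract
            starts = np.concatenate([[0], change])
            stops = np.concatenate([change - 1, [len(idx) - 1]])
            for a, b in zip(starts, stops):
                start_bp = 1 if a == 0 else int((cpos[a - 1] + cpos[a]) // 2 + 1)
                stop_bp = (chrom_length_bp if b == len(idx) - 1
                           else int((cpos[b] + cpos[b + 1]) // 2))
                out[h].append(Tract(str(chrom), start_bp, stop_bp,
                                    _ANCESTRY_NAME[int(s[a])]))
    return out


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig, plant_sweeps: bool = True) -> SimulatedStudy:
    """Full synthetic study: drifted populations + hybrids + (optional) sweeps."""
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_table(cfg, rng)
    n_sites = len(variants)
    freqs = simulate_source_frequencies(cfg, rng=rng, n_sites=n_sites)

    samples, popmap, hap_blocks = [], {}, []
    for pop, n in cfg.sample_sizes.items():
        pool = simulate_haplotypes(freqs[pop], 2 * n, rng)
        ids = [f"{pop}_{i:03d}" for i in range(n)]
        samples += ids
        popmap.update({s: pop for s in ids})
        hap_blocks.append(pool)

    lo, hi = cfg.m_range
    m_ind = rng.uniform(lo, hi, size=cfg.n_hybrids)
    m_per_hap = np.repeat(m_ind, 2)
    hyb_ids = [f"{HYBRID_POP}_{i:03d}" for i in range(cfg.n_hybrids)]
    hap_ids = [f"{s}_h{a}" for s in hyb_ids for a in (0, 1)]
    breed_freqs = [freqs[p] for p in DOMESTIC_POPS if p in cfg.sample_sizes]
    hyb_haps, states = simulate_admixed_haplotypes(
        cfg, variants, freqs["wild_pure"], breed_freqs, m_per_hap, rng, hap_ids)
    samples += hyb_ids
    popmap.update({s: HYBRID_POP for s in hyb_ids})
    hap_blocks.append(hyb_haps)

    haplotypes = np.vstack(hap_blocks)
    genotypes = haplotypes[0::2] + haplotypes[1::2]
    ds = Dataset(variants=variants, samples=samples, genotypes=genotypes,
                 haplotypes=haplotypes, popmap=popmap)
    truth = TruthTracts(
        tracts=_tracts_from_states(states, variants, cfg.chrom_length_bp, hap_ids),
        sweep_regions=[], hybrid_samples=hyb_ids, site_states=states,
        hap_ids=hap_ids, m_per_sample=dict(zip(hyb_ids, m_ind)),
    )
    study = SimulatedStudy(dataset=ds, truth=truth,
                           source_freqs={k: v for k, v in freqs.items()
                                         if not k.startswith("_")},
                           config=cfg)
    if plant_sweeps:
        for region in cfg.sweep_regions:
            study = plant_domestic_sweep(study, region, rng=rng)
    return study


def plant_domestic_sweep(study: SimulatedStudy, region, rng=None) -> SimulatedStudy:
    """Plant a swept domestic haplotype shared by all breeds and all hybrids.

    Inside ``region`` (chrom, start_bp, stop_bp; 1-based closed) every
    domestic-breed haplotype is replaced by one core haplotype mutated at a
    small per-site rate, giving the domestic pool extended haplotype
    homozygosity; every hybrid haplotype is forced to domestic ancestry and
    carries the swept haplotype.  Truth tracts are rebuilt accordingly.
    """
    cfg = study.config
    rng = np.random.default_rng(cfg.seed + 104729) if rng is None else rng
    chrom, start, stop = str(region[0]), int(region[1]), int(region[2])
    ds = study.dataset
    V = ds.variants
    sel = np.flatnonzero((V["chrom"].to_numpy(object) == chrom)
                         & (V["pos_bp"].to_numpy() >= start)
                         & (V["pos_bp"].to_numpy() <= stop))
    if sel.size == 0:
        raise ValueError(f"sweep region {chrom}:{start}-{stop} overlaps no SNPs")

    haplotypes = ds.haplotypes.copy()
    dom_hap_rows = np.concatenate([
        ds.haplotype_indices(p) for p in DOMESTIC_POPS if p in cfg.sample_sizes])
    core = haplotypes[dom_hap_rows[0], sel].copy()

    def mutated(n_rows):
        mut = rng.random((n_rows, sel.size)) < cfg.sweep_mut_rate
        return np.where(mut, 1 - core[None, :], core[None, :]).astype(np.int8)

    haplotypes[np.ix_(dom_hap_rows, sel)] = mutated(dom_hap_rows.size)

    truth = copy.deepcopy(study.truth)
    if truth.hap_ids:
        hyb_hap_rows = ds.haplotype_indices(HYBRID_POP)
        haplotypes[np.ix_(hyb_hap_rows, sel)] = mutated(hyb_hap_rows.size)
        truth.site_states[:, sel] = DOMESTIC
        truth.tracts = _tracts_from_states(truth.site_states, V,
                                           cfg.chrom_length_bp, truth.hap_ids)
    truth.sweep_regions = list(truth.sweep_regions) + [(chrom, start, stop)]

    genotypes = haplotypes[0::2] + haplotypes[1::2]
    new_ds = Dataset(variants=V, samples=ds.samples, genotypes=genotypes,
                     haplotypes=haplotypes, popmap=dict(ds.popmap))
    return SimulatedStudy(dataset=new_ds, truth=truth,
                          source_freqs=study.source_freqs, config=cfg)


def emit_study(cfg: SimConfig, outdir) -> SimulatedStudy:
    """Simulate and write the study files: phased VCF, popmap, genetic map, truth.

    Same seed => byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    write_dataset(study.dataset, outdir / "study.vcf", format="vcf")
    write_popmap(study.dataset.popmap, outdir / "popmap.tsv")
    with open(outdir / "genetic_map.tsv", "w") as fh:
        for c in range(cfg.n_chrom):
            chrom = str(c + 1)
            fh.write(f"{chrom}\t1\t{1 / 1e6 * cfg.cm_per_mb:.8f}\n")
            fh.write(f"{chrom}\t{cfg.chrom_length_bp}\t"
                     f"{cfg.chrom_length_bp / 1e6 * cfg.cm_per_mb:.8f}\n")
    study.truth.to_frame().to_csv(outdir / "truth_tracts.tsv", sep="\t", index=False)
    with open(outdir / "sweep_regions.tsv", "w") as fh:
        fh.write("chrom\tstart_bp\tstop_bp\n")
        for chrom, start, stop in study.truth.sweep_regions:
            fh.write(f"{chrom}\t{start}\t{stop}\n")
    return study
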