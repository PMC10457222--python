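"""End-to-end orchestration: QC -> hybrid screen -> local ancestry ->
enrichment windows -> selection scans -> randomization -> intersection.

The screen stage is the operative hybrid definition: individuals of the
target wild pool flagged by the leave-one-out f3 test (f3 < 0, Z < -3
against pool-minus-self and the pooled domestic breeds) form the target
group for local ancestry and PBS.  All randomness flows from one root seed
through per-stage derived seeds, so a config + seed pair reproduces the run
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ancestry_windows as aw
from . import annotate as ann
from . import local_ancestry as la
from . import popgen_stats as pg
from . import selection_scan as ss
from .genotype_io import Dataset, QcConfig, ld_prune, qc_filter, read_dataset
from .synthetic_data import DOMESTIC_POPS, HYBRID_POP, SimConfig, simulate_study

log = logging.getLogger("introscan")


@dataclass
class PipelineConfig:
    """Single-file configuration for a full run.

    Either ``vcf``/``popmap`` (plus optional ``genetic_map``) point at real
    input files, or ``simulate`` holds simulator settings (a SimConfig or a
    dict of its fields; ``simulate: {}`` uses the defaults).
    """

    vcf: str | None = None
    popmap: str | None = None
    genetic_map: str | None = None
    simulate: SimConfig | dict | None = None
    simulate_only: bool = False

    # population roles; defaults match the simulator's labels
    target_wild: list = field(default_factory=lambda: ["wild_pure", HYBRID_POP])
    ref_wild: str = "wild_ref"
    domestic_breeds: list = field(default_factory=lambda: list(DOMESTIC_POPS))
    outgroup: str = "outgroup"

    # stage parameters
    qc: QcConfig = field(default_factory=QcConfig)
    run_qc: bool = False          # array QC is for structure analyses; the
    run_ld_prune: bool = False    # scan stages use the full panel by default
    block_cm: float = 5.0
    g: float = 20.0
    m_prior: float = 0.2
    call_threshold: float = 0.9
    n_controls: int = 2
    p_thresholds: tuple = (aw.P067, aw.P083)
    min_snps_window: int = 2
    pbs_pct: float = 0.95
    pbs_min_run: int = 5
    randomization_R: int = 20
    recurrence_max: float = 0.2
    xpehh_cutoff: float = 0.05
    xpehh_pct: float = 0.95
    xpehh_merge_bp: int = 500_000
    genes: str | None = None
    gene_flank_bp: int = 100_000

    outdir: str = "introscan_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QcConfig(**raw["qc"])
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            raw["simulate"] = SimConfig(**raw["simulate"])
        return cls(**raw)


def hybrid_prevalence(n_hybrids: int, n_pool: int) -> float:
    """Hybrid percentage in the screened pool, to one decimal place
    (e.g. 3 of 96 animals -> 3.1%)."""
    if n_pool <= 0:
        raise ValueError("pool must be non-empty")
    return round(100.0 * n_hybrids / n_pool, 1)


def _stage_seed(root: int, k: int) -> int:
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % (2**31))


def load_input(cfg: PipelineConfig):
    """Stage 0: simulate or read the dataset; returns (Dataset, truth-or-None)."""
    if cfg.simulate is not None:
        sim = cfg.simulate if isinstance(cfg.simulate, SimConfig) else SimConfig(**cfg.simulate)
        study = simulate_study(sim)
        return study.dataset, study
    ds = read_dataset(cfg.vcf, format="vcf", popmap_path=cfg.popmap,
                      genetic_map_path=cfg.genetic_map)
    return ds, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; write artifacts + summary.json to cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {"seed": cfg.seed, "stages": []}

    ds, study = load_input(cfg)
    summary["n_samples"] = ds.n_samples
    summary["n_variants"] = ds.n_variants
    summary["stages"].append("input")
    if cfg.simulate_only:
        summary["status"] = "simulated_only"
        _write_summary(summary, outdir)
        return summary

    if cfg.run_qc:
        ds_qc = qc_filter(ds, cfg.qc)
        if cfg.run_ld_prune:
            ds_qc = ld_prune(ds_qc, cfg.qc)
        summary["n_variants_post_qc"] = ds_qc.n_variants
        summary["stages"].append("qc")
    else:
        ds_qc = ds

    # ---- hybrid screen (on the unfiltered panel, maximum sites) ----
    # each domestic breed is tested as a separate triad; an individual is a
    # hybrid if any breed gives a significantly negative f3
    target_labels = [p for p in cfg.target_wild if p in ds.populations]
    screen = []
    for breed in cfg.domestic_breeds:
        screen += pg.leave_one_out_screen(ds, target_labels, breed,
                                          block_cm=cfg.block_cm)
    hybrids = sorted({r.target for r in screen if r.is_admixed})
    pool = [s for p in target_labels for s in ds.samples_in(p)]
    pure = [s for s in pool if s not in hybrids]
    _screen_table(screen).to_csv(outdir / "f3_screen.tsv", sep="\t", index=False)
    summary["stages"].append("f3_screen")
    summary["hybrids"] = hybrids
    summary["n_hybrids"] = len(hybrids)
    summary["n_target_pool"] = len(pool)
    summary["hybrid_prevalence_pct"] = hybrid_prevalence(len(hybrids), len(pool))
    if not hybrids:
        summary["status"] = "no_hybrids"
        _write_summary(summary, outdir)
        return summary

    # ---- local ancestry on hybrid + control haplotypes ----
    if not ds.phased:
        raise ValueError("local ancestry requires phased input")
    model = la.AncestryModel.from_dataset_samples(ds, pure, cfg.domestic_breeds,
                                                  g=cfg.g, m=cfg.m_prior)
    controls = pure[: cfg.n_controls]
    la_samples = hybrids + controls
    rows, hap_ids = _hap_rows(ds, la_samples)
    post = la.fit_posteriors(ds.haplotypes[rows], model, ds.variants, hap_ids)
    la.call_ancestry(post, cfg.call_threshold)
    props = la.global_proportions(post, ds.variants)
    tracts = la.extract_tracts(post, ds.variants)
    dom_tracts = [t for s in hybrids for h in (f"{s}_h0", f"{s}_h1")
                  for t in tracts.get(h, []) if t.ancestry == "domestic"]
    try:
        g_hat = la.estimate_generations_from_tracts(
            dom_tracts, m=float(np.mean([p.domestic_proportion for p in props
                                         if p.sample in hybrids])))
    except ValueError:
        g_hat = None
    summary["stages"].append("local_ancestry")
    summary["global_domestic_proportions"] = {
        p.sample: (None if np.isnan(p.domestic_proportion)
                   else round(p.domestic_proportion, 4)) for p in props}
    summary["control_samples"] = controls
    summary["g_hat_from_tracts"] = None if g_hat is None else round(g_hat, 2)
    summary["admixture_age_years"] = (None if g_hat is None
                                      else round(la.generations_to_years(g_hat), 1))
    _tract_table(tracts).to_csv(outdir / "ancestry_tracts.tsv", sep="\t", index=False)

    # ---- enrichment windows over hybrid haplotypes only ----
    hyb_rows_local = [i for i, h in enumerate(hap_ids)
                      if la._sample_of(h) in hybrids]
    hyb_post = la.AncestryPosterior(
        p_domestic=post.p_domestic[hyb_rows_local],
        hap_ids=[hap_ids[i] for i in hyb_rows_local],
        calls=post.calls[hyb_rows_local], threshold=post.threshold)
    frac = aw.per_site_domestic_fraction(hyb_post)
    p67, p83 = cfg.p_thresholds
    win67 = aw.enrichment_windows(frac, ds.variants, p67, cfg.min_snps_window, "p0.67")
    win83 = aw.enrichment_windows(frac, ds.variants, p83, cfg.min_snps_window, "p0.83")
    summary["stages"].append("enrichment_windows")
    summary["n_windows_p067"] = len(win67)
    summary["n_windows_p083"] = len(win83)

    # ---- PBS scan + randomization ----
    pbs = ss.pbs_scan(ds_qc, hybrids, pure, cfg.ref_wild,
                      pct=cfg.pbs_pct, min_run=cfg.pbs_min_run)
    pbs.table.to_csv(outdir / "pbs_per_site.tsv", sep="\t", index=False)
    rand = ss.pbs_randomization(
        ds_qc, hybrids, pure, cfg.ref_wild, n_target=len(hybrids),
        R=cfg.randomization_R, recurrence_max=cfg.recurrence_max,
        pct=cfg.pbs_pct, min_run=cfg.pbs_min_run, seed=_stage_seed(cfg.seed, 3))
    summary["stages"] += ["pbs", "pbs_randomization"]
    summary["pbs_windows"] = [_win_dict(w) for w in pbs.windows]
    summary["pbs_randomization"] = {
        "mean_window_count": rand.mean_count,
        "recurrence": rand.recurrence,
        "unreliable": rand.unreliable,
    }

    # ---- XP-EHH: domestic pool vs pure wild ----
    dom_rows = np.concatenate([ds.haplotype_indices(p) for p in cfg.domestic_breeds])
    pure_rows, _ = _hap_rows(ds, pure)
    xp = ss.xpehh_scan(ds.haplotypes[dom_rows], ds.haplotypes[pure_rows],
                       ds.variants, cutoff=cfg.xpehh_cutoff, pct=cfg.xpehh_pct,
                       merge_bp=cfg.xpehh_merge_bp)
    xp.table.to_csv(outdir / "xpehh_per_site.tsv", sep="\t", index=False)
    summary["stages"].append("xpehh")
    summary["xpehh_windows"] = [_win_dict(w) for w in xp.windows]
    summary["xpehh_top_marker"] = xp.top_marker

    # ---- intersection + annotation ----
    cand = (ann.intersect_windows(win67, pbs.windows, "enrichment", "PBS")
            + ann.intersect_windows(win67, xp.windows, "enrichment", "XP-EHH"))
    genes = ann.read_genes(cfg.genes) if cfg.genes else []
    if genes and xp.top_marker:
        near = ann.genes_near_marker(genes, xp.top_marker[0], xp.top_marker[1],
                                     cfg.gene_flank_bp)
        summary["genes_near_top_xpehh"] = [g.name for g in near]
    summary["stages"].append("intersection")
    summary["candidate_regions"] = [
        {"chrom": r.chrom, "start_bp": r.start_bp, "stop_bp": r.stop_bp,
         "evidence": sorted(r.evidence)} for r in cand]
    aw.window_report(win67 + win83, pbs.windows + xp.windows).to_csv(
        outdir / "enrichment_windows.tsv", sep="\t", index=False)
    summary["status"] = "ok"
    _write_summary(summary, outdir)
    return summary


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _hap_rows(ds: Dataset, samples: list):
    pos = {s: i for i, s in enumerate(ds.samples)}
    rows, ids = [], []
    for s in samples:
        rows += [2 * pos[s], 2 * pos[s] + 1]
        ids += [f"{s}_h0", f"{s}_h1"]
    return np.array(rows, dtype=int), ids


def _screen_table(results):
    import pandas as pd

    return pd.DataFrame([{
        "target": r.target, "sourceA": r.sourceA, "sourceB": r.sourceB,
        "f3": r.f3, "se": r.se, "z": r.z, "n_snps": r.n_snps,
        "flagged": r.is_admixed,
    } for r in results])


def _tract_table(tracts: dict):
    import pandas as pd

    rows = [(t.hap_id, t.chrom, t.start_bp, t.stop_bp, t.ancestry, t.n_snps)
            for trs in tracts.values() for t in trs]
    return pd.DataFrame(rows, columns=["haplotype_id", "chrom", "start_bp",
                                       "stop_bp", "ancestry", "n_snps"])


def _win_dict(w) -> dict:
    return {"chrom": w.chrom, "start_bp": w.start_bp, "stop_bp": w.stop_bp,
            "n_snps": w.n_snps}


def _write_summary(summary: dict, outdir: Path) -> None:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
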