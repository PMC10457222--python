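"""PBS transform and windows, randomization null, EHH and XP-EHH."""

import numpy as np
import pandas as pd
import pytest

from introscan.genotype_io import Dataset
from introscan.popgen_stats import FstSeries
from introscan.selection_scan import (
    Window,
    ehh_at_core,
    pbs_per_site,
    pbs_randomization,
    pbs_scan,
    pbs_windows,
    xpehh_scan,
)

from conftest import variant_frame


def fst_series(values):
    v = np.asarray(values, float)
    return FstSeries(fst=v, a=v, d=np.ones_like(v))


class TestPBS:
    def test_no_differentiation_gives_zero(self):
        v = variant_frame([100])
        res = pbs_per_site(fst_series([0.0]), fst_series([0.0]), fst_series([0.0]), v)
        assert res.pbs[0] == 0.0

    def test_symmetric_closed_form(self):
        # FST = 0.1 on all pairs: T = -ln(0.9) = 0.10536, PBS = T/2 = 0.05268
        v = variant_frame([100])
        res = pbs_per_site(fst_series([0.1]), fst_series([0.1]), fst_series([0.1]), v)
        assert res.table["T_AB"][0] == pytest.approx(0.10536, abs=5e-6)
        assert res.pbs[0] == pytest.approx(0.05268, abs=5e-6)

    def test_log2_closed_form(self):
        v = variant_frame([100])
        res = pbs_per_site(fst_series([0.5]), fst_series([0.5]), fst_series([0.0]), v)
        assert res.pbs[0] == pytest.approx(np.log(2), abs=1e-9)

    def test_identity_holds_exhaustively(self):
        rng = np.random.default_rng(0)
        n = 10_000
        v = variant_frame(np.linspace(1, 1e9, n).astype(int))
        f1, f2, f3 = (rng.uniform(-0.1, 0.9, n) for _ in range(3))
        res = pbs_per_site(fst_series(f1), fst_series(f2), fst_series(f3), v)
        t = res.table
        assert np.allclose(res.pbs, (t["T_AB"] + t["T_AC"] - t["T_BC"]) / 2)
        # clamping: negative FST contributes zero branch length, never NaN/inf
        assert np.isfinite(res.pbs).all()
        assert (t["T_AB"] >= 0).all()

    def test_symmetric_in_non_target_populations(self):
        rng = np.random.default_rng(1)
        n = 100
        v = variant_frame(np.arange(1, n + 1) * 1000)
        ab, ac, bc = (rng.uniform(0, 0.5, n) for _ in range(3))
        r1 = pbs_per_site(fst_series(ab), fst_series(ac), fst_series(bc), v)
        r2 = pbs_per_site(fst_series(ac), fst_series(ab), fst_series(bc), v)
        assert np.allclose(r1.pbs, r2.pbs)

    def test_undefined_sites_propagate_as_nan(self):
        v = variant_frame([100, 200])
        res = pbs_per_site(fst_series([0.1, np.nan]), fst_series([0.1, 0.1]),
                           fst_series([0.1, 0.1]), v)
        assert np.isnan(res.pbs[1]) and np.isfinite(res.pbs[0])


class TestPBSWindows:
    def _result(self, values, pos=None):
        v = variant_frame(pos if pos is not None else
                          (np.arange(len(values)) + 1) * 1000)
        res = pbs_per_site(fst_series(values), fst_series(values),
                           fst_series(np.zeros(len(values))), v)
        return res

    def test_constant_distribution_yields_no_windows(self):
        res = pbs_windows(self._result(np.full(100, 0.2)))
        assert res.windows == []

    def test_contiguous_top_values_form_one_window(self):
        vals = np.linspace(0.01, 0.1, 100)
        vals[40:45] = [0.5, 0.6, 0.7, 0.6, 0.5]  # 5 largest, contiguous
        res = pbs_windows(self._result(vals))
        assert len(res.windows) == 1
        w = res.windows[0]
        assert (w.start_bp, w.stop_bp, w.n_snps) == (41_000, 45_000, 5)

    def test_scattered_top_values_form_no_window(self):
        vals = np.linspace(0.01, 0.1, 100)
        vals[[5, 25, 45, 65, 85]] = 0.9
        res = pbs_windows(self._result(vals))
        assert res.windows == []

    def test_windows_never_overlap_and_all_sites_above_cutoff(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(0.05, 3000)
        res = pbs_windows(self._result(vals))
        pos = res.table["pos_bp"].to_numpy()
        prev_stop = -1
        for w in res.windows:
            assert w.start_bp > prev_stop
            prev_stop = w.stop_bp
            sel = (pos >= w.start_bp) & (pos <= w.stop_bp)
            assert (res.pbs[sel] > res.threshold).all()


def build_dataset(genos_by_pop, n_sites, seed=0):
    rows, samples, popmap = [], [], {}
    for pop, g in genos_by_pop.items():
        for i in range(g.shape[0]):
            samples.append(f"{pop}_{i}")
            popmap[f"{pop}_{i}"] = pop
        rows.append(g)
    v = variant_frame(np.linspace(1, 100e6, n_sites).astype(int))
    return Dataset(variants=v, samples=samples, genotypes=np.vstack(rows),
                   popmap=popmap)


class TestRandomization:
    def _homogeneous(self, seed, n_sites=800, n_pool=24, n_ref=12):
        rng = np.random.default_rng(seed)
        p = rng.beta(2, 2, n_sites)
        pool = rng.binomial(2, p, (n_pool, n_sites)).astype(np.int8)
        ref = rng.binomial(2, np.clip(p + rng.normal(0, 0.1, n_sites), 0.01, 0.99),
                           (n_ref, n_sites)).astype(np.int8)
        return build_dataset({"pool": pool, "ref": ref}, n_sites)

    def test_homogeneous_mean_count_matches_direct_rerun(self):
        ds = self._homogeneous(3)
        pool = ds.samples_in("pool")
        rep = pbs_randomization(ds, pool[:3], pool[3:], "ref", n_target=3,
                                R=12, seed=5)
        # direct no-signal expectation: scans of fresh pseudo-targets
        direct = []
        rng = np.random.default_rng(99)
        for _ in range(12):
            draw = list(rng.choice(pool, 3, replace=False))
            rest = [s for s in pool if s not in draw]
            direct.append(len(pbs_scan(ds, draw, rest, "ref").windows))
        assert abs(rep.mean_count - np.mean(direct)) <= 1.0

    def test_pool_too_small_rejected(self):
        ds = self._homogeneous(1, n_pool=4)
        with pytest.raises(ValueError, match="too small"):
            pbs_randomization(ds, ds.samples_in("pool")[:3],
                              ds.samples_in("pool")[3:], "ref", n_target=3, R=5)


class TestEHH:
    def test_identical_haplotypes_full_homozygosity(self):
        v = variant_frame([1_000_000, 2_000_000, 3_000_000, 4_000_000])
        haps = np.tile([0, 1, 0, 1], (6, 1)).astype(np.int8)
        curve, ihh = ehh_at_core(haps, 1, v)
        assert (curve["ehh"] == 1).all()
        # trapezoid over the full genetic span: 3 cM total
        assert ihh == pytest.approx(3.0)

    def test_two_two_split_combinatorics(self):
        # 4 haplotypes splitting 2/2 at the adjacent marker:
        # EHH = (C(2,2)+C(2,2)) / C(4,2) = 2/6 = 1/3
        v = variant_frame([1_000_000, 2_000_000])
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
        curve, _ = ehh_at_core(haps, 0, v)
        assert curve["ehh"].iloc[-1] == pytest.approx(1 / 3)

    def test_all_distinct_extension_stops(self):
        v = variant_frame([1_000_000, 2_000_000, 3_000_000])
        haps = np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        curve, _ = ehh_at_core(haps, 0, v)
        # adjacent marker splits every pair -> EHH 0 there, no further extension
        assert curve["ehh"].min() == 0.0
        assert curve["pos_bp"].max() == 2_000_000

    def test_monotone_non_increasing_from_core(self, tiny_study):
        ds = tiny_study.dataset
        haps = ds.haplotypes[ds.haplotype_indices("wild_pure")]
        curve, _ = ehh_at_core(haps, 200, ds.variants)
        core_pos = ds.variants["pos_bp"][200]
        left = curve[curve["pos_bp"] <= core_pos]["ehh"].to_numpy()
        right = curve[curve["pos_bp"] >= core_pos]["ehh"].to_numpy()
        assert (np.diff(left) >= -1e-12).all()
        assert (np.diff(right) <= 1e-12).all()

    def test_single_haplotype_rejected(self):
        v = variant_frame([100, 200])
        with pytest.raises(ValueError):
            ehh_at_core(np.array([[0, 1]], dtype=np.int8), 0, v)


class TestXPEHH:
    def test_identical_populations_give_zero_scores(self):
        from introscan.selection_scan import _ihh_all_sites

        rng = np.random.default_rng(3)
        v = variant_frame(np.linspace(1, 20e6, 50).astype(int))
        haps = rng.integers(0, 2, (10, 50)).astype(np.int8)
        ihh_a = _ihh_all_sites(haps, v, 0.05)
        ihh_b = _ihh_all_sites(haps.copy(), v, 0.05)
        assert np.array_equal(ihh_a, ihh_b)  # raw ln-ratio = 0 at every site
        # degenerate zero-variance input is rejected rather than standardized
        with pytest.raises(ValueError, match="zero variance|usable"):
            xpehh_scan(haps, haps.copy(), v)

    def test_standardization_identity(self, tiny_study):
        ds = tiny_study.dataset
        a = ds.haplotypes[ds.haplotype_indices("dom_a")]
        b = ds.haplotypes[ds.haplotype_indices("wild_pure")]
        res = xpehh_scan(a, b, ds.variants)
        std = res.table["std"].dropna()
        assert std.mean() == pytest.approx(0.0, abs=1e-9)
        assert std.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_planted_sweep_has_top_score_inside(self, default_study):
        ds = default_study.dataset
        chrom, start, stop = default_study.truth.sweep_regions[0]
        dom = np.concatenate([ds.haplotype_indices(p)
                              for p in ("dom_a", "dom_b", "dom_c")])
        res = xpehh_scan(ds.haplotypes[dom],
                         ds.haplotypes[ds.haplotype_indices("wild_pure")],
                         ds.variants)
        c, p, score = res.top_marker
        assert c == chrom and start <= p <= stop
        assert score > 3

    def test_window_merging_rule(self):
        from introscan.selection_scan import merge_markers

        wins = merge_markers(["1", "1", "1", "2"],
                             [1_000_000, 1_300_000, 2_500_000, 1_310_000],
                             merge_bp=500_000)
        assert [(w.chrom, w.start_bp, w.stop_bp) for w in wins] == [
            ("1", 1_000_000, 1_300_000), ("1", 2_500_000, 2_500_000),
            ("2", 1_310_000, 1_310_000)]
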