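"""Ancestry HMM posteriors, calls, tracts and dating utilities."""

import itertools

import numpy as np
import pytest

from introscan.local_ancestry import (
    CALL_DOMESTIC,
    CALL_UNASSIGNED,
    CALL_WILD,
    AncestryModel,
    AncestryPosterior,
    call_ancestry,
    estimate_generations_from_tracts,
    expected_backcross_proportion,
    extract_tracts,
    fit_posteriors,
    generations_to_years,
    global_proportions,
)

from conftest import variant_frame


def brute_force_posteriors(hap, fw, fd, cm, g, m):
    """Exact posteriors by enumeration over all 2^T state paths."""
    T = len(hap)
    d = np.diff(cm) / 100.0
    stay = np.exp(-g * d)
    prior = {0: 1 - m, 1: m}

    def emis(s, t):
        f = fd[t] if s == 1 else fw[t]
        return f if hap[t] == 1 else 1 - f

    post = np.zeros(T)
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        p = prior[path[0]] * emis(path[0], 0)
        for t in range(1, T):
            r = stay[t - 1]
            trans = r * (path[t] == path[t - 1]) + (1 - r) * prior[path[t]]
            p *= trans * emis(path[t], t)
        total += p
        for t in range(T):
            if path[t] == 1:
                post[t] += p
    return post / total


class TestPosteriors:
    def test_uninformative_emissions_return_prior_exactly(self):
        n = 50
        f = np.full(n, 0.37)
        model = AncestryModel(g=20, m=0.23, wild_freqs=f, domestic_freqs=f)
        v = variant_frame(np.linspace(1, 50e6, n).astype(int))
        hap = np.random.default_rng(0).integers(0, 2, n)
        post = fit_posteriors(hap, model, v)
        assert np.allclose(post.p_domestic, 0.23, atol=1e-12)

    def test_saturated_evidence_pins_posterior(self):
        n = 40
        model = AncestryModel(g=20, m=0.2,
                              wild_freqs=np.full(n, 1e-3),
                              domestic_freqs=np.full(n, 1 - 1e-3))
        v = variant_frame(np.linspace(1, 40e6, n).astype(int))
        post = fit_posteriors(np.ones(n, dtype=np.int8), model, v)
        assert (post.p_domestic[0, 5:-5] > 0.999).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.integers(3, 13)
        fw = rng.uniform(0.05, 0.95, T)
        fd = rng.uniform(0.05, 0.95, T)
        pos = np.sort(rng.choice(np.arange(1, 40_000_000), T, replace=False))
        v = variant_frame(pos)
        hap = rng.integers(0, 2, T)
        g, m = float(rng.uniform(2, 40)), float(rng.uniform(0.05, 0.6))
        model = AncestryModel(g=g, m=m, wild_freqs=fw, domestic_freqs=fd)
        ours = fit_posteriors(hap, model, v).p_domestic[0]
        oracle = brute_force_posteriors(hap, fw, fd, v["pos_cM"].to_numpy(), g, m)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_multi_chromosome_chains_are_independent(self):
        # posterior on chrom 1 must not leak into chrom 2
        import pandas as pd

        v1 = variant_frame([1000, 2000, 3000], chrom="1")
        v2 = variant_frame([1000, 2000, 3000], chrom="2")
        v = pd.concat([v1, v2], ignore_index=True)
        fw = np.array([0.1] * 3 + [0.5] * 3)
        fd = np.array([0.9] * 3 + [0.5] * 3)
        model = AncestryModel(g=20, m=0.3, wild_freqs=fw, domestic_freqs=fd)
        hap = np.array([1, 1, 1, 0, 1, 0], dtype=np.int8)
        post = fit_posteriors(hap, model, v).p_domestic[0]
        assert (post[:3] > 0.9).all()
        assert np.allclose(post[3:], 0.3, atol=1e-12)

    def test_long_sequences_stay_finite(self):
        n = 20_000
        rng = np.random.default_rng(1)
        model = AncestryModel(g=20, m=0.2,
                              wild_freqs=rng.uniform(0.05, 0.95, n),
                              domestic_freqs=rng.uniform(0.05, 0.95, n))
        v = variant_frame(np.linspace(1, 100e6, n).astype(int))
        post = fit_posteriors(rng.integers(0, 2, n), model, v)
        assert np.isfinite(post.p_domestic).all()
        assert ((post.p_domestic >= 0) & (post.p_domestic <= 1)).all()

    def test_extreme_frequencies_rejected_unsmoothed(self):
        with pytest.raises(ValueError, match="strictly in"):
            AncestryModel(g=20, m=0.2, wild_freqs=np.array([0.0]),
                          domestic_freqs=np.array([0.5]))

    def test_smoothing_from_panel_counts(self):
        m = AncestryModel.from_frequencies(np.array([0.0, 1.0]),
                                           np.array([0.5, 0.5]),
                                           n_wild_haps=18, n_dom_haps=18)
        assert m.wild_freqs[0] == pytest.approx(1 / 20)
        assert m.wild_freqs[1] == pytest.approx(19 / 20)


class TestCalls:
    def _post(self, p):
        return AncestryPosterior(p_domestic=np.array([p], dtype=float),
                                 hap_ids=["h_h0"])

    def test_threshold_bands(self):
        post = call_ancestry(self._post([0.95, 0.85, 0.05]), 0.9)
        assert list(post.calls[0]) == [CALL_DOMESTIC, CALL_UNASSIGNED, CALL_WILD]

    def test_exact_boundaries_inclusive(self):
        post = call_ancestry(self._post([0.9, 0.1]), 0.9)
        assert list(post.calls[0]) == [CALL_DOMESTIC, CALL_WILD]

    def test_low_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_ancestry(self._post([0.5]), 0.5)


class TestSummaries:
    def test_global_proportion_all_domestic(self):
        v = variant_frame([100, 200])
        post = AncestryPosterior(np.array([[0.99, 0.99], [0.99, 0.99]]),
                                 ["s_h0", "s_h1"])
        call_ancestry(post, 0.9)
        (summ,) = global_proportions(post, v)
        assert summ.domestic_proportion == 1.0

    def test_haplotype_average(self):
        v = variant_frame([100, 200])
        post = AncestryPosterior(np.array([[0.99, 0.99], [0.01, 0.01]]),
                                 ["s_h0", "s_h1"])
        call_ancestry(post, 0.9)
        (summ,) = global_proportions(post, v)
        assert summ.domestic_proportion == pytest.approx(0.5)

    def test_unassigned_excluded_from_denominator(self):
        v = variant_frame([100, 200, 300])
        post = AncestryPosterior(np.array([[0.99, 0.7, 0.01]]), ["s_h0"])
        call_ancestry(post, 0.9)
        (summ,) = global_proportions(post, v)
        assert summ.domestic_proportion == pytest.approx(0.5)
        assert summ.n_assigned == 2

    def test_zero_assigned_flagged_undefined(self):
        v = variant_frame([100])
        post = AncestryPosterior(np.array([[0.6], [0.6]]), ["s_h0", "s_h1"])
        call_ancestry(post, 0.9)
        (summ,) = global_proportions(post, v)
        assert np.isnan(summ.domestic_proportion)


class TestTracts:
    def _tracts(self, probs, pos=None):
        v = variant_frame(pos if pos is not None else
                          (np.arange(len(probs)) + 1) * 1000)
        post = AncestryPosterior(np.array([probs], dtype=float), ["s_h0"])
        call_ancestry(post, 0.9)
        return extract_tracts(post, v)["s_h0"]

    def test_single_tract_spans_first_to_last(self):
        trs = self._tracts([0.99] * 5)
        assert len(trs) == 1
        assert (trs[0].start_bp, trs[0].stop_bp) == (1000, 5000)
        assert trs[0].ancestry == "domestic"

    def test_gap_rule_ddudw(self):
        # calls D,D,U,D,W -> [D over sites 1-4], [W over site 5]
        trs = self._tracts([0.99, 0.99, 0.7, 0.99, 0.01])
        assert [(t.ancestry, t.start_bp, t.stop_bp) for t in trs] == [
            ("domestic", 1000, 4000), ("wild", 5000, 5000)]

    def test_unassigned_between_different_calls_breaks(self):
        trs = self._tracts([0.99, 0.7, 0.01])
        assert [(t.ancestry, t.start_bp, t.stop_bp) for t in trs] == [
            ("domestic", 1000, 1000), ("wild", 3000, 3000)]

    def test_recovers_truth_tracts_on_default_scenario(self, default_study):
        from introscan.local_ancestry import AncestryModel, fit_posteriors

        ds = default_study.dataset
        model = AncestryModel.from_dataset(ds, "wild_pure",
                                           ["dom_a", "dom_b", "dom_c"])
        post = fit_posteriors(ds.haplotypes[ds.haplotype_indices("hybrid")],
                              model, ds.variants, default_study.truth.hap_ids)
        call_ancestry(post, 0.9)
        truth = default_study.truth.site_states
        called = post.calls != CALL_UNASSIGNED
        acc = (post.calls[called] == truth[called]).mean()
        assert acc >= 0.90


class TestDating:
    def test_closed_form(self):
        assert estimate_generations_from_tracts([0.1] * 5, m=0.5) == pytest.approx(20)

    def test_doubling_lengths_halves_g(self):
        g1 = estimate_generations_from_tracts([0.05, 0.1, 0.15, 0.1, 0.1], m=0.2)
        g2 = estimate_generations_from_tracts([0.1, 0.2, 0.3, 0.2, 0.2], m=0.2)
        assert g2 == pytest.approx(g1 / 2)

    def test_simulator_truth_recovery(self, default_study):
        truth = default_study.truth
        lengths = [(t.stop_bp - t.start_bp + 1) / 1e8  # 1 cM/Mb -> Morgans
                   for h in truth.hap_ids for t in truth.tracts[h]
                   if t.ancestry == "domestic"]
        ghat = estimate_generations_from_tracts(lengths,
                                                m=truth.site_states.mean())
        assert ghat == pytest.approx(20, rel=0.3)

    def test_too_few_tracts_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            estimate_generations_from_tracts([0.1] * 4, m=0.5)

    def test_backcross_expectation(self):
        assert expected_backcross_proportion(0) == 100.0
        assert expected_backcross_proportion(3) == 12.5
        assert expected_backcross_proportion(4) == 6.25

    def test_generation_time_dating(self):
        assert generations_to_years(20) == 100.0
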