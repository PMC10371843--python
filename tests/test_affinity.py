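"""Foreground/background testing engine: signatures, backgrounds, rank-sum,
heatmaps, variant scores and the evaluation harness."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fmblocks.affinity import (
    BackgroundBlock,
    MutationSignature,
    aggregate_over_mu,
    apply_variants,
    build_patient_heatmap,
    compute_delta_dba_samples,
    cumulative_rank_accuracy,
    derive_mutation_signature,
    evaluate_roc_auc,
    generate_background_blocks,
    rank_sum_p,
    rank_tfs_for_variant,
    score_variant,
)
from fmblocks.affinity import test_tf_block_significance as tf_block_significance
from fmblocks.io import GenomicIntervals
from fmblocks.mussd import MutationBlock, PatientVariant
from fmblocks.pwm import (
    ChemicalPotentialGrid,
    ShuffleSpec,
    delta_dba,
    pwm_to_energy,
)
from conftest import random_pwm, random_seq

V = PatientVariant


class TestMutationSignature:
    def test_single_variant_probability_one(self):
        genome = {"chr1": "TTACATT"}
        sig = derive_mutation_signature([V("P1", "chr1", 3, "C", "G")], genome)
        assert sig.table[("ACA", "G")] == 1.0

    def test_hand_tallied_frequencies(self):
        genome = {"chr1": "AACAACAACGT"}
        variants = [
            V("P1", "chr1", 2, "C", "G"),
            V("P2", "chr1", 2, "C", "T"),
            V("P1", "chr1", 5, "C", "G"),
            V("P3", "chr1", 5, "C", "G"),
            V("P2", "chr1", 8, "C", "A"),
            V("P3", "chr1", 9, "G", "A"),
        ]
        sig = derive_mutation_signature(variants, genome, k=3)
        # context ACA: 4 variants -> G:3, T:1
        assert sig.table[("ACA", "G")] == pytest.approx(0.75)
        assert sig.table[("ACA", "T")] == pytest.approx(0.25)
        assert sig.table[("ACG", "A")] == 1.0
        assert sig.table[("CGT", "A")] == 1.0
        for ctx in sig.contexts():
            total = sum(p for (c, _), p in sig.table.items() if c == ctx)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_edge_and_n_contexts_skipped(self):
        genome = {"chr1": "ANCAT"}
        sig = derive_mutation_signature(
            [V("P1", "chr1", 0, "A", "G"), V("P1", "chr1", 2, "C", "T")], genome
        )
        assert sig.table == {}  # pos 0 has no left flank; pos 2 context has N

    def test_fallback_uniform_for_unseen_context(self):
        sig = MutationSignature(k=3, table={})
        r = np.random.default_rng(0)
        draws = {sig.sample_alt("ACA", r) for _ in range(50)}
        assert draws == {"A", "G", "T"}  # never the center base

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            MutationSignature(k=2)


class TestBackgroundBlocks:
    genome = {"chr1": "".join("ACGT"[i % 4] for i in range(3000))}
    regions = GenomicIntervals.from_tuples([("chr1", 100, 1100)])
    sig = MutationSignature()

    def test_block_length_and_containment(self):
        blocks = generate_background_blocks(
            self.regions, 120, 20, 3, self.sig, self.genome, seed=1
        )
        assert len(blocks) == 20
        for b in blocks:
            assert b.end - b.start == 120
            assert 100 <= b.start and b.end <= 1100
            assert len(b.variants) == 3
            for pos, ref, alt in b.variants:
                assert b.start <= pos < b.end
                assert self.genome["chr1"][pos] == ref
                assert alt != ref

    def test_seed_determinism(self):
        a = generate_background_blocks(self.regions, 50, 5, 2, self.sig, self.genome, 7)
        b = generate_background_blocks(self.regions, 50, 5, 2, self.sig, self.genome, 7)
        c = generate_background_blocks(self.regions, 50, 5, 2, self.sig, self.genome, 8)
        assert [(x.start, x.variants) for x in a] == [(x.start, x.variants) for x in b]
        assert [(x.start) for x in a] != [(x.start) for x in c]

    def test_start_positions_uniform(self):
        # chi-square goodness of fit over all valid placements
        blocks = generate_background_blocks(
            self.regions, 901, 10_000, 1, self.sig, self.genome, seed=42
        )
        starts = np.array([b.start for b in blocks]) - 100
        counts = np.bincount(starts, minlength=100)  # 1000-901+1 placements
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.001

    def test_no_fitting_region_errors(self):
        with pytest.raises(ValueError):
            generate_background_blocks(
                self.regions, 5000, 1, 1, self.sig, self.genome, seed=0
            )


class TestComputeSamples:
    def _setup(self, rng):
        genome = {"chr1": random_seq(rng, 400)}
        variants = [
            V("P1", "chr1", 120, genome["chr1"][120], "A"),
            V("P2", "chr1", 140, genome["chr1"][140], "C"),
        ]
        variants = [
            v if v.ref_base != v.alt_base
            else V(v.patient_id, v.chrom, v.pos, v.ref_base,
                   "G" if v.ref_base != "G" else "T")
            for v in variants
        ]
        block = MutationBlock("block_1_chr1_101_161", "chr1", 100, 161, [], variants)
        return genome, block, variants

    def test_foreground_matches_direct_delta_dba(self, rng):
        genome, block, variants = self._setup(rng)
        models = [pwm_to_energy(random_pwm(rng, name=f"tf{i}")) for i in range(2)]
        grid = ChemicalPotentialGrid(values=np.array([-10.0, -8.0, -6.0]))
        bg = generate_background_blocks(
            GenomicIntervals.from_tuples([("chr1", 0, 400)]),
            block.span_bp, 4, 1, MutationSignature(), genome, seed=5,
        )
        shuffles = ShuffleSpec(count=3, seed=11)
        samples = compute_delta_dba_samples(
            block,
            {"P1": [variants[0]], "P2": [variants[1]]},
            genome, models, grid, bg, shuffles=shuffles,
        )
        ref = genome["chr1"][100:161]
        for model in models:
            for j, patient in enumerate(["P1", "P2"]):
                mut = apply_variants(ref, 100, [variants[j]])
                want = delta_dba(ref, mut, model, grid, background=shuffles)
                assert np.allclose(samples.fg[model.name][j], want.values, atol=1e-10)
                assert samples.fg_agg[model.name][j] == pytest.approx(
                    want.aggregate, abs=1e-12
                )

    def test_zero_variant_patient_contributes_zeros(self, rng):
        genome, block, variants = self._setup(rng)
        models = [pwm_to_energy(random_pwm(rng))]
        grid = ChemicalPotentialGrid(values=np.array([-8.0, -6.0]))
        bg = generate_background_blocks(
            GenomicIntervals.from_tuples([("chr1", 0, 400)]),
            block.span_bp, 2, 1, MutationSignature(), genome, seed=5,
        )
        samples = compute_delta_dba_samples(
            block, {"P1": [variants[0]], "P9": []}, genome, models, grid, bg
        )
        assert samples.zero_patients == ["P9"]
        i = samples.patients.index("P9")
        assert np.all(samples.fg[models[0].name][i] == 0.0)

    def test_background_sample_count(self, rng):
        genome, block, variants = self._setup(rng)
        models = [pwm_to_energy(random_pwm(rng))]
        grid = ChemicalPotentialGrid(values=np.array([-8.0]))
        bg = generate_background_blocks(
            GenomicIntervals.from_tuples([("chr1", 0, 400)]),
            block.span_bp, 7, 2, MutationSignature(), genome, seed=5,
        )
        samples = compute_delta_dba_samples(
            block, {"P1": [variants[0]]}, genome, models, grid, bg
        )
        assert samples.bg[models[0].name].shape == (7, 1)


def exhaustive_rank_sum_p(fg, bg):
    """Two-sided rank-sum p by enumerating every fg/bg label assignment."""
    pooled = np.concatenate([fg, bg])
    n, m = len(fg), len(bg)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        us.append(ranks[list(combo)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    mean = n * m / 2
    p = np.mean(np.abs(us - mean) >= abs(u_obs - mean) - 1e-12)
    return float(p)


class TestRankSum:
    def test_identical_multisets_p_one(self):
        fg = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert rank_sum_p(fg, fg.copy()) >= 0.99

    def test_complete_separation_exact(self):
        fg = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        bg = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        assert rank_sum_p(fg, bg) == pytest.approx(2 / 252, rel=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        for n in range(2, 7):
            for m in range(2, 13 - n):
                fg = rng.normal(size=n)
                bg = rng.normal(size=m)
                got = rank_sum_p(fg, bg)
                want = exhaustive_rank_sum_p(fg, bg)
                assert got == pytest.approx(want, rel=1e-9), (n, m)

    def test_constant_samples_p_one(self):
        assert rank_sum_p(np.zeros(5), np.zeros(8)) == 1.0


class TestTfBlockSignificance:
    def _samples(self, fg_by_tf, bg_by_tf):
        from fmblocks.affinity import DeltaDbaSamples

        mus = np.array([-8.0])
        return DeltaDbaSamples(
            block_id="b1",
            patients=[f"P{i}" for i in range(len(next(iter(fg_by_tf.values()))))],
            mus=mus,
            fg={tf: np.asarray(v)[:, None] for tf, v in fg_by_tf.items()},
            bg={tf: np.asarray(v)[:, None] for tf, v in bg_by_tf.items()},
            fg_agg={tf: np.asarray(v, dtype=float) for tf, v in fg_by_tf.items()},
            bg_agg={tf: np.asarray(v, dtype=float) for tf, v in bg_by_tf.items()},
        )

    def test_bonferroni_over_tested_tfs(self):
        fg = {"t1": [5.0, 6, 7, 8], "t2": [0.1, -0.2, 0.3, -0.1]}
        bg = {"t1": [0.0, 0.1, -0.1, 0.2, 0.0], "t2": [0.0, 0.1, -0.1, 0.2, 0.0]}
        tests = tf_block_significance(self._samples(fg, bg))
        assert len(tests) == 2
        for t in tests:
            assert t.p_adjusted == pytest.approx(min(1.0, t.p_value * 2))

    def test_direction_from_median_display_change(self):
        # positive delta_dbA = binding lost
        fg = {"t1": [5.0, 6, 7, 8]}
        bg = {"t1": [0.0, 0.1, -0.1, 0.2]}
        (t,) = tf_block_significance(self._samples(fg, bg))
        assert t.direction == "loss"
        fg = {"t1": [-5.0, -6, -7, -8]}
        (t,) = tf_block_significance(self._samples(fg, bg))
        assert t.direction == "gain"

    def test_small_samples_skipped(self):
        fg = {"t1": [1.0, 2.0]}
        bg = {"t1": [0.0, 1, 2, 3]}
        assert tf_block_significance(self._samples(fg, bg), min_n=3) == []


class TestPatientHeatmap:
    def _samples(self, fg_agg, bg_agg):
        from fmblocks.affinity import DeltaDbaSamples

        return DeltaDbaSamples(
            block_id="b1",
            patients=[f"P{i}" for i in range(len(next(iter(fg_agg.values()))))],
            mus=np.array([-8.0]),
            fg={}, bg={},
            fg_agg={tf: np.asarray(v, dtype=float) for tf, v in fg_agg.items()},
            bg_agg={tf: np.asarray(v, dtype=float) for tf, v in bg_agg.items()},
        )

    def test_hand_counted_empirical_probability(self):
        samples = self._samples({"t1": [2.5]}, {"t1": [1.0, -2.0, 3.0, -4.0]})
        hm = build_patient_heatmap(samples)
        # 2 of 4 background magnitudes >= 2.5 -> p_emp = 3/5; sign: loss
        want = -(-math.log10(0.6))
        assert hm.matrix.loc["t1", "P0"] == pytest.approx(want, rel=1e-12)

    def test_zero_aggregate_gives_zero_cell(self):
        samples = self._samples({"t1": [0.0]}, {"t1": [1.0, 2.0]})
        hm = build_patient_heatmap(samples)
        assert hm.matrix.loc["t1", "P0"] == 0.0

    def test_extreme_patient_hits_smoothed_floor(self):
        # p_emp floor 1/(B+1); aggregate +9 is a binding loss, so the signed
        # cell is negative
        samples = self._samples({"t1": [9.0]}, {"t1": [1.0, 2.0, 3.0, 4.0]})
        hm = build_patient_heatmap(samples)
        assert hm.matrix.loc["t1", "P0"] == pytest.approx(-math.log10(5), rel=1e-12)

    def test_rpkm_filter_drops_rows(self):
        samples = self._samples(
            {"t1": [1.0], "t2": [1.0]}, {"t1": [0.5], "t2": [0.5]}
        )
        hm = build_patient_heatmap(
            samples, tf_expression={"t1": 0.001, "t2": 1.0}, rpkm_threshold=0.03
        )
        assert list(hm.matrix.index) == ["t2"]

    def test_significance_cutoff_filters_rows(self):
        samples = self._samples(
            {"t1": [1.0], "t2": [1.0]}, {"t1": [0.5], "t2": [0.5]}
        )
        hm = build_patient_heatmap(
            samples, tf_p_values={"t1": 0.001, "t2": 0.5}, p_cutoff=0.01
        )
        assert list(hm.matrix.index) == ["t1"]


class TestScoreVariant:
    def _genome_and_models(self, rng, n_models=5):
        genome = {"chr1": random_seq(rng, 200)}
        models = [pwm_to_energy(random_pwm(rng, name=f"tf{i}")) for i in range(n_models)]
        return genome, models

    def _variant(self, genome, pos=100):
        ref = genome["chr1"][pos]
        alt = "A" if ref != "A" else "C"
        return V("q", "chr1", pos, ref, alt)

    def test_mean_of_fewer_than_top_n(self, rng):
        genome, models = self._genome_and_models(rng, 3)
        v = self._variant(genome)
        grid = ChemicalPotentialGrid(values=np.array([-8.0, -6.0]))
        aggs = []
        for m in models:
            L = len(m)
            ref = genome["chr1"][v.pos - (L - 1): v.pos + L]
            mut = ref[: L - 1] + v.alt_base + ref[L:]
            aggs.append(
                delta_dba(ref, mut, m, grid, background=ShuffleSpec(count=0)).aggregate
            )
        want = np.mean(np.abs(aggs))
        got = score_variant(v, genome, models, grid, top_n=20)
        assert got == pytest.approx(want, rel=1e-9)

    def test_invariant_to_pwm_order(self, rng):
        genome, models = self._genome_and_models(rng, 6)
        v = self._variant(genome)
        a = score_variant(v, genome, models, top_n=3)
        b = score_variant(v, genome, models[::-1], top_n=3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_context_off_chromosome_errors(self, rng):
        genome, models = self._genome_and_models(rng)
        v = self._variant(genome, pos=2)
        with pytest.raises(ValueError):
            score_variant(v, genome, models)

    def test_ranked_tfs_sorted_by_impact(self, rng):
        genome, models = self._genome_and_models(rng, 4)
        v = self._variant(genome)
        ranked = rank_tfs_for_variant(v, genome, models)
        assert sorted(ranked) == sorted(m.name for m in models)


class TestRocAuc:
    def test_perfect_separation(self):
        assert evaluate_roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert evaluate_roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0]) == 0.5

    def test_pairwise_enumeration_example(self):
        assert evaluate_roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_roc_auc([0.5, 0.6], [1, 1])


class TestCumulativeRankAccuracy:
    def test_definition(self):
        ranked = {
            "v1": ["a", "b", "c"],
            "v2": ["x", "y", "z", "t"],
            "v3": ["m"] * 29 + ["t3"],
        }
        truth = {"v1": {"a"}, "v2": {"t"}, "v3": {"t3"}}
        acc = cumulative_rank_accuracy(ranked, truth, [1, 4, 10, 30])
        assert acc[1] == pytest.approx(1 / 3)
        assert acc[4] == pytest.approx(2 / 3)
        assert acc[10] == pytest.approx(2 / 3)
        assert acc[30] == pytest.approx(1.0)

    def test_absent_truth_never_hits(self):
        acc = cumulative_rank_accuracy({"v": ["a", "b"]}, {"v": {"zz"}}, [1, 2, 99])
        assert all(v == 0 for v in acc.values())

    def test_cluster_entries_hit_on_membership(self):
        ranked = {"v": [("p1", "p2"), ("p3",)]}
        acc = cumulative_rank_accuracy(ranked, {"v": {"p3"}}, [1, 2])
        assert acc[1] == 0.0 and acc[2] == 1.0


def test_aggregate_over_mu_modes():
    vals = np.array([[0.5, -2.0, 1.0], [1.0, 1.0, 1.0]])
    assert np.allclose(aggregate_over_mu(vals, "max"), [-2.0, 1.0])
    assert np.allclose(aggregate_over_mu(vals, "mean"), [-1 / 6, 1.0])
    with pytest.raises(ValueError):
        aggregate_over_mu(vals, "median")


def test_apply_variants_checks_reference():
    with pytest.raises(ValueError, match="mismatch"):
        apply_variants("ACGT", 100, [(101, "G", "T")])
    assert apply_variants("ACGT", 100, [(101, "C", "T")]) == "ATGT"
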