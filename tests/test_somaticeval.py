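"""Pileup, binomial somatic calling, truth-set evaluation, contamination
sweep."""

import math

import numpy as np
import pytest

import pdxpurity as px
from pdxpurity.somaticeval import PileupTable, _check_bins
from pdxpurity.synthdata import Contig, Read, SpeciesGenome

from conftest import close_binomial


def table_from_cases(cases, contig="human_1"):
    """Build a PileupTable with one position per (ref_idx, counts) case."""
    counts = np.zeros((4, len(cases)), dtype=np.int32)
    for pos, site in enumerate(cases):
        for base_idx, c in site.items():
            counts[base_idx, pos] = c
    return PileupTable({contig: counts})


def ref_genome(length, base="A", contig="human_1"):
    return SpeciesGenome([Contig(contig, "human", base * length)])


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class TestPileup:
    def test_single_error_free_read(self, genome_pair, hybrid_ref):
        human, _ = genome_pair
        reads = px.simulate_reads(human, 30, 100, 0.0, seed=60)[:1]
        alns = px.align_reads(reads, hybrid_ref)
        pt = px.pileup(alns, reads, hybrid_ref)
        depth = pt.depth("human_1")
        assert depth.sum() == 100
        codes = pt.counts["human_1"]
        seq = human.contigs[0].sequence
        for pos in np.flatnonzero(depth):
            assert codes["ACGT".index(seq[pos]), pos] == 1

    def test_disagreeing_overlap_counts_both_alleles(self, hybrid_ref,
                                                     genome_pair):
        human, _ = genome_pair
        seq = human.contigs[0].sequence
        r1 = Read("a", seq[300:400], "human", "human_1", 300, "+")
        mutated = list(seq[300:400])
        mutated[50] = "ACGT".replace(mutated[50], "")[0]
        r2 = Read("b", "".join(mutated), "human", "human_1", 300, "+")
        pt = px.pileup(px.align_reads([r1, r2], hybrid_ref), [r1, r2],
                       hybrid_ref)
        col = pt.counts["human_1"][:, 350]
        assert col.sum() == 2 and col.max() == 1   # ref:1, alt:1

    def test_missing_read_rejected(self, hybrid_ref):
        rec = px.AlignmentRecord("ghost", "human_1", 0, "+", 100, 1,
                                 "unique")
        with pytest.raises(ValueError):
            px.pileup([rec], [], hybrid_ref)

    def test_modal_depth_near_target(self, genome_pair, hybrid_ref):
        human, _ = genome_pair
        reads = px.simulate_reads(human, 30, 100, 0.0, seed=61)
        keep = px.exclude_mouse(px.align_reads(reads, hybrid_ref),
                                hybrid_ref)
        pt = px.pileup(keep, reads, hybrid_ref)
        depth = pt.depth("human_1")[100:-100]
        vals, cnts = np.unique(depth, return_counts=True)
        assert abs(vals[cnts.argmax()] - 30) <= 5


# ---------------------------------------------------------------------------
# call_somatic
# ---------------------------------------------------------------------------

class TestCallSomatic:
    def test_clear_somatic_site_called(self):
        tumor = table_from_cases([{0: 30, 1: 30}])        # 30 alt / 60
        normal = table_from_cases([{0: 30}])
        calls = px.call_somatic(tumor, normal, ref_genome(1))
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref, c.alt, c.depth, c.alt_count) == ("A", "C", 60, 30)
        assert c.p_value < 1e-30

    def test_no_alt_reads_not_called(self):
        tumor = table_from_cases([{0: 60}])
        normal = table_from_cases([{0: 30}])
        assert px.call_somatic(tumor, normal, ref_genome(1)) == []

    def test_germline_site_excluded(self):
        tumor = table_from_cases([{0: 30, 1: 30}])
        normal = table_from_cases([{0: 15, 1: 15}])
        assert px.call_somatic(tumor, normal, ref_genome(1)) == []

    def test_bad_error_rate_rejected(self):
        with pytest.raises(ValueError):
            px.CallerParams(error_rate=0.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        """Caller decisions equal brute-force enumeration over every
        (depth <= 12, alt count) pileup."""
        params = px.CallerParams()
        cases, expected = [], []
        for depth in range(1, 13):
            for alt in range(depth + 1):
                cases.append({0: depth - alt, 1: alt})
                p = params.error_rate / 3.0
                tail = sum(math.comb(depth, j) * p**j * (1 - p)**(depth - j)
                           for j in range(alt, depth + 1))
                expected.append(depth >= params.min_tumor_depth
                                and alt >= params.min_alt
                                and tail < params.alpha)
        tumor = table_from_cases(cases)
        normal = table_from_cases([{0: 30}] * len(cases))
        calls = px.call_somatic(tumor, normal, ref_genome(len(cases)),
                                params)
        called = {c.pos for c in calls}
        for pos, want in enumerate(expected):
            assert (pos in called) == want, (pos, cases[pos])


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _call(contig, pos, alt, depth=60, alt_count=30):
    return px.VariantCall(contig=contig, pos=pos, ref="A", alt=alt,
                          depth=depth, alt_count=alt_count, p_value=1e-9)


class TestEvaluate:
    def test_perfect_calls(self):
        truth = [px.SomaticMutation("human_1", i, "A", "C", 0.5)
                 for i in range(5)]
        calls = [_call("human_1", m.pos, m.alt) for m in truth]
        overall = px.evaluate(calls, truth)[-1]
        assert (overall.precision, overall.recall, overall.f1) == (1, 1, 1)

    def test_flooded_by_false_positives(self):
        """9 true and 187 spurious calls give precision 9/196."""
        truth = [px.SomaticMutation("human_1", i, "A", "C", 0.5)
                 for i in range(9)]
        calls = [_call("human_1", m.pos, m.alt) for m in truth]
        calls += [_call("human_1", 1000 + i, "G") for i in range(187)]
        overall = px.evaluate(calls, truth)[-1]
        assert (overall.tp, overall.fp, overall.fn) == (9, 187, 0)
        assert overall.precision == pytest.approx(9 / 196)

    def test_no_calls_with_truth(self):
        truth = [px.SomaticMutation("human_1", 5, "A", "C", 0.5)]
        overall = px.evaluate([], truth)[-1]
        assert overall.recall == 0.0 and overall.f1 == 0.0

    def test_wrong_alt_is_false_positive(self):
        truth = [px.SomaticMutation("human_1", 5, "A", "C", 0.5)]
        overall = px.evaluate([_call("human_1", 5, "G")], truth)[-1]
        assert (overall.tp, overall.fp, overall.fn) == (0, 1, 1)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            _check_bins([(0.0, 0.5), (0.4, 1.0)])

    def test_empty_bin_conventions(self):
        pt = px.EvalPoint(lam=None, vaf_bin=(0.0, 1.0), tp=0, fp=0, fn=0)
        assert (pt.precision, pt.recall, pt.f1) == (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# contamination sweep
# ---------------------------------------------------------------------------

class TestContaminationSweep:
    def test_empty_lambda_grid_rejected(self):
        with pytest.raises(ValueError):
            px.ContaminationConfig(lambdas=[])

    def test_truth_partition_at_every_lambda(self, sweep_result):
        """tp + fn = |truth| for the overall row of each lambda."""
        overall = sweep_result.table.query("vaf_lo == 0 and vaf_hi == 1")
        n_truth = len(sweep_result.truth)
        for _, row in overall.iterrows():
            assert row.tp + row.fn == n_truth
            assert row.tp >= 0 and row.fp >= 0 and row.fn >= 0

    def test_clean_sample_high_vaf_near_perfect(self, sweep_result):
        """lambda = 0 with ample depth: VAF >= 0.2 bins call essentially
        perfectly."""
        tab = sweep_result.table
        high = tab.query("`lambda` == 0 and vaf_lo >= 0.2")
        assert (high.f1 >= 0.95).all()

    def test_contamination_hurts_low_vaf_f1(self, sweep_result):
        tab = sweep_result.table
        low = tab.query("vaf_lo == 0 and vaf_hi < 1").set_index("lambda")
        assert low.loc[0.9, "f1"] < low.loc[0.0, "f1"]

    def test_depth_loss_matches_binomial_expectation(self, sweep_result):
        """Mean human DoC at lambda within 4 sigma of (1 - lambda) * 60."""
        L, rl, doc = 20_000, 100, 60
        n0 = round(2 * doc * L / rl)   # simulated before the 2x downsample
        for lam, prof in sweep_result.coverage.items():
            p = 0.5 * (1 - lam)
            sd = math.sqrt(n0 * p * (1 - p)) * rl / L
            assert abs(prof.mean_doc - (1 - lam) * doc) <= 4 * sd + 0.1

    def test_spiked_vaf_recovered_from_pileup(self, sweep_result):
        """Observed alt fractions at truth sites are binomial around the
        spiked VAF (pooled per VAF level, lambda = 0)."""
        calls = sweep_result.calls[0.0]
        by_site = {(c.contig, c.pos, c.alt): c for c in calls}
        pooled: dict[float, list[tuple[int, int]]] = {}
        for m in sweep_result.truth:
            c = by_site.get((m.contig, m.pos, m.alt))
            if c is not None:
                pooled.setdefault(m.vaf, []).append((c.alt_count, c.depth))
        for vaf, obs in pooled.items():
            alt = sum(a for a, _ in obs)
            depth = sum(d for _, d in obs)
            assert close_binomial(alt, depth, vaf)

    def test_human_only_and_hybrid_agree_without_mouse_reads(self):
        """With no contamination and no species-shared segment, calling
        after hybrid alignment equals calling after human-only alignment."""
        cfg = px.GenomePairConfig(length=10_000, divergence=0.10, seed=71)
        human, mouse = px.make_genome_pair(cfg)
        muts = px.spike_mutation_set(human, 20, [0.2, 0.5], seed=72)
        reads = px.spike_reads(
            px.simulate_reads(human, 60, 100, 0.0, seed=73), muts, seed=74)
        normal = px.simulate_reads(human, 30, 100, 0.0, seed=75)
        call_sets = []
        for ref in (px.build_reference(human, k=15),
                    px.build_reference(human, mouse, k=15)):
            keep_t = px.exclude_mouse(px.align_reads(reads, ref), ref)
            keep_n = px.exclude_mouse(px.align_reads(normal, ref), ref)
            calls = px.call_somatic(px.pileup(keep_t, reads, ref),
                                    px.pileup(keep_n, normal, ref), ref)
            call_sets.append({(c.contig, c.pos, c.alt) for c in calls})
        assert call_sets[0] == call_sets[1]

    def test_sweep_bit_reproducible(self):
        kw = dict(n_mutations=10, vafs=(0.5,), normal_doc=10, tumor_doc=20,
                  read_len=100)
        args = (px.ContaminationConfig(lambdas=(0.0, 0.5), seed=5),
                px.GenomePairConfig(length=5000, divergence=0.10, seed=5))
        a = px.contamination_sweep(*args, **kw)
        b = px.contamination_sweep(*args, **kw)
        assert a.table.equals(b.table)
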