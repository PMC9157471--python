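"""Site calling, length-constrained intron pairing and exon assembly."""

import itertools

import numpy as np
import pytest

from conftest import random_dna
from splicewindow.dataset_builder import find_dinucleotide_positions
from splicewindow.exon_caller import (
    ExonCall,
    IntronCall,
    SpliceCall,
    assemble_exons,
    call_introns,
    classify_candidates,
    evaluate_against_truth,
    scan_candidates,
    summarize,
)
from splicewindow.sequence_io import GenomeSequence


class StubModel:
    """Deterministic stand-in classifier: maps center dinucleotide to a
    fixed probability row (synthetic; used to isolate caller logic)."""

    def __init__(self, rows):
        self.rows = rows

    def predict_proba(self, X):
        out = np.empty((len(X), 3))
        for k, row in enumerate(X):
            center = tuple(row[29:31])
            key = {(2, 3): "GT", (1, 2): "AG"}.get(center, "other")
            out[k] = self.rows[key]
        return out


ORACLE_STUB = StubModel({
    "GT": (0.9, 0.05, 0.05),
    "AG": (0.05, 0.9, 0.05),
    "other": (0.05, 0.05, 0.9),
})


class TestScanCandidates:
    def test_single_gt_with_full_flanks(self):
        residues = "C" * 40 + "GT" + "C" * 40
        seq = GenomeSequence("s", residues)
        cands = scan_candidates(seq)
        assert [(p, d) for p, d, _ in cands] == [(41, "GT")]
        assert cands[0][2] == residues[11:71]

    def test_gt_near_edge_skipped(self):
        seq = GenomeSequence("s", "CCCC" + "GT" + "C" * 80)
        cands = scan_candidates(seq)
        assert all(p != 5 for p, _, _ in cands)

    def test_count_matches_dinucleotide_scan(self, rng):
        seq = GenomeSequence("s", random_dna(rng, 2000))
        expected = sum(
            1
            for dinuc in ("GT", "AG")
            for p in find_dinucleotide_positions(seq, dinuc)
            if 30 <= p <= seq.length - 30
        )
        assert len(scan_candidates(seq)) == expected


class TestClassifyCandidates:
    def test_argmax_becomes_typed_call(self, rng):
        seq = GenomeSequence("s", "C" * 40 + "GT" + "C" * 40)
        calls = classify_candidates(ORACLE_STUB, scan_candidates(seq), "s")
        assert len(calls) == 1
        call = calls[0]
        assert call.site_type == "donor" and call.pos == 41
        assert call.probability == pytest.approx(0.9)

    def test_type_label_mismatch_dropped(self):
        # classifier votes acceptor on a GT candidate -> dropped
        stub = StubModel({
            "GT": (0.1, 0.8, 0.1),
            "AG": (0.8, 0.1, 0.1),
            "other": (0.1, 0.1, 0.8),
        })
        seq = GenomeSequence("s", "C" * 40 + "GT" + "C" * 30 + "AG" + "C" * 40)
        assert classify_candidates(stub, scan_candidates(seq), "s") == []

    def test_probability_tie_resolves_to_no_site(self):
        stub = StubModel({
            "GT": (0.4, 0.2, 0.4),
            "AG": (0.2, 0.4, 0.4),
            "other": (0.1, 0.1, 0.8),
        })
        seq = GenomeSequence("s", "C" * 40 + "GT" + "C" * 40)
        assert classify_candidates(stub, scan_candidates(seq), "s") == []


def _sites(donors, acceptors):
    calls = [SpliceCall("s", p, "donor", 1.0) for p in donors]
    calls += [SpliceCall("s", p, "acceptor", 1.0) for p in acceptors]
    return sorted(calls, key=lambda c: c.pos)


class TestCallIntrons:
    def test_length_filter_selects_in_range_acceptor(self):
        introns = call_introns(_sites([101], [130, 195]))
        assert [(i.donor_pos, i.acceptor_pos) for i in introns] == [(101, 195)]
        assert introns[0].length == 96

    def test_no_acceptor_in_range_gives_no_intron(self):
        assert call_introns(_sites([101], [500])) == []

    def test_calls_are_non_overlapping_and_sorted(self, rng):
        donors = sorted(rng.choice(5000, 80, replace=False))
        acceptors = sorted(rng.choice(5000, 80, replace=False))
        introns = call_introns(_sites(donors, acceptors))
        for a, b in itertools.pairwise(introns):
            assert a.end < b.start
        assert all(70 <= i.length <= 100 for i in introns)

    def test_widening_range_never_removes_introns(self, rng):
        donors = sorted(rng.choice(3000, 50, replace=False))
        acceptors = sorted(rng.choice(3000, 50, replace=False))
        narrow = call_introns(_sites(donors, acceptors), 70, 100)
        wide = call_introns(_sites(donors, acceptors), 60, 110)
        assert len(wide) >= len(narrow)

    def test_greedy_matches_exhaustive_oracle_cardinality(self, rng):
        """On small instances greedy should usually find the maximum set of
        non-overlapping in-range pairs (≥ 95% of random instances)."""

        def oracle_max(donors, acceptors, lo=70, hi=100):
            sites = [(p, "d") for p in donors] + [(p, "a") for p in acceptors]
            best = 0
            pairs = [
                (d, a)
                for d in donors
                for a in acceptors
                if lo <= a + 1 - d + 1 <= hi
            ]
            for r in range(len(pairs), 0, -1):
                for combo in itertools.combinations(pairs, r):
                    spans = sorted((d, a + 1) for d, a in combo)
                    used = [p for pair in combo for p in pair]
                    ok = len(set(used)) == len(used) and all(
                        s2 > e1 for (_, e1), (s2, _) in itertools.pairwise(spans)
                    )
                    if ok:
                        return r
            return best

        agree = 0
        trials = 40
        for _ in range(trials):
            positions = sorted(rng.choice(400, size=10, replace=False))
            donors = [int(p) for k, p in enumerate(positions) if k % 2 == 0]
            acceptors = [int(p) for k, p in enumerate(positions) if k % 2 == 1]
            greedy = len(call_introns(_sites(donors, acceptors)))
            assert greedy <= oracle_max(donors, acceptors)
            if greedy == oracle_max(donors, acceptors):
                agree += 1
        assert agree / trials >= 0.95


class TestAssembleExons:
    def test_complement_arithmetic(self):
        introns = [IntronCall("s", 101, 195)]  # span 101..196
        exons = assemble_exons((1, 300), introns, "s")
        assert [(e.start, e.end) for e in exons] == [(1, 100), (197, 300)]

    def test_no_introns_gives_span_itself(self):
        exons = assemble_exons((5, 50), [], "s")
        assert [(e.start, e.end) for e in exons] == [(5, 50)]

    def test_intron_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assemble_exons((1, 100), [IntronCall("s", 90, 140)], "s")

    def test_length_conservation(self, rng):
        for _ in range(20):
            span = (1, int(rng.integers(500, 2000)))
            cursor, introns = 50, []
            while cursor + 120 < span[1]:
                donor = cursor + int(rng.integers(5, 40))
                introns.append(IntronCall("s", donor, donor + 80))
                cursor = donor + 82
            exons = assemble_exons(span, introns, "s")
            total = sum(e.length for e in exons) + sum(i.length for i in introns)
            assert total == span[1] - span[0] + 1
            assert len(exons) == len(introns) + 1


class TestSummarize:
    def test_hand_means(self):
        exons = [ExonCall("s", 1, 100), ExonCall("s", 197, 300)]
        stats = summarize(exons, [])
        assert stats.n_exons == 2 and stats.mean_exon_length == 102

    def test_empty_inputs_give_zeros(self):
        stats = summarize([], [])
        assert (stats.n_exons, stats.n_introns) == (0, 0)
        assert stats.mean_exon_length == stats.mean_intron_length == 0

    def test_matches_independent_recomputation(self, rng):
        introns = [
            IntronCall("s", int(p), int(p) + int(rng.integers(68, 99)))
            for p in rng.choice(10000, 30, replace=False)
        ]
        stats = summarize([], introns)
        lengths = [(i.acceptor_pos + 1) - i.donor_pos + 1 for i in introns]
        assert stats.n_introns == 30
        assert stats.mean_intron_length == round(sum(lengths) / len(lengths))


class TestEvaluateAgainstTruth:
    def test_perfect_prediction(self):
        sites = _sites([10, 200], [95, 285])
        exons = [ExonCall("s", 1, 9)]
        metrics = evaluate_against_truth(
            sites, exons, [10, 200], [95, 285], [(1, 9)]
        )
        for m in metrics.values():
            assert m.precision == m.recall == m.f1 == 1.0

    def test_empty_predictions_flagged(self):
        metrics = evaluate_against_truth([], [], [10], [95], [(1, 9)])
        assert metrics["donor"].recall == 0.0
        assert metrics["donor"].precision == 0.0
        assert metrics["donor"].precision_undefined

    def test_matches_set_intersection_oracle(self, rng):
        pred_d = set(map(int, rng.choice(1000, 40, replace=False)))
        truth_d = set(map(int, rng.choice(1000, 40, replace=False)))
        sites = _sites(sorted(pred_d), [])
        metrics = evaluate_against_truth(sites, [], sorted(truth_d), [], [])
        tp = len(pred_d & truth_d)
        assert metrics["donor"].precision == pytest.approx(tp / 40)
        assert metrics["donor"].recall == pytest.approx(tp / 40)

    def test_coordinate_mismatch_detected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_against_truth([], [], [500], [], [], seq_length=100)
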