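"""Splice-site calling, intron pairing under a length constraint, and exon
assembly.

Candidate windows are cut around every GT and AG occurrence with the same
geometry used in training. A GT candidate becomes a donor call only when
the classifier's argmax label is the donor class (and symmetrically for
AG/acceptor); mismatched candidates are dropped. Called donors and
acceptors are then paired greedily left to right, keeping only pairs whose
implied intron length falls inside ``[min_intron, max_intron]`` (defaults
70–100 nt), and exons are the complementary spans within a gene span.

Intron length convention: first base of GT through last base of AG,
inclusive — ``acceptor_pos + 1 - donor_pos + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .dataset_builder import (
    ACCEPTOR,
    DONOR,
    LEFT_FLANK,
    WINDOW,
    encode_window,
    extract_window,
    find_dinucleotide_positions,
)
from .sequence_io import GenomeSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpliceCall:
    seq_id: str
    pos: int  # 1-based first base of the dinucleotide
    site_type: str  # "donor" or "acceptor"
    probability: float
    support: int = 1

    def __post_init__(self):
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"bad site_type {self.site_type!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class IntronCall:
    seq_id: str
    donor_pos: int
    acceptor_pos: int  # first base of the terminal AG

    kind = "intron"

    @property
    def start(self) -> int:
        return self.donor_pos

    @property
    def end(self) -> int:
        return self.acceptor_pos + 1

    @property
    def length(self) -> int:
        return self.acceptor_pos + 1 - self.donor_pos + 1


@dataclass(frozen=True)
class ExonCall:
    seq_id: str
    start: int
    end: int

    kind = "exon"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PredictionSummary:
    """Counts and integer-rounded mean lengths of the reported calls."""

    n_exons: int
    n_introns: int
    mean_exon_length: int
    mean_intron_length: int


def scan_candidates(
    seq: GenomeSequence,
    window: int = WINDOW,
    left_flank: int = LEFT_FLANK,
) -> list[tuple[int, str, str]]:
    """One candidate per GT and per AG occurrence with full flanks.

    Returns ``(pos, dinucleotide, window_residues)`` triples; positions
    whose window would run off the sequence or contain N are skipped.
    """
    candidates: list[tuple[int, str, str]] = []
    for dinuc in ("GT", "AG"):
        for pos in find_dinucleotide_positions(seq, dinuc):
            residues = extract_window(seq, pos, window, left_flank)
            if residues is not None:
                candidates.append((pos, dinuc, residues))
    candidates.sort()
    return candidates


def classify_candidates(
    model,
    candidates: Sequence[tuple[int, str, str]],
    seq_id: str,
    batch_size: int = 1024,
) -> list[SpliceCall]:
    """Turn classifier output into site calls.

    A GT candidate is kept iff its argmax label is the donor class; an AG
    candidate iff acceptor. Exact probability ties resolve to no-site
    (conservative). Returns calls sorted by position.
    """
    if not candidates:
        return []
    X = np.stack([encode_window(res) for _, _, res in candidates])
    calls: list[SpliceCall] = []
    for start in range(0, len(X), batch_size):
        chunk = candidates[start : start + batch_size]
        probs = model.predict_proba(X[start : start + batch_size])
        labels = probs.argmax(axis=1)
        ties = probs[np.arange(len(probs)), labels] == probs[:, 2]
        labels[ties] = 2
        for (pos, dinuc, _), label, p in zip(chunk, labels, probs):
            if dinuc == "GT" and label == DONOR:
                calls.append(SpliceCall(seq_id, pos, "donor", float(p[DONOR])))
            elif dinuc == "AG" and label == ACCEPTOR:
                calls.append(SpliceCall(seq_id, pos, "acceptor", float(p[ACCEPTOR])))
    calls.sort(key=lambda c: c.pos)
    return calls


def call_introns(
    calls: Sequence[SpliceCall],
    min_intron: int = 70,
    max_intron: int = 100,
) -> list[IntronCall]:
    """Greedy left-to-right donor–acceptor pairing under the length filter.

    Each unconsumed donor takes the nearest unconsumed downstream acceptor
    whose implied intron length lies in ``[min_intron, max_intron]``; both
    sites are then consumed and any site inside the called intron span is
    skipped, so the result is non-overlapping and sorted.
    """
    if min_intron < 4 or max_intron < min_intron:
        raise ValueError("need 4 ≤ min_intron ≤ max_intron")
    import bisect

    ordered = sorted(calls, key=lambda c: c.pos)
    acc_pos = sorted(c.pos for c in ordered if c.site_type == "acceptor")
    consumed: set[int] = set()
    introns: list[IntronCall] = []
    last_end = 0
    for call in ordered:
        if call.site_type != "donor" or call.pos in consumed or call.pos <= last_end:
            continue
        lo = call.pos + min_intron - 2  # acceptor_pos giving length == min
        hi = call.pos + max_intron - 2
        j = bisect.bisect_left(acc_pos, lo)
        while j < len(acc_pos) and acc_pos[j] <= hi:
            if acc_pos[j] not in consumed and acc_pos[j] > last_end:
                introns.append(IntronCall(call.seq_id, call.pos, acc_pos[j]))
                consumed.update((call.pos, acc_pos[j]))
                last_end = acc_pos[j] + 1
                break
            j += 1
    return introns


def assemble_exons(
    gene_span: tuple[int, int],
    introns: Sequence[IntronCall],
    seq_id: str = "",
) -> list[ExonCall]:
    """Complement the introns within a gene span: k introns → k+1 exons
    (empty leading/trailing spans dropped)."""
    start, end = gene_span
    if start > end:
        raise ValueError(f"invalid gene span ({start}, {end})")
    ordered = sorted(introns, key=lambda i: i.start)
    exons: list[ExonCall] = []
    cursor = start
    for intron in ordered:
        if intron.start < start or intron.end > end:
            raise ValueError(
                f"intron ({intron.start}, {intron.end}) outside gene span "
                f"({start}, {end})"
            )
        if intron.start < cursor:
            raise ValueError("introns overlap or are unsorted")
        if intron.start > cursor:
            exons.append(ExonCall(seq_id or intron.seq_id, cursor, intron.start - 1))
        cursor = intron.end + 1
    if cursor <= end:
        exons.append(ExonCall(seq_id, cursor, end))
    return exons


def summarize(
    exons: Sequence[ExonCall], introns: Sequence[IntronCall]
) -> PredictionSummary:
    """Counts and integer-rounded mean lengths."""
    def mean_len(spans) -> int:
        if not spans:
            return 0
        return int(round(float(np.mean([s.length for s in spans]))))

    return PredictionSummary(
        n_exons=len(exons),
        n_introns=len(introns),
        mean_exon_length=mean_len(exons),
        mean_intron_length=mean_len(introns),
    )


@dataclass(frozen=True)
class MatchMetrics:
    precision: float
    recall: float
    f1: float
    n_predicted: int
    n_truth: int
    n_matched: int
    precision_undefined: bool = False


def _prf(predicted: set, truth: set) -> MatchMetrics:
    matched = len(predicted & truth)
    undefined = len(predicted) == 0
    precision = matched / len(predicted) if predicted else 0.0
    recall = matched / len(truth) if truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MatchMetrics(
        precision, recall, f1, len(predicted), len(truth), matched,
        precision_undefined=undefined,
    )


def evaluate_against_truth(
    predicted_sites: Iterable[SpliceCall],
    predicted_exons: Iterable[ExonCall],
    truth_donors: Iterable[int],
    truth_acceptors: Iterable[int],
    truth_exons: Iterable[tuple[int, int]],
    seq_length: Optional[int] = None,
) -> dict[str, MatchMetrics]:
    """Site-level (exact position) and exon-level (exact span) precision,
    recall and F1 against a ground-truth annotation.

    With ``seq_length`` given, truth coordinates beyond the sequence end
    raise an error (coordinate-system mismatch guard).
    """
    donors = {c.pos for c in predicted_sites if c.site_type == "donor"}
    acceptors = {
        c.pos for c in predicted_sites if c.site_type == "acceptor"
    }
    t_donors, t_acceptors = set(truth_donors), set(truth_acceptors)
    t_exons = set(truth_exons)
    if seq_length is not None:
        limit = max(
            [p + 1 for p in t_donors | t_acceptors] + [e for _, e in t_exons],
            default=0,
        )
        if limit > seq_length:
            raise ValueError(
                f"truth coordinate {limit} beyond sequence end {seq_length}: "
                "coordinate-system mismatch?"
            )
    return {
        "donor": _prf(donors, t_donors),
        "acceptor": _prf(acceptors, t_acceptors),
        "exon": _prf({(e.start, e.end) for e in predicted_exons}, t_exons),
    }
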