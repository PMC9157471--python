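"""Open-reading-frame extraction from genomic sequence.

An ORF runs from an ATG to the *first* in-frame stop codon and is reported
when its nucleotide length (stop codon included) reaches ``min_orf_length``.
Nested ATGs inside a reported ORF do not seed further ORFs unless
``all_starts`` is set. Two stop-set presets are provided: the standard
nuclear set {TAA, TAG, TGA} (default) and ``code4`` = {TAA, TAG}, the
protozoan/mold mitochondrial table under which TGA codes tryptophan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequence_io import GenomeSequence

STOP_SETS: dict[str, frozenset[str]] = {
    "standard": frozenset({"TAA", "TAG", "TGA"}),
    "code4": frozenset({"TAA", "TAG"}),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OpenReadingFrame:
    """ATG→stop span; ``start``/``end`` are 1-based inclusive genome
    coordinates (start < end on both strands); ``residues`` is the
    sense-oriented ORF sequence beginning with ATG."""

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    residues: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _scan_strand(
    residues: str, min_orf_length: int, stop_set: frozenset[str], all_starts: bool
) -> list[tuple[int, int, int]]:
    """Return (start0, end0, frame) spans on one strand, 0-based inclusive."""
    n = len(residues)
    spans: list[tuple[int, int, int]] = []
    for frame in range(3):
        pending: list[int] = []  # 0-based positions of ATGs awaiting a stop
        for i in range(frame, n - 2, 3):
            codon = residues[i : i + 3]
            if codon in stop_set:
                for s in pending:
                    end0 = i + 2
                    if end0 - s + 1 >= min_orf_length:
                        spans.append((s, end0, frame))
                    if not all_starts:
                        break  # only the earliest ATG per stop
                pending.clear()
            elif codon == "ATG":
                if all_starts or not pending:
                    pending.append(i)
    return spans


def scan_orfs(
    seq: GenomeSequence,
    min_orf_length: int = 150,
    stop_set: Iterable[str] | str = "standard",
    strands: str = "forward",
    all_starts: bool = False,
) -> list[OpenReadingFrame]:
    """Find all maximal ATG→first-stop ORFs of length ≥ ``min_orf_length``.

    Parameters
    ----------
    min_orf_length
        Minimum span in nucleotides, stop codon included; must be ≥ 6 and a
        multiple of 3.
    stop_set
        Preset name (``"standard"`` or ``"code4"``) or an iterable of stop
        codons.
    strands
        ``"forward"``, ``"reverse"`` or ``"both"``.

    Spans containing N are excluded. Output is sorted by (start, frame).
    """
    if min_orf_length < 6 or min_orf_length % 3:
        raise ValueError("min_orf_length must be ≥ 6 and a multiple of 3")
    if isinstance(stop_set, str):
        stops = STOP_SETS[stop_set]
    else:
        stops = frozenset(c.upper() for c in stop_set)
    if not stops:
        raise ValueError("stop_set must be non-empty")
    if strands not in {"forward", "reverse", "both"}:
        raise ValueError(f"unknown strand selection {strands!r}")

    n = seq.length
    orfs: list[OpenReadingFrame] = []
    if strands in {"forward", "both"}:
        for s0, e0, frame in _scan_strand(seq.residues, min_orf_length, stops, all_starts):
            sub = seq.residues[s0 : e0 + 1]
            if "N" in sub:
                continue
            orfs.append(OpenReadingFrame(seq.id, s0 + 1, e0 + 1, "+", frame, sub))
    if strands in {"reverse", "both"}:
        rc = reverse_complement(seq.residues)
        for s0, e0, frame in _scan_strand(rc, min_orf_length, stops, all_starts):
            sub = rc[s0 : e0 + 1]
            if "N" in sub:
                continue
            # map back: rc position i (0-based) sits at genome position n - i
            orfs.append(
                OpenReadingFrame(seq.id, n - e0, n - s0, "-", frame, sub)
            )
    orfs.sort(key=lambda o: (o.start, o.frame, o.strand))
    return orfs


def extract_orf_residues(
    genome: Sequence[GenomeSequence], orfs: Sequence[OpenReadingFrame]
) -> list[GenomeSequence]:
    """Materialise ORF sequences as FASTA-ready records.

    Record ids follow ``<seq_id>_ORF<k>_<start>_<end>`` with ``k`` the
    1-based position of the ORF in the input order, preserved so downstream
    dataset construction sees a stable concatenation order.
    """
    by_id = {g.id: g for g in genome}
    records: list[GenomeSequence] = []
    for k, orf in enumerate(orfs, start=1):
        if orf.seq_id not in by_id:
            raise ValueError(
                f"ORF {k} references unknown sequence id {orf.seq_id!r}"
            )
        records.append(
            GenomeSequence(
                f"{orf.seq_id}_ORF{k}_{orf.start}_{orf.end}", orf.residues
            )
        )
    return records
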