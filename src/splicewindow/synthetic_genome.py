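"""Synthetic genomes with planted exon–intron gene structures.

Each gene is a codon-aware coding sequence (ATG start, no internal
in-frame stop, terminal stop codon) split into exons and interrupted by
introns whose first two bases are forced to GT and last two to AG, with
lengths drawn uniformly from ``intron_length_range`` (default 70–100 nt).
Background (intergenic and intron-interior) bases are i.i.d. with a single
GC-content parameter (default 30.2%, an AT-rich protozoan-like
composition). Spurious GT/AG occurrences arising by chance anywhere in the
sequence are deliberately retained — they are the negative-class challenge
a site caller must face. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset_builder import (
    ACCEPTOR,
    DONOR,
    LEFT_FLANK,
    NO_SITE,
    WINDOW,
    WindowExample,
    extract_window,
)
from .sequence_io import GenomeSequence

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationParams:
    """Simulation knobs; defaults emulate a compact AT-rich eukaryotic
    genome with short GT…AG introns."""

    n_genes: int = 50
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (70, 100)
    introns_per_gene: tuple[int, int] = (1, 3)
    gc_content: float = 0.302
    intergenic_length_range: tuple[int, int] = (100, 400)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")
        for name in ("exon_length_range", "intron_length_range",
                     "introns_per_gene", "intergenic_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"infeasible {name}: ({lo}, {hi})")
        if self.intron_length_range[0] < 4:
            raise ValueError("introns need at least 4 nt (GT…AG)")
        if self.exon_length_range[0] < 1:
            raise ValueError("exons need at least 1 nt")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted annotation: 1-based inclusive spans and per-site positions."""

    genes: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def donor_positions(self) -> list[int]:
        return [start for start, _ in self.introns]

    @property
    def acceptor_positions(self) -> list[int]:
        # first base of the terminal AG
        return [end - 1 for _, end in self.introns]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)]) if n else ""


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """i.i.d. bases at the given GC, resampling any in-frame stop codon."""
    if n_codons == 0:
        return ""
    arr = np.frombuffer(
        _random_bases(rng, 3 * n_codons, gc).encode(), dtype="S1"
    ).reshape(n_codons, 3).copy()
    while True:
        codons = arr.view("S3").ravel()
        bad = np.isin(codons, np.array(_STOPS, dtype="S3"))
        if not bad.any():
            break
        k = int(bad.sum())
        arr[bad] = np.frombuffer(
            _random_bases(rng, 3 * k, gc).encode(), dtype="S1"
        ).reshape(k, 3)
    return arr.tobytes().decode()


def _make_intron(rng: np.random.Generator, params: SimulationParams) -> str:
    lo, hi = params.intron_length_range
    length = int(rng.integers(lo, hi + 1))
    interior = _random_bases(rng, length - 4, params.gc_content)
    return "GT" + interior + "AG"


def _make_gene(
    rng: np.random.Generator, params: SimulationParams
) -> tuple[str, list[int], list[str]]:
    """Returns (coding sequence pieces joined later, exon lengths, introns)."""
    lo, hi = params.introns_per_gene
    n_introns = int(rng.integers(lo, hi + 1))
    elo, ehi = params.exon_length_range
    exon_lens = [int(rng.integers(elo, ehi + 1)) for _ in range(n_introns + 1)]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3  # keep the spliced CDS in frame
    if exon_lens[-1] < 3:
        exon_lens[-1] += 3
    total = sum(exon_lens)
    n_codons = total // 3
    stop = _STOPS[int(rng.integers(3))]
    cds = "ATG" + _random_codons(rng, n_codons - 2, params.gc_content) + stop
    introns = [_make_intron(rng, params) for _ in range(n_introns)]
    return cds, exon_lens, introns


def simulate_genome(
    params: Optional[SimulationParams] = None, seq_id: str = "synthetic"
) -> tuple[GenomeSequence, GroundTruth]:
    """Generate a genome and its planted ground-truth annotation."""
    params = params if params is not None else SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    ilo, ihi = params.intergenic_length_range
    pieces: list[str] = []
    truth = GroundTruth()
    offset = 0  # length emitted so far

    def emit(fragment: str) -> None:
        nonlocal offset
        pieces.append(fragment)
        offset += len(fragment)

    for _ in range(params.n_genes):
        emit(_random_bases(rng, int(rng.integers(ilo, ihi + 1)), params.gc_content))
        cds, exon_lens, introns = _make_gene(rng, params)
        gene_start = offset + 1
        cut = 0
        for k, exon_len in enumerate(exon_lens):
            exon_start = offset + 1
            emit(cds[cut : cut + exon_len])
            cut += exon_len
            truth.exons.append((exon_start, offset))
            if k < len(introns):
                intron_start = offset + 1
                emit(introns[k])
                truth.introns.append((intron_start, offset))
        truth.genes.append((gene_start, offset))
    emit(_random_bases(rng, int(rng.integers(ilo, ihi + 1)), params.gc_content))
    genome = GenomeSequence(seq_id, "".join(pieces))

    for start, end in truth.introns:  # construction self-check
        res = genome.residues[start - 1 : end]
        assert res.startswith("GT") and res.endswith("AG")
    return genome, truth


def validate_truth(genome: GenomeSequence, truth: GroundTruth) -> None:
    """Raise if the annotation does not describe this genome."""
    for start, end in truth.introns:
        if end > genome.length:
            raise ValueError("truth intron beyond sequence end")
        res = genome.residues[start - 1 : end]
        if not (res.startswith("GT") and res.endswith("AG")):
            raise ValueError(
                f"truth/genome mismatch: intron ({start}, {end}) is not GT…AG"
            )
    for gene_start, gene_end in truth.genes:
        covered = sum(
            end - start + 1
            for start, end in truth.exons + truth.introns
            if gene_start <= start and end <= gene_end
        )
        if covered != gene_end - gene_start + 1:
            raise ValueError("exon/intron spans do not tile the gene span")


def _no_site_anchors(
    genome: GenomeSequence,
    truth: GroundTruth,
    needed: int,
    window: int = WINDOW,
    left_flank: int = LEFT_FLANK,
) -> list[int]:
    """Anchors from truth-exon interiors whose dinucleotide is neither GT
    nor AG, spread across exons; deterministic."""
    anchors: list[int] = []
    shift = 0
    while len(anchors) < needed:
        progressed = False
        for start, end in truth.exons:
            if len(anchors) >= needed:
                break
            pos = (start + end) // 2 + shift
            while pos + 1 <= end:
                if genome.residues[pos - 1 : pos + 1] not in ("GT", "AG"):
                    if extract_window(genome, pos, window, left_flank) is not None:
                        anchors.append(pos)
                        progressed = True
                    break
                pos += 1
        shift += 3
        if not progressed and shift > max(e - s for s, e in truth.exons):
            break
    return anchors[:needed]


def truth_windows(
    genome: GenomeSequence,
    truth: GroundTruth,
    window: int = WINDOW,
    left_flank: int = LEFT_FLANK,
) -> list[WindowExample]:
    """Ground-truth training windows: one donor window per planted donor,
    one acceptor window per planted acceptor, and equal-count no-site
    windows from exon interiors. Classes are truncated to equal size and
    emitted donor, acceptor, no-site."""
    validate_truth(genome, truth)
    donors: list[WindowExample] = []
    acceptors: list[WindowExample] = []
    for pos in truth.donor_positions:
        residues = extract_window(genome, pos, window, left_flank)
        if residues is not None:
            donors.append(WindowExample(residues, DONOR, (genome.id, pos)))
    for pos in truth.acceptor_positions:
        residues = extract_window(genome, pos, window, left_flank)
        if residues is not None:
            acceptors.append(WindowExample(residues, ACCEPTOR, (genome.id, pos)))
    n = min(len(donors), len(acceptors))
    if n == 0:
        raise ValueError("no usable truth windows")
    no_sites = [
        WindowExample(extract_window(genome, pos, window, left_flank), NO_SITE,
                      (genome.id, pos))
        for pos in _no_site_anchors(genome, truth, n, window, left_flank)
    ]
    n = min(n, len(no_sites))
    return donors[:n] + acceptors[:n] + no_sites[:n]
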