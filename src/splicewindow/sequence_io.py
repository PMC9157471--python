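"""FASTA input and GFF3/BED output.

All coordinates in this package are 1-based inclusive, matching GFF3.
Sequences are uppercased on ingestion; RNA ``U`` is normalised to ``T`` and
IUPAC ambiguity codes other than ``N`` are mapped to ``N`` with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_AMBIGUITY = set("RYSWKMBDHV")


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")


def _normalise(record_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if not bad:
        return seq
    if bad <= _AMBIGUITY:
        logger.warning(
            "record %r: mapping ambiguity codes %s to N", record_id, sorted(bad)
        )
        return seq.translate(str.maketrans({c: "N" for c in _AMBIGUITY}))
    # report the first genuinely invalid character with its 1-based position
    for pos, char in enumerate(seq, start=1):
        if char not in _VALID and char not in _AMBIGUITY:
            raise ValueError(
                f"record {record_id!r}: non-nucleotide character {char!r} "
                f"at position {pos}"
            )
    raise AssertionError("unreachable")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Record order is preserved. Raises ``ValueError`` for an empty file,
    duplicate ids, or non-IUPAC characters.
    """
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate sequence id {record.id!r}")
        seen.add(record.id)
        seqs.append(GenomeSequence(record.id, _normalise(record.id, str(record.seq))))
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Sequence[GenomeSequence], path: str | Path) -> Path:
    """Write sequences as 60-column-wrapped FASTA."""
    if not seqs:
        raise ValueError("refusing to write an empty FASTA file")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    path = Path(path)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)
    return path


def _feature_row(feature, default_seq_id: str) -> tuple[int, str]:
    kind = getattr(feature, "kind", type(feature).__name__.replace("Call", "").lower())
    seq_id = getattr(feature, "seq_id", "") or default_seq_id
    start, end = feature.start, feature.end
    if start > end:
        raise ValueError(f"{kind} feature has start {start} > end {end}")
    support = getattr(feature, "support_fraction", None)
    score = "." if support is None else f"{support:.3f}"
    line = "\t".join(
        [seq_id, "splicewindow", kind, str(start), str(end), score, "+", ".", "."]
    )
    return start, line


def write_gff3(features: Iterable, seq_id: str, path: str | Path) -> Path:
    """Write exon/intron calls as GFF3, sorted by start coordinate.

    Features need ``start``/``end`` attributes (1-based inclusive) and a
    ``kind`` attribute naming the feature type; the score column carries the
    call's support fraction when available.
    """
    rows = sorted(_feature_row(f, seq_id) for f in features)
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for _, line in rows:
            handle.write(line + "\n")
    return path


def write_bed(features: Iterable, seq_id: str, path: str | Path) -> Path:
    """BED export: converts 1-based inclusive spans to 0-based half-open."""
    rows = sorted((f.start, f.end, getattr(f, "kind", "feature")) for f in features)
    path = Path(path)
    with open(path, "w") as handle:
        for start, end, kind in rows:
            if start > end:
                raise ValueError(f"feature has start {start} > end {end}")
            handle.write(f"{seq_id}\t{start - 1}\t{end}\t{kind}\n")
    return path


def read_features_gff3(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read exon/intron features from GFF3 as ``{type: [(seq_id, start, end)]}``."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, list[tuple[str, int, int]]] = {}
    for feat in db.all_features():
        out.setdefault(feat.featuretype, []).append(
            (feat.seqid, feat.start, feat.end)
        )
    for rows in out.values():
        rows.sort()
    return out
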