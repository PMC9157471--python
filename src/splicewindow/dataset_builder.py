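"""Three-class splice-site window dataset construction.

From ORF sequences this module catalogs donor (GT) and acceptor (AG)
dinucleotide positions, pairs each GT with its nearest downstream AG (which
makes the donor and acceptor counts equal, as an intron needs one of each),
derives one no-site anchor per pair from the pair midpoint, cuts 60-nt
windows with the site dinucleotide at window positions 30–31 (1-based), and
encodes nucleotides ordinally as A→1, G→2, T→3, C→4. Class labels are
0 = donor, 1 = acceptor, 2 = no-site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import GenomeSequence

logger = logging.getLogger(__name__)

WINDOW = 60
LEFT_FLANK = 29  # 29 nt upstream + 2-nt site + 29 nt downstream = 60
SITE_OFFSET = LEFT_FLANK  # 0-based index of the site's first base in a window

DONOR, ACCEPTOR, NO_SITE = 0, 1, 2
CLASS_NAMES = {DONOR: "donor", ACCEPTOR: "acceptor", NO_SITE: "no_site"}

ENCODING = {"A": 1, "G": 2, "T": 3, "C": 4}
DECODING = {v: k for k, v in ENCODING.items()}


@dataclass(frozen=True)
class WindowExample:
    """One training row: a 60-nt window, its class label and encoding."""

    residues: str
    label: int
    origin: tuple[str, int]  # (source record id, 1-based site position)

    @property
    def encoded(self) -> np.ndarray:
        return encode_window(self.residues)


@dataclass
class DatasetSplit:
    train_X: np.ndarray
    train_Y: np.ndarray
    test_X: np.ndarray
    test_Y: np.ndarray
    train_fraction: float
    seed: int
    class_counts: dict[str, int] = field(default_factory=dict)


def find_dinucleotide_positions(seq: GenomeSequence | str, dinuc: str) -> list[int]:
    """Ascending 1-based positions of every (possibly overlapping)
    occurrence of a 2-mer."""
    if len(dinuc) != 2:
        raise ValueError("dinuc must be a 2-mer")
    residues = seq if isinstance(seq, str) else seq.residues
    pattern = re.compile(f"(?={re.escape(dinuc)})")
    return [m.start() + 1 for m in pattern.finditer(residues)]


def pair_donor_acceptor(
    gt_positions: Sequence[int], ag_positions: Sequence[int]
) -> list[tuple[int, int]]:
    """Pair each GT with the nearest strictly-downstream unconsumed AG.

    An AG qualifies when its position is at least ``gt + 2`` (no overlap
    with the donor dinucleotide). GTs with no available downstream AG are
    dropped, so the returned donor and acceptor lists have equal length.
    """
    pairs: list[tuple[int, int]] = []
    j = 0
    for g in gt_positions:
        while j < len(ag_positions) and ag_positions[j] < g + 2:
            j += 1
        if j == len(ag_positions):
            break
        pairs.append((g, ag_positions[j]))
        j += 1
    return pairs


def derive_no_site_positions(
    pairs: Sequence[tuple[int, int]], seq: GenomeSequence | str
) -> list[int]:
    """One no-site anchor per donor–acceptor pair.

    The anchor starts at the pair midpoint ``floor((gt + ag) / 2)`` and is
    shifted right one base at a time (never beyond the acceptor) until the
    dinucleotide under it is neither GT nor AG; a pair with no such
    position in its span yields no anchor and is logged.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    anchors: list[int] = []
    for g, a in pairs:
        pos = (g + a) // 2
        while pos <= a and pos + 1 <= len(residues):
            if residues[pos - 1 : pos + 1] not in ("GT", "AG"):
                anchors.append(pos)
                break
            pos += 1
        else:
            logger.info("pair (%d, %d): no valid no-site anchor in span", g, a)
    return anchors


def extract_window(
    seq: GenomeSequence | str,
    pos: int,
    window: int = WINDOW,
    left_flank: int = LEFT_FLANK,
) -> str | None:
    """Cut the window whose 1-based positions ``left_flank + 1`` and
    ``left_flank + 2`` hold the site dinucleotide's two bases.

    Returns ``None`` (skip, never pad) when a flank runs off the sequence
    or the slice contains N.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    start = pos - left_flank  # 1-based window start
    end = start + window - 1
    if start < 1 or end > len(residues):
        return None
    sub = residues[start - 1 : end]
    if "N" in sub:
        return None
    return sub


_ENCODE_LUT = np.zeros(256, dtype=np.int64)
for _char, _code in ENCODING.items():
    _ENCODE_LUT[ord(_char)] = _code


def encode_window(residues: str) -> np.ndarray:
    """Ordinal encoding A→1, G→2, T→3, C→4, position by position."""
    out = _ENCODE_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (out == 0).any():
        i = int(np.flatnonzero(out == 0)[0])
        raise ValueError(
            f"cannot encode symbol {residues[i]!r} at position {i + 1}"
        )
    return out


def decode_window(encoded: Sequence[int]) -> str:
    try:
        return "".join(DECODING[int(v)] for v in encoded)
    except KeyError as exc:
        raise ValueError(f"cannot decode value {exc.args[0]!r}") from None


def _check_example(example: WindowExample, window: int, left_flank: int) -> None:
    assert len(example.residues) == window
    site = example.residues[left_flank : left_flank + 2]
    if example.label == DONOR:
        assert site == "GT", example
    elif example.label == ACCEPTOR:
        assert site == "AG", example
    else:
        assert site not in ("GT", "AG"), example


def build_dataset(
    orfs: Sequence[GenomeSequence],
    window: int = WINDOW,
    left_flank: int = LEFT_FLANK,
) -> list[WindowExample]:
    """Run the full cataloging pipeline over a set of ORF records.

    Emits all donor examples first, then acceptors, then no-sites; the
    three classes are truncated to the size of the smallest so that class
    counts are exactly equal. Every emitted example is checked against the
    window-label invariant.
    """
    if not orfs:
        raise ValueError("no ORF records supplied")
    per_class: dict[int, list[WindowExample]] = {DONOR: [], ACCEPTOR: [], NO_SITE: []}
    skipped = 0
    for record in orfs:
        gt = find_dinucleotide_positions(record, "GT")
        ag = find_dinucleotide_positions(record, "AG")
        pairs = pair_donor_acceptor(gt, ag)
        anchors = derive_no_site_positions(pairs, record)
        for label, positions in (
            (DONOR, [g for g, _ in pairs]),
            (ACCEPTOR, [a for _, a in pairs]),
            (NO_SITE, anchors),
        ):
            for pos in positions:
                residues = extract_window(record, pos, window, left_flank)
                if residues is None:
                    skipped += 1
                    continue
                per_class[label].append(WindowExample(residues, label, (record.id, pos)))
    n_min = min(len(v) for v in per_class.values())
    if n_min == 0:
        raise ValueError("no training windows")
    logger.info(
        "windows per class before balancing: donor=%d acceptor=%d no_site=%d "
        "(skipped %d at edges/N)",
        len(per_class[DONOR]), len(per_class[ACCEPTOR]), len(per_class[NO_SITE]),
        skipped,
    )
    examples: list[WindowExample] = []
    for label in (DONOR, ACCEPTOR, NO_SITE):
        for example in per_class[label][:n_min]:
            _check_example(example, window, left_flank)
            examples.append(example)
    return examples


def split_counts(total: int, train_fraction: float) -> tuple[int, int]:
    """Train/test row counts for a given total: ``n_train`` is
    ``train_fraction × total`` rounded half-up."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * total + 0.5))
    return n_train, total - n_train


def _one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float64)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def split_dataset(
    examples: Sequence[WindowExample],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> DatasetSplit:
    """Shuffle and split examples into train/test arrays.

    Stratification allocates per-class train counts by largest remainder so
    the overall train size is exactly ``round(train_fraction × total)``.
    Labels are one-hot encoded to 3 columns.
    """
    if len(examples) < 3:
        raise ValueError("need at least 3 examples to split")
    n_total = len(examples)
    n_train, _ = split_counts(n_total, train_fraction)
    rng = np.random.default_rng(seed)
    X = np.stack([ex.encoded for ex in examples])
    y = np.array([ex.label for ex in examples], dtype=np.int64)

    if stratified:
        train_idx_parts: list[np.ndarray] = []
        test_idx_parts: list[np.ndarray] = []
        classes = np.unique(y)
        quotas = train_fraction * np.array([(y == c).sum() for c in classes])
        base = np.floor(quotas).astype(int)
        remainder = n_train - base.sum()
        order = np.argsort(-(quotas - base))  # largest fractional part first
        base[order[:remainder]] += 1
        for c, k in zip(classes, base):
            idx = rng.permutation(np.flatnonzero(y == c))
            train_idx_parts.append(idx[:k])
            test_idx_parts.append(idx[k:])
        train_idx = rng.permutation(np.concatenate(train_idx_parts))
        test_idx = rng.permutation(np.concatenate(test_idx_parts))
    else:
        perm = rng.permutation(n_total)
        train_idx, test_idx = perm[:n_train], perm[n_train:]

    counts = {CLASS_NAMES[c]: int((y == c).sum()) for c in np.unique(y)}
    return DatasetSplit(
        train_X=X[train_idx],
        train_Y=_one_hot(y[train_idx]),
        test_X=X[test_idx],
        test_Y=_one_hot(y[test_idx]),
        train_fraction=train_fraction,
        seed=seed,
        class_counts=counts,
    )


def save_split(split: DatasetSplit, path) -> None:
    np.savez_compressed(
        path,
        train_X=split.train_X.astype(np.int8),
        train_Y=split.train_Y.astype(np.int8),
        test_X=split.test_X.astype(np.int8),
        test_Y=split.test_Y.astype(np.int8),
        train_fraction=split.train_fraction,
        seed=split.seed,
    )


def load_split(path) -> DatasetSplit:
    with np.load(path) as data:
        return DatasetSplit(
            train_X=data["train_X"].astype(np.int64),
            train_Y=data["train_Y"].astype(np.float64),
            test_X=data["test_X"].astype(np.int64),
            test_Y=data["test_Y"].astype(np.float64),
            train_fraction=float(data["train_fraction"]),
            seed=int(data["seed"]),
        )
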