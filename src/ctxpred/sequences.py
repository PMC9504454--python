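"""Genome sequences, context windows, disqualification masks and annotations.

Conventions used throughout the package:

* coordinates are 0-based; intervals are half-open ``[start, end)`` (BED);
* soft-masked (lowercase) FASTA letters mark repeat-annotated sequence and
  are recorded in per-base ``repeat_flags``;
* any letter outside A/C/G/T (including IUPAC ambiguity codes) is coerced
  to N at parse time;
* a position is *disqualified* for flank size F when its context of F bases
  on either side contains an N, the focus base itself is N, or the position
  lies within F bases of a sequence end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import N, decode, encode

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "ContextWindow",
    "PositionMask",
    "AnnotationSet",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "extract_context",
    "build_position_mask",
    "annotation_to_mask",
]


@dataclass
class GenomeSequence:
    """A named chromosome-like sequence over {A,C,G,T,N}.

    Attributes
    ----------
    name : str
        Record name (FASTA header word).
    codes : uint8 array
        Integer-encoded bases (A=0 .. T=3, N=4).
    repeat_flags : bool array
        True where the source letter was lowercase (soft-masked repeat).
    """

    name: str
    codes: np.ndarray
    repeat_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.repeat_flags is None:
            self.repeat_flags = np.zeros(self.codes.size, dtype=bool)
        self.repeat_flags = np.asarray(self.repeat_flags, dtype=bool)
        if self.repeat_flags.size != self.codes.size:
            raise ValueError("repeat_flags length must equal sequence length")
        if self.codes.size and self.codes.max() > N:
            raise ValueError("invalid base code in sequence")

    @classmethod
    def from_string(cls, name: str, bases: str) -> "GenomeSequence":
        """Build from a base string; lowercase letters set repeat flags."""
        flags = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
        is_lower = (flags >= ord("a")) & (flags <= ord("z"))
        return cls(name, encode(bases), is_lower)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def bases(self) -> str:
        """Upper-case base string."""
        return decode(self.codes)

    def to_string(self, soft_mask: bool = True) -> str:
        """Base string with repeats in lowercase when ``soft_mask``."""
        s = self.bases
        if not soft_mask or not self.repeat_flags.any():
            return s
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        arr[self.repeat_flags] += ord("a") - ord("A")
        return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class ContextWindow:
    """The F bases left and right of a focus position (focus excluded)."""

    left: np.ndarray
    right: np.ndarray
    focus_position: int
    flank_size: int

    def __post_init__(self) -> None:
        if len(self.left) != self.flank_size or len(self.right) != self.flank_size:
            raise ValueError("flanks must have length exactly flank_size")


@dataclass
class PositionMask:
    """Per-position disqualification flags for a given flank size."""

    disqualified: np.ndarray
    flank_size: int

    @property
    def n_disqualified(self) -> int:
        return int(self.disqualified.sum())

    @property
    def qualified_positions(self) -> np.ndarray:
        return np.flatnonzero(~self.disqualified)


@dataclass
class AnnotationSet:
    """Labelled genomic intervals, 0-based half-open, as a flat list."""

    intervals: list  # (chrom, start, end, label)

    def __post_init__(self) -> None:
        for chrom, start, end, label in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {chrom}:{start}-{end} ({label})")

    @property
    def labels(self) -> list:
        seen: dict = {}
        for _, _, _, label in self.intervals:
            seen.setdefault(label, None)
        return list(seen)


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into :class:`GenomeSequence` records.

    Lowercase letters are uppercased with ``repeat_flags`` set; letters
    outside A/C/G/T become N.  Record order is preserved.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise ValueError(f"{path}: empty FASTA file (line 1)")
        if first != ">":
            raise ValueError(f"{path}: malformed FASTA header on line 1 (expected '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence.from_string(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(genomes, path, width: int = 60) -> None:
    """Write genomes as soft-masked FASTA with wrapped lines."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            s = g.to_string(soft_mask=True)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_bed(path) -> AnnotationSet:
    """Read a BED file (3+ tab-separated columns) into an AnnotationSet.

    Column 4, when present, is used as the label; otherwise the label is
    the file's stem.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else path.stem
            intervals.append((chrom, start, end, label))
    return AnnotationSet(intervals)


def build_position_mask(genome: GenomeSequence, flank: int) -> PositionMask:
    """Disqualification mask for flank size F.

    A position is disqualified iff any base in ``[pos-F, pos+F]`` is N
    (including the focus base) or the window falls off a sequence end.
    For an N-free sequence exactly the 2F end positions are disqualified.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = len(genome)
    disq = np.ones(L, dtype=bool)
    if L >= 2 * flank + 1:
        is_n = (genome.codes == N).astype(np.int64)
        cums = np.concatenate([[0], np.cumsum(is_n)])
        # count of N in the full window [i-F, i+F] for interior positions
        win = 2 * flank + 1
        n_in_window = cums[win:] - cums[:-win]
        disq[flank : L - flank] = n_in_window > 0
    return PositionMask(disq, flank)


def extract_context(genome: GenomeSequence, pos: int, flank: int):
    """Context window at ``pos``, or None when the position is disqualified.

    Returns the F bases to the left and right of ``pos`` (focus excluded).
    """
    L = len(genome)
    if not 0 <= pos < L:
        raise IndexError(f"position {pos} out of range for length {L}")
    if pos < flank or pos + flank >= L:
        return None
    left = genome.codes[pos - flank : pos]
    right = genome.codes[pos + 1 : pos + 1 + flank]
    if genome.codes[pos] == N or (left == N).any() or (right == N).any():
        return None
    return ContextWindow(left, right, pos, flank)


def annotation_to_mask(annotations: AnnotationSet, chrom: str, length: int, label: str) -> np.ndarray:
    """Boolean mask of positions covered by >=1 interval with ``label``.

    Intervals extending past ``length`` are clipped with a logged warning.
    """
    mask = np.zeros(length, dtype=bool)
    for c, start, end, lab in annotations.intervals:
        if c != chrom or lab != label:
            continue
        if end > length:
            logger.warning("clipping interval %s:%d-%d (%s) to length %d", c, start, end, lab, length)
            end = length
        if start < length:
            mask[start:end] = True
    return mask
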