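"""Raw-read QC and paired-read merging.

A read pair survives QC iff *both* mates have median Phred strictly above the
threshold (median of an even-length list is the lower central value).  Mates
are then merged at the longest offset at which the forward read and the
reverse-complemented reverse read share an *exactly identical* overlap longer
than 50 bp; pairs with no such overlap are discarded.  Merging is
substitution-aware only in the sense that any mismatch voids an offset —
there is no indel tolerance and no mismatch budget.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dna import revcomp

DEFAULT_MIN_MEDIAN_PHRED = 32
DEFAULT_MIN_OVERLAP = 51  # strict ">50 bp"


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclasses.dataclass
class RawReadPair:
    read_id: str
    fwd_seq: str
    fwd_qual: str  # Phred+33 ASCII
    rev_seq: str
    rev_qual: str

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    @property
    def fwd_phred(self) -> np.ndarray:
        return np.frombuffer(self.fwd_qual.encode("ascii"), dtype=np.uint8) - 33

    @property
    def rev_phred(self) -> np.ndarray:
        return np.frombuffer(self.rev_qual.encode("ascii"), dtype=np.uint8) - 33


@dataclasses.dataclass
class MergedRead:
    read_id: str
    sequence: str
    overlap_length: int


def median_phred(qual: str) -> int:
    """Median quality of a Phred+33 string; even lengths take the lower central value."""
    vals = np.sort(np.frombuffer(qual.encode("ascii"), dtype=np.uint8))
    return int(vals[(len(vals) - 1) // 2]) - 33


def quality_filter(
    pairs: Iterable[RawReadPair], min_median_phred: int = DEFAULT_MIN_MEDIAN_PHRED
) -> list[RawReadPair]:
    """Keep pairs where both mates have median Phred strictly > threshold."""
    return [
        p
        for p in pairs
        if median_phred(p.fwd_qual) > min_median_phred
        and median_phred(p.rev_qual) > min_median_phred
    ]


def merge_pair(pair: RawReadPair, min_overlap: int = DEFAULT_MIN_OVERLAP) -> MergedRead | None:
    """Merge mates at the longest exactly-identical overlap of > 50 bp.

    The candidate overlap at offset ``o`` compares the last ``o`` bases of the
    forward read with the first ``o`` bases of the reverse-complemented
    reverse read; scanning runs longest-first so the first hit wins.  Returns
    ``None`` when no qualifying overlap exists (a normal outcome).
    """
    fwd = pair.fwd_seq
    rcr = revcomp(pair.rev_seq)
    max_o = min(len(fwd), len(rcr))
    for o in range(max_o, min_overlap - 1, -1):
        if fwd[len(fwd) - o :] == rcr[:o]:
            return MergedRead(pair.read_id, fwd + rcr[o:], o)
    return None


def merge_pairs(
    pairs: Iterable[RawReadPair], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[MergedRead]:
    out = []
    for p in pairs:
        m = merge_pair(p, min_overlap)
        if m is not None:
            out.append(m)
    return out


# ---------------------------------------------------------------------- I/O

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples; raise FastqParseError with the record index."""
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(str(exc), i) from exc
            yield title.split()[0], seq.upper(), qual
            i += 1


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[RawReadPair]:
    pairs = []
    for i, ((id1, s1, q1), (id2, s2, q2)) in enumerate(
        zip(read_fastq(r1_path), read_fastq(r2_path))
    ):
        if id1 != id2:
            raise FastqParseError(f"mate id mismatch: {id1!r} vs {id2!r}", i)
        pairs.append(RawReadPair(id1, s1, q1, s2, q2))
    return pairs


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_merged_fasta(path: str | Path, merged: Iterable[MergedRead]) -> None:
    with _open_text(path, "wt") as fh:
        for m in merged:
            fh.write(f">{m.read_id} overlap={m.overlap_length}\n{m.sequence}\n")
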