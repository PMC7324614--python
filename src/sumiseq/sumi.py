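"""Primer/UMI identification and consensus-based error correction.

The barcoded filtering pipeline: merged reads are oriented forward-primer to
reverse-primer by locating the common (MALBAC) primer tails, the 8 bp primer
UMIs are read off at their layout offsets, reads sharing the same (forward,
reverse) UMI pair are grouped — one pair marks one priming event on one
template molecule — and each group is collapsed to a consensus sequence.
Groups of up to four reads must agree completely; larger groups must reach a
per-base (plurality) agreement of at least 80% at every position.  Each
retained consensus counts once downstream regardless of its read support,
which is what removes amplification bias.

The standard (barcode-ignoring) pipeline keeps every read whose gene-specific
primer annealing regions can be found, with no grouping or consensus.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy import stats

from .dna import IUPAC, iupac_mismatches, revcomp
from .germline import PRIMER_SITE_LEN, V_LEN, GermlineDB
from .preprocess import MergedRead

#: edlib equality pairs so degenerate primer codes match their base sets.
_IUPAC_EQUALITIES = [
    (code, base) for code, bases in IUPAC.items() if len(bases) > 1 for base in bases
]


@dataclasses.dataclass(frozen=True)
class Primer:
    """One primer unit: common (MALBAC) tail, UMI slot, gene-specific 3' end.

    ``gene_specific`` is primer-sense and may contain IUPAC degeneracy;
    ``conserved_bases`` are (offset, base) pairs in primer-unit coordinates
    (0 = first MALBAC base) that must match exactly in a read.
    """

    name: str
    gene_specific: str
    malbac_region: str
    umi_length: int = 8
    conserved_bases: tuple[tuple[int, str], ...] = ()

    @property
    def unit_length(self) -> int:
        return len(self.malbac_region) + self.umi_length + len(self.gene_specific)


@dataclasses.dataclass
class PrimerSpec:
    fwd_primers: list[Primer]
    rev_primer: Primer
    sample_barcodes: dict[str, str] | None = None  # barcode DNA -> sample name
    max_primer_mismatches: int = 2
    max_shift: int = 2
    synthetic_umi_offset: int | None = None  # within the insert, 0-based
    synthetic_umi_length: int | None = None

    @property
    def umi_length(self) -> int:
        return self.rev_primer.umi_length


@dataclasses.dataclass
class AnnotatedRead:
    read_id: str
    insert: str
    fwd_umi: str
    rev_umi: str
    synthetic_umi: str | None = None
    sample: str | None = None
    was_reverse_complemented: bool = False


@dataclasses.dataclass
class Rejection:
    read_id: str
    reason: str


@dataclasses.dataclass
class UMIGroup:
    key: tuple[str, str]
    members: list[AnnotatedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class ConsensusRecord:
    consensus: str
    key: tuple[str, str]
    support: int
    per_base_agreement: float
    synthetic_umi: str | None = None


def build_primer_spec(
    germline: GermlineDB,
    umi_length: int = 8,
    synthetic_umi_offset: int | None = None,
    synthetic_umi_length: int | None = None,
    sample_barcodes: dict[str, str] | None = None,
    max_primer_mismatches: int = 2,
) -> PrimerSpec:
    """Primer specification matching the simulator's amplicon architecture.

    One forward primer per V gene (annealing to the FR3 site, the first
    ``PRIMER_SITE_LEN`` bases of the gene) and one consensus reverse primer
    on the J end.  The two MALBAC bases flanking each UMI slot are declared
    conserved.
    """
    from .simulate import MALBAC_FWD, MALBAC_REV

    def conserved(malbac: str) -> tuple[tuple[int, str], ...]:
        m = len(malbac)
        return ((m - 2, malbac[m - 2]), (m - 1, malbac[m - 1]))

    fwd = [
        Primer(
            name=v.gene_id,
            gene_specific=v.sequence[:PRIMER_SITE_LEN],
            malbac_region=MALBAC_FWD,
            umi_length=umi_length,
            conserved_bases=conserved(MALBAC_FWD),
        )
        for v in germline.v_genes
    ]
    j = germline.j_genes[0]
    rev = Primer(
        name="JH-consensus",
        gene_specific=revcomp(j.sequence[-PRIMER_SITE_LEN:]),
        malbac_region=MALBAC_REV,
        umi_length=umi_length,
        conserved_bases=conserved(MALBAC_REV),
    )
    return PrimerSpec(
        fwd_primers=fwd,
        rev_primer=rev,
        sample_barcodes=sample_barcodes,
        max_primer_mismatches=max_primer_mismatches,
        synthetic_umi_offset=synthetic_umi_offset,
        synthetic_umi_length=synthetic_umi_length,
    )


# ----------------------------------------------------------- primer location

def _match_at(seq: str, pattern: str, start: int) -> int | None:
    """IUPAC-aware mismatch count of pattern at a fixed offset, None if out of range."""
    end = start + len(pattern)
    if start < 0 or end > len(seq):
        return None
    return iupac_mismatches(seq[start:end], pattern)


def _best_fwd_layout(seq: str, spec: PrimerSpec) -> tuple[int, int, int] | None:
    """Best (shift, malbac_mismatches, total) for the forward MALBAC tail."""
    malbac = spec.fwd_primers[0].malbac_region
    best = None
    for s in range(spec.max_shift + 1):
        mm = _match_at(seq, malbac, s)
        if mm is not None and (best is None or mm < best[1]):
            best = (s, mm, mm)
    return best


def locate_primers(
    read: MergedRead, spec: PrimerSpec
) -> AnnotatedRead | Rejection:
    """Orient a merged read and extract its UMIs and insert.

    The read (or its reverse complement) must carry the forward primer unit
    (MALBAC tail + UMI + a gene-specific region matching one forward primer)
    at its 5' end and the reverse unit at its 3' end, each region with at
    most ``max_primer_mismatches`` IUPAC-aware mismatches.  Conserved bases
    flanking the UMI slots must match exactly.  The insert keeps the
    gene-specific annealing regions (template-encoded sequence); only the
    MALBAC tails, UMIs and any sample barcode are excised.
    """
    mm_max = spec.max_primer_mismatches
    candidates = []
    for flipped, seq in ((False, read.sequence), (True, revcomp(read.sequence))):
        hit = _best_fwd_layout(seq, spec)
        if hit is not None and hit[1] <= mm_max:
            candidates.append((hit[1], flipped, seq, hit[0]))
    if not candidates:
        return Rejection(read.read_id, "no_primer")
    candidates.sort(key=lambda c: c[0])
    _, flipped, seq, shift = candidates[0]

    sample = None
    if spec.sample_barcodes:
        for bc, name in spec.sample_barcodes.items():
            mm = _match_at(seq, revcomp(bc), len(seq) - len(bc))
            if mm is not None and mm <= 1:
                sample = name
                seq = seq[: len(seq) - len(bc)]
                break

    fwd_malbac_len = len(spec.fwd_primers[0].malbac_region)
    u = spec.umi_length
    gs_start = shift + fwd_malbac_len + u
    fwd_primer = None
    fwd_gs_mm = None
    for p in spec.fwd_primers:
        mm = _match_at(seq, p.gene_specific, gs_start)
        if mm is not None and mm <= mm_max and (fwd_gs_mm is None or mm < fwd_gs_mm):
            fwd_primer, fwd_gs_mm = p, mm
    if fwd_primer is None:
        return Rejection(read.read_id, "no_primer")

    rev = spec.rev_primer
    rev_malbac_len = len(rev.malbac_region)
    L = len(seq)
    rev_unit_len = rev.unit_length
    if L < gs_start + len(fwd_primer.gene_specific) + rev_unit_len:
        return Rejection(read.read_id, "no_primer")
    rev_mm = iupac_mismatches(seq[L - rev_malbac_len :], revcomp(rev.malbac_region))
    rev_gs_end = L - rev_malbac_len - rev.umi_length
    rev_gs_mm = iupac_mismatches(
        seq[rev_gs_end - len(rev.gene_specific) : rev_gs_end], revcomp(rev.gene_specific)
    )
    if rev_mm > mm_max or rev_gs_mm > mm_max:
        return Rejection(read.read_id, "no_primer")

    # conserved-base check, exact: fwd unit in read sense, rev unit via revcomp
    fwd_unit = seq[shift : gs_start + len(fwd_primer.gene_specific)]
    rev_unit = revcomp(seq[L - rev_unit_len :])
    for off, base in fwd_primer.conserved_bases:
        if off >= len(fwd_unit) or fwd_unit[off] != base:
            return Rejection(read.read_id, "barcode_structure")
    for off, base in rev.conserved_bases:
        if off >= len(rev_unit) or rev_unit[off] != base:
            return Rejection(read.read_id, "barcode_structure")

    fwd_umi = seq[shift + fwd_malbac_len : gs_start]
    rev_umi = revcomp(seq[L - rev_malbac_len - u : L - rev_malbac_len])
    insert = seq[gs_start : L - rev_malbac_len - u]
    if not insert:
        return Rejection(read.read_id, "no_primer")

    synthetic_umi = None
    if spec.synthetic_umi_offset is not None and spec.synthetic_umi_length:
        so, sl = spec.synthetic_umi_offset, spec.synthetic_umi_length
        if so + sl <= len(insert):
            synthetic_umi = insert[so : so + sl]
    return AnnotatedRead(
        read_id=read.read_id,
        insert=insert,
        fwd_umi=fwd_umi,
        rev_umi=rev_umi,
        synthetic_umi=synthetic_umi,
        sample=sample,
        was_reverse_complemented=flipped,
    )


def annotate_reads(
    reads: Iterable[MergedRead], spec: PrimerSpec
) -> tuple[list[AnnotatedRead], list[Rejection]]:
    kept: list[AnnotatedRead] = []
    rejected: list[Rejection] = []
    for r in reads:
        res = locate_primers(r, spec)
        (kept if isinstance(res, AnnotatedRead) else rejected).append(res)
    return kept, rejected


# ------------------------------------------------------------- UMI grouping

def group_by_umi(annotated: Iterable[AnnotatedRead]) -> list[UMIGroup]:
    """Exact-match grouping on the (fwd_umi, rev_umi) pair, lexicographic order."""
    groups: dict[tuple[str, str], list[AnnotatedRead]] = {}
    for a in annotated:
        groups.setdefault((a.fwd_umi, a.rev_umi), []).append(a)
    return [UMIGroup(key, groups[key]) for key in sorted(groups)]


# --------------------------------------------------------- consensus calling

def call_consensus(
    group: UMIGroup, min_agreement: float = 0.8, small_group_max: int = 4
) -> ConsensusRecord | Rejection:
    """Collapse one UMI group to a consensus sequence, or discard it.

    Members are first sub-grouped by length (substitution-only comparison
    needs equal lengths); the plurality-length sub-group is kept, a tie
    discarding the group.  Small sub-groups (<= ``small_group_max`` reads)
    must agree completely.  Larger ones take the per-position plurality base
    and are retained only if every position's plurality fraction reaches
    ``min_agreement``; the minimum positional fraction is recorded.
    """
    if not group.members:
        raise ValueError("empty UMI group")
    by_len: dict[int, list[AnnotatedRead]] = {}
    for m in group.members:
        by_len.setdefault(len(m.insert), []).append(m)
    sizes = sorted(((len(v), length) for length, v in by_len.items()), reverse=True)
    if len(sizes) > 1 and sizes[0][0] == sizes[1][0]:
        return Rejection(group.members[0].read_id, "length_tie")
    members = by_len[sizes[0][1]]
    support = len(members)
    seqs = [m.insert for m in members]

    if support <= small_group_max:
        if any(s != seqs[0] for s in seqs[1:]):
            return Rejection(members[0].read_id, "small_group_disagreement")
        consensus, agreement = seqs[0], 1.0
    else:
        arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
            support, -1
        )
        mode = stats.mode(arr, axis=0)
        agreement = float(mode.count.min()) / support
        if agreement < min_agreement:
            return Rejection(members[0].read_id, "low_agreement")
        consensus = mode.mode.astype(np.uint8).tobytes().decode("ascii")

    synth = next((m.synthetic_umi for m in members if m.synthetic_umi), None)
    return ConsensusRecord(
        consensus=consensus,
        key=group.key,
        support=support,
        per_base_agreement=agreement,
        synthetic_umi=synth,
    )


def call_consensus_all(
    groups: Iterable[UMIGroup], min_agreement: float = 0.8, small_group_max: int = 4
) -> tuple[list[ConsensusRecord], list[Rejection]]:
    records: list[ConsensusRecord] = []
    rejections: list[Rejection] = []
    for g in groups:
        res = call_consensus(g, min_agreement, small_group_max)
        (records if isinstance(res, ConsensusRecord) else rejections).append(res)
    return records, rejections


# ------------------------------------------------------------ standard path

def _edlib_best(query: str, target: str, max_dist: int) -> tuple[int, int, int] | None:
    """Best infix match of query in target: (distance, start, end) or None."""
    res = edlib.align(
        query, target, mode="HW", task="locations", k=max_dist,
        additionalEqualities=_IUPAC_EQUALITIES,
    )
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def locate_primers_standard(read: MergedRead, spec: PrimerSpec) -> AnnotatedRead | Rejection:
    """Gene-specific-only primer finding for the barcode-ignoring pipeline.

    Searches both strands for any forward gene-specific region and the
    reverse one (as it appears on the forward strand) at any offset, so it
    applies equally to non-barcoded amplicons and to barcoded reads whose UMI
    information is being deliberately ignored.  The insert spans forward
    annealing-site start to reverse annealing-site end.
    """
    mm_max = spec.max_primer_mismatches
    rev_site = revcomp(spec.rev_primer.gene_specific)  # forward-strand J site
    best = None
    for flipped, seq in ((False, read.sequence), (True, revcomp(read.sequence))):
        fwd_hit = None
        for p in spec.fwd_primers:
            h = _edlib_best(p.gene_specific, seq, mm_max)
            if h is not None and (fwd_hit is None or h[0] < fwd_hit[0]):
                fwd_hit = h
        if fwd_hit is None:
            continue
        rev_hit = _edlib_best(rev_site, seq, mm_max)
        if rev_hit is None or rev_hit[2] <= fwd_hit[1]:
            continue
        score = fwd_hit[0] + rev_hit[0]
        if best is None or score < best[0]:
            best = (score, flipped, seq[fwd_hit[1] : rev_hit[2]])
    if best is None:
        return Rejection(read.read_id, "no_primer")
    _, flipped, insert = best
    return AnnotatedRead(
        read_id=read.read_id,
        insert=insert,
        fwd_umi="",
        rev_umi="",
        was_reverse_complemented=flipped,
    )


def standard_filter(
    reads: Iterable[MergedRead], spec: PrimerSpec
) -> tuple[list[AnnotatedRead], list[Rejection]]:
    """Barcode-ignoring filter: one surviving insert per read with primers."""
    kept: list[AnnotatedRead] = []
    rejected: list[Rejection] = []
    for r in reads:
        res = locate_primers_standard(r, spec)
        if isinstance(res, AnnotatedRead):
            if spec.synthetic_umi_offset is not None and spec.synthetic_umi_length:
                # the standard insert starts at the forward annealing site,
                # same origin as the barcoded insert, so offsets carry over
                so, sl = spec.synthetic_umi_offset, spec.synthetic_umi_length
                if so + sl <= len(res.insert):
                    res.synthetic_umi = res.insert[so : so + sl]
            kept.append(res)
        else:
            rejected.append(res)
    return kept, rejected


# ---------------------------------------------------------------------- I/O

def write_consensus_fasta(path: str | Path, records: Sequence[ConsensusRecord]) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fh.write(
                f">cons_{i:06d} umi_fwd={rec.key[0]} umi_rev={rec.key[1]} "
                f"support={rec.support}\n{rec.consensus}\n"
            )


def write_rejections(path: str | Path, rejections: Sequence[Rejection]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for r in rejections:
            fh.write(f"{r.read_id}\t{r.reason}\n")
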