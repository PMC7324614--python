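"""Germline V/J reference model.

A :class:`GermlineDB` holds V- and J-segment nucleotide sequences together
with a region map (FWR/CDR intervals, 0-based half-open) carried in a sidecar
TSV next to the FASTA.  The bundled synthetic reference mimics the amplified
portion of an IGH locus: each V gene covers the FR3 annealing site of the
forward primer through the conserved cysteine codon, and each J gene covers
the CDR3 tail, the conserved tryptophan codon and FWR4 down to the reverse
primer annealing site.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import random_codons

REGION_NAMES = {"FWR1", "FWR2", "FWR3", "FWR4", "CDR1", "CDR2", "CDR3"}

# geometry of the bundled synthetic reference (all in nt)
V_LEN = 150         # FWR1..FWR3, ending with the conserved TGT (Cys)
V_REGIONS = (
    ("FWR1", 0, 45),
    ("CDR1", 45, 69),
    ("FWR2", 69, 105),
    ("CDR2", 105, 129),
    ("FWR3", 129, 150),
)
J_LEN = 48          # 9 nt CDR3 tail + TGG (Trp) + FWR4
J_CDR3_LEN = 9
PRIMER_SITE_LEN = 21  # gene-specific annealing site at V start / J end


@dataclasses.dataclass(frozen=True)
class GermlineRecord:
    gene_id: str
    segment_class: str  # "V" or "J"
    sequence: str
    region_map: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "J"):
            raise ValueError(f"segment_class must be V or J, got {self.segment_class!r}")
        prev_end = 0
        for name, start, end in self.region_map:
            if name not in REGION_NAMES:
                raise ValueError(f"unknown region name {name!r}")
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"region {name} out of bounds for {self.gene_id}")
            if start < prev_end:
                raise ValueError(f"regions overlap/are unordered in {self.gene_id}")
            prev_end = end

    def region_of(self, pos: int) -> str | None:
        for name, start, end in self.region_map:
            if start <= pos < end:
                return name
        return None


class GermlineDB:
    """Container of germline segments with class-indexed access."""

    def __init__(self, records: list[GermlineRecord]):
        self.records = list(records)
        self.v_genes = [r for r in self.records if r.segment_class == "V"]
        self.j_genes = [r for r in self.records if r.segment_class == "J"]
        self._by_id = {r.gene_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate gene_id in germline records")

    def __getitem__(self, gene_id: str) -> GermlineRecord:
        return self._by_id[gene_id]

    def __len__(self) -> int:
        return len(self.records)

    # ------------------------------------------------------------------ I/O
    def write(self, fasta_path: str | Path, regions_path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.segment_class)
            for r in self.records
        ]
        SeqIO.write(recs, str(fasta_path), "fasta")
        with open(regions_path, "w") as fh:
            fh.write("gene_id\tsegment_class\tregion\tstart\tend\n")
            for r in self.records:
                for name, start, end in r.region_map:
                    fh.write(f"{r.gene_id}\t{r.segment_class}\t{name}\t{start}\t{end}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, regions_path: str | Path) -> "GermlineDB":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        regions: dict[str, list[tuple[str, int, int]]] = {g: [] for g in seqs}
        classes: dict[str, str] = {}
        with open(regions_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                gid = f[idx["gene_id"]]
                if gid not in seqs:
                    raise ValueError(f"region for unknown gene {gid}")
                classes[gid] = f[idx["segment_class"]]
                regions[gid].append((f[idx["region"]], int(f[idx["start"]]), int(f[idx["end"]])))
        records = [
            GermlineRecord(gid, classes.get(gid, "V"), seq, tuple(regions[gid]))
            for gid, seq in seqs.items()
        ]
        return cls(records)


def synthetic_germline(n_v: int = 4, n_j: int = 3, seed: int = 0) -> GermlineDB:
    """Generate a compact synthetic IGH-like reference.

    V genes are stop-free, in frame, end with the conserved cysteine codon
    (TGT) and carry the FWR1..FWR3 / CDR1..CDR2 region map.  J genes start
    with a 9 nt CDR3 tail,
    then the conserved tryptophan codon (TGG) opening FWR4.  Gene families
    share no long exact repeats so V/J assignment is unambiguous.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J gene")
    rng = np.random.default_rng(seed)
    records: list[GermlineRecord] = []
    seen: set[str] = set()
    for i in range(n_v):
        while True:
            body = random_codons(rng, V_LEN // 3 - 1)
            seq = body + "TGT"
            if seq not in seen:
                seen.add(seq)
                break
        records.append(GermlineRecord(f"IGHV{i + 1}-S", "V", seq, V_REGIONS))
    # all J genes share their 3'-terminal primer annealing site, as targeted
    # by a single consensus JH reverse primer
    shared_site = random_codons(rng, PRIMER_SITE_LEN // 3)
    for i in range(n_j):
        while True:
            tail = random_codons(rng, J_CDR3_LEN // 3)
            var_len = J_LEN - J_CDR3_LEN - 3 - PRIMER_SITE_LEN
            fwr4 = "TGG" + random_codons(rng, var_len // 3) + shared_site
            seq = tail + fwr4
            if seq not in seen:
                seen.add(seq)
                break
        records.append(
            GermlineRecord(
                f"IGHJ{i + 1}-S", "J", seq,
                (("CDR3", 0, J_CDR3_LEN), ("FWR4", J_CDR3_LEN, J_LEN)),
            )
        )
    return GermlineDB(records)
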