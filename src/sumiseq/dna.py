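"""Small DNA helpers shared across modules.

Sequences are plain upper-case ``str`` throughout; coordinates are 0-based
half-open.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC code -> set of concrete bases it matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Hamming-style mismatch count of ``observed`` against an IUPAC ``pattern``.

    Lengths must be equal; each N/degenerate code in the pattern matches its
    base set.  The observed sequence is taken literally (no degeneracy).
    """
    if len(observed) != len(pattern):
        raise ValueError("iupac_mismatches requires equal lengths")
    return sum(o not in IUPAC.get(p, p) for o, p in zip(observed, pattern))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence of ``n_codons`` codons with no stop codons."""
    out = []
    while len(out) < n_codons:
        codon = random_dna(rng, 3)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def apply_substitutions(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply i.i.d. substitution errors at ``rate`` per base.

    Substituted bases are drawn uniformly from the three alternatives.
    """
    if rate <= 0.0:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    # offset 1..3 from the current base's index in ACGT
    cur = np.searchsorted(_BASE_ARR, arr[hits])
    new = (cur + rng.integers(1, 4, size=hits.size)) % 4
    arr[hits] = _BASE_ARR[new]
    return array_to_seq(arr)


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence (trailing partial codon ignored)."""
    from Bio.Seq import Seq

    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def has_internal_stop(seq: str) -> bool:
    n = len(seq) - len(seq) % 3
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, n, 3))
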