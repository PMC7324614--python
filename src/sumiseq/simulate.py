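"""Generative model of looped-primer (MALBAC-style) UMI-barcoded amplicon PCR.

The experiment being emulated: BCR-like template molecules (V segment +
junction + J segment), optionally carrying an internal random segment (the
*synthetic DNA-UMI*) that makes every molecule identifiable, are amplified in
two stages.

PCR1 (near-linear): each cycle, each template is primed with probability
``p`` by a barcoded primer pair, producing one amplicon that carries a fresh
random (forward, reverse) primer-UMI pair.  Amplicons self-anneal into loops
and are mostly unavailable for further priming; with small probability ``q``
per cycle an existing amplicon is nevertheless re-primed, producing a copy
with a *new* primer-UMI pair but the same internal synthetic UMI (lineage
``loop_reamplified``).  PCR2 (exponential): every amplicon is linearised and
amplified with a per-molecule efficiency drawn from a scaled Beta law, so its
final abundance is ``(1 + efficiency) ** cycles`` up to normalisation; reads
are then drawn multinomially at the requested depth and sequenced with i.i.d.
per-base substitution errors and a two-component quality model.

The standard (non-barcoded) protocol is modelled for comparison: exponential
branching from cycle 1 with per-template efficiency and no primer UMIs.

Everything is driven by one ``numpy`` Generator seeded from
``SimulationConfig.seed``; a fixed seed gives byte-identical FASTQ and truth
tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dna import random_dna, revcomp
from .germline import J_CDR3_LEN, PRIMER_SITE_LEN, GermlineDB
from .preprocess import RawReadPair, write_fastq

# Common primer tails (arbitrary fixed 27-mers, GC-balanced, homopolymer-free).
MALBAC_FWD = "GTGAGTGATGGTTGAGGTAGTGTGGAG"
MALBAC_REV = "GATGTGAGTGTCGATCGGTAGTGAGGC"

TRUTH_COLUMNS = ["read_id", "template_id", "fwd_umi", "rev_umi", "lineage", "true_insert"]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Probabilities are per cycle; ``seq_error_rate`` is substitutions per base
    per sequenced mate.  ``template_pool_fractions`` gives the molecule share
    of each distinct rearrangement (clone); ``None`` means every molecule is
    its own rearrangement.
    """

    n_templates: int = 100
    template_pool_fractions: Sequence[float] | None = None
    pcr1_cycles: int = 10
    priming_prob_per_cycle: float = 0.9
    loop_reamp_prob_per_cycle: float = 0.005
    pcr2_cycles: int = 20
    efficiency_beta_a: float = 2.0
    efficiency_beta_b: float = 2.0
    efficiency_range: tuple[float, float] = (0.6, 1.0)
    length_penalty: float = 0.0  # per-extra-base multiplicative weight penalty
    seq_error_rate: float = 0.005
    read_length: int = 175
    sequencing_depth: int = 3000
    umi_length: int = 8
    synthetic_umi_length: int = 12  # 0 disables the internal DNA-UMI
    shm_rate: float = 0.0  # expected substitutions per base, pre-weighting
    shm_cdr_weight: float = 3.0
    shm_fwr_weight: float = 1.0
    quality_pass_fraction: float = 0.95
    sample_barcode: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("priming_prob_per_cycle", "loop_reamp_prob_per_cycle", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_templates < 1 or self.sequencing_depth < 1:
            raise ValueError("n_templates and sequencing_depth must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.pcr1_cycles < 1:
            raise ValueError("pcr1_cycles must be >= 1")
        if self.shm_cdr_weight < self.shm_fwr_weight:
            raise ValueError("CDR mutation weight must be >= FWR weight")
        lo, hi = self.efficiency_range
        if not 0.0 <= lo <= hi:
            raise ValueError("efficiency_range must satisfy 0 <= lo <= hi")
        if self.template_pool_fractions is not None:
            tot = float(sum(self.template_pool_fractions))
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"template_pool_fractions must sum to 1, got {tot}")


@dataclasses.dataclass
class Template:
    """One template molecule of the input pool."""

    template_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    synthetic_umi: str
    full_sequence: str
    shm_positions: list[tuple[int, str, str]]
    true_fraction: float


@dataclasses.dataclass
class Amplicon:
    """One PCR1 product: a template copy tagged by a primer-UMI pair."""

    template_index: int
    fwd_umi: str
    rev_umi: str
    lineage: str  # "template_primed" | "loop_reamplified"


def _allocate_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder allocation of n molecules to pool fractions."""
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _junction(rng: np.random.Generator, n_codons: int, umi_len: int) -> tuple[str, str]:
    """N-region of ``3 * n_codons`` nt, embedding a synthetic UMI of umi_len nt.

    The junction sits in frame 0 downstream of the V segment; it is redrawn
    until free of in-frame stop codons so reading-frame filtering stays a
    test of real defects, not of the generator.
    """
    from .dna import has_internal_stop

    total = 3 * n_codons
    while True:
        umi = random_dna(rng, umi_len)
        flank = total - umi_len
        left = random_dna(rng, flank // 2)
        right = random_dna(rng, flank - flank // 2)
        junction = left + umi + right
        if not has_internal_stop(junction):
            return junction, umi


def generate_templates(config: SimulationConfig, germline: GermlineDB) -> list[Template]:
    """Draw the template molecule pool.

    Each distinct rearrangement picks a V and a J gene and a random junction;
    molecules of the same rearrangement share the rearranged sequence but each
    carries its own synthetic UMI (when enabled).  Somatic hypermutation is
    applied per molecule at ``shm_rate`` with CDR positions upweighted over
    FWR positions; substitutions that would create an in-frame stop codon are
    redrawn.  Synthetic-UMI collisions across the pool are rejected and
    redrawn so template identity stays unambiguous.
    """
    if not germline.v_genes or not germline.j_genes:
        raise ValueError("germline database must contain at least one V and one J gene")
    rng = np.random.default_rng(config.seed)
    n = config.n_templates
    fractions = config.template_pool_fractions
    if fractions is None:
        counts = [1] * n
    else:
        counts = _allocate_counts(fractions, n)

    su_len = config.synthetic_umi_length
    # junction length: fixed when a synthetic UMI is embedded (known offset),
    # variable (3-10 codons) for plain repertoire pools
    seen_umis: set[str] = set()
    templates: list[Template] = []
    tid = 0
    for rearr_idx, n_copies in enumerate(counts):
        if n_copies == 0:
            continue
        v = germline.v_genes[int(rng.integers(len(germline.v_genes)))]
        j = germline.j_genes[int(rng.integers(len(germline.j_genes)))]
        if su_len > 0:
            n_codons = max(2, -(-su_len // 3) + 2)  # UMI plus >=6 nt of flank
        else:
            n_codons = int(rng.integers(3, 11))
        junction_core = None  # shared N-region flanks within a rearrangement
        for _ in range(n_copies):
            if su_len > 0:
                if junction_core is None:
                    junction_core, _ = _junction(rng, n_codons, su_len)
                    off = (3 * n_codons - su_len) // 2
                from .dna import has_internal_stop

                while True:
                    umi = random_dna(rng, su_len)
                    if umi in seen_umis:
                        continue
                    junction = junction_core[:off] + umi + junction_core[off + su_len :]
                    if has_internal_stop(junction):
                        continue
                    seen_umis.add(umi)
                    break
            else:
                if junction_core is None:
                    junction_core, _ = _junction(rng, n_codons, 0)
                junction, umi = junction_core, ""
            full = v.sequence + junction + j.sequence
            shm: list[tuple[int, str, str]] = []
            if config.shm_rate > 0.0:
                full, shm = _apply_shm(rng, full, v, j, len(junction), config)
            cdr3 = full[len(v.sequence) : len(v.sequence) + len(junction) + J_CDR3_LEN]
            templates.append(
                Template(
                    template_id=f"T{tid:05d}",
                    v_gene=v.gene_id,
                    j_gene=j.gene_id,
                    cdr3_nt=cdr3,
                    synthetic_umi=umi,
                    full_sequence=full,
                    shm_positions=shm,
                    true_fraction=n_copies / n if fractions is not None else 1.0 / n,
                )
            )
            tid += 1
    return templates


def _apply_shm(
    rng: np.random.Generator,
    full: str,
    v,
    j,
    junction_len: int,
    config: SimulationConfig,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Per-molecule SHM with CDR-over-FWR weighting; stop codons are avoided."""
    from .dna import BASES, STOP_CODONS

    v_len = len(v.sequence)
    weights = np.empty(len(full))
    for pos in range(len(full)):
        if pos < v_len:
            region = v.region_of(pos)
        elif pos < v_len + junction_len:
            region = "CDR3"
        else:
            region = j.region_of(pos - v_len - junction_len)
        is_cdr = region is not None and region.startswith("CDR")
        weights[pos] = config.shm_cdr_weight if is_cdr else config.shm_fwr_weight
    weights *= config.shm_rate / weights.mean()
    np.clip(weights, 0.0, 1.0, out=weights)
    hits = np.nonzero(rng.random(len(full)) < weights)[0]
    seq = list(full)
    muts: list[tuple[int, str, str]] = []
    for pos in hits:
        pos = int(pos)
        old = seq[pos]
        choices = [b for b in BASES if b != old]
        for _ in range(8):
            new = choices[int(rng.integers(3))]
            c0 = pos - pos % 3
            codon = "".join(seq[c0:pos] + [new] + seq[pos + 1 : c0 + 3])
            if len(codon) == 3 and codon in STOP_CODONS:
                continue
            seq[pos] = new
            muts.append((pos, old, new))
            break
    return "".join(seq), muts


def synthetic_umi_layout(config: SimulationConfig) -> tuple[int | None, int | None]:
    """(offset, length) of the synthetic DNA-UMI within the insert, or Nones."""
    from .germline import V_LEN

    su = config.synthetic_umi_length
    if su <= 0:
        return None, None
    n_codons = max(2, -(-su // 3) + 2)
    return V_LEN + (3 * n_codons - su) // 2, su


# ------------------------------------------------------------------- PCR1

def pcr1_events(
    n_templates: int, config: SimulationConfig, rng: np.random.Generator
) -> list[Amplicon]:
    """Near-linear barcoding PCR over ``n_templates`` template molecules.

    Per cycle, loop re-priming of existing amplicons (probability ``q`` each)
    happens first, then each template is primed with probability ``p``; the
    expected amplicon count per template after cycle t therefore follows
    ``a_t = a_{t-1} * (1 + q) + p``.
    """
    p = config.priming_prob_per_cycle
    q = config.loop_reamp_prob_per_cycle
    n = n_templates
    amplicons: list[Amplicon] = []

    def new_umi_pair() -> tuple[str, str]:
        return (
            random_dna(rng, config.umi_length),
            random_dna(rng, config.umi_length),
        )

    for _cycle in range(config.pcr1_cycles):
        if q > 0.0 and amplicons:
            redo = np.nonzero(rng.random(len(amplicons)) < q)[0]
            for i in redo:
                src = amplicons[int(i)]
                fu, ru = new_umi_pair()
                amplicons.append(Amplicon(src.template_index, fu, ru, "loop_reamplified"))
        primed = np.nonzero(rng.random(n) < p)[0] if p < 1.0 else np.arange(n)
        for i in primed:
            fu, ru = new_umi_pair()
            amplicons.append(Amplicon(int(i), fu, ru, "template_primed"))
    return amplicons


def simulate_pcr1(
    templates: list[Template],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[Amplicon]:
    """PCR1 over a template pool; see :func:`pcr1_events`."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    return pcr1_events(len(templates), config, rng)


# ----------------------------------------------------- PCR2 and sequencing

def amplicon_sequence(template: Template, amplicon: Amplicon, config: SimulationConfig) -> str:
    """Fully assembled linearised amplicon in forward orientation."""
    seq = (
        MALBAC_FWD
        + amplicon.fwd_umi
        + template.full_sequence
        + revcomp(amplicon.rev_umi)
        + revcomp(MALBAC_REV)
    )
    if config.sample_barcode:
        seq += revcomp(config.sample_barcode)
    return seq


def _pcr2_weights(
    lengths: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = config.efficiency_range
    if hi > lo:
        eff = lo + (hi - lo) * rng.beta(
            config.efficiency_beta_a, config.efficiency_beta_b, size=lengths.size
        )
    else:
        eff = np.full(lengths.size, lo)
    w = (1.0 + eff) ** config.pcr2_cycles
    if config.length_penalty > 0.0:
        w = w * (1.0 - config.length_penalty) ** (lengths - lengths.min())
    return w


def _quality_string(rng: np.random.Generator, length: int, good: bool) -> str:
    loc, scale = (37.0, 2.0) if good else (28.0, 3.0)
    q = np.clip(np.rint(rng.normal(loc, scale, size=length)), 2, 40).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _sequence_molecules(
    mol_seqs: list[str],
    mol_truth: list[tuple[str, str, str, str]],  # template_id, fwd_umi, rev_umi, lineage
    mol_inserts: list[str],
    weights: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[RawReadPair], pd.DataFrame]:
    """Multinomial read draw, per-mate substitution errors, quality model."""
    from .dna import apply_substitutions

    total = weights.sum()
    if not total > 0.0:
        raise ValueError("total amplification weight is zero; nothing to sequence")
    counts = rng.multinomial(config.sequencing_depth, weights / total)
    L = config.read_length
    e = config.seq_error_rate
    pairs: list[RawReadPair] = []
    truth_rows: list[tuple] = []
    ridx = 0
    for mi in np.nonzero(counts)[0]:
        mi = int(mi)
        amp = mol_seqs[mi]
        fwd_true = amp[:L]
        rev_true = revcomp(amp)[:L]
        overlap = len(fwd_true) + len(rev_true) - len(amp)
        if overlap < 51:
            raise ValueError(
                f"designed overlap {overlap} bp < 51; increase read_length "
                f"(amplicon length {len(amp)})"
            )
        tid, fu, ru, lineage = mol_truth[mi]
        for _ in range(int(counts[mi])):
            rid = f"read_{ridx:07d}"
            ridx += 1
            good = bool(rng.random() < config.quality_pass_fraction)
            pairs.append(
                RawReadPair(
                    rid,
                    apply_substitutions(fwd_true, rng, e),
                    _quality_string(rng, len(fwd_true), good),
                    apply_substitutions(rev_true, rng, e),
                    _quality_string(rng, len(rev_true), good),
                )
            )
            truth_rows.append((rid, tid, fu, ru, lineage, mol_inserts[mi]))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return pairs, truth


def simulate_pcr2_and_sequencing(
    amplicons: list[Amplicon],
    templates: list[Template],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RawReadPair], pd.DataFrame]:
    """Exponential PCR2 with per-molecule efficiency, then paired-end sequencing.

    Returns the read pairs and a truth table with one row per emitted pair.
    """
    if not amplicons:
        raise ValueError("no amplicons to sequence")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mol_seqs = [amplicon_sequence(templates[a.template_index], a, config) for a in amplicons]
    mol_truth = [
        (templates[a.template_index].template_id, a.fwd_umi, a.rev_umi, a.lineage)
        for a in amplicons
    ]
    mol_inserts = [templates[a.template_index].full_sequence for a in amplicons]
    lengths = np.array([len(s) for s in mol_seqs], dtype=float)
    weights = _pcr2_weights(lengths, config, rng)
    return _sequence_molecules(mol_seqs, mol_truth, mol_inserts, weights, config, rng)


def simulate_sumi(
    config: SimulationConfig, germline: GermlineDB
) -> tuple[list[Template], list[Amplicon], list[RawReadPair], pd.DataFrame]:
    """Full sUMI protocol: templates -> PCR1 -> PCR2 -> paired reads + truth."""
    rng = np.random.default_rng(config.seed)
    templates = generate_templates(config, germline)
    amplicons = simulate_pcr1(templates, config, rng)
    reads, truth = simulate_pcr2_and_sequencing(amplicons, templates, config, rng)
    return templates, amplicons, reads, truth


# ------------------------------------------------------------ standard PCR

def standard_amplify_counts(
    n_templates: int, efficiencies: np.ndarray, cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """Branching-process molecule counts: each molecule duplicates with its
    template's efficiency each cycle."""
    counts = np.ones(n_templates, dtype=np.int64)
    for _ in range(cycles):
        counts = counts + rng.binomial(counts, efficiencies)
    return counts


def simulate_standard_pcr(
    templates: list[Template],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    total_cycles: int | None = None,
) -> tuple[list[RawReadPair], pd.DataFrame]:
    """Standard non-barcoded protocol: exponential from cycle 1, no primer UMIs.

    Per-template efficiency is drawn from the same scaled Beta law as PCR2 so
    the two protocols face the same efficiency heterogeneity.
    """
    if not templates:
        raise ValueError("no templates to amplify")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if total_cycles is None:
        total_cycles = config.pcr1_cycles + config.pcr2_cycles
    lo, hi = config.efficiency_range
    n = len(templates)
    if hi > lo:
        eff = lo + (hi - lo) * rng.beta(config.efficiency_beta_a, config.efficiency_beta_b, n)
    else:
        eff = np.full(n, lo)
    counts = standard_amplify_counts(n, eff, total_cycles, rng)
    mol_seqs = [t.full_sequence for t in templates]
    lengths = np.array([len(s) for s in mol_seqs], dtype=float)
    weights = counts.astype(float)
    if config.length_penalty > 0.0:
        weights = weights * (1.0 - config.length_penalty) ** (lengths - lengths.min())
    mol_truth = [(t.template_id, "", "", "template_primed") for t in templates]
    return _sequence_molecules(mol_seqs, mol_truth, mol_seqs, weights, config, rng)


# ---------------------------------------------------------------------- I/O

def write_truth(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_paired_fastq(
    out_dir: str | Path, reads: list[RawReadPair], prefix: str = "sim"
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1 = out_dir / f"{prefix}_R1.fastq"
    r2 = out_dir / f"{prefix}_R2.fastq"
    write_fastq(r1, ((p.read_id, p.fwd_seq, p.fwd_qual) for p in reads))
    write_fastq(r2, ((p.read_id, p.rev_seq, p.rev_qual) for p in reads))
    return r1, r2
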