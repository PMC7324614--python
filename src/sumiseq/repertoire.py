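"""BCR repertoire annotation, clonal networks and diversity statistics.

Sequences surviving the filtering pipelines are annotated against a germline
V/J reference (best-identity assignment, somatic mutation calls classified
by region and codon effect, CDR3 between the conserved V-end cysteine codon
and the J-segment CDR3/FWR4 boundary declared in the region map).  Unique
sequences form the vertices of a repertoire network whose edges join pairs
at Hamming distance 1 (equal length, single substitution); connected
components, merged when they share an identical (CDR3, V, J) triple, are
clones.  Diversity is summarised with a Rényi index over per-clone
unique-sequence counts under depth-normalising subsampling.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np

from .dna import has_internal_stop, translate
from .germline import GermlineDB, GermlineRecord


@dataclasses.dataclass
class Mutation:
    position: int  # 0-based, in read coordinates
    from_base: str
    to_base: str
    region: str  # "CDR" | "FWR"
    effect: str  # "silent" | "non_silent"


@dataclasses.dataclass
class AnnotatedBCR:
    sequence: str
    v_gene: str
    j_gene: str
    v_mismatches: int
    mutations: list[Mutation]
    cdr3_nt: str
    cdr3_aa: str
    in_frame: bool
    abundance: int


@dataclasses.dataclass
class RepertoireGraph:
    graph: nx.Graph  # nodes are unique sequences; node attr "abundance"

    @property
    def vertices(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def clusters(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


@dataclasses.dataclass
class Clone:
    clone_id: int
    members: list[str]  # unique sequences
    total_reads: int
    unique_sequences: int


# ------------------------------------------------------------- annotation

def _best_hit(seq: str, genes: Sequence[GermlineRecord]) -> tuple[GermlineRecord, int, int, int]:
    """Best-identity infix alignment of each germline gene within ``seq``.

    Returns (gene, edit_distance, start, end); ties resolve to the first
    gene in reference order.
    """
    best = None
    for g in genes:
        res = edlib.align(g.sequence, seq, mode="HW", task="locations")
        d = res["editDistance"]
        if best is None or d < best[1]:
            start, end = res["locations"][0]
            best = (g, d, start, end + 1)
    return best


def _call_mutations(
    seq: str, start: int, gene: GermlineRecord, offset_in_gene: int = 0
) -> list[Mutation]:
    """Positional substitution calls versus a germline segment (equal-length only)."""
    muts: list[Mutation] = []
    g = gene.sequence
    for i in range(len(g)):
        obs = seq[start + i]
        if obs == g[i]:
            continue
        region = gene.region_of(i) or "FWR"
        # effect from the full observed codon against the full germline codon
        c0 = i - i % 3
        g_codon = g[c0 : c0 + 3]
        o_codon = seq[start + c0 : start + c0 + 3]
        effect = (
            "silent"
            if len(g_codon) == 3 and len(o_codon) == 3 and translate(o_codon) == translate(g_codon)
            else "non_silent"
        )
        muts.append(
            Mutation(
                position=start + i,
                from_base=g[i],
                to_base=obs,
                region="CDR" if region.startswith("CDR") else "FWR",
                effect=effect,
            )
        )
    return muts


def filter_bcr(
    sequences: Iterable[str] | Mapping[str, int],
    germline: GermlineDB,
    min_identity: float = 0.80,
) -> tuple[list[AnnotatedBCR], list[tuple[str, str]]]:
    """Annotate sequences against the germline reference; reject non-BCRs.

    ``sequences`` is an iterable of molecule sequences (duplicates allowed —
    they accumulate abundance) or a {sequence: abundance} mapping.  A
    sequence is rejected when its best V identity falls below
    ``min_identity``, its best J identity falls below ``min_identity``, or
    an in-frame stop codon interrupts the reading frame from the V segment
    through the junction.  Rejections are returned as (sequence, reason).
    """
    if isinstance(sequences, Mapping):
        abundance = dict(sequences)
    else:
        abundance = {}
        for s in sequences:
            abundance[s] = abundance.get(s, 0) + 1
    if not germline.v_genes or not germline.j_genes:
        raise ValueError("germline database must contain V and J genes")

    annotated: list[AnnotatedBCR] = []
    rejected: list[tuple[str, str]] = []
    for seq, count in abundance.items():
        v, v_dist, v_start, v_end = _best_hit(seq, germline.v_genes)
        if 1.0 - v_dist / len(v.sequence) < min_identity:
            rejected.append((seq, "low_v_identity"))
            continue
        j, j_dist, j_start, j_end = _best_hit(seq, germline.j_genes)
        if 1.0 - j_dist / len(j.sequence) < min_identity or j_start < v_end:
            rejected.append((seq, "no_j_gene"))
            continue
        if has_internal_stop(seq[v_start:j_end]):
            rejected.append((seq, "no_orf"))
            continue

        muts: list[Mutation] = []
        if v_end - v_start == len(v.sequence):
            muts += _call_mutations(seq, v_start, v)
        if j_end - j_start == len(j.sequence):
            muts += _call_mutations(seq, j_start, j)

        cdr3_regions = [r for r in j.region_map if r[0] == "CDR3"]
        j_cdr3_end = cdr3_regions[0][2] if cdr3_regions else 0
        cdr3_nt = seq[v_end : j_start + j_cdr3_end]
        in_frame = (
            len(cdr3_nt) % 3 == 0
            and (v_end - v_start) % 3 == 0
            and not has_internal_stop(cdr3_nt)
        )
        cdr3_aa = translate(cdr3_nt) if in_frame else ""
        annotated.append(
            AnnotatedBCR(
                sequence=seq,
                v_gene=v.gene_id,
                j_gene=j.gene_id,
                v_mismatches=v_dist,
                mutations=muts,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                in_frame=in_frame,
                abundance=count,
            )
        )
    return annotated, rejected


# ---------------------------------------------------------------- networks

def build_network(annotated: Sequence[AnnotatedBCR]) -> RepertoireGraph:
    """Hamming-1 network over unique sequences.

    Vertices are deduplicated sequences with summed abundance; an edge joins
    two vertices iff they have equal length and differ by exactly one
    substitution (indel differences never join).  Neighbour discovery uses
    single-position wildcard bucketing, O(n * length).
    """
    if not annotated:
        raise ValueError("build_network needs at least one sequence")
    g = nx.Graph()
    for a in annotated:
        if g.has_node(a.sequence):
            g.nodes[a.sequence]["abundance"] += a.abundance
        else:
            g.add_node(a.sequence, abundance=a.abundance)
    buckets: dict[tuple[int, int, str], list[str]] = {}
    for seq in g.nodes:
        for i in range(len(seq)):
            buckets.setdefault(
                (len(seq), i, seq[:i] + seq[i + 1 :]), []
            ).append(seq)
    for members in buckets.values():
        for i in range(len(members)):
            for k in range(i + 1, len(members)):
                g.add_edge(members[i], members[k])
    return RepertoireGraph(g)


def define_clones(
    graph: RepertoireGraph, annotated: Sequence[AnnotatedBCR]
) -> list[Clone]:
    """Connected components, merged when they share an exact (CDR3, V, J) triple."""
    info = {a.sequence: a for a in annotated}
    components = sorted(graph.clusters(), key=lambda c: sorted(c)[0])
    parent = list(range(len(components)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    key_to_comp: dict[tuple[str, str, str], int] = {}
    for ci, comp in enumerate(components):
        for seq in comp:
            a = info.get(seq)
            if a is None or not a.cdr3_nt:
                continue
            key = (a.cdr3_nt, a.v_gene, a.j_gene)
            if key in key_to_comp:
                ra, rb = find(key_to_comp[key]), find(ci)
                if ra != rb:
                    parent[rb] = ra
            else:
                key_to_comp[key] = ci

    merged: dict[int, list[str]] = {}
    for ci, comp in enumerate(components):
        merged.setdefault(find(ci), []).extend(sorted(comp))
    clones = []
    for cid, (_, members) in enumerate(sorted(merged.items())):
        total = sum(graph.graph.nodes[s]["abundance"] for s in members)
        clones.append(
            Clone(
                clone_id=cid,
                members=members,
                total_reads=total,
                unique_sequences=len(members),
            )
        )
    return clones


def clone_reads(clone: Clone, graph: RepertoireGraph) -> list[str]:
    """Abundance-expanded read sequences of one clone."""
    out: list[str] = []
    for seq in clone.members:
        out.extend([seq] * graph.graph.nodes[seq]["abundance"])
    return out


# ---------------------------------------------------------------- diversity

def renyi_index(weights: Sequence[float], alpha: float = 2.0) -> float:
    """Rényi entropy of order ``alpha`` of a weight vector (natural log).

    Weights are normalised to sum 1; ``alpha = 1`` returns the Shannon
    limit by continuity.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("renyi_index needs at least one positive weight")
    w = w / w.sum()
    if abs(alpha - 1.0) < 1e-12:
        return float(-(w * np.log(w)).sum())
    return float(np.log((w**alpha).sum()) / (1.0 - alpha))


def clonal_diversification_index(
    clone_read_seqs: Mapping[int, Sequence[str]],
    depth: int = 1000,
    repeats: int = 100,
    alpha: float = 2.0,
    seed: int = 0,
    unit: str = "clones",
) -> float:
    """Mean Rényi index of the per-clone unique-sequence distribution.

    Per repeat the repertoire is subsampled to ``depth`` units — clones
    (default) or reads — without replacement; each sampled clone contributes
    weight proportional to its unique-sequence count within the subsample.
    """
    if unit not in ("clones", "reads"):
        raise ValueError("unit must be 'clones' or 'reads'")
    rng = np.random.default_rng(seed)
    clone_ids = sorted(clone_read_seqs)
    values = np.empty(repeats)
    if unit == "clones":
        uniques = np.array([len(set(clone_read_seqs[c])) for c in clone_ids], dtype=float)
        k = min(depth, len(clone_ids))
        for r in range(repeats):
            idx = rng.choice(len(clone_ids), size=k, replace=False)
            values[r] = renyi_index(uniques[idx], alpha)
    else:
        flat_clone: list[int] = []
        flat_seq: list[str] = []
        for c in clone_ids:
            for s in clone_read_seqs[c]:
                flat_clone.append(c)
                flat_seq.append(s)
        if len(flat_seq) < depth:
            raise ValueError(f"need >= {depth} reads for read-level subsampling")
        flat_clone_arr = np.array(flat_clone)
        for r in range(repeats):
            idx = rng.choice(len(flat_seq), size=depth, replace=False)
            per_clone: dict[int, set[str]] = {}
            for i in idx:
                per_clone.setdefault(int(flat_clone_arr[i]), set()).add(flat_seq[i])
            values[r] = renyi_index([len(v) for v in per_clone.values()], alpha)
    return float(values.mean())


def intraclonal_diversity(
    clone_reads_by_method: Mapping[str, Sequence[str]],
    frac: float = 0.75,
    repeats: int = 50,
    seed: int = 0,
) -> dict[str, float] | None:
    """Depth-matched unique-sequence count of one clone under each method.

    The common depth is ``floor(frac * min_method_read_count)``; each method
    is subsampled to it without replacement and the number of unique
    sequences counted, averaged over ``repeats``.  Returns ``None`` (clone
    skipped) when the common depth is below 1.
    """
    counts = {m: len(r) for m, r in clone_reads_by_method.items()}
    d = int(frac * min(counts.values()))
    if d < 1:
        return None
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for m in sorted(clone_reads_by_method):
        seqs = np.array(clone_reads_by_method[m], dtype=object)
        vals = np.empty(repeats)
        for r in range(repeats):
            idx = rng.choice(seqs.size, size=d, replace=False)
            vals[r] = len(set(seqs[idx]))
        out[m] = float(vals.mean())
    return out


# --------------------------------------------------------------- SHM stats

def shm_stats(annotated: Sequence[AnnotatedBCR]) -> dict:
    """Abundance-weighted repertoire mutation summary.

    ``prop_unmutated`` counts molecules whose V segment is within 1 mismatch
    of germline; ratios with zero denominators are reported as ``None``.
    """
    if not annotated:
        raise ValueError("shm_stats needs at least one annotated sequence")
    total = sum(a.abundance for a in annotated)
    unmutated = sum(a.abundance for a in annotated if a.v_mismatches <= 1)
    silent = nonsilent = cdr = fwr = 0
    for a in annotated:
        for m in a.mutations:
            w = a.abundance
            if m.effect == "silent":
                silent += w
            else:
                nonsilent += w
            if m.region == "CDR":
                cdr += w
            else:
                fwr += w
    in_frame = [a for a in annotated if a.in_frame]
    mean_cdr3 = (
        sum(len(a.cdr3_aa) * a.abundance for a in in_frame)
        / sum(a.abundance for a in in_frame)
        if in_frame
        else None
    )
    return {
        "prop_unmutated": unmutated / total,
        "silent_to_nonsilent_ratio": silent / nonsilent if nonsilent else None,
        "cdr_fwr_mutation_ratio": cdr / fwr if fwr else None,
        "mean_cdr3_aa_length": mean_cdr3,
    }


# ------------------------------------------------------------ visualisation

def viz_subsample(
    graph: RepertoireGraph,
    clones: Sequence[Clone],
    n_clones: int = 1000,
    repeats: int = 100,
    n_bcrs: int = 500,
    seed: int = 0,
) -> RepertoireGraph:
    """Representative subgraph preserving relative clonal architecture.

    ``repeats`` clone subsamples (each of ``min(n_clones, available)``
    clones, without replacement) record their maximum clone size; the repeat
    whose maximum is closest to the median of the recorded maxima (ties to
    the lowest repeat index) is selected, ``n_bcrs`` reads are drawn from
    its clones and the network is rebuilt from those reads.
    """
    if not clones:
        raise ValueError("viz_subsample needs at least one clone")
    k = min(n_clones, len(clones))
    max_sizes = np.empty(repeats)
    picks: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        idx = rng.choice(len(clones), size=k, replace=False)
        picks.append(idx)
        max_sizes[r] = max(clones[i].total_reads for i in idx)
    med = float(np.median(max_sizes))
    chosen = int(np.argmin(np.abs(max_sizes - med)))
    reads: list[str] = []
    for i in sorted(picks[chosen]):
        reads.extend(clone_reads(clones[int(i)], graph))
    if len(reads) > n_bcrs:
        idx = np.random.default_rng(seed + 1 + chosen).choice(
            len(reads), size=n_bcrs, replace=False
        )
        reads = [reads[int(i)] for i in sorted(idx)]
    counts: dict[str, int] = {}
    for s in reads:
        counts[s] = counts.get(s, 0) + 1
    pseudo = [
        AnnotatedBCR(s, "", "", 0, [], "", "", False, c) for s, c in counts.items()
    ]
    return build_network(pseudo)


# ---------------------------------------------------------------------- I/O

def write_annotations(path: str | Path, annotated: Sequence[AnnotatedBCR]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence\tv_gene\tj_gene\tv_mismatches\tn_mutations\t"
            "cdr3_nt\tcdr3_aa\tin_frame\tabundance\n"
        )
        for a in annotated:
            fh.write(
                f"{a.sequence}\t{a.v_gene}\t{a.j_gene}\t{a.v_mismatches}\t"
                f"{len(a.mutations)}\t{a.cdr3_nt}\t{a.cdr3_aa}\t"
                f"{int(a.in_frame)}\t{a.abundance}\n"
            )


def write_clone_table(path: str | Path, clones: Sequence[Clone]) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\ttotal_reads\tunique_sequences\n")
        for c in clones:
            fh.write(f"{c.clone_id}\t{c.total_reads}\t{c.unique_sequences}\n")


def write_edge_list(path: str | Path, graph: RepertoireGraph) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in graph.edges:
            fh.write(f"{a}\t{b}\n")
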