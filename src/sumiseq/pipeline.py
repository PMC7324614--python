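"""End-to-end orchestration of the filtering pipelines.

The canonical workflows:

* ``process_sumi`` — merged-read QC → primer/UMI annotation → UMI grouping →
  consensus calling (barcode-aware error and bias correction).
* ``process_standard`` — the same reads with barcode information ignored:
  QC → gene-specific primer finding only, one sequence per surviving read.
* ``run_sumi_pipeline`` / ``run_comparison`` — file-level drivers that write
  stage outputs, a reconciling run manifest, and (for the comparison) the
  paired repertoire-feature report with Wilcoxon tests.

Stage seeds are derived from one master seed by hashing the stage name, so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import __version__
from .germline import GermlineDB
from .preprocess import (
    DEFAULT_MIN_MEDIAN_PHRED,
    DEFAULT_MIN_OVERLAP,
    MergedRead,
    RawReadPair,
    merge_pairs,
    quality_filter,
    read_fastq_pairs,
    write_merged_fasta,
)
from .repertoire import (
    build_network,
    clone_reads,
    define_clones,
    filter_bcr,
    intraclonal_diversity,
    shm_stats,
    write_annotations,
    write_clone_table,
)
from .sumi import (
    AnnotatedRead,
    ConsensusRecord,
    PrimerSpec,
    Rejection,
    annotate_reads,
    call_consensus_all,
    group_by_umi,
    standard_filter,
    write_consensus_fasta,
    write_rejections,
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stage_counts: dict[str, int]
    rejection_counts: dict[str, dict[str, int]]
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def comparable(self) -> dict:
        """Manifest content with volatile fields (timestamps) removed."""
        d = self.to_dict()
        d.pop("timestamp")
        return d

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _reject_counts(rejections: Sequence[Rejection]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in rejections:
        out[r.reason] = out.get(r.reason, 0) + 1
    return out


@dataclasses.dataclass
class SumiResult:
    merged: list[MergedRead]
    annotated: list[AnnotatedRead]
    consensus: list[ConsensusRecord]
    primer_rejections: list[Rejection]
    consensus_rejections: list[Rejection]
    stage_counts: dict[str, int]
    rejection_counts: dict[str, dict[str, int]]


def process_sumi(
    pairs: Sequence[RawReadPair],
    spec: PrimerSpec,
    min_median_phred: int = DEFAULT_MIN_MEDIAN_PHRED,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_agreement: float = 0.8,
    small_group_max: int = 4,
) -> SumiResult:
    """Barcode-aware pipeline on in-memory read pairs."""
    qc = quality_filter(pairs, min_median_phred)
    merged = merge_pairs(qc, min_overlap)
    annotated, primer_rej = annotate_reads(merged, spec)
    groups = group_by_umi(annotated)
    consensus, cons_rej = call_consensus_all(groups, min_agreement, small_group_max)
    counts = {
        "input_pairs": len(pairs),
        "quality_filtered": len(qc),
        "merged": len(merged),
        "annotated": len(annotated),
        "umi_groups": len(groups),
        "consensus": len(consensus),
    }
    return SumiResult(
        merged=merged,
        annotated=annotated,
        consensus=consensus,
        primer_rejections=primer_rej,
        consensus_rejections=cons_rej,
        stage_counts=counts,
        rejection_counts={
            "locate_primers": _reject_counts(primer_rej),
            "call_consensus": _reject_counts(cons_rej),
        },
    )


@dataclasses.dataclass
class StandardResult:
    merged: list[MergedRead]
    annotated: list[AnnotatedRead]
    primer_rejections: list[Rejection]
    stage_counts: dict[str, int]
    rejection_counts: dict[str, dict[str, int]]


def process_standard(
    pairs: Sequence[RawReadPair],
    spec: PrimerSpec,
    min_median_phred: int = DEFAULT_MIN_MEDIAN_PHRED,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> StandardResult:
    """Barcode-ignoring pipeline on in-memory read pairs."""
    qc = quality_filter(pairs, min_median_phred)
    merged = merge_pairs(qc, min_overlap)
    annotated, rej = standard_filter(merged, spec)
    counts = {
        "input_pairs": len(pairs),
        "quality_filtered": len(qc),
        "merged": len(merged),
        "filtered": len(annotated),
    }
    return StandardResult(
        merged=merged,
        annotated=annotated,
        primer_rejections=rej,
        stage_counts=counts,
        rejection_counts={"standard_filter": _reject_counts(rej)},
    )


def run_sumi_pipeline(
    r1: str | Path,
    r2: str | Path,
    spec: PrimerSpec,
    out_dir: str | Path,
    germline: GermlineDB | None = None,
    seed: int = 0,
    min_median_phred: int = DEFAULT_MIN_MEDIAN_PHRED,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_agreement: float = 0.8,
    small_group_max: int = 4,
    min_identity: float = 0.80,
) -> RunManifest:
    """File-level barcode-aware run; optionally demultiplexed per sample.

    Writes the merged FASTA, consensus FASTA, rejection logs, repertoire
    annotations (when a germline is given) and the run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = read_fastq_pairs(r1, r2)
    result = process_sumi(
        pairs, spec, min_median_phred, min_overlap, min_agreement, small_group_max
    )
    write_merged_fasta(out / "merged.fasta", result.merged)
    write_rejections(out / "primer_rejections.tsv", result.primer_rejections)
    write_rejections(out / "consensus_rejections.tsv", result.consensus_rejections)

    samples: dict[str, list[ConsensusRecord]]
    if spec.sample_barcodes:
        by_sample: dict[str, list[AnnotatedRead]] = {}
        for a in result.annotated:
            by_sample.setdefault(a.sample or "unassigned", []).append(a)
        samples = {}
        for name, reads in sorted(by_sample.items()):
            groups = group_by_umi(reads)
            cons, _ = call_consensus_all(groups, min_agreement, small_group_max)
            samples[name] = cons
    else:
        samples = {"sample": result.consensus}

    for name, cons in samples.items():
        write_consensus_fasta(out / f"consensus_{name}.fasta", cons)
        if germline is not None and cons:
            annotated, _ = filter_bcr(
                {c.consensus: 1 for c in cons}, germline, min_identity
            )
            if annotated:
                write_annotations(out / f"annotations_{name}.tsv", annotated)
                graph = build_network(annotated)
                clones = define_clones(graph, annotated)
                write_clone_table(out / f"clones_{name}.tsv", clones)

    manifest = RunManifest(
        config={
            "r1": str(r1),
            "r2": str(r2),
            "min_median_phred": min_median_phred,
            "min_overlap": min_overlap,
            "min_agreement": min_agreement,
            "small_group_max": small_group_max,
            "n_samples": len(samples),
        },
        seed=seed,
        version=__version__,
        stage_counts=result.stage_counts,
        rejection_counts=result.rejection_counts,
        timestamp=datetime.datetime.now().isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest


def repertoire_features(
    sequences: Mapping[str, int], germline: GermlineDB, min_identity: float = 0.80
) -> dict:
    """Annotate one method's sequence counts and summarise Fig-style features."""
    annotated, rejected = filter_bcr(sequences, germline, min_identity)
    if not annotated:
        raise ValueError("no sequences survived BCR filtering")
    graph = build_network(annotated)
    clones = define_clones(graph, annotated)
    feats = shm_stats(annotated)
    feats.update(
        {
            "n_molecules": sum(a.abundance for a in annotated),
            "n_unique": len(annotated),
            "n_clones": len(clones),
            "n_rejected": len(rejected),
        }
    )
    return {"annotated": annotated, "graph": graph, "clones": clones, "features": feats}


def _clone_key(clone, graph, annotated) -> tuple[str, str, str]:
    """Identify a clone across methods by its most abundant member's annotation."""
    info = {a.sequence: a for a in annotated}
    best = max(clone.members, key=lambda s: (graph.graph.nodes[s]["abundance"], s))
    a = info[best]
    return (a.cdr3_nt, a.v_gene, a.j_gene)


def run_comparison(
    method_sequences: Mapping[str, Mapping[str, int]],
    germline: GermlineDB,
    min_identity: float = 0.80,
    frac: float = 0.75,
    repeats: int = 50,
    seed: int = 0,
    min_clone_fraction: float = 0.01,
) -> dict:
    """Paired comparison of repertoire features between filtering methods.

    ``method_sequences`` maps method name -> {sequence: molecule count}
    (e.g. consensus sequences each counted once versus raw filtered reads).
    Clones are matched across methods by the (CDR3, V, J) key of their
    dominant member; only clones holding at least ``min_clone_fraction`` of
    each method's repertoire are compared (default 1%).  Matched clones are
    compared by depth-normalised intraclonal diversity, with a one-sided
    Wilcoxon signed-rank test when two methods are given.
    """
    per_method = {
        m: repertoire_features(seqs, germline, min_identity)
        for m, seqs in method_sequences.items()
    }
    report: dict = {"features": {m: r["features"] for m, r in per_method.items()}}

    keyed: dict[str, dict[tuple, list[str]]] = {}
    for m, r in per_method.items():
        keyed[m] = {}
        total = sum(c.total_reads for c in r["clones"])
        for clone in r["clones"]:
            if clone.total_reads < min_clone_fraction * total:
                continue
            key = _clone_key(clone, r["graph"], r["annotated"])
            keyed[m][key] = clone_reads(clone, r["graph"])
    common = set.intersection(*(set(k) for k in keyed.values()))
    clone_div: dict[str, dict[str, float]] = {}
    for key in sorted(common):
        res = intraclonal_diversity(
            {m: keyed[m][key] for m in keyed},
            frac=frac,
            repeats=repeats,
            seed=stage_seed(seed, f"intraclonal|{key[0]}"),
        )
        if res is not None:
            clone_div["|".join(key)] = res
    report["intraclonal_diversity"] = clone_div

    methods = sorted(method_sequences)
    if len(methods) == 2 and len(clone_div) >= 2:
        a = np.array([v[methods[0]] for v in clone_div.values()])
        b = np.array([v[methods[1]] for v in clone_div.values()])
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, zero_method="wilcox", alternative="less").pvalue)
        report["intraclonal_wilcoxon_less"] = {f"{methods[0]} < {methods[1]}": p}
    return report
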