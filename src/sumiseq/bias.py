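"""Amplification-bias statistics for synthetic DNA-UMI libraries.

Two bespoke statistics:

* **loop re-amplification rate** — the proportion of reads whose internal
  synthetic DNA-UMI is seen with more than one primer barcode pair, per 1000
  reads.  A synthetic UMI linked to several primer-UMI pairs means the same
  physical molecule was captured by more than one priming event, which under
  low template re-priming is the signature of a looped amplicon being
  re-amplified.

* **relative amplification bias** — after subsampling a filtered dataset to a
  fixed depth (default 3000 reads, without replacement), the maximum number
  of reads carrying any single synthetic DNA-UMI; the mean over repeats
  (default 500) is reported.  A perfectly unbiased library gives 1 at depth
  equal to the number of molecules; differential amplification inflates it.

Plus ordinary least-squares fitting for titration linearity (observed clonal
fraction against input fraction).
"""

from __future__ import annotations

import dataclasses
import itertools
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DEPTH = 3000
DEFAULT_REPEATS = 500


@dataclasses.dataclass
class UMILinkTable:
    """Per-read links between the internal synthetic UMI and the primer-UMI pair."""

    table: pd.DataFrame  # columns: read_id, synthetic_umi, fwd_umi, rev_umi

    REQUIRED = ("read_id", "synthetic_umi", "fwd_umi", "rev_umi")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"link table missing columns: {missing}")

    @property
    def n_reads(self) -> int:
        return len(self.table)

    def pairs_per_synthetic_umi(self) -> pd.Series:
        df = self.table
        key = df["fwd_umi"] + "+" + df["rev_umi"]
        return key.groupby(df["synthetic_umi"]).nunique()

    def reads_per_synthetic_umi(self) -> np.ndarray:
        return self.table["synthetic_umi"].value_counts().to_numpy()

    @classmethod
    def read(cls, path: str | Path) -> "UMILinkTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class BiasResult:
    mean_bias: float
    depth: int
    repeats: int
    seed: int
    per_repeat: np.ndarray

    def __post_init__(self) -> None:
        if not 1.0 <= self.mean_bias <= self.depth:
            raise ValueError(f"mean_bias {self.mean_bias} outside [1, depth]")


def loop_reamp_rate(link_table: UMILinkTable) -> float:
    """Rate (per 1000 reads) of reads whose synthetic UMI has >1 primer pair."""
    if link_table.n_reads < 1:
        raise ValueError("loop_reamp_rate undefined on an empty link table")
    pairs = link_table.pairs_per_synthetic_umi()
    multi = set(pairs.index[pairs > 1])
    n_multi = int(link_table.table["synthetic_umi"].isin(multi).sum())
    return 1000.0 * n_multi / link_table.n_reads


def amplification_bias(
    read_umi_counts: Sequence[int] | np.ndarray,
    depth: int = DEFAULT_DEPTH,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> BiasResult:
    """Mean over repeats of max reads-per-synthetic-UMI in a fixed-depth subsample.

    ``read_umi_counts`` are reads per synthetic UMI; subsampling is without
    replacement (multivariate hypergeometric over UMI categories).
    """
    counts = np.asarray(read_umi_counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"need >= {depth} reads to subsample, have {total}")
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(repeats, dtype=np.int64)
    for r in range(repeats):
        sub = rng.multivariate_hypergeometric(counts, depth)
        per_repeat[r] = sub.max()
    return BiasResult(
        mean_bias=float(per_repeat.mean()),
        depth=depth,
        repeats=repeats,
        seed=seed,
        per_repeat=per_repeat,
    )


def compare_bias(
    methods: Mapping[str, Mapping[str, Sequence[int]]],
    depth: int = DEFAULT_DEPTH,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    paired: bool = True,
) -> dict:
    """Per-method mean bias over shared samples plus pairwise Wilcoxon tests.

    ``methods`` maps method name -> {sample name -> reads-per-synthetic-UMI
    counts}.  Paired designs require identical sample names across methods
    and use the two-sided signed-rank test (zero differences dropped, the
    standard convention; all-zero difference vectors are reported as p = 1).
    Unpaired designs (``paired=False``) use the rank-sum test.  A single
    sample yields descriptive output only.
    """
    if len(methods) < 2:
        raise ValueError("compare_bias needs at least two methods")
    names = list(methods)
    sample_sets = [set(methods[m]) for m in names]
    if paired and any(s != sample_sets[0] for s in sample_sets[1:]):
        raise ValueError("paired comparison requires identical sample names per method")
    samples = sorted(sample_sets[0] if paired else set.union(*sample_sets))

    results: dict[str, dict[str, BiasResult]] = {}
    for m in names:
        results[m] = {}
        for s in sorted(methods[m]):
            # per-sample seed shared across methods: identical tables give
            # identical subsamples (common random numbers tighten pairing)
            sub_seed = seed + (zlib.crc32(s.encode()) % 100003)
            results[m][s] = amplification_bias(methods[m][s], depth, repeats, sub_seed)

    report: dict = {
        "depth": depth,
        "repeats": repeats,
        "mean_bias": {
            m: {s: res.mean_bias for s, res in results[m].items()} for m in names
        },
        "p_values": {},
    }
    if len(samples) >= 2:
        for a, b in itertools.combinations(names, 2):
            if paired:
                xa = np.array([results[a][s].mean_bias for s in samples])
                xb = np.array([results[b][s].mean_bias for s in samples])
                if np.allclose(xa, xb):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(xa, xb, zero_method="wilcox").pvalue)
            else:
                xa = [results[a][s].mean_bias for s in sorted(methods[a])]
                xb = [results[b][s].mean_bias for s in sorted(methods[b])]
                p = float(stats.ranksums(xa, xb).pvalue)
            report["p_values"][f"{a} vs {b}"] = p
    return report


def titration_fit(
    input_fractions: Sequence[float], observed_fractions: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of observed against input fractions: (slope, intercept, r_squared)."""
    x = np.asarray(input_fractions, dtype=float)
    y = np.asarray(observed_fractions, dtype=float)
    if x.size != y.size:
        raise ValueError("input and observed fraction vectors differ in length")
    if x.size < 3:
        raise ValueError("titration fit needs at least 3 points")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


# ------------------------------------------------------------------ helpers

def link_table_from_reads(annotated) -> UMILinkTable:
    """Build the link table from annotated reads that carry a synthetic UMI."""
    rows = [
        (a.read_id, a.synthetic_umi, a.fwd_umi, a.rev_umi)
        for a in annotated
        if a.synthetic_umi
    ]
    return UMILinkTable(
        pd.DataFrame(rows, columns=["read_id", "synthetic_umi", "fwd_umi", "rev_umi"])
    )


def link_table_from_truth(truth: pd.DataFrame, templates) -> UMILinkTable:
    """Ground-truth link table straight from the simulator (error-free links)."""
    umi_of = {t.template_id: t.synthetic_umi for t in templates}
    df = pd.DataFrame(
        {
            "read_id": truth["read_id"],
            "synthetic_umi": truth["template_id"].map(umi_of),
            "fwd_umi": truth["fwd_umi"],
            "rev_umi": truth["rev_umi"],
        }
    )
    return UMILinkTable(df)
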