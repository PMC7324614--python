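"""Canned desk-scale simulation studies.

Each function runs one self-contained in-silico experiment — simulate a
sample, push it through the filtering pipelines, measure the relevant
statistic — and returns plain dictionaries of numbers.  They are the
package's reproducible analogues of the wet-lab analyses: error-correction
efficiency, amplification-bias reduction, titration linearity, loop
re-amplification behaviour, intraclonal-diversity deflation and apparent-SHM
deflation.  Problem sizes default to values a laptop handles in minutes; all
randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias import UMILinkTable, amplification_bias, loop_reamp_rate, titration_fit
from .germline import J_LEN, V_LEN, GermlineDB, synthetic_germline
from .pipeline import process_standard, process_sumi, repertoire_features, run_comparison
from .simulate import (
    SimulationConfig,
    generate_templates,
    pcr1_events,
    simulate_pcr1,
    simulate_pcr2_and_sequencing,
    simulate_standard_pcr,
    synthetic_umi_layout,
)
from .sumi import PrimerSpec, build_primer_spec


def _spec_for(config: SimulationConfig, germline: GermlineDB) -> PrimerSpec:
    off, length = synthetic_umi_layout(config)
    return build_primer_spec(
        germline,
        umi_length=config.umi_length,
        synthetic_umi_offset=off,
        synthetic_umi_length=length,
    )


# ------------------------------------------------------- error correction

def error_correction_study(
    seed: int = 0,
    n_templates: int = 100,
    depth: int = 20_000,
    error_rate: float = 0.005,
    min_support: int = 5,
) -> dict:
    """Consensus-versus-raw mismatch rates against simulator ground truth.

    Raw rate: per-base mismatches of annotated read inserts against the true
    insert of their molecule.  Consensus rate: same comparison for consensus
    sequences with read support >= ``min_support``, matched to their molecule
    through the primer-UMI pair.  Equal-length comparisons only (the
    substitution-only error model makes length changes impossible except
    through mis-merging, which is what the comparison should not absorb).
    """
    germline = synthetic_germline(seed=0)
    config = SimulationConfig(
        n_templates=n_templates,
        sequencing_depth=depth,
        seq_error_rate=error_rate,
        seed=seed,
    )
    from .simulate import simulate_sumi

    _, _, reads, truth = simulate_sumi(config, germline)
    spec = _spec_for(config, germline)
    result = process_sumi(reads, spec)

    insert_of_read = dict(zip(truth.read_id, truth.true_insert))
    insert_of_pair = {
        (r.fwd_umi, r.rev_umi): r.true_insert for r in truth.itertuples()
    }

    def rate(pairs_of_seqs: list[tuple[str, str]]) -> tuple[float, int]:
        mism = bases = 0
        for obs, true in pairs_of_seqs:
            if len(obs) != len(true):
                continue
            bases += len(true)
            mism += sum(a != b for a, b in zip(obs, true))
        return (mism / bases if bases else 0.0), bases

    raw_rate, raw_bases = rate(
        [(a.insert, insert_of_read[a.read_id]) for a in result.annotated]
    )
    cons_pairs = [
        (c.consensus, insert_of_pair[c.key])
        for c in result.consensus
        if c.support >= min_support and c.key in insert_of_pair
    ]
    cons_rate, cons_bases = rate(cons_pairs)
    return {
        "raw_mismatch_rate": raw_rate,
        "consensus_mismatch_rate": cons_rate,
        "rate_ratio": cons_rate / raw_rate if raw_rate else 0.0,
        "n_consensus_compared": len(cons_pairs),
        "raw_bases": raw_bases,
        "consensus_bases": cons_bases,
        "stage_counts": result.stage_counts,
    }


# ------------------------------------------------------- bias correction

def _sample_umi_counts(
    config: SimulationConfig, germline: GermlineDB, spec: PrimerSpec
) -> dict[str, np.ndarray]:
    """Reads-per-synthetic-UMI tables for the two filtering modes of one sample."""
    from .simulate import simulate_sumi

    _, _, reads, _ = simulate_sumi(config, germline)
    sumi_res = process_sumi(reads, spec)
    corrected = pd.Series(
        [c.synthetic_umi for c in sumi_res.consensus if c.synthetic_umi]
    ).value_counts()
    std_res = process_standard(reads, spec)
    uncorrected = pd.Series(
        [a.synthetic_umi for a in std_res.annotated if a.synthetic_umi]
    ).value_counts()
    return {
        "barcode": corrected.to_numpy(),
        "no_barcode": uncorrected.to_numpy(),
    }


def bias_correction_study(
    seed: int = 0,
    n_samples: int = 10,
    n_templates: int = 1000,
    depth: int = 32_000,
    subsample_depth: int = 3000,
    repeats: int = 500,
    include_standard_pcr: bool = False,
) -> dict:
    """Paired amplification-bias comparison across filtering modes.

    Each sample is one synthetic DNA-UMI library amplified with heterogeneous
    per-molecule PCR2 efficiency; the subsampled-maximum bias statistic is
    computed per mode, and barcode-aware filtering is compared to
    barcode-ignoring filtering with a one-sided Wilcoxon signed-rank test.
    """
    germline = synthetic_germline(seed=0)
    rows = []
    for i in range(n_samples):
        config = SimulationConfig(
            n_templates=n_templates,
            pcr1_cycles=5,
            sequencing_depth=depth,
            seed=seed * 1000 + i,
        )
        spec = _spec_for(config, germline)
        tables = _sample_umi_counts(config, germline, spec)
        if include_standard_pcr:
            templates = generate_templates(config, germline)
            std_reads, _ = simulate_standard_pcr(templates, config)
            std_res = process_standard(std_reads, spec)
            tables["standard_pcr"] = (
                pd.Series([a.synthetic_umi for a in std_res.annotated if a.synthetic_umi])
                .value_counts()
                .to_numpy()
            )
        row = {}
        for mode, counts in tables.items():
            res = amplification_bias(
                counts, depth=subsample_depth, repeats=repeats, seed=seed * 7919 + i
            )
            row[mode] = res.mean_bias
        rows.append(row)

    corrected = np.array([r["barcode"] for r in rows])
    uncorrected = np.array([r["no_barcode"] for r in rows])
    wins = int((corrected < uncorrected).sum())
    p = float(
        stats.wilcoxon(corrected, uncorrected, alternative="less").pvalue
    )
    out = {
        "per_sample": rows,
        "mean_bias_barcode": float(corrected.mean()),
        "mean_bias_no_barcode": float(uncorrected.mean()),
        "wins": wins,
        "n_samples": n_samples,
        "wilcoxon_less_p": p,
    }
    if include_standard_pcr:
        out["mean_bias_standard_pcr"] = float(
            np.mean([r["standard_pcr"] for r in rows])
        )
    return out


# ------------------------------------------------------------- titration

def titration_study(
    seed: int = 0,
    fractions: Sequence[float] = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0),
    pool_size: int = 200,
    depth: int = 4000,
) -> dict:
    """Linearity of recovered clonal fraction against input fraction.

    A clonal rearrangement is mixed into a diverse background pool at each
    input fraction; the barcode-corrected observed fraction is the share of
    consensus molecules whose sequence equals the clonal sequence.
    """
    germline = synthetic_germline(seed=0)
    observed = []
    for i, f in enumerate(fractions):
        n_clonal = round(f * pool_size)
        n_bg = pool_size - n_clonal
        pool_fracs = [f] + ([(1.0 - f) / n_bg] * n_bg if n_bg else [])
        config = SimulationConfig(
            n_templates=pool_size,
            template_pool_fractions=pool_fracs,
            pcr1_cycles=8,
            sequencing_depth=depth,
            synthetic_umi_length=0,
            seed=seed,  # same template RNG for all mixtures: same clonal sequence
        )
        templates = generate_templates(config, germline)
        by_seq: dict[str, int] = {}
        for t in templates:
            by_seq[t.full_sequence] = by_seq.get(t.full_sequence, 0) + 1
        clonal_seq = max(by_seq, key=by_seq.get) if n_clonal > 1 else None
        rng = np.random.default_rng(seed * 10_000 + 17 * i + 1)
        amplicons = simulate_pcr1(templates, config, rng)
        reads, _ = simulate_pcr2_and_sequencing(amplicons, templates, config, rng)
        spec = _spec_for(config, germline)
        result = process_sumi(reads, spec)
        n_total = len(result.consensus)
        # clonal identity by junction region (error-tolerant: residual
        # sequencing errors elsewhere in a consensus must not unassign it)
        n_match = 0
        if clonal_seq is not None:
            clonal_junction = clonal_seq[V_LEN : len(clonal_seq) - J_LEN]
            for c in result.consensus:
                junc = c.consensus[V_LEN : len(c.consensus) - J_LEN]
                if len(junc) == len(clonal_junction) and (
                    sum(a != b for a, b in zip(junc, clonal_junction)) <= 2
                ):
                    n_match += 1
        observed.append(n_match / n_total if n_total else 0.0)
    slope, intercept, r2 = titration_fit(list(fractions), observed)
    return {
        "input_fractions": list(fractions),
        "observed_fractions": observed,
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
    }


# ------------------------------------------------- loop re-amplification

def simulate_link_table(
    n_templates: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> UMILinkTable:
    """Molecule-level link table: PCR1 events + multinomial PCR2 read draw.

    Template identity stands in for the synthetic DNA-UMI (the library is
    collision-free by design), so no sequence assembly or sequencing error is
    involved — this isolates the loop-re-amplification statistic from
    read-processing effects.
    """
    amplicons = pcr1_events(n_templates, config, rng)
    if not amplicons:
        return UMILinkTable(
            pd.DataFrame(columns=["read_id", "synthetic_umi", "fwd_umi", "rev_umi"])
        )
    lo, hi = config.efficiency_range
    k = len(amplicons)
    eff = lo + (hi - lo) * rng.beta(
        config.efficiency_beta_a, config.efficiency_beta_b, k
    ) if hi > lo else np.full(k, lo)
    w = (1.0 + eff) ** config.pcr2_cycles
    counts = rng.multinomial(config.sequencing_depth, w / w.sum())
    rows = []
    rid = 0
    for a, c in zip(amplicons, counts):
        for _ in range(int(c)):
            rows.append((f"read_{rid:07d}", f"S{a.template_index}", a.fwd_umi, a.rev_umi))
            rid += 1
    return UMILinkTable(
        pd.DataFrame(rows, columns=["read_id", "synthetic_umi", "fwd_umi", "rev_umi"])
    )


def loop_rate_study(
    seed: int = 0,
    q_values: Sequence[float] = (0.0, 0.005, 0.02),
    cycle_values: Sequence[int] = (5, 10, 20),
    n_seeds: int = 20,
    n_templates: int = 200_000,
    priming_prob: float = 1e-3,
    depth: int = 5000,
) -> dict:
    """Mean loop-re-amplification rate over a (q, cycles) grid.

    Uses the excess-template regime (per-cycle priming probability << 1, as
    in a library whose molecule count far exceeds the number of priming
    events) so duplicated synthetic UMIs trace loop re-amplification and
    occasional double template priming rather than saturated re-priming.
    """
    grid: dict[tuple[float, int], float] = {}
    for q in q_values:
        for cycles in cycle_values:
            rates = []
            for s in range(n_seeds):
                config = SimulationConfig(
                    n_templates=n_templates,
                    priming_prob_per_cycle=priming_prob,
                    loop_reamp_prob_per_cycle=q,
                    pcr1_cycles=cycles,
                    sequencing_depth=depth,
                )
                rng = np.random.default_rng(
                    (seed * 100_003 + round(q * 1e6) * 101 + cycles * 7 + s) % 2**31
                )
                table = simulate_link_table(n_templates, config, rng)
                rates.append(loop_reamp_rate(table))
            grid[(q, cycles)] = float(np.mean(rates))
    return {
        "q_values": list(q_values),
        "cycle_values": list(cycle_values),
        "mean_rate": {f"q={q}|cycles={c}": v for (q, c), v in grid.items()},
        "grid": grid,
    }


# -------------------------------------------------- diversity & SHM shift

def _comparison_sample(
    seed: int,
    n_clones: int = 6,
    molecules_per_clone: int = 10,
    depth: int = 8000,
    error_rate: float = 0.003,
    shm_rate: float = 0.004,
) -> dict:
    """One repertoire sample processed with and without barcode information."""
    germline = synthetic_germline(seed=0)
    n_templates = n_clones * molecules_per_clone
    config = SimulationConfig(
        n_templates=n_templates,
        template_pool_fractions=[1.0 / n_clones] * n_clones,
        pcr1_cycles=8,
        sequencing_depth=depth,
        seq_error_rate=error_rate,
        synthetic_umi_length=0,
        shm_rate=shm_rate,
        shm_cdr_weight=2.0,
        seed=seed,
    )
    from .simulate import simulate_sumi

    _, _, reads, _ = simulate_sumi(config, germline)
    spec = _spec_for(config, germline)
    sumi_res = process_sumi(reads, spec)
    std_res = process_standard(reads, spec)
    corrected: dict[str, int] = {}
    for c in sumi_res.consensus:
        corrected[c.consensus] = corrected.get(c.consensus, 0) + 1
    uncorrected: dict[str, int] = {}
    for a in std_res.annotated:
        uncorrected[a.insert] = uncorrected.get(a.insert, 0) + 1
    return {
        "germline": germline,
        "sequences": {"barcode": corrected, "no_barcode": uncorrected},
    }


def diversity_reduction_study(
    seed: int = 0, n_samples: int = 8, repeats: int = 50, frac: float = 0.75
) -> dict:
    """Depth-matched intraclonal diversity with versus without barcode filtering.

    Pools matched clones across samples; reports per-clone paired means, the
    number of clones where barcode filtering is not higher, and the pooled
    one-sided Wilcoxon signed-rank p-value.
    """
    pairs: list[tuple[float, float]] = []
    for i in range(n_samples):
        sample = _comparison_sample(seed * 1000 + i)
        # the sample holds 6 equal designed clones (~17% each); 5% keeps
        # them all while excluding unstable sub-percent variant fragments
        report = run_comparison(
            sample["sequences"],
            sample["germline"],
            frac=frac,
            repeats=repeats,
            seed=seed * 1000 + i,
            min_clone_fraction=0.05,
        )
        for v in report["intraclonal_diversity"].values():
            pairs.append((v["barcode"], v["no_barcode"]))
    corr = np.array([p[0] for p in pairs])
    uncorr = np.array([p[1] for p in pairs])
    p = float(stats.wilcoxon(corr, uncorr, alternative="less").pvalue)
    return {
        "n_clones": len(pairs),
        "pairs": pairs,
        "n_not_higher": int((corr <= uncorr).sum()),
        "mean_barcode": float(corr.mean()),
        "mean_no_barcode": float(uncorr.mean()),
        "wilcoxon_less_p": p,
    }


def shm_deflation_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_templates: int = 50,
    depth: int = 6000,
    error_rate: float = 0.005,
) -> dict:
    """Apparent somatic hypermutation with a true mutation rate of zero.

    Sequencing errors masquerade as SHM in the barcode-ignoring pipeline;
    consensus filtering should restore a higher proportion of unmutated
    (within 1 mismatch of germline V) molecules.
    """
    germline = synthetic_germline(seed=0)
    rows = []
    for i in range(n_seeds):
        config = SimulationConfig(
            n_templates=n_templates,
            pcr1_cycles=10,
            sequencing_depth=depth,
            seq_error_rate=error_rate,
            synthetic_umi_length=0,
            shm_rate=0.0,
            seed=seed * 1000 + i,
        )
        from .simulate import simulate_sumi

        _, _, reads, _ = simulate_sumi(config, germline)
        spec = _spec_for(config, germline)
        sumi_res = process_sumi(reads, spec)
        std_res = process_standard(reads, spec)
        corrected: dict[str, int] = {}
        for c in sumi_res.consensus:
            corrected[c.consensus] = corrected.get(c.consensus, 0) + 1
        uncorrected: dict[str, int] = {}
        for a in std_res.annotated:
            uncorrected[a.insert] = uncorrected.get(a.insert, 0) + 1
        f_corr = repertoire_features(corrected, germline)["features"]
        f_unc = repertoire_features(uncorrected, germline)["features"]
        rows.append(
            {
                "prop_unmutated_barcode": f_corr["prop_unmutated"],
                "prop_unmutated_no_barcode": f_unc["prop_unmutated"],
            }
        )
    wins = sum(
        1
        for r in rows
        if r["prop_unmutated_barcode"] > r["prop_unmutated_no_barcode"]
    )
    return {
        "per_seed": rows,
        "wins": wins,
        "n_seeds": n_seeds,
        "mean_barcode": float(np.mean([r["prop_unmutated_barcode"] for r in rows])),
        "mean_no_barcode": float(
            np.mean([r["prop_unmutated_no_barcode"] for r in rows])
        ),
    }
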