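# Methods

## The generative model

The simulator emulates a two-stage barcoded amplicon experiment on BCR-like
DNA.

**Templates.** A template molecule is `V + junction + J`: a germline V
segment (150 nt, regions FWR1/CDR1/FWR2/CDR2/FWR3, ending in the conserved
cysteine codon TGT), an N-region junction (random, in frame, stop-free;
fixed 18 nt when it embeds a 12 nt internal *synthetic DNA-UMI*, otherwise
9–30 nt), and a germline J segment (48 nt: 9 nt CDR3 tail, conserved TGG,
FWR4).  The bundled synthetic germline generator draws stop-free in-frame
genes; all J genes share their 3'-terminal 21 nt because a single consensus
JH reverse primer anneals there.  `template_pool_fractions` allocates
molecules to shared rearrangements (clones) by largest-remainder rounding.
Somatic hypermutation is applied per molecule at `shm_rate` substitutions
per base with CDR positions weighted over FWR positions (default 3:1,
constraint CDR ≥ FWR); substitutions that would create an in-frame stop are
redrawn, so reading-frame filtering downstream measures real defects.
Synthetic-UMI collisions are rejected and redrawn (template identity must be
unambiguous); primer-UMI collisions are *not* — tolerating them is the
pipeline's job.

**PCR1 (near-linear barcoding).** Per cycle, each existing amplicon is
loop-re-primed with probability `q` (a copy with a fresh primer-UMI pair,
same synthetic UMI, lineage `loop_reamplified`), then each template is
primed with probability `p` (fresh pair, lineage `template_primed`).  The
expected per-template amplicon count follows `a_t = a_{t-1}(1+q) + p`.  `p`
and `q` are phenomenological: no kinetic constants exist for loop closure,
so they are free parameters.  Defaults `p = 0.9`, `q = 0.005` describe a
molecule-limited library in which nearly every molecule is captured each
cycle — the regime for error-correction and bias studies.  The
loop-rate study instead uses the excess-template regime (2·10⁵ molecules,
`p = 10⁻³`) in which a molecule is captured at most a few times in total;
only there is the duplicated-synthetic-UMI rate a sparse count, as in a
real library whose molecule count dwarfs the number of priming events.
(With `p·cycles ≫ 1` the rate statistic saturates, since every molecule
legitimately accrues several primer pairs through linear re-priming; the
statistic by definition counts those together with loop re-amplification.)

**PCR2 and sequencing.** Each amplicon receives weight
`(1 + eff)^cycles`, `eff ~ lo + (hi−lo)·Beta(a, b)` (defaults a = b = 2 on
[0.6, 1.0]) — bounded, unimodal per-molecule efficiency; an optional
per-base length penalty models poorer amplification of longer inserts.
Reads are drawn multinomially at the requested depth.  Each mate is read
from one end of the amplicon (fixed read length, default 175 nt, giving a
designed true overlap of ~52–64 bp ≥ the >50 bp merge requirement) and
receives i.i.d. substitution errors at `seq_error_rate` (default 0.005,
MiSeq-like).  Qualities come from a two-component model: a fraction of
pairs (default 95%) gets per-base Phred ~ N(37, 2), the rest N(28, 3), so
the median-quality filter has work to do.  Indel errors, chimeras and
quality–error coupling are not modelled.  The standard non-barcoded
protocol is a branching process from cycle 1 (`n ← n + Binomial(n, eff)`
per cycle, per-template efficiency), no primer UMIs.

A fixed seed yields byte-identical FASTQ and truth tables.  What the
simulator does *not* emulate — real primer/template mispriming, indels,
PCR chimeras, base-composition quality effects — bounds what passing tests
show about real libraries: they verify the statistical machinery, not
robustness to every MiSeq artefact.

## Read processing

*Quality filter*: both mates need median Phred strictly > 32 (even-length
medians take the lower central value, applied identically everywhere).
*Merging*: scan overlap offsets longest-first; merge at the first exactly
identical overlap > 50 bp, else discard.  Exactness is deliberate — one
error in the overlap discards the pair, which is why roughly half the
error-bearing pairs drop here at e = 0.005.
*Primer/UMI identification*: reads (or their reverse complements) must
show the forward MALBAC tail at the 5' end (small scan window, default
shift ≤ 2) and the reverse unit at the 3' end; gene-specific regions are
matched IUPAC-aware with ≤ 2 mismatches each; UMI-flanking conserved bases
must match exactly.  The insert keeps the gene-specific annealing regions
(they are template-encoded and needed for V/J assignment); MALBAC tails,
UMIs and any sample barcode are excised.
*Consensus*: groups are sub-grouped by length (substitution-only model ⇒
equal-length positional comparison; a length tie discards the group, and
indel-bearing minority reads leave with their minority length class).
Groups ≤ 4 reads must agree completely.  Larger groups take the per-column
plurality base and must reach ≥ 0.80 plurality at *every* column — the
minimum-over-positions reading of per-base agreement, the stricter of the
two possible readings; a 50/50 column tie fails automatically.  Each
retained record counts once downstream regardless of support: that is the
bias correction.

## Repertoire analytics

V and J are assigned by best edlib (edit-distance) infix alignment against
the germline; sequences are rejected below 80% identity or with an
in-frame stop between V start and J end.  CDR3 spans the end of the V
match to the CDR3/FWR4 boundary declared in the J region map.  Mutation
calls (equal-length alignments only) are classified silent/non-silent by
codon translation and CDR/FWR by the region map; ratios with zero
denominators are reported as missing.  "Unmutated" means V within 1
mismatch of germline.

Networks: vertices are unique sequences (summed abundance), edges join
equal-length pairs at Hamming distance exactly 1 (single-position wildcard
bucketing, O(n·L)); clones are connected components merged when they share
an identical (CDR3, V, J) triple.  The diversification index is the Rényi
entropy (natural log, order α exposed, default 2) of normalised per-clone
unique-sequence counts; subsampling defaults to clone-level draws of 1000
clones (read-level subsampling is available by flag).  Depth-matched
intraclonal diversity subsamples each method to ⌊0.75 · min count⌋ without
replacement, 50 repeats.  The visualisation subsample repeats clone draws
100 times, records each repeat's maximum clone size and keeps the repeat
closest to the median of those maxima (ties to the lowest index), then
draws 500 reads from the selected clones.

Method comparisons pair clones across pipelines by the (CDR3, V, J) key of
each clone's most abundant member and keep clones holding ≥ 1% of each
repertoire by default (major-clone filter); Wilcoxon signed-rank tests are
two-sided for bias comparisons and one-sided where the direction is the
hypothesis, zero differences dropped, with an exact null below n = 26 (the
scipy default) and all-zero difference vectors reported as p = 1.

## Study problem sizes and design choices

* **Error correction**: 100 templates, 20 000 read pairs, e = 0.005;
  consensus records with support ≥ 5 compared to their molecule's true
  insert via the primer-UMI pair.
* **Bias comparison**: 10 samples, 1000 molecules each, 5 PCR1 cycles,
  32 000 read pairs, heterogeneous PCR2 efficiency; bias at depth 3000,
  500 repeats.  Few PCR1 cycles keep the uncorrected arm from averaging
  efficiency over many amplicons per molecule, which would mask the bias
  the barcode information removes.  Subsampling uses the multivariate
  hypergeometric (without replacement), common random numbers across
  methods within a sample.
* **Titration**: clonal fractions {0, 0.1, 0.25, 0.5, 0.75, 1.0} of a 200-
  molecule pool, 4000 read pairs each; a consensus molecule is classified
  clonal when its junction region matches the clonal junction within 2
  mismatches at equal length (error-tolerant: residual singleton errors
  elsewhere must not unassign a molecule); OLS fit of observed vs input.
* **Loop rate**: grid q ∈ {0, 0.005, 0.02} × cycles ∈ {5, 10, 20}, 20
  seeds, 200 000 templates, p = 10⁻³, 5000 reads; molecule-level link
  tables (no sequence assembly) isolate the statistic from read-processing
  effects.
* **Diversity deflation**: 8 samples of 6 equal clones × 10 molecules,
  8000 read pairs, e = 0.003, per-molecule SHM 0.004; clones ≥ 5% of each
  repertoire compared (the designed clones sit near 17%; sub-percent
  error-fragment clones give noise-level matched depths).
* **SHM deflation**: true SHM 0, e = 0.005, 10 seeds, 50 molecules, 6000
  read pairs each; proportion of molecules within 1 mismatch of germline V
  compared between pipelines.

## Known limitations

Substitution-only errors (no indel-tolerant merging or alignment); exact
UMI grouping (no directional UMI-network collapsing); no chimera
detection; the saturating-curve fit of loop-rate versus cycle count is out
of scope (no defined functional form); germline annotation is a light
edit-distance aligner against a user-supplied or synthetic reference, not
an IMGT-grade annotator.
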