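# Methods

This note documents the models behind `mebs`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical conventions that matter for reproducing results.

## Coordinate and format conventions

All internal coordinates are 0-based half-open; SAM (1-based) and GFF3
(1-based inclusive) are converted at the I/O boundary only.  Sequences are
restricted to {A, C, G, T, N}; other IUPAC codes are rejected at parse time
so downstream code never branches on ambiguity codes.  Directional
bisulfite alignments carry the Bismark-style `XG:Z:CT` / `XG:Z:GA` tag for
the original-top / original-bottom conversion strand; a read is treated as
non-unique when MAPQ is 0 or an `XS` tag is present (retained by the
parser, skipped and counted by the caller).

## Consensus reference

The consensus rule is a plain majority vote over read observations at each
pileup column.  Coverage below `min_cov` (default 4, counting
deletion-supporting reads as observations of the position) yields `N`.
Above it, bases and deletion compete in one vote; the reference base is
never privileged — four reads supporting an alternative beat a reference
with no read support.  Exact ties are broken uniformly at random by a
single seeded generator whose draws are consumed in scaffold/position
order, so a given seed fixes the whole consensus, including tie positions.
Insertions are a separate junction vote: the most frequent inserted string
is emitted after a position iff its support exceeds the reads that do not
insert there (ties again random).  Positions covered only by `N` base
calls stay `N`.

The builder emits a per-position liftover map (source position → target
position or deleted).  Regions are lifted by mapping their start to the
first retained position at or after it and their end past the last
retained position before it; regions falling entirely into deleted
segments are dropped and reported.  The map is strictly increasing on
retained positions, which the tests check.

Coverage metrics: average coverage is `reads × read-length / genome-size`;
breadth is the percentage of positions with depth ≥ 1 and mean depth is
taken over covered positions only (reported as 0 for an uncovered track).
Coverage tracks are stored as dense per-position integer arrays — simple
and fast at the scales this package targets.

## Read filter

A read is dropped when (i) it contains the adapter as an exact substring,
(ii) strictly more than 10% of its bases are N, or (iii) strictly more
than 10% of its bases fall below Q20.  Rules run in that order and the
first failure is the recorded reason, so category counts plus kept reads
always equal the input.  Reads sitting exactly at a 10% boundary are kept.
Adapter-containing reads are dropped whole rather than trimmed: trimming
behaviour is not part of the filter definition, and exact-substring
matching is the minimal reproducible choice (mismatch-tolerant trimming is
cutadapt territory and out of scope).  Paired filtering defaults to
drop-pair (both mates must pass); a keep-orphans mode is provided because
either convention is defensible for a paired-end mapper.

## Methylation caller

Directional libraries sequence only the two converted original strands, so
original-top reads inform top-strand cytosines (read C methylated, read T
converted) and original-bottom reads inform bottom-strand cytosines, which
appear at reference G positions in top-strand orientation (read G
methylated, read A converted).  Read bases other than the informative pair
(A/G at a top-strand C) are sequencing or mapping errors and are ignored
rather than counted as unmethylated — conversion evidence requires a C or
T.  Where mates of one fragment overlap, each position is counted once;
the first-seen mate wins on disagreement (configurable in principle; the
choice is arbitrary and affects only discordant overlap bases).  PCR
duplicates are not removed.

Context is classified from the reference on the cytosine's own strand: the
next base G → CG, else the base after next G → CHG, else CHH; an N in the
window or a window off the scaffold end gives `unknown`, which is emitted
but excluded from summaries.  Summaries pool read-level observations:
`%mC(context) = 100 × Σmeth / Σ(meth+unmeth)` per context, plus the same
pooled percentage over all contexts.  Conversion efficiency is the pooled
unconverted-free fraction at CHG+CHH sites, which assumes non-CG cytosines
are biologically unmethylated; true non-CG methylation therefore deflates
the estimate slightly, exactly as it does in real libraries.  Capture
specificity is the percentage of fragments observing at least one cytosine
in which every cytosine read converted — an upper-level diagnostic of how
much unmethylated DNA the MBD capture pulled down.

## CpG islands and promoters

Islands satisfy GC ≥ 55%, observed/expected CpG ≥ 0.65 with
`ObsExp = N_CpG × L / (N_C × N_G)` (defined 0 when either count is zero),
and length ≥ 500 bp, evaluated with a 200 bp window — the published
defaults of the classic sliding-window annotator.  The implementation is
the exhaustive form of that procedure: a vectorized 1 bp scan marks every
qualifying window ("seed"); seeds whose windows chain with gaps below one
window form a candidate cluster (the sub-window merge rule); each cluster
is reduced to its longest sub-span of at least 500 bp that still meets
both criteria over its full span, ties going to the leftmost span.  The
jump-based extension heuristic used by some implementations can strand a
qualifying island when a single extension window fails; the cluster scan
cannot, and its boundaries agree with jump-based output to within one
window, which is also the tolerance the tests use.  Windows containing N
never seed, so islands cannot bridge long runs of undetermined sequence —
important on an N-rich consensus genome.  Island metrics over a full span
count N in the length but not as C or G.

Promoters are the 2 kb upstream of a stranded TSS: `[tss−2000, tss)` on
plus, the mirror `[tss+1, tss+2001)` on minus, clipped at scaffold bounds.
CGI–promoter distance is the gap between closest interval ends (0 on any
≥1 bp overlap), histogrammed in 1 kb bins with an open ≥10 kb tail.

## Region statistics

Region methylation pools observations (Σmeth over Σall inside the region,
both strands), matching the summation convention above; an unweighted mean
of site ratios is available, and the difference between the two is itself
informative (pooling weights deep sites more).  Level histograms assign a
value on a shared edge to the lower bin; two presets reflect the bimodal
methylome view (0–4 / 4–75 / 75–100) and the track-rendering view
(0–40 / 40–60 / 60–100).  Replicate correlation is a plain Pearson r over
positions reaching a depth floor in both libraries (default 1), in depth
or ratio mode; fewer than two shared sites is an error and zero variance
returns NaN.  The shifted-position rule declares two placements consistent
when `|posA − posB| ≤ 0.10 × posA`; the window deliberately scales with
the first coordinate, so the rule is asymmetric and degenerates to exact
matching at position 0 — implemented literally and flagged here.

## Simulator

The generator defines the study conditions for every closed-loop test.

* **Genome** — i.i.d. background at 40% GC, default 200 kb over two
  scaffolds; 10 planted CpG islands (CpG dinucleotides emitted at rate
  0.20 inside 60%-GC island sequence, ~800 bp) and 20 gene models with
  stranded TSS and exons, all with recorded truth coordinates.
* **Methylome** — the genome is tiled into 2–8 kb domains, each
  hypermethylated with probability 0.5; planted CGIs override their domain
  (hyper with probability 0.5).  CpG sites draw Bernoulli(0.90) in hyper
  and Bernoulli(0.02) in hypo regions, realized symmetrically on both
  strands of a CpG as maintenance methylation makes them; CHG and CHH
  sites draw 0.003 and 0.004 per strand everywhere.  Together with a
  conversion-failure rate of 0.005 these defaults reproduce the measured
  regime of MBD-captured mammalian testis libraries: ~0.8% apparent CHG
  and ~0.9% apparent CHH methylation and ~99% estimated conversion
  efficiency.  (Apparent non-CG methylation is true methylation plus
  conversion failure; only their sum is identifiable from context ratios,
  so the split is a modelling choice.)
* **Capture** — MBD2 binds methylated CpG, so capture probability is a
  logistic function of the fragment's methylated-CpG count,
  `σ(m) = 1/(1+exp(−1.2(m−1)))`, giving single-mC fragments substantial
  capture probability (σ(1) = 0.5).  A configurable fraction (default
  0.0126) of captured fragments is drawn instead from realized
  fully-unmethylated molecules — the capture's unspecific contamination.
  Fragments methylated only at non-CG sites are not captured; this
  simplification keeps the contamination parameter interpretable as the
  expected unmethylated share of the library.  Note the read-level
  specificity estimate sits slightly below the molecular contamination
  fraction because a conversion failure makes a contaminant fragment look
  methylated; the truth tables quantify this exactly.
* **Reads** — sequenced fragment lengths are truncated-normal(134, 30) on
  [100, 200] bp, reflecting a size-selected enrichment library; 90 bp
  paired reads from the converted original top or bottom strand (50/50),
  uniform substitution errors at 0.001 per base, no indel errors (keeps
  truth CIGARs simple).  Unmethylated Cs convert with probability 0.995.
  Truth outputs record every fragment's realized methylation, capture
  branch and per-read placement.
* **Relative genome** — SNVs at 1% and 1–3 bp indels at 0.1% per position,
  non-overlapping, with a variant table; the pileup against the source is
  synthesized directly from the exact source↔mutant alignment at a uniform
  configured depth (default 10).  Literal read tiling would only add depth
  ramps at scaffold ends; uniform depth keeps the self-consensus identity
  property exact and the recovery measurement clean.

Everything flows from one seeded numpy generator: identical configuration
and seed give byte-identical FASTQ/SAM/TSV outputs, which the end-to-end
determinism test checks at the byte level.

What the simulator does **not** emulate: quality-score error profiles and
position-dependent error rates, PCR duplicates and chimeras, mappability
and mapping errors (truth alignments are exact), antibody-based (MeDIP)
enrichment, and fine-grained MBD binding affinity beyond the logistic
count model.  Passing tests therefore demonstrate correctness of the
analysis logic under a faithful but idealized data model, not robustness
to every artefact of real libraries.

## Problem sizes used in the checks

The acceptance machinery runs at desk scale by design: 1,000 random
pileup columns plus 10,000 tie draws for the consensus oracle; a 1 Mb
single-scaffold genome for mutation recovery; 1,000 read pairs with
50/30/20 planted failures for the filter; 20,000–50,000 captured fragments
on the 200 kb default genome for methylome recovery; 200 random ≤5 kb
sequences plus 10 planted 800 bp islands in 100 kb for the island oracle;
≥500 randomized small instances per statistics oracle.  These sizes give
binomial standard errors comfortably inside the asserted tolerances while
keeping the full suite in the minutes range.

## Known limitations

* The consensus is quality-blind (no BAQ) and does not realign around
  indels; multi-allelic insertion strings compete as exact strings.
* The caller offers no differential-methylation testing; it produces
  calls, summaries and tracks.
* CGI detection on genomes with megabase-scale unbroken CpG-rich runs
  falls back to a quadratic trim search when a merged cluster fails the
  full-span criteria; on biological inputs the fast path (whole cluster
  qualifies) dominates.
* `capture_specificity` conflates capture contamination with fragments
  whose methylated sites were all unobserved; at the default fragment and
  read lengths the latter term is ~0.1%.
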