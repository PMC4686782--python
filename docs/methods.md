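# Methods

## Coordinate model

All analysis runs in CDS nucleotide coordinates, 1-based inclusive, in
transcription direction. Residue `i` occupies nucleotides `3i − 2 .. 3i`; a
*junction slot* `k` is the position between nucleotides `k` and `k + 1`
(`1 ≤ k ≤ L − 1`), and a gene with exon CDS lengths `l_1..l_n` has its
internal junctions at the partial sums `k_j = Σ_{i≤j} l_i`, `j < n`. The
phase of a junction is `k mod 3`; exon `j`'s 5′ phase is the previous
junction's phase (0 for the first exon) and its 3′ phase is `k_j mod 3`; a
complete CDS (`L mod 3 = 0`) always closes in phase 0. Genes with
`L mod 3 ≠ 0` are flagged incomplete, excluded from every analysis and
logged — never silently truncated. Minus-strand genes are reordered into
transcription direction at load time (GTF is 1-based inclusive, BED12
0-based half-open; conversions happen only at the I/O boundary), so all
downstream logic is strand-free. Exon indices are 0-based in code and
1-based in all report tables.

A site codon is *boundary-associated* when an internal junction falls at
slot `3i − 3` (phase 0, 5′ flank), `3i − 2` (phase 1, split), `3i − 1`
(phase 2, split) or `3i` (phase 0, 3′ flank). A phase-0 junction therefore
flanks two codons and is counted once per residue — a deliberate
per-residue convention, so one junction between two site residues
contributes two events.

## Classification and discontinuity

An exon is EC when it intersects the codon span of at least one residue of
at least one site (union over sites; overlapping sites are kept distinct).
A residue whose codon straddles a junction marks both flanking exons EC:
each then codes part of that residue. The site area runs from the first to
the last site residue; its observed discontinuity is the number of internal
junctions in slot range `[3·first − 2, 3·last − 1]`, and the number of
exons spanning the area is that count plus one. Discontinuity is computed
per site, not per protein. Terminal (first/last) exons are excluded only in
the phase stage; the length and discontinuity stages keep them (a flag can
drop them everywhere).

## Null models

**Randomized boundaries.** For a gene with `m` junctions, each replicate
redraws `m` slots uniformly without replacement from `{1..L − 1}` (default
10 replicates per gene). Sampling is in CDS space because the counted
statistic lives there; intron lengths are irrelevant. The replicate mean of
borders inside an area with `s` slots converges to the hypergeometric value
`m·s/(L − 1)`. No minimum exon length is enforced in the null.

**Site permutation.** Each replicate redraws a site's residue positions
uniformly without replacement over the protein (default 1,000 replicates;
an option restricts the eligible positions to residues outside terminal
exons). Boundary-phase events of the permuted residues are pooled over the
sample into per-replicate phase fractions; replicates with zero events are
dropped and logged. Under this null each phase-0 junction contributes
events at rate 2·k/P per site of k residues on a protein of length P, and
each phase-1/2 junction at rate k/P, giving the analytic expectation the
tests check against. With the default junction-phase mix (0.47, 0.30,
0.23) the expected phase-0 fraction is 2·0.47/(2·0.47 + 0.53) ≈ 0.64.

Reproducibility: every consumer takes one top-level seed; per-gene
substreams are derived from `(seed, CRC32(gene_id))`, so results do not
depend on processing order and repeated runs are byte-identical.

## Statistical tests

Pearson χ² without continuity correction (a zero marginal is an error, not
a 0-statistic). The two-sample length comparison bins both samples on a
shared grid (default 3 nt) and merges adjacent bins right-to-left until
every expected count reaches 5; df = bins − 1; the binning is reported in
the result metadata. Mann–Whitney U and the paired Wilcoxon signed-rank use
exact p-values for small untied samples and tie-corrected normal
approximations otherwise (the Wilcoxon Z is reported alongside; zero
differences are dropped and logged). All p-values are two-sided. Bonferroni
correction is applied within the phase stage across its family of χ² tests
— the only family-wise correction the pipeline performs; the per-gene
Wilcoxon there pairs, within each gene having both classes, the fraction of
5′-phase-0 exons among EC against ENC, which is one reasonable reading of
an ambiguous pairing unit and is declared in the report metadata.

## Discontinuity inference: two statistics

The discontinuity stage reports two comparisons of observed vs resampled
border counts:

* an **unpaired Mann–Whitney** on the pooled per-site observed counts
  against the pooled replicate counts — the comparison conventionally
  reported for this analysis; and
* a **paired sign test** of each site's observed count against one
  independent null draw for the same area (the first replicate), with ties
  dropped, tested against Binomial(n, ½).

The distinction matters. Observed and resampled counts for one site share
the same area, and areas vary enormously across sites, so the two pooled
samples are strongly positively dependent; the 10 replicates per site are
also mutually clustered. Both effects violate the unpaired Mann–Whitney's
independence assumptions: in simulation under an exactly true null it
essentially never rejects at α = 0.05, while under realistic exon-length
processes at a few hundred genes it rejects far too often (see below). The
paired sign test conditions on each site's area, so under within-pair
exchangeability it is exactly calibrated regardless of cross-site
heterogeneity; it is the stage's inferentially reliable statistic, at the
cost of using one replicate and discarding count magnitudes.

A second, scientific caveat: the uniform-slot null is only exactly true
when junction positions are themselves uniform. Realistic exon-length
distributions (log-normal here) deplete junctions near the CDS ends and
space them more regularly than uniform; uniformly placed site areas are
also interior-biased, so they capture ~10% more real junctions (at ~6
exons per gene) than the null's mean predicts. The bias points toward
"more discontinuous than expected", i.e. it is conservative with respect
to the clustering signal this pipeline is designed to detect. Calibration
is therefore verified on generator structures whose junctions are drawn as
uniform slots (`exon_length_distribution: {kind: uniform_junctions}`),
the condition under which the null model holds by construction.

## Synthetic data

The generator emulates a vertebrate-like annotated sample: exon count per
gene 2 + Poisson(8) (≈10 coding exons), exon lengths log-normal with
median 120 nt and σ = 0.6 (mean ≈ 144 nt), junction phases (0.47, 0.30,
0.23), 1 + Poisson(2) sites per gene, 2 + Poisson(2) residues per site,
and clustered site placement in a 20-residue window inside one exon when
one fits. Junction phases are controlled by nudging each internal exon
length by 0–2 nt after sampling, so phase and length distributions are set
nearly independently; the final exon is padded to a codon multiple.
Genomic coordinates are fabricated on one synthetic chromosome with fixed
200-nt introns and alternating strands — only the CDS structure matters
downstream. Protein sequences are not generated (no analysis consumes
amino-acid identities); poly-X FASTA emission exists for format checks.

What the generator does *not* emulate: homology families and redundancy
(inputs are non-redundant by construction; a per-group representative
picker is provided for callers who bring their own grouping), overlapping
chains/structures per protein, alternative isoforms, UTRs, sequence-level
realism, and any coupling between site placement and phase. Passing tests
therefore demonstrate the correctness and calibration of the machinery on
data satisfying the stated generating assumptions, not the real-data
prevalence of any effect. In strict clustered mode every boundary-associated
site codon is necessarily a phase-0 flank event (clustered residues are
fully coded by one exon), so the observed phase-0 fraction is 1 by
construction there; uniform mode exercises the full event mix.

## Problem sizes and numerical choices

Default replicate counts follow the analysis conventions (10 boundary
replicates, 1,000 permutations), and are configurable. The test suite uses
larger replicate counts where Monte-Carlo precision is asserted (up to
100,000 replicates for the closed-form null mean) and 1,000 simulated
datasets of 100 genes for the calibration property; the full pipeline on
the default 1,000-gene configuration completes in seconds on one CPU.
Without-replacement draws use rejection sampling when the draw is small
relative to the pool and full per-row permutation otherwise; both paths are
deterministic given the seed. Degenerate inputs fail loudly with typed
errors: empty exon lists, incomplete CDS, residues beyond the protein,
all-zero difference pairings, zero-marginal tables, single-bin histograms.

## Known limitations

* The boundary-resampling null's mis-centring under realistic exon-length
  processes (above) means the Mann-Whitney discontinuity p-values should be
  read qualitatively; the sign test carries the calibrated inference.
* The per-residue counting of shared phase-0 junctions double-counts a
  junction lying between two adjacent site residues, which slightly weights
  phase 0 in the census; observed and permutation-expected censuses use the
  identical convention, so their comparison is internally consistent.
* One transcript per gene is assumed; multi-isoform GTFs take the longest
  CDS (or error on request).
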