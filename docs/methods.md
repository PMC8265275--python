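# Methods

`cernax` implements a multi-stage discovery procedure for competing
endogenous RNA (ceRNA) axes — lncRNA → miRNA → mRNA triples in which a
lncRNA both cis-regulates a neighbouring gene and sponges a miRNA that
targets the same gene — from a two-group (low-fat L vs high-fat H, six
replicates each) transcript-level RNA-seq design.  This note records the
model behind each stage, the tunable parameters and their defaults, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Biotype classification

Novel transcripts are labelled by an ensemble vote over four
coding-potential assessments: a CPC-like score (threshold 0), a
txCdsPredict-like score (threshold 500), a CNC-like score (threshold 0),
and Pfam membership.  Each assessment below its threshold (or absent
from Pfam) casts one noncoding vote; three or more of the four votes in
agreement decide the call, and a 2–2 split is `ambiguous` and excluded
from both downstream sets.  Threshold comparisons are strict (`<`), so a
score exactly at 0 or 500 votes coding.  The enumeration of all 16 vote
patterns gives 5 lncRNA, 5 mRNA, and 6 ambiguous outcomes.

When external tool scores are unavailable, a built-in scorer produces
values on the same threshold scales: the txCdsPredict-like score is the
longest forward-strand ORF length in nucleotides (start codon through
stop, all three frames), the CPC-like score is ORF coverage − 0.3, and
the CNC-like score is the Fickett TESTCODE statistic − 0.95 (0.95 being
TESTCODE's classical coding cut-off), with the Pfam vote always
noncoding.  The TESTCODE statistic uses the classical position-asymmetry
and composition lookup tables.  An externally supplied score table takes
precedence over the built-in scorer.  Only the presented strand is
scanned: transcripts are already stranded.

Small-RNA reads with database hits are categorised by fixed priority
miRBase > piRNAbank > snoRNA > Rfam.

## Differential expression

The test statistic is a pooled binomial proportion z-test: replicate
counts are summed within group, and the H-group share k_H/(k_H+k_L) is
tested against the null share N_H/(N_H+N_L) given by the group library
totals, with the null-variance (score) standard error.  This is the
closest defined statistic to the random-sampling model used by
two-library count DE tools; negative-binomial GLMs and dispersion
shrinkage are out of scope.  Features with no counts get p = 1.

Fold changes are computed separately from the test: each sample is
scaled to counts per million, group means are averaged over replicates,
a pseudo-expression of 0.1 normalized units replaces a zero group mean
(only for the ratio, never for the test), and log2FC = log2(mean_H /
mean_L).  Multiple testing uses Benjamini–Hochberg step-up; the gate is
|FC| ≥ 2 and Q ≤ 0.001, both comparisons inclusive.  Gene-level testing
sums transcript counts by gene before testing.

When reproducing published fold changes from printed group expression
values, an unknown between-library scale constant is absorbed by
`fit_scale_from_reference`: each reference row implies a constant
c_i = 2^log2FC / (H/L), and the median over rows calibrates
log2FC = log2(c · H/L).  On the bundled reference tables this recovers
c ≈ 1.094 for the long-RNA libraries and c ≈ 1.368 for the small-RNA
libraries, after which every held-out row's printed value is reproduced
to well within 0.01.

FPKM abundance summaries bin features per sample at FPKM ≤ 1,
1 < FPKM < 10, and FPKM ≥ 10.

## Cis target assignment

A lncRNA is positionally paired with an mRNA when it lies within 10 kb
upstream or 20 kb downstream of it.  Choices the window rule needs:

- Upstream/downstream is defined relative to the mRNA's strand (the
  promoter-side meaning of "upstream of the adjacent coding gene").
- Distance is the nearest-boundary gap between transcript spans (not
  TSS-to-TSS), and window boundaries are inclusive: a gap of exactly
  10,000 nt upstream still counts.
- Intersecting spans are `overlap` on the same strand and
  `anti-overlap` on opposite strands, at distance 0.
- Every lncRNA is paired with *all* mRNAs within the window, not only
  the single nearest one.
- Transcript spans (not gene spans) are the default interval unit.

A positional pair becomes a target pair only when Pearson *and*
Spearman correlations of the two FPKM profiles across all 12 samples
(groups pooled) are ≥ 0.6.  Correlations on counts rather than FPKM are
a caller option; FPKM is the default because abundance comparisons
across transcripts of different lengths require it.

The trans rule — for lncRNA–mRNA pairs outside the window — slides
40-nt windows at 20-nt stride over both sequences and calls a trans
candidate when the minimum windowed duplex MFE falls below
−30 kcal/mol.  It is exposed as a library operation; the network stages
operate on cis pairs, which are what the axis logic requires.

## miRNA target scanning

Candidate sites require a seed match: miRNA positions 2–8 all paired
antiparallel with at most one G:U wobble and no mismatch.  This
definition is the narrowest one that detects the experimentally
validated heptamer class (a 7mer with a single position-2 G:U) while
rejecting its printed mutant.  Seed hits anchor 30-nt windows on a 5-nt
stride grid, positioned so the window extends 5′ of the seed on the
target (where 3′-supplementary miRNA pairing falls).

Each candidate window is scored twice:

- **Alignment score** (miRanda-style): best antiparallel local
  alignment under Watson–Crick +5, G:U +2, mismatch −3, gap open −9,
  gap extend −4, with all contributions at miRNA positions 2–8
  weighted ×4.  A perfectly complemented 22-mer scores
  7·5·4 + 15·5 = 215.
- **Duplex MFE** (RNAhybrid-style): minimum free energy over
  intermolecular secondary structures with no intramolecular pairs and
  no pseudoknots, by dynamic programming over "last pair" states.
  Stack energies come from a hard-coded nearest-neighbour table
  collapsed to the unordered pair-class level (GC-type −3.3, mixed
  GC/AU −2.4, AU-type −1.1, wobble-containing −2.1/−1.4/−0.5 kcal/mol;
  magnitudes follow published Turner-style scales), with bulge
  penalties 3.8/2.8/3.2 (1–3 nt) and internal-loop penalties
  1.5/2.2/2.7 (2–4 nt total).  Internal loops are capped at 4 nt and
  bulges at 3 nt.  The energy of zero is returned when no stabilizing
  structure exists.  This is a deliberate simplification: bit-exact
  reproduction of external tools is a non-goal, and the collapsed table
  makes the energy symmetric in its two strands by construction.

A site passes when alignment score, energy of the aligned duplex, and
unconstrained duplex MFE all clear their gates.  The published gates
(score ≥ 300, alignment MFE ≤ −45 kcal/mol, hybridization MFE ≤ −30
kcal/mol) are on external tool scales; the score gate is rescaled onto
the built-in scale by the ratio of perfect-22-mer scores
(300 × 215/460 ≈ 140.2), while the energy gates apply unchanged.
Externally supplied score tables bypass the calibration.  Gates apply
per site; a gene passes if any site passes.  Overlapping passing sites
merge, keeping the best-scoring representative.

## Networks and axis nomination

Cis pairs whose lncRNA and gene are both significantly DE split into an
up–up and a down–down network; discordant pairs join neither.  Passing
miRNA sites on DE genes collapse to one signed edge per (miRNA, gene):
negative when the two move in opposite directions, positive otherwise.
Genes targeted in both kinds of network are candidate ceRNA hubs.  For
each such gene, every (cis-paired lncRNA) × (targeting miRNA)
combination where the lncRNA also carries a passing site for that miRNA
(the sponge interaction, gated identically to mRNA sites) becomes an
axis candidate.  A candidate is direction-consistent when the lncRNA
and gene share a direction and the miRNA opposes it; inconsistent
candidates are reported with `consistent = false` rather than dropped.
Candidates are ranked by (consistent, summed |log2FC| of the three
members); the ranking is a presentation choice, not an inference.

## Synthetic data

The generator emulates the assumed study conditions: 200 genes, 50
lncRNAs, 30 miRNAs, 6 samples per group, negative-binomial counts
(dispersion 0.05) around lognormal base means with median 500,
differential features shifted by 2^±2, and a 15% background DE
fraction.  Per-sample library depths vary lognormally (σ = 0.15) and
every feature carries a lognormal biological factor (σ = 0.3), so the
DE test is exercised under realistic overdispersion.

Planted structure: each axis consists of an upregulated gene, a
co-regulated lncRNA placed within the upstream window whose counts ride
the gene's realized per-sample counts times lognormal noise (σ = 0.2) —
this is what produces the above-gate co-expression — and a
downregulated miRNA whose exact 22-nt antiparallel complement is
spliced into both the gene's 3′UTR and the lncRNA.  miRNA base
composition is drawn GC-rich enough (50–70%) that planted full-site
duplexes clear the energy gates.  Decoys exercise every gate: shared
genes whose lncRNA lacks the sponge site, near-window lncRNAs at a gap
of exactly window + 1, low-correlation neighbours with independent
expression, and sponge sites with scrambled (seed-destroyed) sequence.
Coding sequences are built from a positionally biased codon pool and
verified against the built-in classifier at generation time, as are
noncoding sequences; generation retries until the planted property
holds, so the truth set is guaranteed by construction.

All randomness flows from one seed through spawned child generators;
identical parameters and seed give byte-identical output files.

What the benchmark does *not* show: real annotation complexity
(multi-exon transcripts, overlapping genes, transcript/gene many-to-one
maps), realistic codon usage or conservation signal, miRNA site
context effects, or library-preparation biases.  Passing tests
demonstrate that the gates, scores and intersections behave as
specified on data satisfying their assumptions, not that the procedure
recovers true biology from any particular real dataset; the published
pair and network counts depend on the original sequencing data and are
explicitly not reproduction targets.

## Problem sizes and determinism

The bundled verification runs use the default simulation size (280
features, 12 samples), 20 replicates for DE operating characteristics,
10 null replicates for type-I control, and enumeration oracles on
sequences ≤ 10 nt — sizes at which the exhaustive references are exact
and the full suite stays interactive.  Fold-change reproduction from
the reference tables is deterministic; all stochastic tests fix their
seeds.  Ties in BH adjustment use stable sorting; correlation ties get
average ranks; the axis ranking breaks ties lexicographically.

## Known limitations

- The pooled proportion test is anti-conservative under strong
  overdispersion if used without the fold-change gate; the published
  gate pair (|FC| ≥ 2 *and* Q ≤ 0.001) is what controls false calls,
  and the pipeline always applies both.
- The duplex energy model ignores dangling ends, terminal mismatches,
  coaxial stacking and loop-sequence effects; absolute energies are
  approximate even though the gate logic matches the external-tool
  thresholds.
- cis windows use transcript spans; promoter-centric definitions
  (TSS ± window) would shift borderline pairs.
- The built-in coding scorer is a stand-in on the external tools'
  scales, not a reimplementation of their models.
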