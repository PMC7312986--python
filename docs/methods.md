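# Methods

## Intron catalog

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on read, and BED output keeps half-open semantics. Every
inter-exon gap of every multi-exon transcript yields one intron; sequences
are stored in transcript orientation (minus-strand introns are
reverse-complemented), so the donor site is always the 5′ end of the stored
string and all PWMs are applied in one orientation. Ranks run 1..n along the
transcript 5′→3′. When several transcripts of a gene share a genomic intron,
classification operates on the gene-level deduplicated set while rank-based
adjacency distances consider all rank assignments within the gene and take
the minimum; whether a published analysis would deduplicate the same way is
not documented anywhere we know of, so the choice is exposed as
`deduplicate_catalog` rather than hidden. Overlapping exons within one
transcript are rejected rather than repaired; trans-splicing and implicit
UTR inference are out of scope.

## Splice-site models and classification

PWMs are per-position log2-odds against a background composition
(uniform by default; a genome-derived mononucleotide vector may be
supplied):

    logodds[i][b] = log2( (count[i][b] + λ·q_b) / (n + λ) / q_b ),  λ = 1

`N` in training data contributes 0.25 to every base; `N` in a scored window
contributes 0 bits. Window geometry: donor = intronic +1..+12 (12 nt),
U12 branch = 9 nt searched wholly inside offsets −40..−8 from the 3′ end
(feasible window starts −40..−16, i.e. the motif sits 8–40 nt upstream of
the acceptor, the canonical U12 branch-point zone), U2 acceptor = intronic
−14..−1 (14 nt, polypyrimidine tract + NYAG). Branch-site ties break toward
the 3′ end. The U2 model scores donor + acceptor only; scoring a U2 branch
site adds nothing discriminative at these widths because the U2 branch
motif is weak.

An intron is assigned U12-\<subtype\> when all of:

1. best U12 composite (donor + best branch) − U2 composite (donor +
   acceptor) > `margin_threshold` (default 0 bits, the equal-priors Bayes
   point, exposed in the API and CLI);
2. the winning subtype's branch score, and its donor score *excluding the
   two terminal-dinucleotide columns*, are each positive;
3. the terminal dinucleotides match the winning subtype (AT…AC or GT…AG).

Condition 2 exists because the margin alone misbehaves on sequences that
resemble *neither* model: with both composites negative, the sign of their
difference is noise, and canonical termini (worth ~4 bits in the donor
columns) would otherwise tip such sequences into U12 calls. Requiring each
U12 site to carry positive evidence of its own — beyond the columns already
spent on the termini gate — drops the false-call rate on motif-free
sequence to ~10⁻³–10⁻⁵ while costing ~2% sensitivity on model-sampled U12
introns. Subtype ties prefer the termini-matching subtype, then GT–AG (the
more common subtype in mammals). Sequences over 50% `N` are called U2 with
a warning; introns too short to host the windows cannot be called U12.

The shipped PWMs are built from small hand-written training alignments
around the canonical mammalian consensi (GTATCCTT/ATATCCTT donors, the
TTCCTTAAC branch with its adenosine at position 8, GTAAGT, and a
polypyrimidine+NYAG acceptor). They are synthetic fixtures for testing and
demonstration, not matrices trained on any intron database; real analyses
should supply their own alignments via `build_pwm`.

## PSI and differential calls

PSI is the plain ratio `100·I/(I+E)` — deliberately free of the internal
corrections quantification tools layer on top, so the contract is exactly
testable. Group summaries are unweighted means over replicates (not pooled
counts), ΔPSI = mean(MU) − mean(WT), and calls require strict
`|ΔPSI| > threshold` (default 10 percentage points) plus a coverage filter
of ≥ `min_reads` (default 10) in *every* sample. A 0/0 sample leaves PSI
undefined and the event reported `low_coverage` without raising. Class
proportions are reported per direction; no significance test is attached to
ΔPSI itself.

## Enrichment layer

U12 enrichment among called IR events uses the exact binomial upper tail —
expected counts at a 0.04% null are far too small for χ². The default null
(0.0004) is the genome-wide U12 intron share; on synthetic catalogs, where
the generator deliberately inflates the U12 fraction, the null must be the
generated catalog's own fraction. Proportion comparisons use the pooled
two-proportion z-test, two-sided (the direction of published comparisons is
known, but two-sided is the conservative default); degenerate pooled
proportions (0 or 1) return p = 1 with a flag. Per-event-class enrichment
across the five classes is Benjamini–Hochberg corrected. DE consensus
requires adjusted p < α (default 0.01) in both tables *and* concordant
fold-change sign; a gene absent from one table counts as not significant
there.

## Cross genetics

Alleles segregate Mendelian-exactly with `fractions.Fraction` probabilities:
the egg carries one *Zrsr1* allele and one X; the sperm carries one *Zrsr1*
allele and X or Y (sex ratio fixed 1:1). Expression rules are modelled
all-or-none: *Zrsr1* maternal imprinting is complete (paternal allele
expressed), and imprinted XCI silences the paternal *Zrsr2* completely
before the blastocyst (maternal allele expressed; males are hemizygous for
the maternal X anyway). Viability = paternal *Zrsr1* WT OR maternal *Zrsr2*
WT, evaluated at the early-embryo stage only — the observed ~20% of double
mutants that straggle to morula before failing, and post-transfer failures
of rescued embryos, are outside the viability rule and can instead be probed
with the litter consistency test. That test is exact: two categories use the
two-sided binomial, more use full multinomial enumeration (point
probabilities ≤ that of the observation, with a 1e−9 relative tie
tolerance), feasible for litter-scale n; an observation in a
zero-probability category gives p = 0. Leaky imprinting was deliberately not
parameterised: the all-or-none litter outcomes give such a parameter no
identifiable signal.

## Synthetic generator

`SimConfig` defaults define the study conditions: 500 genes, 3–6 introns
each (70–150 nt introns, 60–120 nt exons — long enough for all scoring
windows, small enough that a full catalog builds in ~1 s), U12 gene fraction
0.03 with exactly one U12 intron per U12 gene (AT–AC share 0.3), read depth
100, 3 replicates per group, baseline IR PSI 5, 20 planted retention effects
of +25 ΔPSI landing on U12 introns with probability 0.5. The 0.03 fraction
is ~8× the genomic share of U12-bearing genes, a deliberate inflation that
keeps desk-scale catalogs non-degenerate (~15 U12 introns); consequently
enrichment nulls in tests come from the generated catalog, never the
literature constant. n_planted = 20 keeps the expected number of U12-planted
events (10) below the available U12 introns so the bias parameter is
actually realised. Splice-site blocks are sampled position-wise from the
fixture PWMs of the true class, branch blocks at a uniform offset inside the
search zone, interiors uniform random, termini forced canonical. Inclusion
reads are Binomial(depth, PSI/100) — the simplest model consistent with the
PSI contract — with optional beta-binomial overdispersion for robustness
checks; planted effects increase retention in the mutant (the dominant
observed direction), sign configurable. Cross offspring are i.i.d. draws
from the enumerated outcome distribution with arrest recorded, and CT tables
invert the 2^−ΔΔCT formula with Gaussian cycle noise. All stages draw from
`numpy` Generators seeded as `[seed, stream]`, so identical configs give
byte-identical outputs and stages are mutually independent.

What the generator does *not* emulate: overdispersion beyond the optional
beta-binomial, mapping/positional biases, annotation errors, shared-junction
ambiguity between neighbouring events, multi-transcript genes, and realistic
intron length distributions. Passing recovery benchmarks therefore show the
pipeline is correct under its own model assumptions, not that those
assumptions hold for any particular real dataset.

## qPCR fold changes

ΔCT = CT_target − CT_reference after averaging technical replicates at the
CT level; the calibrator is the sample with the highest ΔCT (lowest
expression), so folds = 2^−ΔΔCT ≥ 1 with the calibrator at exactly 1.
Amplification-efficiency correction is not modelled (efficiencies are
assumed ≈ 1). The "expressed" threshold for expressed-fraction summaries
defaults to value > 0 in normalised units and is configurable, since any
fixed cutoff is arbitrary without knowing the normalisation.

## Benchmark problem sizes

The recovery benchmarks run at: one 500-gene catalog (~2,250 introns) for
classifier sensitivity/specificity; 25 seeded count tables (500 planted
events total) for ΔPSI direction recovery; 100 seeded pipeline runs each for
the biased and unbiased enrichment rejection rates. These sizes give
denominators of several hundred per rate while keeping the whole
reproduction script under a minute on one CPU.
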