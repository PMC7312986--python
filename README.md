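# u12retain

Analysis toolkit for minor-spliceosome (U12-dependent) intron retention in
two-condition transcriptome experiments, with the genetics of the mouse
*Zrsr1*/*Zrsr2* system built in. It is aimed at RNA biologists and
computational groups studying the minor spliceosome — in particular the
situation where loss of ZRSR splicing factors in early embryos leaves
U12-type introns unspliced — who need a transparent, testable version of the
standard analysis chain without raw sequencing data.

## What it computes

**Intron classification.** Introns are extracted strand-aware from a
FASTA/GTF pair and scored with position weight matrices for the donor and
branch sites of the two U12 subtypes (AT–AC and GT–AG) and the donor and
acceptor of U2 introns. A PWM column holds log-odds
`log2((c_ib + λ·q_b) / (n + λ) / q_b)` against background `q`; window scores
are additive in bits. An intron is called U12 when the best U12 composite
(donor + best branch placement within 8–40 nt of the 3′ end) beats the U2
composite (donor + acceptor) by a configurable margin, both U12 sites carry
positive evidence of their own, and the terminal dinucleotides match the
subtype.

**Differential splicing.** Inclusion levels are percent-spliced-in,
`PSI = 100·I/(I+E)` from inclusion/exclusion read counts; group means are
averaged over replicates and events with `|ΔPSI| > 10` (strict) that pass a
per-sample coverage filter are called, per event class (IR, ES, 3SS, 5SS,
MIC).

**Enrichment statistics.** U12 share among upregulated IR events is tested
with an exact binomial against the genome-wide U12 fraction (~0.04%);
adjacency of affected U2 introns to U12 introns uses per-gene rank
distances; proportion comparisons use the pooled two-proportion z-test; DE
consensus takes genes significant in two methods with concordant direction.

**Cross genetics.** *Zrsr1* is maternally imprinted and the paternal
*Zrsr2* (X-linked) is silenced by imprinted X inactivation pre-blastocyst,
so an embryo is viable iff its paternal *Zrsr1* or maternal *Zrsr2* allele
is wild type. Crosses are enumerated exactly (Fraction arithmetic), with
conditional survivor spectra and exact multinomial litter tests.

**Synthetic data.** A seeded generator produces genomes/annotations with
planted U12 introns, binomial two-condition count tables with retention
effects biased toward U12 introns, cross offspring, and qPCR CT tables — so
every stage is benchmarked against known truth.

## Worked example

```python
from u12retain import binomial_enrichment, two_proportion_ztest

enr = binomial_enrichment(observed=53, total=710, expected_fraction=0.0004)
z = two_proportion_ztest(121, 197, 5, 129)
```

Running `python examples/05_count_statistics.py` prints:

```
U12 IR enrichment : 53/710 = 7.5% vs 0.04% expected (fold 187, exact binomial p = 2.62e-100)
rescue z-test     : z = 10.43, p = 1.74e-25 (p < 0.01)
```

i.e. 53 of 710 mutant-upregulated intron-retention events fall on U12-type
introns — 7.5% observed against a 0.04% genome-wide expectation, a ~190-fold
enrichment that an exact binomial test rejects overwhelmingly — and
injecting wild-type *Zrsr1* mRNA raises embryo development from 3.9% (5/129)
to 61.4% (121/197), significant by the two-proportion z-test. The other
scripts in `examples/` walk through intron classification
(`01_classify_introns.py`), the ΔPSI pipeline with U12 enrichment on
synthetic data (`02_...`), cross viability (`03_...`) and 2^−ΔΔCT fold
changes (`04_...`); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library: `u12retain extract | classify |
diff-splice | enrich | adjacency | overlap | cross | cross-test | ddct |
simulate` (see `u12retain --help`).

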