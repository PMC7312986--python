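"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the data regime of a minor-splicing perturbation
experiment: a gene catalog in which a small fraction of genes carry exactly
one U12-type intron among ordinary U2 introns (splice-site blocks sampled
position-wise from the class-specific PWMs, interiors uniform random,
termini forced to the class-canonical dinucleotides); two-condition
replicated intron-retention count tables in which inclusion reads are
binomial around a true PSI, with retention effects planted preferentially on
U12 introns; offspring of genetic crosses drawn from the exact enumerated
distribution; and qPCR CT tables built to invert the 2^-ddCT formula.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import default_pwms
from .genetics import OffspringOutcome, ParentGenotype, enumerate_offspring, is_viable
from .pwm import BASES, SpliceSitePwm

__all__ = [
    "SimConfig",
    "simulate_catalog_truth",
    "simulate_intron_catalog",
    "simulate_event_counts",
    "simulate_cross_offspring",
    "simulate_ct_table",
    "write_fasta",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    The catalog-level U12 gene fraction (0.03) is deliberately far above the
    genomic ~0.004 so that small test catalogs contain U12 introns at all;
    enrichment nulls in tests must therefore use the *generated* catalog's
    U12 fraction, not the genome-wide constant.
    """

    seed: int
    n_genes: int = 500
    introns_per_gene: tuple[int, int] = (3, 6)  # inclusive range
    u12_gene_fraction: float = 0.03
    u12_atac_share: float = 0.3
    read_depth: int = 100
    n_replicates: int = 3
    planted_ir_effect: float = 25.0  # dPSI planted in MU
    planted_u12_bias: float = 0.5  # P(a planted effect lands on a U12 intron)
    baseline_psi: float = 5.0
    n_planted: int = 20
    intron_length: tuple[int, int] = (70, 150)
    exon_length: tuple[int, int] = (60, 120)
    overdispersion: float = 0.0  # beta-binomial intra-class correlation; 0 = binomial

    def __post_init__(self) -> None:
        for name in ("u12_gene_fraction", "u12_atac_share", "planted_u12_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def simulate_catalog_truth(config: SimConfig) -> pd.DataFrame:
    """Gene/intron skeleton with true intron classes (no sequences).

    One transcript per gene; round(n_genes * u12_gene_fraction) genes carry
    exactly one U12 intron at a random rank, AT-AC with probability
    ``u12_atac_share``.  Intron ids follow the catalog naming ``<tx>.i<rank>``.
    """
    rng = _rng(config, 0)
    lo, hi = config.introns_per_gene
    n_u12_genes = int(round(config.n_genes * config.u12_gene_fraction))
    u12_genes = set(
        rng.choice(config.n_genes, size=n_u12_genes, replace=False).tolist()
    )
    rows = []
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        tx_id = f"{gene_id}.t1"
        n_introns = int(rng.integers(lo, hi + 1))
        u12_rank = None
        subtype = None
        if g in u12_genes:
            u12_rank = int(rng.integers(1, n_introns + 1))
            subtype = "U12-ATAC" if rng.random() < config.u12_atac_share else "U12-GTAG"
        for rank in range(1, n_introns + 1):
            rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "intron_id": f"{tx_id}.i{rank}",
                    "rank": rank,
                    "true_class": subtype if rank == u12_rank else "U2",
                }
            )
    return pd.DataFrame(rows)


def _sample_from_pwm(pwm: SpliceSitePwm, rng: np.random.Generator) -> str:
    probs = pwm.probabilities
    idx = [rng.choice(4, p=probs[i] / probs[i].sum()) for i in range(pwm.width)]
    return "".join(BASES[i] for i in idx)


_TERMINI = {"U2": ("GT", "AG"), "U12-GTAG": ("GT", "AG"), "U12-ATAC": ("AT", "AC")}


def _sample_intron(true_class: str, length: int, rng: np.random.Generator, pwms) -> str:
    if length < 52:
        raise ValueError("intron too short to hold donor + branch search window")
    seq = list(rng.choice(list(BASES), size=length))
    if true_class == "U2":
        donor = _sample_from_pwm(pwms[("donor", "U2")], rng)
        acceptor = _sample_from_pwm(pwms[("acceptor", "U2")], rng)
        seq[: len(donor)] = donor
        seq[-len(acceptor) :] = acceptor
    else:
        donor = _sample_from_pwm(pwms[("donor", true_class)], rng)
        branch_pwm = pwms[("branch", true_class)]
        branch = _sample_from_pwm(branch_pwm, rng)
        seq[: len(donor)] = donor
        # plant the branch window inside the classifier search interval
        # [-40, -8]: window starts -40..-16 keep the motif fully in range
        off = int(rng.integers(-40, -15))
        seq[length + off : length + off + branch_pwm.width] = branch
    d, a = _TERMINI[true_class]
    seq[0:2] = d
    seq[-2:] = a
    return "".join(seq)


def simulate_intron_catalog(
    config: SimConfig,
) -> tuple[dict[str, str], str, pd.DataFrame]:
    """Genome + annotation + truth for a synthetic gene catalog.

    Returns ``(genome, gtf_text, truth)`` where genome maps chromosome name
    to sequence and gtf_text is GTF with gene/transcript/exon features.
    Gene strands are random; intron sequences are built in transcript
    orientation then reverse-complemented into the genome for minus-strand
    genes.
    """
    truth = simulate_catalog_truth(config)
    if config.n_genes == 0:
        return {}, "", truth
    rng = _rng(config, 1)
    pwms = default_pwms()
    ilo, ihi = config.intron_length
    elo, ehi = config.exon_length
    if ilo < 52:
        raise ValueError("intron_length minimum must be >= 52 (donor + branch window)")

    comp = str.maketrans("ACGT", "TGCA")
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    gtf_lines: list[str] = []
    strands: dict[str, str] = {}

    for gene_id, gene_truth in truth.groupby("gene_id", sort=True):
        tx_id = gene_truth["transcript_id"].iloc[0]
        strand = "+" if rng.random() < 0.5 else "-"
        strands[gene_id] = strand
        n_introns = len(gene_truth)
        exon_lens = rng.integers(elo, ehi + 1, size=n_introns + 1)
        intron_lens = rng.integers(ilo, ihi + 1, size=n_introns)
        # transcript-oriented sequence and block structure
        blocks: list[tuple[str, str]] = []  # (kind, seq)
        for k in range(n_introns + 1):
            exon = "".join(rng.choice(list(BASES), size=int(exon_lens[k])))
            blocks.append(("exon", exon))
            if k < n_introns:
                cls = gene_truth.iloc[k]["true_class"]
                blocks.append(
                    ("intron", _sample_intron(cls, int(intron_lens[k]), rng, pwms))
                )
        tx_seq = "".join(s for _, s in blocks)
        tx_len = len(tx_seq)
        gene_start = cursor
        segment = tx_seq if strand == "+" else tx_seq.translate(comp)[::-1]
        genome_parts.append(segment)
        genome_parts.append("".join(rng.choice(list(BASES), size=25)))  # spacer
        cursor += tx_len + 25

        # exon genomic coordinates (0-based half-open) from transcript blocks
        exon_spans = []
        pos = 0
        for kind, s in blocks:
            if kind == "exon":
                a, b = pos, pos + len(s)
                if strand == "+":
                    exon_spans.append((gene_start + a, gene_start + b))
                else:
                    exon_spans.append((gene_start + tx_len - b, gene_start + tx_len - a))
            pos += len(s)
        exon_spans.sort()
        g0, g1 = gene_start, gene_start + tx_len
        attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
        gtf_lines.append(
            f"{chrom}\tsim\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t" f'gene_id "{gene_id}";'
        )
        gtf_lines.append(f"{chrom}\tsim\ttranscript\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t{attrs}")
        for a, b in exon_spans:
            gtf_lines.append(f"{chrom}\tsim\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}")

    genome = {chrom: "".join(genome_parts)}
    truth = truth.copy()
    truth["chrom"] = chrom
    truth["strand"] = truth["gene_id"].map(strands)
    return genome, "\n".join(gtf_lines) + "\n", truth


def simulate_event_counts(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition IR event-count table + event-level truth.

    One intron-retention event per catalog intron.  ``n_planted`` events get
    a retention increase of ``planted_ir_effect`` dPSI in the MU group; the
    number landing on U12 introns is Binomial(n_planted, planted_u12_bias),
    capped by availability.  Inclusion reads are Binomial(read_depth,
    PSI/100) per sample (beta-binomial when overdispersion > 0).
    """
    if config.read_depth <= 0:
        raise ValueError("read depth must be positive")
    rng = _rng(config, 2)
    truth = truth.reset_index(drop=True)
    is_u12 = truth["true_class"].str.startswith("U12").to_numpy()
    u12_idx = np.flatnonzero(is_u12)
    u2_idx = np.flatnonzero(~is_u12)

    n_planted = min(config.n_planted, len(truth))
    n_on_u12 = int(rng.binomial(n_planted, config.planted_u12_bias))
    n_on_u12 = min(n_on_u12, len(u12_idx))
    n_on_u2 = min(n_planted - n_on_u12, len(u2_idx))
    planted = np.zeros(len(truth), dtype=bool)
    if n_on_u12:
        planted[rng.choice(u12_idx, size=n_on_u12, replace=False)] = True
    if n_on_u2:
        planted[rng.choice(u2_idx, size=n_on_u2, replace=False)] = True

    psi_wt = np.full(len(truth), config.baseline_psi)
    psi_mu = psi_wt + np.where(planted, config.planted_ir_effect, 0.0)
    psi_mu = np.clip(psi_mu, 0.0, 100.0)

    samples = [("WT", psi_wt, f"WT_{r + 1}") for r in range(config.n_replicates)] + [
        ("MU", psi_mu, f"MU_{r + 1}") for r in range(config.n_replicates)
    ]
    frames = []
    depth = config.read_depth
    for group, psi, sample in samples:
        p = psi / 100.0
        if config.overdispersion > 0:
            rho = config.overdispersion
            conc = (1 - rho) / rho
            a = np.clip(p * conc, 1e-9, None)
            b = np.clip((1 - p) * conc, 1e-9, None)
            p = rng.beta(a, b)
        inc = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "event_id": "IR:" + truth["intron_id"],
                    "event_class": "IR",
                    "gene_id": truth["gene_id"],
                    "intron_id": truth["intron_id"],
                    "sample": sample,
                    "group": group,
                    "inclusion_reads": inc,
                    "exclusion_reads": depth - inc,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    event_truth = pd.DataFrame(
        {
            "event_id": "IR:" + truth["intron_id"],
            "intron_id": truth["intron_id"],
            "gene_id": truth["gene_id"],
            "true_class": truth["true_class"],
            "planted": planted,
            "true_psi_wt": psi_wt,
            "true_psi_mu": psi_mu,
        }
    )
    return counts, event_truth


def simulate_cross_offspring(
    mother: ParentGenotype,
    father: ParentGenotype,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """i.i.d. draws from the enumerated cross distribution; arrest applied.

    Non-viable conceptuses are recorded with status ``arrested`` rather than
    dropped, so structural zeros (fully arrested crosses) remain visible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(int(seed) % (2**31))
    outcomes = enumerate_offspring(mother, father)
    probs = np.array([float(o.probability) for o in outcomes])
    picks = rng.choice(len(outcomes), size=n, p=probs)
    rows = []
    for i in picks:
        o = outcomes[i]
        rows.append(
            {
                "sex": o.sex,
                "zrsr1_maternal": o.zrsr1_maternal,
                "zrsr1_paternal": o.zrsr1_paternal,
                "zrsr2_maternal": o.zrsr2_maternal,
                "zrsr2_paternal": o.zrsr2_paternal if o.zrsr2_paternal else "Y",
                "viable": is_viable(o),
                "status": "live" if is_viable(o) else "arrested",
            }
        )
    return pd.DataFrame(rows)


def simulate_ct_table(
    true_fold_changes: Mapping[str, Sequence[float]],
    noise_sd: float,
    seed: int,
    reference_gene: str = "H2afz",
) -> pd.DataFrame:
    """CT table whose 2^-ddCT analysis recovers the given folds (up to noise).

    ``true_fold_changes`` maps each target gene to per-sample expression
    levels relative to that gene's lowest-expressed sample (the generator
    renormalises by the minimum, matching the max-dCT calibrator rule).
    Gaussian noise of ``noise_sd`` cycles is added to every CT independently.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    genes = sorted(true_fold_changes)
    n_samples = {len(v) for v in true_fold_changes.values()}
    if len(n_samples) != 1:
        raise ValueError("all genes must provide folds for the same samples")
    n = n_samples.pop()
    rows = []
    for s in range(n):
        sample = f"s{s + 1:02d}"
        ref_ct = 20.0 + rng.normal(0.0, noise_sd)
        rows.append({"sample_id": sample, "gene_id": reference_gene, "ct": ref_ct})
        for gene in genes:
            folds = np.asarray(true_fold_changes[gene], dtype=float)
            if (folds <= 0).any():
                raise ValueError("fold changes must be positive")
            rel = folds / folds.min()
            dct = 8.0 - np.log2(rel[s])  # higher expression -> lower CT
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": gene,
                    "ct": ref_ct + dct + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
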