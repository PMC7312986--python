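"""U2 / U12 intron classification by splice-site PWM scoring.

Each intron is scored with donor + branch PWMs for the two U12 subtypes
(AT-AC and GT-AG) and donor + acceptor PWMs for U2.  The composite U12 score
of a subtype is donor + best branch placement; the U2 composite is donor +
acceptor.  An intron is called U12-<subtype> when (i) the best U12 composite
exceeds the U2 composite by more than ``margin_threshold`` bits, (ii) the
winning subtype's branch score AND its donor score *beyond the terminal
dinucleotide* are each positive — both sites must beat the background
model on their own evidence (the first two donor columns are already
spent on the termini gate), not merely be less unlike U12 than U2 —
and (iii) the terminal dinucleotides
match the winning subtype's canonical pair; otherwise it is called U2.
Condition (ii) prevents sequences resembling neither model (both composites
negative) from being assigned by the sign of a meaningless difference.  U12 introns lack the U2 polypyrimidine tract but carry an
exceptionally conserved donor and branch point, which is what the composite
contrast exploits.

The module ships small fixture PWMs built from hand-curated consensus-derived
training alignments (synthetic stand-ins written around the canonical
mammalian site consensi, not drawn from any intron database); users may build
their own PWMs from real alignments with :func:`u12retain.pwm.build_pwm`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import pandas as pd

from .intron_catalog import IntronRecord, deduplicate_catalog, terminal_dinucleotides
from .pwm import SpliceSitePwm, build_pwm, locate_branch_point, score_window

__all__ = [
    "IntronClassification",
    "classify_intron",
    "classify_catalog",
    "default_pwms",
    "DEFAULT_BRANCH_SEARCH",
]

DEFAULT_BRANCH_SEARCH = (-40, -8)

# Canonical terminal dinucleotide pairs per U12 subtype.
_CANONICAL_TERMINI = {"U12-ATAC": ("AT", "AC"), "U12-GTAG": ("GT", "AG")}

# --- fixture training alignments (synthetic, consensus-derived) -------------
# Donor windows are intronic positions +1..+12; the U12 donor block
# RTATCCTT is strongly conserved, the tail is variable.
_U12_GTAG_DONOR = [
    "GTATCCTTTACT",
    "GTATCCTTAACT",
    "GTATCCTTTGCT",
    "GTATCCTTTACC",
    "GTATCCTTCACT",
    "GTATCCTTTATT",
    "GTATCCTTAGCT",
    "GTATCCTTTCCT",
    "GTATCCTCTACT",
    "GTATCCTTTACG",
]
_U12_ATAC_DONOR = ["A" + s[1:] for s in _U12_GTAG_DONOR]
# U12 branch point, consensus TTCCTTAAC (branch adenosine at position 8);
# the same alignment trains both subtypes' branch matrices.
_U12_BRANCH = [
    "TTCCTTAAC",
    "TTCCTTAAC",
    "TTCCTGAAC",
    "TCCCTTAAC",
    "TTCCTTGAC",
    "TTTCTTAAC",
    "TTCCTCAAC",
    "TTCCTTAAT",
    "CTCCTTAAC",
    "TTCCTTAAG",
]
# U2 donor: GTAAGT core, weakly constrained tail.
_U2_DONOR = [
    "GTAAGTATGGAC",
    "GTAAGTCTAGTT",
    "GTGAGTATTCCA",
    "GTAAGAGTCTGA",
    "GTAAGTTAGCCT",
    "GTATGTAACGAG",
    "GTAAGCATCAGT",
    "GTGAGTGCTATC",
    "GTAAGTGGATCA",
    "GTAAGTTTCTGG",
]
# U2 acceptor: polypyrimidine tract + NYAG, intronic positions -14..-1.
_U2_ACCEPTOR = [
    "TTTTCTTTTTACAG",
    "TCTTTCCTCTGCAG",
    "TTCTTTTTTCTTAG",
    "CTTTCTTCCTACAG",
    "TTTTTTCTTTTCAG",
    "TTCCTTTCTTGTAG",
    "TTTCTCTTCCACAG",
    "CTCTTTTTCTTCAG",
    "TTTTCTCCTTATAG",
    "TCTTTTTCTTACAG",
]

_TRAINING = {
    ("donor", "U12-ATAC"): _U12_ATAC_DONOR,
    ("donor", "U12-GTAG"): _U12_GTAG_DONOR,
    ("branch", "U12-ATAC"): _U12_BRANCH,
    ("branch", "U12-GTAG"): _U12_BRANCH,
    ("donor", "U2"): _U2_DONOR,
    ("acceptor", "U2"): _U2_ACCEPTOR,
}


@lru_cache(maxsize=1)
def default_pwms() -> dict[tuple[str, str], SpliceSitePwm]:
    """The fixture PWM set keyed by (site_kind, subtype)."""
    return {
        key: build_pwm(seqs, site_kind=key[0], subtype=key[1])
        for key, seqs in _TRAINING.items()
    }


@dataclass
class IntronClassification:
    intron_id: str
    gene_id: str
    scores: dict[tuple[str, str], float]
    branch_pos: int | None
    assigned_class: str  # U2 | U12-ATAC | U12-GTAG
    margin: float  # best U12 composite minus U2 composite


def _n_fraction(seq: str) -> float:
    if not seq:
        return 1.0
    return seq.upper().count("N") / len(seq)


def classify_intron(
    record: IntronRecord,
    pwms: Mapping[tuple[str, str], SpliceSitePwm] | None = None,
    margin_threshold: float = 0.0,
    branch_search: tuple[int, int] = DEFAULT_BRANCH_SEARCH,
) -> IntronClassification:
    """Classify one intron as U2, U12-ATAC or U12-GTAG."""
    pwms = default_pwms() if pwms is None else pwms
    seq = record.sequence.upper()

    if _n_fraction(seq) > 0.5:
        warnings.warn(
            f"intron {record.intron_id}: >50% ambiguous bases, classified U2",
            stacklevel=2,
        )
        return IntronClassification(record.intron_id, record.gene_id, {}, None, "U2", float("-inf"))

    scores: dict[tuple[str, str], float] = {}
    branch_offsets: dict[str, int | None] = {}
    neg_inf = float("-inf")

    def donor_score(subtype: str) -> float:
        p = pwms[("donor", subtype)]
        if len(seq) < p.width:
            return neg_inf
        return score_window(p, seq[: p.width])

    for subtype in ("U12-ATAC", "U12-GTAG"):
        scores[("donor", subtype)] = donor_score(subtype)
        off, s = locate_branch_point(pwms[("branch", subtype)], seq, branch_search)
        scores[("branch", subtype)] = s
        branch_offsets[subtype] = off
    scores[("donor", "U2")] = donor_score("U2")
    acc = pwms[("acceptor", "U2")]
    scores[("acceptor", "U2")] = (
        score_window(acc, seq[-acc.width :]) if len(seq) >= acc.width else neg_inf
    )

    composites = {
        st: scores[("donor", st)] + scores[("branch", st)] for st in ("U12-ATAC", "U12-GTAG")
    }
    u2_composite = scores[("donor", "U2")] + scores[("acceptor", "U2")]

    termini = terminal_dinucleotides(record) if len(seq) >= 4 else ("", "")
    if composites["U12-ATAC"] == composites["U12-GTAG"]:
        # tie: prefer the termini-matching subtype, else GT-AG (more common)
        winner = "U12-ATAC" if termini == _CANONICAL_TERMINI["U12-ATAC"] else "U12-GTAG"
    else:
        winner = max(composites, key=composites.get)
    margin = composites[winner] - u2_composite

    assigned = "U2"
    donor_pwm = pwms[("donor", winner)]
    if len(seq) >= donor_pwm.width:
        terminal_bits = sum(
            donor_pwm.logodds[i, "ACGT".index(seq[i])] if seq[i] in "ACGT" else 0.0
            for i in range(2)
        )
        donor_inner = scores[("donor", winner)] - terminal_bits
    else:
        donor_inner = neg_inf
    if (
        margin > margin_threshold
        and donor_inner > 0
        and scores[("branch", winner)] > 0
        and termini == _CANONICAL_TERMINI[winner]
    ):
        assigned = winner
    return IntronClassification(
        intron_id=record.intron_id,
        gene_id=record.gene_id,
        scores=scores,
        branch_pos=branch_offsets[winner],
        assigned_class=assigned,
        margin=margin,
    )


def classify_catalog(
    catalog: Sequence[IntronRecord],
    pwms: Mapping[tuple[str, str], SpliceSitePwm] | None = None,
    margin_threshold: float = 0.0,
    branch_search: tuple[int, int] = DEFAULT_BRANCH_SEARCH,
) -> tuple[pd.DataFrame, Counter]:
    """Classify every gene-level deduplicated intron of a catalog.

    Returns a classification table and per-class summary counts (the counts
    sum to the number of deduplicated introns).
    """
    unique = deduplicate_catalog(catalog)
    rows = []
    counts: Counter = Counter({"U2": 0, "U12-ATAC": 0, "U12-GTAG": 0})
    for rec in unique:
        cls = classify_intron(rec, pwms, margin_threshold, branch_search)
        counts[cls.assigned_class] += 1
        rows.append(
            {
                "intron_id": cls.intron_id,
                "gene_id": cls.gene_id,
                "assigned_class": cls.assigned_class,
                "margin": cls.margin,
                "branch_offset": cls.branch_pos,
                "donor_u12_atac": cls.scores.get(("donor", "U12-ATAC")),
                "donor_u12_gtag": cls.scores.get(("donor", "U12-GTAG")),
                "branch_u12_atac": cls.scores.get(("branch", "U12-ATAC")),
                "branch_u12_gtag": cls.scores.get(("branch", "U12-GTAG")),
                "donor_u2": cls.scores.get(("donor", "U2")),
                "acceptor_u2": cls.scores.get(("acceptor", "U2")),
            }
        )
    cols = [
        "intron_id",
        "gene_id",
        "assigned_class",
        "margin",
        "branch_offset",
        "donor_u12_atac",
        "donor_u12_gtag",
        "branch_u12_atac",
        "branch_u12_gtag",
        "donor_u2",
        "acceptor_u2",
    ]
    return pd.DataFrame(rows, columns=cols), counts
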