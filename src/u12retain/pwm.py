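"""Position weight matrices for splice-site scoring.

A PWM is built from an alignment of equal-length site sequences as a
per-position log2-odds matrix against a background composition:

    logodds[i][b] = log2( (count[i][b] + pseudocount * bg[b]) / (n + pseudocount) / bg[b] )

Scores are additive over positions (bits); an ``N`` in a scored window
contributes 0 at its position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpliceSitePwm",
    "build_pwm",
    "score_window",
    "locate_branch_point",
    "write_pwm_text",
    "read_pwm_text",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SITE_KINDS = ("donor", "branch", "acceptor")
SUBTYPES = ("U12-ATAC", "U12-GTAG", "U2")


@dataclass
class SpliceSitePwm:
    site_kind: str
    subtype: str
    width: int
    logodds: np.ndarray  # width x 4, A C G T order
    background: np.ndarray  # length-4 probability vector
    pseudocount: float
    n_training: int

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.site_kind not in SITE_KINDS:
            raise ValueError(f"unknown site_kind {self.site_kind!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.width < 2 or self.logodds.shape != (self.width, 4):
            raise ValueError("logodds must be width x 4 with width >= 2")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.logodds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Per-position base probabilities implied by the log-odds."""
        p = np.exp2(self.logodds) * self.background
        return p / p.sum(axis=1, keepdims=True)


def build_pwm(
    aligned_sites: Sequence[str],
    site_kind: str,
    subtype: str,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> SpliceSitePwm:
    """Build a log-odds PWM from equal-length aligned site sequences.

    ``N`` contributes 0.25 to every base count at its position.  The
    pseudocount is distributed over bases by the background composition.
    """
    if not aligned_sites:
        raise ValueError("empty training set")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError("training sequences must all have the same length")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for s in aligned_sites:
        for i, c in enumerate(s.upper()):
            if c == "N":
                counts[i] += 0.25
            elif c in _BASE_INDEX:
                counts[i, _BASE_INDEX[c]] += 1.0
            else:
                raise ValueError(f"invalid character {c!r} in training sequence")
    n = len(aligned_sites)
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    logodds = np.log2(freq / bg)
    return SpliceSitePwm(
        site_kind=site_kind,
        subtype=subtype,
        width=width,
        logodds=logodds,
        background=bg,
        pseudocount=pseudocount,
        n_training=n,
    )


def score_window(pwm: SpliceSitePwm, window: str) -> float:
    """Sum of per-position log-odds for ``window``; N scores 0 at its position."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != pwm width {pwm.width}")
    total = 0.0
    for i, c in enumerate(window.upper()):
        if c == "N":
            continue
        if c not in _BASE_INDEX:
            raise ValueError(f"invalid character {c!r} in window")
        total += pwm.logodds[i, _BASE_INDEX[c]]
    return float(total)


def locate_branch_point(
    pwm: SpliceSitePwm,
    intron_sequence: str,
    search_window: tuple[int, int] = (-40, -8),
) -> tuple[int | None, float]:
    """Best branch-site placement near the intron 3' end.

    ``search_window`` is the interval of offsets from the 3' end (negative,
    inclusive) that the branch window must lie entirely within: with the
    default (-40, -8) and width 9, feasible window starts run from -40 to
    -16, keeping the whole motif 8-40 nt upstream of the acceptor.  The
    window must also fit inside the intron, so an intron shorter than
    width + |hi| has no feasible placement.  Ties are broken toward the 3'
    end.  With no feasible placement, returns ``(None, -inf)`` — such an
    intron cannot be called U12.
    """
    seq = intron_sequence.upper()
    L = len(seq)
    lo, hi = search_window
    best_off: int | None = None
    best = float("-inf")
    for off in range(lo, hi - pwm.width + 2):
        start = L + off
        if start < 0 or start + pwm.width > L:
            continue
        s = score_window(pwm, seq[start : start + pwm.width])
        if s >= best:  # >= prefers the later (3'-most) placement on ties
            best = s
            best_off = off
    return best_off, best


def write_pwm_text(pwm: SpliceSitePwm, path) -> None:
    """MEME-motif-style probability matrix plus the log-odds, plain text."""
    probs = pwm.probabilities
    with open(path, "w") as fh:
        fh.write("MOTIF %s/%s\n" % (pwm.site_kind, pwm.subtype))
        fh.write(
            "letter-probability matrix: alength= 4 w= %d nsites= %d\n"
            % (pwm.width, pwm.n_training)
        )
        for row in probs:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        fh.write("background: " + " ".join(f"{x:.6f}" for x in pwm.background) + "\n")
        fh.write(f"pseudocount: {pwm.pseudocount}\n")
        fh.write("log-odds:\n")
        for row in pwm.logodds:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_pwm_text(path) -> SpliceSitePwm:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    site_kind, subtype = lines[0].split()[1].split("/")
    header = lines[1].split()
    width = int(header[header.index("w=") + 1])
    n = int(header[header.index("nsites=") + 1])
    background = np.array([float(x) for x in lines[2 + width].split()[1:]])
    pseudocount = float(lines[3 + width].split()[1])
    lo_start = 5 + width
    logodds = np.array(
        [[float(x) for x in lines[lo_start + i].split()] for i in range(width)]
    )
    return SpliceSitePwm(
        site_kind=site_kind,
        subtype=subtype,
        width=width,
        logodds=logodds,
        background=background,
        pseudocount=pseudocount,
        n_training=n,
    )
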