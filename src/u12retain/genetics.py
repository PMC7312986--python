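"""Viability genetics of Zrsr1 x Zrsr2 crosses under imprinting and imprinted XCI.

Zrsr1 is autosomal and maternally imprinted: the embryo expresses only the
paternal allele.  Zrsr2 is X-linked, and the paternal X is inactivated during
early preimplantation development (imprinted X-chromosome inactivation), so
early embryos express only the maternal Zrsr2 allele; males carry a single,
maternal X anyway.  A preimplantation embryo survives the 2-cell transition
iff at least one functional minor-spliceosome ZRSR protein is expressed:

    viable  <=>  paternal Zrsr1 allele is WT  OR  maternal Zrsr2 allele is WT

Imprinting is modelled as complete (no leaky expression) and the sex ratio is
fixed 1:1; viability is evaluated at the early-embryo stage only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Mapping

from scipy import stats

__all__ = [
    "ParentGenotype",
    "OffspringOutcome",
    "parse_parent",
    "enumerate_offspring",
    "is_viable",
    "viable_fraction",
    "surviving_genotype_spectrum",
    "litter_consistency_test",
]

ALLELES = ("WT", "mu")


@dataclass(frozen=True)
class ParentGenotype:
    """Parental genotype at Zrsr1 (autosomal) and Zrsr2 (X-linked)."""

    sex: str  # 'female' | 'male'
    zrsr1: tuple[str, str]
    zrsr2: tuple[str, ...]  # two alleles for females, one (the X) for males

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male"}:
            raise ValueError("sex must be 'female' or 'male'")
        if len(self.zrsr1) != 2 or any(a not in ALLELES for a in self.zrsr1):
            raise ValueError("Zrsr1 must carry two alleles from {WT, mu}")
        expected = 2 if self.sex == "female" else 1
        if len(self.zrsr2) != expected or any(a not in ALLELES for a in self.zrsr2):
            raise ValueError(
                f"{self.sex} must carry {expected} Zrsr2 allele(s) from {{WT, mu}}"
            )


_SPEC_RE = re.compile(
    r"Zrsr1:(?P<z1>\S+)\s+Zrsr2:(?P<z2>\S+)\s+sex:(?P<sex>[FMfm])"
)


def parse_parent(spec: str) -> ParentGenotype:
    """Parse a genotype string like ``'Zrsr1:WT/mu Zrsr2:mu/mu sex:F'``.

    Males write the hemizygous X as ``Zrsr2:WT/y`` (or ``mu/y``).
    """
    m = _SPEC_RE.fullmatch(spec.strip())
    if not m:
        raise ValueError(f"malformed genotype spec: {spec!r}")
    sex = "female" if m.group("sex").upper() == "F" else "male"
    z1 = tuple(m.group("z1").split("/"))
    z2_parts = m.group("z2").split("/")
    if sex == "male":
        if len(z2_parts) == 2 and z2_parts[1].lower() == "y":
            z2_parts = z2_parts[:1]
        if len(z2_parts) != 1:
            raise ValueError("male Zrsr2 spec must be '<allele>/y' or a single allele")
    z2 = tuple(z2_parts)
    return ParentGenotype(sex=sex, zrsr1=z1, zrsr2=z2)


@dataclass(frozen=True)
class OffspringOutcome:
    sex: str
    zrsr1_maternal: str
    zrsr1_paternal: str
    zrsr2_maternal: str
    zrsr2_paternal: str | None  # None on the Y-bearing sperm
    probability: Fraction

    @property
    def expressed_zrsr1(self) -> str:
        """Zrsr1 is maternally imprinted: only the paternal copy is expressed."""
        return self.zrsr1_paternal

    @property
    def expressed_zrsr2_early(self) -> str:
        """Imprinted XCI silences the paternal X pre-blastocyst."""
        return self.zrsr2_maternal

    @property
    def viable(self) -> bool:
        return is_viable(self)


def is_viable(outcome: OffspringOutcome) -> bool:
    """One WT Zrsr1 from the father or one WT Zrsr2 from the mother suffices."""
    return outcome.expressed_zrsr1 == "WT" or outcome.expressed_zrsr2_early == "WT"


def enumerate_offspring(
    mother: ParentGenotype, father: ParentGenotype
) -> list[OffspringOutcome]:
    """Exact Mendelian enumeration of offspring outcomes with probabilities.

    Zrsr1 segregates independently of the sex chromosome; the sperm carries
    either the paternal X (with its Zrsr2 allele; daughter) or the Y (son),
    each with probability 1/2.  Identical outcomes are merged; probabilities
    sum to 1 exactly (Fraction arithmetic).
    """
    if mother.sex != "female" or father.sex != "male":
        raise ValueError("cross requires a female mother and a male father")
    half = Fraction(1, 2)
    # egg: one Zrsr1 allele x one X (Zrsr2 allele)
    eggs = [
        (a1, x, half * half)
        for a1 in mother.zrsr1
        for x in mother.zrsr2
    ]
    # sperm: one Zrsr1 allele x (paternal X | Y)
    sperm = [
        (a1, sx, half * half)
        for a1 in father.zrsr1
        for sx in (father.zrsr2[0], None)
    ]
    merged: dict[tuple, Fraction] = {}
    for (m1, mx, pm), (f1, fx, pf) in product(eggs, sperm):
        sex = "male" if fx is None else "female"
        key = (sex, m1, f1, mx, fx)
        merged[key] = merged.get(key, Fraction(0)) + pm * pf
    out = [
        OffspringOutcome(
            sex=sex,
            zrsr1_maternal=m1,
            zrsr1_paternal=f1,
            zrsr2_maternal=mx,
            zrsr2_paternal=fx,
            probability=p,
        )
        for (sex, m1, f1, mx, fx), p in sorted(
            merged.items(), key=lambda kv: repr(kv[0])
        )
    ]
    assert sum(o.probability for o in out) == 1
    return out


def viable_fraction(mother: ParentGenotype, father: ParentGenotype) -> float:
    return float(
        sum(o.probability for o in enumerate_offspring(mother, father) if is_viable(o))
    )


def surviving_genotype_spectrum(
    mother: ParentGenotype, father: ParentGenotype
) -> dict[OffspringOutcome, float]:
    """Genotype distribution conditional on early-embryo viability.

    Returns an empty dict when no outcome is viable (fully arrested cross).
    """
    outcomes = enumerate_offspring(mother, father)
    viable = [o for o in outcomes if is_viable(o)]
    total = sum(o.probability for o in viable)
    if total == 0:
        return {}
    return {o: float(o.probability / total) for o in viable}


def litter_consistency_test(
    predicted_spectrum: Mapping, observed_counts: Mapping
) -> float:
    """Exact goodness-of-fit p-value of observed litter counts vs a predicted spectrum.

    Any observation in a zero-probability (or absent) category gives p = 0.
    Two effective categories use the exact two-sided binomial; more use the
    exact multinomial (sum of point probabilities <= that of the observation).
    """
    probs = {k: float(v) for k, v in predicted_spectrum.items()}
    for cat, n in observed_counts.items():
        if n > 0 and probs.get(cat, 0.0) == 0.0:
            return 0.0
    cats = sorted(probs, key=repr)
    p = [probs[c] for c in cats]
    x = [int(observed_counts.get(c, 0)) for c in cats]
    n = sum(x)
    if n == 0 or len(cats) == 1:
        return 1.0
    if len(cats) == 2:
        return float(stats.binomtest(x[0], n, p[0]).pvalue)
    return _exact_multinomial_p(x, p)


def _exact_multinomial_p(x: list[int], p: list[float]) -> float:
    """Exact multinomial test: total probability of outcomes no more likely
    than the observed one.  Enumerates all compositions; intended for litter-
    scale n."""
    n = sum(x)
    k = len(p)
    if math.comb(n + k - 1, k - 1) > 2_000_000:
        raise ValueError("exact multinomial enumeration too large; bin categories")
    dist = stats.multinomial(n, p)
    p_obs = dist.pmf(x)
    total = 0.0

    def compositions(remaining: int, parts: int):
        if parts == 1:
            yield (remaining,)
            return
        for i in range(remaining + 1):
            for rest in compositions(remaining - i, parts - 1):
                yield (i,) + rest

    for comp in compositions(n, k):
        q = dist.pmf(comp)
        if q <= p_obs * (1 + 1e-9):
            total += q
    return float(min(total, 1.0))
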