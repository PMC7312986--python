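"""Cross enumeration, viability rules, conditional spectra, litter tests."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from u12retain import (
    ParentGenotype,
    enumerate_offspring,
    is_viable,
    litter_consistency_test,
    parse_parent,
    surviving_genotype_spectrum,
    viable_fraction,
)

WT_MOTHER = ParentGenotype("female", ("WT", "WT"), ("WT", "WT"))
WT_FATHER = ParentGenotype("male", ("WT", "WT"), ("WT",))


def test_parse_parent_round_trips_examples():
    m = parse_parent("Zrsr1:WT/mu Zrsr2:mu/mu sex:F")
    assert m == ParentGenotype("female", ("WT", "mu"), ("mu", "mu"))
    f = parse_parent("Zrsr1:mu/mu Zrsr2:WT/y sex:M")
    assert f == ParentGenotype("male", ("mu", "mu"), ("WT",))
    with pytest.raises(ValueError):
        parse_parent("Zrsr1:WT sex:F")


def test_malformed_genotypes_raise():
    with pytest.raises(ValueError):
        ParentGenotype("male", ("WT", "WT"), ("WT", "WT"))  # two X alleles in a male
    with pytest.raises(ValueError):
        ParentGenotype("female", ("WT",), ("WT", "WT"))


def test_wt_cross_all_viable():
    outcomes = enumerate_offspring(WT_MOTHER, WT_FATHER)
    assert sum(o.probability for o in outcomes) == 1
    assert all(is_viable(o) for o in outcomes)


def test_double_mutant_cross_fully_arrested():
    # Zrsr2^mu/mu mother x Zrsr1^mu/mu father: paternal Zrsr1 = mu and
    # maternal Zrsr2 = mu in every conceptus -> no viable offspring
    mother = parse_parent("Zrsr1:WT/WT Zrsr2:mu/mu sex:F")
    father = parse_parent("Zrsr1:mu/mu Zrsr2:WT/y sex:M")
    outcomes = enumerate_offspring(mother, father)
    assert all(o.expressed_zrsr1 == "mu" and o.expressed_zrsr2_early == "mu" for o in outcomes)
    assert viable_fraction(mother, father) == 0.0
    assert surviving_genotype_spectrum(mother, father) == {}


def test_reciprocal_cross_fully_viable():
    # mother Zrsr1^mu/mu (Zrsr2 WT) x father Zrsr2^mu/y: maternal Zrsr2 is WT
    mother = parse_parent("Zrsr1:mu/mu Zrsr2:WT/WT sex:F")
    father = parse_parent("Zrsr1:WT/WT Zrsr2:mu/y sex:M")
    assert viable_fraction(mother, father) == 1.0


def test_expression_rules_read_off():
    mother = parse_parent("Zrsr1:WT/WT Zrsr2:mu/mu sex:F")
    father = parse_parent("Zrsr1:WT/WT Zrsr2:WT/y sex:M")
    for o in enumerate_offspring(mother, father):
        assert o.expressed_zrsr1 == o.zrsr1_paternal == "WT"
        assert o.expressed_zrsr2_early == o.zrsr2_maternal == "mu"
        assert is_viable(o)  # paternal Zrsr1 WT suffices
    # paternal Zrsr1 mu + maternal Zrsr2 WT is also viable
    mother2 = parse_parent("Zrsr1:WT/WT Zrsr2:WT/WT sex:F")
    father2 = parse_parent("Zrsr1:mu/mu Zrsr2:WT/y sex:M")
    assert viable_fraction(mother2, father2) == 1.0


def test_no_mutant_zrsr2_carriers_among_survivors():
    # heterozygous Zrsr2 mother x Zrsr1^mu/mu father: every survivor carries
    # the WT maternal Zrsr2 allele
    mother = parse_parent("Zrsr1:WT/WT Zrsr2:WT/mu sex:F")
    father = parse_parent("Zrsr1:mu/mu Zrsr2:WT/y sex:M")
    spectrum = surviving_genotype_spectrum(mother, father)
    assert spectrum
    p_mutant_carrier = sum(p for o, p in spectrum.items() if o.zrsr2_maternal == "mu")
    assert p_mutant_carrier == 0.0


def _gamete_product_oracle(mother, father):
    """Independent enumeration: explicit gamete x gamete product."""
    eggs = [
        (a1, x, 0.25) for a1 in mother.zrsr1 for x in mother.zrsr2
    ]
    sperm = [
        (a1, sx, 0.25) for a1 in father.zrsr1 for sx in [father.zrsr2[0], None]
    ]
    dist = {}
    for (m1, mx, pm), (f1, fx, pf) in product(eggs, sperm):
        sex = "male" if fx is None else "female"
        key = (sex, m1, f1, mx, fx)
        dist[key] = dist.get(key, 0.0) + pm * pf
    return dist


def test_enumeration_matches_gamete_product_oracle():
    rng = np.random.default_rng(0)
    alleles = np.array(["WT", "mu"])
    for _ in range(20):
        mother = ParentGenotype(
            "female", tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 2))
        )
        father = ParentGenotype(
            "male", tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 1))
        )
        oracle = _gamete_product_oracle(mother, father)
        got = {
            (o.sex, o.zrsr1_maternal, o.zrsr1_paternal, o.zrsr2_maternal, o.zrsr2_paternal): float(o.probability)
            for o in enumerate_offspring(mother, father)
        }
        assert set(got) == set(oracle)
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k])


def test_viability_monotone_in_wt_alleles():
    # converting any mu allele to WT never decreases the viable fraction
    rng = np.random.default_rng(1)
    alleles = np.array(["WT", "mu"])
    for _ in range(30):
        m1, m2 = tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 2))
        f1, f2 = tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 1))
        base = viable_fraction(
            ParentGenotype("female", m1, m2), ParentGenotype("male", f1, f2)
        )
        for which, idx in [("m1", 0), ("m1", 1), ("m2", 0), ("m2", 1), ("f1", 0), ("f1", 1), ("f2", 0)]:
            g = {"m1": list(m1), "m2": list(m2), "f1": list(f1), "f2": list(f2)}
            g[which][idx] = "WT"
            up = viable_fraction(
                ParentGenotype("female", tuple(g["m1"]), tuple(g["m2"])),
                ParentGenotype("male", tuple(g["f1"]), tuple(g["f2"])),
            )
            assert up >= base


def test_spectrum_sums_to_one_when_nonempty():
    rng = np.random.default_rng(2)
    alleles = np.array(["WT", "mu"])
    for _ in range(20):
        mother = ParentGenotype("female", tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 2)))
        father = ParentGenotype("male", tuple(rng.choice(alleles, 2)), tuple(rng.choice(alleles, 1)))
        spec = surviving_genotype_spectrum(mother, father)
        if spec:
            assert sum(spec.values()) == pytest.approx(1.0)


def test_litter_test_trivial_and_closed_form_cases():
    assert litter_consistency_test({"A": 1.0}, {"A": 10}) == 1.0
    # two-sided exact binomial, all-A outcome: p = 2 * 0.5^10
    p = litter_consistency_test({"A": 0.5, "B": 0.5}, {"A": 10, "B": 0})
    assert p == pytest.approx(2 * 0.5**10)
    assert litter_consistency_test({"A": 1.0, "B": 0.0}, {"B": 1}) == 0.0


def test_litter_test_multinomial_exact_small_case():
    # perfect agreement with expectation is the modal outcome -> p = 1-ish
    p = litter_consistency_test({"A": 0.25, "B": 0.5, "C": 0.25}, {"A": 2, "B": 4, "C": 2})
    assert 0.5 < p <= 1.0
    # extreme outcome has a tiny exact p
    p2 = litter_consistency_test({"A": 0.25, "B": 0.5, "C": 0.25}, {"A": 20, "B": 0, "C": 0})
    assert p2 < 1e-6
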