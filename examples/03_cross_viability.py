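"""Predict offspring viability for Zrsr1 x Zrsr2 crosses.

Zrsr1 is maternally imprinted (only the paternal allele is expressed) and the
paternal Zrsr2 (X-linked) is silenced by imprinted X inactivation in early
embryos, so a conceptus survives iff the paternal Zrsr1 OR the maternal Zrsr2
allele is wild type.  Three informative crosses are enumerated exactly.
"""

from u12retain import parse_parent, surviving_genotype_spectrum, viable_fraction

crosses = {
    "Zrsr2^mu/mu female x Zrsr1^mu/mu male": (
        "Zrsr1:WT/WT Zrsr2:mu/mu sex:F", "Zrsr1:mu/mu Zrsr2:WT/y sex:M"),
    "reciprocal: Zrsr1^mu/mu female x Zrsr2^mu/y male": (
        "Zrsr1:mu/mu Zrsr2:WT/WT sex:F", "Zrsr1:WT/WT Zrsr2:mu/y sex:M"),
    "Zrsr2^WT/mu female x Zrsr1^mu/mu male": (
        "Zrsr1:WT/WT Zrsr2:WT/mu sex:F", "Zrsr1:mu/mu Zrsr2:WT/y sex:M"),
}

for name, (m, f) in crosses.items():
    mother, father = parse_parent(m), parse_parent(f)
    vf = viable_fraction(mother, father)
    print(f"{name}\n  viable fraction: {vf:.2f}")
    spectrum = surviving_genotype_spectrum(mother, father)
    if spectrum:
        p_mu_carrier = sum(p for o, p in spectrum.items() if o.zrsr2_maternal == "mu")
        print(f"  P(survivor carries maternal mutant Zrsr2): {p_mu_carrier:.2f}")
# The first cross is fully arrested (0.00), the reciprocal fully viable
# (1.00), and heterozygous mothers never transmit the mutant Zrsr2 to a
# surviving pup (0.00) - the parent-of-origin asymmetry of the two genes.
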