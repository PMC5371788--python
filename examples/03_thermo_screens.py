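"""Thermodynamic and complementarity screens on single oligos.

Computes nearest-neighbor melting temperatures (with the 50 mM / 10 mM salt
conditions), duplex free energy, hairpin stems and self-complementarity for
a panel of bench-validated primers.
"""

import stitchkit as sk
from stitchkit.thermo import ThermoModel

primers = {
    "4F": "CGCAGAATGGAAGAAGAA",
    "16F": "TGTACCGTACTTCCAGTCCC",
    "1R": "CCGGTTGGAGGTGAAGAT",
    "3R": "GGTTGACGATTAAAGACGAT",
}

m50 = ThermoModel(salt_mM=50)
m10 = ThermoModel(salt_mM=10)
print(f"{'name':5s} {'Tm@50mM':>8s} {'Tm@10mM':>8s} {'selfW':>6s} {'3pm':>4s} {'stem':>5s}")
for name, seq in primers.items():
    rep = sk.self_complementarity(seq)
    hp = sk.hairpin_score(seq)
    print(
        f"{name:5s} {sk.melting_temperature(seq, m50):8.2f} "
        f"{sk.melting_temperature(seq, m10):8.2f} "
        f"{rep.weighted_score:6.1f} {rep.three_prime_matches:4d} {hp.score:5d}"
    )
# Tm drops ~11.6 C from 50 mM to 10 mM salt (16.6*log10 ratio); selfW is the
# weighted self-annealing score (matches, doubled near 3' ends, +1 if the
# best run is strong); stem is the longest hairpin stem with a >=3 nt loop.

# Cross-dimer check between a primer pair, tails included:
d = sk.dimer_score(primers["16F"], primers["1R"])
print(
    f"\n16F vs 1R cross-dimer: {d.total_matches} matches, longest run "
    f"{d.longest_run} (dG {d.run_dG:.2f} kcal/mol), weighted {d.weighted_score:.1f}"
)
print("duplex dG of GAATTC duplex:", round(sk.duplex_delta_g("GAATTC"), 2), "kcal/mol")
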