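"""Design primers at both ends of a sequence and list compatible pairs.

Builds a deterministic 1 kb test sequence, enumerates primer candidates in
the first and last 100 bp, filters them, and prints the passing primers and
the best compatible forward/reverse combinations.
"""

import stitchkit as sk

rec = sk.generate_fixture(seed=1, length=1000, gc_fraction=0.5)
params = sk.DesignParameters()  # 20-mers, 100 bp search areas, 2 bp steps

fwds = sk.enumerate_candidates(rec, params, "forward")
revs = sk.enumerate_candidates(rec, params, "reverse")

print(f"{len(fwds)} forward and {len(revs)} reverse candidates enumerated")
for cand in fwds + revs:
    if cand.passes:
        print(
            f"  {cand.name:4s} [{cand.start:4d},{cand.end:4d}] {cand.core_seq}  "
            f"GC {cand.gc_percent:4.1f}%  Tm {cand.tm_celsius:5.2f} C  "
            f"self {cand.self_report.weighted_score:4.1f}  "
            f"hairpin {cand.hairpin.score}"
        )

pairs = sk.compatible_pairs(
    fwds, revs, max_tm_diff=params.max_tm_diff, cutoffs=params.cutoffs
)
print(f"\n{len(pairs)} compatible pairs (dimer-quietest first):")
for p in pairs:
    print(
        f"  {p.fwd.name}+{p.rev.name}: product {p.product_len} bp, "
        f"dTm {p.tm_diff:.2f} C, cross-dimer score {p.pair_report.weighted_score:.1f}"
    )
# A pair is compatible when both primers pass their individual filters, the
# amplicon length is positive, the Tm gap is small and cross-dimer risk low.
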