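"""Build fusion primers carrying an overlap tail for overlapping PCR.

Fusion PCR stitches two amplicons through a primer whose 5' tail is
complementary to the partner fragment.  This script lists the bundled
overlap library, rebuilds a classic GFP-promoter fusion oligo, and attaches
a tail to freshly designed reverse primers.
"""

import stitchkit as sk

print("Bundled overlap fragments:")
for frag in sk.load_overlap_library().values():
    print(f"  {frag.name:36s} {frag.seq}")

# The C. elegans GFP tail reverse-complements to the forward primer used to
# amplify the GFP cassette itself -- that is what makes the two amplicons
# overlap:
tail = sk.get_overlap("GFP_Celegans")
print("\ntail               :", tail.seq)
print("rc(tail) == GFP-F  :", sk.reverse_complement(tail.seq))

# Tail + gene-specific core = the fusion oligo ordered from the synthesizer.
core = "GTGGTCGTGGGTTTGATG"  # myo-3 promoter-specific core
fusion = sk.build_fusion_primer(tail, core)
print(f"fusion primer      : {fusion}  ({len(tail.seq)} nt tail + {len(core)} nt core)")

# In a design run the tail rides on every reverse candidate; the overhang
# screen then checks the tail cannot anneal to its own primer or itself.
rec = sk.generate_fixture(seed=2, length=800)
params = sk.DesignParameters()
revs = sk.attach_overlap(
    sk.enumerate_candidates(rec, params, "reverse"), tail, params
)
best = next(c for c in revs if c.passes)
print(
    f"\nexample fusion reverse primer {best.name}: {best.full_seq}\n"
    f"  overhang screen score {best.overhang_report.weighted_score:.1f} "
    f"(cutoff {params.cutoffs.overhang_max})"
)
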