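"""Mutagenesis mode, pinned primers and the composition profile.

Site-directed mutagenesis by overlapping PCR needs the mutant oligo, its
reverse complement, and one flanking primer pair.  Users can also pin a
primer at exact coordinates (e.g. on an exon boundary) and have it scored
without being auto-rejected.
"""

import stitchkit as sk

rec = sk.generate_fixture(seed=3, length=600)
params = sk.DesignParameters(search_area_5p=80, search_area_3p=80)

mutant = "GATCCAGTTGCAGATTACA"  # the user's mutagenic forward oligo
fwd, rev, mutant_rev = sk.design_mutant_pair(rec, mutant, params)
print("mutant fwd oligo :", mutant)
print("mutant rev oligo :", mutant_rev, "(auto reverse complement)")
print(
    f"flanking pair    : {fwd.name} [{fwd.start},{fwd.end}] Tm {fwd.tm_celsius:.2f} C"
    f"  /  {rev.name} [{rev.start},{rev.end}] Tm {rev.tm_celsius:.2f} C"
)

pin = sk.score_pinned_primer(rec, 101, 120, "forward", params, name="exon1")
print(
    f"\npinned primer exon1 [{pin.start},{pin.end}]: {pin.core_seq}\n"
    f"  GC {pin.gc_percent:.1f}%  Tm {pin.tm_celsius:.2f} C  "
    f"fail reasons: {list(pin.fail_reasons) or 'none'}"
)
# Pinned primers keep their fail reasons as information only.

prof = sk.composition_profile(rec, window=100, step=100)
print("\nGC% in 100 bp windows:",
      [round(w.gc_percent, 1) for w in prof.windows])
print("global GC%:", round(prof.gc_percent_global, 2))
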