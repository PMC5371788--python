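# stitchkit

Primer design for **overlapping (fusion) PCR** — reporter-gene fusions,
adapter tagging, site-directed mutagenesis by overlap extension.  Given a
single DNA sequence, stitchkit enumerates forward and reverse primer
candidates inside user-set 5'/3' search areas, screens them with
nearest-neighbor thermodynamics and weighted complementarity scores,
attaches predefined or user-defined overlap tails, and emits primer
tables, compatible-pair tables, a composition profile and a primer map.

Who it is for: molecular biologists stitching DNA fragments together —
fusing a promoter to GFP, adding Illumina adapters, or introducing point
mutations — who want scriptable, auditable primer QC instead of a web
form.

## The model in brief

Melting temperature comes from the nearest-neighbor two-state model,

$$T_m = \frac{\Delta H^\circ \cdot 1000}{\Delta S^\circ + R\,\ln(C_T/4)} - 273.15 + 16.6\,\log_{10}[\mathrm{Na}^+],$$

with ΔH°/ΔS° summed over dinucleotide stacks (unified parameters by
default, Breslauer table selectable; both ship as editable TSVs) at 50 mM
monovalent salt (10 mM optional) and C_T = 250 nM.  Duplex ΔG° is
evaluated at 37 °C.  Every complementarity screen (self, 3', overhang,
cross-dimer) slides the two oligos antiparallel at every ungapped offset
and reports a weighted score

$$W = \text{matches} + (w_3-1)\cdot\text{3'-window matches} + \mathbf{1}\{\Delta G^\circ_{\text{best run}} < -6\ \text{kcal/mol}\},$$

so matches at extension-competent 3' ends count double and strongly
stacked runs earn a stability point.  Hairpins are scored by their maximal
stem length with a ≥3 nt loop.  See `docs/methods.md` for the full model,
parameter defaults and calibration.

## Worked example

```python
import stitchkit as sk

rec = sk.generate_fixture(seed=1, length=1000)     # or sk.read_fasta_path("my.fa")
params = sk.DesignParameters()                     # 20-mers, 100 bp areas, 2 bp step

fwds = sk.enumerate_candidates(rec, params, "forward")
revs = sk.enumerate_candidates(rec, params, "reverse")
pairs = sk.compatible_pairs(fwds, revs, max_tm_diff=params.max_tm_diff,
                            cutoffs=params.cutoffs)
best = pairs[0]
print(best.fwd.name, best.rev.name, best.product_len,
      round(best.tm_diff, 2), best.pair_report.weighted_score)
```

prints

```
F24 R25 906 2.27 5.0
```

meaning: forward primer F24 and reverse primer R25 are the
quietest-dimerizing compatible pair (cross-dimer weighted score 5.0), they
amplify a 906 bp product and their melting temperatures differ by 2.27 °C.

Building the classic promoter→GFP fusion oligo:

```python
tail = sk.get_overlap("GFP_Celegans")              # 24 nt overlap fragment
sk.build_fusion_primer(tail, "GTGGTCGTGGGTTTGATG")
# -> 'AGTCGACCTGCAGGCATGCAAGCTGTGGTCGTGGGTTTGATG'
```

The tail's reverse complement (`AGCTTGCATGCCTGCAGGTCGACT`) is exactly the
forward primer that amplifies the GFP cassette — that shared sequence is
what lets the two amplicons anneal and extend into the fusion product.

More narrative walkthroughs live in `examples/` (candidate design, fusion
overlaps, thermodynamic screens, mutagenesis and pinned primers); each is
a runnable script that prints what it computes.

## Command line

```sh
stitchkit design input.fa --area5 150 --area3 150 --overlap GFP \
    --outputs all --out results/
stitchkit overlaps        # list the bundled overlap-fragment library
stitchkit tm CGCAGAATGGAAGAAGAA
```

`stitchkit design` mirrors every library parameter (sizes, search areas,
GC/Tm bounds, salt, clamps, increments, score cutoffs, N removal, repeat
filter, overlap/mutant modes, pinned primers) and writes TSV/JSON tables
plus a BED primer map.

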