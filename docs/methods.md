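# Methods

## Scope and model

stitchkit designs primers for overlapping (fusion) PCR from a single DNA
sequence.  Two amplicons are joined by giving one primer a 5' tail (the
*overlap fragment*) that is the reverse complement of the partner
fragment's terminal primer; after separate amplifications the tailed
products anneal through the shared overlap and extend into the fused
product.  The library therefore does four things: enumerate candidate
primers near the sequence ends, screen them thermodynamically, attach
overlap tails, and enumerate compatible forward/reverse pairs.

## Melting temperature

Tm uses the two-state nearest-neighbor model:

    Tm = ΔH·1000 / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10([Na+])

with ΔH (kcal/mol) and ΔS (cal/mol·K) summed over dinucleotide stacks plus
duplex-initiation terms, R = 1.987 cal/(mol·K), total strand concentration
C_T (non-self-complementary duplex, hence C_T/4), and the classic
Schildkraut–Lifson monovalent-salt correction.  The default parameter set
is the unified table (SantaLucia 1998) with per-terminal A·T / G·C
initiation terms; the Breslauer 1986 table (one-shot −10.8 cal/mol·K
initiation entropy) is selectable.  Both ship as plain-text TSV files under
`stitchkit/data/` so the tables are auditable and swappable.

Defaults: 50 mM Na+ (10 mM is the second supported condition; any positive
value is accepted programmatically) and C_T = 250 nM, a common
design-tool default.  No Mg2+/dNTP correction, dangling ends or terminal
mismatch terms are modelled.  Note that 16.6·log10(0.05) ≈ −21.6 °C, so
absolute values on this scale sit well below wet-lab annealing
temperatures; it is the scale's *internal consistency* that matters for
ranking and pairing, and it tracks other unified-parameter implementations
essentially exactly (the acceptance script measures R² against an
independent implementation over 544 primers).

Duplex ΔG° is evaluated at 37 °C as ΔH − T·ΔS over the same tables.
Standalone duplex calls include initiation; the best-run ΔG° inside
complementarity scans is stacking-only, because a short matched run sits
inside a longer, already-initiated heteroduplex.

## Complementarity screens

All screens use the same primitive: slide oligo *a* (5'→3') against oligo
*b* (3'→5') at every ungapped offset and keep the offset with the most
Watson–Crick matches; ties prefer the longer contiguous run, then the
smaller signed offset (determinism).  Gapless scanning is the standard
regime for primer QC and keeps the exhaustive oracle O(n²).

The weighted score is

    W = matches + (w₃−1)·three_prime_matches + 1{ΔG°(best run) < −6 kcal/mol}

with a 5-base 3' window and w₃ = 2 by default: matches near an
extension-competent 3' terminus are doubly dangerous, and one point is
added when the best run is thermodynamically strong.  This form was chosen
as the simplest score combining the three signals that matter (raw
complementarity, 3' placement, run stability) with one tunable each.

Screens: *self* (primer vs itself), *3'* (terminal-window matches), 
*overhang* (tail vs its own core, vs itself and, when known, vs the
partner primer — worst case reported), *dimer* (forward vs reverse full
sequences, tails included, since tails participate in real cross-dimers).

### Cutoff calibration

The score cutoffs have no published values; they were calibrated once so
that every bench-validated design in the source system's validation panel
passes its screen: eight validated primers reach self-weighted 16 and
3'-window 6, validated pairs reach cross-dimer 14, and the validated
GFP-fusion overlap scores 16 on the overhang screen.  Defaults are
therefore self ≤ 16, 3' ≤ 6, overhang ≤ 16, dimer ≤ 14, all exposed as
flags for stricter designs.

## Hairpins

The hairpin screen finds the maximal stem: the longest L such that
`seq[i:i+L]` equals the reverse complement of a downstream run with at
least `min_loop` (default 3) unpaired bases between the arms.  The score
is the stem length — a per-primer scalar — with the stem's stacking ΔG°
reported alongside; candidates fail when the stem exceeds `hairpin_max`
(default 4, a separate parameter because the score is a length, not a
weighted match count).  The implementation is exact (anchor-pair
extension, O(n³)) and is tested against an O(n⁴) enumeration.

## Candidate enumeration and filters

Forward windows of `fwd_size` start at offsets 0, inc, 2·inc, … while they
fit inside the 5' search area; reverse windows step identically inward
from the 3' end and are reverse-complemented.  The candidate count is
exactly `floor((area − size)/inc) + 1`.  Primer sizes constrain the
gene-specific core only — an overlap tail never counts toward the size.

Filters annotate rather than drop: each violated rule appends one fail
reason (`gc_range`, `tm_range`, `gc_clamp`, `repetitive`,
`self_complementarity`, `three_prime`, `hairpin`, `overhang`,
`ambiguous_base`), so reports can show near-misses.  The GC clamp, when
enabled (off by default), requires a G or C at the 3' terminus — the
simplest standard definition.  Repetitive sequence is a homopolymer run of
≥ 4 bases or ≥ 4 consecutive identical dinucleotide units (8 nt);
three units (e.g. CGCGCG) pass.  Candidates overlapping an excised-N
position are annotated (`spans_removed_n`), not rejected.  Default Tm
bounds are 40–60 °C, bracketing the validated primer panel (42.2–49.4 °C)
on this Tm scale; default GC bounds 30–70%.

Mutagenesis mode reverse-complements the user's forward mutant oligo and
returns one flanking pair: the best passing candidate per area, ranked by
(weighted self score, |Tm − midpoint of the Tm bounds|, proximity to the
sequence end) — a deterministic ordering.  When nothing passes, the error
names the best near-miss and its fail reasons.

## Pairing

Every forward×reverse combination is evaluated.  Compatibility requires:
both primers pass individually, the reverse primer lies 3' of the forward
one (product length = rev.end − fwd.start + 1 > 0), |ΔTm| ≤ 5 °C (a
conventional pairing tolerance, flag-exposed), and a cross-dimer weighted
score within the cutoff.  Pairs are sorted by (dimer score ascending,
product length descending).  Raising any cutoff can only grow the
compatible set (tested as a monotonicity property).

## Input handling and reports

FASTA parsing (one record only, mixed case accepted, blank lines ignored,
gaps rejected) goes through Biopython; the accepted alphabet is
A/C/G/T/N — other IUPAC ambiguity codes are rejected because no screen can
score them.  N removal excises ambiguous bases and records their original
1-based positions.  Composition profiling reports per-base counts and
sliding windows of GC%/AT% (window 50, step 1 by default; the resolution is
a free choice exposed as flags); a final partial window is flagged.

Coordinates are 0-based half-open internally and 1-based inclusive in all
tables; the primer map is additionally written as BED (0-based half-open).
Tables are UTF-8 TSV with header rows and '.' decimals; the JSON bundle
mirrors the tables row for row.  Summaries report min/average/max of GC%,
Tm, weighted self score, start, length and hairpin score over *passing*
candidates only, per strand; an empty set yields an explicitly empty
summary.

## Synthetic fixtures

`generate_fixture` draws i.i.d. bases with P(G or C) = `gc_fraction`
(default 0.5) and optionally plants N bases and a repeat at reproducible
interior positions; the same seed always yields the same record.  It
emulates composition only — no genes, no repeats beyond those planted, no
homology structure — so passing tests demonstrate correctness of the
algorithms on realistic base composition, not primer performance on any
particular genome.  The test suite and worked examples use a 1 kb fixture
at 50% GC; the acceptance script scores 544 random primers of 18–25 nt
and 30–70% GC, the batch size used in the original Tm-concordance
comparison.

## Known limitations

- Two-state NN model only: no Mg2+, dNTP or dangling-end corrections, no
  partition-function secondary structure.
- Gapless complementarity: bulged dimers/hairpins are invisible.
- Single-sequence input; no multi-fragment assembly planning (the overlap
  library plus pair tables cover the two-fragment fusion workflow).
- The weighted-score form and cutoff magnitudes are this package's own
  calibration (see above); they rank designs sensibly but are not
  thermodynamic probabilities.
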