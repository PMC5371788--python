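"""Primer candidate enumeration and filtering.

Candidates are enumerated by stepping a fixed-size window inward from each
sequence end (5' search area for forward primers, 3' for reverse) at a
user-set increment, then annotated with GC%, Tm, self-complementarity,
3'-complementarity and hairpin metrics.  Filtering never drops a candidate:
each violated rule appends a fail reason, so reports can show near-misses.

Mutagenesis mode takes a forward mutant oligo, emits its reverse complement,
and picks the single best-scoring flanking primer from each search area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import re

from . import complementarity as comp
from . import thermo
from .complementarity import ComplementarityReport, ScoreCutoffs
from .errors import DesignFailureError, ParameterError
from .sequence_io import InputSequence, gc_percent, reverse_complement

_HOMOPOLYMER = re.compile(r"([ACGT])\1{3}")       # 4+ identical bases
_DINUC_REPEAT = re.compile(r"([ACGT]{2})\1{3}")   # 4+ identical dinucleotide units


@dataclass(frozen=True)
class DesignParameters:
    """Every tunable of the design form, with defaults.

    Sizes constrain the gene-specific core only; an attached overlap tail
    does not count toward ``fwd_size``/``rev_size``.  Search areas are
    measured from the respective sequence ends.  Salt defaults to 50 mM with
    10 mM as the alternative supported condition.
    """

    design_forward: bool = True
    design_reverse: bool = True
    fwd_size: int = 20
    rev_size: int = 20
    search_area_5p: int = 100
    search_area_3p: int = 100
    gc_min: float = 30.0
    gc_max: float = 70.0
    tm_min: float = 40.0
    tm_max: float = 60.0
    salt_mM: float = 50.0
    primer_conc_nM: float = 250.0
    gc_clamp_fwd: bool = False
    gc_clamp_rev: bool = False
    increment_fwd: int = 2
    increment_rev: int = 2
    cutoffs: ScoreCutoffs = field(default_factory=ScoreCutoffs)
    hairpin_max: int = 4
    min_hairpin_loop: int = 3
    remove_n: bool = False
    exclude_repeats: bool = True
    max_tm_diff: float = 5.0
    thermo_table: str = "santalucia1998"

    def __post_init__(self):
        if self.fwd_size < 8 or self.rev_size < 8:
            raise ParameterError("primer sizes must be >= 8 nt")
        if self.increment_fwd < 1 or self.increment_rev < 1:
            raise ParameterError("increments must be >= 1")
        if self.gc_min > self.gc_max:
            raise ParameterError("gc_min must not exceed gc_max")
        if self.tm_min > self.tm_max:
            raise ParameterError("tm_min must not exceed tm_max")

    def thermo_model(self) -> thermo.ThermoModel:
        return thermo.ThermoModel(
            table_name=self.thermo_table,
            salt_mM=self.salt_mM,
            primer_conc_nM=self.primer_conc_nM,
        )


@dataclass(frozen=True)
class PrimerCandidate:
    """An annotated primer window.

    ``start``/``end`` are 1-based inclusive coordinates of the core on the
    input's forward strand; a reverse candidate's ``core_seq`` is the
    reverse complement of that slice.  ``full_seq`` prepends any overlap
    tail at the 5' end.
    """

    name: str
    strand: str  # "forward" | "reverse"
    core_seq: str
    start: int
    end: int
    overlap_seq: str = ""
    overlap_name: str = ""
    gc_percent: float = 0.0
    tm_celsius: float | None = None
    self_report: ComplementarityReport | None = None
    hairpin: thermo.HairpinResult | None = None
    overhang_report: ComplementarityReport | None = None
    spans_removed_n: bool = False
    fail_reasons: tuple[str, ...] = ()

    @property
    def full_seq(self) -> str:
        return self.overlap_seq + self.core_seq

    @property
    def passes(self) -> bool:
        return not self.fail_reasons


def is_repetitive(seq: str) -> bool:
    """True iff the sequence contains a homopolymer run of >= 4 bases
    (e.g. CCCC, TTTT) or >= 4 consecutive identical dinucleotide units
    (e.g. CGCGCGCG, TGTGTGTG)."""
    seq = seq.upper()
    return bool(_HOMOPOLYMER.search(seq) or _DINUC_REPEAT.search(seq))


def _annotate(
    cand: PrimerCandidate, params: DesignParameters, model: thermo.ThermoModel
) -> PrimerCandidate:
    core = cand.core_seq
    gc = gc_percent(core)
    tm = None
    self_rep = None
    hp = None
    if "N" not in core:
        tm = thermo.melting_temperature(core, model)
        self_rep = comp.self_complementarity(core, model=model)
        hp = thermo.hairpin_score(core, params.min_hairpin_loop, model)
    return replace(
        cand, gc_percent=gc, tm_celsius=tm, self_report=self_rep, hairpin=hp
    )


def passes_filters(
    cand: PrimerCandidate, params: DesignParameters
) -> PrimerCandidate:
    """Append one fail reason per violated rule; never drop the candidate."""
    reasons: list[str] = []
    core = cand.core_seq
    if "N" in core:
        reasons.append("ambiguous_base")
    if not (params.gc_min <= cand.gc_percent <= params.gc_max):
        reasons.append("gc_range")
    if cand.tm_celsius is not None and not (
        params.tm_min <= cand.tm_celsius <= params.tm_max
    ):
        reasons.append("tm_range")
    clamp_on = (
        params.gc_clamp_fwd if cand.strand == "forward" else params.gc_clamp_rev
    )
    if clamp_on and core[-1] not in "GC":
        reasons.append("gc_clamp")
    if params.exclude_repeats and is_repetitive(core):
        reasons.append("repetitive")
    if cand.self_report is not None:
        if cand.self_report.weighted_score > params.cutoffs.self_max:
            reasons.append("self_complementarity")
        if cand.self_report.three_prime_matches > params.cutoffs.three_prime_max:
            reasons.append("three_prime")
    if cand.hairpin is not None and cand.hairpin.score > params.hairpin_max:
        reasons.append("hairpin")
    if (
        cand.overhang_report is not None
        and cand.overhang_report.weighted_score > params.cutoffs.overhang_max
    ):
        reasons.append("overhang")
    return replace(cand, fail_reasons=tuple(reasons))


def candidate_count(area: int, size: int, increment: int) -> int:
    """Closed-form number of windows: floor((area - size) / inc) + 1."""
    if area < size:
        raise ParameterError(
            f"search area ({area}) is smaller than the primer size ({size})"
        )
    return (area - size) // increment + 1


def enumerate_candidates(
    rec: InputSequence,
    params: DesignParameters,
    strand: str,
    annotate: bool = True,
) -> list[PrimerCandidate]:
    """All annotated primer windows for one strand.

    Forward windows start at offsets 0, inc, 2*inc, ... within the 5'
    search area; reverse windows step identically inward from the 3' end
    within the 3' search area and are reverse-complemented.  With
    ``annotate=False`` only coordinates and sequences are filled in (fast
    path for counting and mapping).
    """
    if strand not in ("forward", "reverse"):
        raise ParameterError(f"strand must be 'forward' or 'reverse', not {strand!r}")
    fwd = strand == "forward"
    size = params.fwd_size if fwd else params.rev_size
    area = params.search_area_5p if fwd else params.search_area_3p
    inc = params.increment_fwd if fwd else params.increment_rev
    if area > rec.length:
        raise ParameterError(
            f"search area ({area}) exceeds the sequence length ({rec.length})"
        )
    n = candidate_count(area, size, inc)
    model = params.thermo_model()
    removed = set(rec.removed_n_positions)
    out: list[PrimerCandidate] = []
    for k in range(n):
        off = k * inc
        if fwd:
            start0 = off
            slice_ = rec.seq[start0:start0 + size]
            core = slice_
            name = f"F{k + 1}"
        else:
            start0 = rec.length - size - off
            slice_ = rec.seq[start0:start0 + size]
            core = reverse_complement(slice_)
            name = f"R{k + 1}"
        start, end = start0 + 1, start0 + size
        spans_n = any(start <= p <= end for p in removed)
        cand = PrimerCandidate(
            name=name, strand=strand, core_seq=core,
            start=start, end=end, spans_removed_n=spans_n,
        )
        if annotate:
            cand = passes_filters(_annotate(cand, params, model), params)
        out.append(cand)
    return out


def _rank_key(cand: PrimerCandidate, params: DesignParameters):
    tm_mid = (params.tm_min + params.tm_max) / 2.0
    self_w = cand.self_report.weighted_score if cand.self_report else 0.0
    tm_dev = abs((cand.tm_celsius or tm_mid) - tm_mid)
    # proximity to the relevant sequence end: smaller start for forward,
    # larger end for reverse (encoded as the enumeration order via name)
    edge = cand.start if cand.strand == "forward" else -cand.end
    return (self_w, tm_dev, edge)


def best_candidate(
    cands: list[PrimerCandidate], params: DesignParameters
) -> PrimerCandidate:
    passing = [c for c in cands if c.passes]
    if not passing:
        near = min(cands, key=lambda c: len(c.fail_reasons)) if cands else None
        detail = (
            f"; best near-miss {near.name} at [{near.start},{near.end}] "
            f"failed: {', '.join(near.fail_reasons)}"
            if near else ""
        )
        raise DesignFailureError(f"no candidate passed all filters{detail}")
    return min(passing, key=lambda c: _rank_key(c, params))


def design_mutant_pair(
    rec: InputSequence,
    mutant_fwd: str,
    params: DesignParameters,
) -> tuple[PrimerCandidate, PrimerCandidate, str]:
    """Mutagenesis mode: reverse mutant oligo plus one flanking primer pair.

    Returns (best forward primer from the 5' area, best reverse primer from
    the 3' area, reverse complement of the mutant oligo).
    """
    if not mutant_fwd:
        raise ParameterError("mutant oligo must be non-empty")
    mutant_rev = reverse_complement(mutant_fwd.upper())
    fwd = best_candidate(enumerate_candidates(rec, params, "forward"), params)
    rev = best_candidate(enumerate_candidates(rec, params, "reverse"), params)
    return fwd, rev, mutant_rev
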