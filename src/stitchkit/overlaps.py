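"""Overlap-fragment library, fusion-primer construction and pair tables.

Fusion PCR joins two amplicons through a primer carrying a 5' tail (the
overlap fragment) complementary to the partner fragment.  A library of
commonly used tails (fluorophore anchors, Illumina adapters) ships as a
two-column TSV that users can extend; user-defined tails are plain strings.
Overlap tails attach to reverse primers, matching the convention that the
user-supplied overlap serves the reverse primer of the upstream amplicon.

`compatible_pairs` evaluates every forward x reverse combination for
orientation, product size, Tm balance and cross-dimer risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

from . import complementarity as comp
from . import thermo
from .complementarity import ComplementarityReport, ScoreCutoffs
from .design import DesignParameters, PrimerCandidate, passes_filters
from .errors import StitchkitError, UnknownOverlapError
from .sequence_io import DNA_ALPHABET


@dataclass(frozen=True)
class OverlapFragment:
    name: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise StitchkitError(f"overlap fragment {self.name!r} has no sequence")
        bad = set(self.seq) - (DNA_ALPHABET - {"N"})
        if bad:
            raise StitchkitError(
                f"overlap fragment {self.name!r} contains invalid characters: "
                f"{', '.join(sorted(bad))}"
            )


def load_overlap_library(path=None) -> dict[str, OverlapFragment]:
    """Load the overlap library (bundled file by default)."""
    if path is None:
        text = resources.files("stitchkit.data").joinpath("overlaps.tsv").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lib: dict[str, OverlapFragment] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        name, seq = line.split("\t")
        if name in lib:
            raise StitchkitError(f"duplicate overlap name {name!r} in library")
        lib[name] = OverlapFragment(name=name, seq=seq.upper())
    return lib


_LIBRARY: dict[str, OverlapFragment] | None = None


def get_overlap(name: str) -> OverlapFragment:
    """Look up a predefined overlap fragment by name."""
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = load_overlap_library()
    try:
        return _LIBRARY[name]
    except KeyError:
        raise UnknownOverlapError(name, sorted(_LIBRARY)) from None


def build_fusion_primer(overlap: OverlapFragment | str, core: str) -> str:
    """Concatenate the overlap tail (5') with the gene-specific core (3').

    Primer-size parameters constrain the core only, never the full fusion
    oligo.  An empty overlap returns the core unchanged.
    """
    if not core:
        raise StitchkitError("fusion primer needs a non-empty core")
    tail = overlap.seq if isinstance(overlap, OverlapFragment) else (overlap or "")
    return tail.upper() + core.upper()


def attach_overlap(
    cands: list[PrimerCandidate],
    overlap: OverlapFragment | str,
    params: DesignParameters,
) -> list[PrimerCandidate]:
    """Attach a 5' overlap tail to candidates and re-screen.

    Adds the overhang-complementarity report (tail vs its own core and vs
    itself) and re-runs the filters so an `overhang` fail reason can appear.
    """
    if isinstance(overlap, str):
        overlap = OverlapFragment(name="user_defined", seq=overlap.upper())
    model = params.thermo_model()
    out = []
    for c in cands:
        rep = (
            comp.overhang_score(overlap.seq, c.core_seq, model=model)
            if "N" not in c.core_seq else None
        )
        c2 = replace(c, overlap_seq=overlap.seq, overlap_name=overlap.name,
                     overhang_report=rep)
        out.append(passes_filters(c2, params))
    return out


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse combination with joint metrics."""

    fwd: PrimerCandidate
    rev: PrimerCandidate
    product_len: int
    tm_diff: float
    pair_report: ComplementarityReport
    compatible: bool
    incompatibility: tuple[str, ...] = ()


def evaluate_pair(
    fwd: PrimerCandidate,
    rev: PrimerCandidate,
    max_tm_diff: float,
    cutoffs: ScoreCutoffs,
    model: thermo.ThermoModel = thermo.DEFAULT_MODEL,
) -> PrimerPair:
    """Joint metrics and the compatibility verdict for one combination.

    Dimer scanning uses the full sequences (overlap tails included) since
    tails participate in real cross-dimers.
    """
    product_len = rev.end - fwd.start + 1
    tm_f = fwd.tm_celsius
    tm_r = rev.tm_celsius
    tm_diff = abs(tm_f - tm_r) if tm_f is not None and tm_r is not None else float("inf")
    report = comp.dimer_score(fwd.full_seq, rev.full_seq, model=model)
    problems = []
    if not fwd.passes:
        problems.append("fwd_fails_filters")
    if not rev.passes:
        problems.append("rev_fails_filters")
    if product_len <= 0:
        problems.append("orientation")
    if tm_diff > max_tm_diff:
        problems.append("tm_diff")
    if report.weighted_score > cutoffs.dimer_max:
        problems.append("dimer")
    return PrimerPair(
        fwd=fwd, rev=rev, product_len=product_len, tm_diff=tm_diff,
        pair_report=report, compatible=not problems,
        incompatibility=tuple(problems),
    )


def compatible_pairs(
    fwds: list[PrimerCandidate],
    revs: list[PrimerCandidate],
    max_tm_diff: float = 5.0,
    cutoffs: ScoreCutoffs | None = None,
    model: thermo.ThermoModel = thermo.DEFAULT_MODEL,
    include_incompatible: bool = False,
) -> list[PrimerPair]:
    """Evaluate all forward x reverse combinations.

    Compatible pairs require both primers to pass their individual filters,
    the reverse primer to lie 3' of the forward one (positive product
    length), a Tm difference within ``max_tm_diff`` and a cross-dimer
    weighted score at or below ``cutoffs.dimer_max``.  Sorted by (dimer
    weighted score ascending, product length descending).
    """
    cutoffs = cutoffs or ScoreCutoffs()
    pairs = [
        evaluate_pair(f, r, max_tm_diff, cutoffs, model)
        for f in fwds for r in revs
    ]
    if not include_incompatible:
        pairs = [p for p in pairs if p.compatible]
    pairs.sort(key=lambda p: (p.pair_report.weighted_score, -p.product_len))
    return pairs
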