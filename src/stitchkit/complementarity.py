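"""Ungapped complementarity scoring for primer screening.

Two oligos are slid against each other in antiparallel orientation at every
possible offset; the best offset is the one with the most Watson-Crick
matches (ties: longer contiguous run, then smaller offset).  From that
alignment we report the match count, the longest perfectly paired run and
its stacking free energy, the number of matches falling near either 3' end,
and a weighted score:

    W = matches + (w3 - 1) * three_prime_matches + [run_dG < -6 kcal/mol]

The extra weight on 3'-window matches (window 5, weight 2 by default)
penalises extension-competent annealing; the single stability bonus fires
when the best run is thermodynamically strong.  Self-complementarity,
overhang complementarity and primer-dimer screens are all instances of the
same scan.  Scanning is gapless, the standard regime for primer QC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import thermo
from .errors import StitchkitError

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

#: size of the terminal window emphasised by the weighted score, in bases
THREE_PRIME_WINDOW = 5
#: multiplier applied to matches inside the 3' window
THREE_PRIME_WEIGHT = 2.0
#: best-run stability threshold (kcal/mol) granting the +1 bonus
STABILITY_DG_THRESHOLD = -6.0


@dataclass(frozen=True)
class ComplementarityReport:
    """Scan result for one oligo against another (or itself)."""

    best_offset: int
    total_matches: int
    longest_run: int
    run_seq: str
    run_dG: float
    three_prime_matches: int
    weighted_score: float

    def exceeds(self, cutoff: float) -> bool:
        return self.weighted_score > cutoff


@dataclass(frozen=True)
class ScoreCutoffs:
    """Maximum tolerated weighted scores per screen; user-overridable.

    Defaults are calibrated so that every wet-lab-validated primer, primer
    pair and fusion overlap passes its screen (see the methods note); make
    them smaller for more stringent designs.
    """

    self_max: float = 16.0
    three_prime_max: float = 6.0
    overhang_max: float = 16.0
    dimer_max: float = 14.0

    def __post_init__(self):
        for name in ("self_max", "three_prime_max", "overhang_max", "dimer_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _matches_at_offset(a: str, b_rev: str, offset: int) -> list[int]:
    """Indices i of ``a`` matched when a[i] faces b_rev[offset + i]."""
    out = []
    nb = len(b_rev)
    for i in range(len(a)):
        j = offset + i
        if 0 <= j < nb and (a[i], b_rev[j]) in WC_PAIRS:
            out.append(i)
    return out


def _longest_run(match_idx: list[int]) -> tuple[int, int]:
    """(length, start index within a) of the longest consecutive stretch."""
    best_len = best_start = 0
    cur_len = 0
    cur_start = 0
    prev = None
    for i in match_idx:
        if prev is not None and i == prev + 1:
            cur_len += 1
        else:
            cur_start, cur_len = i, 1
        if cur_len > best_len:
            best_len, best_start = cur_len, cur_start
        prev = i
    return best_len, best_start


def complementarity_scan(
    a: str,
    b: str,
    three_prime_window: int = THREE_PRIME_WINDOW,
    three_prime_weight: float = THREE_PRIME_WEIGHT,
    model: thermo.ThermoModel = thermo.DEFAULT_MODEL,
) -> ComplementarityReport:
    """Best ungapped antiparallel alignment of ``a`` (5'->3') against ``b``.

    ``b`` is read 3'->5' (i.e. reversed) so each aligned column is a
    potential Watson-Crick pair.  Offsets run over every sliding with at
    least one overlapping column.
    """
    if not a or not b:
        raise StitchkitError("complementarity_scan requires non-empty sequences")
    a = a.upper()
    b_rev = b.upper()[::-1]
    best_key = None
    best = None
    for offset in range(-(len(a) - 1), len(b_rev)):
        idx = _matches_at_offset(a, b_rev, offset)
        run_len, _ = _longest_run(idx)
        key = (len(idx), run_len, -offset)
        if best_key is None or key > best_key:
            best_key = key
            best = offset
    idx = _matches_at_offset(a, b_rev, best)
    run_len, run_start = _longest_run(idx)
    run_seq = a[run_start:run_start + run_len]
    try:
        run_dg = (
            thermo.duplex_delta_g(run_seq, model, include_initiation=False)
            if run_len > 0 else 0.0
        )
    except StitchkitError:
        run_dg = 0.0
    tp = _three_prime_count(idx, best, len(a), len(b_rev), three_prime_window)
    weighted = _weighted(len(idx), tp, run_dg, three_prime_weight)
    return ComplementarityReport(
        best_offset=best,
        total_matches=len(idx),
        longest_run=run_len,
        run_seq=run_seq,
        run_dG=run_dg,
        three_prime_matches=tp,
        weighted_score=weighted,
    )


def _three_prime_count(
    match_idx: list[int], offset: int, len_a: int, len_b: int, window: int
) -> int:
    """Matches within ``window`` bases of either oligo's 3' terminus.

    a's 3' end is its last ``window`` positions; b's 3' end maps to the
    first ``window`` positions of the reversed strand.
    """
    if window <= 0:
        return 0
    count = 0
    for i in match_idx:
        in_a_3p = i >= len_a - window
        in_b_3p = (offset + i) < window
        if in_a_3p or in_b_3p:
            count += 1
    return count


def _weighted(matches: int, tp: int, run_dg: float, w3: float) -> float:
    if matches == 0:
        return 0.0
    score = matches + (w3 - 1.0) * tp
    if run_dg < STABILITY_DG_THRESHOLD:
        score += 1.0
    return score


def weighted_score(
    report: ComplementarityReport, three_prime_weight: float = THREE_PRIME_WEIGHT
) -> float:
    """Recompute the weighted score of a report with a different 3' weight."""
    return _weighted(
        report.total_matches,
        report.three_prime_matches,
        report.run_dG,
        three_prime_weight,
    )


def self_complementarity(p: str, **kwargs) -> ComplementarityReport:
    """Scan a primer against another copy of itself."""
    return complementarity_scan(p, p, **kwargs)


def three_prime_score(a: str, b: str, window: int = THREE_PRIME_WINDOW) -> int:
    """Matched positions near either 3' terminus at the best offset."""
    if window < 0:
        raise StitchkitError("window must be non-negative")
    if window == 0:
        return 0
    return complementarity_scan(a, b, three_prime_window=window).three_prime_matches


def dimer_score(a: str, b: str, **kwargs) -> ComplementarityReport:
    """Cross-dimer scan between two (full, overlap-included) primers."""
    return complementarity_scan(a, b, **kwargs)


def overhang_score(
    overlap: str, core: str, partner: str | None = None, **kwargs
) -> ComplementarityReport:
    """Worst-case annealing of an overlap tail.

    The tail is scanned against its own primer core, against itself, and —
    when known — against the partner primer; the highest weighted score
    (worst case) is returned.
    """
    if not overlap:
        raise StitchkitError("overhang_score requires a non-empty overlap")
    reports = [
        complementarity_scan(overlap, core, **kwargs),
        complementarity_scan(overlap, overlap, **kwargs),
    ]
    if partner:
        reports.append(complementarity_scan(overlap, partner, **kwargs))
    return max(reports, key=lambda r: r.weighted_score)
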