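"""Read, validate and clean the single FASTA input sequence.

The design engine operates on one DNA record at a time.  This module parses
FASTA text (via Bio.SeqIO), enforces the A/C/G/T/N alphabet, optionally
excises ambiguous N bases while recording their original positions, and
provides reverse-complement and sliding-window composition analysis.

Coordinates are 0-based half-open internally; every user-facing report uses
1-based inclusive coordinates (bench convention).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import (
    InvalidAlphabetError,
    MalformedFastaError,
    MultipleRecordsError,
    ParameterError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class InputSequence:
    """A validated, cleaned DNA record.

    ``removed_n_positions`` holds the original 1-based positions of any N
    bases excised by :func:`clean_sequence`, so downstream coordinates can be
    traced back to the raw input.
    """

    id: str
    seq: str
    description: str = ""
    removed_n_positions: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self):
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise InvalidAlphabetError(
                f"sequence {self.id!r} contains non-DNA characters: "
                f"{', '.join(sorted(bad))} (allowed: A,C,G,T,N)"
            )
        if list(self.removed_n_positions) != sorted(set(self.removed_n_positions)):
            raise ValueError("removed_n_positions must be strictly increasing")


@dataclass(frozen=True)
class Window:
    """One sliding window; coordinates 1-based inclusive."""

    start: int
    end: int
    gc_percent: float
    at_percent: float
    partial: bool = False


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict[str, int]
    gc_percent_global: float
    windows: tuple[Window, ...]
    window_size: int
    step: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "start": w.start,
                "end": w.end,
                "gc_percent": round(w.gc_percent, 2),
                "at_percent": round(w.at_percent, 2),
                "partial": int(w.partial),
            }
            for w in self.windows
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "gc_percent_global": round(self.gc_percent_global, 4),
                "window_size": self.window_size,
                "step": self.step,
                "windows": self.to_rows(),
            },
            indent=1,
        )


def read_fasta(text: str) -> InputSequence:
    """Parse FASTA text holding exactly one DNA record.

    Case and line breaks are normalised; blank lines are ignored; the
    description after the first whitespace of the header is kept as metadata.
    Alignment gaps (``-``) and any character outside A/C/G/T/N are rejected.
    """
    if not text or not text.strip():
        raise MalformedFastaError("empty input")
    stripped = text.lstrip()
    if not stripped.startswith(">"):
        raise MalformedFastaError("no FASTA header line (expected '>')")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise MalformedFastaError("no sequence record found")
    if len(records) > 1:
        raise MultipleRecordsError(
            f"input holds {len(records)} records; exactly one sequence is required"
        )
    rec = records[0]
    seq = "".join(str(rec.seq).split()).upper()
    desc = rec.description[len(rec.id):].strip() if rec.description else ""
    return InputSequence(id=rec.id, seq=seq, description=desc)


def read_fasta_path(path) -> InputSequence:
    with open(path, encoding="utf-8") as fh:
        return read_fasta(fh.read())


def clean_sequence(rec: InputSequence, remove_n: bool = True) -> InputSequence:
    """Excise N bases (recording 1-based positions) or just report them."""
    if not remove_n:
        return rec  # unchanged; positions surfaced via find_n_positions
    n_positions = tuple(i + 1 for i, b in enumerate(rec.seq) if b == "N")
    return InputSequence(
        id=rec.id,
        seq=rec.seq.replace("N", ""),
        description=rec.description,
        removed_n_positions=n_positions,
    )


def find_n_positions(rec: InputSequence) -> tuple[int, ...]:
    """1-based positions of N bases present in the record."""
    return tuple(i + 1 for i, b in enumerate(rec.seq) if b == "N")


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"cannot reverse-complement characters: {', '.join(sorted(bad))}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def composition_profile(
    rec: InputSequence, window: int = 50, step: int = 1
) -> CompositionProfile:
    """Per-base counts plus sliding windows of GC% and AT%.

    Full windows tile ``[1, length]`` at the given step; if they do not reach
    the 3' end, one final partial window (flagged) completes the coverage.
    Windows containing N sum to less than 100% GC+AT.
    """
    length = rec.length
    if window < 1 or window > length:
        raise ParameterError(
            f"window size {window} must be in [1, sequence length {length}]"
        )
    if step < 1:
        raise ParameterError("step must be >= 1")

    counts = {b: rec.seq.count(b) for b in "ACGTN"}
    windows: list[Window] = []
    start = 0  # 0-based
    last_full_start = length - window
    while start <= last_full_start:
        sub = rec.seq[start:start + window]
        windows.append(Window(
            start=start + 1, end=start + window,
            gc_percent=gc_percent(sub),
            at_percent=100.0 * sum(sub.count(b) for b in "AT") / window,
        ))
        start += step
    if windows and windows[-1].end < length:
        sub = rec.seq[start:]
        windows.append(Window(
            start=start + 1, end=length,
            gc_percent=gc_percent(sub),
            at_percent=100.0 * sum(sub.count(b) for b in "AT") / len(sub),
            partial=True,
        ))
    return CompositionProfile(
        counts=counts,
        gc_percent_global=gc_percent(rec.seq),
        windows=tuple(windows),
        window_size=window,
        step=step,
    )
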