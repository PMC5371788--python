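"""Output tables, design summaries, pinned primers and fixture generation.

Everything user-facing is a UTF-8 TSV with a header row ('.' decimal,
1-based inclusive coordinates) plus a JSON bundle that mirrors the tables
bit-for-bit; the primer map is additionally emitted as BED (0-based
half-open).  `run_design` is the end-to-end pipeline behind the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import sequence_io as sio
from .design import (
    DesignParameters,
    PrimerCandidate,
    enumerate_candidates,
    design_mutant_pair,
    passes_filters,
    _annotate,
)
from .errors import ParameterError
from .overlaps import attach_overlap, compatible_pairs, get_overlap
from .sequence_io import InputSequence, reverse_complement

log = logging.getLogger("stitchkit")

PRIMER_COLUMNS = [
    "name", "start", "end", "strand", "sequence", "full_sequence",
    "gc_percent", "tm", "self_matches", "self_weighted", "three_prime",
    "hairpin", "pass", "fail_reasons",
]

PAIR_COLUMNS = [
    "fwd_name", "rev_name", "product_len", "tm_fwd", "tm_rev", "tm_diff",
    "dimer_matches", "dimer_weighted", "compatible",
]

SUMMARY_METRICS = ("gc_percent", "tm", "weighted_self", "start", "length", "hairpin")


def primer_row(c: PrimerCandidate) -> dict:
    return {
        "name": c.name,
        "start": c.start,
        "end": c.end,
        "strand": c.strand,
        "sequence": c.core_seq,
        "full_sequence": c.full_seq,
        "gc_percent": round(c.gc_percent, 2),
        "tm": round(c.tm_celsius, 2) if c.tm_celsius is not None else "",
        "self_matches": c.self_report.total_matches if c.self_report else "",
        "self_weighted": c.self_report.weighted_score if c.self_report else "",
        "three_prime": c.self_report.three_prime_matches if c.self_report else "",
        "hairpin": c.hairpin.score if c.hairpin else "",
        "pass": int(c.passes),
        "fail_reasons": ";".join(c.fail_reasons),
    }


def primers_frame(cands: list[PrimerCandidate]) -> pd.DataFrame:
    return pd.DataFrame([primer_row(c) for c in cands], columns=PRIMER_COLUMNS)


def pairs_frame(pairs) -> pd.DataFrame:
    rows = [
        {
            "fwd_name": p.fwd.name,
            "rev_name": p.rev.name,
            "product_len": p.product_len,
            "tm_fwd": round(p.fwd.tm_celsius, 2) if p.fwd.tm_celsius is not None else "",
            "tm_rev": round(p.rev.tm_celsius, 2) if p.rev.tm_celsius is not None else "",
            "tm_diff": round(p.tm_diff, 2) if p.tm_diff != float("inf") else "",
            "dimer_matches": p.pair_report.total_matches,
            "dimer_weighted": p.pair_report.weighted_score,
            "compatible": int(p.compatible),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@dataclass(frozen=True)
class MetricSummary:
    average: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class DesignSummary:
    """Min/average/max of each primer metric over passing candidates."""

    strand: str
    n_passing: int
    metrics: dict[str, MetricSummary]

    @property
    def empty(self) -> bool:
        return self.n_passing == 0


def summarize(cands: list[PrimerCandidate], strand: str = "all") -> DesignSummary:
    """Per-metric min/avg/max over passing candidates; explicitly empty when
    nothing passes (never a row of zeros)."""
    passing = [c for c in cands if c.passes]
    if strand != "all":
        passing = [c for c in passing if c.strand == strand]
    if not passing:
        return DesignSummary(strand=strand, n_passing=0, metrics={})
    values = {
        "gc_percent": [c.gc_percent for c in passing],
        "tm": [c.tm_celsius for c in passing if c.tm_celsius is not None],
        "weighted_self": [
            c.self_report.weighted_score for c in passing if c.self_report
        ],
        "start": [float(c.start) for c in passing],
        "length": [float(len(c.core_seq)) for c in passing],
        "hairpin": [float(c.hairpin.score) for c in passing if c.hairpin],
    }
    metrics = {
        k: MetricSummary(
            average=float(np.mean(v)), minimum=float(min(v)), maximum=float(max(v))
        )
        for k, v in values.items() if v
    }
    return DesignSummary(strand=strand, n_passing=len(passing), metrics=metrics)


def summary_frame(summaries: list[DesignSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for metric in SUMMARY_METRICS:
            if metric in s.metrics:
                m = s.metrics[metric]
                rows.append({
                    "strand": s.strand, "metric": metric,
                    "average": round(m.average, 3),
                    "minimum": round(m.minimum, 3),
                    "maximum": round(m.maximum, 3),
                })
    return pd.DataFrame(rows, columns=["strand", "metric", "average", "minimum", "maximum"])


def score_pinned_primer(
    rec: InputSequence, start: int, end: int, strand: str,
    params: DesignParameters, name: str = "pinned",
) -> PrimerCandidate:
    """Fully annotate a user-specified primer window.

    The drawn primer is never auto-rejected; fail reasons are informational.
    Coordinates are 1-based inclusive on the forward strand.
    """
    if not (1 <= start <= end <= rec.length):
        raise ParameterError(
            f"pinned coordinates [{start},{end}] outside [1,{rec.length}]"
        )
    slice_ = rec.seq[start - 1:end]
    core = slice_ if strand == "forward" else reverse_complement(slice_)
    cand = PrimerCandidate(
        name=name, strand=strand, core_seq=core, start=start, end=end,
        spans_removed_n=any(start <= p <= end for p in rec.removed_n_positions),
    )
    cand = _annotate(cand, params, params.thermo_model())
    return passes_filters(cand, params)


def primer_map_rows(cands: list[PrimerCandidate], categories=None) -> list[dict]:
    """Primer map entries (1-based inclusive), sorted by start."""
    rows = []
    for c in cands:
        rows.append({
            "name": c.name, "start": c.start, "end": c.end,
            "strand": c.strand,
            "category": (categories or {}).get(c.name, c.strand),
        })
    return sorted(rows, key=lambda r: (r["start"], r["name"]))


def write_bed(rows: list[dict], rec_id: str, path: Path) -> None:
    """Primer map as BED: 0-based half-open, strand +/-."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            strand = "+" if r["strand"] == "forward" else "-"
            fh.write(
                f"{rec_id}\t{r['start'] - 1}\t{r['end']}\t{r['name']}\t0\t{strand}\n"
            )


def generate_fixture(
    seed: int,
    length: int = 1000,
    gc_fraction: float = 0.5,
    n_count: int = 0,
    repeat_insert: str | None = None,
    name: str = "fixture",
) -> InputSequence:
    """Deterministic pseudorandom test sequence.

    Base identities are i.i.d. with P(G or C) = ``gc_fraction``; ``n_count``
    Ns and an optional planted repeat are placed at reproducible interior
    positions.  The same seed always yields the same record.
    """
    if length < 50:
        raise ParameterError("fixture length must be >= 50")
    rng = np.random.default_rng(seed)
    gc = rng.random(length) < gc_fraction
    pick = rng.integers(0, 2, size=length)
    bases = np.where(gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    seq = list("".join(bases))
    if repeat_insert:
        pos = int(rng.integers(length // 4, 3 * length // 4))
        seq[pos:pos + len(repeat_insert)] = list(repeat_insert.upper())
    if n_count:
        n_pos = rng.choice(
            np.arange(length // 10, 9 * length // 10), size=n_count, replace=False
        )
        for p in sorted(int(x) for x in n_pos):
            seq[p] = "N"
    return InputSequence(id=name, seq="".join(seq)[:length])


def run_design(
    fasta_path,
    params: DesignParameters,
    out_dir,
    outputs: set[str] = frozenset({"tables", "pairs"}),
    overlap_name: str | None = None,
    overlap_seq: str | None = None,
    mutant_seq: str | None = None,
    pins: list[tuple[int, int, str]] | None = None,
    composition_window: int = 50,
    composition_step: int = 1,
) -> dict[str, Path]:
    """End-to-end design run; returns the manifest of files written.

    Always writes the forward/reverse primer tables and the pairs table;
    composition, summary, map and the JSON bundle are written when selected
    (``outputs`` may contain tables, pairs, composition, summary, map, json
    or all).  Every parameter value used is logged for reproducibility.
    Zero passing primers is not an error: tables are written with headers
    and a warning is logged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "all" in outputs:
        outputs = {"tables", "pairs", "composition", "summary", "map", "json"}

    rec = sio.read_fasta_path(fasta_path)
    log.info("input %s: %d bp", rec.id, rec.length)
    for key, val in sorted(asdict(params).items()):
        log.info("parameter %s = %r", key, val)
    rec = sio.clean_sequence(rec, remove_n=params.remove_n)
    if rec.removed_n_positions:
        log.info("removed %d N bases at positions %s",
                 len(rec.removed_n_positions), list(rec.removed_n_positions))

    overlap = None
    if overlap_name:
        overlap = get_overlap(overlap_name)
    elif overlap_seq:
        overlap = overlap_seq.upper()

    manifest: dict[str, Path] = {}
    extras: list[PrimerCandidate] = []
    categories: dict[str, str] = {}

    if mutant_seq:
        fwd_best, rev_best, mutant_rev = design_mutant_pair(rec, mutant_seq, params)
        fwds, revs = [fwd_best], [rev_best]
        categories[fwd_best.name] = categories[rev_best.name] = "mutant"
        (out_dir / "mutant_oligos.tsv").write_text(
            "name\tsequence\nmutant_fwd\t%s\nmutant_rev\t%s\n"
            % (mutant_seq.upper(), mutant_rev),
            encoding="utf-8",
        )
        manifest["mutant"] = out_dir / "mutant_oligos.tsv"
    else:
        fwds = enumerate_candidates(rec, params, "forward") if params.design_forward else []
        revs = enumerate_candidates(rec, params, "reverse") if params.design_reverse else []

    if overlap is not None and revs:
        revs = attach_overlap(revs, overlap, params)

    for start, end, strand in pins or []:
        pin = score_pinned_primer(
            rec, start, end, strand, params, name=f"pin_{start}_{end}"
        )
        extras.append(pin)
        categories[pin.name] = "pinned"

    n_pass = sum(c.passes for c in fwds + revs)
    if n_pass == 0:
        log.warning("no primer passed all filters; tables written with headers only")

    fwd_df = primers_frame(fwds)
    rev_df = primers_frame(revs)
    fwd_df.to_csv(out_dir / "forward_primers.tsv", sep="\t", index=False)
    rev_df.to_csv(out_dir / "reverse_primers.tsv", sep="\t", index=False)
    manifest["forward"] = out_dir / "forward_primers.tsv"
    manifest["reverse"] = out_dir / "reverse_primers.tsv"

    pairs = compatible_pairs(
        fwds, revs, max_tm_diff=params.max_tm_diff, cutoffs=params.cutoffs,
        model=params.thermo_model(),
    )
    pair_df = pairs_frame(pairs)
    pair_df.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    manifest["pairs"] = out_dir / "pairs.tsv"

    comp_profile = None
    if "composition" in outputs:
        win = min(composition_window, rec.length)
        comp_profile = sio.composition_profile(rec, window=win, step=composition_step)
        pd.DataFrame(comp_profile.to_rows()).to_csv(
            out_dir / "composition.tsv", sep="\t", index=False
        )
        manifest["composition"] = out_dir / "composition.tsv"

    summaries = None
    if "summary" in outputs:
        summaries = [
            summarize(fwds, "forward"),
            summarize(revs, "reverse"),
            summarize(fwds + revs, "all"),
        ]
        summary_frame(summaries).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        manifest["summary"] = out_dir / "summary.tsv"

    map_rows = None
    if "map" in outputs:
        map_rows = primer_map_rows(fwds + revs + extras, categories)
        pd.DataFrame(map_rows, columns=["name", "start", "end", "strand", "category"]).to_csv(
            out_dir / "primer_map.tsv", sep="\t", index=False
        )
        write_bed(map_rows, rec.id, out_dir / "primer_map.bed")
        manifest["map"] = out_dir / "primer_map.tsv"
        manifest["map_bed"] = out_dir / "primer_map.bed"

    if extras:
        primers_frame(extras).to_csv(out_dir / "pinned_primers.tsv", sep="\t", index=False)
        manifest["pinned"] = out_dir / "pinned_primers.tsv"

    if "json" in outputs:
        bundle = {
            "input": {
                "id": rec.id, "length": rec.length,
                "removed_n_positions": list(rec.removed_n_positions),
            },
            "parameters": asdict(params),
            "forward_primers": fwd_df.to_dict(orient="records"),
            "reverse_primers": rev_df.to_dict(orient="records"),
            "pairs": pair_df.to_dict(orient="records"),
        }
        if comp_profile is not None:
            bundle["composition"] = comp_profile.to_rows()
        if map_rows is not None:
            bundle["primer_map"] = map_rows
        (out_dir / "design.json").write_text(
            json.dumps(bundle, indent=1, default=str), encoding="utf-8"
        )
        manifest["json"] = out_dir / "design.json"

    return manifest
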