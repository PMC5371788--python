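"""Nearest-neighbor DNA thermodynamics.

Melting temperature from dinucleotide-stack enthalpy/entropy sums with a
monovalent-salt correction, duplex Gibbs free energy at 37 degC, and a simple
hairpin screen (maximal self-complementary stem with a minimum loop).

Two published parameter tables ship as plain-text data files: the unified
set (SantaLucia 1998, default) and the older Breslauer 1986 set.  The 10
unique stacks are mirrored onto their reverse complements, so all 16
dinucleotides resolve.

Model::

    Tm = dH * 1000 / (dS + R * ln(C_T / 4)) - 273.15 + 16.6 * log10([Na+])

with dH in kcal/mol, dS in cal/(mol K), R = 1.987 cal/(mol K), total strand
concentration C_T in mol/L and [Na+] in mol/L (Schildkraut-Lifson salt term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from .errors import InvalidAlphabetError, ParameterError
from .sequence_io import reverse_complement

R_GAS = 1.987  # cal/(mol K)
DG_TEMPERATURE_K = 310.15  # 37 degC, where duplex dG is evaluated


def _load_table(name: str) -> dict[str, tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}
    text = resources.files("stitchkit.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    # mirror each stack onto its reverse complement (duplex symmetry)
    for stack in list(table):
        if len(stack) == 2:
            rc = reverse_complement(stack)
            table.setdefault(rc, table[stack])
    return table


@dataclass(frozen=True)
class ThermoModel:
    """Nearest-neighbor parameter set plus solution conditions.

    ``salt_mM`` is the monovalent cation concentration (50 mM default, the
    10 mM alternative mirrors the second supported condition); any positive
    value is accepted programmatically.  ``primer_conc_nM`` is total strand
    concentration C_T.
    """

    table_name: str = "santalucia1998"
    salt_mM: float = 50.0
    primer_conc_nM: float = 250.0
    params: dict[str, tuple[float, float]] = field(default=None, repr=False)

    def __post_init__(self):
        if self.salt_mM <= 0:
            raise ParameterError("salt_mM must be positive")
        if self.primer_conc_nM <= 0:
            raise ParameterError("primer_conc_nM must be positive")
        if self.params is None:
            object.__setattr__(
                self, "params", _load_table(f"{self.table_name}.tsv")
            )

    def stack(self, dinuc: str) -> tuple[float, float]:
        try:
            return self.params[dinuc]
        except KeyError:
            raise InvalidAlphabetError(f"no stack parameters for {dinuc!r}") from None

    def initiation(self, seq: str) -> tuple[float, float]:
        """Duplex-initiation dH/dS: one global term plus per-terminal terms."""
        dh, ds = self.params["init"]
        for base in (seq[0], seq[-1]):
            key = "init_GC" if base in "GC" else "init_AT"
            dh += self.params[key][0]
            ds += self.params[key][1]
        return dh, ds


DEFAULT_MODEL = ThermoModel()


def _check_seq(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise InvalidAlphabetError(
            f"thermodynamic calculations need unambiguous bases; found "
            f"{', '.join(sorted(bad))}"
        )


def duplex_sums(seq: str, model: ThermoModel) -> tuple[float, float]:
    """Total (dH, dS) of the perfect duplex of ``seq``, initiation included."""
    _check_seq(seq)
    dh, ds = model.initiation(seq)
    for i in range(len(seq) - 1):
        sdh, sds = model.stack(seq[i:i + 2])
        dh += sdh
        ds += sds
    return dh, ds


def melting_temperature(seq: str, model: ThermoModel = DEFAULT_MODEL) -> float:
    """Nearest-neighbor Tm (degC) of the perfect duplex, salt-corrected."""
    seq = seq.upper()
    if len(seq) < 8:
        raise ParameterError(f"primer too short for the duplex model: {len(seq)} nt")
    _check_seq(seq)
    dh, ds = duplex_sums(seq, model)
    c_t = model.primer_conc_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(c_t / 4.0))
    na_molar = model.salt_mM / 1000.0
    return tm_k - 273.15 + 16.6 * math.log10(na_molar)


def duplex_delta_g(
    run_seq: str,
    model: ThermoModel = DEFAULT_MODEL,
    include_initiation: bool = True,
) -> float:
    """Gibbs free energy (kcal/mol, 37 degC) of a perfectly paired run.

    ``run_seq`` is the top strand 5'->3' of a contiguous complementary run.
    More negative means more stable.  An empty run contributes only the
    initiation term (or exactly 0 with ``include_initiation=False``); runs
    inside complementarity scans are scored stacking-only, since they sit
    within a longer, already-initiated duplex.
    """
    run_seq = run_seq.upper()
    if not run_seq:
        if not include_initiation:
            return 0.0
        dh, ds = model.params["init"]
        return dh - DG_TEMPERATURE_K * ds / 1000.0
    _check_seq(run_seq)
    if include_initiation:
        dh, ds = model.initiation(run_seq)
    else:
        dh, ds = 0.0, 0.0
    for i in range(len(run_seq) - 1):
        sdh, sds = model.stack(run_seq[i:i + 2])
        dh += sdh
        ds += sds
    return dh - DG_TEMPERATURE_K * ds / 1000.0


@dataclass(frozen=True)
class HairpinResult:
    """Best self-folding stem found in a single oligo.

    ``score`` is the stem length in base pairs (0 when no stem exists with
    the required loop); ``stem_dG`` is the stacking free energy of that stem.
    """

    stem_len: int
    loop_len: int
    stem_dG: float
    score: int

    @classmethod
    def none(cls) -> "HairpinResult":
        return cls(stem_len=0, loop_len=0, stem_dG=0.0, score=0)


def hairpin_score(
    seq: str, min_loop: int = 3, model: ThermoModel = DEFAULT_MODEL
) -> HairpinResult:
    """Maximal hairpin stem over all substring pairs with loop >= ``min_loop``.

    A stem of length L pairs ``seq[i:i+L]`` with ``seq[j:j+L]`` when the
    former equals the reverse complement of the latter and the unpaired loop
    ``j - (i + L)`` is at least ``min_loop``.  Ties prefer the shorter loop,
    then the 5'-most stem.  Sequences too short to fold score 0.
    """
    seq = seq.upper()
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (stem_len, -loop, -i) maximised
    best_run = ""
    if n >= 2 + min_loop:
        rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i in range(n):
            for j in range(i + 1 + min_loop, n):
                # extend a stem pairing seq[i+k] with seq[j-k]
                length = 0
                while (
                    i + length < j - length
                    and j - length < n
                    and (j - length) - (i + length) - 1 >= min_loop
                    and seq[i + length] in rc
                    and rc.get(seq[i + length]) == seq[j - length]
                ):
                    length += 1
                if length == 0:
                    continue
                loop = (j - (length - 1)) - (i + length)
                key = (length, -loop, -i)
                if best is None or key > best:
                    best = key
                    best_run = seq[i:i + length]
    if best is None:
        return HairpinResult.none()
    stem_len, neg_loop, _ = best
    try:
        dg = duplex_delta_g(best_run, model, include_initiation=False)
    except InvalidAlphabetError:
        dg = 0.0
    return HairpinResult(
        stem_len=stem_len, loop_len=-neg_loop, stem_dG=dg, score=stem_len
    )
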