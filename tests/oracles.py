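"""Independently coded brute-force references used by the test suite.

These deliberately avoid every code path of the package: the Tm oracle
carries its own hand-typed parameter dictionary and formula; the scan and
hairpin oracles are naive enumerations over all offsets / substring pairs.
"""

import math

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# unified nearest-neighbor parameters, typed independently:
# stack -> (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def tm_oracle(seq: str, salt_mM: float = 50.0, conc_nM: float = 250.0) -> float:
    """Brute-force dH/dS summation Tm with Schildkraut-Lifson salt term."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        dh += _INIT[end][0]
        ds += _INIT[end][1]
    for a, b in zip(seq, seq[1:]):
        sdh, sds = _NN[a + b]
        dh += sdh
        ds += sds
    ct = conc_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + 1.987 * math.log(ct / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(salt_mM / 1000.0)


def scan_oracle(a: str, b: str):
    """Naive best antiparallel sliding: (offset, matches, longest_run).

    Ties resolved toward the longer run, then the smaller offset.
    """
    c = b[::-1]
    best = None
    for off in range(-(len(a) - 1), len(c)):
        matches = 0
        run = cur = 0
        for i, base in enumerate(a):
            j = off + i
            ok = 0 <= j < len(c) and _COMP.get(base) == c[j]
            if ok:
                matches += 1
                cur += 1
                run = max(run, cur)
            else:
                cur = 0
        key = (matches, run, -off)
        if best is None or key > best:
            best = key
    matches, run, neg_off = best
    return -neg_off, matches, run


def hairpin_oracle(seq: str, min_loop: int = 3) -> int:
    """Maximal stem length by O(n^4) enumeration of all arm pairs."""
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(n):
            for L in range(1, n + 1):
                if i + L > n or j + L > n or j - (i + L) < min_loop:
                    break
                arm1 = seq[i:i + L]
                arm2 = seq[j:j + L]
                rc2 = "".join(_COMP[b] for b in reversed(arm2))
                if arm1 == rc2:
                    best = max(best, L)
    return best
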