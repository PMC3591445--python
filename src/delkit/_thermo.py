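"""Vectorized nearest-neighbor melting temperatures.

Computes the same quantity as ``Bio.SeqUtils.MeltingTemp.Tm_NN`` (DNA_NN3
table, 50 mM monovalent salt, salt-correction method 5, 25 nM each strand)
for *every* fixed-length window of a template at once, which is what makes
exhaustive primer-candidate enumeration affordable.  The scalar Biopython
routine is the reference; the test suite asserts agreement.  The only
intentional divergence is that self-complementary windows are treated like
ordinary duplexes (no symmetry term) — such windows are vanishingly rare
among accepted primers and never arise in the fixtures.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

R_GAS = 1.987  # cal / (K mol)
_DNAC1 = 25.0  # nM
_DNAC2 = 25.0  # nM
_K_CONC = (_DNAC1 - _DNAC2 / 2.0) * 1e-9
_MONOVALENT = 0.05  # mol/L, i.e. Na=50 mM


def _step_tables() -> tuple[np.ndarray, np.ndarray]:
    """4x4 dH/dS lookup for each dinucleotide step, from Biopython's table."""
    dh = np.zeros((4, 4))
    ds = np.zeros((4, 4))
    for a in _BASES:
        for b in _BASES:
            key = a + b + "/" + _COMP[a] + _COMP[b]
            if key in _mt.DNA_NN3:
                h, s = _mt.DNA_NN3[key]
            else:
                h, s = _mt.DNA_NN3[key[::-1]]
            dh[_CODE[a], _CODE[b]] = h
            ds[_CODE[a], _CODE[b]] = s
    return dh, ds


_DH_STEP, _DS_STEP = _step_tables()
_INIT_AT = _mt.DNA_NN3["init_A/T"]
_INIT_GC = _mt.DNA_NN3["init_G/C"]

# terminal penalty per base (A/T vs G/C)
_TERM_DH = np.array([_INIT_AT[0], _INIT_GC[0], _INIT_GC[0], _INIT_AT[0]])
_TERM_DS = np.array([_INIT_AT[1], _INIT_GC[1], _INIT_GC[1], _INIT_AT[1]])


def encode(seq: str) -> np.ndarray:
    """Encode DNA into int codes; A,C,G,T -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def window_tm(codes: np.ndarray, length: int) -> np.ndarray:
    """Tm (deg C) for every window of ``length`` over an encoded template.

    Windows containing non-ACGT characters get ``nan``.
    """
    n = codes.size
    if n < length:
        return np.empty(0)
    valid = codes >= 0
    safe = np.where(valid, codes, 0)

    step_dh = _DH_STEP[safe[:-1], safe[1:]]
    step_ds = _DS_STEP[safe[:-1], safe[1:]]
    cum_dh = np.concatenate(([0.0], np.cumsum(step_dh)))
    cum_ds = np.concatenate(([0.0], np.cumsum(step_ds)))
    nwin = n - length + 1
    dh = cum_dh[length - 1 : length - 1 + nwin] - cum_dh[:nwin]
    ds = cum_ds[length - 1 : length - 1 + nwin] - cum_ds[:nwin]

    first = safe[:nwin]
    last = safe[length - 1 : length - 1 + nwin]
    dh = dh + _TERM_DH[first] + _TERM_DH[last]
    ds = ds + _TERM_DS[first] + _TERM_DS[last]

    ds = ds + 0.368 * (length - 1) * math.log(_MONOVALENT)
    tm = (1000.0 * dh) / (ds + R_GAS * math.log(_K_CONC)) - 273.15

    bad = ~valid
    if bad.any():
        cum_bad = np.concatenate(([0], np.cumsum(bad)))
        has_bad = (cum_bad[length:] - cum_bad[:nwin]) > 0
        tm[has_bad] = np.nan
    return tm


def primer_tm(seq: str) -> float:
    """Scalar Tm of one primer, matching the window computation exactly."""
    codes = encode(seq)
    return float(window_tm(codes, len(seq))[0])


def window_gc(codes: np.ndarray, length: int) -> np.ndarray:
    """GC fraction of every window of ``length``."""
    n = codes.size
    if n < length:
        return np.empty(0)
    is_gc = ((codes == 1) | (codes == 2)).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(is_gc)))
    nwin = n - length + 1
    return (cum[length:] - cum[:nwin]) / float(length)


def run_lengths(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position homopolymer run lengths.

    Returns ``(ending, starting)`` where ``ending[i]`` is the length of the
    run of identical bases ending at ``i`` and ``starting[i]`` the length of
    the run starting at ``i``.
    """
    n = codes.size
    idx = np.arange(n)

    def _ending(c: np.ndarray) -> np.ndarray:
        change = np.empty(n, dtype=bool)
        change[0] = True
        change[1:] = c[1:] != c[:-1]
        run_start = np.maximum.accumulate(np.where(change, idx, 0))
        return (idx - run_start + 1).astype(np.int32)

    ending = _ending(codes)
    starting = _ending(codes[::-1])[::-1]
    return ending, starting
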