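"""Duplex melting temperature from unified nearest-neighbor thermodynamics.

The model sums published dinucleotide stacking enthalpies/entropies
(unified parameter set of Allawi & SantaLucia, frozen in
``data/nn_unified.json``), adds duplex-initiation terms for the two
terminal base pairs, applies the entropic monovalent-salt correction
0.368·(N−1)·ln[Na+], and converts to a melting temperature via

    Tm = ΔH / (ΔS + R·ln(C_T/4)) − 273.15

for a non-self-complementary primer at total strand concentration C_T.
Default conditions are 50 mM Na+ and 500 nM primer.
"""

from __future__ import annotations

import json
import math
from importlib import resources

__all__ = ["tm_nearest_neighbor", "reverse_complement", "gc_fraction"]

_R = 1.987  # cal / (mol K)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _load_nn_table() -> tuple[dict[str, tuple[float, float]], tuple[float, float], tuple[float, float]]:
    text = resources.files("allelequant.data").joinpath("nn_unified.json").read_text()
    raw = json.loads(text)
    stacks = {k: (v[0], v[1]) for k, v in raw["stacks"].items()}
    return stacks, tuple(raw["init_at"]), tuple(raw["init_gc"])


_STACKS, _INIT_AT, _INIT_GC = _load_nn_table()


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an ACGT string (uppercase)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    return (sequence.count("G") + sequence.count("C")) / len(sequence) if sequence else 0.0


def tm_nearest_neighbor(
    sequence: str,
    na_mM: float = 50.0,
    primer_nM: float = 500.0,
) -> float:
    """Melting temperature (°C) of a primer–template duplex.

    Parameters
    ----------
    sequence
        Primer sequence, 5'→3', ACGT only, length ≥ 8.
    na_mM
        Monovalent cation concentration in mM.
    primer_nM
        Total single-strand concentration in nM; the effective annealing
        concentration is C_T/4 (neither strand self-complementary, equal
        concentrations).

    The value is invariant under reverse complement, because every stack
    maps onto the stack of its complementary strand with identical
    parameters and terminal A·T / G·C classes are preserved.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError(f"primer too short for nearest-neighbor Tm: {len(seq)} nt < 8")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous or invalid bases in primer: {sorted(bad)}")
    if na_mM <= 0 or primer_nM <= 0:
        raise ValueError("salt and primer concentrations must be positive")

    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for i in range(len(seq) - 1):
        h, s = _STACKS[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_AT if terminal in "AT" else _INIT_GC
        dh += h
        ds += s

    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    c_t = primer_nM * 1e-9
    return dh * 1000.0 / (ds + _R * math.log(c_t / 4.0)) - 273.15
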