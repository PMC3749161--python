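"""Small shared helpers: sequence encoding, Hamming distance, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

BASES = "ACGT"
BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    BASE_TO_IDX[ord(_b)] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence (read-only)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def seq_to_idx(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 (other characters -> 255)."""
    return BASE_TO_IDX[seq_to_u8(seq)]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to `ndigits` decimals (table convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def chunk_spans(length: int, n_chunks: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_chunks near-equal contiguous spans.

    Used for pigeonhole candidate lookup: a sequence within k substitutions of
    another shares at least one of k+1 chunks exactly.
    """
    bounds = np.linspace(0, length, n_chunks + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_chunks)]
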