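"""Lempel-Ziv (LZ76) complexity of binary meta-state sequences.

The complexity ``c(n)`` counts the distinct phrases in the exhaustive-history
parsing of a binary sequence (Kaspar-Schuster counting); a sequence with more
unique patterns is less predictable, hence more entropic.  Normalised
complexity here is ``c(n) / n``, i.e. compressibility per symbol; the common
``c(n) * log2(n) / n`` variant is available behind a flag.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lz76_complexity", "normalized_lz"]


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits, dtype=int).ravel()
    if arr.size == 0:
        raise ValueError("sequence must be nonempty")
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError("sequence must contain only 0 and 1")
    return arr


def lz76_complexity(bits) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing.

    Kaspar-Schuster counting: scan the sequence, extending the current phrase
    while it can be copied from anywhere in the history; each time the copy
    fails, close the phrase and start a new one.  A constant sequence parses
    into 2 phrases; ``c(n) <= n`` always.
    """
    arr = _as_bits(bits)
    s = "".join("01"[b] for b in arr)
    n = len(s)
    c = 0
    l = 0
    while l < n:
        # grow the phrase while it can be copied from the exhaustive history,
        # i.e. while s[l:l+k] occurs starting before position l (overlap allowed)
        k = 1
        while l + k <= n and s[l : l + k] in s[: l + k - 1]:
            k += 1
        c += 1
        l += k
    return c


def normalized_lz(bits, log_normalized: bool = False) -> float:
    """Compressibility of a binary sequence: ``c(n)/n`` by default.

    With ``log_normalized=True`` returns ``c(n) * log2(n) / n``, the
    asymptotic-rate normalisation (a fair-coin sequence then tends to 1).
    """
    s = _as_bits(bits)
    n = len(s)
    c = lz76_complexity(s)
    if log_normalized:
        return c * np.log2(n) / n
    return c / n
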