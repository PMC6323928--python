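"""Terminal-repeat detection for putative complete (circular) genomes.

An assembled circular genome typically carries a direct terminal repeat
(DTR): the assembler walks around the circle and reproduces the start of the
contig at its end. Some linear-but-complete genomes instead carry long
repeats near both termini, direct (``direct_internal``) or inverted (ITR,
``inverted``). Three rules are applied in order:

1. DTR — the longest exact match between a prefix starting at base 0 and a
   suffix ending at the last base; circular if >= ``min_dtr_len`` (10 bp).
2. direct repeat of >= ``min_terminal_repeat_len`` (20 bp) whose 5' copy
   starts within ``terminal_window`` (50 bp) of the 5' end and whose 3' copy
   ends within 50 bp of the 3' end.
3. as rule 2 but the 3' copy is the reverse complement of the 5' copy.

Matches are exact; ``N`` never matches anything, including another ``N``.
The repeat-window anchoring (copy *start* within the window at the 5' end,
copy *end* within the window at the 3' end) is this package's convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .records import ViralContig, reverse_complement

MECHANISMS = ("DTR", "direct_internal", "inverted", "none")


@dataclass(frozen=True)
class CircularityParams:
    """Detection thresholds: 10 bp DTR floor, 20 bp windowed-repeat floor,
    50 bp terminal window."""

    min_dtr_len: int = 10
    min_terminal_repeat_len: int = 20
    terminal_window: int = 50

    def __post_init__(self) -> None:
        if min(self.min_dtr_len, self.min_terminal_repeat_len, self.terminal_window) <= 0:
            raise ValueError("all circularity parameters must be positive")
        if self.min_dtr_len > self.min_terminal_repeat_len:
            raise ValueError("min_dtr_len must not exceed min_terminal_repeat_len")


@dataclass(frozen=True)
class CircularityCall:
    """Outcome of circularity detection.

    ``five_prime_pos``/``three_prime_pos`` are the 0-based starts of the two
    repeat copies on the contig (the 3' copy of an inverted repeat is given
    by its position on the forward strand).
    """

    is_circular: bool
    mechanism: str
    repeat_length: int = 0
    five_prime_pos: Optional[int] = None
    three_prime_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


NON_CIRCULAR = CircularityCall(is_circular=False, mechanism="none")


def longest_terminal_dtr(seq: str) -> int:
    """Length of the longest exact, N-free match between a prefix anchored
    at base 0 and a suffix ending at the last base (0 if none)."""
    n = len(seq)
    for k in range(n // 2, 0, -1):
        prefix = seq[:k]
        if prefix == seq[n - k :] and "N" not in prefix:
            return k
    return 0


def _extend_forward(a: str, b: str, i: int, j: int) -> int:
    """Length of the maximal exact N-free run a[i..] == b[j..]."""
    length = 0
    na, nb = len(a), len(b)
    while i + length < na and j + length < nb:
        ca = a[i + length]
        if ca != b[j + length] or ca == "N":
            break
        length += 1
    return length


def longest_windowed_direct_repeat(
    seq: str, min_len: int, window: int
) -> Optional[tuple[int, int, int]]:
    """Longest exact direct repeat with the 5' copy starting within
    ``window`` of the 5' end and the 3' copy ending within ``window`` of the
    3' end. Returns (length, start_5p, start_3p) or None.

    Anchor 5'-window seeds of length ``min_len`` and extend each downstream
    occurrence; a candidate qualifies when its maximal extension reaches the
    terminal window at the 3' end.
    """
    n = len(seq)
    best: Optional[tuple[int, int, int]] = None
    for s1 in range(0, min(window, n - min_len) + 1):
        pattern = seq[s1 : s1 + min_len]
        if len(pattern) < min_len or "N" in pattern:
            continue
        search_from = s1 + 1
        while True:
            s2 = seq.find(pattern, search_from)
            if s2 == -1:
                break
            search_from = s2 + 1
            length = min_len + _extend_forward(seq, seq, s1 + min_len, s2 + min_len)
            if s2 + length >= n - window and (best is None or length > best[0]):
                best = (length, s1, s2)
    return best


def longest_windowed_inverted_repeat(
    seq: str, min_len: int, window: int
) -> Optional[tuple[int, int, int]]:
    """Longest exact inverted repeat: 5' copy starts within ``window`` of
    the 5' end, its reverse complement ends within ``window`` of the 3' end.
    Returns (length, start_5p, start_3p_forward_coords) or None.
    """
    n = len(seq)
    rc = reverse_complement(seq)
    best: Optional[tuple[int, int, int]] = None
    for s1 in range(0, min(window, n - min_len) + 1):
        pattern = seq[s1 : s1 + min_len]
        if len(pattern) < min_len or "N" in pattern:
            continue
        search_from = 0
        while True:
            # position p on the reverse complement <=> copy ending p bases
            # from the 3' end of the forward strand
            p = rc.find(pattern, search_from)
            if p == -1 or p > window:
                break
            search_from = p + 1
            length = min_len + _extend_forward(seq, rc, s1 + min_len, p + min_len)
            s2 = n - p - length  # forward-strand start of the 3' copy
            if s2 > s1 and (best is None or length > best[0]):
                best = (length, s1, s2)
    return best


def detect_circularity(
    contig: ViralContig, params: CircularityParams | None = None
) -> CircularityCall:
    """Apply the three terminal-repeat rules in order (DTR first).

    Sequences no longer than twice the terminal window cannot separate a
    5' window from a 3' window; they get a non-circular call and a warning.
    """
    params = params or CircularityParams()
    seq = contig.sequence
    n = len(seq)
    if n <= 2 * params.terminal_window:
        warnings.warn(
            f"contig {contig.id!r} is too short ({n} bp) for circularity "
            f"detection (needs > {2 * params.terminal_window} bp)",
            stacklevel=2,
        )
        return NON_CIRCULAR

    dtr = longest_terminal_dtr(seq)
    if dtr >= params.min_dtr_len:
        return CircularityCall(True, "DTR", dtr, 0, n - dtr)

    direct = longest_windowed_direct_repeat(
        seq, params.min_terminal_repeat_len, params.terminal_window
    )
    if direct is not None:
        length, s1, s2 = direct
        return CircularityCall(True, "direct_internal", length, s1, s2)

    inverted = longest_windowed_inverted_repeat(
        seq, params.min_terminal_repeat_len, params.terminal_window
    )
    if inverted is not None:
        length, s1, s2 = inverted
        return CircularityCall(True, "inverted", length, s1, s2)

    return NON_CIRCULAR
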