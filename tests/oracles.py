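"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive quadratic scans and a hand-rolled union-find,
sharing no code with the package's detectors.
"""
from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "!"}  # N matches nothing


def brute_longest_dtr(seq: str) -> int:
    """Ascending scan of every prefix/suffix pair (N-free exact matches)."""
    n = len(seq)
    best = 0
    for k in range(1, n // 2 + 1):
        if seq[:k] == seq[n - k :] and "N" not in seq[:k]:
            best = k
    return best


def brute_windowed_direct(seq: str, min_len: int, window: int) -> int:
    """Longest direct repeat: 5' copy start <= window from the 5' end,
    3' copy end <= window from the 3' end. All (start, start) pairs."""
    n = len(seq)
    best = 0
    for s1 in range(0, min(window, n - 1) + 1):
        for s2 in range(s1 + 1, n):
            length = 0
            while (
                s2 + length < n
                and seq[s1 + length] == seq[s2 + length]
                and seq[s1 + length] != "N"
            ):
                length += 1
            if length >= min_len and s2 + length >= n - window:
                best = max(best, length)
    return best


def brute_windowed_inverted(seq: str, min_len: int, window: int) -> int:
    """Longest inverted repeat: 5' copy start and reverse-complement 3'
    copy end both within the terminal windows. All (start, end) anchors."""
    n = len(seq)
    best = 0
    for s1 in range(0, min(window, n - 1) + 1):
        for end in range(max(n - window, 1), n + 1):
            length = 0
            while (
                s1 + length < n
                and end - 1 - length >= 0
                and seq[s1 + length] == _COMP[seq[end - 1 - length]]
            ):
                length += 1
            if length >= min_len and (end - length) > s1:
                best = max(best, length)
    return best


def brute_detect(seq: str, min_dtr: int = 10, min_repeat: int = 20, window: int = 50):
    """Rule order as in the detector: DTR, then windowed direct, then
    inverted. Returns (is_circular, mechanism, repeat_length)."""
    dtr = brute_longest_dtr(seq)
    if dtr >= min_dtr:
        return True, "DTR", dtr
    direct = brute_windowed_direct(seq, min_repeat, window)
    if direct >= min_repeat:
        return True, "direct_internal", direct
    inverted = brute_windowed_inverted(seq, min_repeat, window)
    if inverted >= min_repeat:
        return True, "inverted", inverted
    return False, "none", 0


def brute_spacer_scan(contig: str, spacer: str, max_mm: int) -> set[tuple[int, str, int]]:
    """Sliding-window comparison on both strands; N counts as a mismatch."""
    rc = "".join(_COMP[c] if _COMP[c] != "!" else "N" for c in reversed(spacer))
    hits: set[tuple[int, str, int]] = set()
    oriented = [("+", spacer)]
    if rc != spacer:
        oriented.append(("-", rc))
    for strand, probe in oriented:
        for pos in range(len(contig) - len(probe) + 1):
            mm = sum(
                1
                for a, b in zip(contig[pos : pos + len(probe)], probe)
                if a != b or a == "N" or b == "N"
            )
            if mm <= max_mm:
                hits.add((pos, strand, mm))
    return hits


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> list[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]


def brute_single_linkage(ids, edges) -> set[frozenset]:
    """Union-find over a precomputed edge list."""
    uf = UnionFind(ids)
    for a, b in edges:
        uf.union(a, b)
    return set(uf.components())
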