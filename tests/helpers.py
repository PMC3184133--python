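"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools

import numpy as np

from emtcre.promoters import revcomp

BASES = "ACGT"
IDX = {b: i for i, b in enumerate(BASES)}


def brute_force_scan(seq: str, log_odds: np.ndarray, threshold: float
                     ) -> list[tuple[int, str, float]]:
    """Score every window on both strands by explicit loops."""
    L = log_odds.shape[1]
    out = []
    for strand in "+-":
        probe = seq if strand == "+" else None
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            w = window if strand == "+" else revcomp(window)
            score = 0.0
            ok = True
            for j, b in enumerate(w.upper()):
                if b not in IDX:
                    ok = False
                    break
                score += log_odds[IDX[b], j]
            if ok and score >= threshold:
                out.append((i, strand, score))
    return sorted(out)


def brute_force_venn(sets: dict[str, set]) -> dict[frozenset, set]:
    """Enumerate every element and assign it to its membership region."""
    names = list(sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = set()
    for el in set().union(*sets.values()):
        member = frozenset(n for n in names if el in sets[n])
        regions[member].add(el)
    return regions


def brute_force_average_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Merge order of average-linkage clustering by explicit recomputation."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dist[i, j] for i in a for j in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        merges.append((a, b))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def brute_force_longest_revcomp_block(s1: str, s2: str) -> int:
    """Longest substring of s1 whose reverse complement occurs in s2."""
    s1, s2 = s1.lower(), s2.lower()
    best = 0
    for i in range(len(s1)):
        for j in range(i + 1, len(s1) + 1):
            if j - i > best and revcomp(s1[i:j]) in s2:
                best = j - i
    return best


def brute_force_tandem(seq: str) -> tuple[str, int]:
    """Longest 5'-anchored unit repeating >= 2 times, by trying all lengths."""
    n = len(seq)
    for u in range(n // 2, 0, -1):
        count = 1
        while seq[count * u:(count + 1) * u] == seq[:u]:
            count += 1
        if count >= 2:
            return seq[:u], count
    return seq, 1
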