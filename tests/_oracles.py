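"""Independent brute-force oracles used by the test suite.

Deliberately written as plain Python loops over pixel pairs, sharing no
code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def quantize(img: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = [img[r, c] for r, c in zip(*np.nonzero(mask))]
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return np.zeros(img.shape, dtype=int)
    q = np.zeros(img.shape, dtype=int)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            q[r, c] = min(int((img[r, c] - lo) / (hi - lo) * levels), levels - 1)
    return q


def glcm_stats_bruteforce(
    img: np.ndarray, mask: np.ndarray, g: int, levels: int
):
    """(entropy_mean, entropy_std, homogeneity_mean, homogeneity_std).

    Counts symmetric in-mask co-occurrences at offset ``g`` for the four
    directions by explicit iteration.  Returns ``None`` when a direction
    has no pair.
    """
    q = quantize(img, mask, levels)
    h, w = img.shape
    entropies, homogeneities = [], []
    for dr, dc in ((0, g), (g, g), (g, 0), (g, -g)):
        counts: dict[tuple[int, int], int] = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    for pair in ((q[r, c], q[r2, c2]), (q[r2, c2], q[r, c])):
                        counts[pair] = counts.get(pair, 0) + 1
        total = sum(counts.values())
        if total == 0:
            return None
        ent = 0.0
        hom = 0.0
        for (i, j), n in counts.items():
            p = n / total
            ent -= p * math.log2(p)
            hom += p / (1 + abs(i - j))
        entropies.append(ent)
        homogeneities.append(hom)

    def mean(xs):
        return sum(xs) / len(xs)

    def std(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))

    return (
        mean(entropies),
        std(entropies),
        mean(homogeneities),
        std(homogeneities),
    )
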