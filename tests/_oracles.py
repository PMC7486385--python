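"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's sweep/sort implementations: interval
algebra is recomputed on per-base boolean vectors, the elbow cutoff by a
plain double loop over all tangent positions, and the t-test from the
textbook closed form.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from hcdkit.intervals import GenomicInterval, IntervalSet


def coverage(intervals, genome_len: int) -> np.ndarray:
    v = np.zeros(genome_len, dtype=bool)
    for iv in intervals:
        v[iv.start : iv.end] = True
    return v


def runs(v: np.ndarray, chrom: str = "chr1") -> list[GenomicInterval]:
    """Maximal True runs of a boolean vector as intervals."""
    out = []
    padded = np.concatenate(([False], v, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def merge_oracle(intervals, max_gap: int, genome_len: int) -> list[GenomicInterval]:
    """Boolean-OR coverage, then close every gap of <= max_gap bases."""
    v = coverage(intervals, genome_len)
    base = runs(v)
    merged = []
    for iv in base:
        if merged and iv.start - merged[-1].end <= max_gap:
            merged[-1] = GenomicInterval("chr1", merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def intersect_oracle(a, b, genome_len: int) -> list[GenomicInterval]:
    return runs(coverage(a, genome_len) & coverage(b, genome_len))


def connected_union_oracle(a, b) -> list[tuple[int, int]]:
    """Union-find over the explicit pairwise overlap graph; returns spans of
    components holding members of both inputs, sorted."""
    items = [(iv, 0) for iv in a] + [(iv, 1) for iv in b]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][0].overlaps(items[j][0]):
                union(i, j)
    comps: dict[int, list[tuple[GenomicInterval, int]]] = {}
    for i, item in enumerate(items):
        comps.setdefault(find(i), []).append(item)
    spans = []
    for members in comps.values():
        tags = {t for _, t in members}
        if tags == {0, 1}:
            spans.append(
                (min(iv.start for iv, _ in members), max(iv.end for iv, _ in members))
            )
    return sorted(spans)


def random_interval_set(rng, genome_len: int = 10_000, max_n: int = 20) -> IntervalSet:
    n = int(rng.integers(0, max_n + 1))
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, genome_len - 1))
        length = int(rng.integers(1, max(2, genome_len // 10)))
        ivs.append(GenomicInterval("chr1", start, min(start + length, genome_len)))
    return IntervalSet(ivs).sorted()


def elbow_oracle(scores) -> tuple[float, int]:
    """Exhaustive tangent-position search, plain Python double loop."""
    s = sorted(max(float(v), 0.0) for v in scores)
    n = len(s)
    slope = (s[-1] - s[0]) / n
    best_x, best_count = 0, None
    for x in range(n):
        count = 0
        for j in range(n):
            if s[j] < s[x] + slope * (j - x):
                count += 1
        if best_count is None or count < best_count:
            best_x, best_count = x, count
    return s[best_x], best_x + 1


def ttest_closed_form(x, y) -> tuple[float, float, float]:
    """Pooled two-sample t, df and two-tailed p from the textbook formula.

    p uses the regularised incomplete beta function directly:
    p = I_{df/(df+t^2)}(df/2, 1/2).
    """
    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return t, float(df), p


def optimal_matching_count(called, truth, min_jaccard: float) -> int:
    """Maximum one-to-one matching with all Jaccards >= threshold, via
    augmenting-path maximum bipartite matching (tiny inputs only)."""
    from hcdkit.simulate import _jaccard

    adj = [
        [j for j, t in enumerate(truth) if _jaccard(c, t) >= min_jaccard]
        for c in called
    ]
    match_t: dict[int, int] = {}

    def augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_t or augment(match_t[j], seen):
                match_t[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(len(called)))
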