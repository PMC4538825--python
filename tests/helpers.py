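"""Independent brute-force oracles used to grade the interval kernel.

Everything here works on explicit per-base boolean masks over small
chromosomes, deliberately ignoring the package's own interval algebra.
"""

from __future__ import annotations

import numpy as np

from phantompeaks import IntervalSet


def mask_from_set(s: IntervalSet, chrom: str, length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for c, a, b in s.df[["chrom", "start", "end"]].itertuples(index=False):
        if c == chrom:
            m[a:b] = True
    return m


def runs_from_mask(mask: np.ndarray, chrom: str) -> list[tuple[str, int, int]]:
    """Extract maximal True runs as intervals."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append((chrom, int(s), int(e)))
    return out


def random_interval_set(
    rng: np.random.Generator,
    chroms: list[str],
    length: int,
    n: int,
    max_width: int = 300,
) -> IntervalSet:
    rows = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, max(1, length - w)))
        rows.append((c, s, s + w))
    return IntervalSet(rows)


def brute_merge(s: IntervalSet, chroms: list[str], length: int,
                min_gap: int = 0) -> list[tuple[str, int, int]]:
    """Merge via mask dilation: close gaps < min_gap, then extract runs."""
    out = []
    for c in chroms:
        m = mask_from_set(s, c, length + min_gap + 1)
        if min_gap > 0:
            # join runs separated by fewer than min_gap free bases
            runs = runs_from_mask(m, c)
            m2 = np.zeros_like(m)
            for _, a, b in runs:
                m2[a:b] = True
            for (_, a1, b1), (_, a2, b2) in zip(runs, runs[1:]):
                if a2 - b1 <= min_gap:
                    m2[b1:a2] = True
            m = m2
        out.extend(runs_from_mask(m, c))
    return out


def brute_hits(
    query: IntervalSet, subject: IntervalSet, min_overlap: int,
    chroms: list[str], length: int,
) -> np.ndarray:
    """All-pairs scan against the merged subject (per-base merge oracle)."""
    merged = []
    for c in chroms:
        merged.extend(runs_from_mask(mask_from_set(subject, c, length), c))
    hits = np.zeros(len(query), dtype=bool)
    for i, (c, a, b) in enumerate(
        query.df[["chrom", "start", "end"]].itertuples(index=False)
    ):
        for mc, ms, me in merged:
            if mc == c and min(b, me) - max(a, ms) >= min_overlap:
                hits[i] = True
    return hits
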