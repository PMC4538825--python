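"""Fixed-width peak calling and consensus calling across antibody replicates.

The caller identifies fixed-width windows of ChIP enrichment over a local
input background — the strategy that gives fixed-width callers their
sensitivity for punctate binding. It is deliberately simple and fully
specified: ChIP and input tracks are depth-normalized to a common total,
sliding windows are scored by ChIP signal, the expected signal per window is
the larger of the local and genome-wide input mean scaled to window width,
and a window is a candidate iff it clears both a Poisson upper-tail test and
a minimum fold enrichment. Candidates are reduced to non-overlapping peaks
greedily by decreasing fold (ties broken leftmost). Downstream stages accept
externally produced BED peak sets, so any other caller can be substituted.

Replicate profiles (e.g. different antibodies against the same factor) are
combined by :func:`consensus_peaks` via single-linkage chaining on the
pairwise >= ``min_overlap`` bp relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .intervals import IntervalSet
from .io import CoverageTrack, normalize_track


@dataclass
class PeakCallConfig:
    """Tunable parameters of the fixed-width caller.

    peak_width and step must be multiples of the track bin size;
    ``target_total`` is the common depth both libraries are scaled to
    before testing (1e6, mirroring per-million library-size normalization).
    """

    peak_width: int = 200
    step: int | None = None  # default: one bin
    min_fold_over_input: float = 4.0
    poisson_alpha: float = 1e-4
    local_background_halfwidth: int = 5000
    target_total: float = 1e6

    def __post_init__(self) -> None:
        if not 0 < self.poisson_alpha < 1:
            raise ValueError("poisson_alpha must be in (0, 1)")
        if self.min_fold_over_input <= 1:
            raise ValueError("min_fold_over_input must exceed 1")
        if self.peak_width < 1:
            raise ValueError("peak_width must be positive")


def _poisson_upper_tail(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """P(X >= observed) for X ~ Poisson(expected), continuous in observed.

    Uses the regularized lower incomplete gamma function, which coincides
    with the Poisson upper tail at integer observed counts and extends it
    smoothly to the fractional counts produced by depth normalization.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    out = np.ones_like(obs)
    pos = obs > 0
    out[pos] = special.gammainc(obs[pos], exp[pos])
    return out


def call_fixed_width_peaks(
    chip: CoverageTrack,
    input_: CoverageTrack,
    cfg: PeakCallConfig | None = None,
) -> IntervalSet:
    """Call fixed-width peaks from a ChIP track against an input track.

    Returns an IntervalSet whose rows carry ``name`` (``peak_N``) and
    ``score`` (observed/expected fold). All peaks have width
    ``cfg.peak_width`` and never overlap one another.
    """
    cfg = cfg or PeakCallConfig()
    if chip.bin_size != input_.bin_size:
        raise ValueError(
            f"bin size mismatch: chip {chip.bin_size} vs input {input_.bin_size}"
        )
    if set(chip.data) != set(input_.data) or any(
        len(chip.data[c]) != len(input_.data[c]) for c in chip.data
    ):
        raise ValueError("chip and input tracks cover different chromosomes")
    bin_size = chip.bin_size
    if cfg.peak_width < bin_size:
        raise ValueError("peak_width smaller than bin size")
    if cfg.peak_width % bin_size != 0:
        raise ValueError("peak_width must be a multiple of bin_size")
    step = cfg.step if cfg.step is not None else bin_size
    if step % bin_size != 0:
        raise ValueError("step must be a multiple of bin_size")
    if chip.total_signal == 0 or input_.total_signal == 0:
        if chip.total_signal == 0:
            return IntervalSet()
        raise ValueError("input track has zero total signal")

    chip_n = normalize_track(chip, cfg.target_total)
    input_n = normalize_track(input_, cfg.target_total)
    k = cfg.peak_width // bin_size
    step_bins = step // bin_size
    hb = max(1, cfg.local_background_halfwidth // bin_size)
    global_mean = input_n.total_signal / input_n.n_bins()

    candidates = []  # (fold, chrom, start_bp, end_bp)
    for chrom in sorted(chip_n.data):
        c = chip_n.data[chrom]
        iv = input_n.data[chrom]
        n = len(c)
        if n < k:
            continue
        ccum = np.concatenate([[0.0], np.cumsum(c)])
        icum = np.concatenate([[0.0], np.cumsum(iv)])
        starts = np.arange(0, n - k + 1, step_bins)
        obs = ccum[starts + k] - ccum[starts]
        centers = starts + k // 2
        lo = np.maximum(0, centers - hb)
        hi = np.minimum(n, centers + hb + 1)
        local_mean = (icum[hi] - icum[lo]) / (hi - lo)
        expected = np.maximum(local_mean, global_mean) * k
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(expected > 0, obs / expected, np.inf)
        pvals = _poisson_upper_tail(obs, expected)
        keep = (pvals < cfg.poisson_alpha) & (fold >= cfg.min_fold_over_input)
        for s, f in zip(starts[keep], fold[keep]):
            candidates.append(
                (float(f), chrom, int(s) * bin_size, (int(s) + k) * bin_size)
            )

    # greedy non-overlap resolution: best fold first, ties leftmost
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for fold, chrom, start, end in candidates:
        taken = chosen.setdefault(chrom, [])
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        rows.append((chrom, start, end, fold))
    rows.sort(key=lambda t: (t[0], t[1]))
    records = [
        (chrom, start, end, f"peak_{i + 1}", fold)
        for i, (chrom, start, end, fold) in enumerate(rows)
    ]
    return IntervalSet(records, name=chip.library_label or "peaks")


def consensus_peaks(
    replicates: list[IntervalSet],
    min_support: int,
    min_overlap: int = 50,
) -> IntervalSet:
    """Combine replicate peak sets into a consensus list.

    Peaks across replicates are grouped by single-linkage chaining on the
    pairwise ">= min_overlap bp overlap" relation; every maximal group drawing
    on at least ``min_support`` distinct replicates yields one consensus
    peak: a fixed-width window centered on the score-weighted mean of member
    centers, scored by the mean member score.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if not 1 <= min_support <= len(replicates):
        raise ValueError(
            f"min_support must be in [1, {len(replicates)}], got {min_support}"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    # flatten: (chrom, start, end, score, replicate_index)
    peaks = []
    for r, rep in enumerate(replicates):
        df = rep.df
        scores = (
            df["score"].to_numpy(dtype=float)
            if "score" in df.columns
            else np.ones(len(df))
        )
        for (chrom, start, end), score in zip(
            df[["chrom", "start", "end"]].itertuples(index=False), scores
        ):
            peaks.append((chrom, int(start), int(end), float(score), r))
    n = len(peaks)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    order = sorted(range(n), key=lambda i: (peaks[i][0], peaks[i][1]))
    active: list[int] = []
    for i in order:
        chrom, start, end, _, _ = peaks[i]
        active = [
            j for j in active
            if peaks[j][0] == chrom and peaks[j][2] > start
        ]
        for j in active:
            ov = min(end, peaks[j][2]) - max(start, peaks[j][1])
            if ov >= min_overlap:
                union(i, j)
        active.append(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    rows = []
    for members in groups.values():
        reps = {peaks[i][4] for i in members}
        if len(reps) < min_support:
            continue
        chrom = peaks[members[0]][0]
        centers = np.array([(peaks[i][1] + peaks[i][2]) // 2 for i in members])
        scores = np.array([peaks[i][3] for i in members])
        widths = np.array([peaks[i][2] - peaks[i][1] for i in members])
        wsum = scores.sum()
        weights = scores / wsum if wsum > 0 else np.full(len(members), 1 / len(members))
        center = int(round(float((weights * centers).sum())))
        width = int(round(float(widths.mean())))
        start = max(0, center - width // 2)
        rows.append((chrom, start, start + width, float(scores.mean())))
    rows.sort(key=lambda t: (t[0], t[1]))
    records = [
        (chrom, start, end, f"consensus_{i + 1}", score)
        for i, (chrom, start, end, score) in enumerate(rows)
    ]
    return IntervalSet(records, name="consensus")
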