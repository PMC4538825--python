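"""Readers and writers for the formats the pipeline touches.

Supported formats: BED3/BED5/BED6 (peaks, catalogs, HDRs, reference
regions), bedGraph and fixed-step wiggle (coverage), a simplified GTF subset
or a documented TSV dialect (gene models), and TSV (expression tables,
DamID probe tables).

Conventions enforced here, at the I/O boundary:

* Internal coordinates are always 0-based half-open; GTF (1-based
  inclusive) is converted on load.
* Chromosome names are taken verbatim — no "chr" stripping or adding.
* Readers reject structural violations with an error naming file and line
  rather than silently repairing them.

The TSV gene-model dialect is tab-separated with columns: gene_id, chrom,
strand, txStart, txEnd, comma-separated exon starts, comma-separated exon
ends — all coordinates 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet

DEFAULT_BIN_SIZE = 25  # bp; fine enough to localize 200 bp peaks


class ParseError(ValueError):
    """A structural violation in an input file, with file and line context."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# -- coverage tracks --------------------------------------------------------


class CoverageTrack:
    """Per-chromosome binned read-density vectors.

    Parameters
    ----------
    bin_size
        Width of each bin in bp.
    data
        Mapping chromosome -> 1-D float vector of per-bin values (>= 0).
        ``len(vector) * bin_size`` spans the chromosome.
    library_label
        Free-text label of the sequencing library the track came from.
    """

    def __init__(
        self,
        bin_size: int,
        data: dict[str, np.ndarray],
        library_label: str = "",
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, v in self.data.items():
            if v.ndim != 1:
                raise ValueError(f"{chrom}: coverage vector must be 1-D")
            if (v < 0).any():
                raise ValueError(f"{chrom}: negative coverage value")
        self.library_label = library_label

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length(c) for c in self.data}

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.data.values()))

    def all_values(self) -> np.ndarray:
        """All bin values genome-wide, concatenated in chromosome order."""
        if not self.data:
            return np.array([], dtype=float)
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            self.library_label,
        )


def normalize_track(t: CoverageTrack, target_total: float) -> CoverageTrack:
    """Scale a track so its total signal equals ``target_total``.

    Mirrors library-size normalization of sequencing depth (the study
    convention is 1 million reads per library); the shape of the track is
    preserved up to one global scalar.
    """
    total = t.total_signal
    if total <= 0:
        raise ValueError("cannot normalize a track with zero total signal")
    scale = float(target_total) / total
    return CoverageTrack(
        t.bin_size,
        {c: v * scale for c, v in t.data.items()},
        t.library_label,
    )


# -- gene models / expression / DamID probes --------------------------------


@dataclass
class GeneModel:
    """A simplified transcript model with strand-resolved TSS and TTS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tss == self.tts:
            raise ValueError(f"{self.gene_id}: tss == tts")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has zero exons")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = [(int(s), int(e)) for s, e in ex]

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tts), max(self.tss, self.tts))

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class ExpressionTable:
    """gene_id -> non-negative expression value (arbitrary units)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{g}: expression must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def get(self, gene_id: str):
        return self.values.get(gene_id)


@dataclass
class DamIdProbeTable:
    """Microarray probe positions with scores (one record per probe)."""

    records: pd.DataFrame  # columns: chrom, position, score, probe_id

    def __post_init__(self) -> None:
        df = self.records
        needed = {"chrom", "position", "score", "probe_id"}
        if not needed.issubset(df.columns):
            raise ValueError(f"probe table needs columns {sorted(needed)}")
        if (df["position"] < 0).any():
            raise ValueError("probe positions must be >= 0")
        if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
            raise ValueError("probe scores must be finite")

    def __len__(self) -> int:
        return len(self.records)


# -- BED --------------------------------------------------------------------


def read_bed(path) -> IntervalSet:
    """Read BED3/BED5/BED6 into an IntervalSet (scores/names kept if present).

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Unsorted input is accepted and sorted on load; a record with
    ``end <= start`` is rejected with its line number.
    """
    rows = []
    ncol_seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if start < 0:
                raise ParseError(path, lineno, f"negative start {start}")
            if end <= start:
                raise ParseError(
                    path, lineno, f"end <= start ([{start}, {end}))"
                )
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                row["name"] = parts[3]
            if len(parts) >= 5:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric score")
            if len(parts) >= 6:
                row["strand"] = parts[5]
            ncol_seen = max(ncol_seen, min(len(parts), 6))
            rows.append(row)
    df = pd.DataFrame(rows) if rows else None
    return IntervalSet(df, name=Path(path).stem)


def write_bed(s: IntervalSet, path, header: str | None = None) -> None:
    """Write an IntervalSet as BED; ``header`` becomes a ``#`` comment line
    carrying provenance (command, parameters, seed)."""
    df = s.df
    cols = ["chrom", "start", "end"]
    for c in ("name", "score", "strand"):
        if c in df.columns:
            cols.append(c)
        else:
            break
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


# -- bedGraph / wiggle ------------------------------------------------------


def read_bedgraph(
    path,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_sizes: dict[str, int] | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a binned CoverageTrack.

    Record values are length-weighted into bins when boundaries do not fall
    on bin edges, so the total signal (record value x record length in bins,
    summed) is conserved exactly. Overlapping records and negative values
    are rejected.
    """
    recs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(path, lineno, "fewer than 4 columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(path, lineno, "malformed record")
            if end <= start:
                raise ParseError(path, lineno, "end <= start")
            if value < 0:
                raise ParseError(path, lineno, f"negative value {value}")
            recs.setdefault(chrom, []).append((start, end, value))
    data: dict[str, np.ndarray] = {}
    for chrom, rows in recs.items():
        rows.sort()
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ParseError(
                    path, 0, f"overlapping bedGraph records on {chrom}"
                )
        span = rows[-1][1]
        if chrom_sizes and chrom in chrom_sizes:
            span = max(span, chrom_sizes[chrom])
        nbins = -(-span // bin_size)
        vec = np.zeros(nbins)
        for start, end, value in rows:
            b0, b1 = start // bin_size, -(-end // bin_size)
            for b in range(b0, b1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                vec[b] += value * (hi - lo)
        # a record of value v spanning L bp contributes v * L / bin_size in
        # total, so "chrom 0 200 3.0" at bin_size=100 yields bins [3.0, 3.0]
        # and the track total is the length-weighted sum of record values
        # with length measured in bins
        data[chrom] = vec / bin_size
    return CoverageTrack(bin_size, data, library_label=Path(path).stem)


def write_bedgraph(t: CoverageTrack, path, header: str | None = None) -> None:
    """Write a CoverageTrack as bedGraph, one record per bin (zeros skipped)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for chrom in sorted(t.data):
            v = t.data[chrom]
            for b in np.flatnonzero(v):
                fh.write(
                    f"{chrom}\t{b * t.bin_size}\t{(b + 1) * t.bin_size}"
                    f"\t{v[b]:g}\n"
                )


def read_fixedstep_wig(path) -> CoverageTrack:
    """Read a fixed-step wiggle file; the step doubles as the bin size.

    Requires ``span == step`` (contiguous bins) and a consistent step across
    declaration blocks.
    """
    data: dict[str, list[float]] = {}
    step = None
    chrom = None
    pos = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                try:
                    chrom = fields["chrom"]
                    start = int(fields["start"])  # wiggle is 1-based
                    this_step = int(fields.get("step", 1))
                except (KeyError, ValueError):
                    raise ParseError(path, lineno, "malformed fixedStep header")
                span = int(fields.get("span", this_step))
                if span != this_step:
                    raise ParseError(path, lineno, "span != step unsupported")
                if step is None:
                    step = this_step
                elif step != this_step:
                    raise ParseError(path, lineno, "inconsistent step")
                pos = start - 1
                if pos % step != 0:
                    raise ParseError(
                        path, lineno, "start not aligned to step grid"
                    )
                data.setdefault(chrom, [])
                vec = data[chrom]
                while len(vec) < pos // step:
                    vec.append(0.0)
                continue
            if chrom is None:
                raise ParseError(path, lineno, "data before fixedStep header")
            try:
                value = float(line)
            except ValueError:
                raise ParseError(path, lineno, "non-numeric value")
            if value < 0:
                raise ParseError(path, lineno, f"negative value {value}")
            vec = data[chrom]
            idx = pos // step
            while len(vec) <= idx:
                vec.append(0.0)
            vec[idx] = value
            pos += step
    if step is None:
        return CoverageTrack(DEFAULT_BIN_SIZE, {}, library_label=Path(path).stem)
    return CoverageTrack(
        step,
        {c: np.array(v) for c, v in data.items()},
        library_label=Path(path).stem,
    )


# -- gene models ------------------------------------------------------------


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from the TSV dialect or a simplified GTF.

    Files whose data lines have 9 tab-separated fields with a feature column
    are treated as GTF (1-based inclusive, converted on load; ``exon``
    features grouped by ``gene_id``); otherwise the 7-column TSV dialect is
    expected. TSS is the start of the transcript on ``+``, its end on ``-``.
    """
    with open(path) as fh:
        first_data = None
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first_data = line
                break
    if first_data is None:
        return []
    nfields = len(first_data.rstrip("\n").split("\t"))
    if nfields == 9:
        return _read_gtf(path)
    return _read_gene_tsv(path)


def _read_gene_tsv(path) -> list[GeneModel]:
    models = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(path, lineno, "expected 7 columns")
            gid, chrom, strand, tx_s, tx_e, ex_s, ex_e = parts
            if gid in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gid}")
            seen.add(gid)
            try:
                tx_s, tx_e = int(tx_s), int(tx_e)
                starts = [int(x) for x in ex_s.split(",") if x]
                ends = [int(x) for x in ex_e.split(",") if x]
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinate")
            if len(starts) != len(ends) or not starts:
                raise ParseError(path, lineno, f"gene {gid} has zero exons")
            tss, tts = (tx_s, tx_e) if strand == "+" else (tx_e, tx_s)
            try:
                models.append(
                    GeneModel(gid, chrom, strand, tss, tts,
                              list(zip(starts, ends)))
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    return models


def _read_gtf(path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, "expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature != "exon":
                continue
            try:
                # GTF is 1-based inclusive -> 0-based half-open
                s, e = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinate")
            gid = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gid = item.split(None, 1)[1].strip().strip('"')
            if gid is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            if gid not in exons:
                exons[gid] = []
                meta[gid] = (chrom, strand)
                order.append(gid)
            elif meta[gid] != (chrom, strand):
                raise ParseError(
                    path, lineno, f"gene {gid} spans chrom/strand"
                )
            exons[gid].append((s, e))
    models = []
    for gid in order:
        chrom, strand = meta[gid]
        ex = sorted(exons[gid])
        tx_s, tx_e = ex[0][0], ex[-1][1]
        tss, tts = (tx_s, tx_e) if strand == "+" else (tx_e, tx_s)
        models.append(GeneModel(gid, chrom, strand, tss, tts, ex))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    """Write gene models in the 7-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                "\t".join([
                    m.gene_id, m.chrom, m.strand, str(lo), str(hi),
                    ",".join(str(s) for s, _ in m.exons),
                    ",".join(str(e) for _, e in m.exons),
                ]) + "\n"
            )


def read_expression(path) -> ExpressionTable:
    """Read a 2-column TSV ``gene_id<TAB>value`` into an ExpressionTable."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, "expected 2 columns")
            gid = parts[0]
            if gid in values:
                raise ParseError(path, lineno, f"duplicate gene_id {gid}")
            try:
                values[gid] = float(parts[1])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric expression value")
    return ExpressionTable(values)


def write_expression(expr: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\texpression\n")
        for gid, v in expr.values.items():
            fh.write(f"{gid}\t{v:g}\n")


def read_damid(path) -> DamIdProbeTable:
    """Read a DamID probe table: TSV chrom, position, score[, probe_id]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "expected >= 3 columns")
            try:
                pos, score = int(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "malformed probe record")
            pid = parts[3] if len(parts) >= 4 else f"probe_{lineno}"
            rows.append((parts[0], pos, score, pid))
    df = pd.DataFrame(rows, columns=["chrom", "position", "score", "probe_id"])
    return DamIdProbeTable(df)


def write_damid(probes: DamIdProbeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tposition\tscore\tprobe_id\n")
        for row in probes.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.score:g}\t{row.probe_id}\n")
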