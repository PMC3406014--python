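"""BED input and BED/bedGraph output with strict coordinate conventions.

All coordinates are 0-based half-open (UCSC BED convention); chromosome
names are passed through verbatim.  Aligned reads are held in a pandas
DataFrame (``ReadTable``) with columns ``chrom, start, end, strand`` —
one row per read, grouped by chromosome and sorted by start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column layout of a read table.
READ_COLUMNS = ["chrom", "start", "end", "strand"]

# Alias so call sites can annotate intent; a ReadTable is a plain DataFrame
# with READ_COLUMNS, sorted by (chrom, start).
ReadTable = pd.DataFrame

#: BED score cap used when a p-value underflows to exactly 0.
SCORE_CAP = 1000.0


@dataclass
class RegionCall:
    """A called peak (TF) or island (HM).

    ``start``/``end`` delimit the above-threshold area, 0-based half-open.
    ``summit`` (TF only) is the single position of maximal posterior mean;
    ``sub_start``/``sub_end`` delimit the sub-area grown from the summit
    block while adjacent posterior means differ by less than one.
    ``score`` is -log10 of the input-control p-value, capped at
    ``SCORE_CAP`` when the p-value underflows.
    """

    chrom: str
    start: int
    end: int
    mean_level: float
    summit: Optional[int] = None
    sub_start: Optional[int] = None
    sub_end: Optional[int] = None
    pvalue: float = 1.0
    score: float = 0.0
    chip_count: int = 0
    lambda0: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end} is empty or inverted")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError("summit lies outside the region")

    @property
    def length(self) -> int:
        return self.end - self.start


def score_from_pvalue(pvalue: float, cap: float = SCORE_CAP) -> float:
    """-log10(p), capped for p that underflows to 0."""
    if pvalue <= 0.0:
        return cap
    return min(-np.log10(pvalue), cap)


def _parse_strand(token: str, lineno: int) -> str:
    # Tolerate the typographic minus occasionally produced by text exports.
    if token in ("+",):
        return "+"
    if token in ("-", "−"):
        return "-"
    if token == ".":
        return "."
    raise ValueError(f"line {lineno}: invalid strand {token!r}")


def read_bed(path, *, require_strand: bool = False) -> ReadTable:
    """Parse a BED file of aligned reads into a ReadTable.

    Accepts BED6 (strand in column 6) or bare BED3; 3-column records get
    strand "+" with a logged warning.  With ``require_strand=True`` (TF
    mode, where the fragment-shift estimate needs strands) a missing
    strand column is an error instead.

    Raises
    ------
    ValueError
        On a malformed line (naming the line number) or an inverted
        interval (``end <= start``).
    """
    chroms: List[str] = []
    starts: List[int] = []
    ends: List[int] = []
    strands: List[str] = []
    warned_strand = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValueError(f"line {lineno}: negative start {start}")
            if end <= start:
                raise ValueError(f"line {lineno}: end {end} <= start {start}")
            if len(fields) >= 6:
                strand = _parse_strand(fields[5], lineno)
                if strand == ".":
                    strand = ""
            else:
                strand = ""
            if not strand:
                if require_strand:
                    raise ValueError(f"line {lineno}: strand required but absent")
                if not warned_strand:
                    logger.warning("%s: records without strand; defaulting to '+'", path)
                    warned_strand = True
                strand = "+"
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    reads = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "start": pd.Series(starts, dtype="int64"),
            "end": pd.Series(ends, dtype="int64"),
            "strand": pd.Series(strands, dtype="object"),
        }
    )
    return reads.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def reads_from_arrays(chrom, start, end, strand) -> ReadTable:
    """Assemble a sorted ReadTable from parallel arrays (simulator helper)."""
    reads = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": np.asarray(strand, dtype=object),
        }
    )
    return reads.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_reads_bed(reads: ReadTable, path, name_prefix: str = "read") -> None:
    """Write a ReadTable as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for i, row in enumerate(reads.itertuples(index=False), start=1):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name_prefix}_{i}\t0\t{row.strand}\n")


def write_regions_bed(regions: Sequence[RegionCall], path, mode: str = "hm") -> None:
    """Write called regions as BED6 (+ summit offset column in TF mode).

    Columns: chrom, start, end, name (``peak_N``/``island_N``), score
    (-log10 p, capped), strand ".".  TF mode appends the summit offset
    relative to ``start`` as a 7th column.
    """
    label = "peak" if mode == "tf" else "island"
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand" + ("\tsummit_offset" if mode == "tf" else "") + "\n")
        for i, r in enumerate(regions, start=1):
            score = score_from_pvalue(r.pvalue) if r.score == 0.0 and r.pvalue < 1.0 else r.score
            line = f"{r.chrom}\t{r.start}\t{r.end}\t{label}_{i}\t{score:g}\t."
            if mode == "tf":
                offset = (r.summit - r.start) if r.summit is not None else -1
                line += f"\t{offset}"
            fh.write(line + "\n")


def write_bedgraph(track, path, precision: int = 4) -> None:
    """Write a posterior-mean track as bedGraph, merging equal-value runs.

    ``track`` is a PosteriorTrack (or any object with ``chrom``, block
    ``edges`` and per-block ``values``).  Adjacent blocks whose values
    agree after rounding to ``precision`` decimals are merged into one
    line; zero values are written, not suppressed, so the output exactly
    tiles the track's span.
    """
    edges = np.asarray(track.edges)
    values = np.round(np.asarray(track.values, dtype=float), precision)

    def _emit(fh):
        i = 0
        n = len(values)
        while i < n:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            fh.write(f"{track.chrom}\t{edges[i]}\t{edges[j + 1]}\t{values[i]:.{precision}f}\n")
            i = j + 1

    if hasattr(path, "write"):  # already-open handle: append to it
        _emit(path)
    else:
        with open(path, "w") as fh:
            _emit(fh)


def read_intervals_bed(path) -> pd.DataFrame:
    """Read a BED file of plain intervals (features, motif hits, truth sets)."""
    chroms: List[str] = []
    starts: List[int] = []
    ends: List[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED fields")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
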