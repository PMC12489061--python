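"""Genome fraction at risk of paralog-mediated rearrangement.

A double-strand break (DSB) can engage an ectopic repeat (a paralogous gene)
under two geometries:

* **CO geometry** — the break falls inside the repeat itself, with at least a
  margin of intact homology on each side of the cut, so that the canonical
  double-strand-break-repair pathway can form a crossover (a translocation).

* **Resection-exposure geometry** — one-ended pathways (half-crossover,
  break-induced replication, multi-invasion-induced rearrangement) only need
  the repeat to be *exposed* as single-stranded DNA by 5'->3' end resection.
  Resection proceeds bidirectionally from the break at speed ``v`` (bp/h), so
  after time ``t`` each end has resected a tract of length ``L = v * t``.  A
  repeat engages recombination once at least ``E_min`` contiguous bp of it are
  single-stranded on at least one side of the break.

For a repeat occupying the half-open interval ``[s, e)`` on a chromosome, with
``len = e - s``, the set of integer DSB positions ``x`` whose right-hand tract
``[x, x+L)`` exposes ``>= E_min`` bp of the repeat is the closed interval
``[s-(L-E_min), e-E_min]``, and the left-hand tract ``[x-L, x)`` works for
``x`` in ``[s+E_min, e+(L-E_min)]`` (both empty when ``L < E_min`` or
``len < E_min``).  In half-open coordinates these are
``[s-(L-E_min), e-E_min+1)`` and ``[s+E_min, e+(L-E_min)+1)``; the two arms
coalesce once ``len >= 2*E_min - 1``.  The union of these sets over all
repeats, merged and clipped to the chromosomes, divided by total genome
length, is the at-risk genome fraction.  A brute-force per-position oracle
(:func:`per_base_oracle`) reproduces the same fraction exactly and is used to
validate the closed form.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input is
converted on parsing.  Adjacent half-open intervals merge (position-set union
semantics).
"""

from __future__ import annotations

import dataclasses
import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "ResectionParams",
    "RiskProfile",
    "parse_annotation",
    "read_chrom_sizes",
    "merge_intervals",
    "exposure_intervals",
    "co_eligible_zone",
    "co_risk_fraction",
    "resection_risk_fraction",
    "risk_profile",
    "per_base_oracle",
    "per_base_co_oracle",
    "repeat_coverage",
]

PER_BASE_LIMIT = 10_000_000  # largest genome the brute-force oracle will scan

INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "strand"]


# ---------------------------------------------------------------------------
# Annotation container and parsing
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus named, stranded repeat intervals.

    ``intervals`` is a DataFrame with columns chrom/start/end/name/strand in
    0-based half-open coordinates.  Intervals may overlap one another (tandem
    paralog arrays do); gene names must be unique.
    """

    chrom_sizes: dict[str, int]
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        df = self.intervals
        if list(df.columns) != INTERVAL_COLUMNS:
            df = df.reindex(columns=INTERVAL_COLUMNS)
            self.intervals = df
        if len(df):
            if df["name"].duplicated().any():
                dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
                raise ValueError(f"duplicate gene ID {dup!r} in annotation")
            for row in df.itertuples(index=False):
                size = self.chrom_sizes.get(row.chrom)
                if size is None:
                    raise ValueError(f"interval {row.name!r} on unknown chromosome {row.chrom!r}")
                if not (0 <= row.start < row.end <= size):
                    raise ValueError(
                        f"interval {row.name!r} ({row.chrom}:{row.start}-{row.end}) "
                        f"outside [0, {size})"
                    )

    @property
    def genome_bp(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def intervals_on(self, chrom: str) -> np.ndarray:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)


@dataclass
class ResectionParams:
    """Resection-exposure model parameters.

    speed_bp_per_hr : resection speed v; ~4000 bp/h in S. cerevisiae.
    min_exposure_bp : E_min, minimal contiguous single-stranded repeat length
        (300 bp) needed to engage recombination.
    co_margin_bp    : margin from each repeat edge required for CO geometry
        (300 bp).
    times_hr        : time grid in hours; L = v*t.
    """

    speed_bp_per_hr: float = 4000.0
    min_exposure_bp: int = 300
    co_margin_bp: int = 300
    times_hr: Sequence[float] = field(default_factory=lambda: tuple(np.round(np.arange(0, 4.0 + 1e-9, 0.1), 10)))
    naive_extend: bool = False
    both_ends: bool = False

    def __post_init__(self) -> None:
        if self.speed_bp_per_hr <= 0:
            raise ValueError("resection speed must be > 0")
        if self.min_exposure_bp <= 0:
            raise ValueError("min_exposure_bp must be > 0")
        if self.co_margin_bp < 0:
            raise ValueError("co_margin_bp must be >= 0")
        if any(t < 0 for t in self.times_hr):
            raise ValueError("time grid must be non-negative")

    def tract_length(self, t_hours: float) -> int:
        return int(round(self.speed_bp_per_hr * t_hours))


def read_chrom_sizes(path: str | os.PathLike | io.TextIOBase) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length in bp)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "size"], dtype={"chrom": str})
    return {str(r.chrom): int(r.size) for r in df.itertuples(index=False)}


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|Name|gene_id)=([^;]+)")


def parse_annotation(path: str | os.PathLike,
                     chrom_sizes: str | os.PathLike | dict[str, int],
                     fmt: str | None = None) -> GenomeAnnotation:
    """Parse repeat intervals from BED6 or GFF3 against chromosome sizes.

    BED is consumed as 0-based half-open; GFF3 (1-based closed) is converted.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    sizes = chrom_sizes if isinstance(chrom_sizes, dict) else read_chrom_sizes(chrom_sizes)
    if fmt is None:
        name = str(path).lower()
        fmt = "gff" if name.endswith((".gff", ".gff3", ".gtf")) else "bed"
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                    strand = fields[6] if len(fields) > 6 else "."
                    m = _GFF_ID_RE.search(fields[8]) if len(fields) > 8 else None
                    gene = m.group(1) if m else f"feature_{lineno}"
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed {fmt.upper()} line {lineno}: {line!r}") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end ({end}) <= start ({start})")
            if chrom not in sizes:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            records.append((chrom, start, end, gene, strand))
    df = pd.DataFrame(records, columns=INTERVAL_COLUMNS)
    return GenomeAnnotation(chrom_sizes=sizes, intervals=df)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> pd.DataFrame:
    """Merge possibly-overlapping half-open intervals into a disjoint cover.

    Adjacent intervals ([0,10) + [10,20)) merge: the result represents the
    union of positions.  Returns a DataFrame (chrom, start, end) sorted by
    chromosome then start; total bp equals the cardinality of the union.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end > start:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _total_bp(merged: pd.DataFrame) -> int:
    if not len(merged):
        return 0
    return int((merged["end"] - merged["start"]).sum())


def repeat_coverage(ann: GenomeAnnotation) -> tuple[int, int]:
    """(merged bp, unmerged bp) covered by the annotated repeats."""
    ivs = [(r.chrom, r.start, r.end) for r in ann.intervals.itertuples(index=False)]
    merged = merge_intervals(ivs)
    unmerged = int((ann.intervals["end"] - ann.intervals["start"]).sum()) if len(ann.intervals) else 0
    return _total_bp(merged), unmerged


# ---------------------------------------------------------------------------
# CO geometry
# ---------------------------------------------------------------------------

def co_eligible_zone(start: int, end: int, margin: int, chrom_length: int) -> list[tuple[int, int]]:
    """DSB positions inside ``[start, end)`` with >= margin intact repeat bp on
    each side of the broken base: the half-open zone [start+margin, end-margin),
    i.e. max(0, len - 2*margin) positions."""
    lo, hi = start + margin, end - margin
    lo, hi = max(lo, 0), min(hi, chrom_length)
    return [(lo, hi)] if hi > lo else []


def co_risk_fraction(ann: GenomeAnnotation, margin: int | None = None,
                     params: ResectionParams | None = None) -> float:
    """Fraction of the genome from which a DSB can yield a CO between repeats.

    Eligible zones of overlapping repeats are merged before summing; an empty
    annotation yields 0.0.
    """
    if margin is None:
        margin = (params or ResectionParams()).co_margin_bp
    if margin < 0:
        raise ValueError("margin must be >= 0")
    zones = []
    for row in ann.intervals.itertuples(index=False):
        for s, e in co_eligible_zone(row.start, row.end, margin, ann.chrom_sizes[row.chrom]):
            zones.append((row.chrom, s, e))
    return _total_bp(merge_intervals(zones)) / ann.genome_bp


# ---------------------------------------------------------------------------
# Resection-exposure geometry
# ---------------------------------------------------------------------------

def exposure_intervals(start: int, end: int, tract_len: int, min_exposure: int,
                       chrom_length: int, naive_extend: bool = False) -> list[tuple[int, int]]:
    """DSB positions from which resection of ``tract_len`` bp exposes
    >= ``min_exposure`` contiguous bp of the repeat ``[start, end)`` on at
    least one side of the break.

    Returns clipped half-open intervals (the two arms coalesce when the repeat
    is long enough).  Empty when ``tract_len < min_exposure`` or the repeat is
    shorter than ``min_exposure``.  With ``naive_extend`` the repeat interval
    is simply extended by ``tract_len`` on both sides (compatibility mode; no
    minimal-exposure requirement).
    """
    length = end - start
    if naive_extend:
        lo, hi = max(start - tract_len, 0), min(end + tract_len, chrom_length)
        return [(lo, hi)] if hi > lo else []
    L, E = tract_len, min_exposure
    if L < E or length < E:
        return []
    # right tract [x, x+L): x in [s-(L-E), e-E]; left tract [x-L, x): x in [s+E, e+L-E]
    arms = [(start - (L - E), end - E + 1), (start + E, end + (L - E) + 1)]
    if arms[0][1] >= arms[1][0]:
        arms = [(arms[0][0], arms[1][1])]
    out = []
    for lo, hi in arms:
        lo, hi = max(lo, 0), min(hi, chrom_length)
        if hi > lo:
            out.append((lo, hi))
    return out


def _one_sided_risk_sets(ann: GenomeAnnotation, L: int, E: int, side: str) -> list[tuple[str, int, int]]:
    """Per-repeat risk intervals for a single tract side ('left' or 'right')."""
    out = []
    for row in ann.intervals.itertuples(index=False):
        length = row.end - row.start
        if L < E or length < E:
            continue
        if side == "right":
            lo, hi = row.start - (L - E), row.end - E + 1
        else:
            lo, hi = row.start + E, row.end + (L - E) + 1
        lo, hi = max(lo, 0), min(hi, ann.chrom_sizes[row.chrom])
        if hi > lo:
            out.append((row.chrom, lo, hi))
    return out


def at_risk_intervals(ann: GenomeAnnotation, tract_len: int, min_exposure: int,
                      naive_extend: bool = False, both_ends: bool = False) -> pd.DataFrame:
    """Merged at-risk interval set for a given resection tract length."""
    if both_ends and not naive_extend:
        left = merge_intervals(_one_sided_risk_sets(ann, tract_len, min_exposure, "left"))
        right = merge_intervals(_one_sided_risk_sets(ann, tract_len, min_exposure, "right"))
        return _intersect_merged(left, right)
    ivs = []
    for row in ann.intervals.itertuples(index=False):
        for s, e in exposure_intervals(row.start, row.end, tract_len, min_exposure,
                                       ann.chrom_sizes[row.chrom], naive_extend=naive_extend):
            ivs.append((row.chrom, s, e))
    return merge_intervals(ivs)


def _intersect_merged(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ia = a[a["chrom"] == chrom][["start", "end"]].to_numpy()
        ib = b[b["chrom"] == chrom][["start", "end"]].to_numpy()
        i = j = 0
        while i < len(ia) and j < len(ib):
            lo = max(ia[i, 0], ib[j, 0])
            hi = min(ia[i, 1], ib[j, 1])
            if hi > lo:
                out.append((chrom, int(lo), int(hi)))
            if ia[i, 1] < ib[j, 1]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def resection_risk_fraction(ann: GenomeAnnotation, params: ResectionParams,
                            t_hours: float) -> float:
    """Genome fraction at risk at ``t_hours`` after break formation (L = v*t)."""
    if t_hours < 0:
        raise ValueError("time must be non-negative")
    L = params.tract_length(t_hours)
    merged = at_risk_intervals(ann, L, params.min_exposure_bp,
                               naive_extend=params.naive_extend, both_ends=params.both_ends)
    return _total_bp(merged) / ann.genome_bp


@dataclass
class RiskProfile:
    """Risk fraction as a function of time after break formation."""

    table: pd.DataFrame                       # t_hours, L_bp, at_risk_bp, genome_fraction
    params: ResectionParams
    repeat_coverage_bp: int                   # merged repeat bp
    repeat_coverage_bp_unmerged: int
    genome_bp: int

    @property
    def repeat_coverage_fraction(self) -> float:
        return self.repeat_coverage_bp / self.genome_bp

    def at_risk_intervals(self, ann: GenomeAnnotation, t_hours: float) -> pd.DataFrame:
        return at_risk_intervals(ann, self.params.tract_length(t_hours),
                                 self.params.min_exposure_bp,
                                 naive_extend=self.params.naive_extend,
                                 both_ends=self.params.both_ends)


def risk_profile(ann: GenomeAnnotation, params: ResectionParams | None = None) -> RiskProfile:
    """Evaluate the at-risk genome fraction over the parameter time grid."""
    params = params or ResectionParams()
    if len(params.times_hr) == 0:
        raise ValueError("time grid must be non-empty")
    rows = []
    for t in params.times_hr:
        L = params.tract_length(t)
        merged = at_risk_intervals(ann, L, params.min_exposure_bp,
                                   naive_extend=params.naive_extend,
                                   both_ends=params.both_ends)
        bp = _total_bp(merged)
        rows.append((float(t), L, bp, bp / ann.genome_bp))
    table = pd.DataFrame(rows, columns=["t_hours", "L_bp", "at_risk_bp", "genome_fraction"])
    cov, cov_unmerged = repeat_coverage(ann)
    return RiskProfile(table=table, params=params, repeat_coverage_bp=cov,
                       repeat_coverage_bp_unmerged=cov_unmerged, genome_bp=ann.genome_bp)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def per_base_oracle(ann: GenomeAnnotation, tract_len: int, min_exposure: int,
                    both_ends: bool = False) -> float:
    """Fraction of genomic positions at risk, by direct per-position scan.

    For every position x, the two resection tracts [x-L, x) and [x, x+L) are
    intersected with every repeat; x is at risk if some repeat has >=
    ``min_exposure`` contiguous bp inside a single tract (both tracts must
    succeed when ``both_ends``).  Independent of the closed form; quadratic in
    practice, so refuses genomes above ~10 Mb.
    """
    if ann.genome_bp > PER_BASE_LIMIT:
        raise ValueError(
            f"genome of {ann.genome_bp} bp too large for the per-base oracle; "
            "use resection_risk_fraction (closed form)"
        )
    L, E = int(tract_len), int(min_exposure)
    at_risk = 0
    for chrom, size in ann.chrom_sizes.items():
        x = np.arange(size, dtype=np.int64)
        left_ok = np.zeros(size, dtype=bool)
        right_ok = np.zeros(size, dtype=bool)
        for s, e in ann.intervals_on(chrom):
            # contiguous overlap of tract [x-L, x) with repeat [s, e)
            left_ov = np.minimum(x, e) - np.maximum(x - L, s)
            right_ov = np.minimum(x + L, e) - np.maximum(x, s)
            left_ok |= left_ov >= E
            right_ok |= right_ov >= E
        marked = (left_ok & right_ok) if both_ends else (left_ok | right_ok)
        at_risk += int(marked.sum())
    return at_risk / ann.genome_bp


def per_base_co_oracle(ann: GenomeAnnotation, margin: int) -> float:
    """CO eligibility by per-position scan: position x (the broken base) is
    eligible if some repeat [s, e) contains it with >= margin intact bp
    strictly on each side (x - s >= margin and e - 1 - x >= margin)."""
    if ann.genome_bp > PER_BASE_LIMIT:
        raise ValueError("genome too large for the per-base oracle")
    at_risk = 0
    for chrom, size in ann.chrom_sizes.items():
        x = np.arange(size, dtype=np.int64)
        ok = np.zeros(size, dtype=bool)
        for s, e in ann.intervals_on(chrom):
            ok |= (x - s >= margin) & (e - 1 - x >= margin)
        at_risk += int(ok.sum())
    return at_risk / ann.genome_bp


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: RiskProfile, path: str | os.PathLike,
                      header_lines: Sequence[str] = ()) -> None:
    """Write a RiskProfile table as TSV with '#'-prefixed provenance lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        p = profile.params
        fh.write(f"# speed_bp_per_hr={p.speed_bp_per_hr} min_exposure_bp={p.min_exposure_bp} "
                 f"co_margin_bp={p.co_margin_bp} naive_extend={p.naive_extend} "
                 f"both_ends={p.both_ends}\n")
        fh.write(f"# repeat_coverage_bp={profile.repeat_coverage_bp} "
                 f"repeat_coverage_bp_unmerged={profile.repeat_coverage_bp_unmerged} "
                 f"genome_bp={profile.genome_bp}\n")
        profile.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_intervals_bed(merged: pd.DataFrame, path: str | os.PathLike,
                        header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for row in merged.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
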