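"""Genomic interval primitives and the interval algebra used across the pipeline.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs and two intervals abut
without overlapping when one ends where the other starts.  Strand is one of
``+``, ``-`` or ``.`` and is ignored by the overlap operations (overlap is
strand-blind throughout); it matters only where 5'->3' orientation does,
e.g. transcription start sites and meta-profiles.

The in-memory currency is :class:`IntervalSet`, a thin validated wrapper
around a :class:`pandas.DataFrame` with columns
``chrom, start, end, name, score, strand``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "merge",
    "overlaps",
    "complement",
    "nearest_within",
    "read_gene_table",
    "write_gene_table",
    "tss_positions",
    "point_windows",
    "gene_intervals",
]

_STRANDS = {"+", "-", "."}
_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class Genome:
    """An ordered map of chromosome name -> length in bp, plus a role label.

    ``label`` distinguishes the target genome from the exogenous spike-in
    genome when both are carried through a calibrated experiment.
    """

    sizes: Mapping[str, int]
    label: str = "target"

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError("genome must declare at least one chromosome")
        for chrom, length in self.sizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "sizes", dict(self.sizes))

    @property
    def total_bp(self) -> int:
        return int(sum(self.sizes.values()))

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, label: str = "target") -> "Genome":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, length = line.split("\t")[:2]
                sizes[chrom] = int(length)
        return cls(sizes, label=label)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.sizes.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open, optionally stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col, default in (("name", ""), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["strand"] = df["strand"].astype(str)
        if validate and len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.values)[0])
                row = df.iloc[i]
                raise ValueError(
                    f"invalid interval {row.chrom}:{row.start}-{row.end} at row {i}"
                )
            if not df["strand"].isin(_STRANDS).all():
                raise ValueError("strand must be one of +, -, .")
        self._df = df

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple], columns: Sequence[str] = ("chrom", "start", "end")
    ) -> "IntervalSet":
        return cls(pd.DataFrame.from_records(list(records), columns=list(columns)))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=_COLUMNS))

    # -- basic accessors --------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end), row.strand, row.name, row.score
            )

    def lengths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    def coverage_bp(self) -> int:
        """Total bp covered after merging overlapping intervals."""
        return int(merge(self).lengths().sum())

    def sort(self) -> "IntervalSet":
        out = self._df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(out, validate=False)

    def validate_against(self, genome: Genome) -> None:
        for row in self._df.itertuples():
            if row.chrom not in genome.sizes:
                raise ValueError(f"unknown chromosome {row.chrom!r} (row {row.Index})")
            if row.end > genome.sizes[row.chrom]:
                raise ValueError(
                    f"interval {row.chrom}:{row.start}-{row.end} exceeds chromosome "
                    f"length {genome.sizes[row.chrom]}"
                )


# -- BED I/O ---------------------------------------------------------------

def read_bed(
    path: str | Path,
    genome: Optional[Genome] = None,
    on_unknown_chrom: str = "error",
) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Malformed lines (fewer than three columns, non-numeric or empty/inverted
    coordinates) are rejected with their line numbers.  When ``genome`` is
    given, intervals on undeclared chromosomes either raise
    (``on_unknown_chrom="error"``) or are dropped with a warning
    (``"drop"``).
    """
    if on_unknown_chrom not in ("error", "drop"):
        raise ValueError("on_unknown_chrom must be 'error' or 'drop'")
    records = []
    errors = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append(f"line {lineno}: expected >=3 tab-separated columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start < 0 or start >= end:
                errors.append(f"line {lineno}: empty or inverted interval [{start}, {end})")
                continue
            chrom = fields[0]
            if genome is not None and chrom not in genome.sizes:
                if on_unknown_chrom == "error":
                    errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
                else:
                    dropped += 1
                continue
            name = fields[3] if len(fields) > 3 else ""
            score = np.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            records.append((chrom, start, end, name, score, strand))
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} interval(s) on unknown chromosomes")
    iset = IntervalSet(pd.DataFrame(records, columns=_COLUMNS))
    if genome is not None:
        iset.validate_against(genome)
    return iset


def _format_score(x: float) -> str:
    if np.isnan(x):
        return "."
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 when no name/score/strand is set, BED6 otherwise."""
    df = iset.df
    bed3 = (
        (df["name"] == "").all()
        and df["score"].isna().all()
        and (df["strand"] == ".").all()
    )
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if bed3:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                name = row.name if row.name != "" else "."
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t"
                    f"{_format_score(row.score)}\t{row.strand}\n"
                )


# -- interval algebra ------------------------------------------------------

def merge(a: IntervalSet) -> IntervalSet:
    """Merge overlapping or abutting intervals; strand and names are dropped."""
    if len(a) == 0:
        return IntervalSet.empty()
    df = a.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is None or row.chrom != cur[0] or row.start > cur[2]:
            if cur is not None:
                out.append(cur)
            cur = [row.chrom, row.start, row.end]
        else:
            cur[2] = max(cur[2], row.end)
    out.append(cur)
    return IntervalSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))


def _trees(b: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in b.df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy())
        )
    return trees


def overlaps(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> np.ndarray:
    """Boolean vector over ``a``: does any interval of ``b`` share >= min_bp?

    Strand-blind; ``min_bp`` is the number of shared base pairs with a
    *single* interval of ``b`` (shared bp are not pooled across intervals).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _trees(b)
    hits = np.zeros(len(a), dtype=bool)
    for i, row in enumerate(a.df.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            if min(iv.end, row.end) - max(iv.begin, row.start) >= min_bp:
                hits[i] = True
                break
    return hits


def complement(a: IntervalSet, genome: Genome) -> IntervalSet:
    """Regions of ``genome`` not covered by any interval of ``a``."""
    merged = merge(a)
    by_chrom = {c: sub for c, sub in merged.df.groupby("chrom", sort=False)}
    records = []
    for chrom, length in genome.sizes.items():
        sub = by_chrom.get(chrom)
        pos = 0
        if sub is not None:
            for row in sub.itertuples(index=False):
                s, e = max(0, row.start), min(length, row.end)
                if s > pos:
                    records.append((chrom, pos, s))
                pos = max(pos, e)
        if pos < length:
            records.append((chrom, pos, length))
    if not records:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(records, columns=["chrom", "start", "end"]))


def nearest_within(
    query: IntervalSet, subject: IntervalSet, max_dist: int
) -> pd.DataFrame:
    """For every query interval, the nearest subject within ``max_dist`` bp.

    Distance is 0 for any overlap (and for half-open abutment), otherwise the
    gap in bp between the closest ends.  Ties are broken toward the subject
    with the lower start coordinate, then the lower index in ``subject``.
    Queries with no subject within ``max_dist`` get ``subject_index = -1``
    and ``distance = NaN``.

    Returns a DataFrame aligned to ``query`` with columns
    ``subject_index`` (position in ``subject``) and ``distance``.
    """
    n = len(query)
    idx_out = np.full(n, -1, dtype=np.int64)
    dist_out = np.full(n, np.nan)
    subj = subject.df
    by_chrom = {
        c: (
            sub.index.to_numpy(),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )
        for c, sub in subj.groupby("chrom", sort=False)
    }
    for i, row in enumerate(query.df.itertuples(index=False)):
        got = by_chrom.get(row.chrom)
        if got is None:
            continue
        sidx, ss, se = got
        d = np.maximum(np.maximum(ss - row.end, row.start - se), 0)
        ok = d <= max_dist
        if not ok.any():
            continue
        order = np.lexsort((sidx[ok], ss[ok], d[ok]))
        j = order[0]
        idx_out[i] = sidx[ok][j]
        dist_out[i] = d[ok][j]
    return pd.DataFrame({"subject_index": idx_out, "distance": dist_out})


# -- gene models -----------------------------------------------------------

def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (chrom, start, end, strand, gene_id)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "start", "end", "strand", "gene_id"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return genes


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "strand", "gene_id"]
    genes[cols].to_csv(path, sep="\t", index=False)


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """TSS of each gene: ``start`` on +, ``end - 1`` on - (5'-most base).

    Unstranded genes are treated as plus-strand.  The TSS always lies inside
    the half-open gene interval.
    """
    minus = genes["strand"].to_numpy() == "-"
    return np.where(minus, genes["end"].to_numpy() - 1, genes["start"].to_numpy())


def point_windows(
    genes: pd.DataFrame,
    flank: int,
    genome: Optional[Genome] = None,
    anchor: str = "tss",
) -> IntervalSet:
    """Symmetric windows ``[pos - flank, pos + flank)`` around per-gene anchors.

    Windows are clipped to chromosome bounds when a genome is given; a window
    that clips to nothing is dropped with a warning.  The gene_id travels in
    the ``name`` column and the gene strand is preserved.
    """
    if anchor != "tss":
        raise ValueError("only anchor='tss' is supported")
    pos = tss_positions(genes)
    start = pos - flank
    end = pos + flank
    df = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "name": genes["gene_id"].to_numpy(),
            "strand": genes["strand"].to_numpy(),
        }
    )
    df["start"] = df["start"].clip(lower=0)
    if genome is not None:
        limits = df["chrom"].map(genome.sizes)
        df["end"] = np.minimum(df["end"], limits)
    empty = df["start"] >= df["end"]
    if empty.any():
        warnings.warn(f"dropped {int(empty.sum())} window(s) clipped to nothing")
        df = df[~empty]
    return IntervalSet(df)


def gene_intervals(genes: pd.DataFrame) -> IntervalSet:
    return IntervalSet(
        genes.rename(columns={"gene_id": "name"})[["chrom", "start", "end", "name", "strand"]]
    )
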