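"""Genome tables, origin lists, stranded fragments and binned strand-specific coverage.

All coordinates are 0-based, half-open (BED convention).  A "fragment" is either
an Okazaki fragment (an interval) or a single-base 5'-end read (``end == start + 1``).
Fragment collections are carried around as :class:`pandas.DataFrame` objects with
columns ``chrom, start, end, strand``; most functions also accept plain iterables
of :class:`StrandedFragment`.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from typing import NamedTuple

import numpy as np
import pandas as pd

#: strand symbols: Watson is the top ("+") reference strand, Crick the bottom ("-")
WATSON = "+"
CRICK = "-"
STRANDS = (WATSON, CRICK)

FRAGMENT_COLUMNS = ("chrom", "start", "end", "strand")


class Genome(Mapping):
    """Ordered chromosome-name -> length (bp) map with an optional exclusion set.

    The exclusion set marks chromosomes to be dropped from genome-wide totals
    (e.g. an rDNA-bearing chromosome); it must be a subset of the names.
    """

    def __init__(self, lengths, exclude: Iterable[str] = ()):
        items = lengths.items() if isinstance(lengths, Mapping) else lengths
        self._lengths: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            length = int(length)
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}: {length}")
            self._lengths[name] = length
        if not self._lengths:
            raise ValueError("genome has no chromosomes")
        self.exclude = frozenset(str(n) for n in exclude)
        unknown = self.exclude - set(self._lengths)
        if unknown:
            raise ValueError(f"exclusion set names unknown chromosomes: {sorted(unknown)}")

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    @property
    def included(self) -> tuple[str, ...]:
        """Chromosome names not in the exclusion set, in genome order."""
        return tuple(n for n in self._lengths if n not in self.exclude)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome({len(self)} chromosomes, {sum(self._lengths.values())} bp)"


def load_genome(path, exclude: Iterable[str] = ()) -> Genome:
    """Read a two-column chrom-sizes TSV (name, length) into a :class:`Genome`.

    Row order is preserved.  Raises :class:`ValueError` on malformed rows,
    duplicate names or non-positive lengths.
    """
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed length {parts[1]!r}") from exc
            rows.append((parts[0], length))
    if not rows:
        raise ValueError(f"{path}: empty chrom-sizes file")
    return Genome(rows, exclude=exclude)


@dataclass(frozen=True)
class Origin:
    """A replication origin interval; ``midpoint`` anchors all per-origin statistics."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid origin interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def load_origins(path, genome: Genome) -> list[Origin]:
    """Read a BED3+ origin list, validate against *genome*, sort by (chrom, midpoint).

    Chromosome order follows the genome; ids are taken from column 4 when
    present, otherwise auto-assigned (``origin_0001`` ...) after sorting.
    """
    records: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or start >= end or end > genome[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: interval {start}-{end} outside {chrom} (len {genome[chrom]})"
                )
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else ""
            records.append((chrom, start, end, name))
    order = {name: i for i, name in enumerate(genome.names)}
    records.sort(key=lambda r: (order[r[0]], (r[1] + r[2]) // 2))
    origins = []
    for i, (chrom, start, end, name) in enumerate(records, start=1):
        origins.append(Origin(chrom, start, end, name or f"origin_{i:04d}"))
    return origins


def origins_frame(origins: Iterable[Origin]) -> pd.DataFrame:
    """Tabulate origins (id, chrom, start, end, midpoint)."""
    rows = [(o.id, o.chrom, o.start, o.end, o.midpoint) for o in origins]
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "midpoint"])


class StrandedFragment(NamedTuple):
    """One Okazaki fragment or single-base end read."""

    chrom: str
    start: int
    end: int
    strand: str


def fragment_frame(frags) -> pd.DataFrame:
    """Coerce a fragment collection to the canonical DataFrame representation."""
    if isinstance(frags, pd.DataFrame):
        missing = set(FRAGMENT_COLUMNS) - set(frags.columns)
        if missing:
            raise ValueError(f"fragment frame missing columns: {sorted(missing)}")
        return frags
    rows = list(frags)
    if not rows:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str)}
        )
    return pd.DataFrame(rows, columns=list(FRAGMENT_COLUMNS))


def _validate_fragment_frame(frame: pd.DataFrame, genome: Genome, where: str) -> pd.DataFrame:
    bad_strand = ~frame["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValueError(f"{where}: {int(bad_strand.sum())} record(s) with missing/invalid strand")
    unknown = ~frame["chrom"].isin(genome.names)
    if unknown.any():
        names = sorted(frame.loc[unknown, "chrom"].unique())
        raise ValueError(f"{where}: unknown chromosome(s) {names}")
    if (frame["start"] >= frame["end"]).any():
        raise ValueError(f"{where}: record(s) with start >= end")
    if (frame["start"] < 0).any():
        raise ValueError(f"{where}: negative start coordinate(s)")
    lengths = frame["chrom"].map(dict(genome))
    if (frame["end"] > lengths).any():
        raise ValueError(f"{where}: record(s) extending past chromosome end")
    return frame.reset_index(drop=True)


def load_fragments(path, genome: Genome, mate_strand: int = 1) -> pd.DataFrame:
    """Load aligned reads from BED6 or 10-column BEDPE into a fragment frame.

    The dialect is sniffed from the first data line.  For BEDPE, a fragment is
    the outer span ``min(start1, start2)..max(end1, end2)`` on the shared
    chromosome, and its strand comes from mate ``mate_strand`` (1 or 2).
    """
    if mate_strand not in (1, 2):
        raise ValueError("mate_strand must be 1 or 2")
    first = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if first is None:
        return _validate_fragment_frame(fragment_frame([]), genome, str(path))
    ncols = len(first.split("\t"))
    if ncols >= 10:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                   "name", "score", "strand1", "strand2"],
            usecols=list(range(10)),
            dtype={"chrom1": str, "chrom2": str, "strand1": str, "strand2": str},
        )
        if (raw["chrom1"] != raw["chrom2"]).any():
            raise ValueError(f"{path}: BEDPE mate pair(s) on different chromosomes")
        frame = pd.DataFrame(
            {
                "chrom": raw["chrom1"],
                "start": np.minimum(raw["start1"], raw["start2"]).astype(np.int64),
                "end": np.maximum(raw["end1"], raw["end2"]).astype(np.int64),
                "strand": raw["strand1"] if mate_strand == 1 else raw["strand2"],
            }
        )
    elif ncols >= 6:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=list(range(6)), dtype={"chrom": str, "strand": str},
        )
        frame = raw[["chrom", "start", "end", "strand"]].astype(
            {"start": np.int64, "end": np.int64}
        )
    else:
        raise ValueError(f"{path}: expected BED6 (>=6 columns) or BEDPE (>=10), got {ncols}")
    return _validate_fragment_frame(frame, genome, str(path))


def write_bed6(frags, path) -> None:
    """Write fragments as BED6 (name '.', score 0); deterministic row order."""
    frame = fragment_frame(frags)
    out = frame.assign(name=".", score=0)[["chrom", "start", "end", "name", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def load_intervals(path, genome: Genome) -> pd.DataFrame:
    """Read a BED3+ interval file (e.g. restriction sites) as chrom/start/end rows."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or start >= end or end > genome[chrom]:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end} on {chrom}")
            rows.append((chrom, start, end))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def deduplicate(frags):
    """Drop exact (chrom, start, end, strand) duplicates, keeping first occurrences.

    Idempotent; the surviving multiset does not depend on input order.  Returns
    the same kind of collection it was given (frame in, frame out).
    """
    if isinstance(frags, pd.DataFrame):
        return frags.drop_duplicates(subset=list(FRAGMENT_COLUMNS), keep="first", ignore_index=True)
    seen = set()
    out = []
    for f in frags:
        key = (f.chrom, f.start, f.end, f.strand)
        if key not in seen:
            seen.add(key)
            out.append(StrandedFragment(*key))
    return out


@dataclass
class CoverageTrack:
    """Per-chromosome, per-strand fragment counts at a fixed bin width.

    ``counts[chrom]`` is a ``(2, n_bins)`` int array: row 0 Watson, row 1 Crick.
    Each fragment contributes one count to the bin containing its midpoint.
    """

    bin_width: int
    counts: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def same_grid(self, other: "CoverageTrack") -> bool:
        if self.bin_width != other.bin_width or set(self.counts) != set(other.counts):
            return False
        return all(self.counts[c].shape == other.counts[c].shape for c in self.counts)

    def total_vector(self, chroms: Iterable[str] | None = None) -> np.ndarray:
        """Watson+Crick per-bin totals concatenated over chromosomes (genome order)."""
        names = list(chroms) if chroms is not None else list(self.counts)
        return np.concatenate([self.counts[c].sum(axis=0) for c in names])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# chrom\tbin_start\tbin_end\twatson\tcrick\t"
                f"(0-based half-open bins, width={self.bin_width} bp; fragment-midpoint counts)\n"
            )
            for chrom, arr in self.counts.items():
                for i in range(arr.shape[1]):
                    fh.write(
                        f"{chrom}\t{i * self.bin_width}\t{(i + 1) * self.bin_width}"
                        f"\t{arr[0, i]}\t{arr[1, i]}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "CoverageTrack":
        frame = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "bin_start", "bin_end", "watson", "crick"],
            dtype={"chrom": str},
        )
        if frame.empty:
            raise ValueError(f"{path}: empty coverage file")
        bin_width = int(frame["bin_end"].iloc[0] - frame["bin_start"].iloc[0])
        counts = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            counts[chrom] = np.vstack(
                [sub["watson"].to_numpy(np.int64), sub["crick"].to_numpy(np.int64)]
            )
        return cls(bin_width=bin_width, counts=counts)


def coverage(frags, genome: Genome, bin_width: int) -> CoverageTrack:
    """Bin fragments into a strand-specific :class:`CoverageTrack`.

    Assignment is by fragment midpoint, so the per-bin totals conserve the
    fragment count exactly (no per-base overlap double counting).
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    frame = fragment_frame(frags)
    counts = {
        chrom: np.zeros((2, math.ceil(length / bin_width)), dtype=np.int64)
        for chrom, length in genome.items()
    }
    if len(frame) == 0:
        return CoverageTrack(bin_width=bin_width, counts=counts)
    mids = (frame["start"].to_numpy(np.int64) + frame["end"].to_numpy(np.int64)) // 2
    bins = mids // bin_width
    strand_row = (frame["strand"].to_numpy() == CRICK).astype(np.int64)
    for chrom, idx in frame.groupby("chrom", sort=False).indices.items():
        if chrom not in counts:
            raise ValueError(f"fragment on chromosome {chrom!r} absent from genome")
        arr = counts[chrom]
        for row in (0, 1):
            sel = idx[strand_row[idx] == row]
            if len(sel):
                arr[row] += np.bincount(bins[sel], minlength=arr.shape[1])[: arr.shape[1]]
    return CoverageTrack(bin_width=bin_width, counts=counts)
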