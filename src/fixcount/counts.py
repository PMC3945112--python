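"""Per-base count containers, bedGraph/BED input, and count histograms.

Counts live in two shapes: a per-base table tied to genomic coordinates
(:class:`PerBaseCounts`) and the coordinate-free histogram ``c_k = number of
bases with exactly k reads`` (:class:`CountHistogram`), which is the
sufficient statistic for every model in this package.  All coordinates are
0-based, half-open, matching the bedGraph/BED conventions.  Files ending in
``.gz`` are read and written transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np

__all__ = [
    "PerBaseCounts",
    "CountHistogram",
    "read_bedgraph",
    "read_bed_reads",
    "read_chrom_sizes",
    "write_bedgraph",
    "histogram",
    "read_histogram",
    "write_histogram",
]


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class PerBaseCounts:
    """Per-base values over a genomic domain of ``total_bases`` positions.

    Only materialised positions are stored; any position of the domain that
    is absent from ``pos`` implicitly carries the value 0 (raw counts) and,
    after a transform, the transform's image of 0.  Records are kept sorted
    by (chrom, pos); positions must be unique within a chromosome.

    Parameters
    ----------
    chrom, pos, value
        Parallel record arrays.  ``value`` is a non-negative integer count
        for raw data and may be fractional after count adjustment.
    total_bases
        Size of the considered (mappable) domain, including zero-count
        bases.  ``c_0`` of the histogram is derived from it, so it must be
        stated honestly.
    """

    chrom: np.ndarray
    pos: np.ndarray
    value: np.ndarray
    total_bases: int

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=str)
        pos = np.asarray(self.pos, dtype=np.int64)
        value = np.asarray(self.value, dtype=np.float64)
        if not (chrom.shape == pos.shape == value.shape):
            raise ValueError("chrom, pos and value must have equal length")
        if value.size and (not np.all(np.isfinite(value)) or value.min() < 0):
            raise ValueError("count values must be finite and >= 0")
        if pos.size and pos.min() < 0:
            raise ValueError("positions must be >= 0")
        # canonical order: (chrom, pos)
        if pos.size:
            _, codes = np.unique(chrom, return_inverse=True)
            order = np.lexsort((pos, codes))
            chrom, pos, value = chrom[order], pos[order], value[order]
            same = (chrom[1:] == chrom[:-1]) & (pos[1:] == pos[:-1])
            if same.any():
                i = int(np.flatnonzero(same)[0])
                raise ValueError(
                    f"duplicate position {chrom[i]}:{pos[i]} in per-base records"
                )
        self.chrom, self.pos, self.value = chrom, pos, value
        self.total_bases = int(self.total_bases)
        n_nonzero = int(np.count_nonzero(value))
        if n_nonzero > self.total_bases:
            raise ValueError(
                f"{n_nonzero} nonzero bases exceed total_bases={self.total_bases}"
            )

    def __len__(self) -> int:
        return self.pos.size

    @property
    def n_reads(self) -> float:
        """Total signal; equals the number of mapped reads for raw counts."""
        return float(self.value.sum())

    def with_values(self, value: np.ndarray) -> "PerBaseCounts":
        """Copy with the same positions but new values."""
        return PerBaseCounts(self.chrom.copy(), self.pos.copy(),
                             np.asarray(value, dtype=np.float64),
                             self.total_bases)


@dataclass
class CountHistogram:
    """Dense count histogram: ``counts[k]`` bases carry exactly ``k`` reads."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("histogram must be a non-empty 1-d array")
        if np.any(c < 0) or not np.allclose(c, np.rint(c)):
            raise ValueError("histogram entries must be non-negative integers")
        c = np.rint(c).astype(np.int64)
        # trim trailing empty levels but always keep level 0
        last = int(np.flatnonzero(c)[-1]) if c.any() else 0
        self.counts = c[: last + 1]

    @property
    def N(self) -> int:
        """Total number of bases, including zero-count bases."""
        return int(self.counts.sum())

    @property
    def max_level(self) -> int:
        return self.counts.size - 1

    @property
    def n_reads(self) -> int:
        return int(np.dot(np.arange(self.counts.size), self.counts))

    @property
    def levels(self) -> dict[int, int]:
        return {int(k): int(c) for k, c in enumerate(self.counts) if c > 0}

    def nonzero_levels(self) -> tuple[np.ndarray, np.ndarray]:
        """Levels with ``c_k > 0`` (including k=0) and their counts."""
        k = np.flatnonzero(self.counts > 0)
        return k, self.counts[k]

    @property
    def mean(self) -> float:
        return self.n_reads / self.N

    @property
    def variance(self) -> float:
        """Unbiased sample variance of the per-base counts."""
        n = self.N
        if n < 2:
            return 0.0
        k = np.arange(self.counts.size, dtype=np.float64)
        m = self.mean
        return float(np.dot(self.counts, (k - m) ** 2) / (n - 1))

    @classmethod
    def from_levels(cls, levels: Mapping[int, int],
                    total_bases: int | None = None) -> "CountHistogram":
        """Build from a ``{level: count}`` mapping.

        If ``total_bases`` is given and the mapping has no explicit 0 level,
        ``c_0`` is derived as ``total_bases - sum(c_k, k >= 1)``.
        """
        if not levels and total_bases is None:
            raise ValueError("empty histogram requires total_bases")
        kmax = max(levels) if levels else 0
        c = np.zeros(kmax + 1, dtype=np.int64)
        for k, v in levels.items():
            if k < 0:
                raise ValueError("count levels must be >= 0")
            c[k] = v
        if total_bases is not None and 0 not in levels:
            rest = int(c[1:].sum())
            if rest > total_bases:
                raise ValueError("levels exceed total_bases")
            c[0] = total_bases - rest
        return cls(c)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def _resolve_total(covered: int, total_bases, chrom_sizes) -> int:
    if chrom_sizes is not None:
        sizes = chrom_sizes if isinstance(chrom_sizes, dict) else read_chrom_sizes(chrom_sizes)
        return int(sum(sizes.values()))
    if total_bases is not None:
        return int(total_bases)
    return covered


def read_bedgraph(path, *, total_bases: int | None = None,
                  chrom_sizes=None) -> PerBaseCounts:
    """Read a 4-column bedGraph and expand intervals to per-base records.

    Intervals must be non-overlapping within a chromosome and carry
    non-negative values.  The domain size ``total_bases`` defaults to the
    summed length of all intervals (including zero-valued ones); pass
    ``total_bases`` or ``chrom_sizes`` explicitly when zero-count bases
    outside the covered intervals matter (they do, for fitting).
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
            chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if val < 0:
                raise ValueError(f"bedGraph line {lineno}: negative value {val}")
            if end <= start:
                raise ValueError(f"bedGraph line {lineno}: empty interval")
            per_chrom.setdefault(chrom, []).append((start, end, val))

    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    covered = 0
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom])
        prev_end = -1
        for start, end, _ in ivs:
            if start < prev_end:
                raise ValueError(
                    f"overlapping bedGraph intervals on {chrom} at {start}"
                )
            prev_end = end
        covered += sum(e - s for s, e, _ in ivs)
        nz = [(s, e, v) for s, e, v in ivs if v != 0]
        if not nz:
            continue
        pos = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e, _ in nz])
        val = np.concatenate([np.full(e - s, v) for s, e, v in nz])
        chroms.append(np.full(pos.size, chrom, dtype=object))
        poss.append(pos)
        vals.append(val)

    if poss:
        chrom_arr = np.concatenate(chroms).astype(str)
        pos_arr = np.concatenate(poss)
        val_arr = np.concatenate(vals)
    else:
        chrom_arr = np.empty(0, dtype=str)
        pos_arr = np.empty(0, dtype=np.int64)
        val_arr = np.empty(0, dtype=np.float64)
    total = _resolve_total(covered, total_bases, chrom_sizes)
    return PerBaseCounts(chrom_arr, pos_arr, val_arr, total)


def read_bed_reads(path, *, shift: int = 0, total_bases: int | None = None,
                   chrom_sizes=None) -> PerBaseCounts:
    """Collapse a BED file of mapped reads to per-base 5'-end counts.

    Each read contributes one count at its strand-aware 5' base: ``start``
    for ``+`` reads, ``end - 1`` for ``-`` reads.  ``shift`` moves that base
    in the 3' direction (``+shift`` for plus-strand, ``-shift`` for
    minus-strand reads); strands are pooled.  Reads missing a strand column
    are treated as plus-strand.
    """
    keys: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(f"BED line {lineno}: empty interval")
            strand = parts[5] if len(parts) >= 6 else "+"
            if strand not in "+-.":
                raise ValueError(f"BED line {lineno}: bad strand {strand!r}")
            if strand == "-":
                p = end - 1 - shift
            else:
                p = start + shift
            if p < 0:
                raise ValueError(f"BED line {lineno}: shifted position < 0")
            keys.append((chrom, p))

    if keys:
        chrom_arr = np.array([k[0] for k in keys], dtype=str)
        pos_arr = np.array([k[1] for k in keys], dtype=np.int64)
        _, codes = np.unique(chrom_arr, return_inverse=True)
        combo = codes.astype(np.int64) * (pos_arr.max() + 1) + pos_arr
        uniq, inverse, cnt = np.unique(combo, return_inverse=True, return_counts=True)
        first = np.zeros(uniq.size, dtype=np.int64)
        first[inverse[::-1]] = np.arange(len(combo) - 1, -1, -1)
        chrom_u = chrom_arr[first]
        pos_u = pos_arr[first]
        val_u = cnt.astype(np.float64)
    else:
        chrom_u = np.empty(0, dtype=str)
        pos_u = np.empty(0, dtype=np.int64)
        val_u = np.empty(0, dtype=np.float64)
    covered = int(val_u.size)
    total = _resolve_total(covered, total_bases, chrom_sizes)
    return PerBaseCounts(chrom_u, pos_u, val_u, total)


def _fmt(v: float, precision: int) -> str:
    if v == int(v):
        return str(int(v))
    s = f"{v:.{precision}f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_bedgraph(counts: PerBaseCounts, path, *, precision: int = 4) -> None:
    """Write per-base values as bedGraph, merging equal-valued adjacent bases.

    Zero-valued bases are omitted (sparse convention); round-trips with
    :func:`read_bedgraph` up to ``10**-precision`` on the values.
    """
    with _open_text(path, "wt") as fh:
        n = len(counts)
        if n == 0:
            return
        texts = [_fmt(v, precision) for v in counts.value]
        start = 0
        for i in range(1, n + 1):
            boundary = (
                i == n
                or counts.chrom[i] != counts.chrom[start]
                or counts.pos[i] != counts.pos[i - 1] + 1
                or texts[i] != texts[start]
            )
            if boundary:
                if texts[start] != "0":
                    fh.write(
                        f"{counts.chrom[start]}\t{counts.pos[start]}\t"
                        f"{counts.pos[i - 1] + 1}\t{texts[start]}\n"
                    )
                start = i


def histogram(counts: PerBaseCounts) -> CountHistogram:
    """Reduce raw integer per-base counts to the histogram ``c_k``.

    ``c_0`` is derived from ``total_bases``; fractional (adjusted) values
    are rejected because the histogram is defined on raw counts only.
    """
    vals = counts.value
    if vals.size and not np.allclose(vals, np.rint(vals), atol=1e-9):
        raise ValueError("histogram requires integer raw counts")
    iv = np.rint(vals).astype(np.int64)
    c = np.bincount(iv) if iv.size else np.zeros(1, dtype=np.int64)
    implicit_zeros = counts.total_bases - iv.size
    if implicit_zeros < 0:
        raise ValueError("more records than total_bases")
    c = c.astype(np.int64)
    c[0] += implicit_zeros
    return CountHistogram(c)


def read_histogram(path, *, total_bases: int | None = None) -> CountHistogram:
    """Read a two-column ``k<TAB>c_k`` text histogram.

    If the file lacks an explicit ``k=0`` line, ``total_bases`` (when given)
    supplies the domain size from which ``c_0`` is derived.
    """
    levels: dict[int, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"histogram line {lineno}: expected 2 columns")
            k, c = int(parts[0]), int(parts[1])
            if k in levels:
                raise ValueError(f"histogram line {lineno}: duplicate level {k}")
            levels[k] = c
    if 0 in levels:
        return CountHistogram.from_levels(levels)
    return CountHistogram.from_levels(levels, total_bases=total_bases)


def write_histogram(hist: CountHistogram, path) -> None:
    """Write the histogram as ``k<TAB>c_k`` lines (nonzero levels plus k=0)."""
    with _open_text(path, "wt") as fh:
        fh.write(f"0\t{hist.counts[0]}\n")
        for k in range(1, hist.counts.size):
            if hist.counts[k]:
                fh.write(f"{k}\t{hist.counts[k]}\n")
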