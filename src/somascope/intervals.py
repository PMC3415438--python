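"""Half-open genomic interval sets with numpy-backed set algebra.

All coordinates are 0-based, half-open ``[start, end)``.  A
:class:`GenomeIntervals` instance stores, per chromosome, a sorted and
merged ``(n, 2)`` integer array; every public operation preserves that
normal form, so membership tests reduce to a single ``searchsorted``
against the flattened edge array.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Tuple

import numpy as np
import pandas as pd


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or touching intervals; drop empties."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(arr, dtype=np.int64)
    arr = arr[arr[:, 1] > arr[:, 0]]
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    starts, ends = arr[:, 0], arr[:, 1]
    # A new run starts where the start exceeds the running max of prior ends.
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_end[:-1]
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    out = np.empty((n_runs, 2), dtype=np.int64)
    out[:, 0] = starts[new_run]
    # per-run max end = cumulative max sampled at each run's last element
    last_idx = np.flatnonzero(np.append(new_run[1:], True))
    out[:, 1] = run_end[last_idx]
    return out


class GenomeIntervals:
    """An immutable set of disjoint half-open intervals keyed by chromosome."""

    def __init__(self, data: Dict[str, np.ndarray] | None = None):
        self._data: Dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                norm = _normalize(np.asarray(arr).reshape(-1, 2))
                if len(norm):
                    self._data[chrom] = norm

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, int]]) -> "GenomeIntervals":
        by_chrom: Dict[str, list] = {}
        for chrom, start, end in records:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeIntervals":
        return cls.from_records(zip(df["chrom"], df["start"], df["end"]))

    @classmethod
    def whole_genome(cls, chrom_lengths: Dict[str, int]) -> "GenomeIntervals":
        return cls({c: np.array([[0, n]]) for c, n in chrom_lengths.items()})

    # -- basic accessors ------------------------------------------------
    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self._data))

    def intervals(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def records(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.chroms:
            for start, end in self._data[chrom]:
                yield chrom, int(start), int(end)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.records())
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeIntervals):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return (f"GenomeIntervals({len(self)} intervals, "
                f"{self.total_length} bp, {len(self._data)} chroms)")

    # -- set algebra ----------------------------------------------------
    def _combine(self, other: "GenomeIntervals", keep_depth) -> "GenomeIntervals":
        out = {}
        for chrom in set(self._data) | set(other._data):
            a = self.intervals(chrom)
            b = other.intervals(chrom)
            # event sweep: +1 at starts, -1 at ends
            pos = np.concatenate([a[:, 0], a[:, 1], b[:, 0], b[:, 1]])
            delta = np.concatenate([
                np.ones(len(a)), -np.ones(len(a)),
                2 * np.ones(len(b)), -2 * np.ones(len(b)),
            ])
            order = np.argsort(pos, kind="stable")
            pos, delta = pos[order], np.cumsum(delta[order])
            # collapse duplicate positions: state after the last event at pos
            keep_last = np.append(pos[1:] != pos[:-1], True)
            pos, state = pos[keep_last], delta[keep_last]
            inside = keep_depth(state[:-1]) if len(pos) > 1 else np.empty(0, bool)
            if inside.any():
                segs = np.column_stack([pos[:-1][inside], pos[1:][inside]])
                out[chrom] = segs
        return GenomeIntervals(out)

    def union(self, other: "GenomeIntervals") -> "GenomeIntervals":
        return self._combine(other, lambda s: s > 0)

    def intersect(self, other: "GenomeIntervals") -> "GenomeIntervals":
        return self._combine(other, lambda s: s == 3)

    def subtract(self, other: "GenomeIntervals") -> "GenomeIntervals":
        return self._combine(other, lambda s: s == 1)

    # -- queries --------------------------------------------------------
    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of positions on one chromosome."""
        edges = self.intervals(chrom).ravel()
        idx = np.searchsorted(edges, np.asarray(positions), side="right")
        return idx % 2 == 1

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        arr = self.intervals(chrom)
        if len(arr) == 0:
            return False
        i = np.searchsorted(arr[:, 1], start, side="right")
        return i < len(arr) and arr[i, 0] < end

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Number of covered bases within [start, end)."""
        arr = self.intervals(chrom)
        if len(arr) == 0:
            return 0
        ov = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
        return int(ov[ov > 0].sum())

    def expand(self, pad: int, chrom_lengths: Dict[str, int] | None = None) -> "GenomeIntervals":
        """Pad every interval by ``pad`` bases on each side (clipped at 0)."""
        out = {}
        for chrom, arr in self._data.items():
            lo = np.maximum(arr[:, 0] - pad, 0)
            hi = arr[:, 1] + pad
            if chrom_lengths and chrom in chrom_lengths:
                hi = np.minimum(hi, chrom_lengths[chrom])
            out[chrom] = np.column_stack([lo, hi])
        return GenomeIntervals(out)
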