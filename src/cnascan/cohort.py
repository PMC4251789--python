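"""Cohort-wide breakpoint-union segment grid.

Association statistics are computed on genome segments chosen so that no
segment contains a copy-number breakpoint of any sample in the cohort: the
interval boundaries are the union of every sample's segment boundaries.
Within such a segment each sample is in a single allele-specific state, so
per-segment 2x2 tables are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segio import SampleProfile, ValidationError

Interval = tuple[int, int, int]  # (chrom, start, end), 0-based half-open

MISSING = -1  # sentinel state for uncovered (gap) regions


def union_breakpoints(profiles: Sequence[SampleProfile]) -> list[Interval]:
    """Partition the cohort's covered genome at the union of all breakpoints.

    Per chromosome, every segment start/end of every sample becomes a
    boundary; each interval between consecutive boundaries is emitted iff it
    lies inside at least one sample's coverage.  The result is disjoint,
    sorted, covers exactly the base-pair union of input coverage, and no
    interval straddles any sample's breakpoint.
    """
    if not profiles:
        raise ValidationError("union_breakpoints requires at least one profile")
    chroms = sorted({s.chrom for p in profiles for s in p.segments})
    out: list[Interval] = []
    for chrom in chroms:
        bounds: set[int] = set()
        cover: list[tuple[int, int]] = []
        for p in profiles:
            for s in p.segments_on(chrom):
                bounds.add(s.start)
                bounds.add(s.end)
                cover.append((s.start, s.end))
        cover.sort()
        # merge coverage to test interval membership
        merged: list[list[int]] = []
        for a, b in cover:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        b = np.array(sorted(bounds))
        mids = (b[:-1] + b[1:]) // 2
        idx = np.searchsorted(starts, mids, side="right") - 1
        keep = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
        out.extend(
            (chrom, int(lo), int(hi))
            for lo, hi in zip(b[:-1][keep], b[1:][keep])
        )
    return out


def project_profile(
    profile: SampleProfile, intervals: Sequence[Interval]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """State of ``profile`` on each union interval.

    Returns (total, minor, source_length) int arrays aligned with
    ``intervals``; MISSING where the profile has no coverage.
    ``source_length`` is the length of the profile's own segment containing
    the interval — the relevant length for focal-alteration calls, which
    refer to the caller's segment, not the (shorter) union interval.
    """
    n = len(intervals)
    total = np.full(n, MISSING, dtype=np.int64)
    minor = np.full(n, MISSING, dtype=np.int64)
    src_len = np.full(n, MISSING, dtype=np.int64)
    by_chrom: dict[int, list] = {}
    for s in profile.segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    ichrom = np.fromiter((c for c, _, _ in intervals), dtype=np.int64, count=n)
    ilo = np.fromiter((lo for _, lo, _ in intervals), dtype=np.int64, count=n)
    ihi = np.fromiter((hi for _, _, hi in intervals), dtype=np.int64, count=n)
    for chrom, segs in by_chrom.items():
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        tot = np.array([s.total_cn for s in segs])
        mnr = np.array([s.minor_cn for s in segs])
        sel = np.nonzero(ichrom == chrom)[0]
        if sel.size == 0:
            continue
        j = np.searchsorted(starts, ilo[sel], side="right") - 1
        inside = (j >= 0) & (ilo[sel] < ends[np.clip(j, 0, None)])
        hit = sel[inside]
        jj = j[inside]
        if np.any(ihi[hit] > ends[jj]):
            k = hit[np.argmax(ihi[hit] > ends[jj])]
            raise ValidationError(
                f"interval chr{chrom}:[{ilo[k]},{ihi[k]}) straddles a breakpoint "
                f"of sample {profile.sample_id}; grid not built from this cohort?"
            )
        total[hit] = tot[jj]
        minor[hit] = mnr[jj]
        src_len[hit] = ends[jj] - starts[jj]
    return total, minor, src_len


@dataclass(frozen=True)
class UnionGrid:
    """Breakpoint-union intervals with per-(interval, sample) states.

    ``total``/``minor``/``source_length`` are (n_intervals, n_samples) int
    arrays; MISSING (-1) marks gaps in a sample's coverage.
    """

    intervals: tuple[Interval, ...]
    samples: tuple[str, ...]
    total: np.ndarray
    minor: np.ndarray
    source_length: np.ndarray

    @classmethod
    def from_profiles(cls, profiles: Sequence[SampleProfile]) -> "UnionGrid":
        intervals = union_breakpoints(profiles)
        cols_t, cols_m, cols_l = [], [], []
        for p in profiles:
            t, m, l = project_profile(p, intervals)
            cols_t.append(t)
            cols_m.append(m)
            cols_l.append(l)
        return cls(
            intervals=tuple(intervals),
            samples=tuple(p.sample_id for p in profiles),
            total=np.column_stack(cols_t) if cols_t else np.empty((0, 0), int),
            minor=np.column_stack(cols_m),
            source_length=np.column_stack(cols_l),
        )

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([hi - lo for _, lo, hi in self.intervals], dtype=np.int64)

    @property
    def covered(self) -> np.ndarray:
        """Boolean (n_intervals, n_samples): sample has a state here."""
        return self.total != MISSING

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_samples(self, sample_ids: Iterable[str]) -> "UnionGrid":
        """Grid restricted to (and reordered by) the given samples.

        Intervals are kept as-is: they remain breakpoint-free for any subset.
        """
        idx = [self.sample_index(s) for s in sample_ids]
        return UnionGrid(
            intervals=self.intervals,
            samples=tuple(self.samples[i] for i in idx),
            total=self.total[:, idx],
            minor=self.minor[:, idx],
            source_length=self.source_length[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Matrix export: one row per interval, '<total>/<minor>' cells,
        '.' for missing."""
        cells = {}
        for j, sid in enumerate(self.samples):
            col = []
            for i in range(self.n_intervals):
                t = self.total[i, j]
                col.append("." if t == MISSING else f"{t}/{self.minor[i, j]}")
            cells[sid] = col
        pos = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        return pd.concat([pos, pd.DataFrame(cells)], axis=1)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
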