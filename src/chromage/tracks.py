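"""Binned genomic signal tracks (bedGraph-style coverage)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalTrack"]


class SignalTrack:
    """Non-overlapping, per-chromosome-sorted coverage bins.

    Bins are 0-based half-open ``(chrom, start, end, value)`` with finite,
    non-negative values — the in-memory form of a bedGraph track.  Queries
    exploit the sorted, non-overlapping layout: every overlap query is a
    contiguous slice found by bisection.
    """

    def __init__(self, bins: pd.DataFrame) -> None:
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(bins.columns):
            raise ValueError(f"bins need columns {sorted(required)}")
        frame = bins.loc[:, ["chrom", "start", "end", "value"]].copy()
        frame["chrom"] = frame["chrom"].astype(str)
        frame = frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        values = frame["value"].to_numpy(float)
        if len(values) and not np.all(np.isfinite(values)):
            raise ValueError("bin values must be finite")
        if len(values) and values.min() < 0:
            raise ValueError("bin values must be >= 0")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted bin")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping bins")
            self._by_chrom[str(chrom)] = (starts, ends, sub["value"].to_numpy(float))
        self._frame = frame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                rows.append((chrom, int(start), int(end), float(value)))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self._frame.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self._frame.equals(other._frame)

    def scale(self, factor: float) -> "SignalTrack":
        frame = self.frame
        frame["value"] *= factor
        return SignalTrack(frame)

    # -- queries -----------------------------------------------------------

    def overlapping(self, chrom: str, start: int, end: int):
        """(starts, ends, values) of bins overlapping [start, end) by >= 1 base."""
        hit = self._by_chrom.get(chrom)
        if hit is None or end <= start:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        starts, ends, values = hit
        lo = int(np.searchsorted(ends, start, "right"))
        hi = int(np.searchsorted(starts, end, "left"))
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def mean_value(self, chrom: str, start: int, end: int, weighted: bool = False) -> float:
        """Mean of bin values over bins overlapping the region; 0 if none.

        Unweighted (default): plain mean of the overlapping bins' values.
        Weighted: mean weighted by the number of overlapping bases.
        """
        starts, ends, values = self.overlapping(chrom, start, end)
        if len(values) == 0:
            return 0.0
        if not weighted:
            return float(np.mean(values))
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        return float(np.sum(values * ov) / np.sum(ov))

    def weighted_mean(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(coverage-weighted mean, number of covered bases) over the region."""
        starts, ends, values = self.overlapping(chrom, start, end)
        if len(values) == 0:
            return float("nan"), 0
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        covered = int(np.sum(ov))
        return float(np.sum(values * ov) / covered), covered
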