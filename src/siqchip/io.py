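"""Plain-text genomics I/O: BED3 fragments, BED4 annotations, bedGraph tracks.

All coordinates are BED-convention 0-based half-open.  Strand is ignored:
a fragment is the physical double-stranded insert implied by a properly
paired read pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Fragment:
    """One sequenced fragment; ``length`` is the per-fragment L_i in bp."""

    chrom: str
    start: int
    stop: int

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError(f"fragment stop must exceed start: {self.chrom}:{self.start}-{self.stop}")

    @property
    def length(self) -> int:
        return self.stop - self.start


class FragmentSet:
    """Ordered collection of fragments backed by a (chrom, start, stop) frame."""

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns[:3]) != ["chrom", "start", "stop"]:
            frame = frame.iloc[:, :3].set_axis(["chrom", "start", "stop"], axis=1)
        if len(frame) and (frame["stop"] <= frame["start"]).any():
            bad = frame.index[(frame["stop"] <= frame["start"])][0]
            row = frame.loc[bad]
            raise ValueError(f"zero/negative-length fragment at record {bad + 1}: {row.chrom}:{row.start}-{row.stop}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, chroms, starts, stops) -> "FragmentSet":
        return cls(pd.DataFrame({"chrom": np.asarray(chroms, dtype=object),
                                 "start": np.asarray(starts, dtype=np.int64),
                                 "stop": np.asarray(stops, dtype=np.int64)}))

    @property
    def depth(self) -> int:
        """Number of fragments (the track-normalization depth R-hat)."""
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frame["stop"] - self.frame["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.stop))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(starts, stops) arrays per chromosome, input order preserved."""
        out = {}
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            out[str(chrom)] = (sub["start"].to_numpy(np.int64), sub["stop"].to_numpy(np.int64))
        return out

    def filter_length(self, min_bp=None, max_bp=None) -> "FragmentSet":
        """Optional length filter; the filtered depth is the new R-hat."""
        lengths = self.lengths
        keep = np.ones(len(self.frame), dtype=bool)
        if min_bp is not None:
            keep &= lengths >= min_bp
        if max_bp is not None:
            keep &= lengths <= max_bp
        return FragmentSet(self.frame[keep])


def read_fragments(path) -> FragmentSet:
    """Read a BED3 fragment file; the record count is the depth R-hat."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            usecols=[0, 1, 2], names=["chrom", "start", "stop"],
                            dtype={"chrom": str, "start": np.int64, "stop": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed BED3 fragment file: {exc}") from exc
    return FragmentSet(frame)


def write_fragments(fragments: FragmentSet, path) -> None:
    fragments.frame.to_csv(path, sep="\t", header=False, index=False)


class AnnotationSet:
    """A labeled genome segmentation (e.g. a 15-state chromHMM model).

    Within each chromosome the intervals are sorted and validated to be
    non-overlapping: a segmentation is a partition, and the deterministic
    first-overlap assignment rule depends on it.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, sub in frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            stops = sub["stop"].to_numpy()
            if (stops <= starts).any():
                raise ValueError(f"annotation with non-positive length on {chrom}")
            if len(sub) > 1 and (starts[1:] < stops[:-1]).any():
                i = int(np.argmax(starts[1:] < stops[:-1]))
                raise ValueError(
                    f"overlapping annotations on {chrom}: "
                    f"[{starts[i]},{stops[i]}) and [{starts[i + 1]},{stops[i + 1]})")
        self.frame = frame
        self._index = {
            str(chrom): (sub["start"].to_numpy(np.int64),
                         sub["stop"].to_numpy(np.int64),
                         sub["state"].to_numpy(object))
            for chrom, sub in frame.groupby("chrom", sort=False)
        }

    @property
    def states(self) -> list[str]:
        """Distinct state labels, in order of first appearance."""
        return list(dict.fromkeys(self.frame["state"]))

    def __len__(self) -> int:
        return len(self.frame)

    def chrom_arrays(self, chrom: str):
        """(starts, stops, labels) for one chromosome, or None."""
        return self._index.get(chrom)


def read_annotations(path) -> AnnotationSet:
    """Read a BED4 segmentation (chrom, start, stop, state label)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 4:
        raise ValueError(f"{path}: annotation BED needs >= 4 columns (chrom, start, stop, state)")
    frame = frame.iloc[:, :4].set_axis(["chrom", "start", "stop", "state"], axis=1)
    frame["chrom"] = frame["chrom"].astype(str)
    frame["state"] = frame["state"].astype(str)
    if frame["state"].str.len().eq(0).any():
        raise ValueError(f"{path}: empty state label")
    return AnnotationSet(frame)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chromosome sizes table (name, length in bp)."""
    sizes = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_bedgraph(track, path, header_lines=()) -> None:
    """Write a binned track as 4-column bedGraph.

    Adjacent equal-valued bins are merged into one record; masked (NaN)
    bins are omitted; the final bin is clipped to the chromosome length.
    Values are printed with 8 significant digits.
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for chrom, values in track.values.items():
            chrom_len = track.chrom_sizes[chrom]
            finite = np.isfinite(values)
            if not finite.any():
                continue
            # run-length encode over (value, finite) change points
            change = np.empty(len(values), dtype=bool)
            change[0] = True
            same = (values[1:] == values[:-1]) | (~finite[1:] & ~finite[:-1])
            change[1:] = ~same
            run_starts = np.flatnonzero(change)
            run_ends = np.append(run_starts[1:], len(values))
            for rs, re in zip(run_starts, run_ends):
                if not finite[rs]:
                    continue
                start_bp = rs * bs
                stop_bp = min(re * bs, chrom_len)
                fh.write(f"{chrom}\t{start_bp}\t{stop_bp}\t{values[rs]:.8g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_size: int):
    """Read a bedGraph written by :func:`write_bedgraph` back into bin arrays.

    Returns (values, meta) where values maps chrom -> array with NaN at
    bins the file does not cover, and meta holds any ``#key=value`` header
    entries (e.g. the alpha and depths stamped by the CLI).
    """
    meta = {}
    values = {
        chrom: np.full(-(-length // bin_size), np.nan)
        for chrom, length in chrom_sizes.items()
    }
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#"):
                entry = raw[1:].strip()
                if "=" in entry:
                    key, _, val = entry.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not raw.strip() or raw.startswith(("track", "browser")):
                continue
            chrom, start, stop, value = raw.split("\t")
            if chrom not in values:
                raise ValueError(f"{path}: chromosome {chrom!r} absent from chrom sizes")
            start, stop = int(start), int(stop)
            if start % bin_size:
                raise ValueError(f"{path}: record at {chrom}:{start} not aligned to bin size {bin_size}")
            b0 = start // bin_size
            b1 = -(-stop // bin_size)
            values[chrom][b0:b1] = float(value)
    return values, meta
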