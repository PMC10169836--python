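"""Normalized coverage f(x) and the siQ-scaled efficiency track s(x).

A browser track is only compatible with absolute scaling if it is a
probability distribution over the genome after depth division.  The
length-weighted counting rule achieves this: fragment i adds +1/L_i at
every base pair it covers, so each fragment contributes exactly 1 to the
track total and sum_x f(x) = R-hat (the fragment count).  The usual +1
rule over-counts fragment i exactly L_i times and is provided only for
comparison.

At bin size B the per-bp rule generalizes exactly: a fragment adds
(overlap with bin, in bp) / L_i to each bin, which preserves the
normalization at any resolution and reduces to +1/L_i at B = 1.

The siQ track s(x) = alpha * f_IP(x) / f_in(x) is the estimated IP
capture efficiency at x.  Bins with zero input coverage are masked (NaN),
never pseudo-counted: s is a physical ratio and fabricated input coverage
would corrupt the scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import FragmentSet

LENGTH_WEIGHTED = "length_weighted"
UNIT = "unit"


def _n_bins(chrom_len: int, bin_size: int) -> int:
    return -(-chrom_len // bin_size)


@dataclass
class CoverageTrack:
    """Binned fragment histogram with its normalization depth.

    ``values[chrom]`` are bin weights; ``depth`` is the fragment count
    R-hat used for normalization; ``scheme`` records the counting rule.
    """

    values: dict[str, np.ndarray]
    bin_size: int
    depth: int
    scheme: str
    chrom_sizes: dict[str, int] = field(repr=False)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def rebin(self, k: int) -> "CoverageTrack":
        """Coarsen by summing k adjacent bins (exact, preserves the total)."""
        if k < 1 or int(k) != k:
            raise ValueError("rebin factor must be a positive integer")
        new = {}
        for chrom, v in self.values.items():
            pad = (-len(v)) % k
            padded = np.pad(v, (0, pad)) if pad else v
            new[chrom] = padded.reshape(-1, k).sum(axis=1)
        return CoverageTrack(new, self.bin_size * k, self.depth, self.scheme, self.chrom_sizes)


@dataclass
class SiqTrack:
    """Per-bin capture efficiency s(x) with provenance.

    Masked bins (no input coverage) are NaN in ``values``.
    """

    values: dict[str, np.ndarray]
    bin_size: int
    alpha: float
    depth_ip: int
    depth_in: int
    chrom_sizes: dict[str, int] = field(repr=False)

    def mask(self, chrom: str) -> np.ndarray:
        """True where the bin is masked (undefined efficiency)."""
        return ~np.isfinite(self.values[chrom])

    def unmasked_values(self) -> np.ndarray:
        parts = [v[np.isfinite(v)] for v in self.values.values()]
        return np.concatenate(parts) if parts else np.empty(0)


def _accumulate(starts, stops, per_bp_weight, n_bins, bin_size):
    """Add overlap_bp * per-bp-weight of each fragment into its bins.

    Boundary bins get exact partial overlaps via scatter-add; interior
    full bins are scatter-added from expanded index ranges (chunked to
    bound memory).  Every bin receives contributions only from fragments
    that overlap it, so disjoint pile-up islands stay bit-exactly
    independent.
    """
    arr = np.zeros(n_bins)
    if len(starts) == 0:
        return arr
    b0 = starts // bin_size
    b1 = (stops - 1) // bin_size
    same = b0 == b1
    if same.any():
        np.add.at(arr, b0[same], (stops[same] - starts[same]) * per_bp_weight[same])
    multi = ~same
    if multi.any():
        s, e, w = starts[multi], stops[multi], per_bp_weight[multi]
        lo, hi = b0[multi], b1[multi]
        np.add.at(arr, lo, ((lo + 1) * bin_size - s) * w)
        np.add.at(arr, hi, (e - hi * bin_size) * w)
        counts = hi - lo - 1
        inner = counts > 0
        lo_i, counts_i, w_i = lo[inner], counts[inner], w[inner]
        if len(lo_i):
            chunk = 4_000_000
            cum = np.cumsum(counts_i)
            cuts = np.searchsorted(cum, np.arange(chunk, cum[-1] + chunk, chunk), side="left") + 1
            pos = 0
            for end in np.minimum(cuts, len(lo_i)):
                if end <= pos:
                    continue
                c = counts_i[pos:end]
                base = np.repeat(lo_i[pos:end] + 1, c)
                offsets = np.arange(len(base)) - np.repeat(np.cumsum(c) - c, c)
                np.add.at(arr, base + offsets, np.repeat(bin_size * w_i[pos:end], c))
                pos = end
    return arr


def _build(fragments: FragmentSet, chrom_sizes, bin_size, scheme, clip):
    if bin_size < 1 or int(bin_size) != bin_size:
        raise ValueError("bin_size must be a positive integer")
    values = {chrom: np.zeros(_n_bins(length, bin_size)) for chrom, length in chrom_sizes.items()}
    for chrom, (starts, stops) in fragments.by_chrom().items():
        if chrom not in chrom_sizes:
            raise ValueError(f"fragment chromosome {chrom!r} absent from chrom sizes")
        chrom_len = chrom_sizes[chrom]
        if (starts < 0).any():
            raise ValueError(f"fragment with negative start on {chrom}")
        lengths = (stops - starts).astype(float)
        if (stops > chrom_len).any():
            if not clip:
                i = int(np.argmax(stops > chrom_len))
                raise ValueError(
                    f"fragment beyond end of {chrom} ({chrom_len} bp): "
                    f"[{starts[i]},{stops[i]}) (pass clip=True to truncate)")
            stops = np.minimum(stops, chrom_len)
            keep = stops > starts
            starts, stops, lengths = starts[keep], stops[keep], lengths[keep]
        weight = 1.0 / lengths if scheme == LENGTH_WEIGHTED else np.ones_like(lengths)
        values[chrom] += _accumulate(starts, stops, weight, len(values[chrom]), bin_size)
    return CoverageTrack(values, int(bin_size), fragments.depth, scheme, dict(chrom_sizes))


def build_normalized_coverage(fragments: FragmentSet, chrom_sizes, bin_size=1, *, clip=False) -> CoverageTrack:
    """Length-weighted normalized coverage: sum of bins equals the depth."""
    return _build(fragments, chrom_sizes, bin_size, LENGTH_WEIGHTED, clip)


def build_unit_coverage(fragments: FragmentSet, chrom_sizes, bin_size=1, *, clip=False) -> CoverageTrack:
    """Conventional +1-per-bp pile-up; over-counts fragment i by L_i.

    Provided for comparison; it does not satisfy the normalization
    constraint unless all fragments share one length.
    """
    return _build(fragments, chrom_sizes, bin_size, UNIT, clip)


def check_normalization(track: CoverageTrack) -> float:
    """Relative residual |sum f - depth| / depth (0 for an empty track)."""
    if track.depth == 0:
        return 0.0
    return abs(track.total() - track.depth) / track.depth


def build_siq_track(f_ip: CoverageTrack, f_in: CoverageTrack, alpha: float) -> SiqTrack:
    """s(x) = alpha * f_IP(x) / f_in(x), masked where input is zero."""
    if f_ip.bin_size != f_in.bin_size:
        raise ValueError(f"bin size mismatch: IP {f_ip.bin_size} vs input {f_in.bin_size}")
    if set(f_ip.values) != set(f_in.values):
        raise ValueError("chromosome sets differ between IP and input tracks")
    if not alpha > 0:
        raise ValueError("alpha must be strictly positive")
    values = {}
    n_above_one = 0
    for chrom, ip in f_ip.values.items():
        inp = f_in.values[chrom]
        if ip.shape != inp.shape:
            raise ValueError(f"bin count mismatch on {chrom}")
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(inp > 0, alpha * ip / np.where(inp > 0, inp, 1.0), np.nan)
        n_above_one += int(np.sum(s[np.isfinite(s)] > 1.0))
        values[chrom] = s
    if n_above_one:
        warnings.warn(
            f"{n_above_one} bins have efficiency > 1; this indicates bookkeeping "
            "error or sampling noise", stacklevel=2)
    return SiqTrack(values, f_ip.bin_size, float(alpha), f_ip.depth, f_in.depth, dict(f_ip.chrom_sizes))


def mass_on_interval(track: CoverageTrack, m_ip: float, interval) -> float:
    """Project the IP mass onto a genomic interval: m_IP * f(interval) / R-hat.

    Partial bin overlaps are pro-rated so interval masses over any
    partition of the genome sum exactly to m_IP.
    """
    if track.scheme != LENGTH_WEIGHTED:
        raise ValueError("mass projection requires a length-weighted track")
    chrom, start, stop = interval
    if chrom not in track.values:
        raise ValueError(f"interval chromosome {chrom!r} not in track")
    chrom_len = track.chrom_sizes[chrom]
    if not (0 <= start < stop <= chrom_len):
        raise ValueError(f"interval [{start},{stop}) outside {chrom} of length {chrom_len}")
    bs = track.bin_size
    v = track.values[chrom]
    b0, b1 = start // bs, (stop - 1) // bs
    idx = np.arange(b0, b1 + 1)
    bin_start = idx * bs
    bin_stop = np.minimum(bin_start + bs, chrom_len)
    overlap = np.minimum(bin_stop, stop) - np.maximum(bin_start, start)
    f_sum = float(np.sum(v[idx] * overlap / (bin_stop - bin_start)))
    return m_ip * f_sum / track.depth
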