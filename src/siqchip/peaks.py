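"""Peak intervals, peak responses, and the track-comparison database.

A perturbation experiment is summarized by first calling peak intervals
X_i on the *control* efficiency track, then measuring on every interval
the area under s(x) in both the control and the experimental track.  The
response r_i = area_control / area_experiment quantifies the fold change
in captured material; its histogram mu(r) over all peaks, and the exact
decomposition of that histogram by annotation state, characterize the
whole genome without inspecting a single browser window.  A discrete
Frechet distance between the two curves on each interval scores shape
change independently of amplitude.

The peak caller here is a deliberately simple, deterministic, fully
parameterized thresholding scheme (threshold / minimum width / merge
gap): it exists so the database machinery is testable and reproducible,
and it makes no statistical significance claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import label_interval
from .io import AnnotationSet
from .coverage import SiqTrack

#: Default peak-caller / histogram parameters.
DEFAULT_MIN_WIDTH_BINS = 4
DEFAULT_MERGE_GAP_BINS = 2
DEFAULT_DR = 0.25
DEFAULT_R_MAX = 20.0

FLAG_UNDEFINED_RESPONSE = "undefined_response"
FLAG_NO_SHAPE = "no_common_bins"


def call_peaks(track: SiqTrack, threshold: float | None = None,
               min_width_bp: int | None = None, merge_gap_bp: int | None = None):
    """Maximal above-threshold runs of unmasked bins, merged and filtered.

    threshold : signal floor (default: 75th percentile of unmasked values)
    min_width_bp : drop merged runs narrower than this (default 4 bins)
    merge_gap_bp : merge runs separated by at most this gap (default 2 bins)

    Returns a sorted list of (chrom, start_bp, stop_bp) intervals.
    """
    bs = track.bin_size
    if threshold is None:
        unmasked = track.unmasked_values()
        if len(unmasked) == 0:
            return []
        threshold = float(np.percentile(unmasked, 75))
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    min_width_bp = DEFAULT_MIN_WIDTH_BINS * bs if min_width_bp is None else min_width_bp
    merge_gap_bp = DEFAULT_MERGE_GAP_BINS * bs if merge_gap_bp is None else merge_gap_bp
    if min_width_bp < 0 or merge_gap_bp < 0:
        raise ValueError("peak widths/gaps must be >= 0")
    peaks = []
    for chrom in sorted(track.values):
        v = track.values[chrom]
        above = np.isfinite(v) & (v >= threshold)
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        # merge runs whose gap (bp) is at most merge_gap_bp
        merged = [[starts[0], stops[0]]]
        for s, e in zip(starts[1:], stops[1:]):
            if (s - merged[-1][1]) * bs <= merge_gap_bp:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        chrom_len = track.chrom_sizes[chrom]
        for s, e in merged:
            if (e - s) * bs >= min_width_bp:
                peaks.append((chrom, int(s * bs), int(min(e * bs, chrom_len))))
    return peaks


def peak_area(track: SiqTrack, interval) -> float:
    """Area under s(x) on the interval: bare sum over unmasked bins.

    The bin width cancels in the response ratio, so no width factor is
    applied.
    """
    chrom, start, stop = interval
    if chrom not in track.values:
        raise ValueError(f"interval chromosome {chrom!r} not in track")
    if stop <= start:
        raise ValueError("interval stop must exceed start")
    bs = track.bin_size
    v = track.values[chrom][start // bs:(stop - 1) // bs + 1]
    return float(np.nansum(v))


def response(area_control: float, area_experiment: float) -> float:
    """r = area_control / area_experiment (fold loss upon perturbation)."""
    if area_control < 0 or area_experiment < 0:
        raise ValueError("areas must be >= 0")
    if area_experiment == 0:
        raise ZeroDivisionError("zero experimental area: response undefined")
    return area_control / area_experiment


def discrete_frechet(curve_a, curve_b) -> float:
    """Discrete Frechet distance between two polygonal curves.

    Standard dynamic program under the Euclidean point metric; the curves
    are sequences of (position, value) pairs.  Symmetric, zero iff the
    point sequences coincide.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("curves must be non-empty")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("curves must be sequences of (position, value) pairs")
    # pairwise distances, then the coupled min-max recursion
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    f = np.empty_like(d)
    f[0, 0] = d[0, 0]
    for j in range(1, len(b)):
        f[0, j] = max(f[0, j - 1], d[0, j])
    for i in range(1, len(a)):
        f[i, 0] = max(f[i - 1, 0], d[i, 0])
        row_prev, row = f[i - 1], f[i]
        for j in range(1, len(b)):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(f[-1, -1])


def _shape_curves(ctrl_vals, exp_vals, normalize):
    """Common-support curves for the shape comparison.

    Positions are mapped to [0, 1] over the interval and both value
    series divided by the control maximum (one shared scale), so shape
    rather than amplitude dominates; ``normalize=False`` keeps raw bins.
    """
    both = np.isfinite(ctrl_vals) & np.isfinite(exp_vals)
    if not both.any():
        return None, None
    idx = np.flatnonzero(both)
    pos = idx.astype(float)
    if normalize:
        span = pos[-1] - pos[0]
        pos = (pos - pos[0]) / span if span > 0 else np.zeros_like(pos)
        scale = np.max(ctrl_vals[idx])
        if scale > 0:
            return np.column_stack([pos, ctrl_vals[idx] / scale]), np.column_stack([pos, exp_vals[idx] / scale])
    return np.column_stack([pos, ctrl_vals[idx]]), np.column_stack([pos, exp_vals[idx]])


def build_response_database(track_control: SiqTrack, track_experiment: SiqTrack,
                            annotations: AnnotationSet | None = None,
                            threshold: float | None = None,
                            min_width_bp: int | None = None,
                            merge_gap_bp: int | None = None,
                            normalize_shape: bool = True) -> pd.DataFrame:
    """Peak-wise comparison database between a control and an experiment.

    Peaks are called on the control track only; every record carries the
    interval, both areas, the response, the Frechet shape distance, the
    first-overlap annotation label and any flags.
    """
    if track_control.bin_size != track_experiment.bin_size:
        raise ValueError("control and experimental tracks have different bin sizes")
    if set(track_control.values) != set(track_experiment.values):
        raise ValueError("control and experimental tracks cover different chromosomes")
    bs = track_control.bin_size
    intervals = call_peaks(track_control, threshold, min_width_bp, merge_gap_bp)
    records = []
    for chrom, start, stop in intervals:
        sl = slice(start // bs, (stop - 1) // bs + 1)
        ctrl_vals = track_control.values[chrom][sl]
        exp_vals = track_experiment.values[chrom][sl]
        area_c = float(np.nansum(ctrl_vals))
        area_e = float(np.nansum(exp_vals))
        flags = []
        if area_e > 0:
            r = area_c / area_e
        else:
            r = np.nan
            flags.append(FLAG_UNDEFINED_RESPONSE)
        ca, cb = _shape_curves(ctrl_vals, exp_vals, normalize_shape)
        if ca is None:
            frechet = np.nan
            flags.append(FLAG_NO_SHAPE)
        else:
            frechet = discrete_frechet(ca, cb)
        state = label_interval(annotations, chrom, start, stop) if annotations is not None else ""
        records.append((chrom, start, stop, area_c, area_e, r, frechet, state, ",".join(flags)))
    return pd.DataFrame(records, columns=[
        "chrom", "start", "stop", "area_cntr", "area_exp", "response", "frechet", "state", "flags"])


@dataclass
class ResponseDistribution:
    """Unnormalized histogram mu(r) of peak responses, with binwidth dr.

    ``total[k]`` counts peaks with r in [edges[k], edges[k+1]); the final
    bin is an overflow bin for r > r_max.  ``per_state`` holds the exact
    decomposition mu(r) = sum_states mu(r | state); ``n_undefined`` peaks
    (zero experimental area) are tallied separately, never binned.
    """

    edges: np.ndarray
    total: np.ndarray
    per_state: dict[str, np.ndarray]
    n_undefined: int
    dr: float

    def to_frame(self) -> pd.DataFrame:
        low = np.append(self.edges[:-1], self.edges[-1])
        high = np.append(self.edges[1:], np.inf)
        data = {"r_bin_low": low, "r_bin_high": high, "total": self.total}
        for state, counts in self.per_state.items():
            data[state] = counts
        return pd.DataFrame(data)


def response_distribution(records: pd.DataFrame, dr: float = DEFAULT_DR,
                          r_max: float = DEFAULT_R_MAX) -> ResponseDistribution:
    """Histogram the responses of a peak database, decomposed by state."""
    if not dr > 0:
        raise ValueError("dr must be strictly positive")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1

    def hist(r_values):
        counts = np.zeros(n_bins + 1, dtype=np.int64)
        counts[:n_bins], _ = np.histogram(r_values, bins=edges)
        counts[n_bins] = int(np.sum(np.asarray(r_values) > edges[-1]))
        # histogram drops values above r_max; count them in the overflow bin
        return counts

    defined = records[np.isfinite(records["response"])]
    total = hist(defined["response"].to_numpy())
    per_state = {}
    for state, sub in defined.groupby("state", sort=True):
        per_state[str(state)] = hist(sub["response"].to_numpy())
    n_undefined = int(len(records) - len(defined))
    return ResponseDistribution(edges, total, per_state, n_undefined, float(dr))
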