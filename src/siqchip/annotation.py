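"""Decomposition of IP and input sequencing over a labeled segmentation.

Every fragment is assigned to exactly one state: the first (lowest-start)
annotation it overlaps on its chromosome, or an explicit "unannotated"
bucket.  The per-state counts f(a_i) then sum to the depth R-hat, which
makes three conservation laws hold exactly: counts sum to R-hat, mass
projections sum to m_IP, fractional compositions sum to 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AnnotationSet, FragmentSet
from .metadata import DNA_BP_MW, ExperimentMetadata, compute_alpha, concentration_coefficients

#: Label for fragments that overlap no annotation (keeps conservation exact
#: for segmentations with gaps or missing chromosomes).
UNANNOTATED = "unannotated"


def label_fragments(fragments: FragmentSet, annotations: AnnotationSet) -> np.ndarray:
    """State label of every fragment under the first-overlap rule.

    For fragment [s, e) the assigned annotation is the lowest-start
    interval with stop > s and start < e; non-overlapping fragments get
    ``UNANNOTATED``.  Deterministic and order-independent because the
    segmentation is validated non-overlapping.
    """
    labels = np.full(len(fragments), UNANNOTATED, dtype=object)
    frame = fragments.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        arrays = annotations.chrom_arrays(str(chrom))
        if arrays is None:
            continue
        ann_starts, ann_stops, ann_labels = arrays
        s = sub["start"].to_numpy(np.int64)
        e = sub["stop"].to_numpy(np.int64)
        # first annotation not entirely left of the fragment
        idx = np.searchsorted(ann_stops, s, side="right")
        hit = (idx < len(ann_starts)) & (ann_starts[np.minimum(idx, len(ann_starts) - 1)] < e)
        rows = sub.index.to_numpy()[hit]
        labels[rows] = ann_labels[idx[hit]]
    return labels


def label_interval(annotations: AnnotationSet, chrom: str, start: int, stop: int) -> str:
    """First-overlap state label for one interval (used for peaks)."""
    arrays = annotations.chrom_arrays(chrom)
    if arrays is None:
        return UNANNOTATED
    ann_starts, ann_stops, ann_labels = arrays
    idx = int(np.searchsorted(ann_stops, start, side="right"))
    if idx < len(ann_starts) and ann_starts[idx] < stop:
        return str(ann_labels[idx])
    return UNANNOTATED


def assign_fragments(fragments: FragmentSet, annotations: AnnotationSet) -> dict[str, int]:
    """Per-state fragment counts f(a_i); values sum to the depth exactly."""
    labels = label_fragments(fragments, annotations)
    states = annotations.states + [UNANNOTATED]
    counts = {state: 0 for state in states}
    uniq, n = np.unique(labels, return_counts=True)
    for state, c in zip(uniq, n):
        counts[str(state)] = int(c)
    return counts


def annotation_mass(counts: dict[str, int], meta: ExperimentMetadata) -> dict[str, float]:
    """IP mass projected onto the annotations, in ng.

    Computed as L * v_ip * 660 * c_IP * f(a_i), which simplifies to
    m_IP * f(a_i) / R-hat; both forms are evaluated and checked against
    each other.
    """
    c_ip = concentration_coefficients(meta).c_ip
    out = {}
    for state, count in counts.items():
        via_concentration = meta.L * meta.v_ip * DNA_BP_MW * c_ip * count
        via_mass = meta.m_ip * count / meta.depth_ip
        if abs(via_concentration - via_mass) > 1e-9 * max(abs(via_mass), 1e-300):
            raise AssertionError("mass projection forms disagree (bookkeeping bug)")
        out[state] = via_mass
    return out


def annotation_efficiency(counts_ip: dict[str, int], counts_in: dict[str, int], alpha: float) -> dict[str, float]:
    """Per-state capture efficiency e_i = alpha * f_IP(a_i) / f_in(a_i).

    States with zero input count have undefined efficiency and are masked
    as NaN (with a warning): the ratio has no physical value there.
    """
    if not alpha > 0:
        raise ValueError("alpha must be strictly positive")
    out = {}
    masked = []
    for state, n_ip in counts_ip.items():
        n_in = counts_in.get(state, 0)
        if n_in == 0:
            out[state] = float("nan")
            masked.append(state)
        else:
            out[state] = alpha * n_ip / n_in
    if masked:
        warnings.warn(f"states with zero input count masked: {masked}", stacklevel=2)
    return out


def fractional_composition(counts: dict[str, int], depth: int) -> dict[str, float]:
    """f(a_i) / R-hat: probability a random fragment carries state a_i."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return {state: count / depth for state, count in counts.items()}


def summarize(fragments_ip: FragmentSet, fragments_in: FragmentSet,
              annotations: AnnotationSet, meta: ExperimentMetadata) -> pd.DataFrame:
    """Full per-state summary table: counts, mass, fractions, efficiency."""
    counts_ip = assign_fragments(fragments_ip, annotations)
    counts_in = assign_fragments(fragments_in, annotations)
    alpha = compute_alpha(meta)
    mass = annotation_mass(counts_ip, meta)
    frac_ip = fractional_composition(counts_ip, fragments_ip.depth)
    frac_in = fractional_composition(counts_in, fragments_in.depth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eff = annotation_efficiency(counts_ip, counts_in, alpha)
    states = list(counts_ip)
    return pd.DataFrame({
        "state": states,
        "count_ip": [counts_ip[s] for s in states],
        "count_in": [counts_in[s] for s in states],
        "mass_ng": [mass[s] for s in states],
        "fraction_ip": [frac_ip[s] for s in states],
        "fraction_in": [frac_in[s] for s in states],
        "efficiency": [eff[s] for s in states],
    })


def metaplot(track, intervals, n_body_bins: int, flank_bp: int, n_flank_bins: int):
    """Mean signal profile over a set of intervals (e.g. one state's blocks).

    Each interval's body is rescaled to ``n_body_bins`` by averaging the
    track bins that fall in each proportional chunk (mean-within-bin, so
    area is preserved, not interpolated); flanks cover a fixed ``flank_bp``
    each side split into ``n_flank_bins``.  Masked bins and genome edges
    are excluded from the means.  Returns (profile, n_intervals_used)
    where the profile has n_flank_bins + n_body_bins + n_flank_bins
    entries.
    """
    if len(intervals) == 0:
        raise ValueError("metaplot requires at least one interval")
    if n_body_bins < 1 or n_flank_bins < 0:
        raise ValueError("bad metaplot bin counts")
    bs = track.bin_size
    rows = []
    for chrom, start, stop in intervals:
        if chrom not in track.values:
            continue
        v = track.values[chrom]

        def chunked(lo_bp, hi_bp, n_chunks):
            j0, j1 = lo_bp // bs, -(-hi_bp // bs)
            seg = np.full(j1 - j0, np.nan)
            lo_clip, hi_clip = max(j0, 0), min(j1, len(v))
            if hi_clip > lo_clip:
                seg[lo_clip - j0:hi_clip - j0] = v[lo_clip:hi_clip]
            n = len(seg)
            edges = (np.arange(n_chunks + 1) * n) // n_chunks
            out = np.full(n_chunks, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                for k in range(n_chunks):
                    chunk = seg[edges[k]:edges[k + 1]]
                    if len(chunk):
                        out[k] = np.nanmean(chunk)
            return out

        body = chunked(start, stop, n_body_bins)
        if n_flank_bins:
            left = chunked(start - flank_bp, start, n_flank_bins)
            right = chunked(stop, stop + flank_bp, n_flank_bins)
            rows.append(np.concatenate([left, body, right]))
        else:
            rows.append(body)
    if not rows:
        raise ValueError("no interval lies on a track chromosome")
    stacked = np.vstack(rows)
    used = int(np.sum(np.isfinite(stacked).any(axis=1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmean(stacked, axis=0)
    return profile, used
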