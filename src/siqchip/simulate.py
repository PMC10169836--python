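"""Synthetic experiments with known ground truth.

The generator emulates the physical picture behind the quantitative
scale: a chromatin preparation of fixed concentration is split into an
input aliquot (volume ``v_in``) and an IP reaction (volume ``v_ip``), and
each fragment in the IP reaction is captured independently with a
probability equal to the capture efficiency of its chromatin state
(Bernoulli capture -- the coarsest faithful reading of the Langmuir
species model; no antibody competition is simulated).

Concretely, a fragment pool of size ``n_input_fragments / e_bar`` (with
``e_bar`` the designed genome-wide capture fraction) represents the IP
reaction; capture on the pool yields the IP library, and the first
``n_input_fragments`` pool fragments are the sequenced input library.
Sizing the pool this way makes the two library depths comparable, so the
metadata the generator emits -- masses from concentration x volume x the
realized mass-capture fraction, depths and mean lengths realized from the
files -- yields a scale alpha approximately equal to the designed capture
fraction, and the per-state efficiency estimator recovers the designed
e's to within binomial sampling error.  When every state has e = 1 the IP
library is byte-identical to the input library.

Everything is driven by one integer seed through a PCG64 generator, so
identical seeds give byte-identical output files on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import label_fragments
from .io import AnnotationSet, FragmentSet
from .metadata import ExperimentMetadata, LegacyBookkeeping, DNA_BP_MW


@dataclass(frozen=True)
class SimulationDesign:
    """Ground-truth description of a synthetic siQ-ChIP experiment.

    Defaults describe a desk-scale experiment: a 2 Mb two-chromosome
    genome segmented into alternating state blocks, MNase-like
    mono-nucleosome fragment lengths (truncated normal, mean 180 bp,
    sd 20, range 100-400), and three states spanning strong enrichment to
    background-level capture.
    """

    genome: tuple = (("chr1", 1_000_000), ("chr2", 1_000_000))
    true_efficiency: dict = field(default_factory=lambda: {"TssA": 0.5, "Enh": 0.1, "Quies": 0.02})
    block_length_range: tuple = (5_000, 20_000)
    n_input_fragments: int = 200_000
    fragment_length: tuple = (180.0, 20.0, 100, 400)  # mean, sd, min, max (bp)
    v_in: float = 50.0
    v_ip: float = 200.0
    chromatin_conc: float = 2.0  # ng/uL of sheared chromatin DNA
    seed: int = 0

    def __post_init__(self):
        if not self.genome:
            raise ValueError("genome must be non-empty")
        if not self.true_efficiency:
            raise ValueError("at least one state with a true efficiency is required")
        for state, e in self.true_efficiency.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"true efficiency for {state!r} must lie in [0, 1], got {e!r}")
        if self.n_input_fragments < 1:
            raise ValueError("n_input_fragments must be >= 1")
        mean, sd, lo, hi = self.fragment_length
        if not (0 < lo <= mean <= hi) or sd < 0:
            raise ValueError("fragment length distribution must satisfy 0 < min <= mean <= max, sd >= 0")
        if min(length for _, length in self.genome) < hi:
            raise ValueError("every chromosome must be at least max fragment length long")
        if not (self.v_in > 0 and self.v_ip > 0 and self.chromatin_conc > 0):
            raise ValueError("volumes and chromatin concentration must be strictly positive")


@dataclass
class SimulationResult:
    """Everything a pipeline run needs, plus the ground truth."""

    annotations: AnnotationSet
    fragments_in: FragmentSet
    fragments_ip: FragmentSet
    metadata: ExperimentMetadata
    truth: pd.DataFrame
    designed_capture_fraction: float
    realized_capture_fraction: float

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self._chrom_sizes)


def _segment_genome(design: SimulationDesign, rng) -> AnnotationSet:
    """Alternating labeled blocks with uniform block lengths."""
    labels = list(design.true_efficiency)
    lo, hi = design.block_length_range
    rows = []
    k = 0
    for chrom, length in design.genome:
        pos = 0
        while pos < length:
            block = int(rng.integers(lo, hi + 1))
            stop = min(pos + block, length)
            rows.append((chrom, pos, stop, labels[k % len(labels)]))
            pos = stop
            k += 1
    return AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "stop", "state"]))


def _truncated_normal_lengths(n, mean, sd, lo, hi, rng) -> np.ndarray:
    if sd == 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        out[need] = draw
        need = (out < lo) | (out > hi)
    return np.rint(out).astype(np.int64)


def _sample_fragments(n, design: SimulationDesign, rng) -> FragmentSet:
    """Uniformly placed fragments with truncated-normal lengths."""
    chroms = [c for c, _ in design.genome]
    sizes = np.array([length for _, length in design.genome], dtype=float)
    mean, sd, lo, hi = design.fragment_length
    lengths = _truncated_normal_lengths(n, mean, sd, lo, hi, rng)
    which = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    starts = np.floor(rng.random(n) * (sizes[which] - lengths + 1)).astype(np.int64)
    chrom_col = np.array(chroms, dtype=object)[which]
    return FragmentSet.from_arrays(chrom_col, starts, starts + lengths)


def simulate_experiment(design: SimulationDesign) -> SimulationResult:
    """Generate a full consistent experiment from a design.

    Returns the segmentation, input and IP fragment sets, metadata whose
    six parameters are mutually consistent with the realized sequencing,
    and a per-state truth table (designed e, genome fraction, realized
    counts and efficiencies).
    """
    rng = np.random.default_rng(design.seed)
    annotations = _segment_genome(design, rng)

    # genome fraction per state and the designed overall capture fraction
    seg = annotations.frame
    bp = (seg["stop"] - seg["start"]).groupby(seg["state"]).sum()
    w = (bp / bp.sum()).to_dict()
    e_map = design.true_efficiency
    e_bar = float(sum(w[s] * e_map[s] for s in e_map))
    if e_bar <= 0:
        raise ValueError("designed overall capture fraction is zero; raise some efficiency")

    n_in = design.n_input_fragments
    n_pool = max(n_in, int(round(n_in / e_bar)))
    pool = _sample_fragments(n_pool, design, rng)
    states = label_fragments(pool, annotations)
    e_per_fragment = np.array([e_map[s] for s in states])
    captured = rng.random(n_pool) < e_per_fragment
    if not captured.any():
        raise ValueError("no fragments captured; increase n_input_fragments or the efficiencies")

    fragments_in = FragmentSet(pool.frame.iloc[:n_in])
    fragments_ip = FragmentSet(pool.frame[captured])

    pool_lengths = pool.lengths.astype(float)
    mass_capture = float(pool_lengths[captured].sum() / pool_lengths.sum())
    m_in = design.chromatin_conc * design.v_in
    m_ip = mass_capture * design.chromatin_conc * design.v_ip
    meta = ExperimentMetadata(
        v_in=design.v_in, v_ip=design.v_ip,
        m_ip=m_ip, m_in=m_in,
        L=float(fragments_ip.lengths.mean()),
        L_in=float(fragments_in.lengths.mean()),
        depth_ip=fragments_ip.depth, depth_in=fragments_in.depth,
    )

    rows = []
    in_states = states[:n_in]
    for state in e_map:
        n_pool_state = int(np.sum(states == state))
        n_cap_state = int(np.sum(captured & (states == state)))
        rows.append({
            "state": state,
            "e_true": e_map[state],
            "genome_fraction": w.get(state, 0.0),
            "n_pool": n_pool_state,
            "n_captured": n_cap_state,
            "n_input": int(np.sum(in_states == state)),
            "e_realized": n_cap_state / n_pool_state if n_pool_state else float("nan"),
        })
    truth = pd.DataFrame(rows)

    result = SimulationResult(
        annotations=annotations,
        fragments_in=fragments_in,
        fragments_ip=fragments_ip,
        metadata=meta,
        truth=truth,
        designed_capture_fraction=e_bar,
        realized_capture_fraction=float(captured.mean()),
    )
    result._chrom_sizes = dict(design.genome)
    return result


def two_island_fragments() -> FragmentSet:
    """Six fragments forming two disjoint pile-up islands on one chromosome.

    The left island holds three short fragments, the right three long
    ones; both islands reach the same maximum pile-up depth (3), so the
    +1 counting rule gives equal peak heights while the +1/L_i rule gives
    the long-fragment island a strictly lower peak.  Use a chromosome of
    100 bp when building tracks from it.
    """
    rows = [
        ("chr1", 10, 18),   # L = 8
        ("chr1", 12, 22),   # L = 10
        ("chr1", 14, 26),   # L = 12
        ("chr1", 60, 76),   # L = 16
        ("chr1", 64, 84),   # L = 20
        ("chr1", 68, 92),   # L = 24
    ]
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "stop"]))

#: chromosome sizes matching :func:`two_island_fragments`
TWO_ISLAND_CHROM_SIZES = {"chr1": 100}


def generate_legacy_bookkeeping(meta: ExperimentMetadata, seed: int) -> LegacyBookkeeping:
    """Random but internally consistent historical bookkeeping for ``meta``.

    Intermediate masses are drawn freely where the telescoping product
    cancels them; the loaded masses are then fixed by a single shared
    moles-to-reads conversion (reads per mole of library fragments is the
    same for both libraries, as on a multiplexed flow cell), and the same
    amplification cycle count is used for IP and input.  The resulting
    bookkeeping reproduces the six-parameter scale to floating-point
    accuracy for any seed.
    """
    rng = np.random.default_rng(seed)
    cycles = int(rng.integers(8, 15))

    frac_to_lib_ip = float(rng.uniform(0.3, 1.0))
    m_to_lib_ip = frac_to_lib_ip * meta.m_ip
    lib_eff_ip = float(rng.uniform(0.1, 0.9))
    m_lib_ip = lib_eff_ip * 2.0**cycles * m_to_lib_ip
    frac_lib_ip = float(rng.uniform(0.2, 0.9))
    m_loaded_ip = frac_lib_ip * m_lib_ip

    # shared sequencer yield: reads per mole of loaded library
    reads_per_mole = meta.depth_ip * DNA_BP_MW * meta.L / m_loaded_ip
    m_loaded_in = meta.depth_in * DNA_BP_MW * meta.L_in / reads_per_mole

    frac_to_lib_in = float(rng.uniform(0.3, 1.0))
    m_to_lib_in = frac_to_lib_in * meta.m_in
    frac_lib_in = float(rng.uniform(0.2, 0.9))
    m_lib_in = m_loaded_in / frac_lib_in
    lib_eff_in = m_lib_in / (2.0**cycles * m_to_lib_in)

    return LegacyBookkeeping(
        frac_lib_ip=frac_lib_ip, frac_lib_in=frac_lib_in,
        lib_eff_ip=lib_eff_ip, lib_eff_in=lib_eff_in,
        frac_to_lib_ip=frac_to_lib_ip, frac_to_lib_in=frac_to_lib_in,
        cycles_ip=cycles, cycles_in=cycles,
        m_loaded_ip=m_loaded_ip, m_loaded_in=m_loaded_in,
        m_to_lib_ip=m_to_lib_ip, m_to_lib_in=m_to_lib_in,
        m_lib_ip=m_lib_ip, m_lib_in=m_lib_in,
    )
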