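"""Experiment bookkeeping and the quantitative scale alpha.

siQ-ChIP ("sans spike-in quantitative ChIP-seq") places IP and input
sequencing on a common absolute scale without spike-ins.  The scale is a
single unitless constant

    alpha = (v_in / v_ip) * (m_IP / m_in) * (R_in / R_IP) * (L_in / L)

built from six bench-side parameters -- the input aliquot volume ``v_in``
(uL), the IP reaction volume ``v_ip`` (uL), the total IP and input DNA
masses (ng), and the average library fragment lengths (bp) -- plus the two
sequencing depths, which are counted directly from the mapped fragment
files.  Multiplying the IP/input coverage ratio by alpha converts it into
the physical capture efficiency of the IP reaction (the fraction of
chromatin from a locus that ended up antibody-bound).

This module houses that expression, the older bookkeeping-chain form it
supersedes (library fractions, efficiencies and amplification doublings),
and the mass-to-concentration coefficients whose ratio reproduces alpha
exactly.  The factor 660 g/mol/bp (average molecular weight of a DNA base
pair) cancels inside alpha but appears explicitly in the concentration
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

#: Average molecular weight of a double-stranded DNA base pair, g/mol/bp.
DNA_BP_MW = 660.0


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ExperimentMetadata:
    """The six reported siQ parameters plus the two sequencing depths.

    Parameters
    ----------
    v_in : float
        Volume of the input aliquot, uL.
    v_ip : float
        Volume of the IP reaction (total reaction volume minus the input
        aliquot), uL.
    m_ip : float
        Total IP'd DNA mass, ng.
    m_in : float
        Total input DNA mass, ng.
    L : float
        Average IP library fragment length, bp (e.g. from a Bioanalyzer
        trace; used verbatim, no adapter correction).
    L_in : float
        Average input library fragment length, bp.
    depth_ip, depth_in : int
        Number of sequenced fragments for IP and input.  These must be
        the *actual* counts from the fragment files, not the requested
        sequencing depth, or the normalization below breaks.
    """

    v_in: float
    v_ip: float
    m_ip: float
    m_in: float
    L: float
    L_in: float
    depth_ip: int
    depth_in: int

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])
        for name in ("depth_ip", "depth_in"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValueError(f"ExperimentMetadata.{name} must be an integer >= 1, got {value!r}")

    @classmethod
    def from_file(cls, path, depth_ip=None, depth_in=None) -> "ExperimentMetadata":
        """Parse a flat key-value metadata file.

        Accepted keys: ``v_in, v_ip, m_ip, m_in, L, L_in`` and optionally
        ``depth_ip, depth_in``.  ``V`` (total reaction volume) may be given
        instead of ``v_ip``; then ``v_ip = V - v_in``.  Separators may be
        whitespace, ``:`` or ``=``; ``#`` starts a comment.
        """
        values: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in (":", "="):
                line = line.replace(sep, " ")
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'key value', got {raw!r}")
            key, val = parts
            values[key] = float(val)
        if "v_ip" not in values and "V" in values:
            values["v_ip"] = values["V"] - values.get("v_in", 0.0)
        values.pop("V", None)
        if depth_ip is not None:
            values["depth_ip"] = depth_ip
        if depth_in is not None:
            values["depth_in"] = depth_in
        required = {"v_in", "v_ip", "m_ip", "m_in", "L", "L_in", "depth_ip", "depth_in"}
        missing = required - values.keys()
        if missing:
            raise ValueError(f"{path}: missing metadata keys: {sorted(missing)}")
        unknown = values.keys() - required
        if unknown:
            raise ValueError(f"{path}: unknown metadata keys: {sorted(unknown)}")
        values["depth_ip"] = int(values["depth_ip"])
        values["depth_in"] = int(values["depth_in"])
        return cls(**values)

    def to_file(self, path) -> None:
        lines = [f"{f.name}\t{getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class LegacyBookkeeping:
    """The older per-sample library bookkeeping chain.

    The historical scale was assembled from the fraction of each library
    sequenced (``frac_lib``), the library efficiency ``rho`` (library mass
    over the theoretical post-amplification mass), the fraction of IP'd /
    input material taken into library prep (``frac_to_lib``) and the
    number of amplification doublings.  The intermediate masses are kept
    so the chain can be checked for internal consistency:

        frac_lib = m_loaded / m_lib
        rho      = m_lib / (2**cycles * m_to_lib)
        frac_to_lib = m_to_lib / m_sample
    """

    frac_lib_ip: float
    frac_lib_in: float
    lib_eff_ip: float
    lib_eff_in: float
    frac_to_lib_ip: float
    frac_to_lib_in: float
    cycles_ip: int
    cycles_in: int
    m_loaded_ip: float
    m_loaded_in: float
    m_to_lib_ip: float
    m_to_lib_in: float
    m_lib_ip: float
    m_lib_in: float

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self) if not f.name.startswith("cycles")])
        for name in ("frac_lib_ip", "frac_lib_in", "frac_to_lib_ip", "frac_to_lib_in"):
            if getattr(self, name) > 1:
                raise ValueError(f"LegacyBookkeeping.{name} must lie in (0, 1], got {getattr(self, name)!r}")
        for name in ("cycles_ip", "cycles_in"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"LegacyBookkeeping.{name} must be an integer >= 0, got {value!r}")


@dataclass(frozen=True)
class ConcentrationCoefficients:
    """Per-read mass-to-concentration factors for IP and input.

    ``c_ip = m_IP / (660 * L * v_ip * depth_ip)`` and analogously for
    input.  Each is the product of a direct units conversion (mass to
    molar concentration of fragments) and a depth normalization; their
    ratio equals alpha identically.
    """

    c_ip: float
    c_in: float

    def __post_init__(self):
        _require_positive(self, ("c_ip", "c_in"))

    @property
    def alpha(self) -> float:
        return self.c_ip / self.c_in


def compute_alpha(meta: ExperimentMetadata) -> float:
    """The quantitative scale from the six-parameter form.

    alpha = (v_in/v_ip) (m_IP/m_in) (depth_in/depth_ip) (L_in/L).
    The 660 g/mol/bp factors cancel exactly and do not appear.
    """
    return (
        (meta.v_in / meta.v_ip)
        * (meta.m_ip / meta.m_in)
        * (meta.depth_in / meta.depth_ip)
        * (meta.L_in / meta.L)
    )


def compute_alpha_legacy(legacy: LegacyBookkeeping, v_in: float, v_ip: float) -> float:
    """The historical bookkeeping-chain form of the scale.

    alpha = (v_in/v_ip) (rho_in/rho) (frac_lib_in/frac_lib) (frac_to_lib_in/frac_to_lib).
    Agrees with :func:`compute_alpha` whenever the chain is internally
    consistent and the moles-to-reads conversion of the sequencer is the
    same for both libraries.
    """
    if not v_in > 0 or not v_ip > 0:
        raise ValueError("volumes must be strictly positive")
    return (
        (v_in / v_ip)
        * (legacy.lib_eff_in / legacy.lib_eff_ip)
        * (legacy.frac_lib_in / legacy.frac_lib_ip)
        * (legacy.frac_to_lib_in / legacy.frac_to_lib_ip)
    )


def total_possible_reads(m_ip: float, depth: float, m_loaded: float) -> float:
    """Total reads extractable from an IP if its full mass were sequenced.

    R = m_IP * (depth / m_loaded): the observed reads-per-mass yield
    applied to the whole IP mass.
    """
    if not m_ip > 0 or not depth > 0:
        raise ValueError("m_ip and depth must be strictly positive")
    if not m_loaded > 0:
        raise ValueError("m_loaded must be strictly positive")
    return m_ip * depth / m_loaded


def concentration_coefficients(meta: ExperimentMetadata) -> ConcentrationCoefficients:
    """Mass-to-concentration coefficients whose ratio is alpha."""
    c_ip = meta.m_ip / (DNA_BP_MW * meta.L * meta.v_ip * meta.depth_ip)
    c_in = meta.m_in / (DNA_BP_MW * meta.L_in * meta.v_in * meta.depth_in)
    return ConcentrationCoefficients(c_ip=c_ip, c_in=c_in)


def expected_response(alpha_control: float, alpha_experiment: float) -> float:
    """Genome-wide expected peak response: the ratio of the two scales.

    When a perturbation changes the total capture (hence alpha) without
    reshaping the track, every peak's control:experiment area ratio should
    sit near alpha_control / alpha_experiment.
    """
    if not alpha_control > 0:
        raise ValueError("alpha_control must be strictly positive")
    if not alpha_experiment > 0:
        raise ValueError("alpha_experiment must be strictly positive")
    return alpha_control / alpha_experiment
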