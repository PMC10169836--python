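"""Relative binding constants from siQ capture efficiencies.

The efficiency of a species (or annotation class) follows a Langmuir
isotherm in the free antibody concentration AB_f and the binding constant
K_B:  e = AB_f K_B / (1 + AB_f K_B), hence the odds e/(1-e) = AB_f K_B.
Taking the ratio of odds for two classes cancels AB_f and yields the
*relative* (apparent) binding constant K_B,i / K_B,j -- accessible from
sequencing alone, without titration.  Because an annotation aggregates
many chromatin species, these are apparent constants, not single-species
values.
"""

from __future__ import annotations

import math
import warnings


def efficiency_odds(e: float) -> float:
    """Binding odds AB_f * K_B = e / (1 - e); requires 0 <= e < 1."""
    if not 0 <= e < 1:
        raise ValueError(f"efficiency must lie in [0, 1): got {e!r} "
                         "(>= 1 signals an upstream bookkeeping problem)")
    return e / (1.0 - e)


def relative_kb(e_i: float, e_j: float) -> float:
    """K_B,i / K_B,j = odds(e_i) / odds(e_j); the free-antibody term cancels."""
    odds_j = efficiency_odds(e_j)
    if odds_j == 0:
        raise ValueError("reference efficiency e_j = 0: relative constant undefined")
    return efficiency_odds(e_i) / odds_j


def relative_kb_table(efficiencies: dict[str, float], reference_state: str) -> dict[str, float]:
    """Relative binding constant of every state versus one reference state.

    The reference maps to exactly 1.  States whose efficiency is >= 1, not
    finite, or (for the reference) 0 are masked as NaN with a warning
    rather than clipped: the odds transform is undefined there and a
    clipped value would fabricate a constant.
    """
    if reference_state not in efficiencies:
        raise KeyError(f"reference state {reference_state!r} not in table")
    e_ref = efficiencies[reference_state]
    if not (math.isfinite(e_ref) and 0 < e_ref < 1):
        raise ValueError(f"reference efficiency must lie in (0, 1), got {e_ref!r}")
    out = {}
    masked = []
    for state, e in efficiencies.items():
        if state == reference_state:
            out[state] = 1.0
        elif math.isfinite(e) and 0 <= e < 1:
            out[state] = relative_kb(e, e_ref)
        else:
            out[state] = float("nan")
            masked.append(state)
    if masked:
        warnings.warn(f"states with efficiency outside [0, 1) masked: {masked}", stacklevel=2)
    return out
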