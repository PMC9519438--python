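"""Entropy of plectoneme pinning by state counting, S = kB ln W.

A bound bending protein that pins the plectoneme apex at its own location
collapses the number of available apex positions W from about half the
circle (an apex and its partner apex are related by symmetry, so only half
of the ring gives distinct states) to one.  The associated entropic cost is
``delta S = kB ln(W_before / W_after)``, or ``T delta S`` in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN_KCAL",
    "EntropyEstimate",
    "apex_state_count",
    "entropy_reduction",
    "shannon_entropy",
]

#: Boltzmann constant in kcal/(mol K); kB * 300 K = 0.59616 kcal/mol
BOLTZMANN_KCAL = 0.0019872


@dataclass(frozen=True)
class EntropyEstimate:
    """State-counting entropy difference in kB and kcal/mol."""

    w_states: float
    delta_s_kb: float
    t_delta_s_kcal: float
    temperature: float


def apex_state_count(n_bp: int, fraction_accessible: float = 1.0) -> int:
    """Number of candidate apex positions on an ``n_bp`` circle.

    An apex can be pinned to each bp along half of the minicircle;
    ``fraction_accessible`` < 1 models the fact that not all positions are
    equally probable (some conformations are preferred).
    """
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    if not 0.0 < fraction_accessible <= 1.0:
        raise ValueError("fraction_accessible must lie in (0, 1]")
    # at least one state is always accessible (the pinned apex itself)
    return max(1, int(np.floor(fraction_accessible * n_bp / 2)))


def entropy_reduction(
    w_before: float, w_after: float = 1.0, temperature: float = 300.0
) -> EntropyEstimate:
    """Entropic reduction when the state count drops from w_before to w_after.

    Returns delta S = ln(w_before / w_after) in units of kB, and
    T delta S = kB T ln(w_before / w_after) in kcal/mol.
    """
    if w_after < 1 or w_before < w_after:
        raise ValueError("need w_before >= w_after >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    ratio = float(w_before) / float(w_after)
    delta_s = float(np.log(ratio))
    return EntropyEstimate(
        w_states=ratio,
        delta_s_kb=delta_s,
        t_delta_s_kcal=BOLTZMANN_KCAL * temperature * delta_s,
        temperature=temperature,
    )


def shannon_entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy -sum p ln p of an empirical apex-position histogram.

    Generalizes the uniform state count: for W equiprobable states it equals
    ln W, and by the Gibbs bound it never exceeds ln W for W observed states.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())
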