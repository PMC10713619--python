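"""Hunt/rest mode switching.

A chaser hunts until a stochastic clock sends it to rest and vice versa:
after ``t_hunt`` time units of continuous hunting the per-step probability
of switching to rest is ``min(t_hunt / T_hunt, 1)``, and symmetrically for
waking up.  A spell therefore never exceeds its cap by more than one step.
The draw happens once per step *before* movement, using the timer value
accumulated so far, and the active timer is incremented afterwards — so a
fresh spell always survives its first draw (p = 0).
"""

from __future__ import annotations

import numpy as np

from .core import ChaserState, Mode, SimulationConfig

__all__ = ["rest_probability", "hunt_probability", "advance_mode"]


def rest_probability(t_hunt: float, T_hunt: float) -> float:
    """Probability that a chaser hunting for ``t_hunt`` switches to rest."""
    return min(t_hunt / T_hunt, 1.0)


def hunt_probability(t_rest: float, T_rest: float) -> float:
    """Probability that a chaser resting for ``t_rest`` resumes hunting."""
    return min(t_rest / T_rest, 1.0)


def advance_mode(
    chaser: ChaserState, cfg: SimulationConfig, rng: np.random.Generator
) -> ChaserState:
    """Draw the mode switch for one chaser and advance its timers in place.

    Consumes exactly one uniform per call (also when p is 0 or 1) so the
    stream stays aligned with the compiled kernel.  On a switch the
    destination-mode timer restarts at zero; either way the timer of the
    mode the chaser is in *after* the draw grows by ``delta_t``.
    Capture success never resets the hunting clock.
    """
    u = rng.random()
    if chaser.mode == Mode.HUNT:
        if u < rest_probability(chaser.t_hunt, cfg.T_hunt):
            chaser.mode = Mode.REST
            chaser.t_rest = 0.0
    else:
        if u < hunt_probability(chaser.t_rest, cfg.T_rest):
            chaser.mode = Mode.HUNT
            chaser.t_hunt = 0.0
    if chaser.mode == Mode.HUNT:
        chaser.t_hunt += cfg.delta_t
    else:
        chaser.t_rest += cfg.delta_t
    return chaser
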