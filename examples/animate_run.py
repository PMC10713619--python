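"""Render a short trajectory animation (optional; needs matplotlib).

Writes an animated GIF of a small dense world: red = direct chasers,
green = group chasers, blue = targets; faded markers are resting
chasers.  Purely illustrative — not part of the tested surface.
"""

import numpy as np

import groupchase as gc
from groupchase.engine import initialize_world, step

try:
    import matplotlib.pyplot as plt
    from matplotlib.animation import FuncAnimation, PillowWriter
except ImportError:  # pragma: no cover
    raise SystemExit("this example needs matplotlib (pip install "
                     "groupchase[plot])")

cfg = gc.SimulationConfig(model="B", v_D=0.082, N_C=30, N_T=15, R=60.0,
                          r_haz=20.0, T_max=2000, seed=2)
world = initialize_world(cfg)

frames = []
for s in range(1200):
    world, _ = step(world, cfg)
    if s % 10 == 0:
        frames.append((world.chaser_pos.copy(), world.chaser_mode.copy(),
                       world.chaser_strategy.copy(),
                       world.target_pos.copy()))

fig, ax = plt.subplots(figsize=(5, 5))
ax.add_artist(plt.Circle((0, 0), cfg.R, fill=False, lw=1))
ax.set_xlim(-cfg.R * 1.05, cfg.R * 1.05)
ax.set_ylim(-cfg.R * 1.05, cfg.R * 1.05)
ax.set_aspect("equal")
ax.set_axis_off()
sc_d = ax.scatter([], [], c="tab:red", s=18, label="DCS")
sc_g = ax.scatter([], [], c="tab:green", s=18, marker="^", label="GCS")
sc_t = ax.scatter([], [], c="tab:blue", s=24, marker="*", label="target")
ax.legend(loc="upper right", fontsize=7)


def update(k):
    cpos, mode, strat, tpos = frames[k]
    hunting = mode == 0
    d = strat == 0
    sc_d.set_offsets(cpos[d])
    sc_d.set_alpha(np.where(hunting[d], 1.0, 0.25))
    sc_g.set_offsets(cpos[~d])
    sc_g.set_alpha(np.where(hunting[~d], 1.0, 0.25))
    sc_t.set_offsets(tpos)
    return sc_d, sc_g, sc_t


anim = FuncAnimation(fig, update, frames=len(frames), interval=50)
anim.save("scratch_run.gif", writer=PillowWriter(fps=20))
print("wrote scratch_run.gif")
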