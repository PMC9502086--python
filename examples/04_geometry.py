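"""Side-chain orientation angle, minimum distances, and RMSF.

Runs the geometry metrics on a synthetic bound salt-bridge pair and on
a jittered Cα trajectory with a known fluctuation amplitude.
"""

import numpy as np

from loopscan.core_io import Atom, Trajectory
from loopscan.geometry import AngleSpec, angle_series, distance_series, rmsf
from loopscan.synthetic import ContactPairScenario, ContactScenario, gen_contact_trajectory

traj, truth = gen_contact_trajectory(
    ContactScenario(pairs=(ContactPairScenario(p=1.0, resid_a=236, resid_b=264),),
                    n_frames=300, seed=7)
)

theta = angle_series(traj, AngleSpec(a=(236, "NH1"), b=(236, "CA"), c=(264, "CA")))
print(f"orientation angle: mean {theta.values.mean():.1f} deg over {len(theta.values)} frames")

dist = distance_series(traj, 236, 264, scope="sidechain")
print(f"min side-chain distance: mean {dist.values.mean():.3f} nm (always bound: < 0.33 nm)")

rng = np.random.default_rng(0)
sigma, n_res = 0.05, 40
base = rng.normal(size=(n_res, 3))
frames = np.tile(base, (5000, 1, 1))
frames[:, 0, :] += rng.normal(0.0, sigma, size=(5000, 3))
ca = Trajectory([Atom(i + 1, "CA", "ALA", i + 1) for i in range(n_res)], frames)
core = "resid " + " ".join(str(i) for i in range(2, n_res + 1))
table = rmsf(ca, selection="resid 1", fit_selection=core)
print(f"RMSF of the jittered residue: {table.rmsf_nm[0]:.4f} nm "
      f"(expected sigma*sqrt(3) = {sigma * np.sqrt(3):.4f} nm)")
print()
print("RMSF is computed after Kabsch superposition, so rigid-body motion")
print("does not contribute; an isotropic per-axis jitter sigma appears as")
print("a fluctuation of sigma*sqrt(3).")
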