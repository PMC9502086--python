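"""Contact occupancy of a salt bridge with known ground truth.

Generates a two-residue Arg/Glu pair whose bound/unbound state follows a
telegraph process (target occupancy 67%, lag-1 autocorrelation 0.5),
then measures the occupancy back with the 0.33 nm cutoff.
"""

from loopscan import occupancy
from loopscan.synthetic import ContactPairScenario, ContactScenario, gen_contact_trajectory

scenario = ContactScenario(
    pairs=(ContactPairScenario(p=0.67, phi=0.5),),
    n_frames=5000,
    seed=42,
)
traj, truth = gen_contact_trajectory(scenario)
spec = truth.specs[0]

est = occupancy(traj, spec, cutoff=0.33)
print(f"pair:                {spec.label} ({spec.kind})")
print(f"target occupancy:    67.0 %")
print(f"realized (truth):    {truth.realized_occupancy(0):.1f} %")
print(f"measured occupancy:  {est:.1f} %")
print()
print("The measured value counts frames whose minimum N...O distance is")
print("within 0.33 nm; it matches the generator's realized duty cycle up")
print("to the (rare) frames the positional noise pushes across the cutoff.")
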