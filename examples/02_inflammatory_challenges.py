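"""Simulate repeated inflammatory challenges and report remodelling outcomes.

Ten allergen challenges (one every 5 days for 50 days) drive the global
inflammatory status mu; above the mild threshold, contractile smooth-muscle
cells switch to the proliferative phenotype, wall mass accumulates, and the
airway grows inward.  After the challenge window the tissue partially
recovers toward homeostasis.
"""

import numpy as np

from airwaymorph import (ChallengeProtocol, SimulationConfig,
                         agonist_resolution_time, remodelled_inner_radius,
                         run_simulation)

cfg = SimulationConfig(
    protocol=ChallengeProtocol.periodic(omega=0.2, horizon=150.0),
    challenge_mode="inflammation_only",
)
res = run_simulation(cfg)

i50 = np.searchsorted(res.t, 50.0)
print(f"peak inflammatory status mu      : {res.mu.max():.3f}")
print(f"grown inner radius at day 0      : {res.xi1[0]:.4f} mm")
print(f"grown inner radius at day 50     : {res.xi1[i50]:.4f} mm")
print(f"remodelled radius (+5 d post)    : {remodelled_inner_radius(res):.4f} mm")
print(f"grown inner radius at day 150    : {res.xi1[-1]:.4f} mm")
rt = agonist_resolution_time(res)
print(f"agonist resolution time          : {rt.days:.1f} days (censored={rt.censored})")
print("\nThe wall thickens inward during challenges (radius drops from 1.8 mm),")
print("then partially recovers once inflammation clears — remodelling outlasts")
print("the stimulus but is not fully persistent at this operating point.")
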