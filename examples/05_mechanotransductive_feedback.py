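"""Hyper-responsiveness and the self-perpetuating agonist feedback loop.

Agonist-only challenges at two levels of intrinsic smooth-muscle
responsiveness T_c.  At normal responsiveness the agonist clears within
weeks of the final challenge.  At high T_c with strong stress-mediated
release, constriction raises tensile fibre stress, which releases more
agonist, which sustains constriction: the resolution time is censored and
remodelling continues long after the challenges stop.
"""

from airwaymorph import (ChallengeProtocol, SimulationConfig,
                         agonist_resolution_time, run_simulation, set_param)

base = SimulationConfig(
    protocol=ChallengeProtocol.periodic(omega=0.2, horizon=150.0),
    challenge_mode="agonist_only",
    nodes_per_layer=51, dt=0.1,
)

for label, T_c, a_c in (("normal responsiveness", 20.0, 0.02),
                        ("hyper-responsive + strong feedback", 60.0, 0.1)):
    cfg = set_param(set_param(base, "mat.T_c", T_c), "rates.a_c", a_c)
    res = run_simulation(cfg)
    rt = agonist_resolution_time(res)
    days = "never (censored)" if rt.censored else f"{rt.days:.1f} days"
    print(f"{label}: T_c={T_c:g} kPa, a_c={a_c:g}")
    print(f"  min loaded inner radius : {res.r1.min():.3f} mm")
    print(f"  agonist resolution time : {days}")
    print(f"  airway closed           : {res.closed}")
print("\nThe censored case is the mechanotransductive feedback loop: tensile")
print("fibre stress keeps releasing agonist, so bronchoconstriction and")
print("remodelling become self-sustaining.")
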