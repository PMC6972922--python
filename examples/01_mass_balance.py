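"""Mass-balance a small foodweb and read off ecotrophic efficiencies.

EE_i is the fraction of group i's annual production that is consumed by
predators, caught or exported; a web is balanced when every EE lies in
[0, 1]. The leftover production, PB*(1-EE), is the non-predation natural
mortality used to close the dynamic model.
"""
import numpy as np

from marinefutures import FoodWeb, FunctionalGroup, compute_ecopath_balance

groups = [
    FunctionalGroup("phyto", "producer", B0=10, PB=20),
    FunctionalGroup("zoop", "consumer", B0=2, PB=5, QB=40, unassim=0.3),
    FunctionalGroup("anchovy", "consumer", B0=0.8, PB=1.5, QB=8, unassim=0.25,
                    F0_commercial=0.2),
    FunctionalGroup("detritus", "detritus", B0=50),
]
diet = np.zeros((4, 4))
diet[0, 1] = 1.0                       # zooplankton eats phytoplankton
diet[1, 2], diet[3, 2] = 0.8, 0.2      # anchovy eats zooplankton + detritus

web = FoodWeb(groups, diet)
bw = compute_ecopath_balance(web)

print(f"{'group':10s} {'EE':>7s} {'M0 (yr^-1)':>11s}")
for g, ee, m0 in zip(web.groups, bw.EE, bw.M0):
    print(f"{g.name:10s} {ee:7.3f} {m0:11.3f}")
print(f"\nmax balance residual: {bw.residual:.2e}")
print("zooplankton EE = consumption by anchovy / production "
      f"= {0.8 * 0.8 * 8 / (2 * 5):.3f} (hand check)")
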