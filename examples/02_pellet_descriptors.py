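"""Pellet core/annulus descriptors from the forward-scatter pulse shape.

Builds three archetypal pellet pulses — a dense young pellet, a degraded
(vacuolized) one, and a hairy one — and prints their relative annular
diameter (RAD) and core compactness.
"""

import numpy as np

import pulsemorph as pm

SAT = 1e4


def trapezoid(left, core, right, dip_len=0):
    """Ramp–plateau–ramp FWS pulse; the plateau saturates the detector."""
    l = np.linspace(0.1 * SAT, 0.9 * SAT, left, endpoint=False)
    r = np.linspace(0.9 * SAT, 0.1 * SAT, right)
    c = np.full(core, SAT)
    if dip_len:
        start = (core - dip_len) // 2
        c[start : start + dip_len] = 0.5 * SAT  # unsaturated, degraded centre
    return pm.PulseShape(pm.Channel.FWS, np.concatenate([l, c, r]), 1.0, SAT)


cases = {
    "dense young pellet   ": trapezoid(13, 74, 13),
    "degraded core pellet ": trapezoid(6, 88, 6, dip_len=45),
    "hairy pellet         ": trapezoid(23, 54, 23),
}
print("pellet                 RAD   compactness")
for name, pulse in cases.items():
    rad = pm.compute_rad(pulse)
    comp = pm.compute_compactness(pulse)
    print(f"{name} {rad:.2f}  {comp:.2f}")

print()
print("RAD = annular diameter / particle length: the hairy outer layer's share.")
print("Compactness = saturated fraction of the core: drops with vacuolization,")
print("so high RAD + low compactness flags a degraded/broken pellet rather")
print("than a young rough one.")
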