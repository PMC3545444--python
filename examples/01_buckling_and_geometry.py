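"""Closed-form worked examples: buckling force, breakage curvature, head count.

The actin segment spanned by the myofilament bare zone behaves as an
elastic rod.  Its bending rigidity follows from the persistence length
(EI = lp * kT), the compressive force needed to buckle it is the Euler
force pi^2 EI / l^2, and the filament snaps once bent below a 0.18 um
radius.  The number of heads that load it follows from the myofilament's
measured length and its known crown structure.
"""

from myofil import (
    MyofilamentGeometry,
    bending_rigidity,
    critical_curvature,
    euler_buckling_force,
    head_pair_count,
    interacting_head_count,
)

EI = bending_rigidity(lp_um=15.0, kT=4.0)
F_c = euler_buckling_force(EI, l=160.0)
print(f"bending rigidity EI = {EI:.3g} pN nm^2 (from lp = 15 um)")
print(f"Euler buckling force of the 160 nm bare-zone segment: {F_c:.1f} pN (~23 pN)")
print(f"breakage curvature 1/r at r = 0.18 um: {critical_curvature(0.18):.2f} um^-1 (~5.6)")

geom = MyofilamentGeometry(total_length=560.0, bare_zone=160.0)
pairs = head_pair_count(geom)
heads = interacting_head_count(pairs)
print(f"head pairs on a 560 nm myofilament: {pairs} (exact {geom.head_pairs_exact:.1f})")
print(f"heads positioned to interact with one actin filament: {heads}")
print(
    "\nA ~30-head myofilament therefore needs to generate ~23 pN of internal"
    "\ntension before the actin under its bare zone buckles and can break."
)
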