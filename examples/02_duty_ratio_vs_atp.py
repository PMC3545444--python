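"""Steady-state occupancy of the head cycle as a function of ATP.

Only the ATP-binding rate k5 = kt*[ATP] depends on nucleotide
concentration, so at low ATP a head dwells long in the rigor state and the
duty ratio (time spent actin-bound, states 3-6) climbs towards 1.  This is
the chemical origin of processivity and force build-up at low ATP.
"""

from myofil import make_rates, steady_state_occupancy

print("ATP (uM)   k5 (1/s)   duty ratio   rigor occupancy")
for atp in (0.1, 1.0, 10.0, 100.0, 1000.0, 4000.0):
    rates = make_rates(atp)
    occ = steady_state_occupancy(rates)
    print(
        f"{atp:8.1f} {rates.k5:10.1f} {occ.bound_fraction:12.3f} {occ[5]:16.3f}"
    )
print(
    "\nThe duty ratio falls from ~0.9 at 0.1 uM ATP to ~0.04 at saturating"
    "\nATP; the drop is carried almost entirely by the rigor state, whose"
    "\ndwell 1/k5 shrinks as ATP rises."
)
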