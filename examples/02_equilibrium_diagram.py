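"""Equilibrium bifurcation structure under somatic and dendritic drive.

Continues the S-shaped curve of steady states over I in [-500, 500] for the
CA3 cell (gCa=10) and prints the folds (SN1 = rheobase, SN2, and for
dendritic drive SN3) and the supercritical Hopf (HB) where the depolarised
branch gains stability.
"""

from pyrcell import ModelParameters, equilibrium_diagram

for bif_param in ("ISapp", "IDapp"):
    d = equilibrium_diagram(ModelParameters(), bif_param)
    print(f"--- {bif_param} (gCa = 10) ---")
    for row in d.table():
        print(f"  {row['label']:12s} {bif_param} = {row['value']:10.5g}   "
              f"Vs = {row['Vs']:7.2f} mV")

print("\nSN1 is the rheobase fold ending the hyperpolarised resting branch; "
      "SN2 turns the saddle branch around; HB is where periodic spiking "
      "is born.  HB_singular marks a tiny-frequency pair crossing within "
      "1e-4 of SN1 (invisible at figure scale).")
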