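"""Periodic spiking branch: torus pair, period doubling, homoclinic tail.

Seeds the stable spiking cycle at ISapp = 10, continues it upward to the
Hopf and downward through the period doubling into the high-period tail,
and classifies the termination (homoclinic for the CA3 cell: the limiting
saddle is distinct from the SN1 fold equilibrium).

The tail is capped at a moderate period (~160 ms) — enough to identify the
limiting saddle — and the homoclinic parameter is then pinned by bisection
on the saddle's unstable-manifold fate; expect a few minutes.
"""

from pyrcell import ModelParameters, full_diagram

d = full_diagram(ModelParameters(), "ISapp", start_p=10.0, period_cap=160.0)
print("--- ISapp (gCa = 10) ---")
for row in d.table():
    print(f"  {row['label']:12s} ISapp = {row['value']:10.5g}")
term = d.termination
print(f"\ntermination: {term.kind} at ISapp ~ {term.p_est:.4f} "
      f"(approximating orbit period {term.period:.3g} ms)")
print(f"saddle-to-fold distance (scaled): {term.dist_saddle_fold:.3g} "
      "-> homoclinic (saddle distinct from SN1)" if term.kind == "HC"
      else "-> SNIC (saddle is the SN1 fold)")
print("\nTR1/TR2 bound the unstable waxing-waning window, PD starts the "
      "doublet/aperiodic cascade, and the branch dies in a global "
      "bifurcation where the period diverges.")
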