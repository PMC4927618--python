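# pyrcell

Bifurcation analysis toolkit for a smooth two-compartment hippocampal
pyramidal cell model.

## The problem

The classic two-compartment CA3 pyramidal cell model couples an axosomatic
compartment (transient Na⁺, delayed-rectifier K⁺, leak) to a dendritic
compartment (persistent Ca²⁺, Ca²⁺-activated K⁺, slow AHP K⁺, leak)
through an ohmic conductance, and reproduces the cell's repertoire of
resting, bursting and spiking.  Its original kinetics are non-smooth
(Heaviside switches and `min`-caps), which blocks the standard machinery
of numerical bifurcation analysis.  `pyrcell` implements the *smooth*
re-formulation — the discontinuous pieces replaced by fitted continuous
curves with errors of order 10⁻²–10⁻³ — together with the analysis
toolkit needed to map its dynamical landscape:

* stiff simulation, spike/burst detection and firing-pattern
  classification, f/I curves;
* pseudo-arclength equilibrium continuation with saddle-node and Hopf
  detection (exact SymPy-generated Jacobians);
* limit-cycle continuation by multiple shooting with Floquet-multiplier
  detection of torus, period-doubling and fold-of-cycles points;
* classification of branch terminations as homoclinic (HC) or
  saddle-node-on-invariant-circle (SNIC);
* two-parameter (I, g_Ca) continuation of fold and Hopf loci and
  bracketing of the codimension-2 SNIC point;
* fast–slow dissection of bursting with a frozen slow variable (q or Ca)
  and burster classification in the fold/subHopf taxonomy.

The model state is `(V_s, V_d, h, n, s, c, q, Ca)`; the somatic Na⁺
activation is instantaneous (`m_∞²(V_s)`), gates relax as
`dx/dt = (x_∞ − x)/τ_x`, and calcium follows
`dCa/dt = −0.13 I_Ca − 0.075 Ca`.  Audience: computational
neuroscientists and applied dynamicists who need the dynamical skeleton
of this widely used cell model — or a template for doing the same to a
related conductance-based model.

## A worked example

```python
from pyrcell import ModelParameters, equilibrium_diagram

d = equilibrium_diagram(ModelParameters(), "ISapp")
for row in d.table():
    print(f"{row['label']:12s} ISapp = {row['value']:.5g}")
```

prints (somatic drive, CA3 parameters, gCa = 10):

```
HB           ISapp = 23.692
HB_singular  ISapp = 0.02644
SN1          ISapp = 0.026508
SN2          ISapp = -81.574
```

SN1 is the rheobase: the fold where the hyperpolarised resting state is
lost.  SN2 turns the saddle branch around, and at the supercritical Hopf
HB ≈ 23.69 the depolarised branch gains stability and periodic spiking is
born.  (`HB_singular` is a tiny singular-Hopf pair hugging the fold,
invisible at figure scale.)  Continuing the spiking cycle itself
(`full_diagram`, or `examples/03_spiking_branch.py`) adds the torus pair
TR1 ≈ 21.1 / TR2 ≈ 15.9, the period doubling PD ≈ 2.29 and a homoclinic
termination near ISapp ≈ −12.4 whose saddle is distinct from SN1; at the
CA1-like conductance gCa = 7 the same tail instead dies on the SN1 fold —
a SNIC — which is how lowering the calcium conductance abolishes bursting.

The `examples/` directory has one short narrative script per capability
(firing patterns, equilibrium diagrams, the spiking branch, fast–slow
dissection, two-parameter loci, smoothing validation, phase analysis).
A thin CLI mirrors the library:

```bash
pyrcell continue-eq --preset ca3_default --param isapp --range -500 500 --out branch.csv
pyrcell fast-slow --freeze q --isapp 0.3 --out fs_q.csv
pyrcell validate-smoothing
```

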