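# cgsterol

Analysis toolkit for coarse-grained (CG) simulations of sterol- and
oxysterol-containing lipid bilayers, built around a concrete question from
vascular biology: exposure of endothelial cells to low-density lipoprotein
(LDL) mildly raises membrane cholesterol, while oxidized LDL instead
deposits the oxysterol 7-ketocholesterol (7KC). Even though both changes
are subtle (cholesterol moving between ~38 and ~43 mol%, 7KC between ~0.2
and ~2 mol%), they push membrane structure in opposite directions —
cholesterol condenses and orders the bilayer, 7KC condenses it weakly while
sitting more tilted and *dis*ordering the lipid tails. `cgsterol` provides
the complete computational chain needed to quantify that dichotomy from CG
trajectories, plus a synthetic-membrane generator that makes every analyzer
verifiable by parameter recovery.

The package is used from Python; the `examples/` directory contains one
short narrative script per capability.

## What it computes

**Lipidomics → composition.** Mass-spec sterol content S (pmol sterol per
nmol lipid phosphate) converts to mole percent as

    mol% = 100 · S / (1000 + S),

treating the membrane as phospholipid + sterol. The phospholipid remainder
R = 100 − CHOL − 7KC is split 70:30 into PC:SM and the PC share 80:20 into
POPC:DPPC (endothelial proportions); largest-remainder apportionment turns
percentages into integer molecule counts for two equal leaflets.

**7-ketocholesterol topology.** The eight-site MARTINI 2 virtual-site
cholesterol model with the third ring bead (SC3) replaced by a heavier,
more polar SNa bead (52.66 u) representing the C7 ketone; serialized as an
ITP `[atoms]` block, with splicing into a user-supplied base cholesterol
ITP so bonded geometry is inherited.

**Bilayer observables** from GRO/XTC trajectories (orthorhombic box,
bilayer normal ẑ):

* area per lipid A = LxLy / N_leaflet, per frame;
* thickness d = |⟨z⟩_upper − ⟨z⟩_lower| over phosphate beads;
* lateral diffusion D = ¼ lim d/dt MSD(t), from the time-origin-averaged,
  periodic-boundary-unwrapped in-plane MSD (FFT formulation) and an OLS
  slope fit;
* sterol tilt θ = arccos |v̂ · ẑ| for the ring axis v (K5→KOH for 7KC,
  R5→ROH for cholesterol), folded to [0°, 90°];
* tail pseudobond order parameters, reported in both sign conventions:
  `standard_P2` = ⟨(3cos²θ − 1)/2⟩ and `as_printed` = −⟨(3cos²θ − 1)/2⟩;
* unpaired two-sided Student's t-tests (pooled variance) for group
  comparisons.

**Free energies.** A Bennett acceptance ratio (BAR) estimator — the tool
used to validate sterol topologies via octanol–water partition free
energies — solving Σ_F f(M + W_F − ΔF) = Σ_R f(−M + W_R + ΔF) by robust
bracketing, with the standard asymptotic error estimate and kJ/mol
conversion at 310.15 K.

**Synthetic membranes.** `cgsterol.synthetic` builds two-leaflet lattices
and Brownian-dynamics trajectories in which every one of the above
quantities has a known ground-truth value; `cgsterol.recovery` measures
them all back. See `docs/methods.md` for the generator's model and its
limits.

## Worked example

```sh
python examples/synthetic_recovery.py
```

```
membrane: 128 lipids/leaflet, 500 frames at 100 ps

recovered vs. target:
  area/lipid     43.999 Å²   (target 44.000)
  thickness      42.997 Å    (target 43.000)
  D[POPC]      1.0191 Å²/ns (target 1.0000)
  D[DPPC]      0.8125 Å²/ns (target 0.8000)
  D[SM  ]      0.7102 Å²/ns (target 0.7000)
  D[CHOL]      0.6082 Å²/ns (target 0.6000)
  D[7KC ]      0.9371 Å²/ns (target 0.9000)
  tilt[CHOL]    24.66°     (target 24.52°)
  tilt[7KC ]    41.09°     (target 41.15°)
  order parameters: 17 bonds, max |ΔP2| = 0.0054
```

Each line compares an observable measured from the generated trajectory
with the value the generator was asked to produce: the lateral box area
over the leaflet lipid count recovers the target area per lipid, the
phosphate-plane separation the thickness, the MSD slope/4 each species'
diffusion coefficient (in Å²/ns; 1 Å²/ns = 10⁻⁷ cm²/s), the ring-axis
angles the tilt-distribution mean, and ⟨(3cos²θ−1)/2⟩ per tail bond its
order-parameter target. At the full benchmark size (512 lipids/leaflet,
2,000 frames) the same recovery tightens to <1 % on D and <0.002 on P2;
`tests/test_acceptance.py` asserts those tolerances.

The other examples print the composition table derived from the measured
sterol contents (`composition_from_lipidomics.py`), the 7KC site table and
its single-bead difference from cholesterol (`sterol_topology.py`), the
BAR estimate on an analytically solvable Gaussian work pair
(`bar_free_energy.py`), and the order/tilt dichotomy sweeps
(`sterol_dichotomy.py`).

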