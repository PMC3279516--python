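# igh-elastica

Mechanics and geometry of modular **Ig-domain / α-helix protein
filaments**, modelled on the C-terminal filament of the muscle M-band
protein myomesin, My9–My10–My11–My12–(My13)₂–My12′–…–My9′.  Each repeat
is a folded immunoglobulin (Ig) domain followed by an exposed α-helical
linker; the helices unfold reversibly near equilibrium at ~30 pN and act
as molecular springs, while the Ig domains unfold stochastically and
irreversibly at higher force.  The package is for structural biologists
and single-molecule biophysicists who want to simulate, analyze or
sanity-check the elasticity and geometry of such tandem filaments.

## What it computes

**Forward mechanics** (`igh_elastica.mechanics`).  A serial chain of
elements shares one force *F*.  Unfolded polypeptide stretches as a
Marko–Siggia worm-like chain,

    F(x) = (kT/p) · [ x/L + 1/(4(1−x/L)²) − 1/4 ],      p = 0.5 nm,

folded Ig domains unfold with the Bell–Evans rate
*k(F) = k₀·exp(F·Δx/kT)* (releasing a contour increment ΔL), and each
helical linker is a reversible two-state element whose unfolded
occupancy is the Boltzmann logistic
*1/(1+exp(−(F−F½)·ΔL_eff/kT))*, sampled with single-flip kinetics that
satisfy detailed balance.  `simulate_pull` drives a constant-velocity
stage against the chain through a cantilever spring (6 pN/nm, 20 kHz
sampling, 3 pN Gaussian force noise) and solves the quasi-static
balance `stage = F/k_c + x(F)` at every sample.

**Trace analysis** (`igh_elastica.analysis`).  Saw-tooth event
detection, per-segment WLC fits at fixed persistence length (contour
length is the only free parameter, ΔL = successive differences), the
contour-length transformation *L = x / f(F)* of plateau data, Gaussian
peak-spacing of the resulting contour-length histogram, plateau
detection and stretch/relax hysteresis.

**Extension arithmetic** (`igh_elastica.extension`).  Per-residue axial
rises (1.5 Å/residue helical, 3.6 Å extended, 3.8 Å Cα–Cα unfolded,
0.365 nm/residue AFM contour calibration), helix unfolding gains,
extended filament length and the extension ratio.

**Structural geometry** (`igh_elastica.geometry`).  PDB reading/writing,
Kabsch superposition on a shared domain (for composite-model assembly),
per-domain centroids, k-th-neighbor centroid distance spectra,
tilt/twist angles between domains (inertia-tensor frames, swing–twist
decomposition), the pair distance distribution p(r) with Rg and Dmax,
and a synthetic superhelix builder.

## Worked example

```sh
python examples/simulate_and_analyze_pull.py
```

```text
simulated 8400 samples at 20 kHz; 8 Ig unfolding events in the generator log
detected 8 saw-tooth events
fitted contour lengths (nm): [106.8 136.6 166.3 196.  225.7 255.4 285.1 314.8 344.5]
contour increments dL (nm) : [29.73 29.71 29.72 29.69 29.7  29.7  29.69 29.7 ]
mean dL = 29.70 nm (one unfolded Ig domain's released contour length)
```

One fast (1 µm/s) pull of the dimer produces the classic saw-tooth: each
force peak is one Ig domain unfolding, and the WLC fit of each rising
branch grows by ΔL ≈ 29.7 nm — the contour length released by one
unfolded domain.  The slow-pull example shows the other half of the
mechanics:

```sh
python examples/plateau_substructure.py
```

```text
plateau: median force 31.1 pN over extensions 24-42 nm (span 18 nm)
contour-length levels (nm): [32.1 38.  43.9 49.8 56.2]
mean peak-to-peak spacing : 6.02 nm (the contour released by one helix)
```

At 10 nm/s the four helical linkers of one arm unfold and refold near
equilibrium, producing a force plateau near 30 pN whose samples convert
to discrete contour-length levels spaced by the 6 nm per-helix gain.
`examples/extension_arithmetic.py` prints the straightened-filament
bookkeeping (290 Å domains + 570 Å linkers = 860 Å, 2.5× the resting
length), `examples/stretch_relax_reversibility.py` shows that
stretch–relax cycles through the plateau enclose no net area, and
`examples/superhelix_geometry.py` runs the geometry toolkit on a
synthetic superhelical filament.  `examples/composite_from_pdb.py`
assembles a composite model from user-supplied PDB fragments.

A thin CLI wraps the same functions:
`igh-elastica {simulate, analyze, extend, geometry}`; every run writes a
JSON manifest with the config hash, seed and input checksums.

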