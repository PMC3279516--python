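# Methods

This note documents the models, parameter choices and numerical
procedures behind `igh-elastica`, and what the synthetic data do and do
not establish about real measurements.

## Mechanical model of the filament

The filament is a serial chain of mechanical elements that share a
common tension *F*: folded Ig domains, α-helical linkers, unfolded
polypeptide, and passive segments (the central dimerization module).
Unfolded polypeptide follows the Marko–Siggia worm-like-chain (WLC)
interpolation with persistence length *p* = 0.5 nm and temperature
298 K (kT = 4.114 pN·nm).  Because every WLC segment at a common force
has the same relative extension *f(F)*, the chain extends as a single
WLC of the summed contour length plus the summed rigid extents — this
makes the quasi-static force balance a scalar root-finding problem.

**Folded elements.**  By default a folded element contributes its
folded extent *as WLC contour* (`folded_mode="contour"`), so the whole
chain is exactly one WLC whose contour length grows by the element's
`contour_gain_unfolded` when it unfolds.  This is the convention of
standard Monte Carlo simulations of tandem-Ig pulling, and it makes the
generator exactly consistent with the single-WLC fits the analyzer
performs: the fitted contour increment equals the generator's ΔL with
no model-mismatch bias.  A `folded_mode="rigid"` option treats folded
extents as force-independent lengths instead; it is physically closer
to a rigid body but introduces a systematic ≈ −0.5 nm bias in fitted
ΔL (a rigid 4.6 nm insert is not a 4.6 nm WLC), which is why it is not
the default.  Defaults: Ig domains 94 residues, folded extent 4.61 nm,
ΔL = 29.7 nm (so that ΔL = 94 × 0.365 − 4.61 exactly); helices folded
extent 2.25 nm, contour gain 6 nm.

**Ig unfolding** is stochastic and irreversible within a trace, with
the Bell–Evans rate *k(F) = k₀ exp(F·Δx/kT)*.  The kinetic parameters
are not identifiable from the data the package emulates, so they are
free configuration with defaults k₀ = 10⁻⁴ s⁻¹ and Δx = 0.3 nm —
typical tandem-Ig values that put unfolding forces near 150–250 pN at
1 µm/s.  Per step the transition fires with probability
1 − exp(−k(F)·dt), exact for a constant rate within a step.

**Helix elements** unfold reversibly and close to equilibrium.  The
unfolded occupancy at force *F* is the two-state Boltzmann logistic
with midpoint *F½* (default 30 pN) and width kT/ΔL_eff, where ΔL_eff
is the extension gained at the midpoint force (≈ 4.3 nm for a 6 nm
contour gain at 30 pN, giving a ≈ 1 pN logistic width).  States are
updated with single-flip kinetics satisfying detailed balance:
unfolding rate ν·p(F), refolding rate ν·(1 − p(F)), with attempt
frequency ν = 10⁴ s⁻¹ (dwell times of ~0.1–1 ms, so the flicker
between adjacent contour levels is resolved at 20 kHz, as it is in slow
experimental recordings).  An alternative mode that redraws every helix
state independently from its occupancy each step is retained for
comparison but is *not* the default: with several helices coupled
through one force, collective redraw produces unphysical all-or-none
contour fluctuations that destroy the force plateau; the single-flip
scheme recovers the experimentally observed behaviour — a plateau of
flickering steps centred near the midpoint force.  With finitely many
identical helices the plateau is not perfectly flat: binomial state
multiplicities tilt the step ladder by roughly ±1.3 pN across it, and
the detected median sits ~1 pN above the midpoint.

**Pulling protocol.**  Constant-velocity stage segments (stretch and
relax), cantilever stiffness 6 pN/nm, sampling 20 kHz, Gaussian force
noise of 3 pN added after the mechanics so that transition logic is
noise-free.  At every sample the quasi-static balance
`stage = F/k_c + C + L·f(F)` is solved by a warm-started Newton
iteration on *f* (stage residual < 10⁻⁸ nm, i.e. force residual
< 10⁻⁶ pN; the largest residual of a run is reported in the trace
metadata).  A single seeded generator drives all randomness; identical
seeds give bit-identical traces.

## Trace analysis

* **Event detection.**  The force is boxcar-smoothed over half the
  detection window (default window 1 ms); peaks with prominence
  ≥ `min_drop` qualify as events when the drop persists to the end of
  the window.  The persistence test rejects reversible helix flickers
  (which recover within ~0.2 ms) while keeping irreversible Ig drops.
  `min_drop` defaults to 25 pN: single-helix plateau steps produce
  drops up to ~26 pN near the plateau exit, while Ig drops in fast
  pulls exceed 60 pN.  Near-coincident double unfoldings (two domains
  within a few ms) occasionally merge into one detected event with a
  doubled ΔL; they are rare (≈ 1–4 per 400 events at 1 µm/s) and are
  reported as-is.
* **WLC segment fits.**  Each rising branch between detected events is
  fitted with a Marko–Siggia WLC in force-residual space; persistence
  is fixed at 0.5 nm and only the contour length is free (bounded
  scalar minimization).  Samples below 30 pN are excluded so the fit
  rides the taut part of the branch above the helix plateau; segments
  with fewer than 10 usable samples are skipped with a warning.
* **Contour-length transformation.**  For the Marko–Siggia chain the
  relative extension depends only on force, so each sample maps to
  *L = x / f(F)*.  Samples below a 5 pN force floor are excluded (the
  inversion amplifies noise at low force); the count of excluded
  samples is reported.  Restricting the transform to a detected
  plateau's extension range reproduces the published style of plateau
  substructure analysis.
* **Peak spacing.**  The contour-length histogram (0.5 nm bins,
  zero-padded so edge clusters count as maxima) seeds a Gaussian
  mixture with one component per local maximum above 8 % relative
  prominence; the spacing is the mean of successive component-mean
  differences.  For a four-helix arm the plateau data resolve the
  baseline level plus four increment levels (4–5 peaks; 4 gaps of
  ≈ 6 nm).
* **Plateau detection.**  Over a grid of extension intervals (1 nm
  bins, prefix-sum regression) the detector keeps intervals whose
  least-squares force-vs-extension slope is ≤ 0.6 pN/nm — over the
  interval *and over each half*, so a steep approach cannot be traded
  against plateau length — and whose every populated bin has mean
  force ≥ 15 pN; the longest interval spanning ≥ 10 nm wins and its
  median raw force is reported.  The slope tolerance sits above the
  intrinsic ladder tilt of a finite helix battery (~0.4 pN/nm for four
  helices) and below the WLC rise at comparable forces for contour
  lengths up to ~100 nm; the force floor separates the plateau from
  the flat low-force toe of a long WLC.
* **Hysteresis.**  Stretch and relax curves are interpolated onto a
  common extension grid over their overlap and the signed enclosed
  area is integrated by the trapezoid rule.

## Extension arithmetic

Two distinct unfolded-chain constants coexist and are never
interchanged: 3.8 Å/residue (Cα–Cα spacing, used for the
straight extended-filament length model) and 0.365 nm/residue (AFM
contour calibration, used for expected WLC contour gains).  The
canonical dimer architecture carries five My domains and four helical
linkers per protomer (two ≈15-residue "four-turn" and two ≈22-residue
"six-turn" helices), mirrored about the (My13)₂ module; exact linker
residue counts are only known graphically and are parameters.  The
per-class decomposition (ten straightened domains 290 Å, 150 linker
residues × 3.8 Å = 570 Å, total 860 Å) is available directly via
`movie_decomposition`; the element-level canonical architecture gives
852 Å, consistent within 1 %.  Ratios are reported to one decimal.

## Geometry

Centroids are unweighted Cα means by default (mass-weighted all-atom
behind a flag) — the data the analyses rest on do not specify the
weighting, and Cα centroids are reproducible without mass tables.
Domain frames come from the Cα covariance tensor: the long axis is the
largest-variance eigenvector, sign-fixed from the N- to the C-terminal
Cα; the second axis is sign-fixed toward the first Cα and
re-orthogonalized.  Tilt is the angle between long axes; twist is the
swing–twist component, about the inter-centroid axis, of the rotation
carrying one frame onto the other.  For filaments whose modules advance
mostly along the filament axis the inter-centroid axis approximates the
helix axis well (for the default synthetic superhelix, rise 49.8 Å and
radius 5 Å, the twist recovery error of this convention is < 0.03°).
Near-spherical domains (degenerate inertia) and collinear superposition
sets are rejected with errors.  p(r) uses all unordered Cα pair
distances in 2 Å bins, unnormalized; Rg is the root-mean-square
distance from the centroid and Dmax the largest pair distance.
Superposition matches Cα atoms by residue index and uses the SVD
(Kabsch) least-squares rotation.

PDB handling: first model only, ATOM records only, altlocs other than
blank/'A' dropped, author 1-based numbering preserved, insertion codes
rejected with an error naming the line, malformed coordinate fields
reported with their line number.

## Synthetic data: scope and limits

The generator emulates constant-velocity AFM pulls of a serial
Ig/helix chain with cantilever coupling, equilibrium helix flicker,
Bell–Evans Ig unfolding and white Gaussian force noise, and the
synthetic superhelix provides geometrically exact module stacks.  It
does **not** emulate instrument drift or 1/f noise, cantilever
resonance/damping, surface and multi-tether artifacts, Ig refolding,
heterogeneous domain stabilities, or the irregular My12–My13 twist of
the real filament; passing the closure tests therefore shows the
*procedures* are correct and self-consistent at realistic noise levels,
not that real traces are free of these confounds.  Geometry claims
about the real composite filament model require the deposited fragment
coordinates, which are not shipped; `examples/composite_from_pdb.py`
shows how to run the identical pipeline on downloaded files.

## Problem sizes and reproducibility

The test suite and the acceptance script use 50 fast pulls (1 µm/s,
~8 400 samples each) for the ΔL statistics, 20 slow pulls (10 nm/s,
96 000 samples each) for the plateau substructure, and 20 stretch–relax
cycles for the plateau force and hysteresis; the whole acceptance run
takes ~40 s on one CPU.  Per-pull random streams are derived from the
user seed and the pull index, so every number is reproducible from the
seed alone.
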