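# Methods

This note documents the models implemented in `pepmem`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Quenching models (`pepmem.quench`)

**Stern–Volmer.** F0/F versus quencher molar concentration is fitted by
ordinary least squares, either with a free intercept (default, a diagnostic
for static quenching or mixing errors) or with the theoretical intercept of
1 imposed (`fix_intercept`). The standard error of the slope is reported
from the residual variance. Input series must have strictly increasing
non-negative concentrations and positive ratios; when a zero-quencher point
is present its ratio must be 1 within a tolerance (default 0.2, widened to
5·noise SD for simulated series) — tight enough to catch mislabelled
columns, loose enough to admit real noisy titrations.

**Normalized accessibility factor.** NAF = Ksv(membrane)/Ksv(buffer).
When standard deviations of both constants are supplied the ratio
uncertainty is propagated to first order,
sd = NAF·√((sd_m/Ksv_m)² + (sd_b/Ksv_b)²). Values are carried at full
precision; a `rounded(2)` accessor mirrors the convention of reporting
NAF to two decimals.

**Distribution analysis.** ln F0/F(h) = S/(σ√(2π))·exp(−(h−hm)²/(2σ²)).
For exactly three depths the solution is closed-form: y = ln ln F0/F is
quadratic in h, the interpolating parabola y = ah² + bh + c must have
negative curvature (otherwise `FitDegenerateError`), and then
σ² = −1/(2a), hm = −b/(2a), S = exp(y_vertex)·σ√(2π). For more depths a
trust-region least-squares refinement (xtol/ftol 1e-14) is seeded from the
closed-form solve on the three most-quenched points. Non-positive ln F0/F
is a log-domain error: the Gaussian model cannot produce it.

**Parallax method.** ln F0/F(h) = πC(Rc² − (h−hm)²). The same parabola
machinery applies directly to ln F0/F: C = −a/π, hm at the vertex,
Rc = √(y_vertex/(πC)); negative curvature and a positive vertex ordinate
are required. Two conventions for C are exposed because published fits
differ and the original analyses do not always state the choice:

* free C (default) — the 3-point closed form determines it;
* `c_fixed` — C is supplied (helper `in_plane_concentration(x, A_L)` with
  x the quencher mole fraction and area per lipid A_L defaulting to 70 Å²)
  and only (hm, Rc) are fitted; two depths then suffice.

Truncation of the parabola (0 outside |h−hm| > Rc) is applied at
model-evaluation and simulation time only, never during fitting: all
calibrated bromine depths lie inside the fitted quenching radius, so the
untruncated quadratic is the regime the estimator actually sees, and it
keeps the fit smooth. Both depth models are single-leaflet as written; a
symmetric two-leaflet variant (mirrored term at −hm) exists behind
`two_leaflet=True` but is off by default, matching how 3-point profiles
are conventionally fitted.

**Simulation.** `simulate_depth_quenching` adds Gaussian noise to
ln F0/F — the simplest noise model that respects positivity of F — and
records the generating parameters in the profile metadata.
`profile_area` integrates the fitted Gaussian over hm ± 8σ by adaptive
quadrature; the area equals S to well below 1e-6.

## Frames and geometry (`pepmem.frame`, `pepmem.geometry`)

Coordinates are Å throughout; the bilayer normal is +z unless a frame
overrides it. Atoms carry name, element, mass, 1-based residue index,
residue name and a group tag in {peptide, lipid, water, ion} inferred from
residue names on file input.

* **Bilayer center**: mass-weighted lipid centroid (default) or the
  midpoint of the two leaflet phosphate means; both are reported by the
  diagnostics helper because they differ for asymmetric leaflets.
* **Tilt**: angle between the Cα(N-side)→Cα(C-side) vector (defaults:
  residues 2 and 13) and the *outward* normal of the leaflet hosting the
  peptide COM. This makes tilt < 90° mean "N-terminus deeper" and lets a
  flipped membrane analyze identically. An axis-based variant uses the
  principal axis of the Cα trace (SVD, oriented N→C); the two agree within
  ~3° on ideal helices, the residual coming from the off-axis positions of
  individual Cα atoms.
* **Azimuth**: angle in the plane normal to the helix axis between the
  projected outward normal and the projected side-chain direction
  (side-chain COM − Cα) of a reference residue; 0° = side chain pointing
  straight at the water, 180° = at the membrane center. Rotating the frame
  by +δ about the axis lowers the reported azimuth by δ.
* **Depths**: per-frame |z − z_center| for Cα and side-chain COM (side
  chain = all non-backbone atoms including hydrogens). Glycine-like
  residues without side-chain atoms are flagged and report Cα depth only.
  A configurable leading fraction of frames can be discarded before
  averaging.
* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 3.5 Å and
  H–donor···acceptor angle ≤ 30° — the default criterion of the common MD
  analysis tools, adopted because published H-bond counts rarely state
  one; both thresholds are arguments. Hydrogens are resolved from donor
  names by the PDB v3 convention (NE→HE, NH1→HH11/HH12, …); donors without
  hydrogens either raise or fall back to distance-only with a warning.
  An arginine is *bidentate* in a frame iff ≥ 2 simultaneous bonds run
  from its guanidinium nitrogens to oxygens of a single phosphate group
  (one phosphate per lipid residue is assumed when grouping by acceptor
  residue).
* **π-cation**: contact iff guanidinium Cζ to indole-ring centroid
  ≤ 6.0 Å; the 6 Å default matches the distance regime of reported
  side-chain COM–COM contact distances. The angle between the ring normal
  (smallest principal direction of the 9 ring atoms) and the Cζ–centroid
  vector is recorded but not thresholded.
* **Helical wheel**: angle(i) = (i−1)·100° mod 360. The summary reports
  circular means and resultant lengths of two residue classes (default Trp
  vs Arg), the gap between the class means, and the minimal arc containing
  class A — for an idealized amphipathic sequence the six tryptophans fall
  within a 140° arc.
* Minimum-image wrapping is applied to pair vectors only when a box is
  present; peptides are never wrapped mid-analysis (whole-molecule
  convention).

## Secondary structure (`pepmem.secstruct`)

Backbone hydrogen bonds use the classical electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
below −0.5 kcal/mol; distances under 0.5 Å raise a clash error. Missing
amide hydrogens are placed 1.00 Å from N opposite the bisector of the
C(i−1)→N and Cα(i)→N directions — within 0.35 Å of the reference geometry
on explicit-hydrogen fixtures. An n-turn at residue i means CO(i) accepts
from NH(i+n); two consecutive n-turns produce a minimal helix (H for n=4,
G for n=3, I for n=5) with priority H > G > I on overlap, isolated turns
give T, the rest C. Strand machinery is deliberately not implemented —
the target peptides have no β content — but long-range bonds that would
form bridges trigger a warning. π-helix (I) assignment is sensitive to the
priority convention; implementations that rank I above G on overlap will
disagree on rare frames.

**Helix fractions** count H, G and I as helical. Per trajectory, frames
before `discard_ns` (default 10) are dropped, the remainder is split into
`blocks_per_traj` (default 2) equal blocks, and the mean and sample SD are
taken across all blocks of all trajectories — three trajectories × two
blocks give six block values.

**Secondary chemical shifts** subtract a shipped random-coil Hα reference
(a standard published random-coil set; swappable via the `reference`
argument). A run of ≥ 4 consecutive negative deltas (configurable) flags a
helix.

**sPRE**: per atom, intensities are normalized to the zero-agent point, a
least-squares slope versus concentration is fitted, and |slope| is min–max
normalized across the dataset into a score in [0, 1] (1 = most exposed).
The normalization is per-dataset because the underlying measurements are
reported on an arbitrary intensity scale.

## Density profiles (`pepmem.profiles`)

Mass density (amu/Å³) per uniform z bin per named group, recentred on the
bilayer center per frame (profiles are conventionally plotted relative to
the center, and recentring makes them translation-invariant), divided by
bin volume (box cross-section × bin width, default 0.5 Å) and averaged
over frames. Mass density rather than number density is the default —
the choice is not always stated alongside published profiles, and mass
density is what the marker-particle fixtures conserve exactly. Integration
recovers the selected mass to machine precision by construction. Peak
summaries report both the mass-weighted mean |z| and the modal bin.

## Synthetic generators (`pepmem.synthetic`)

The generators produce the study conditions for every analysis, with
complete ground truth in metadata:

* `build_ideal_helix` — backbone from standard internal coordinates at
  φ = −57°, ψ = −47° (rise ≈ 1.5 Å, twist ≈ 100°/residue), explicit amide
  hydrogens, and one pseudo side-chain particle per residue 2.5 Å radially
  outward from Cα carrying the residue's side-chain mass. Sufficient for
  tilt/azimuth/depth/COM analyses; atomic side-chain detail exists only in
  the dedicated contact fixtures.
* `build_slab` — marker particles per lipid (choline N at ±22 Å,
  phosphate ±20 Å, glycerol ±16 Å, chain fillers at ±4/8/12 Å) on a
  jittered lattice at 70 Å²/lipid, emulating a ~30 Å hydrocarbon core in a
  ~50 Å bilayer, plus single-particle water (mass 18.015 amu) at a
  down-sampled 0.01 Å⁻³ in the water slabs. Depths are idealized
  constants, not force-field samples.
* `place_helix` — rotates the helix axis to the requested tilt, spins it
  about its own axis until the *analysis* azimuth of the reference residue
  equals the request (closing the loop through the same convention the
  analyzer uses), and translates the axis midpoint to the requested depth.
* `make_ensemble` — i.i.d. Gaussian jitter per atom per frame, optional
  smoothed tilt drift, times at fixed spacing, deterministic per seed.
* `build_guanidinium_phosphate` / `build_arg_trp_pocket` — idealized
  contact fixtures (labelled synthetic) that satisfy or violate the
  detection criteria by construction.
* `make_shift_table` / `make_spre_table` — tabular twins with controllable
  helical offset and decay slopes.

What passing tests on these fixtures shows: the estimators invert their
own forward models exactly, conventions are self-consistent
(construction → recovery within 2° tilt, 0.5 Å depth, 5° azimuth at zero
noise), and counting logic is correct on unambiguous geometry. What it
does not show: behavior on real force-field ensembles with lipid disorder,
water defects, peptide flexibility beyond rigid jitter, or experimental
noise structure. Trajectory-scale observables (hydrogen-bond plateaus,
equilibrium tilt distributions) therefore require user-supplied
trajectories of equivalent content; the pipeline computes them, but their
published magnitudes are not reproduced at desk scale.

## Numerical choices and problem sizes

* Closed-form 3-point solves use `np.polyfit` (exact interpolation);
  refinements use `scipy.optimize.least_squares` at xtol = ftol = 1e-14.
* Degenerate inputs fail loudly: zero curvature, non-positive vertex,
  non-positive log arguments, empty selections, coincident reference
  atoms, clashes.
* The test suite and the acceptance script run on small problem sizes
  chosen as the smallest that exercise every protocol branch — 36
  lipids/leaflet slabs, 200-frame jittered ensembles, 15-frame static
  ensembles for the blocking protocol (discard 10 time units, two blocks),
  100 random profiles for the vertex-identity property.
* SDs across blocks use the sample convention (ddof = 1); per-frame
  summary SDs use the population convention (ddof = 0).

## Known limitations

* No β-sheet assignment, no lipid order parameters, no electron/neutron
  density modes, no binary trajectory formats (the XYZ + topology dialect
  is the adapter point), no spectral preprocessing of raw fluorescence.
* The bidentate definition keys on acceptor residue, which conflates
  phosphate groups only if a single lipid residue carried several.
* `QuenchSeries` admits at most one zero-concentration point (strictly
  increasing concentrations); replicate measurements should be averaged
  upstream.
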