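# Methods

## Problem and model

Contact basket catheters sample the fibrillating atrium at 64 sites
(8 splines A–H × 8 electrodes 1–8). Two natural coordinate systems
coexist: the **unfolded 2D grid** (splines as columns, electrodes as
rows, unit electrode spacing) and the **curved 3D shell** spanned by the
electrodes inside the atrium. Rotational activation — a spiral wave —
appears in either representation as a phase singularity: a point where
the instantaneous phase is undefined and winds by ±2π around any
enclosing loop. The package implements both representations end to end
and quantifies their agreement; the underlying expectation, borne out by
the synthetic studies here, is that a smooth deformation of the grid
onto a curved surface cannot move a tip relative to its four surrounding
electrodes unless splines cross.

## Signal chain

*QRS removal.* Unipolar atrial electrograms carry ventricular far-field
deflections. R peaks are found on a reference ECG lead by a
Pan–Tompkins-style detector (5–20 Hz band-pass, squared derivative,
150 ms integration window, adaptive threshold at 20 % of the envelope
maximum, 200 ms refractory); the detector is deterministic. The
electrogram's own morphology in a window around every R peak (default
100 ms before to 150 ms after; configurable) is averaged into a template
and subtracted at each beat. Beats whose window leaves the record are
excluded from both averaging and subtraction.

*Filtering.* 1.5–25 Hz Butterworth of order 4, run forward–backward
(`sosfiltfilt`) so the net phase response is zero — phase maps cannot
tolerate filter delay. Note that subtraction and filtering commute to
<1 % RMS only for artifacts whose energy lies inside the pass band; a
template with net area leaves a high-pass ring-down that escapes the
subtraction window (≈1–3 % residual). This is a property of the method,
not an implementation artifact.

*Dominant cycle length.* Welch PSD (Hann, 2048-sample segments, 50 %
overlap ⇒ 0.49 Hz bins at 1 kHz), argmax restricted to 2–12 Hz — the
physiological AF frequency band; T_CL = 1000/f_dom ms. T_CL is computed
on the filtered, artifact-free signal (the stage order is fixed:
subtraction → band-pass → T_CL).

*Recomposition and phase.* Each sample with negative forward-difference
slope d_k = (e_{k+1} − e_k)·fs < 0 launches one sine period
|d_k|·sin(2πu/T_CL) starting at that sample (value 0, ascending);
positive slopes contribute nothing; wavelets truncate at the record end.
The sum is computed as a convolution of the negative-slope train with
one sine period. The wavelet phase origin is arbitrary (the cited
construction does not pin it); any fixed offset shifts all phases by a
constant, and winding numbers are offset-invariant, so tips are
unaffected — the zero-ascending start is chosen so activation (the
negative-going zero crossing) falls inside the wavelet. Phase is the
angle of the analytic signal via a full-record FFT Hilbert transform
after mean removal. The Hilbert phase of the recomposed signal
*increases* through time while the activation phase convention
(θ = φ − ωt) decreases; this inversion is absorbed by the loop
orientation convention below.

## Geometry

*2D grid.* 8×8 nodes, 49 sub-squares, each split along the A1→B2
diagonal into triangles (A1,B1,B2) and (A1,B2,A2); 98 triangles, open
boundary.

*Basket shell.* The same connectivity applied to the 64 coordinates,
plus the wraparound column (H back to A) and each pole octagon closed by
a 6-triangle fan from its spline-A vertex: 124 faces, 186 edges, Euler
characteristic 2. The fan is one of several closures consistent with the
refined counts; any triangulation of the octagons with no interior
vertices gives the same totals. Winding is normalized so face normals
point away from the centroid; any face still pointing inward after the
global normalization indicates crossed splines and is a hard error (the
automated replacement for visual inspection).

*Subdivision.* Three rounds of flat 4-way subdivision (edge midpoints,
no smoothing): V' = V + E, E' = 2E + 3F, F' = 4F, hence 64 → 3970
vertices and 124 → 7936 faces. Flatness is essential: every refined
vertex stays on its ancestral face, so its value is an exact convex
(barycentric) combination of that face's three electrode values, kept as
an explicit (3970 × 64) weight matrix. A smoothing scheme would decouple
interpolation from geometry. Each refined face stores its level-0
ancestor; each level-0 face maps to a sub-square (i, j), the wrap
column, or a pole cap. Side faces are emitted in the same order as the
grid faces, so face index f < 98 denotes the *same* sub-triangle on both
surfaces and 2D↔3D transfer is: same face index, same barycentric
weights.

A consequence worth stating: because interpolation weights and face
loops are purely combinatorial, 3D tip detection is invariant to the
actual electrode coordinates — exactly the deformation argument above,
now by construction. Geometry enters only through curvature, shell
projection, and mm conversions.

## Detection, tracking, densities

2D frames interpolate the 64 analytic signals bilinearly onto a 29×29
lattice (3 inserted points per interval per direction); 3D frames apply
the electrode-weight matrix; both exploit linearity of the Hilbert
transform (interpolate-then-transform ≡ transform-then-interpolate,
verified to 1e−6 rad). Frames are emitted every 10 samples (10 ms) by
default — tip densities are stride-robust for persistent tips, and the
source frame rate for density averaging is otherwise a free choice.

The winding number of every elementary 2D cell (28×28) and every refined
3D face is the wrapped-difference sum divided by 2π, rounded. Loops run
counterclockwise in (electrode, spline) axes in 2D and outward-consistent
in 3D; with these orientations a detected charge of +1 is a
counterclockwise rotor as seen from outside the basket, and 2D and 3D
charges agree for the same rotor. On the closed shell charges always sum
to zero (each edge is traversed once per direction), so a single spiral
in the mapped field is necessarily accompanied by an opposite charge —
in the synthetic studies it lives on the wraparound seam or pole caps,
which are tallied outside the 7×7 matrix, as the matrix indexes only the
7 non-wrap spline pairs.

Tracking is greedy nearest-neighbour: matching charge, jump ≤ 1
electrode spacing per step, gaps of one frame bridged; tracks persisting
≥ 3·T_CL are reported. (The tracker replaces the human persistence
review used clinically; its gates are package choices.) Densities:
D[i][j] = fraction of frames with ≥1 tip in sub-square (i, j).

## Curvature and shell projection

Principal curvatures come from a local quadric fit over each vertex's
2-ring in the frame of its area-weighted outward normal
(h = ax² + bxy + cy² + dx + ey; Weingarten eigenvalues, signed so a
sphere has H > 0). Vertices with fewer than 5 ring points are flagged
unreliable. Accuracy on analytic surfaces: sphere H within 3 %, K within
6 %; plane below 1e−6; cylinder H within 10 %. On the flat-subdivided
basket shell the curvature concentrates at level-0 edges (the facets are
flat), which still ranks genuinely bent regions first; tests that need
true surface curvature project the refined vertices onto the analytic
surface first.

Shell projection casts a ray from the electrode centroid through every
shell vertex and assigns the value of the first basket face hit
(vectorized Möller–Trumbore; smallest positive ray parameter, then
smallest face index — determinism over elegance). Vertices whose ray
misses (degenerate shells) fall back to the angularly nearest face
centroid and are flagged. The face *value* is assigned, not
interpolated within the face, matching the stated projection rule.

## Comparison statistics

Pearson r over masked density entries (means over the mask only); pole
mask rows i ∈ {1,7}, equator i = 4; curvature masks take the k = 7
entries owning the highest/lowest-curvature reliable vertices
(vertex → ancestral face → sub-square; ties at rank k resolved
lexicographically). Max-density distance uses lexicographic argmax
tie-breaks. The paired Wilcoxon signed-rank statistic is exact for
n ≤ 25 (dynamic program over the signed-rank distribution, midranks
doubled to integers to stay exact under ties) and a tie-corrected normal
approximation beyond; p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1.
Quartiles are linear-interpolation (type 7).

## Synthetic data

Activation is kinematic, defined on the grid parameterization
(x = spline, y = electrode) and shared with the shell through it, so 2D
and 3D truth coincide sub-square by sub-square:

* spiral: θ = σ·atan2(y−y₀, x−x₀) − ωt + k·r, default period 180 ms
  (a typical AF cycle length), arm wavenumber 0.7 rad/spacing
  (wavelength ≈ 9 spacings, i.e. larger than the grid, as for real
  rotors), optional sinusoidal core meander (default off);
* figure-of-eight: two superposed vortices of opposite chirality;
* planar wave: zero winding everywhere.

Electrodes fire a biphasic deflection at every zero crossing of their
local activation phase: a derivative-of-Gaussian spike (width 5 ms,
steep negative slope at the activation instant) plus a low-amplitude
recovery hump (0.45, 40 ms later, 30 ms wide). The hump mirrors the
repolarization content of real unipolar electrograms and keeps the
spectral fundamental at the activation rate; a bare spike train puts
more Welch power into its harmonics than into 1/T. White noise and a
shared periodic Q-R-S template (with a clean copy as the ECG reference
lead) are optional; all randomness flows from one seed.

Basket geometries place electrodes on a sphere or ellipsoid at 8 equal
azimuths × colatitudes π(2i−1)/16, with optional seeded jitter up to
10 % of the spacing (retried at half amplitude if splines cross).
Default radius 25 mm (adult atrial scale); ellipsoids 25×25×35 mm.

The standard ten-case comparison study (`standard_case_suite`) covers
spiral and figure-of-eight activation on sphere and ellipsoid baskets
with cores distributed over equatorial *and* polar rows (two
figure-of-eight cases use vertical core offsets so one rotor sits near a
pole). Regional correlations are only informative where the region
contains activity; a suite with all cores mid-grid would test the pole
rows on single-frame interpolation transients rather than on signal.
Undefined regional correlations (no tips in the region in either map)
are excluded from the paired test.

What the generator does **not** emulate: biophysical wavebreak and
meander statistics, fibrosis, electrode contact loss, far-field atrial
components, mapping-system coordinate noise. Passing tests therefore
demonstrate the correctness of the mapping mathematics on controlled
rotational patterns, not clinical detection performance.

## Numerical choices and degenerate inputs

Phases wrap to (−π, π]; the wrapped-difference sum around any loop is an
exact multiple of 2π up to float error, so rounding to the nearest
integer is safe away from exact-π differences (which have measure zero
for real data). Barycentric weights tolerate −1e−9 before a point is
declared outside a face. All-zero signals raise degenerate-signal
errors rather than returning arbitrary phase. Problem sizes in tests and
the acceptance study — 4 s windows at 1 kHz, 400 frames per case, ten
cases — match the clinical mapping-window format and keep a full case
under a second of compute.

## Known limitations

* Fixed T_CL per channel over the whole window; episodes with drifting
  cycle length get suboptimal recomposed signals.
* The 2D grid is open: activity crossing the H–A seam is visible only in
  3D (reported off-matrix).
* Curvature on the flat-subdivided shell is facet-bend curvature, not
  smooth-surface curvature.
* The tracker is single-hypothesis greedy; crossing tips could swap
  identities.
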