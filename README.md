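# phasebasket

Phase mapping of atrial fibrillation (AF) from 64-electrode basket
catheters — in the flat 2D electrode grid, on the reconstructed curved 3D
basket shell, and projected onto an anatomical shell — with quantitative
comparison of the two representations.

## Who this is for

Cardiac-electrophysiology researchers who record AF with 8-spline ×
8-electrode contact baskets and want mapping software that is independent
of proprietary systems: given unipolar electrograms and the 3D electrode
coordinates, the package reconstructs instantaneous phase, finds
phase singularities (spiral-wave / rotor tips), and answers the question
*does unfolding the curved basket into a flat 8×8 map move the tips?*

## Method

Per channel, with electrogram e(t) sampled at 1 kHz:

1. **Ventricular artifact removal** — R peaks are detected on a reference
   ECG lead; the electrogram morphology in a window around every R peak is
   averaged into a template and subtracted at each beat.
2. **Band-pass** — 1.5–25 Hz fourth-order Butterworth, applied
   forward–backward (zero phase).
3. **Dominant cycle length** — T_CL = 1000/f_dom ms, where f_dom is the
   Welch-PSD argmax in the 2–12 Hz AF band.
4. **Sinusoidal recomposition** — every sample k with negative slope d_k
   contributes one wavelet |d_k|·sin(2πu/T_CL), u ∈ [0, T_CL); the sum
   s(t) oscillates about zero and its negative-going zero crossings are
   the activation times.
5. **Phase** — θ(t) = arg(s + i·H[s]) via the Hilbert transform H.

Phase singularities are points where the phase winds by ±2π:
w = (1/2π) Σ wrap(θ_{k+1} − θ_k) around a closed loop, w = ±1 at a tip.
In 2D the loop is every elementary cell of a 29×29 lattice (3 points
inserted per inter-electrode interval by bilinear interpolation); in 3D
it is every face of the basket shell — the 64 coordinates triangulated
with the grid connectivity (spline H wrapped to A, pole octagons capped),
subdivided 4-way three times to 3970 vertices / 7936 faces, with the
recomposed signal interpolated barycentrically from the electrode
vertices. Per-frame tips are binned into the 7×7 matrix of
inter-electrode sub-squares, D_ij = fraction of frames with a tip in
sub-square (i, j), and the two maps are compared by the Pearson
correlation r of D²ᴰ and D³ᴰ (full matrix, pole rows i ∈ {1,7}, equator
i = 4, highest/lowest-curvature regions), the distance between their
maxima, and Wilcoxon signed-rank tests across cases.

Because no public basket recordings of human AF exist, the package ships
a synthetic generator (spiral, figure-of-eight and planar activation with
known tip positions, realistic deflections, noise and QRS artifact) that
every stage is validated against.

## Worked example

```sh
python examples/01_simulate_and_map.py
```

prints

```
median dominant cycle length: 186.2 ms (generator period 180 ms)
frames analysed: 400 at 10 ms
persistent 2D track: chirality +1, mean position (3.52, 3.52) electrode spacings, duration 3840 ms
2D density peak: sub-square (i=4, j=4) occupied 92% of frames
2D/3D tip-density correlation r = 0.9999
```

The generator placed a counterclockwise spiral with a 180 ms period at
grid position (3.5, 3.5): the pipeline recovers the cycle length to
within one Welch bin (0.49 Hz), finds exactly one persistent tip at the
injected core with the right chirality, and the 2D and 3D density maps
are statistically indistinguishable (r ≈ 1), i.e. unfolding the basket
did not move the tip. The other `examples/` scripts walk through mesh
construction and curvature, the single-channel signal chain, the
ten-case 2D/3D comparison study, and anatomical-shell projection.

A thin CLI wraps the same calls:

```sh
phasebasket simulate --model spiral --period 180 --seed 7 --out sim/
phasebasket all --egm sim/electrograms.csv --coords sim/electrodes.csv --out run/
```

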