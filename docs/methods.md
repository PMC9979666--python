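# Methods

## The problem and the model

Angled-scan lightsheet modalities (oblique-plane microscopy and relatives)
image tilted optical sections: the excitation sheet makes an angle α with
the axis along which the sample (or sheet) is scanned.  Because the camera
frame lies in the sheet plane, consecutive frames are laterally offset in
the row direction by the shear factor

    l = z · cos(α)        (micrometres; divide by the pixel size for pixels)

where z is the scan step between frames.  A viewer that stacks the raw
frames without accounting for l shows a distorted sample — a cylinder's
circular cross-section appears stretched by 1/sin(α).

Deskewing reintroduces the shifts: frame *k* is remapped into a larger
canvas at row offset *k·l*.  Instead of materialising the deskewed volume,
this package folds each remapped frame into a running pixelwise maximum.
Since `max` is associative and commutative, the final canvas equals the
maximum-intensity projection (MIP) of the full deskewed volume, but memory
stays at three raw-frame-sized arrays plus one projection-sized array, and
a partial projection exists at every instant of the acquisition — which is
what makes a live view possible.

### Viewing rotation (shear-warp)

The projection of a volume rotated by θ about its centre equals the
projection of the same volume sheared and then vertically scaled by
cos(θ) (the shear-warp factorisation).  Here the rotation is realised by
evaluating the shear at α + θ instead of α and rescaling the finished
projection by cos(θ) with bilinear interpolation; θ = 0 recovers the
identity.  This composition replaces the exact shear-warp shear increment
(∝ tan θ) with a cos(α+θ) evaluation; the two differ in vertical
displacement by a factor cos(θ), i.e. the approximation error grows as
(1 − cos θ) ≈ θ²/2 and is a small fraction of a pixel on desk-scale
volumes for |θ| ≤ 20°.  The fidelity test quantifies this directly against
a brute-force 3D rotation + MIP oracle (normalised RMS error ≤ 5 %, and in
practice ≤ 3 % on the 8×16×16 test volume).

Rotation combinations with α + θ outside (0°, 90°] are rejected rather
than extrapolated; mirrored scan directions are handled by the geometry's
`shear_sign` flag instead of negative shears.

## Update modes

* **Global** — frames are folded into an in-progress canvas; one warped
  projection is emitted per completed stack, then the canvas resets to
  zeros.  Right for short exposures, where stacks complete at several Hz.
* **Rolling** — a ring buffer keyed by cyclic stack position holds the
  most recent stack's worth of frames; a warped projection is emitted
  after *every* frame.  Because `max` cannot be inverted, evicting a frame
  is handled by zeroing and recomputing only the canvas rows the evicted
  and inserted slices touch (at most one frame height plus the shear, per
  side), from the buffer.  Before the buffer first fills, emissions are
  flagged `partial`; what a live display should show in that window is a
  UI policy, and the engine makes the state explicit instead of hiding it.

A view change never produces a mixed-view output: rolling mode rebuilds
the canvas from the buffer immediately; global mode defers the change to
the next stack so the in-progress canvas stays consistent.

## Slice mode

For scattering samples, projecting the full volume can wash out contrast.
Slice mode zeroes all rows of each raw frame outside a central horizontal
band before folding, reconstructing only a thin optical section around the
sheet centre.  A band of *b* rows on a frame of height *h* keeps rows
`[floor((h−b)/2), floor((h−b)/2) + b)` — fixed floor-based centring so odd
and even combinations are deterministic.  The physical depth of the
reconstructed slice is the plain product `b · pixel_size` (reported to two
significant figures): 12 px at 115 nm pixels → 1.4 µm.  No sheet-angle
projection factor is applied to this number; the depth is measured along
the sheet plane, which is the axis the band selects.

## Sub-pixel offsets

The per-slice offset *k·l* is rarely integral.  Two placement policies are
exposed:

* `nearest` (default) — round to the nearest canvas row, ties toward +∞.
  Integer placement makes the streaming path bit-exact against the
  full-volume oracle and costs no interpolation, which is what a live view
  wants.
* `linear` — resample the slice at its fractional offset: each canvas row
  receives the linear blend of the two straddling slice rows, so the block
  spans one extra row and its edge rows taper against the implicit zeros
  outside the slice.  Used where geometric accuracy matters more than
  exactness (e.g. the rotation-fidelity comparison).  An earlier design
  that placed two weighted copies and folded both through `max` was
  rejected: taking the max of complementary-weighted copies attenuates
  peaks by up to ½ rather than interpolating.

Max-folding happens in the raw integer dtype in `nearest` mode (exact);
`linear` mode accumulates in float64.  Only the final warp interpolates,
and integer canvases are rounded half-up back to their dtype.

## Streaming architecture

The live system runs acquisition, processing and display concurrently,
joined by bounded FIFO queues; as long as the consumer keeps pace, queue
depth — and hence RAM — stays O(1) for arbitrarily long sessions.  The
package reproduces this as a deterministic discrete-event simulation: a
`SimulatedCamera` replays a phantom stack on a simulated clock, and
`run_pipeline` models enqueue/dequeue times analytically for a single
producer and consumer.  A frame arriving at a full queue records a
backpressure event and stalls acquisition until a slot frees; frames are
never dropped, and delivery is exactly-once and in-order under every
timing.  What is preserved is the concurrency *contract*, not the
mechanism — the emitted projections are bit-identical to a serial
`submit_frame` loop, which the tests assert.  A real camera adapter can
replace the simulator by implementing the three-tuple `FrameSource`
iterator; scan-position control is hardware-side and is represented only
implicitly by the stack index.

## Synthetic phantoms

Scenes are defined analytically (cylinder with axis along the lateral
axis; spherical beads) in sample coordinates (s = scan axis, v = vertical,
x = lateral), rasterised onto an isotropic voxel grid, and forward-sampled
by trilinear interpolation on the tilted sheet plane of each frame:

    s = k·z + j·p·cos(α),   v = j·p·sin(α),   x = i·p

for frame k, row j, column i, pixel size p.  Planes leaving the volume
sample as zero.  The optional camera model is Poisson shot noise on the
signal plus Gaussian read noise, both driven by the scene seed (identical
seed ⇒ bit-identical stack).  Deliberately not modelled: sheet thickness
(the deskew math assumes planar sections), PSF blur, scattering and
bleaching.  Passing the phantom tests therefore demonstrates geometric
correctness of the reconstruction, not robustness to real-microscope
optics.

Default study conditions for the cylinder-recovery check: 0.5 µm pixels,
0.5 µm scan step, 64 slices, 80×48 px ROI, cylinder radius 5 µm with
length equal to its diameter (so the deskewed projection of the recovered
cross-section is isotropic), rasterised at 0.25 µm voxels, noiseless.  The
scene builder places the cylinder so every point of its cross-section is
intersected by at least one sheet plane; with these sizes the recovered
aspect ratio is within ±0.1 of 1 for α ∈ {30°, 45°, 60°} while the naive
raw-stack MIP shows the predicted 1/sin(α) stretch (within ~10 %, limited
by 0.5-threshold discretisation of ~20 px extents).

## Numerical choices and degenerate inputs

* α = 90° pins the shear to exactly 0 (float cos(π/2) is ~6e-17), so the
  perpendicular-sheet limit reduces bit-exactly to a plain stack MIP.
* Canvas height uses `ceil((n−1)·l)` so fractional shears never clip a
  slice; width equals the raw width.
* The warp resamples with endpoints aligned (`linspace(0, Y−1, round(Y·cosθ))`),
  so a constant canvas stays constant and θ = 0 is the identity.
* Projection comparisons (`projection_nrmse`) align by an exhaustive
  integer shift search plus coordinate-descent subpixel refinement rather
  than phase correlation, which is unreliable on ~20 px test images; the
  two renderings differ by a pure translation by construction, so
  shift-only alignment is exact up to interpolation.
* Device-memory accounting is exact integer arithmetic:
  `3·raw + 1·projection` arrays times bytes per pixel.

## Problem sizes

Tests and the acceptance checks run on deliberately small inputs — stacks
of ≤ 64 slices at ≤ 80×48 px, volumes of 8×16×16 — chosen so the whole
suite completes in seconds while still exercising every code path
(fractional shears, buffer wrap, backpressure, both offset modes).  The
algorithms are O(canvas area) per frame and scale to camera-sized ROIs
unchanged.

## Known limitations

* The GPU path of the original live tool is out of scope here; the
  reference implementation is NumPy and the memory estimate documents what
  a device-resident implementation would hold.
* Rolling mode recomputes affected rows on every frame; at very large
  shears (affected region ≈ whole canvas) this degenerates to a full
  recompute.
* Bidirectional (sawtooth vs triangle) scanning is not modelled; positions
  cycle modulo the stack length.
* The shear-warp rotation is the cos(α+θ) composition described above, not
  the exact tan-shear factorisation; for |θ| beyond ~30° the approximation
  error becomes visible.
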