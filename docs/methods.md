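# Methods

This note records the model behind `dendrotrace`, the parameters that
matter, what the synthetic renderer does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Image model and assumptions

The pipeline assumes transmitted-light (bright-field) stacks of a
dark-stained neuron: background near 1.0 after unit-max normalization,
neurites darker than background at every depth, and a point-spread
function elongated in z so that structures cast shadows above and
below their true plane. Dark-field input is handled by inversion on
load. All geometry is in micrometres; voxel index (z, y, x) maps to
physical position by multiplication with the spacing (dx, dy, dz).
The stack is assumed already assembled (pages in z order); tile
positions come from a layout file, not from microscope metadata.

Two structural assumptions shape the algorithm. First, a 2D
minimum-intensity projection preserves every neurite (true when no
structure is hidden *exactly* behind another at all depths; z-slab
subdivision mitigates the exceptions). Second, a neurite cross-section
is an isolated inverse peak in an intensity profile — the basis of the
validity test that arbitrates everything the earlier stages propose.

## Stage-by-stage parameters

Defaults live in `PipelineConfig` (flat `section.key` YAML; unknown
keys are rejected).

**Background removal** — `background.scale_um = 20`: Gaussian scale of
the illumination estimate, chosen ≫ any dendrite diameter so only the
slowly varying field is removed. After subtraction the image is
re-shifted by the blurred image's mean and clipped to [0, 1], so
absolute thresholds downstream keep their meaning. This re-ranging
rule is a package choice; only the subtraction itself is dictated by
the image model.

**Valley detection** — `valley.scale_um = 0.8` (band width the
detector is tuned to, a thin-dendrite diameter), σ_across = scale/2,
σ_along = 2·scale, `valley.n_orientations = 12`, kernels mean-
subtracted and L2-normalized so responses are comparable across
spacings. The threshold is relative: τ = median + k·MAD of λ₁ with
`valley.tau_k = 6`, because the response noise floor depends on the
image; the anisotropy gate uses `valley.delta_frac = 0.5`. A darkness
gate additionally requires mask pixels to lie below the median
projection intensity minus σ (= 0.03): the oriented detectors respond
over a neighbourhood, producing halo responses near strong structure,
but a valley-floor pixel must itself be dark. Thick structures are
deliberately *not* the valley detector's job (see recovery below).

**Mask smoothing** — specks under `mask.min_speck_px = 8` pixels are
removed; a closing+opening of radius `mask.closing_radius_px = 1`
rounds the boundary.

**Depth seams** — `seam.max_step = 2` planes per path step: at 0.5 μm
plane spacing a dendrite rarely dives faster than ~1 μm per pixel of
lateral travel. Seam ties break toward smaller z.

**Point placement** — spacing ≈ sum of the two adjacent radii, halved
when |Δr| > `place.rapid_dr_frac = 0.5` × the smaller radius. The
pipeline places points incrementally: the next gap uses the *adjusted*
radius of the last accepted point, and a failed candidate does not
advance the walk — the path is retried pixel by pixel, which is what
lets fully fragmented (beaded) branches be sampled bead by bead.

**Validity** — σ = 0.03 intensity-fluctuation scale; baseline = 80th
percentile of the detrended patch; depth threshold baseline − 2σ
(relaxed: 1σ, used during 3D extension to admit faint branches);
patch side max(4r, 4 μm); profile smoothing Gaussian σ = 2 samples at
one-pixel steps with bilinear interpolation; peak width measured
between the derivative extrema *within* the half-threshold crossing
interval around the minimum, so a second dip further out (another
bead, a neighbouring branch) cannot masquerade as a flank; three
adjustment iterations; rejection if total xy drift exceeds twice the
original radius or the radius leaves [0.2, 10] μm. When the patch
centre is dark but no profile shows two flanks, the structure is wider
than the current radius estimate, and the patch is enlarged (×2, ×4)
before the point is declared invalid — this lets points seeded with a
thin-dendrite radius latch onto thick trunks. The z profile used to
refine depth is smoothed with σ = max(2, r/dz) planes: a thick
structure is dark across many planes, so its profile bottom is flat
and noise-driven unless smoothed at the structure's own scale.

**Linking** — gates `link.max_gap_um = 5`, `link.max_angle_deg = 100`
(sharp turns are biologically rare and flag errors), and
`link.max_dz_um = 5`. The gap gate exists to catch distances created
by point *removal*; since natural spacing is the sum of the two radii,
the effective threshold is max(5 μm, 1.5·(r_a + r_b)), so thick chains
link at their natural spacing.

**Occupancy** — every linked pair stamps a capsule (half-sphere caps,
linearly interpolated radius). Points are never created on occupied
volume (except within their own predecessor's capsule), which prevents
duplicate traces of one branch at the source.

**Thick/soma recovery** — triggered when the robust (1st percentile)
minimum intensity under the traced points' footprints is brighter than
the global 1st percentile by more than `soma.margin = 0.1`: the
darkest structures are then untraced. An Otsu threshold on the
projection outside a `soma.exclusion_um = 2` zone around existing
points builds a recovery mask, traced with soma-scale radii allowed.
Recovery runs *before* 3D extension so recovered seeds can grow.
Afterwards, points whose centre lies inside a soma-scale (≥2 μm)
point's ball are absorbed into it — the valley mask tends to leave a
ring of spurious small points around a soma, and a thick structure can
be detected more than once.

**3D extension** — arc radius max(`extend.arc_floor_um = 3`, 2r), span
±60°, 1° sampling, distance-profile smoothing σ = 3 samples. The
candidate march starts just outside the end point's own capsule.
Hitting foreign occupied volume stops extension and connects the end
to the occupying structure when within reach — this is what rejoins a
side branch to its trunk at a junction the mask got wrong.

**Connection** — candidate end pairs from different components within
max(`connect.max_gap_um = 5`, 1.5·(r_a+r_b)), passing the angle and
depth gates (soma-scale ends are exempt from the angle gate: branches
leave a soma at any angle); greedy ascending-gap order, mutual-nearest
pairs first, union-find guard against cycles; evenly spaced points are
interpolated across gaps wider than the sum of the end radii.
Connection is attempted once before the isolated-point noise filter
(so genuinely fragmented structure is not thrown away) and again after
extension.

**Pruning** — components with cable < 20 μm and tip-terminated twigs
of < 5 points attached at a branch point are removed, iterated to a
fixed point (hence idempotent). Anything containing a soma-scale point
is exempt: noise is thin. The largest-radius point becomes the root
(type 1) and ids are renumbered from 1.

## The synthetic renderer

The renderer is a geometric absorption model, not physical optics:
tubes darken voxels inside swept capsules (antialiased over one
pixel), intensity = background − contrast, a z-elongated Gaussian PSF
(σ_z = 4 σ_xy by default) produces the out-of-focus shadows, and
i.i.d. Gaussian sensor noise is added and clipped. It emulates the
artifact taxonomy that matters to the algorithm: blob artifacts (dye
spills, dirt), beading (dark spheres — swellings 1.6× the branch
radius — separated by faint gaps at 8% of the neurite contrast), and
branch proximity. It does **not** emulate diffraction rings, depth-
dependent aberrations, tissue scattering, staining gradients along a
branch, or correlated noise; passing tests therefore demonstrate
algorithmic correctness under the stated image model, not performance
on any particular microscope's data. Rendering is bit-exact
reproducible under a fixed seed.

Canonical benchmark scenes (`dendrotrace.scenarios`) use 0.2 μm pixels
and 0.5 μm planes. Tubes run 22.5 μm in a 128² px field; the branched
scene holds a 3 μm soma and a three-bifurcation tree with 12 μm
segments in a 192×160 px field; the beaded scene is a 26 μm, 0.4 μm-
radius branch fully fragmented with 2 μm gaps; the tiled scene is a
one-bifurcation neuron over two tiles with 20% overlap and ±5 px
jitter. Segment lengths are chosen so that genuine branches carry at
least five points and components comfortably exceed the 20 μm noise
floor, as real dendrites do; stack sizes keep a full test run in tens
of seconds on one CPU.

## Known limitations

* Depth inside thick structures is genuinely ambiguous in transmitted
  light; traced z can wander within the structure. The evaluation
  metric accordingly counts cable as recovered when the trace passes
  within max(1 μm, local radius) of the true axis.
* The 1.5–2.5 μm radius range under noise is the hardest regime: the
  valley detector sees mostly edges while the thick-recovery route
  only triggers once coverage fails, and recall can dip below 90% for
  unlucky noise draws.
* On some renderer seeds a short spurious branch near a junction
  survives pruning (five points rather than four tips); crossing
  resolution beyond the angle/depth gates is out of scope.
* Tile offsets are refined in 2D on projections with the z offset kept
  nominal; single-session lateral mosaics are assumed.
* The connection heuristics are a declared greedy distance-gated rule
  set; they are the spirit, not a transcription, of any particular
  richer rule set.
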