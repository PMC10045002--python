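# Methods

## Model and procedure

`sympose` registers two binary voxel models of the same bone (pre- and
post-operative, or plan and outcome) under a rigid transform, using the
bone's bilateral symmetry rather than raw point proximity as the anchor. The
pipeline is: symmetry-plane detection on each volume → marching-cubes surface
→ planar silhouette contour on the symmetry plane → anchor-based initial
superposition → iterative 2D contour registration → 3D lift → deviation
metrics. A classic point-to-point 3D ICP is included as the comparison
baseline, not as part of the method.

The central assumption is that the object is *nearly* bilaterally symmetric
and stays so through the intervention: deformations and artifacts may change
the 3D shape substantially as long as the mid-sagittal silhouette and the
symmetry plane survive. A second, weaker assumption is gantry-aligned
acquisition: volumes arrive roughly axis-aligned, as clinical CT of the spine
does, which the initial search plane and one axis-sign convention rely on. Objects posed more than ~30° away from axis alignment are out of scope.

## Symmetry plane

The score of a plane is the fraction of occupied voxels whose mirrored center,
rounded to the nearest voxel (half-grid ties toward the negative index), is
not an occupied in-grid voxel. The denominator is the occupied-voxel count,
not the domain volume: with the latter the score could never reach zero and
its stated [0, 1] bounds would fail. Pairing is one-directional by design; a
voxel can be paired while its partner is not.

The objective is piecewise constant (integer counts), so the search is
derivative-free throughout:

1. a coarse scan, ±15° in 5° steps in both plane angles and ±3 voxels of
   offset. Offsets are centered per candidate normal on the *foreground
   centroid* projection, which makes the scan invariant to how the voxel grid
   happens to be laid out around the object;
2. Nelder–Mead from the scan optimum plus four ±5° restarts (simplex spread
   tolerance 1e-5, ≤400 evaluations per run);
3. plateau centering: along each parameter in turn, the contiguous run of
   equal-score planes through the optimum is measured (0.1° / one-sixteenth
   voxel steps) and the midpoint taken. Because the objective is a ratio of
   integers, exact score equality is meaningful; the midpoint is an unbiased
   sub-voxel estimate of the symmetric plateau's center and is what makes the
   final lateral alignment sub-voxel accurate.

The mid-grid sagittal plane is always evaluated first, so the returned score
is never worse than the initial guess. An optional coarse-to-fine mode
(×4 → ×2 → ×1 downsampling) bounds runtime on large volumes; it is off by
default at the phantom sizes used here.

## Contouring

Mesh vertices projected onto the symmetry plane form a dense but gappy 2D
cloud. It is rasterized at a configurable pitch (default: the smallest voxel
spacing), closed with one 3×3 binary closing, reduced to its largest
8-connected component, and traced with Moore neighbor tracing (clockwise wall
following from the top-left-most filled cell, Jacob's stopping criterion).
Inner holes are discarded and the boundary is normalized counter-clockwise.
Degenerate ribbons (1-cell-wide rasters) trace correctly but revisit cells;
blobs with interior yield simple closed boundaries. Overlap areas are
computed by polygon rasterization at half the contour pitch; plain polygon
areas use the shoelace formula.

## Initial superposition

The local frame takes x from the plane normal (canonical sign: the
largest-magnitude component positive) and z from the third principal axis of
the vertex cloud projected into the plane. The z *sign* is set by a
`superior_hint` direction, world +z by default — the scanner's
superior axis under gantry alignment. A data-driven sign rule
(centroid-to-extreme extent along the axis) was evaluated and kept only as
the fallback for a hint orthogonal to the axis: on realistic near-symmetric
shapes the two extents differ by under 15%, so that rule flips
unpredictably between a pre/post pair and can produce a 180°-off initial
superposition, while the hint is unambiguous whenever the acquisition
assumption above holds.

Turning points are thresholded strict local maxima of the normalized bending
value over a ±k cyclic window, restricted to the posterior band (γ = 0.4 of
the contour's y-extent from the y_min end), with one detection kept per 2k
window. Numerical details: the chord ratio is maximized over half-widths
1..k; a vanishing denominator (a perfect fold) scores +inf; Bv ≥ 1 always,
with equality exactly on collinear triples.

Parameter defaults, with units and reasons:

* **γ = 0.4** (dimensionless): posterior band fraction; covers the spinous
  region of a vertebral silhouette without reaching the body corners.
* **bending threshold = 1.8** (dimensionless): a 90° corner scores √2 ≈ 1.41
  and a pointed (~35°) process scores ≳ 2.2, so 1.8 separates true spinous
  tips from rectangular silhouette corners. An alternative k-scaled form of
  the criterion (threshold × k) is available via
  `threshold_mode="scaled_by_k"` for compatibility with formulations built on
  an unnormalized bending value; it is dimensionally inconsistent with the
  normalized ratio (the product exceeds its attainable range for k ≥ 2) and
  is not the default.
* **k = max(3, round(0.05·m))** for an m-point contour: the ±k window must
  reach past the raster's corner-blunting zone (about three cells at any
  pitch); 1% of a raster contour (~100–250 points) does not, and a window
  that small never sees a turning point.
* **contour pitch = min(voxel spacing)** (mm): no finer information exists in
  the segmentation.

P1 is the *arithmetic* centroid of the turning points (coordinates can be
negative, so a literal geometric mean is undefined); P2 the projected vertex
centroid; P3 the maximum-z projected vertex (ties to the lowest index — P3
only disambiguates the frame's w sign, so its exact choice on a flat superior
rim is immaterial). Anchor frames use u ∥ P1P2, w ∥ P1P2 × P1P3, v = w × u;
the initial superposition is X_init = T_A⁻¹ ∘ T_B in the column-vector
convention used everywhere (a row-vector formulation of the same frame
transform transposes into this on construction).

## Contour registration

Fixed contour A, moving contour B, no outlier rejection: each a_i takes its
nearest b_j (K-D tree; exact distance ties to the smallest index). The rigid
update is the closed-form least-squares fit: H = Σ b̄ᵢ āᵢᵀ (this index order
makes R map B onto A, consistent with the residual E = Σ|R·bⱼ + t − aᵢ|),
H = UΛVᵀ, R = VUᵀ, with the smaller singular direction flipped when
det(R) = −1 so the result is always a proper rotation; t = ā − R·b̄. The
reported E is the sum of distances while the SVD minimizes the sum of
squares — the two disagree on which rotation is optimal for arbitrary point
sets, and the least-squares solution is the one implemented and tested.

Convergence follows the overlap-area criterion: stop when the rasterized
intersection area of the two contours changes by < 0.001 mm² between
iterations (area evaluated at half the contour pitch), with a guard on a
vanishing residual change to catch raster plateaus, and a hard cap of 200
iterations (non-convergence is reported, not raised).

Pure cell-vertex matching on uniformly spaced closed curves has stable fixed
points at half-pitch tangential offsets: matches on runs parallel to the
offset push forward by (pitch − δ) while perpendicular runs pull back by δ,
balancing at δ ≈ pitch/2 (measured: about two thirds of random in-plane
perturbations lock at RMS ≈ 0.25 mm at 0.5 mm pitch). After the area
criterion fires, a *polish* phase therefore re-matches each A point against
B's continuous polyline (point-to-segment) and repeats the same fit until the
residual stalls. With polish, identical shapes under any tested perturbation
(|θ| ≤ 20°, ‖t‖ ≤ 10 mm) re-align to numerical exactness. Polish is a
default-on flag (`polish=False` restores the raw vertex iteration).

The cumulative 2D motion is lifted to 3D as the rigid map fixing the plane
normal, expressed in A's frame and composed after X_init.

The ICP baseline is the textbook point-to-point form: nearest neighbors into
the target cloud, 3D Kabsch/SVD update with determinant correction, stop when
the mean residual changes by < 1e-6 mm; sources above `max_points` are
subsampled by uniform stride.

## Synthetic phantom

The generator emulates what the method needs from a vertebra and no more:
bilateral topology with distinguishable body/posterior regions. The solid is
an elliptic-cylinder body (default 16 × 12 mm axes, 10 mm tall — shorter than
it is wide, so the third principal axis is unambiguous) with a domed superior
endplate (adds superior extent without moving the centroid much, so
superior-inferior conventions resolve deterministically), two pedicle
cylinders, a lamina bar, and a spinous process that tapers to a point over
its length (its silhouette tip, ~35°, is the dominant turning-point feature,
as on a real spinous process). Everything is built as a function of |x − cx|
on the voxel lattice, so the emitted volume is *exactly* mirror-symmetric
about the grid-aligned plane x = cx when no degradations are requested. The
body is shifted 1 mm superior and the posterior elements 1 mm inferior,
breaking the (non-anatomical) superior-inferior mirror symmetry.

Degradations, all driven by one seed:

* **Asymmetry** — a Gaussian-filtered random field (σ = 3 cells), scaled to a
  maximum |displacement| in mm, inflates/erodes the signed-distance surface
  on one lateral half only. Default in study pairs: 0.5 mm, a mild natural
  asymmetry.
* **Lamina removal** — the stated fraction of posterior-element voxels is
  deleted in descending |x − cx| order (most lateral first). This emulates
  laminoplasty/laminectomy: the lateral arch is carved while the midline
  sagittal silhouette and the spinous tip largely survive. (Amputating the
  posterior tip instead destroys the very symmetric feature the method
  anchors on — a deformation regime the method explicitly does not claim.)
* **Artifacts** — spheres unioned into the foreground near the pedicles,
  alternating sides (implants are bilateral). Study pairs default to 8 blobs
  of 2.5 mm radius, ≈10% of the foreground — the "appreciable volume ratio"
  regime in which metal artifacts are known to derail closest-point
  registration. Artifact voxels are tracked separately from the anatomy.

What the phantom does **not** model: real CT intensities, partial-volume
effects, beam-hardening streak geometry (artifacts are blobs, not streaks),
cortical/trabecular structure, or inter-subject shape variation. Passing
tests on phantoms therefore demonstrate the geometric correctness and the
claimed robustness *mechanism* (2D silhouette stability under 3D posterior
change), not clinical-grade accuracy figures.

Study-pair conditions (fixed): 48³ voxels at 0.7 mm, asymmetry 0.5 mm, lamina
removal 0.25, 8 × 2.5 mm artifact blobs, random rigid motion up to 8° / 4 mm.
Single-phantom analyses use 64³ at 0.5 mm. These sizes keep a full pair
registration around two seconds while staying within the clinical range of
voxel resolutions.

## Degenerate inputs and tie-breaks

Empty volumes, empty meshes, all-degenerate STL facets, contours shorter than
2k+1, rasters under 3 cells, coincident correspondence sets, collinear or
coincident anchors, and a third principal axis within 1° of the plane normal
all raise typed errors rather than returning garbage. Nearest-neighbor ties
go to the smallest index; half-grid rounding ties go toward the negative
index; the plane's canonical sign makes the largest-magnitude normal
component positive (ties to the first axis).

## Known limitations

* The OSP offset (and hence lateral alignment) is accurate to a fraction of a
  voxel only via plateau centering; heavily asymmetric objects have no
  well-defined plateau and inherit the raw optimizer resolution.
* Out-of-plane pose error is bounded by the symmetry-plane accuracy of the
  *worse* of the two volumes; nothing downstream can correct it.
* The no-rejection A→B correspondence rule means large missing features in
  the moving contour (a fully amputated process) bias the fit by ~1 mm; the
  method targets deformations that preserve the silhouette.
* Frames and band selection assume gantry-aligned poses; beyond ~30° the
  initial search plane and the superior hint both become unreliable.
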