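# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. Units are mm, mm⁻¹ and W throughout.

## Photon-packet transport

The simulator solves the steady-state radiative transfer problem by weighted
Monte Carlo. A packet is born uniformly inside the source shape (bounding-box
rejection sampling; a candidate outside the shape is redrawn, and 10⁶
consecutive rejections raise a degenerate-source error) with an isotropic
direction `φ = 2πξ`, `cos θ = 2ξ − 1`. The source is purely emissive: it has
no optical properties, and transport starts in whatever tissue region
contains the birth point.

Stepping uses the dimensionless-path formulation: a packet carries
`τ = −ln ξ` and advances `s = τ/μt` in the current region. If a boundary
interrupts the step, the consumed part is subtracted from `τ` and the
remainder is rescaled by the far side's `μt` after the boundary event. This
carried-residual convention is unbiased in layered media; resampling the
path at each boundary would bias thin, high-contrast inclusions.
Absorption and scattering happen only at the end of a *completed* free
path: the packet deposits `ΔW = W μa/μt` into the voxel at the interaction
site, then scatters.

Scattering uses the Henyey–Greenstein inverse CDF for `g ≠ 0` and
`cos θ = 2ξ − 1` for `g = 0`. The direction update rotates the deflection
out of the local frame whose z-axis is the old direction; when
`|dz| > 1 − 10⁻⁶` a degenerate-frame formula avoids catastrophic
cancellation, and the result is renormalized every event (unit norm
preserved to 10⁻⁹ over millions of events).

Boundary events draw once against the unpolarized Fresnel average

    R = ½ [ sin²(θi−θt)/sin²(θi+θt) + tan²(θi−θt)/tan²(θi+θt) ]

and either reflect (`d ← d − 2(d·N)N`, stay) or transmit (Snell-refracted
direction, region becomes the far side). Conventions:

- `θi = 0` is a removable 0/0; the analytic limit `((ni−nt)/(ni+nt))²` is
  substituted below `sin θi < 10⁻⁹`.
- Total internal reflection (`ni sin θi / nt ≥ 1`) gives `R = 1`. When
  `ni ≤ nt` there is no critical angle (`θc = π/2`) and Fresnel applies at
  all incidence angles. A literal reading of the tabulated branch
  conditions would totally reflect every packet entering a denser medium,
  which is unphysical; this implementation takes the physical branch.
- Escaping packets add their residual weight to the transmission record at
  the exit point (position, power, and triangle index for mesh surfaces).

Russian roulette triggers when `W` falls below `10⁻⁴ ×` the initial packet
power (threshold configurable; only the survival factor m = 10 is
canonical): survive with probability `1/m` at weight `mW`, else die. The
expectation is exactly preserved, so launched = absorbed + transmitted
holds in expectation; at 10⁵ packets the realized imbalance is ~10⁻⁶ %
because roulette rarely fires in the reference phantoms. A per-packet event
cap (default 10⁶) guards against pathological geometry; capped weight is
reported as `lost_w` in the run summary, never silently dropped.

## Geometry and the clipping semantics

A scene is a containment tree rooted at one outermost region. Analytic
shapes are first-class and exact; triangle meshes are validated closed
(watertight, consistently outward-oriented; zero-area faces dropped with a
warning). Ray queries intersect *all* region surfaces and take the nearest
crossing; region membership is then re-resolved at the nudged far-side
point. Membership itself is clipped: a point belongs to a region only if
the region's shape *and every ancestor shape* contain it, and among
candidates the deepest wins, ties to the later-listed region.

For properly nested scenes this is equivalent to the textbook
current-region/children search. Its purpose is the heterogeneous reference
phantom, whose printed region table is *not* strictly nested (two
inclusions extend past the root caps, and three sibling pairs overlap).
Under clipping semantics the phantom is still well-defined: regions are
truncated by the root surface and overlaps resolve deterministically.
Strict validation (sampled containment/overlap test, 2000 points per
region pair) remains the default for user scenes; the heterogeneous
fixture opts out with a warning.

Epsilons: ray-parameter and barycentric tolerance 10⁻¹²; after every
boundary event the position is nudged 10⁻⁷ mm along the new direction to
avoid re-intersection. Points within ~10⁻⁹ mm of a surface may resolve to
either side; the transport loop never depends on the boundary case.
How a packet landing exactly on a shared edge of two tissues should behave
is genuinely undefined in the underlying model; the nudge is this package's
choice.

## Random streams

All randomness comes from Philox4x32-10 counter-based streams. Worker `i`
of a run with master seed `s` uses key `(s mod 2³², (s >> 32) XOR
(i·0x9E3779B9 mod 2³²))`; the multiplier is odd, so distinct workers give
distinct keys and therefore disjoint keyed sequences for any draw count —
the substream contract (reproducible, non-overlapping, no communication)
without jump-ahead bookkeeping. Doubles take 53 bits from each 128-bit
block, so `ξ ∈ [0,1)` with `P(ξ=0) = 2⁻⁵³`; exact zeros are redrawn
wherever `ln ξ` is taken. Workers execute sequentially over private
tallies that the host sums, so `(seed, workers)` fixes the output bitwise
regardless of scheduling.

## Tallies, rasterization, comparison

The absorption grid covers the root bounding box at a configurable pitch
(default 0.5 mm). Escape records are kept per packet and binned on demand;
for a cylinder root the side surface unwraps to rows = z, columns = arc
length (φ = 0 at +x, counterclockwise from +z), pixel value = power/area.
Raster dimensions truncate (`int(extent/pixel)`): the reference 0.06 mm
pixel on the 15 × 30 mm cylinder gives the canonical 500 × 1570 map; a
pixel that misses the extents by more than half a pixel warns. End caps are
excluded from the unwrap and their power is available separately
(`cap_power`) so conservation closes: map·area + caps + absorbed + lost =
launched.

NRMSE is the plain `sqrt(mean((d1−d2)²))` of two equal-length vectors —
an L2 distance scaled by `1/√N`, hence symmetric with the triangle
inequality. Published comparisons of "normalized" maps never state the
normalization; this package normalizes each dataset by its own maximum
(the figures are labeled normalized flux density), with sum-normalization
available as an option.

## Free-space model

SIMPLE mode is the exact radiosity transfer between a Lambertian surface
element and a pixel (midpoint rule at pixel centers; subdivision is a
convergence-check option). Visibility is by cosine sign, with
`cos θs = 0` (the limb) counting invisible — a zero-radiance direction
contributes nothing anyway. LENS mode adds the thin-lens factor: each
element is weighted by a visibility test toward the lens center (cosine
sign plus a self-occlusion ray against the scene surface) and the
denominator becomes `|rd − r − (t·u₂·cosθ/f)·s|²` with `t = v/u` the
magnification, `θ` the line-of-sight/axis angle and `u₂` the element's
axial distance to the lens plane. The printed source of this term is
ambiguous (the `u₂`/`u²` exponent and the cos θ placement are lost in the
published form); this reading is dimensionally consistent and is the only
one of the candidates that converges to SIMPLE × t² as `f → ∞` at fixed
magnification, which the suite checks coarsely. LENS-mode magnitudes
should be treated as qualitative; aperture blur and aberrations beyond
this single term are out of scope by design.

## Reference phantoms and what the tests show

The homogeneous phantom gives only `μa` and `μs′`; transport needs
`(μs, g)`, so the fixture uses g = 0.9 (typical of soft tissue at red
wavelengths) with `μs = μs′/(1−g)`, both configurable. In this diffusive
regime results are g-insensitive by similarity, which the suite checks by
comparing z = 0 profiles at two g values against the reseed noise floor.
The refractive index is unstated; the default is matched (n = 1.0), which
makes energy conservation exact-in-expectation and keeps the property
tests clean, and an n = 1.37 variant exercises the Fresnel/TIR code. The
heterogeneous phantom's published source coordinate lies outside the
phantom; the fixture centers the source in the low-absorption tube region
(the glow-stick-capsule analog), which is the only region that can contain
an emitter of the stated size without further assumptions.

Validation is property-based: energy conservation, the Beer–Lambert shell
law for a pure absorber, exact sampling moments, Fresnel closed forms and
reciprocity, roulette unbiasedness, Lambertian closure, mirror symmetry of
the surface map, and the `1/√N` error scaling (independent-seed profile
NRMSE halves, ±30%, when packets go 2.5·10⁴ → 10⁵). Test problem sizes
(10⁵-packet transport runs, 2 mm raster for noise-limited comparisons,
10⁶-draw moment checks) were chosen so each property's statistical
tolerance is meaningful at suite scale. These tests demonstrate internal
physical consistency of the implementation — they do not by themselves
validate against external measurements, which would require instrument
data (CCD response, lens aperture, calibration) this package does not
model.

## Known limitations

- Steady-state only; no time-resolved or frequency-domain transport, no
  polarization, no fluorescence coupling; one spectral band per run.
- Internal sources only; no external/collimated illumination.
- Analytic shapes are axis-aligned (cylinder axis along z); arbitrary
  orientation requires a mesh.
- Mesh ray queries are a linear scan over triangles — fine for
  fixture-scale meshes (10²–10⁴ triangles), not tuned for organ-atlas
  meshes (10⁵+); an acceleration structure would be the natural extension.
- Worker substreams partition the random sequence; execution itself is
  sequential (the worker count exists for reproducibility semantics, not
  wall-clock speedup).
- LENS mode is one documented interpretation of an ambiguous published
  form; SIMPLE mode is the validated path.
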