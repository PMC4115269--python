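# scosfire

Trainable hierarchical shape detection with COSFIRE filters.

A COSFIRE (Combination Of Shifted FIlter REsponses) filter detects a pattern
by combining the blurred, shifted responses of simpler subunit filters
arranged around its center. This package implements a three-layer hierarchy
inspired by the ventral visual stream:

1. **Gabor energy** (V1 analogue) — an orientation-selective,
   contrast-sign-invariant front end built from quadrature Gabor pairs, with
   optional isotropic surround suppression to favor isolated contours over
   texture.
2. **V-COSFIRE vertex filters** (V4 analogue) — corner detectors built from
   Gabor channels sampled on concentric circles around a prototype vertex. A
   standard bank of 60 filters covers 12 orientations × 5 aperture angles.
3. **S-COSFIRE shape filters** (IT analogue) — shape detectors built from
   vertex filters at polar positions around a point of interest.

Filters are *configured*, not hand-designed: presented with a single
prototype image and a point of interest, the configuration step
automatically selects which subunits respond where, and the resulting tuple
set *(subunit, ρ, φ)* defines the filter. The response combines the
subunit responses by a weighted geometric mean — an AND-type combination
that peaks where all parts are present in the learned arrangement and is
exactly zero when any part is missing. Explicit tuple-set transformations
provide tolerance to rotation, scale, and reflection.

Because the shape layer sees only vertex responses, not contours, an
S-COSFIRE filter configured on an outlined triangle also responds at the
center of a Kanizsa-style illusory triangle whose inducer discs produce the
same corner arrangement with no connecting contours.

## Worked example

Configure a shape filter on an equilateral triangle outline (circumradius
50 px, apex up, centered in a 512×512 canvas) and detect it:

```
$ scosfire fixture triangle --out tri.png
triangle -> tri.png
$ scosfire configure tri.png --center 255.5 255.5 --out tri.json
configured 3 tuples -> tri.json
$ scosfire detect tri.png --filter tri.json --out-csv dets.csv
1 detections -> dets.csv
$ cat dets.csv
rank,x,y,row,col,score,psi,upsilon,reflected
0,256.0,255.0,256.0,256.0,0.8218884627887514,0.0,1.0,False
```

The built-in self test runs the same example through the library API and
prints the configured tuples:

```
$ scosfire selftest
configured tuples: 3
  vertex filter f21: rho=49.5 phi=1.581 rad
  vertex filter f17: rho=49.1 phi=5.760 rad
  vertex filter f13: rho=49.1 phi=3.665 rad
self-match peak at (256, 255)
selftest PASSED
```

Configuration selects exactly the three π/3-aperture corner filters of the
bank (f13, f17, f21), each at ρ ≈ 50 px and φ within a few degrees of the
vertex directions π/2, 7π/6, and 11π/6 — the triangle is represented as
"three 60° corners, 50 px from the center, at 120° spacing". The same
filter applied to a scene containing an outlined triangle and a
Kanizsa-inducer triangle detects both centers, because the corner
arrangement, not the contour, drives the response.

The same pipeline is available from Python:

```python
import scosfire as sc

p = sc.preset("fig4-triangle")
proto = sc.make_triangle(50.0, canvas=(512, 512))
bank = sc.build_vertex_bank(blur=p.blur, response_t1=p.v_t1)
filt = sc.configure_s_cosfire(proto, (255.5, 255.5), bank,
                              t1=p.t1, t2=p.t2, blur=p.blur,
                              t3=p.t3, frontend=p.frontend)
resp = sc.apply_s_cosfire(proto, filt)   # peaks at (256, 255), score 0.82
```

## Reproduction

The two headline quantities are reproduced by:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports `t1` — the tuple weight ω at ρ = ρ_max with the automatic
σ′ (exactly 0.5, the half-response construction) — and `t4` — the ρ of
each tuple configured from the triangle prototype (measured
[49.06, 49.06, 49.50] px against the nominal 50 px vertex distance; the
sub-pixel deficit is corner localization bias of the vertex detectors).

See `docs/methods.md` for the model definition, parameter conventions,
numerical choices, and limitations.
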