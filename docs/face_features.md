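# The canonical 30 facial-geometry features

This table is the package's frozen definition of the facial feature
space (`affectlink.facefeat.FACE_FEATURE_TABLE`).  Downstream loading
analysis depends on a stable feature identity, so the rows, their order
and their formulas are versioned with the code; changing them is a
breaking change.

## Landmark layout (49 points, 0-based)

Pixel coordinates with y increasing downward ("left" = image left).

| indices | region |
|---|---|
| 0-4 | left eyebrow, outer to inner end |
| 5-9 | right eyebrow, inner to outer end |
| 10-13 | nose bridge, top to just above tip |
| 14-18 | nose base, left to right (16 = centre under the tip) |
| 19-24 | left eye: outer corner, 2 top, inner corner, 2 bottom |
| 25-30 | right eye: outer corner, 2 top, inner corner, 2 bottom |
| 31-42 | outer lip: left corner, 5 top (l→r), right corner, 5 bottom (r→l) |
| 43-48 | inner lip: left corner, 2 top, right corner, 2 bottom |

The synthetic template for this layout is
`affectlink.synthdata.face_template`.

## Formula kinds and normalizers

With the detected face box `(x, y, W, H)`, `c(A)` the centroid of the
points in index set A, and shoelace() the unsigned polygon area:

| kind | formula | normalizer |
|---|---|---|
| dx | abs horizontal distance between `c(A)` and `c(B)` | / W |
| dy | abs vertical distance between `c(A)` and `c(B)` | / H |
| dist | Euclidean distance between `c(A)` and `c(B)` | / sqrt(W·H) |
| area | shoelace(A), A an ordered vertex ring | / (W·H) |

All features are therefore dimensionless and exactly invariant to
scaling and translation of the landmarks together with the face box.

## The 30 features

| # | name | kind | A | B |
|---|---|---|---|---|
| 1 | left_eye_height | dy | 20,21 | 23,24 |
| 2 | right_eye_height | dy | 26,27 | 29,30 |
| 3 | left_eye_width | dx | 19 | 22 |
| 4 | right_eye_width | dx | 25 | 28 |
| 5 | left_eye_area | area | 19-24 | — |
| 6 | right_eye_area | area | 25-30 | — |
| 7 | left_brow_eye_dist | dy | 0-4 | 19-24 |
| 8 | right_brow_eye_dist | dy | 5-9 | 25-30 |
| 9 | left_brow_lip_dist | dist | 0-4 | 31-42 |
| 10 | right_brow_lip_dist | dist | 5-9 | 31-42 |
| 11 | brow_separation | dx | 4 | 5 |
| 12 | left_brow_length | dist | 0 | 4 |
| 13 | right_brow_length | dist | 5 | 9 |
| 14 | lip_width | dx | 31 | 37 |
| 15 | lip_height | dy | 34 | 40 |
| 16 | outer_mouth_area | area | 31-42 | — |
| 17 | inner_mouth_area | area | 43-48 | — |
| 18 | nose_width | dx | 14 | 18 |
| 19 | nose_height | dy | 10 | 16 |
| 20 | nose_area | area | 10,14,15,16,17,18 | — |
| 21 | eye_separation_inner | dx | 22 | 28 |
| 22 | eye_separation_outer | dx | 19 | 25 |
| 23 | nose_lip_dist | dy | 16 | 34 |
| 24 | left_eye_lip_dist | dist | 22 | 31 |
| 25 | right_eye_lip_dist | dist | 28 | 37 |
| 26 | lip_corner_tilt | dy | 31 | 37 |
| 27 | brow_nose_dist | dy | 0-9 | 16 |
| 28 | inner_lip_height | dy | 44,45 | 47,48 |
| 29 | eye_mouth_dist | dy | 19-30 | 31-42 |
| 30 | nose_eye_dist | dist | 16 | 22,28 |

Rows 1-4, 7-10, 14-20 cover the distances and areas that affective
facial-expression work conventionally measures (eye opening, eyebrow
positions relative to eyes and lips, mouth extent and areas, nose
geometry); the remaining rows are hand-picked stable geometry chosen to
complete the 30-dimensional space (documented here so their meaning is
never ambiguous in loading plots).
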