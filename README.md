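# femur3d

Automated three-dimensional measurement of canine femoral angles from an
isolated femur surface mesh, for preoperative planning of patellar-luxation
(PL) surgery.

Femoral deformity — varus/valgus, abnormal neck inclination, and excessive
or deficient torsion — is a major driver of patellar luxation in dogs.
Deciding between traditional soft-tissue/trochlear techniques and a
corrective femoral osteotomy hinges on three angles:

* **aLDFA** (anatomical lateral distal femoral angle): the frontal-plane
  angle between the diaphyseal anatomical axis and the distal joint
  orientation line, measured on the lateral-distal side.  Varus raises it,
  valgus lowers it.
* **FNA** (femoral neck angle): the frontal-plane inclination of the
  head–neck axis against the shaft (≈130–140° in normal dogs).
* **FTA** (femoral torsion angle): the signed axial-plane angle between the
  head–neck axis and the transcondylar axis; positive is anteversion.

Manual radiographic measurement of these angles is landmark-dependent and
operator-sensitive, especially with multiplanar deformities.  `femur3d`
instead computes them automatically from a CT-derived STL mesh with exactly
one manual input — a single click anywhere on the femoral head — plus a
left/right side flag:

1. internal mesh shells (endosteal surfaces) are removed automatically;
2. the **anatomical axis** is the total-least-squares line through the
   arc-length centroids of mid-diaphyseal cross-sections (25–75 % of bone
   length, iteratively re-sliced perpendicular to the converging axis);
3. the **femoral head** is a region-grown best-fit sphere from the seed
   click, which keeps head vertices and sheds neck/acetabular ones;
4. the **neck** is isolated by a spherical section concentric with the
   head at 1.25× its radius; its center joined to the head center gives
   the head–neck axis;
5. the **condyles** are two best-fit spheres on the distocaudal articular
   surfaces; their common tangent at the distocaudal points is the distal
   joint orientation line;
6. the three angles are projections in the frame these axes define — so
   the result is independent of how the bone is oriented in space.

The package also ships a parametric **synthetic femur generator** (an
implicit-surface phantom with analytically known ground-truth angles) used
to validate the pipeline by parameter recovery, a **surgical planner**
implementing the published decision bands (90° < aLDFA < 102°;
18° ≤ FTA ≤ 35°), and a typed model of the associated 41-dog / 47-limb
clinical **cohort tables** with honest recounting of every descriptive
statistic.

## Worked example

Generate a deformed right femur — varus (aLDFA 104°) with low torsion
(FTA 12°), the classic medial-patellar-luxation deformity pattern — then
measure and plan:

```sh
$ femur3d synth --aldfa 104 --fna 135 --fta 12 --seed 1 --out f.stl
{
  "angles": {"aLDFA": 104.0, "FNA": 135.0, "FTA": 12.0},
  "seed_point": [-24.474, 5.202, 184.474],
  "stl": "f.stl",
  "truth": "f.truth.json"
}

$ femur3d measure f.stl --seed -24.474 5.202 184.474 --side R --out report.json
$ python -c "import json; d=json.load(open('report.json')); \
             print(d['aLDFA'], d['FNA'], d['FTA'])"
104.0 134.97 12.18
```

The measured triple (104.0°, 134.97°, 12.18°) recovers the constructed
deformity to within 0.2°.  The planner flags both components:

```sh
$ femur3d plan report.json
[ { "label": "report.json", "aLDFA": 104.0, "FNA": 134.97, "FTA": 12.18,
    "DFO": true, "FDO": true, "traditional_only": false,
    "frontal_correction": 8.0, "torsional_correction": -14.32, ... } ]
1 of 1 limbs flagged for corrective osteotomy
```

i.e. a distal femoral osteotomy (aLDFA above the 102° bound, 8° frontal
correction toward the 96° target) combined with a detorsional osteotomy
(FTA below the 18° bound).  Cohort summaries come from
`femur3d cohort [--recount-outcomes]`.

## Scope

CT acquisition and segmentation are upstream of this package (input is an
isolated femur STL, millimetre units by contract).  Tibial measurements,
mechanical-axis angles, implant selection and cutting-guide design are out
of scope.  See `docs/methods.md` for the model, parameter defaults,
numerical choices and known limitations.
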