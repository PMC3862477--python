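# stiflemech

Joint alignment and femorotibial contact mechanics for the *ex vivo* canine
Pond–Nuki model — the classic experimental osteoarthritis preparation in
which the cranial cruciate ligament (CCL) of a stifle (canine knee) is
transected.

The package is written for biomechanics researchers who test cadaver limbs
in a materials testing machine while recording two kinds of raw data:

* **digitized 3-D points** — three nylon-screw markers per bone captured in
  a CT/bone frame and again in the lab frame under each loading condition,
  plus anatomical landmarks (condyle centers/edges, femoral head center,
  distal tibia center, CCL origin and insertion) identified on bone models;
* **thin-film pressure maps** — per-compartment sensel grids (30.9 mm ×
  12.0 mm sensing areas, 0.01 MPa sensitivity, 30 MPa range) placed beneath
  the menisci, with the cranial and caudal tibial-condyle margins digitized
  on the map.

From these it reconstructs, for each specimen and condition:

* the six-component femorotibial pose in the **Grood–Suntay joint
  coordinate system** — flexion/extension reported as the included joint
  angle (180° = bones collinear), varus/valgus (+ = varus) and
  internal/external tibial rotation (+ = external) about body-fixed axes in
  that order, plus the three translations of the CCL origin→insertion
  vector resolved in the tibial anatomic frame (+ = cranial, medial,
  distracted);
* the **contact metrics**: contact area (in-contact sensels × sensel area),
  peak and mean contact pressure over the contact area, the peak-pressure
  location as a fraction of tibial-condyle length from the caudal margin,
  and the contact force in the cranial/central/caudal thirds of the condyle
  (pressure × sensel area sums, MPa·mm² = N);
* the **paired statistics**: intact vs. CCL-deficient paired t-tests per
  metric at each flexion angle (~135° stance-phase and ~90° high-flexion)
  and a blocked linear model of the regional forces with per-region status
  contrasts, all at α = 0.01.

Because no public dataset of this kind exists, a first-class
**synthetic-specimen generator** inverts the entire pipeline: it draws
ground-truth poses and contact patches from configurable per-condition
distributions (the defaults encode the measured condition summaries of the
modelled experiment, n = 8 limbs), renders lab-frame marker triads with
0.23 mm digitizer noise and sensel grids with controllable patch location,
area and peak, and the analysis recovers the ground truth — exactly at zero
noise.

## Worked example

Simulate a cohort and run the full study from the shell:

```sh
stiflemech simulate --seed 17 --n 8 --out demo/inputs
printf 'input_dir: demo/inputs\noutput_dir: demo/results\n' > demo/study.yaml
stiflemech study --config demo/study.yaml
# analyzed 8 specimens; 13 significant scalar contrasts at alpha=0.01
```

`demo/results/` then holds per-specimen intermediates
(`per_condition.csv`, `regional.csv`), the three summary tables, the test
results and a QC report. For this seed, the medial-compartment row of
`table1.csv` reads

| metric | 135° intact | 135° transected | p < 0.01 @135° | p < 0.01 @90° |
|---|---|---|---|---|
| contact area (mm²) | 174.3 ± 11.7 | 72.6 ± 8.9 | yes | no |
| peak location (% of condyle) | 55 | 15 | yes | no |

and `table3.csv` shows the cranial tibial translation rising from 10.1 mm
(intact) to 23.5 mm after transection at the stance-phase angle — the
hallmark of CCL loss: the tibia subluxates cranially, the femoral condyles
slide caudally down the sloped plateau, and the contact patch shifts
caudally, shrinks and sharpens, while the flexed 90° configuration shows no
significant change.

The same analyses are available in Python:

```python
import stiflemech as sm
from stiflemech.io import cohort_to_records

cohort = sm.make_cohort(n=8, seed=17)
report = sm.analyze_records(cohort_to_records(cohort))
print(report.table1)        # contact metrics, mean±sd + significance flags
print(report.qc)            # 50:50±10% medial:lateral seating checks, etc.
```

Logged warnings during a run are QC, not errors: sensels in contact outside
the digitized condyle margins are clamped into the terminal regions (so no
force is lost), and intact stance specimens whose medial:lateral force
split leaves 0.5 ± 0.1 are flagged.

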