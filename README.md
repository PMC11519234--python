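# frthresh

Exercise-threshold detection for incremental cycling tests (CPET).

During a graded exercise test, two physiological breakpoints separate the
moderate, heavy and severe intensity domains. The reference way to locate
them is the **V-slope** procedure on gas-exchange data: the second
gas-exchange threshold (GET2, respiratory-compensation point) is the
breakpoint of V̇_E vs V̇co₂, and the first (GET1, classic anaerobic
threshold) the breakpoint of V̇co₂ vs V̇o₂. Gas exchange requires a
metabolic cart; **respiratory frequency (f_R)** does not — it can be
measured with a chest strap in the field. `frthresh` implements an
objective detector of two respiratory-frequency thresholds (fRT1, fRT2)
from the f_R-vs-HR relation, alongside the V-slope reference method and
the agreement statistics needed to compare the two on a cohort.

## Methods in brief

**Respiratory-frequency thresholds.** For stage *i* with respiratory
frequency f_Ri, let m_{i−1} and s_{i−1} be the mean and sample SD of f_R
over all previous stages. The first stage with

    f_Ri − m_{i−1} > 2·s_{i−1}   and   PO_i > 60 W

is the provisional first threshold; the first later stage triggering again
is the provisional second. Three OLS lines of f_R on HR are then fitted —
RL1 (start → provisional 1), RL2 (provisional 1 → provisional 2), RL3
(provisional 2 → last stage), boundary stages shared — and the final
thresholds are the RL1×RL2 and RL2×RL3 intersections, mapped to V̇o₂ and
power output through the V̇o₂-vs-HR and V̇o₂-vs-PO regressions when gas
data exist.

**V-slope.** Every admissible split of the (filtered) points into a lower
and upper least-squares limb is scored by the ratio of the perpendicular
distance from the limb intersection to the single all-points line, over
the single line's residual mean square; the maximising split wins. GET2 is
accepted only for a slope increase > 15% (of the lower slope), GET1 only
for an absolute slope increase > 0.1; otherwise the threshold is
*undetermined*.

**Agreement statistics.** Bland–Altman bias ± 1.96·SD limits of agreement,
Pearson r with magnitude classes (0.1/0.3/0.5/0.7/0.9), regression SEE
with precision classes (<2/<5/<10/<15/<20/≥20 % of the mean), Hedges' g
with the small-sample correction (classes 0.2/0.6/1.2/2.0), paired t.

## Worked example

The package bundles a fully worked 14-stage test (0–260 W, +20 W/min):

```python
from frthresh import detect_frt
from frthresh.datasets import example_participant

res = detect_frt(example_participant())
print(res.frt1)
print(res.frt2)
```

prints

```
fRT1: f_R = 22.3 breaths/min, HR = 145 beats/min
fRT2: f_R = 29.3 breaths/min, HR = 166 beats/min
```

`res.scan` holds the stage-by-stage 2·SD scan (the provisional thresholds
fall at the 100 W and 160 W stages: excess 5.4 > gate 4.8, and 13.1 > 6.5),
and `res.lines` the three fitted segments,

```
RL1: f_R = 0.1399*HR + 1.9233   (n = 6)
RL2: f_R = 0.3333*HR - 26.1794  (n = 4)
RL3: f_R = 2.3453*HR - 361.1735 (n = 6)
```

whose intersections give the thresholds above: fRT1 at f_R 22.3
breaths·min⁻¹ (HR ≈ 145) and fRT2 at f_R 29.3 breaths·min⁻¹ (HR ≈ 166).
`res.summary()` prints the whole report.

The same pipeline is available from the shell:

```sh
frthresh detect --input stages.csv --output results.json --scan-table scan.csv
frthresh vslope --input stages.csv --output gets.json
frthresh simulate --n 42 --seed 7 --outdir cohort/
frthresh batch --input-dir cohort/ --output batch.json
frthresh compare --a batch.json --b batch.json --variable hr \
    --name-a fRT1 --name-b GET1 --output agreement.json
```

`simulate` writes a synthetic cohort with known, embedded threshold
locations (see `frthresh.synthetic`), which is how detector accuracy is
validated end to end without any data download.

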