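# pouchyoung

Quantitative ontogeny of marsupial pouch young from linear skeletal
measurements: growth-curve age estimation, ontogenetic allometry of the
limb long bones, limb heterochrony, and skeletal-count taxon diagnosis.

The package grew out of the developmental series of the thylacine
(*Thylacinus cynocephalus*, the Tasmanian tiger), whose entire known
record of pouch life consists of a handful of ethanol-preserved museum
specimens in six litters. It is written for morphologists and museum
scientists who have tabular skeletal measurements (from CT
reconstructions, callipers or tape) and want to date specimens, quantify
growth trends and check specimen identity — without access to the
original material.

## What it computes

**Age estimation by inverse prediction.** Crown–rump length (CRL) — and
secondarily head length — grows linearly with age during marsupial pouch
life. Given litters of known age ("anchors"), the package fits an
ordinary least-squares line *L = β₀ + β₁·t* (mm vs weeks) and dates an
undated litter of mean length *L̄* at

&nbsp;&nbsp;&nbsp;&nbsp;*t̂ = (L̄ − β₀) / β₁*,

averaging across available traits and rounding to a half-week grid. The
quality of the recalibrated series is summarised by the R² of an OLS fit
over anchors plus newly dated points.

**Ontogenetic allometry by RMA regression.** For each limb long bone
(humerus, radius, femur, tibia) the natural logs of length and midshaft
circumference are fit by reduced major axis (RMA) regression — the
symmetric estimator appropriate when both variables carry measurement
error — with slope sign(r)·s_y/s_x. 95% confidence intervals come from a
case-resampling bootstrap (default 10 000 resamples, percentile
interval). Slope and CI above 1 is positive allometry (the bone grows
slender), below 1 negative (it grows robust), CI spanning 1 isometry. A
packaged table of published slopes for other marsupials and placentals
supports cross-taxon comparison.

**Body proportions and heterochrony.** Each skeletal component is
tracked as a percentage of trunk length (%TL, trunk = thoracic + lumbar
vertebral sums). The age at which the hindlimb series overtakes the
forelimb — the heterochrony crossover — is solved exactly by
piecewise-linear interpolation between stages.

**Taxon diagnosis.** Thylacines have 2 sacral and 23–25 caudal vertebrae
and lack ossified epipubic bones; other dasyurids have 3 sacrals, 20–21
caudals and prominent epipubics. A pure decision rule scores each known
character and returns a verdict only when all known characters agree.

**Synthetic data.** Generators emulate both statistical structures the
analyses assume — litters on a linear growth line with Gaussian
measurement noise, and log-linear length/circumference pairs with a
configurable allometric exponent — so the full pipeline is testable
without specimen data.

## Worked example

```python
import numpy as np
import pouchyoung as py

# Date the undated thylacine litters against the two anchor litters
# (neonates: 26 mm CRL at 1.5 weeks; oldest pup: 214 mm at 12 weeks).
table = py.reference_crl_table()
anchors = py.reference_anchors()
unknowns = [s for s in py.litter_summary(table, "crown_rump_length")
            if s.litter_id not in {"DZCU8021", "AMS_P762"}]
for e in sorted(py.estimate_ages(anchors, unknowns), key=lambda e: e.age_raw):
    print(f"{e.litter_id}: {e.age_rounded:g} weeks (raw {e.age_raw:.3f})")

# Heterochrony: when does the hindlimb overtake the forelimb (%TL)?
props = py.reference_limb_proportions()
fore = [p for p in props["forelimb"] if p.stage_age in (5.25, 9.5)]
hind = [p for p in props["hindlimb"] if p.stage_age in (5.25, 9.5)]
print(py.crossover_time(fore, hind))

# RMA allometry on a synthetic humerus with true exponent 1.2.
recs = py.simulate_allometric_bones(py.AllomSimSpec(slope_b=1.2, n=13,
                                                    noise_sd=0.05, seed=1))
x = np.log([r.circumference for r in recs])
y = np.log([r.length for r in recs])
res = py.rma_bootstrap(x, y, n_boot=10_000, seed=1)
print(f"slope {res.slope:.3f}  95% CI ({res.ci_low:.3f}, {res.ci_high:.3f})  "
      f"{res.allometry_class}")
```

prints

```
NMV_C5755-57: 4.5 weeks (raw 4.293)
TMAG_A931: 5 weeks (raw 5.019)
TMAG_A930: 9.5 weeks (raw 9.375)
Crossover(age=7.90625, tangent=False)
slope 1.195  95% CI (1.171, 1.230)  positive
```

The NMV litter dates to 4.5 weeks and the A930 pup to 9.5 weeks, the
ages under which these specimens are now described. (A931 lands at 5.0
weeks from CRL alone; its published 5.25-week age also drew on head
length, which is not part of the packaged series — see
`docs/methods.md`.) The fore/hindlimb proportion series cross at ≈7.9
weeks, i.e. the hindlimb's developmental lag is overcome at about 8
weeks of pouch life. The synthetic humerus recovers its generating
exponent, with a bootstrap CI entirely above 1: positive allometry.

A command-line interface wraps the same pipeline
(`pouchyoung age | allometry | proportions | identify | simulate`);
see `pouchyoung --help`.

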