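# fdgquant

Quantification pipeline for dynamic [18F]FDG-PET/MR studies of an orthotopic,
syngeneic mouse model of cholangiocarcinoma (CCA).  It is aimed at
preclinical imaging groups who monitor liver-tumor growth and glucose
metabolism weekly over a month and need the full chain from 4-D activity
volumes to kinetic and growth parameters, reproducibly and under test.

The pipeline covers:

* **TAC extraction** — per-organ time–activity curves (tumor, brain, heart,
  liver, vena cava) as unweighted VOI means per frame of a 23-frame/60-min
  dynamic acquisition, plus SUV conversion and 0–60 min AUCs.
* **Image-derived input function (IDIF)** — the vena-cava curve scaled to
  the liver curve at the last time frame, converted to plasma with a
  time-dependent plasma-to-blood equilibrium ratio
  r(t) = r_eq + (r0 − r_eq)e^(−t/τ).
* **Patlak graphical analysis** — for an irreversibly trapped tracer,
  C_ROI(T)/C_p(T) = K_i·[∫₀ᵀC_p dt / C_p(T)] + Int becomes linear after
  t* = 10 min; the slope is the net influx rate K_i (mL·min⁻¹·mL⁻¹).
* **Glucose metrics** — MRGlu = C_glu·K_i/LC with organ lumped constants
  (tumor 1, brain 0.625, heart 0.67); SUV_mean/SUV_max and
  SUVglu = SUV·C_glu from static 45–60 min images.
* **Growth analysis** — log-linear doubling-time fits per animal and per
  cohort, and regression screens of kinetic metrics on blood glucose.
* **Synthetic phantoms** — a two-tissue-compartment simulator (Feng plasma
  input, voxelized ellipsoid organs, counting-statistics-like noise,
  lognormal growth cohorts) so every stage is testable with exactly known
  ground truth.  See `docs/methods.md` for models, defaults and rationale.

## Worked example

Simulate a noise-free phantom session, build the IDIF, and recover the
tumor's net influx rate:

```python
import fdgquant as fq

phantom = fq.build_phantom_session(fq.PhantomConfig(noise_level=0.0), seed=1)
session = phantom.session
input_fn = fq.build_input_function(
    fq.extract_tac(session.image, session.mask, "vena_cava"),
    fq.extract_tac(session.image, session.mask, "liver"),
    phantom.input_params.ratio,
)
tumor = fq.extract_tac(session.image, session.mask, "tumor")
fit = fq.patlak_fit(fq.patlak_points(tumor, input_fn))
cglu = fq.average_blood_glucose(session.glucose_pre_mmol_l,
                                session.glucose_post_mmol_l)
met = fq.metabolic_rate_glucose(fit.ki, cglu, organ="tumor")
```

which prints, with the default phantom:

```
IDIF scale factor : 1.000
tumor Ki          : 0.01991 mL/min/mL  (truth 0.02000)
Patlak intercept  : 0.335   R^2 0.99999  n 6
MRGlu             : 0.1971 umol/min/mL  (Cglu 9.9 mmol/L, LC 1.0)
```

The fitted K_i sits within 0.5% of the generator's ground truth
K1·k3/(k2+k3) = 0.1·0.05/0.25 = 0.02; the six points beyond t* = 10 min are
collinear (R² > 0.9999); MRGlu follows as 9.9 mmol/L × K_i / 1.  A growth
cohort behaves the same way:

```python
cohort = fq.generate_growth_cohort(fq.growth_preset("weekly-means"), 20, seed=1)
td, per_animal = fq.fit_cohort_doubling_time(cohort)
# td -> 5.04 days, generator preset 5.01 days
```

The same chain is available from the shell via `fdgquant simulate`,
`extract-tacs`, `idif`, `patlak`, `static-uptake`, `growth` and `correlate`;
every subcommand reads and writes plain NIfTI/JSON/CSV.

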