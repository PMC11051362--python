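# Methods

## Scope and model structure

`sfrtsim` models the response of a single, inhomogeneously oxygenated
tumor to spatially fractionated radiotherapy followed by immunotherapy.
It is a deterministic, volume-level model: the state is a handful of
compartment volumes (cm³) evolving on a daily grid, not a spatial or
cell-population simulation. Distant-site (abscopal) effects, mechanistic
immunology, dose-gradient propagation beyond the vertex spheres, and
stochastic generalizations are out of scope.

### Geometry

The GTV splits into necrotic, hypoxic and normoxic compartments whose
volumes must sum to the GTV (relative tolerance 10⁻⁶ by default; negative
volumes and conservation failures are reported as distinct errors). The
model commits to three roles:

* **necrotic** — dead: never grows, never a radiotherapy target; carried
  as bookkeeping only;
* **hypoxic** — viable but non-proliferating: radiosensitive with an OER,
  excluded from regrowth;
* **normoxic** — proliferating: radiosensitive at OER 1, the compartment
  the growth law and the post-therapy calculus act on.

Vertices are represented by count and diameter; their total volume is
`count·(π/6)·d³`. Because the package works with volumes rather than
coordinates, vertex/compartment overlap is supplied as two explicit
fractions (in-hypoxic, in-necrotic; remainder normoxic) and checked
against the host compartment volumes. The vertex dose acts only on the
sub-volumes inside the vertices; no propagation model to the surrounding
rim is implemented.

### Radiation response

Per dose event, each targeted viable sub-volume is multiplied by the LQ
surviving fraction with effective dose `d/OER`. The OER-as-dose-reduction
convention (equivalently α/OER and β/OER²) is the standard radiobiological
one and is the choice consistent with the pair of schedule-level factors
the default calibration reproduces simultaneously.

Fractionated schedules assume complete inter-fraction repair and, by
default, negligible inter-fraction regrowth, so per-event survivals
multiply and the factor of a schedule equals the product over any
partition of it. Setting `options.include_interfraction_growth: true`
instead grows the normoxic compartment by the analytic Gompertz step
between daily events (sub-volumes rescaled proportionally, since the
growth law is formulated on the compartment total).

### Calibration of (α, β)

`calibrate_lq` inverts the two log-survival equations

```
n(αd + βd²)          = −ln f_normoxic
n(αd/oer + β(d/oer)²) = −ln f_hypoxic
```

as an exact 2×2 linear solve. OER = 1 makes the system singular
(rejected); a negative solution component means the two factors are
inconsistent with an LQ response (rejected as non-physical). The package
defaults, α ≈ 0.2593 Gy⁻¹ and β ≈ 0.0140 Gy⁻², are *reconstructed* this
way from the built-in scenario's factors (1.19×10⁻⁴ normoxic, 3.2×10⁻³
hypoxic at OER 1.5 for 10 × 3 Gy) — they are schedule-level estimates, not
measured radiosensitivities, and should be overridden when tissue values
are available.

### Post-therapy evolution

After the last fraction at day `n`, the proliferating volume follows

```
V(t) = V(n+)·exp(L(t)),
L(t) = ln(V∞/V(n+))·(1 − e^{−k(t−n)}) − A(t) − B(t).
```

This is the Gompertz solution written in log space relative to the
end-of-therapy volume, with the immune terms entering as cumulative
log-kill offsets (dimensionless), not rates. The form is fixed by two
requirements: with A = B = 0 it is exactly the closed-form Gompertz
curve, and with constant A its zero crossing reproduces the closed-form
regrowth time `−(1/k)·ln(1 − A/ln(V∞/V(n+)))` — both are enforced by
tests. The non-proliferating hypoxic remnant is held constant after
therapy (it neither regrows nor is further killed) and reported
separately; the trajectory's `total_viable` column is the sum.

`A(t)` defaults to constant at its end-of-therapy value `A(0) = −ln ΔV`
(the reasonable assumption over the few-week window where the estimate is
used); a callable decay profile can be supplied for a time-dependent
response, in which case the regrowth time comes from bracketed
root-finding rather than the closed form. Whether activation also acts
*during* the fractionated course is left off by default: the during-course
formulation is not constrained by the quantities the package calibrates
against, and the end-of-therapy inference absorbs its integrated effect.

`B(t)` is the cumulative immunotherapy effect, zero before its start day:
`linear` (constant per-time effect I), `logarithmic` (I ~ 1/t), or
`custom` (numerical integral of a user integrand, quadrature tolerance
10⁻⁸). Negative coefficients are rejected; B is non-decreasing for
non-negative integrands.

### Outcome classification

The sign of L drives the decision calculus, evaluated over a horizon
(default 730 days — long enough for the slow linear-B recovery regime to
resolve, at negligible cost):

* **complete-recovery** — the proliferating volume falls below the
  detection floor (default 10⁻⁶ cm³) within the horizon, or L stays
  negative throughout;
* **transient-shrinkage-then-regrowth** — L starts negative and crosses
  zero from below; the crossing (volume back at its end-of-therapy value,
  matching the closed form's definition of "beginning of regrowth") is
  refined by Brent's method on the daily grid to below 10⁻⁶ day and
  reported as `regrowth_day`;
* **immediate-regrowth** — L is already positive at the first
  post-therapy grid point.

The floor takes precedence over a crossing: a strong but slowly
accumulating B can let L bump briefly above zero before driving the
volume to extinction, and the clinically meaningful label for that
trajectory is recovery. The transient crossing is still reported in the
outcome's `conditions`, as are the recovery margin `ln(V∞/V(n+)) − A(0)`,
the first-order early margin `k·m·ln(V∞/V(n+)) − A(0)` (valid for
k·m ≪ 1), L at the first post-therapy day and at the horizon, and the
volume minimum.

### The assessment pipeline and measurement precision

`run_assessment` chains the nine clinical steps (initial volume, LQ
prediction, observation, comparison, activation, lethal log-ratio,
recovery condition, early condition, regrowth prediction) and logs each
step. Two deliberate choices:

* **Reporting resolution.** End-of-therapy volumes at the edge of
  detectability are clinically reported at roughly 1 mm³ precision, so
  the observed/theoretical ratio is formed from volumes quantized to
  `reporting_resolution_cm3` (default 0.001 cm³; set 0 to disable). For
  the built-in scenario this makes the comparison 0.006/0.009 rather than
  0.006/0.0085085 — the ratio a clinician would actually write down. The
  exact unquantized prediction is carried alongside in the report.
* **Undetectable residue.** When no observation is available (or it lies
  below the detection floor), the assessment proceeds with the scenario's
  assumed stand-in volume and records that the comparison "cannot be
  exactly carried out". An observation *above* the LQ prediction yields a
  negative activation with a warning (the model assumes ΔV < 1); the
  downstream conditions then use A = 0.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| α, β | Gy⁻¹, Gy⁻² | 0.2593, 0.0140 | calibrated from the fixture factors; override per tissue |
| OER (hypoxic) | — | 1.5 | effective-dose divisor |
| k | day⁻¹ | none (fixture: 0.01) | must be supplied; the fixture value is a representative literature-scale rate, not a measured one |
| V∞ | cm³ | 1000 | lethal carrying volume (~10¹² cells ≈ 1 liter); the sphere-diameter description of that cell count (~12 cm ⇒ ~905 cm³) is slightly inconsistent with 1 liter — 1000 cm³ is used and configurable |
| detection floor | cm³ | 10⁻⁶ | complete-recovery threshold |
| reporting resolution | cm³ | 10⁻³ | volume quantization for the A inference |
| horizon | days | 730 | classification window |

## Scenario generation

`generate_scenario("case-report")` returns the built-in clinical fixture
verbatim. `generate_scenario("random", seed)` draws necrotic (0–100 cm³),
hypoxic (5–50), normoxic (10–100) volumes (GTV their sum, so conservation
holds by construction), 0–5 vertices of 0.5–1 cm with attribution
fractions capped by the host volumes, an optional 10–20 Gy vertex shot
plus 5–15 daily fractions of 2–4 Gy, α ∈ [0.1, 0.4], β ∈ [0.005, 0.05],
OER ∈ [1.2, 3], k ∈ [0.005, 0.05] day⁻¹, A(0) ∈ [0, 1], and a random
B-form with coefficient up to 0.1 starting the day after therapy. These
ranges emulate plausible clinical variety for fuzzing the pipeline; they
do not emulate measurement noise, imaging segmentation error, or
patient-level correlation between parameters, so passing on random
scenarios demonstrates robustness of the machinery, not clinical
validity.

## Numerical choices

* Exact closed forms wherever they exist (LQ products, Gompertz/logistic
  steps, the 2×2 calibration, the constant-A regrowth time); iterative
  methods only for root-finding (Brent, xtol 10⁻⁹ day) and custom-B
  quadrature (tolerance 10⁻⁸).
* The daily grid mirrors the clinical Δt = 1 day; all crossings are
  refined continuously within the bracketing day, so grid resolution does
  not limit reported times.
* Calibration clips solution components within 10⁻¹² of zero to zero
  (rounding noise); anything more negative is a hard error.
* Volumes that would quantize to zero at the reporting resolution are
  compared unquantized, keeping −ln ΔV well defined.

## Known limitations

* Volume-level only: no spatial dose distribution; the vertex dose does
  not propagate into the surrounding rim.
* The post-therapy calculus is Gompertz-specific; the logistic law is
  available for pure-growth evolution only and is rejected in the
  recovery/regrowth computations.
* Hypoxic cells neither reoxygenate nor proliferate; compartment
  transitions (e.g. reoxygenation after vertex kill) are not modelled.
* A and B are phenomenological cumulative log-kills; no pharmacokinetics
  or immune-cell dynamics.
* The during-therapy immune contribution is folded into the end-of-therapy
  inference rather than modelled explicitly.
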