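# Methods

## Problem and model chain

Targeted alpha therapy with ²²⁵Ac-PSMA is dose-limited by salivary-gland
toxicity (xerostomia). Because the ²²⁵Ac gamma yield is too low for
quantitative post-injection imaging, organ kinetics are measured with
¹⁷⁷Lu-PSMA — the biodistribution is governed by the PSMA carrier, not the
isotope — and converted to a predictive ²²⁵Ac dose, which is then pushed
through a radiobiological model to a complication probability. The package
implements that chain as five coupled stages; each is summarised below with
its assumptions.

### 1. Planar kinetics

Organ activity is quantified from anterior/posterior planar counts with the
triple-energy-window scatter estimate `(C_low/w_low + C_up/w_up)·w_main/2`
(clamped so corrected counts stay non-negative; default widths 41.6/17.5/
23.8 keV for the 208 keV main and 175/238 keV flanking windows) and the
conjugate-view geometric mean relative to the earliest whole-body image,
which is taken as 100% of the injected activity. No attenuation correction
is applied anywhere — a deliberate protocol match to the comparison data,
not an oversight; it biases absolute fractions but cancels in the
protector/no-protector comparison.

Washout is fitted as Σᵢ Aᵢ·e^(−λᵢt) with amplitudes constrained ≥ 0 and
rates ≥ 10⁻⁶ h⁻¹ (uptake phases are not modelled; a constant curve drives
the rate to the floor rather than erroring). The default objective is
unweighted least squares on the linear scale; per-point weights are
accepted. Initialisation is closed-form: log-linear regression for the
mono-exponential, curve peeling (tail fit, then residual) for the
bi-exponential, refined by bounded trust-region least squares. For
bi-exponential fits every downstream use of "the" rate takes the **slow**
phase (terms are stored rate-ascending), since it dominates the 0→∞
integral and the BED decay constant. The residence time is the analytic
integral τ = Σ Aᵢ/λᵢ; no separate physical-decay tail rule is applied.

Isotope conversion multiplies each point by exp(+ln2·t/T_Lu) (giving the
biological curve, marked with an infinite physical half-life) and then by
exp(−ln2·t/T_Ac), with T_Lu = 159.5 h and T_Ac = 238.1 h. For a
mono-exponential biological rate λ_b this scales τ by λ_b/(λ_b + λ_Ac),
which the tests verify against closed form.

### 2. Decay chain

The packaged table (`data/nuclides_ac225.json`) carries, per nuclide:
half-life, yield per ²²⁵Ac decay, and yield-weighted emission energies per
decay by type (total alpha, mean beta, total photon), compiled from public
evaluated nuclear data (NNDC/ENSDF; ICRP-107-style totals). The ²¹³Bi
branching is fixed at 2% ²⁰⁹Tl / 98% ²¹³Po — the convention of the study
being reproduced; evaluated data give 2.2/97.8 and can be supplied via the
JSON override. The stable endpoint ²⁰⁹Bi is omitted; recoil energy and
daughter translocation are not modelled (²¹³Po diffusion can be *bounded*
with the exclusion toggle, which removes ≈30% of the unweighted dose).

Secular equilibrium is justified structurally: the longest daughter
half-life (²⁰⁹Pb, 3.25 h) is ~70× shorter than the parent's 238 h, so all
daughters decay at the parent's effective rate and location; the chain
validator enforces the half-life ordering and yield constraints.

### 3. Sphere dose engine

Salivary glands are unit-density spheres. Alpha and beta energy is
deposited locally (absorbed fraction 1 — ranges are ≪ the 33–89 g / 13–34 g
gland sizes); the photon absorbed fraction defaults to 0 with a per-organ
override, because photons contribute ≤ 0.15% of the weighted dose and
published sphere photon fractions for this geometry are not available at
the needed granularity. Decays per MBq injected are τ·3600·10⁶·yield; doses
are MeV→J (1.602 176 634×10⁻¹³) over mass. With the default data and
RBE 5 the alpha share of the weighted total is 99.5%, inside the reference
range (98.20–99.79%), and ²¹³Po alone carries ≈29% of the unweighted dose.
Kidney/liver/marrow/whole-body coefficients are phantom-derived in the
source study and are carried only as fixtures — the sphere engine is not
applicable to them.

### 4. Radiobiology

High-LET BED uses the brachytherapy mixture formalism for exponentially
decaying dose rates with a shared decay constant λ (the parent's slow-phase
effective constant) and repair rate μ. The implementation evaluates the
double sum over nuclide pairs literally and the tests verify it equals
(Σ R₀)², i.e. the BED is invariant to how the total initial dose rate is
partitioned — the nonlinearity acts on the *total* dose rate because all
components irradiate the same target simultaneously. Only the unweighted
alpha dose enters the dose rates; the RBE enters once, through
RBE_M = 8.2 in the linear term (RBE_exp = 5, d = 2 Gy, α/β = 3 Gy). A
`dose_input="weighted"` switch exists in the cohort layer because the
literature is not unambiguous about which dose feeds the quadratic term;
the default follows the alpha-only reading. A numeric double-quadrature
oracle (BED = RBE_M·D + (2/αβ)·∫Ṙ(t)∫Ṙ(u)e^(−μ(t−u)) du dt) pins the
closed form to 10⁻⁶ relative over λ ∈ [0.005, 0.5] h⁻¹, R₀ ∈ [0.001, 1] Gy/h.

Low-LET comparison: BED_L = D·(1 + (D/N)/(α/β)) — the 26 Gy/30-fraction
parotid constraint gives 33.5 Gy — and EQD2 = BED/(1 + 2/(α/β)). The LKB
NTCP is the probit Φ((EQD2 − TD50)/(m·TD50)) with TD50 = 14 Gy_EQD2 and
m = 0.88 (grade ≥2 xerostomia, salivary flow < 45% of baseline at
3 months), evaluated via the error function, never by numerical
integration.

Defaults (α/β = 3 Gy, μ = 0.46 h⁻¹, RBE_exp = 5, d = 2 Gy, TD50 = 14 Gy,
m = 0.88, reference injection 100 kBq/kg) live in
`data/table2_radiobiology_parameters.csv` and in `RadiobiologyParams`.

### 5. Cohort layer

Summary statistics follow the clinical-table conventions: order-statistic
median, range, mean, and *sample* (n−1) standard deviation — both choices
validated cell-by-cell against the packaged tables. The per-patient
salivary value is the arithmetic PG/SG mean. Rescaling to the no-protector
reference multiplies every coefficient by (reference mean)/(cohort mean) =
2.33/1.08 ≈ 2.16, i.e. the protector cohort sits ≈54% below the reference.

NTCP-vs-activity recomputes the BED per patient at each activity (the BED
is superlinear in activity, so curves cannot be rescaled linearly). Two
input routes exist: from dose coefficients (converted to unweighted alpha
dose via the chain's energy bookkeeping; washout constant and weight
default to the cohort medians — 25.5 h/10.0 h effective half-life for
PG/SG, their mean for salivary, 80 kg — when a record lacks them), or from
a recorded BED at the reference activity, inverted through the quadratic
RBE_M·x + c·x² and scaled in x. Because the published per-patient BED table
cannot be regenerated from the published coefficients (the per-patient
washout constants and weights are not printed), the BED table is packaged
as a fixture and the second route reproduces the published figure's
candidate operating points. No single cohort aggregation is canonical, so
three are implemented and reported side by side — NTCP of the mean EQD2, of
the median EQD2, and the mean of per-patient NTCPs (at 100 kBq/kg on the
fixture cohort: ≈98%, ≈92%, ≈79%). Confidence intervals are percentile
bootstrap over patients (default B = 2000) with a fixed seed; repeated runs
are bit-identical.

## Synthetic data

The generator emulates the study conditions: 13 patients by default, body
weight uniform in 72–105 kg, parotid mass uniform in 33–89 g and
submandibular in 13–34 g, sampling at the four imaging windows (0.5–1,
16–24, 36–48, ~120 h, uniformly jittered; the last window gets ±2 h since
no interval is specified), and multiplicative lognormal noise with CV 5%
(mean-one parameterisation; planar quantification error is positive and
roughly proportional), switchable to truncated Gaussian. Biological
half-lives are log-uniform over the printed effective ranges with the
¹⁷⁷Lu decay divided out (parotid 1.75–65 h, submandibular 2.85–41 h), so
generated effective half-lives land in the printed ranges (verified ≥95%
of patients). Uptake amplitudes are log-uniform over 0.3–3% (parotid) and
0.2–2% (submandibular) of injected activity — not a published quantity;
chosen once so the resulting dose coefficients match the observed
magnitude (~0.4–2.5 Bd_RBE5/MBq). Ground truth (amplitudes, rates, both
residence times, the sphere coefficient) is computed in closed form and
carried with each cohort.

What the generator does **not** emulate: Poisson count statistics, organ
overlap and background in planar projections, uptake phases, voiding
effects on the whole-body normalisation, and daughter redistribution.
Passing recovery tests therefore demonstrate correctness of the estimator
chain under the stated error model, not robustness to every artefact of
real planar dosimetry.

## Numerical choices

* Fit rates bounded below at 10⁻⁶ h⁻¹; amplitudes at 0. Non-convergence
  raises an error carrying the initial guess.
* Bi-exponential terms sorted rate-ascending; ties are impossible at the
  bound-separated initialisation but would keep the first term slow.
* TEW correction clamps at zero counts.
* Covariances from the Gauss–Newton approximation, reported only when the
  fit has positive degrees of freedom.
* Problem sizes in the test suite — 200-patient recovery cohorts, 400 for
  range coverage, 3×3 quadrature grids, B ≤ 2000 bootstrap — are chosen so
  Monte-Carlo error is well below the asserted tolerances while the whole
  suite stays interactive (well under a minute).

## Known limitations

* Absolute dose coefficients inherit the no-attenuation planar protocol;
  they are comparable across cohorts measured the same way, not with
  SPECT/CT dosimetry.
* The sphere model yields mean organ dose only; no dose–volume information,
  no microdosimetry, no RBE_min term in the quadratic component — the model
  is conservative (it overestimates complication rates against reported
  clinical experience).
* Daughter redistribution is only bounded (²¹³Po exclusion), not modelled
  pharmacokinetically.
* The LKB parameters are transferred from external-beam data; their use for
  continuous low-dose-rate alpha irradiation is itself a modelling
  assumption under test, not a validated fact.
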