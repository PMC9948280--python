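# Methods

## Follicle-pool decline model

The primordial-follicle pool N(t) declines from birth to menopause in a
biexponential fashion: slowly through most of reproductive life, then at
an accelerated rate once roughly 25,000 follicles remain (around age 37).
We model this as a count-triggered two-phase exponential,

    dN/dt = −k(N)·N,    k(N) = k1  if N > n_break,
                               k2  otherwise (k2 > k1),

with the boundary N = n_break assigned to the accelerated phase. The two
rates are calibrated from three anchors — N(0) = n0, N(age_break) =
n_break, N(age_menopause) = n_menopause — giving

    k1 = ln(n0/n_break)/age_break = 0.090106 /yr,
    k2 = ln(n_break/n_menopause)/(age_menopause − age_break) = 0.229920 /yr

for the defaults n0 = 701,200, n_break = 25,000 at 37 y, n_menopause =
1,000 at 51 y. The calibrated trajectory passes exactly through all three
anchors.

Two assumptions matter:

- **The trigger is the count, not the age.** An irradiated pool that
  drops below 25,000 immediately adopts the accelerated rate, because the
  acceleration is attributed to the remaining follicle number rather than
  to chronological age. A corollary is that the dynamics are autonomous
  in N: a pool of size N behaves exactly like an unirradiated pool
  observed at the age where it would naturally hold N follicles, which
  gives every downstream quantity a closed form.
- **Post-irradiation decay equals unirradiated decay.** No repair or
  recovery kinetics; the dose only resets the pool size.

The model starts at birth (no prenatal rise to the mid-gestation peak)
and treats the pool as a continuous quantity (no per-follicle
stochasticity).

## Numerical integration

The ODE is integrated by classic fixed-step fourth-order Runge–Kutta
(default step 0.01 yr), with the closed-form piecewise exponential as the
analytical oracle. The right-hand side is discontinuous at N = n_break;
stepping blindly across that switch costs a local O(h) error (~3×10⁻⁴
relative at h = 0.01 yr) and destroys the fourth-order convergence. The
integrator therefore locates the crossing instant inside the affected
step (Brent root-find on the slow-phase RK4 sub-step, machine-precision
tolerance) and splits the step there, so each sub-step integrates a
smooth exponential. With that, RK4 at h = 0.01 yr matches the closed form
to ~4×10⁻¹³ relative error over [0, 51] y, and halving a coarse step
(0.5 → 0.25 yr) shrinks the maximum error by the expected ≈16×.

All production quantities (insufficiency age, LOF) use the closed form;
RK4 exists to validate it and to honor the stated solution method. The
threshold crossing is located analytically, never by scanning the
integration grid, so LOF carries no step-size artifacts.

## Dose response

The oocyte surviving fraction after a total ovarian dose z (Gy) is
log-linear: f(z) = 10^(−α·z), α = 0.15 per Gy, so f(0) = 1 and the LD50
is log₁₀(2)/0.15 ≈ 2.0 Gy, consistent with the radiobiology literature on
the human oocyte. The published formula prints the survival *percentage*
with a square root whose literal reading is inconsistent at z = 0 (it
would give 10,000%); we take the percentage as g(z) = 10^(2−0.15z), i.e.
the fraction above. The dose is the total fractionated dose, assumed
equal in both ovaries, applied as an instantaneous pool reduction at the
age of treatment; no linear-quadratic fraction-size correction.

Derived: the sterilizing dose at age a is z* = log₁₀(N(a)/n_menopause)/α,
the smallest dose causing immediate insufficiency (≈11.93 Gy at 27 y,
decreasing with age, 0 at the menopause age itself).

## LOF grid and regression

LOF(a, z) = 100·(T₀ − T₁)/T₀ with T₀ = age_menopause − a and T₁ the
post-dose remaining time. The simulation grid spans ages 10–50 y in 1-y
steps and doses from 0.5 Gy in 0.5-Gy steps up to (and excluding) each
age's sterilizing dose — the grid increments are not fixed by the source
and are configurable; these defaults keep every record at 0 < LOF < 100.
The exact sterilizing-dose endpoint rows (LOF = 100) are excluded.

A dose-only OLS model LOF = a + b·z (with intercept — the physical
constraint LOF(0) = 0 is deliberately not imposed, the small positive
intercept being a regression artifact of the curvature) is fitted twice:
on the complete grid, and restricted to ages ≤ 40 and doses < 5 Gy, the
clinical equation's validity domain. Model quality is reported as R² and
as the leave-one-out cross-validated RMSE, computed via the PRESS
identity (held-out residual = residual/(1 − leverage)), which is
algebraically exact and verified against naive n-refit brute force to
10⁻¹⁰. Fitting goes through statsmodels OLS.

On the default grid this yields LOF ≈ 3.18 + 11.01×Dose (LOO RMSE 4.35,
n = 279) restricted, versus a clearly degraded complete-grid fit (LOO
RMSE 11.1, R² 82.7%, n = 818): women past the accelerated-loss onset
follow a different LOF–dose pattern, which is exactly why the clinical
equation is restricted to under-40s. The published restricted equation is
LOF = 2.70 + 11.08×Dose with LOO RMSE 3.05; our slope agrees to 0.7% and
the intercept to ~18%, but the scatter statistics (both RMSEs, full-grid
R²) differ because the source's underlying decline ODE is not printed and
this package's two-phase surrogate, while reproducing every printed
anchor and the headline slope, has different curvature across the grid.
These scatter statistics are the model's one reconstruction-dependent
surface; the corresponding end-to-end test is left failing rather than
loosened, as a marker of that gap.

## Clinical calculator

The calculator applies the published coefficients (intercept 2.70 %,
slope 11.08 %/Gy, LOO RMSE 3.05 %, natural menopause age 51 y — all
configurable) rather than refitted ones, since those are the externally
validated numbers: years_lost = T₀·LOF/100 and predicted menopause age
= age + T₀ − years_lost, with LOF capped at 100% so predictions never
precede the treatment age. The 95% band propagates ±1.96×RMSE percentage
points of LOF through the same linearization (±6% of T₀, i.e. ±6 years
of function per the published interval) and is clamped to [treatment age,
natural menopause age]; it is not shrunk further for older patients —
that clamping convention is ours. Clinical display rounds LOF to whole
percent and ages to whole years; CSV/JSON outputs keep full precision.
Scenarios outside age < 40 and dose < 5 Gy are computed but flagged as
outside the validity domain.

## Known limitations

- The decline ODE is a surrogate for an unprinted source model; absolute
  scatter statistics of the grid regression inherit that uncertainty
  (see above).
- No chemotherapy gonadotoxicity, uterine radiation effects, per-ovary
  dose asymmetry, fractionation scheduling, or ovarian transposition;
  both ovaries are assumed to receive the same total dose.
- The synthetic LOF grid emulates the simulation design (ages 10–50,
  doses 0.5 Gy upward), not a patient cohort: passing tests show internal
  consistency and agreement with the published equation, not clinical
  validation on outcome data.
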