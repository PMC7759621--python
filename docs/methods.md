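# Methods

`tachem` models the speciation of Fe(III) with tannic acid (TA), a
polygalloyl-glucose mixture treated formally as decagalloyl glucose
(MW 1701.20 g/mol). The package has two halves: estimators (MCR-ALS,
PARAFAC, Job analysis, the conditional-constant model) and seeded
synthetic-data generators that emulate the three experiments those
estimators are designed for. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not demonstrate.

## The chemical model

TA has no meaningful molar concentration — it is a mixture of
polygalloyl species — so binding strength is expressed through the
single-site conditional constant used for humic substances:

    cK_n = [MTA_n] / ([M] (TA)_total)          (L/g)

with `[MTA_n]` the metal bound in complex n, `[M]` the free metal
(mol/L), and `(TA)_total` the ligand mass concentration (g/L). The
formalism assumes 1:1 metal-site binding, one dominant site class,
position-independent site strength, a fixed number of active sites, no
proton exchange of the binding sites, and no electrostatic site-site
interactions (all six are listed in `speciation.MODEL_ASSUMPTIONS`).
The no-proton-exchange assumption is knowingly violated below ~pH 5 —
catecholate sites deprotonate as they coordinate — which is exactly why
cK is conditional and must be tabulated per pH; the package annotates
this rather than enforcing it.

With the dimensionless products `c'K_n = cK_n (TA)_total` and the metal
mass balance `M_total = [M] + [MTA1] + [MTA2]`, the species
concentrations and the mixture absorbance follow in closed form
(`species_conc`, `predict_absorbance`). Mass conservation holds to
1e-12 relative by construction; computing cK back from the closed-form
concentrations reproduces the input to 1e-10 (both are property
tests).

Two complex species are carried: MTA1 (band maximum 580 nm, extinction
maximum 3487 1/(M cm)), consistent with a bis-catecholate chromophore,
and MTA2 (513 nm, 7576 1/(M cm)), the wine-red species that grows above
pH 5. Components resolved by MCR are mapped to species by proximity of
their band maxima to these references.

Free metal below 1e-12 mol/L raises a "free metal exhausted" error in
`conditional_k`; `k_profile_from_mcr` instead flags such rows as
`saturated` and reports no constant there. A separate per-species
quantification floor (`c_floor`) marks constants whose complex
concentration is below the curve-resolution noise as non-quantifiable
while still reporting the value; the closed-loop analyses use
`c_floor = 0.05 * M_total` (~1e-6 mol/L), about 20x the ~5e-8 mol/L
concentration noise of a resolved profile under the default noise
level, so anything below it carries order-of-magnitude uncertainty in
cK. This mirrors the usual practice of excluding titration-inflection
points from conditional-constant plots.

## The UV-vis generator and MCR-ALS

The titration generator builds `X = C S^T + E`: concentration rows from
the speciation closed form at each pH, Gaussian extinction bands for
the spectra (Beer-Lambert, 1 cm path), and homoscedastic Gaussian noise
of 0.002 AU. Band shapes are single Gaussians (FWHM 150 nm for MTA1,
120 nm for MTA2) — broad charge-transfer bands; the true shapes are not
known, so recovery tests compare against the generator's own truth.

The pH dependence of the conditional constants is piecewise-linear in
log10: anchored at the pH-4 values (52.9 and 3.78 L/g), rising with
slopes of 2.0 and 1.5 decades/pH, and frozen above pH 5 (K1) and pH 7
(K2). The staggered plateaus are deliberate: if both constants froze at
the same pH the two concentration profiles would be exactly
proportional over most of the titration and the bilinear factorization
would be rotationally unidentifiable. With these defaults MTA1
dominates near pH 5 and MTA2 above pH 6.5, giving each component a
nearly selective region.

The packaged `fe_ta_uvvis` scenario spans pH 4.5-8.5 (17 samples,
0.25 steps). The window starts at 4.5 because the closure constraint —
rescaling every concentration row to the total metal 2.00e-5 mol/L —
is only chemically consistent where binding is essentially complete;
with the pH-4 anchor constants, free Fe(III) is 34% of the total at
pH 4 and ~5% at pH 4.5. A closure total that includes free metal while
the model only carries absorbing complexes would bias every recovered
quantity. The companion `fe_ta_uvvis_wide` scenario (pH 3.5-8.5, 0.5
steps) retains the low-pH region for speciation work, where closure is
not applied.

MCR-ALS follows the standard scheme: SIMPLISMA pure-variable selection
(offset 1% of the largest row mean; determinant-weighted purity;
ties broken toward the lowest index) provides initial spectra; ALS then
alternates non-negative least-squares half-steps for C and S.
Constrained subproblems with up to 6 components are solved exactly by
enumerating active sets, vectorized over all right-hand sides (the NNLS
optimum satisfies the unconstrained normal equations on its own
support); this agrees with `scipy.optimize.nnls` to solver precision
and is checked against it property-wise. Closure is applied after the
C half-step by row rescaling. Convergence is a relative RSS change
below 1e-6 between full iterations (default cap 150); an RSS below
1e-14 of SS(X) counts as numerically exact. Non-convergence is flagged,
not raised.

Closure is a projection, not a descent step, so it can raise the RSS.
At the converged state the residual jump measures how inconsistent the
stated mass balance is with the data: it is ~0 on consistent noiseless
data and of order (noise/signal)^2 otherwise. The fit reports
`closure_violation` when the converged jump exceeds 10x the tolerance;
on any realistically noisy matrix this flag is expected to be set and
is diagnostic, not an error.

Band maxima of resolved spectra are reported after a two-pass local
quadratic refinement (+-30 nm window, recentered once, snapped to the
2 nm grid). The bands are 60-75x wider than the grid step, so a raw
argmax wanders several grid steps under noise while the refined vertex
is stable; the refinement halves the localization error in a direct
simulation. With closure fixing the concentration scale, spectra are
in extinction units and the refined peak height estimates the
extinction maximum.

Residual rotational ambiguity is the dominant systematic: even
noiseless closure fits recover component congruence ~0.999, band maxima
within one 2 nm grid step (578/514 vs 580/513 — note 513 itself is off
the even-nm grid), and extinction maxima within ~2-3%. Those are the
honest limits of a soft-modeled two-band system with this overlap, and
the recovery tests assert medians over 20 seeded replicates at exactly
those tolerances (one grid step; 5% on extinctions).

For speciation the package separates scale fixing from quantification:
`calibrate_epsilon` rescales an unclosed fit to reference extinctions,
and `project_concentrations` quantifies any other sample series by a
single non-negative Beer-Lambert regression onto already-resolved
spectra. The closed-loop analysis resolves spectra on the
closure-consistent titration, projects the wide-pH series, tabulates
cK(pH), and predicts the pH-4 absorbance at 570 nm; over 20 replicates
the quantifiable log cK values recover the generator truth within 0.1
and the predicted absorbance is within ~1% (median).

## The EEM generator and PARAFAC

The EEM generator emits an exactly trilinear stack: per-component
Gaussian excitation peak(s) (with an optional shoulder) and emission
band, unit-normalized, scaled by a logistic pH score profile. The
TA-only scenario has the main band at Ex 210/Em 360 with a 260 nm
excitation shoulder and a high-pH band at Ex 325/Em 405; the Fe
scenario replaces the latter with the 260/370 band and suppresses the
main band by the quench factor (0.005) — Fe(III) complexation quenches
TA fluorescence. Scatter is added as Gaussian ridges along emission:
first-order Rayleigh at Em = Ex (amplitude 2x the signal maximum),
second order at Em = 2 Ex, and the water Raman line at a 3400 1/cm
shift; ridge cross-sections have 4-5 nm sd, matching the 10 nm
bandpass, so the standard removal widths leave wings below the noise.

Noise is heteroscedastic: an additive floor of 1% of the signal maximum
plus a 3% signal-proportional term. The proportional term is the
photon-counting/source-flicker component every fluorometer has, and it
matters for model-order diagnostics: with purely iid noise, an
overfactored non-negative PARAFAC fit parks its extra component on an
orthogonal noise direction and the least-squares Tucker core stays
near-superdiagonal, so core consistency fails to collapse — a direct
simulation shows the canonical collapse only returns once residuals are
signal-correlated. Validation under iid noise would therefore overstate
how well core consistency works on real data.

Scatter handling: `remove_scatter` masks cells within +-15 nm of either
Rayleigh order and +-10 nm of the Raman line (a zero width disables a
band). `interpolate_scatter` bridges each masked cell twice with a
shape-preserving monotone cubic (PCHIP) spline — along the emission
slice and along the excitation slice — and keeps the fill from the axis
whose bracketing anchors agree better (then the narrower bracket;
emission on ties), extending linearly from the local slope where a band
touches the grid edge, and clipping only filled cells at zero. The
two-axis choice matters in the low-emission corner where the merged
Rayleigh and Raman bands leave the emission axis anchored on one side
only: a one-axis cubic fill there overshoots band flanks by up to ~20%
of the signal maximum and fabricates a spurious trilinear ridge that
both inflates the selected model order and biases loadings. After
interpolation, slabs correlate with the scatter-free truth at r > 0.99.

The trilinear ALS fits `x_ijk = sum_n a_in b_jn c_kn` by alternating
exact non-negative least squares over the three modes, 50 random
non-negative starts (start s seeded by `[seed, s]`), up to 5000
iterations per start, relative-loss tolerance 1e-6, keeping the lowest
final loss. Emission and excitation loadings are rescaled to unit
maximum with the scale absorbed into the scores; the reconstruction is
unchanged to 1e-12. Core consistency is the standard CORCONDIA
(least-squares Tucker core vs the superidentity); a 1-component model
returns exactly 100 by convention, and rank-deficient loadings return
NaN. Model order is chosen as the largest n whose core consistency
stays at or above 90%, scanning upward and stopping at the first
failure. On the packaged scenarios this selects 2 components (TA-only)
vs 1 (Fe-quenched) in >= 80% of 20 seeded replicates. Overfactored fits
collapse strongly but not universally (roughly 60% of replicates fall
below 50%, ~90% below the 90% rule) — under non-negativity the extra
component sometimes lands on a benign noise direction, a known
limitation of the diagnostic that the tests encode at
simulation-calibrated bounds rather than an idealized one.

## Job analysis and binding capacity

The continuous-variation generator computes bound metal under
saturating n-site binding, `bound = min(x T, n (1-x) T)` at total
concentration T = 2.00e-5 mol/L (a finite per-site association constant
solves the 1:1 site quadratic instead), and converts to absorbance at
570 nm with 3472 1/(M cm) per occupied site. `jobs_maximum` refines the
series maximum with a quadratic through the top three points and snaps
to the measurement grid when the vertex lands within half a grid step —
on clean data this reproduces the direct grid reading (0.8 for four
sites, hence n = round(0.8/0.2) = 4) while staying robust to noise; an
edge maximum raises an "unbracketed maximum" error. The capacity
arithmetic is exact: SCC = n/MW = 2.35e-3 mol/g for four sites, and
[L]_total = (TA)molar x MW x SCC (4.0e-5 mol/L at 1e-5 M TA), which
composes to n x (TA)molar identically. `saturation_breakpoint` fits a
continuous rise-then-plateau line with the plateau slope fixed at zero
(precipitation above ratio ~5 makes a fitted plateau slope
untrustworthy) over a candidate-knot grid and declares "no saturation"
when a single straight line fits at least as well.

## What the synthetic validation shows — and does not

Passing recovery tests demonstrate that the estimators are correct and
well-calibrated for data that actually follow the bilinear/trilinear
models with Gaussian band shapes, the stated noise models, and the
single-site binding chemistry. Real Fe-TA spectra differ in ways the
generators deliberately omit: non-Gaussian and pH-drifting band shapes,
baseline drift, inner-filter effects (not corrected here — scatter
removal alone is applied), lamp and detector artifacts, TA's chemical
heterogeneity across suppliers, and slow redox chemistry near the low
pH edge. Recovery tolerances met on synthetic data are therefore
necessary, not sufficient, evidence for experimental performance.
Dataset-level fit statistics of any particular experimental campaign
are not reproducible from synthetic data and are not targeted.

## Problem sizes and determinism

Default study sizes: 17 x 251 titration matrices (11 x 251 wide), 9 x
36 x 31 EEM stacks, 9-point Job series; recovery and closed-loop
statistics use 20 seeded replicates, and the model-order study 20
replicates per scenario at the full 50-start settings. Every stochastic
step flows from one integer seed per scenario (replicates derive theirs
from a base seed), so all results in the README and tests are exactly
reproducible. `scripts/acceptance.py` derives every scenario seed from
its `--seed` argument.

## Known limitations

* Rotational ambiguity bounds MCR accuracy at ~1 grid step / 2-3% even
  without noise; no angle or hard-model constraint is offered.
* Core consistency under non-negativity is an imperfect overfactoring
  detector (see above); the 90% rule is a heuristic, not a test.
* The closure constraint and the free-metal mass balance are mutually
  exclusive on the same fit; the package resolves this by separating
  scale calibration from quantification rather than by a soft closure.
* `conditional_k` treats (TA)_total as undepleted by bound metal, as
  the single-site formalism defines it; at high metal loadings this
  overstates the available ligand mass.
* Unimodality and normalization constraints are minimal implementations
  (monotone-envelope repair; unit-maximum rescaling), included for
  completeness, and are not exercised by the packaged studies.
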