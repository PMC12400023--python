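# Methods note

This note records the model implemented by `hdrskit`, the numerical and
statistical choices made, and their limitations. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` actually
compute.

## Spectral model

All spectra live on a strictly increasing wavelength grid within
250–450 nm; the canonical working grid is 290–400 nm at 1 nm. Spectra
carry a kind (`reflectance`, `transmission`, `absorbance`, `ratio`) with
kind-specific validity bounds (fractions in [0, 1.05] to tolerate
instrument overshoot; absorbance floored at −0.05; ratios positive and
unbounded). Resampling is linear interpolation without extrapolation.

**In vivo absorbance.** `A_DRS(λ) = −log10(R(λ)/R0(λ))` from the
protected and bare-skin diffuse reflectances. This treats the skin as an
unchanged backing reflector, so `R/R0` is the double-pass film
transmission; chromophore changes between the two measurements violate
the assumption and are not modelled.

**Hybridization.** A single scale factor
`c = mean(A_DRS over W) / mean(Avt0 over W)` over the window
`W = [320, 345]` nm (legacy: `[320, 330]`; a mean-of-ratios estimator is
available). The hybrid spectrum is `c·Avt0` below `W.lo` and `A_DRS` at
and above it. Proportionality of the two spectra inside `W` is assumed;
the splice can be discontinuous at `W.lo` when it is violated. A signal
check flags window wavelengths whose bare-skin reflectance is at the
noise floor (relevant for low-ITA, i.e. darker, skin).

**Photodegradation.** `srpd(λ) = 10^(Avt1 − Avt0)`; band summaries are
source-weighted means over the UVB ([290, 320) nm) and UVA
([320, 400] nm). Classification: *stable* if both band summaries exceed
the threshold (default 0.8), *moderately unstable* if the worse one is
within 0.2 below it, *strongly unstable* otherwise; `srpd > 1.05` is
flagged as anomalous (post-exposure absorbance gain). Two corrections:

- *linear in T* (legacy): `A ← max(A + log10(srpd), 0)` — an absolute
  translation, independent of the hybrid amplitude;
- *case-dependent* (default): `A ← A · g(srpd)` with
  `g = clip(srpd, threshold, 1)`; `g` is pluggable for product-specific
  behaviour.

Both reduce to the identity without degradation and can only lower the
protection factors when `srpd ≤ 1`.

**Protection factors.** Discrete 1 nm sums
`PF = Σ E·S·Δλ / Σ E·S·10^(−max(A,0))·Δλ`, with the CIE erythema closed
form and the full 290–400 nm band for SPF, and PPD weighting over
320–400 nm for UVA-PF. The packaged PPD and source (SSR-like) spectra
are smooth synthetic stand-ins, clearly labelled as such; both are
injectable, and every result that matters end-to-end is invariant to the
choice because the synthetic generator and the pipeline share the same
weighting. Measured 1 nm-vs-0.1 nm quadrature agreement: better than
0.5 % for smooth spectra with peak absorbance ≤ 1.2, degrading to ~1.5 %
near SPF 70 (reported, not hidden, by the tests).

**Calibration.** Power-law reading `pf_cal = pf_raw^c_led · e^b` with
`c_led = 0.8695` (legacy) or `0.9174` and `b = 0.164`; a purely
multiplicative mode is available behind a switch. Inputs below 1 are
rejected.

**Panels.** Geometric mean of per-volunteer factors; the c-statistic is
`100·(e^hw − 1)` with `hw` the two-sided 95 % t-interval half-width of
the mean ln PF, flagged above 17 %. Standard-sunscreen acceptance ranges
are packaged for P5 and P8 (inclusive bounds); other standards are
user-suppliable.

## Ring-study validation

The balanced factorial layout assigns, per product group of 4 products ×
2 duplicates, the factors panel, in vivo technician and in vitro
technician as mutually orthogonal ±1 contrasts (each level appears in 4
of 8 rows). This orthogonality gives a clean method-of-moments
decomposition of ln-scale results:

- per-lab factor contrasts `T_Fk` with `E[T²] = 2σ_Fk² + 2σ_r²/P`;
- within-lab least-squares residuals (P − 3 df per lab) estimate σ_r²;
- two-way lab×product mean squares give
  `σ_prod² = MS_int − σ_r²/2` and
  `σ_pers² = (MS_lab − MS_int)/P − Σσ_Fk²/2`.

Negative estimates are truncated at 0; `s_R` is the square root of the
summed variances. Unbalanced data fall back to a coarse two-component
estimate with a warning. The decomposition is hand-authored (not a
generic mixed-model fit) so the balanced closed forms are exact; it was
verified by parameter recovery on simulations (generating
`s_L,pers = 0.3`, `s_r = 0.1` recovered within 15 % relative error over
seeded replicates) and by the two-lab closed form `s_L,pers = δ/√2`.

Criteria (percent of limit; met ≤ 100, almost met ≤ 110, not met above):

1. `100·s_R,alt / s_R,ref`
2. `100·s_L,pers / AL`, AL = 0.3 ln units
3. `100·√(s_R² + var(product biases)) / s_R,ref`
4. `100·|group bias| / DL`, DL = 0.3 (0.4 for product group 2)
5. `100·sd(group biases) / CL`, CL = 0.093 (sample sd, ddof = 1)

Product bias is `ln(mean_alt / mean_ref)`; the optional bias correction
shifts ln results by +0.164 before criteria 4/5 (criteria 1–3 are
shift-invariant). The robust overall bias is an MU-Hampel M-estimate:
iteratively reweighted, standard-error-weighted location with the
three-part Hampel ψ (a = 1.5, b = 3.0, c = 4.5), cross-checked against a
grid-search minimizer of the Σρ objective.

## Synthetic data generator (scope)

The generator exists to exercise the pipeline with known ground truth,
not to emulate instrument physics:

- products are two-Gaussian absorber mixes (UVB bump 307/14 nm, UVA bump
  355/30 nm) solved by alternating bisection to hit target SPF/UVA-PF
  within 1 %; a flat profile gives closed-form factors;
- skin baselines are a monotone ITA→reflectance map with a linear
  spectral tilt — only the light/dark signal-level behaviour is modelled;
- the forward model is `R = R0·10^(−A_film)·(1 + noise)`,
  `Avt0 = A_film/path_scale`, `Avt1 = Avt0·(1 − photostability)`, so at
  zero noise the pipeline inverts it exactly and `path_scale` is
  absorbed by the hybridization scale factor;
- ring studies add independent ln-scale lab, lab×product, lab×factor and
  residual effects around true ln PF, using one root `SeedSequence` with
  per-entity spawned substreams (adding entities does not perturb
  existing draws).

## Numerical choices

- 1 nm rectangle sums for the protection-factor integrals (the field's
  convention), with the quadrature error characterized above.
- `brentq` bisection for product construction; alternating
  coordinate-wise solves, 60 iterations, 1 % relative tolerance,
  infeasible target pairs rejected with a clear error.
- MU-Hampel convergence at 1e−9 absolute change, 500-iteration cap.
- All statistics on the ln scale; sample standard deviations use
  ddof = 1 throughout.

## Limitations

- The PPD and source spectra are synthetic stand-ins; absolute SPF and
  UVA-PF values computed with them are not comparable to ISO-weighted
  values (relative and structural results are unaffected).
- Published headline precision tables cannot be recomputed because the
  per-measurement ring data are not public; validation relies on printed
  worked examples and seeded simulations.
- One printed worked value (product P6's SPF bias, 0.45) is not exactly
  reproducible from the printed 1-dp means (ln(67.1/43.0) = 0.445); the
  acceptance test allows the propagated rounding bound of the published
  means.
- The variance decomposition assumes the balanced factorial layout;
  unbalanced data get a degraded estimator with a warning, not the full
  model.
- No modelling of erythema-dose safety, instrument spectral response, or
  the ITA→reflectance relation beyond monotonicity.
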