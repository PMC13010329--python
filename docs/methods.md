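# Methods

## Chamber flux computation

Each tree sits in a two-compartment open-flow chamber: a conditioned
airstream of known CO₂ and H₂O content (defaults 445.6 ppm and
8.0 mmol mol⁻¹) is supplied at a constant molar flow, and the returned
sample stream is measured against the reference. The compartment flux is
the mass balance `F = −ṁ(C_sample − C_ref)` with both CO₂ mole fractions
converted to a dry-air basis first (`C_dry = C_wet/(1 − w/1000)`), because
transpiration dilutes the sample stream and would otherwise masquerade as
CO₂ uptake. Background fluxes are handled by two plant-free blank chambers
(one per compartment section, filled with the same substrate): the blank's
sample-minus-reference differential, measured nearest in time (within one
±90 min measurement cycle), is subtracted from the plant chamber's
differential — CO₂ on the dry basis, water vapour on the wet basis. The
subtraction order (dry first, then blank) is a convention of this package;
with blank offsets of ±0.15 ppm the difference between orders is far below
instrument noise.

Leaf-area-normalised quantities assume a well-stirred ventilated chamber
with leaf temperature equal to air temperature and no boundary-layer term:
`E = ṁ·(x_s − x_r)/(1 − x_s)/LA` (the denominator accounts for the flow
added by the vapour itself), `g_sw = E/Δw` with
`Δw = (e_sat(T_air) − e_air)/P`, and the Tetens saturation curve
`e_sat(T) = 0.6108·exp(17.27T/(T+237.3))` kPa (adequate 0–40 °C).
Saturated-chamber points (`Δw ≤ 0`) and zero-conductance WUE_i points are
masked as NaN, never zero-filled, and masked points are excluded from every
daily mean downstream.

Irregular per-chamber clocks (the instrument multiplexes chambers in ~80 min
cycles) are handled by `resample_cycle`: linear interpolation onto a common
hourly grid, with stretches between source points longer than 3 h left
missing rather than bridged.

## Carbon budget

Daily compartment rates are mean-of-valid-hours × 12.01 g mol⁻¹ × 86 400 s,
deliberately *not* trapezoidal integration: with a regular sampling grid the
mean is the unbiased estimator and it is robust to isolated masked hours.
Days with fewer than 12 valid hours (configurable) in either compartment
are flagged; flagged days contribute zero to cumulative carbon but remain
visible. The plant rate is the exact float sum of shoot and root rates, so
additivity holds to the last bit. Day boundaries are local midnight, which
aligns the budget with the nighttime reporting window (00:00–05:00).
End-of-recovery accumulation rates are per-tree OLS slopes of cumulative
carbon over the final 10 days.

## Zero-growth dendrometry

Displacement (µm) is anchored to a caliper-measured initial diameter,
converted to basal area assuming a circular cross-section, and decomposed
with a running maximum: `growth_cum = runmax(area) − area(t₀)`,
`twd = runmax − area`. The running maximum is never reset across the
drought→recovery boundary: rehydration back to a pre-drought maximum is not
growth. The first recovery day is additionally masked outright from daily
growth reports, so a same-day overshoot during bulk rehydration cannot be
booked as growth either.

Diurnal partitioning splits each day's increments at the half-open
05:00–17:00 midday window; the reported midday *rate* is the OLS slope of
the mean within-day cumulative composite against hour (the per-week
regression traces reduce to this on one week of data), while the daytime
*fraction* uses the increment sums directly, computed per window so the
partition is exact.

The Huber value uses whole basal area (over bark, the quantity a dendrometer
actually measures) as the sapwood proxy, by default with the running-max
rule so sapwood does not "shrink" when the stem dehydrates. The unit
convention is mm² sapwood per cm² leaf area, which places seedling-scale
values near the ~0.08 operating point at which maximal conductance and
daytime growth become possible; the scale is configurable because it is a
convention, not a measurement.

## Synthetic scenario generator

The generator emulates the full experiment — 6/5/4 chamber trees in
control/mild/severe treatments, 28 d drought + 35 d recovery from
2023-06-06, hourly chamber records, 10-min dendrometer traces, daily soil
water content, destructive ψ/ABA/NSC samples at six timepoints — and works
backwards from true quantities to observables, retaining the truth for
recovery tests.

Gas exchange: shoot assimilation follows a truncated sinusoid over the 15 h
photoperiod (peak 7.5 µmol m⁻² s⁻¹), minus a constant 0.5 µmol m⁻² s⁻¹ dark
respiration; root respiration is constant (5.8 × 10⁻⁸ mol s⁻¹ for a
mean-size tree). Treatment effects are daily multipliers on the whole flux
profile: mild ramps linearly to 0.45 over the drought and recovers to 0.95;
severe ramps to ~0 and recovers to 0.5, holding 0.5 for the final 10 days so
the injected end-of-recovery severe:control ratio is exactly one half — the
quantity the tail-slope recovery test checks. The chamber inversion adds the
true transpiration's vapour load and a small constant background flux
(−1.5 × 10⁻⁸ mol CO₂ s⁻¹, +3 × 10⁻⁶ mol H₂O s⁻¹, chosen to reproduce blank
offsets of +0.15 ppm and +0.03 mmol mol⁻¹ at the default 0.1 mol s⁻¹ flow)
to every chamber including the blanks. Because the background enters as a
flux, dry-basis blank subtraction cancels it exactly and the noise-free
chain returns the injected fluxes to machine precision.

Growth: daily basal-area rates of 0.58/0.28/~0 mm² d⁻¹ (drought) and
0.80/0.61/0.40 mm² d⁻¹ (recovery) for control/mild/severe, with severe
growth fading over the first 5 drought days and resuming only in the second
recovery week. A configured fraction of each day's growth (0.30 control,
0.10 mild, 0 severe) is placed in the midday window. Reversible diurnal
shrinkage (5/12/20 µm amplitude) vanishes at night, and the severe
treatment's drought contraction (up to 200 µm of diameter, releasing over
1.5 d after rewatering) is applied only while the growth envelope is flat —
together these guarantee that the running maximum at midnight equals the
injected envelope, making the zero-growth decomposition exactly invertible
on noise-free traces. Ground-truth daily growth is booked to the day of the
later reading, matching how dendrometer daily sums are formed.

Noise is per-channel Gaussian (defaults: 0.2/0.3 ppm on reference/sample
CO₂, 0.01/0.05 mmol on water, 1.5 µm dendrometer resolution) and every
tree × instrument stream draws from an independent child generator keyed by
(seed, tree id, stream), so adding a tree never perturbs existing streams.

What the generator does **not** emulate: soil–plant hydraulics (treatment
trajectories are prescribed, not mechanistic), VPD feedback on transpiration,
leaf-area dynamics, chamber leaks, instrument drift, or serially correlated
noise. Passing recovery tests therefore demonstrates the correctness of the
analysis chain under the stated statistical structure, not robustness to
every artefact of real instrument data.

## Numerical choices

- Flux-recovery error is reported as max absolute error normalised by the
  series' peak |true flux|; a pointwise ratio is unstable where the true
  flux crosses zero.
- Time-of-day windows are half-open `[start, end)` to avoid double counting
  boundary samples.
- OLS slopes require ≥ 3 points and come from `scipy.stats.linregress`.
- Treatment statistics always average within an individual first; SE is
  sd/√n across individuals and is undefined (NaN) for n = 1.
- CSV artifacts are written at 17-significant-digit precision, so write/read
  round trips are exact and identical runs are bit-identical (checked by a
  SHA-256 digest over the artifact directory in the run manifest).
- Problem sizes in the test suite (2 trees per treatment, hourly dendrometer
  traces, 20-seed recovery loops) are chosen to keep the full suite under a
  minute while leaving every estimate's sampling error well inside the
  asserted tolerances.

## Known limitations

- Stomatal conductance assumes leaf temperature equals air temperature; under
  strong radiative load this biases g_sw.
- The blank-subtraction and dilution conventions (dry basis, blank after
  drying) are one defensible ordering among several; alternatives differ at
  the sub-ppm level.
- Basal area over bark overstates sapwood area, so Huber values are an index,
  comparable within an experiment rather than across studies.
- The destructive-sample module generates treatment-level curves for
  plumbing and summary tests only; no physiology links them to the fluxes.
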