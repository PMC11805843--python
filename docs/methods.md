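# Methods

## The model and its assumptions

The package treats the proximal circulation as a linear, periodic system:
over one cardiac cycle, central aortic pressure and flow are fully described
by their Fourier harmonics, and the vascular load by the complex ratio
`Z_k = P_k / Q_k` at each harmonic (linear-velocity convention:
pressure in dyn/cm² per velocity in cm/s, so |Z| is in dyn·s/cm³).
Linearity and strict periodicity are the standard assumptions of
input-impedance analysis; beat-to-beat variability, valve-jet fluid dynamics
(the venturi pressure drop near a stenotic orifice), and regurgitant flow
are outside the model.

The inverse problem — impedance from a cuff pressure and echo scalars alone
— is underdetermined, and the method resolves it statistically: sample
candidate spectra from physiologic ranges, filter by consistency with the
measurement and with the known morphology of human pressure waveforms, and
report survivor medians. The implicit assumption is that the physiologic
prior (bounds plus waveform criteria) concentrates the surviving set near
the true spectrum; the synthetic-recovery experiments quantify how well
that holds under a Windkessel ground truth.

## Flow-waveform construction

Routine echo gives only scalars, so the systolic velocity pulse is a
synthetic shape constrained by them: v(0)=0, unique maximum `V_max` at
`t=AT`, v(ED)=0, identically zero in diastole. We use a degree-5 piecewise
polynomial — a quintic smoothstep rise on [0, AT] and a mirrored fall on
[AT, ED] — with zero first and second derivatives at 0, AT, and ED. This
is C² across the whole cycle (including the junction with the zero diastole),
non-negative by construction for every admissible (AT, ED) geometry, and has
closed-form area `V_max · ED / 2`. Earlier prototypes that interpolated
through free-height interior knots could swing negative or lose the peak
constraint for short- or long-descent geometries; the smoothstep pair is the
minimal shape that meets every stated constraint robustly, at the cost of
fixing the rise/fall asymmetry entirely through AT and ED.

The ejection duration is found by bisection on
`AVA · ∫₀^ED v dt = SV` over `(AT + 2Δt, period − 2Δt)`; the area is
monotone in ED so the solution is unique, and the optimizer matches the
trapezoidal area of the *sampled* waveform so the volume-consistency
invariant holds on the grid the rest of the pipeline uses. Tolerance
0.1 mL; infeasible targets raise an error naming the maximum achievable
volume. Default sampling is 512 samples/period (≫ the 10 Hz band that
matters for characteristic impedance); doubling it changes areas by <0.1%.

## Spectral conventions

One-sided amplitudes: harmonic 0 carries the signal mean, harmonic k ≥ 1
the peak amplitude of `a_k cos(2πk f₁ t + φ_k)`, with the Nyquist bin (when
present) carrying weight 1 rather than 2 so that decompose/reconstruct is an
exact identity. Phases live in (−π, π], ties at the branch cut resolving to
+π. A negative-mean signal is encoded as DC phase π so round trips stay
exact; physiologic signals never exercise this. Pressure–flow unit
conversion uses 1 mmHg = 1333.22 dyn/cm². The impedance ratio is undefined
where the flow amplitude vanishes (< 1e−12); such harmonics raise a flagged
error rather than propagating infinities.

## Transfer function

Central-to-brachial mapping is a per-frequency gain and phase shift applied
multiplicatively to harmonics, with gain pinned to 1 at 0 Hz (mean pressure
conserved). Device transfer functions are proprietary, so the shipped
default is a synthetic stand-in with the qualitative shape of published
upper-limb curves: amplification rising to ~1.3× at 3–5 Hz, decaying toward
unity, monotone phase lag saturating near −1.1 rad. Any tabulated curve can
replace it via a `freq_hz,gain,phase_rad` CSV. Because the synthetic
patients are generated and inverted with the *same* curve, pipeline
correctness is testable independently of the curve's absolute fidelity;
absolute brachial-waveform realism is exactly as good as the curve supplied.
Evaluation beyond the tabulated grid clamps to the last value (logged).

## Inverse search

Candidates are drawn uniformly and independently per harmonic within the
bounds after symmetric 20% widening (amplitude floors clamp at zero). Draws
come from one row-contiguous uniform block per chunk, so the candidate
stream — and hence the survivor set — is bit-identical regardless of chunk
size; fixed seed implies bit-identical results end to end. The default
desk-scale candidate count is 10⁵ (configurable upward; evaluation is
chunked at constant memory, ~8k candidates per chunk).

Filters are applied in sequence for efficiency — the vectorized cuff-match
first, the six morphology criteria on its survivors — but each criterion is
evaluated independently and the result is identical to checking all seven on
every candidate. Per-filter rejection counts are reported (morphology
counts refer to the cuff-matching subset), and a zero-survivor run is a
reported outcome with a diagnostic, not an error.

Interpretation choices fixed here, where the criteria statements leave room:

- "pressure falls after end-systole" = non-increasing from the end of
  ejection to the end of the cycle, allowing one contiguous dicrotic rise of
  at most the 3 mmHg gap (consistent with the other diastolic criteria);
- end-systole is the flow model's ejection duration — the only systole
  marker the pipeline has;
- local extrema are strict against both neighbours on the sampled grid;
  plateaus take their first sample; a flat waveform has no local maximum and
  fails the "first maximum is global" clause by convention;
- the cuff-match bound is inclusive at exactly ±2.5 mmHg;
- "peak pressure after peak flow" is strict (ties fail);
- a secondary rise with no preceding trough after the peak fails the
  dicrotic-gap clause (it cannot be bounded).

Aggregation: per-harmonic median amplitude; per-harmonic circular-median
phase (the survivor value minimizing summed absolute angular deviation,
first-index tie-break); pointwise-median central waveform. The afterload
metrics are computed from these median quantities, not as medians of
per-candidate metrics — the median spectrum is the method's single reported
"answer", and metrics of the answer are what a downstream user consumes.

In central calibration mode the extrema check is applied to the central
(pre-transfer-function) waveform against the extrema of a supplied central
pressure waveform; this isolates the transfer function's contribution to
the error budget.

## Afterload metrics

- **Characteristic impedance**: mean of the 2–10 Hz impedance amplitudes
  after a single exclusion pass dropping values > mean + 2 SD (sample SD).
  The exclusion is not iterated. If everything is excluded the untrimmed
  mean is returned with a warning.
- **Wave separation / intensity**: frequency-domain Z_c is used (both arms
  share the same flow data, so any downstream disagreement is attributable
  to the impedance estimate, not the separation constant). Wave intensity
  uses time-normalized derivatives (central differences with periodic
  wrap), SI units internally; the separated totals
  `∫dI₊ dt ≥ 0 ≥ ∫dI₋ dt` are the reported quantities (the
  separated-component integral, not the signed lobes of the net intensity),
  presented scaled ×10⁻⁴ in W·m⁻²·s⁻¹.
- **Hydraulic work**: total `T⁻¹∫pq dt`, steady `⟨p⟩⟨q⟩`, pulsatile the
  difference; by Parseval the pulsatile term equals the harmonic sum
  `½Σ|P_k||Q_k|cos Δφ_k`, which the tests verify to 1e−6 relative.

## Synthetic ground truth

Patients are generated from a three-element Windkessel
(`Z(ω) = R_c + R_p/(1 + jω R_p C)`, optional series inertance for a
four-element variant) with elements drawn from truncated normals:
R_c 90 ± 25, R_p 900 ± 180 dyn·s/cm³, time constant 1.4 ± 0.3 s — values
chosen so cohort mean pressure, pulse pressure, characteristic impedance
(tens of dyn·s/cm³) and hydraulic work (~1.2 W steady, ~0.2 W pulsatile)
land in the severe-AS clinical range. Echo scalars come from truncated
normals at severe-AS cohort means/SDs (V_max 425 ± 79 cm/s, AT
0.119 ± 0.022 s, HR 75 ± 12 bpm, SV 74 ± 27 mL, AVA 0.71 ± 0.26 cm²),
rejection-sampled for timing feasibility and for plausible implied cuff
pressures (DBP ≥ 40, SBP ≤ 220, pulse pressure ≥ 20 mmHg). The patient's
cuff values are the extrema of the noiseless brachial waveform, so a
noiseless patient is exactly self-consistent; optional additive Gaussian
noise models pressure-recording error. Flow noise is deliberately absent:
both comparison arms share the same flow data, mirroring how the method is
used.

What the generator does *not* emulate: transfer-function mismatch (the same
curve generates and inverts), non-Windkessel impedance shapes (no
distributed-tree oscillations in |Z|), beat-to-beat variability, and
echo measurement error in the scalars themselves. Passing recovery tests
therefore demonstrate the inverse machinery is correct and well-conditioned
under the stated prior — not that clinical accuracy matches any particular
cohort.

## Validation scales and numerical choices

The desk-scale validation runs 20 synthetic patients × 10⁵ candidates
(seconds per patient on one CPU); the recovery criteria are median
characteristic impedance within 15%, median steady work within 5%, and
median central-waveform RMSE under 5 mmHg, with bounds bracketing truth at
±30%. Survivor counts scale approximately linearly with the candidate
count, so wider literature bounds simply require proportionally more
candidates (the method was designed around 5×10⁸ draws; the engine streams
chunks at constant memory if driven that hard).

Other numerics: bisection tolerance 0.1 mL on volume; phase-wrap ties to
+π; waveform alignment for agreement statistics by circular
cross-correlation maximizing Pearson correlation (first maximum wins ties);
Bland–Altman limits use 1.96 × sample SD (n−1); differences are oriented
recorded − simulated; the LoA-severity score is
`100 · max(|LoA_low|, |LoA_high|) / SD(simulated)`.

## Known limitations

- The transfer function is a stand-in; absolute brachial fidelity is
  untested and an AS-specific curve would be needed for clinical claims.
- The shipped bounds table is representative, not a reproduction of any
  study's table; with wide bounds and small candidate counts, zero-survivor
  runs are expected and reported as such.
- Metrics are computed from the median spectrum/waveform; the alternative
  (median of per-candidate metrics) would differ when the survivor set is
  small or skewed.
- Backward wave intensity is noise-sensitive: it depends on the separation
  point through Z_c, and small Z_c errors move it proportionally more than
  any other metric.
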