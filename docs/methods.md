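# Model description and methods

This document describes the mathematical model implemented by
`cardioresp`: state variables, constitutive laws, control loops,
numerics, steady-state detection, and the calibration approach used for
the two packaged scenarios.

## Units

| Quantity | Unit |
|---|---|
| pressure | mmHg |
| volume | cm^3 (ml) |
| flow (instantaneous) | cm^3/s |
| flow (reported summaries) | l/min |
| resistance | mmHg·s/cm^3 |
| compliance | cm^3/mmHg |
| inertance | mmHg·s^2/cm^3 |
| gas content | ml gas / 100 ml blood (summaries), ml/ml (state) |
| gas tension | mmHg |
| ventilation | l/min BTPS |
| pump speed | rpm |
| time | s |

## State vector

The closed loop is a single autonomous ODE system with 42 states:

* 14 compartment volumes: left atrium, left ventricle, systemic
  arteries, five parallel systemic peripheral districts (upper body,
  kidney, splanchnic, left leg, right leg), systemic veins, right
  atrium, right ventricle, pulmonary arteries, pulmonary veins;
* distal aortic flow (inertial) and VAD flow (inertial);
* two first-order filters on carotid pressure (mean and pulse);
* sympathetic and vagal tone states;
* five metabolic vasodilation states (one per district);
* ventilation state, breathing phase, and respiratory-drive filter;
* arterial O2/CO2 contents, five district venous O2 contents, five
  district venous CO2 contents, alveolar O2 and CO2 tensions.

31 derived channels (chamber pressures, valve and pump flows, heart
rate, activation, intrathoracic pressure, gas exchange rates,
ventilatory pattern, …) are recomputed at output time from the states.

## Cardiac chambers

Ventricular pressure combines an activated elastance with a passive
exponential diastolic wall law:

    P(V, t) = vc(t) · Es · (V − V0) + (1 − vc(t)) · a · exp(b·V) + P_intr

where `vc ∈ [0, 1]` is the activation function, `Es` the end-systolic
elastance, and `P_intr` the intrathoracic pressure (additive, so cardiac
pressures are referenced to atmosphere but driven by thoracic swings).
Activation is a squared half-sine over the systolic interval with a
cosine relaxation tail; systolic duration scales with the square root of
the cardiac period, `T_sys = k_s · sqrt(RR)`.

Atria are passive compliances plus a late-diastolic contraction
("atrial kick") modeled as a narrow activation burst placed at a fixed
fraction of the cycle before ventricular systole.

Valves are ideal diodes: flow = ΔP/R when ΔP > 0, else 0; valve flows
are therefore non-negative by construction.

## Vascular network

Systemic arteries and both pulmonary compartments are Windkessels. The
systemic periphery is five parallel RC districts; each district
resistance is multiplied by its metabolic vasodilation state and by the
sympathetic tone contribution. Venous return from the legs passes
through collapsible segments (Starling resistor): when external muscle
pressure exceeds internal venous pressure the segment operates on its
waterfall branch. During pedalling the two legs are squeezed in
antiphase at the pedalling cadence, which produces the muscle-pump
boost to venous return.

Vessel pressure–volume laws are piecewise: linear above the unstressed
volume and exponentially collapsing below it, so transmural pressure is
continuous and monotone in volume across regimes.

Pulmonary arterial compliance stiffens with congestion: the effective
compliance decreases as mean pulmonary pressure rises, which steepens
the pulmonary pressure response during exercise.

Total blood volume is conserved exactly by construction: the 14 volume
derivatives are flows in minus flows out of each compartment and sum to
zero analytically (verified numerically to < 0.1 cm^3 drift over 60 s).

## Autonomic and metabolic control

An arterial baroreflex compares low-pass-filtered carotid pressure with
a set point; a central command term proportional to the metabolic rate
above rest adds feed-forward drive. The combined autonomic drive

    A = clip( 0.5 + k_b·(P_set_eff − P_filtered) + k_c·ΔVO2 , 0, 1 )

feeds a fast vagal withdrawal state (τ = 4 s) and a slower sympathetic
activation state (τ = 12 s). These tones set heart rate, ventricular
end-systolic elastances, arteriolar resistance, and venous unstressed
volume. The set point itself resets upward with exercise intensity
(`P_set_eff = P_set + r_g·ΔVO2`), reproducing the exercise hypertensive
response.

Local metabolic control lowers each district's arteriolar resistance
when its venous O2 content falls below a reference, with a first-order
time constant of 12 s and a district-specific floor. The exercising
legs carry most of the dilation.

## Gas transport and ventilation

O2 is carried per the Hill dissociation curve (`1.34·Hb·S(P) + α·P`
with dissolved O2 `α = 0.003 ml/dl/mmHg`); CO2 content is an affine
function of tension. Each district consumes O2 and produces CO2 at a
rate set by the exercise protocol (total body VO2 in ml/min/kg times
body mass, partitioned across districts); uptake is supply-limited with
a small tissue O2 store that buffers beat-to-beat and muscle-pump
fluctuations. Mixed venous blood is the flow-weighted sum of district
effluents. Alveolar O2 and CO2 tensions evolve with alveolar
ventilation and pulmonary capillary exchange; arterial contents
equilibrate to alveolar tensions.

Ventilatory drive is a chemoreflex on arterial CO2 plus a feed-forward
exercise term; minute ventilation follows with a first-order lag.
Breathing frequency and tidal volume are partitioned from minute
ventilation, and the breathing phase drives the intrathoracic pressure
waveform (hence the respiratory modulation of all cardiac signals).

## VAD pump

The pump static head is

    H = k_w·ω² − k_q1·Q − k_q2·Q·|Q|

in series with an inlet cannula resistance and inertance between LV
apex and ascending aorta. Flow can transiently reverse; there is no
valve in the pump path. `calibrate_vad` recovers the characteristic
coefficients from tabulated (ω, Q, H) operating points by linear least
squares and rejects degenerate designs.

## Numerics

The full system is advanced with a fixed-step classical 4th-order
Runge-Kutta scheme at dt = 0.5 ms, compiled with numba. Output is
decimated to 5 ms. There is no randomness anywhere in the model;
repeated runs are bit-identical.

## Steady-state detection and summaries

Each protocol phase integrates until consecutive 15-cardiac-cycle
windows agree to within 0.5% in cardiac output, mean arterial pressure,
wedge pressure, **and** arteriovenous O2 difference. The last criterion
matters because blood-gas stores (~1.2 l of venous and arterial blood)
equilibrate much more slowly than the hemodynamics; without it the Fick
principle (VO2 = CO · avO2) would not yet close when hemodynamics look
settled. A secondary bounded-oscillation criterion accepts phases whose
windows oscillate within a small band without drifting (respiratory and
muscle-pump rhythms alias against the averaging window).

Reported summaries are means over the final 15 cardiac cycles: heart
rate, cardiac output, mean arterial and pulmonary pressures, wedge
(≈ mean left atrial) pressure, right atrial pressure, end-diastolic and
end-systolic LV volumes, minute ventilation, arteriovenous O2
difference, transaortic (native) and pump flows, ejection fraction, and
VO2. Summary objects validate their own internal consistency
(VED > VES, CO ≈ Q_lv + Q_vad).

## Scenarios and calibration

Two scenarios ship as YAML fixtures:

* **hf** — severe dilated heart failure; protocol: rest, then a 60 s
  ramp to peak exercise at VO2 = 11.5 ml/min/kg.
* **hf-vad** — heart failure with an apical continuous-flow VAD;
  protocol: rest at 9500 rpm, peak exercise (VO2 = 15.2 ml/min/kg) at
  9500 rpm, then a speed step to 12000 rpm at fixed workload.

The two scenarios represent different patient cohorts, so chamber
properties, reflex gains, and hemoglobin differ between the files, not
just the presence of the pump. Printed clinical anchors (resting heart
rate and ejection fraction, district resistances, ventricular stiffness
coefficients, rest/peak pressures and flows) fix most parameters
directly; the remaining gains (reflex gains, metabolic gains, pump
coefficients) were calibrated once against rest and peak operating
points and then frozen. Respiratory quotient at peak (1.2) follows from
the reported ventilatory equivalents. Metabolic vasodilation gains are
set so the leg districts remain on the active branch of the control law
at both pump speeds; the pump head curve slope was chosen so the 9500-
and 12000-rpm operating points and the resting flow are simultaneously
consistent.

No parameter depends on wall-clock time, environment, or random state.
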