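# Methods

This note records the model equations' interpretation, the numerical
scheme, parameter provenance and calibration, the choices made where the
design was genuinely open, and what the simulated conditions do and do not
show.  Units are ms, μM, mV, pS and litres throughout.

## Compartments and fluxes

The bouton is a sphere of 0.122 μm³ treated as well mixed, with two
microdomains expressed through volume ratios: δ₁ = 100 (cytosol :
IP₃R-cluster microdomain), δ₂ = 10 (cytosol : ER), δ₃ = 60 (cytosol :
AZ/VGCC microdomain).  All fluxes are written per cytosolic volume; the
δ factors in the microdomain balance equations convert them to local
concentration rates.  The ER concentration is algebraic,
Ca_ER = δ₂(Ca_total − Ca_cyt + Ca_IPRn/δ₁ − Ca_AZ), evaluated each step
rather than integrated.  Because the AZ term enters this expression
without a volume weight, Ca_ER dips transiently while the AZ microdomain
holds a large Ca²⁺ load during an action potential; the flux evaluation
clamps Ca_ER (and any transiently negative substage concentration) at
zero, which is the only numerical guard applied to the continuous system.

Pump fluxes are Hill forms (PMCA: V=3.195 μM/ms, K=0.5 μM, n=2; SERCA:
V=10 μM/ms, K=0.26 μM, n=1.75); leaks are linear in their gradients.
The plasma-membrane influx Jin = 0.03115 + 0.2·[IP₃] μM/ms fixes the
true resting cytosolic Ca²⁺ near 0.064 μM (slightly below the nominal
0.1 μM initial condition, whose imbalance relaxes within seconds).

### ER–AZ coupling

J_coupling = Vc (Ca_AZ² − k̄·Ca_IPRn²)/(Ca_AZ² + Kc²), positive from AZ
to the IP₃R microdomain; presets NC (k̄ = 5, Kc = 20) and HC (k̄ = 15,
Kc = 10), Vc = 118 μM/ms.  k̄ multiplies a squared concentration and is
stored dimensionless.  The denominator is additive: a difference form
would have a pole at Ca_AZ = Kc, whereas the bidirectional pump models
this flux is patterned on saturate; the difference form remains available
behind `CouplingParams.printed_denominator` with a guard band.  High
coupling stands in for the down-regulated Ca²⁺ buffering of the diseased
terminal.

## IP₃ metabolism

The IP₃ equation uses τ_IP₃ = 1/(k3k + k5p).  The degradation and
cascade rate constants are stored as s⁻¹ converted to ms⁻¹ (the table
that lists them prints "μs⁻¹", which taken literally would give
sub-microsecond IP₃ turnover; the conversion used here yields
τ_IP₃ ≈ 0.66 s, the timescale of a slow second messenger, and is recorded
in every output manifest).  The amyloid-β drive q(t) = Aβ·e^{−r(t−t₁)}
through the G-protein/PLC cascade is implemented but defaults to
Aβ = 0 in both conditions: the disease phenotype enters through the
fitted AD parameter differences, not through an acute Aβ application.
With Aβ = 0 the cascade sits at its fixed point and IP₃ stays within a
few percent of its 0.1 μM resting value on experiment timescales.

## IP₃R gating

Four states R(0 Ca²⁺ bound), A(2), O(2), I(5).  The transition rates are
harmonic combinations of elementary binding steps (j constants) scaled by
IP₃ occupancy factors KO, KA, KI (Hill functions with amplitudes a₁, a₂,
a₃).  Two reading choices matter:

* **KI uses a₃.**  The printed occupancy table reuses a₂ in KI, but a₃
  is otherwise orphaned, carries the μM⁻⁵ units matching the five bound
  Ca²⁺ of the inactive state, and is the only occupancy amplitude that
  differs between conditions.  With a₃ the stationary open probability
  reproduces the fitted WT/AD values (0.065 / 0.422 at Ca = 1 μM,
  IP₃ = 10 μM); with a₂ both come out several-fold too high.
* **Gating ligand in the coupled model.**  The gating parameters were
  fitted to patch-clamp records in which the ligands are clamped.  If the
  channel instead reads its own cluster microdomain, a single opening
  raises that microdomain to ~27 μM within microseconds, where the
  fitted O→I rate exceeds 10³ ms⁻¹: every opening self-terminates in
  ~1 μs, the in-situ open probability collapses to ~3×10⁻⁵ in *both*
  conditions, and the disease phenotype disappears.  The coupled
  simulation therefore gates IP₃Rs on bulk cytosolic Ca²⁺ by default
  (`IP3RGatingParams.gating_ligand = "cytosol"`); the microdomain variant
  is available for comparison.  Clamped-ligand operations (stationary
  P_o, dwell times, P_o surfaces) are unaffected — they take the clamped
  value directly.

The chain satisfies detailed balance; the stationary distribution is
proportional to (1, KA·c², KO·c², KI·c⁵), which the linear-algebra solver
and the stochastic simulator are both tested against.

Two printed curiosities are implemented as printed: the inactivation
Hill exponent nI = 56.8 (an effective step function of IP₃ at
KId = 0.09 μM), and the near-vanishing AD escape rate j̃45 = 8.5×10⁻⁸
μM⁻⁵ms⁻¹ (the AD channel recovers from inactivation through O, not R).

## VGCC gating and Ca²⁺ influx

Five-state Cav2.1 chain with αᵢ(V) = αᵢ₀e^{V/kᵢ} and
βᵢ(V) = βᵢ₀e^{−V/kᵢ}.  The source prints the same exponent sign for both
directions, which would make the open fraction voltage-independent
(~0.64 at rest); the deactivation sign used here restores the
high-threshold behaviour of the underlying kinetic scheme.

Single-channel current Is = g·Po·(V − E_Ca) with g = 2.7 pS and
E_Ca = +50 mV — calibration values typical of physiological-Ca²⁺ Cav2.1
modelling (the source cites them to external work without printing
numbers).  Cluster current uses channel density N_VGCC/(AZ_area·N_AZ)
over a 25 nm cluster (area 1.963×10⁻³ μm²).  The flux conversion
J_VGCC = −I_Ca/(zF·V_eff) uses an **effective volume V_eff = 2.0×10⁻¹⁷
L**, the model's single influx-calibration knob: the per-bouton reading
(1.22×10⁻¹⁶ L) makes single-AP release ~25-fold too weak and the
AZ-microdomain reading (2.0×10⁻¹⁸ L) makes it release the entire primed
pool per AP; the default was calibrated once so that the wild-type
reference synapse (NC coupling, 35 VGCCs) has a first-pulse release
probability ≈ 0.14, and then frozen before any other protocol was
examined.  (The printed "terminal volume 1.22×10⁻⁶ L" is dimensionally
inconsistent with the 0.122 μm³ bouton and is not used.)

## Membrane

Hodgkin–Huxley currents with instantaneous Na⁺ activation (m = m∞),
gated n and h scaled by φ = 5, split active/leak conductances, and a
Ca²⁺-dependent AHP conductance gAHP·Ca/(1+Ca) in the K⁺ current.
Reversal potentials are not printed in the source; defaults are
E_Na = +55, E_K = −90, E_Cl = −70 mV.  E_Cl = −65 mV (a common default)
puts the resting state on a limit cycle — the Na⁺ window current at the
−58 mV leak equilibrium drives spontaneous ~22 Hz firing — whereas
−70 mV gives a stable rest near −59 mV and exactly one action potential
per stimulus pulse, which the protocols require.  The stimulus is a
rectangular current pulse, 1 ms × 20 μA/cm² (verified suprathreshold);
the cluster Ca²⁺ current enters the voltage balance as a depolarising
−I_Ca/Area term over the bouton surface (≈1.19 μm²), a ~10⁻² μA/cm²
perturbation.

## Vesicle cycle, sensors, refractoriness

Reserve R ⇌ docked U (kmob·Ca_cyt, kdemob), U ⇌ primed-detached V
(kpriming·Ca_cyt gated by free release sites, kunpr), V ⇌
channel-attached W (kattach·Ca_AZ, kdetach).  Sensor occupancy (m ≤ 5
synchronous, n ≤ 2 asynchronous) evolves with on-rates (5−m)·α·Ca and
(2−n)·λ·Ca and cooperative off-rates m·β·b^{m−1}, n·δ·b^{n−1};
V vesicles read Ca_cyt, W vesicles Ca_AZ, and occupancy is carried across
V⇌W transitions.  Fusion hazards: γ₂ at m = 5 (synchronous), γ₃ = a·γ₂
at n = 2 (asynchronous), γ₁ at (0,0) (spontaneous); in the deterministic
mode a state satisfying several conditions contributes to each mode in
proportion to its hazard, in the stochastic mode the branch order is
sync > async > spont.  A fused site is refractory and recovers at
kRF = 0.01 ms⁻¹ (the table's "10.34−1 ms⁻¹" entry is superseded by the
stated choice of 0.01 ms⁻¹).

Pool sizes are not printed.  Defaults: 8 release sites, fully primed at
t = 0 (RRP = V+W = 8, split by the resting attach/detach balance, so the
fast pool starts nearly empty), and a 100-vesicle reserve.  A fully
primed RRP of 8 puts the resting spontaneous fusion rate at
γ₁ × 8 ≈ 7×10⁻⁵ ms⁻¹, inside the experimentally reported
10⁻⁵–10⁻⁴ ms⁻¹ window for these synapses.  The printed kinetics imply a
much smaller *equilibrium* primed pool (~0.15 vesicle) at rest, so the
fully primed initial condition is a prepared state, not the pool
equilibrium: over a long train the RRP drains by unpriming as well as by
release, and depression is correspondingly strong.

Two execution modes share all rate definitions: deterministic mass-action
occupancy ODEs over the 6×3 sensor grid (smooth rate profiles, expected
values) and a stochastic per-vesicle jump process (event logs, trial
statistics).  Their agreement on mean cumulative release is tested
against an independently coded Monte Carlo.

## Numerical scheme

RK4 with dt = 1 μs advances the continuous state with channel states
frozen; each discrete subsystem then takes one jump-process step.  The
per-step exit probability is 1 − e^{−k_total·dt} with proportional
branching — first-order equivalent to the plain rate·dt rule (and to the
Gillespie algorithm with fixed step), but a valid probability even where
the coupled model's instantaneous rates exceed 10³ ms⁻¹.  The standalone
single-channel simulators keep the literal rate·dt rule with an enforced
(total exit rate)·dt < 0.1 guard.  State is recorded every 10 steps.
One global seed expands into per-trial seeds through a seed sequence, so
runs are replayable bit-identically and earlier trials do not reshuffle
when the trial count grows.

Release probability is scored per stimulus as vesicles released in
[onset_k, onset_{k+1}) (the final window extends one inter-pulse
interval), divided by the initial RRP.  Decay times use a tolerance band
(rate within basal + 5% of peak); cumulative Ca²⁺ is the area of the
Ca_AZ excursion above rest over the window, residual Ca²⁺ its post-peak
part.

## Problem sizes

Default protocols: single AP (120–150 ms), paired pulse (40 ms interval),
20 pulses at 20 Hz (~1.05 s), 100 trials.  The test suite exercises the
same protocols at reduced sweep sizes (4–5 VGCC counts between 10 and
120, 40–100 trials) chosen to keep the full suite within a routine
development cycle while leaving Monte-Carlo standard errors well below
the effect sizes asserted; the acceptance script uses 100 trials for the
release-probability target.

## What the simulated conditions show — and do not

The simulator reproduces, from the printed parameters: the WT/AD IP₃R
open-probability and dwell-time contrast at clamped ligands; a stable
resting state with spontaneous release in the reported window; one AP per
stimulus; Ca²⁺-clamp dose–response with rising peak rate and shrinking
latency; strong inverse dependence of the paired-pulse ratio on initial
release probability; and train depression driven by RRP depletion.

The *quantitative* disease contrast at the release level is weaker than
the source reports.  With the printed rates, ER flux through the IP₃R
cluster is a minor term next to VGCC influx at the active zone, so AD−WT
differences in single-AP release probability, PPR and residual Ca²⁺ are
a few percent — consistently signed in the mean for residual Ca²⁺ and
PPR at intermediate release probabilities, but within Monte-Carlo noise
per sweep point at practical trial counts — and the spike–release
synchrony index exceeds 0.9 in both conditions (asynchronous release is
rare at these sensor rates), leaving no measurable synchrony deficit in
AD.  These gaps are documented rather than tuned away; the acceptance
suite asserts the source's orderings as stated and reports honestly where
the printed model does not produce them.

Other known limitations: no RyR kinetics, mitochondria, presenilin ER
leak channels, spatially resolved buffered diffusion, N-/R-type VGCCs or
VGCC spatial distributions, lateral inhibition or release-site
inactivation, and no postsynaptic currents.  The synthetic conditions are
a single bouton with one IP₃R cluster (10 channels) and one effective
VGCC cluster; real terminals vary in geometry, cluster counts and vesicle
numbers far beyond this idealisation, so passing tests certify the
implementation of this model, not the biology of any particular synapse.
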