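# Methods

## Model

One cortical column is a pair of neural mass populations, pyramidal (p)
and inhibitory (i), with mean membrane potentials V_p, V_i (mV) evolving
on a membrane time constant τ = 30 ms under four currents: leak
g_L (V − E_L); recurrent AMPA-ergic excitation
β_intra ḡ_AMPA s_kp (V_k − E_AMPA); GABA-ergic inhibition
β_GABA,k ḡ_GABA s_ki (V_k − E_GABA); and, on the pyramidal population
only, a sodium-gated potassium current
I_KNa = (τ_p/C_m) ḡ_KNa w([Na]) (V_p − E_K) with gating
w = 0.37 / (1 + (38.7/[Na])^3.5).  Sodium obeys
τ_Na [Ṅa] = α_Na Q_p − Na_pump([Na]) with a cubic saturating pump that
vanishes at the 9.5 mM equilibrium; its linearised relaxation time is a
few hundred ms, the slow variable behind Up-state termination.

Firing rates are sigmoid, Q(V) = Q_max/2 (1 + tanh(π(V−θ)/(2√3 σ))) —
the hyperbolic form of a logistic with slope π/(√3 σ) — with
Q_max = 30 Hz (p) and 60 Hz (i), θ = −58.5 mV, σ = 6.7 / 6.0 mV.
Synaptic responses follow critically damped second-order kinetics
s̈ = γ²(drive − s) − 2γṡ (alpha-function impulse response peaking at
1/γ; γ_p = 0.07 ms⁻¹, γ_i = 0.0586 ms⁻¹).  The drive is N_kk′ Q_k′ with
mean synapse counts N_pp = 144, N_ip = 36, N_pi = 160, N_ii = 40 within
a column, 16/4 between columns, and 16/4 for the stimulus pathway.

**Units.** Time is in ms and potentials in mV.  Rates enter drives and
the sodium influx in ms⁻¹ (Hz/1000); synaptic gains are treated as
dimensionless (the leak gain, not printed with the other conductances,
defaults to 1 under the same convention).  Currents stay in these mixed
model units.  This bookkeeping was validated globally: with it, the
closed-form calibration reproduces the published inhibitory scaling
factors of both network layouts to three decimals at integer-Hz
Up-state targets (see below), which no alternative scaling we tried
does.

**Noise.** Independent Gaussian fluctuations are added to the recurrent
excitatory drive of each population's synapse equation (two streams per
column).  The stated 1.2 ms⁻¹ standard deviation is interpreted as the
intensity of a white process: the per-step draw has std 1.2/√dt (3.79
at dt = 0.1 ms), making the integrated fluctuation invariant under step
refinement.  The weaker per-step reading (std 1.2 at dt = 0.1 ms)
produces a filtered synaptic fluctuation of only ~2% of the drive,
which leaves the baseline parked at its stable up-state equilibrium —
no bimodality, no slow oscillation — so the white-intensity reading is
the only one consistent with the NREM regime the model is built to
show.

## Integration and ensembles

Stochastic Heun (predictor-corrector, the same noise realisation in
both stages) at dt = 0.1 ms; deterministic order 2 when noise is off
(verified against a linear oracle).  Trials run 8 s, the first 4 s are
discarded as transient, and recording defaults to every step with a
configurable decimation (analyses use 1 kHz).  Initial conditions are
uniform inside the physiological basin: V ~ U(−70, −50) mV,
Na ~ U(9, 11) mM, active synaptic responses s ~ U(0, 1) with zero
derivative.  Each trial owns a random stream spawned from the ensemble
seed, so ensembles are bit-reproducible and trial i is independent of
the ensemble size.  Trials are integrated as one vectorised array;
wall-clock cost is nearly independent of trial count up to a few
hundred trials.

## Calibration (E/I balance)

The NREM baseline (all scaling factors 1) alternates between Up and
Down states; pooled firing-rate distributions are bimodal.  Up-state
targets are the active modes of the pooled rate distributions of a
baseline ensemble — histograms with 0.25 Hz bins, Gaussian-smoothed
with a 1 Hz kernel, peaks located with a 5%-prominence criterion and
parabolic sub-bin refinement — mapped to potentials through the inverse
sigmoid.  Extraction is done in rate space rather than potential space
for two reasons: the sigmoid compresses all Down-state potentials into
near-zero rates, so the rate distribution carries an unambiguous silent
mode while the pooled potential distribution has only a broad
hyperpolarised tail; and the published factor tables are exactly
reproduced by closed-form solves at integer-Hz rate targets (23 Hz
pyramidal, 51 Hz inhibitory), identifying rate-mode extraction as the
procedure behind them.

Wake configurations upscale excitation (β_intra, β_inter ≥ 1) and pin
the noise-free fixed point back to the Up-state targets.  At such a
fixed point every synaptic response equals its steady drive
s* = N Q(V*) and sodium solves α_Na Q_p(V_p*) = Na_pump([Na]*) (unique
root by pump monotonicity, found by bracketed bisection).  Each
population's current balance is then *linear* in its inhibitory factor
and solves in closed form; the residual of the full right-hand side at
the implied state is checked below 1e-8.  The two-column solve uses the
symmetric fixed point (both columns at the same targets), which adds
the inter-column drive terms.

The coupled model's NREM baseline is the one case without a wake fixed
point to pin: there the inhibitory factors are chosen so that the
coupled system's *deterministic equilibrium* coincides with the single
column's NREM equilibrium — the inter-column excitation is compensated
exactly at steady state and the coupled columns inherit the uncoupled
baseline.  This choice reproduces the published coupled-baseline
factors (1.180 / 1.149) to all printed digits, whereas any solve
against Up-state-mode targets is linear in the scaling factors and
therefore provably cannot produce them (the published wake cells fix
the linear coefficients; extrapolating them to the baseline cell gives
~0.73 / 1.06).

**Known limitation.** With the a-priori mode estimator the simulated
active modes land at (22.3–22.9, 51.5–52.4) Hz across seeds, against
the integer (23, 51) Hz implied by the published factors.  The
pyramidal factors are insensitive (recovered within ~2%); the
inhibitory factor moves about −6% per Hz of inhibitory-mode error and
lands 4–6% below the published column.  The offset is systematic, not
sampling noise, and likely reflects unrecoverable microdetails of the
source noise implementation; the estimator was fixed before the
comparison and not adjusted toward it.

## Stimulation and evoked readouts

Stimuli are boxcar presynaptic-rate trains (default intensities 10–90
Hz in 20 Hz steps) through the long-range pathway into one column, both
populations, scaled by β_inter.  The boxcar is active on the half-open
window [onset, onset+duration); the duration is not stated anywhere in
the printed protocols and defaults to 100 ms, matching the lag at which
spontaneous activity is sampled before onset.  Random-onset mode draws
per-trial onsets uniformly over the recorded window (leaving 100 ms
before and the boxcar after), snapped to the recording grid.

Noise-free evoked runs start at the calibrated fixed point (or the
solved NREM equilibrium), so the prestimulus trace is exactly constant.
The amplitude is the rate at the offset sample (last sample strictly
inside the window) minus the sample immediately preceding onset.  The
net evoked current |E|−|I| on the pyramidal population is computed from
the recorded state trajectory; across calibrated configurations its
prestimulus value is identical by construction — the E/I-balance
contract.  Stochastic batteries record per-trial rates at the offset
sample and 100 ms before onset; their means converge to the
deterministic amplitudes as trials grow.

## Spectral analysis

Welch PSD with Hann windows and 50% overlap after mean removal, on
1-kHz-decimated rate signals; the default segment is half the recorded
window (2 s → 0.5 Hz bins on the standard protocol), the coarsest
resolution that still isolates the slow-oscillation band, with
cross-trial averaging supplying variance reduction.  Band ratios are
band-integrated power over total power on the uniform grid (tiling
bands sum to one exactly).  Bands: SO < 1 Hz (a 0.5–1 Hz variant is
available), Delta 1–4, Theta 4–7, Alpha 7–13, Beta 13–30, Gamma 30–100
Hz; the printed "3–30 Hz" Beta edge conflicts with the Alpha band and
is read as 13–30 Hz.  Mode counting on rate histograms uses the same
smoothing/prominence conventions as the calibration estimator.

## Information metrics

NMI is mutual information (bits) of the label contingency normalised by
the geometric mean of the marginal entropies, with the 0/0 (constant
labeling) convention set to 0; the implementation is cross-checked
against an independent library implementation on random labelings.
Detection pools equal numbers of spontaneous (100 ms before onset) and
evoked (offset) samples; differentiation pools evoked samples per
intensity.  Both use stratified 10-fold cross-validation; per fold,
1-D K-means (k = number of classes, random centroid initialisation, 10
restarts keeping the best inertia, seeded) is fitted on the training
folds and test samples are assigned to the nearest centroid.  Scores
are fold-averaged with a 95% CI from the t distribution (9 df).
Robustness variants swap the clusterer for a (multinomial) logistic
classifier, a two-sample t-test / one-way ANOVA (null calibration of
p-values verified on synthetic fixtures), or plug-in mutual information
between intensity and the offset response discretised into 20
equal-width bins (no bias correction; the estimator's positive bias at
independence is covered by the tests' tolerance).

## Synthetic fixtures

The fixture generators emulate the two inputs the analysis stack
consumes without the simulator: labeled Gaussian ensembles of scalar
rates (class means/SDs/sizes seeded exactly) and two-component Gaussian
mixtures of membrane potentials for mode-extraction tests.  They test
the metrics' arithmetic and the estimators' behaviour on known ground
truth; they do not carry the temporal correlations, skewed Up-state
peaks or state-dependent variance of simulated ensembles, so passing
metric tests on fixtures says nothing about the dynamics — the
acceptance layer runs the simulator itself for those claims.

## Problem sizes

The acceptance computations use a 300-trial calibration baseline (the
published pipeline used 500; modes are stable from ~100 trials),
100-trial ensembles for the phenomenology assertions and 200 trials per
class for the information orderings — sizes chosen to keep a full
verification run within minutes on one CPU while leaving every assertion
comfortably inside its stochastic margins, except the inhibitory
calibration column discussed above.
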