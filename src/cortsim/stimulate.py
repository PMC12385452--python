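"""Stimulus delivery and evoked-response readouts.

Stimuli are boxcar trains of presynaptic firing at a chosen intensity
(Hz), delivered through long-range excitatory synapses onto both
populations of one column (the perturbed column).  The standard readout
is the evoked amplitude: firing rate at stimulus offset minus the
prestimulus rate, taken from noise-free simulations started at the
(calibrated) fixed point.  The net evoked synaptic current |E| - |I| on
the pyramidal population decomposes the response into the competing
effects of recurrent upscaling (pulling: larger spontaneous currents
damp the response) and long-range upscaling (driving: larger
stimulus-borne currents amplify it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import IVP, NetworkConfig, syn_index
from .simulate import SimProtocol, TrialEnsemble, run_ensemble

__all__ = [
    "StimulusProtocol",
    "EvokedSummary",
    "stimulus_drive",
    "evoked_amplitude",
    "net_evoked_current",
    "deterministic_evoked",
    "run_stimulus_battery",
]

#: spontaneous activity is sampled this long before stimulus onset (ms)
PRESTIM_LAG = 100.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Boxcar stimulus configuration.

    intensities : presynaptic rates (Hz) of the battery
    duration : boxcar length (ms); the printed protocols shade but never
        state it, so it defaults to 100 ms, matching the lag at which
        spontaneous activity is sampled before onset
    onset : fixed onset time (ms), used when onset_mode == "fixed"
    onset_mode : "fixed" or "random" (uniform over the recorded window,
        leaving room for the prestimulus lag before and the boxcar after)
    intensity : the single intensity (Hz) a concrete run delivers
    """

    intensities: tuple = (10.0, 30.0, 50.0, 70.0, 90.0)
    duration: float = 100.0
    onset: float | None = None
    onset_mode: str = "fixed"
    intensity: float | None = None

    def __post_init__(self) -> None:
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be non-negative")
        if self.onset_mode not in ("fixed", "random"):
            raise ValueError("onset_mode must be 'fixed' or 'random'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def draw_onsets(self, protocol: SimProtocol, rngs) -> np.ndarray:
        """Per-trial onsets (ms), snapped to the recording grid."""
        grid = protocol.dt * protocol.record_every
        if self.onset_mode == "fixed":
            if self.onset is None:
                raise ValueError("fixed onset mode requires an onset time")
            onsets = np.full(len(rngs), float(self.onset))
        else:
            lo = protocol.discard + PRESTIM_LAG
            hi = protocol.total_duration - self.duration
            if hi <= lo:
                raise ValueError("recorded window too short for the stimulus")
            onsets = np.array([rng.uniform(lo, hi) for rng in rngs])
        return np.round(onsets / grid) * grid


@dataclass
class EvokedSummary:
    """Per-intensity evoked readouts of a stimulus battery.

    amplitude[(intensity, column)] : rate at offset minus prestimulus
        rate (Hz); net_current[(intensity, column)] : |E| - |I| on the
        pyramidal population at the offset sample (model units);
        baseline_net_current[column] : prestimulus |E| - |I|.
    offset_samples / prestim_samples hold the per-trial rates (Hz) of
    stochastic batteries, keyed by intensity, arrays (n_trials, n_columns).
    """

    amplitude: dict = field(default_factory=dict)
    net_current: dict = field(default_factory=dict)
    baseline_net_current: dict = field(default_factory=dict)
    offset_samples: dict = field(default_factory=dict)
    prestim_samples: dict = field(default_factory=dict)
    deterministic: bool = True


def stimulus_drive(t, protocol: StimulusProtocol, intensity: float) -> np.ndarray:
    """Boxcar presynaptic rate (Hz) at time t: intensity on [onset, onset+duration)."""
    if protocol.onset is None:
        raise ValueError("stimulus_drive requires a fixed onset")
    t = np.asarray(t, dtype=float)
    active = (t >= protocol.onset) & (t < protocol.onset + protocol.duration)
    return np.where(active, float(intensity), 0.0)


def _sample_index(ensemble: TrialEnsemble, t: float) -> int:
    grid = ensemble.protocol.dt * ensemble.protocol.record_every
    idx = int(round((t - ensemble.time[0]) / grid))
    if not 0 <= idx < len(ensemble.time):
        raise ValueError(f"sample time {t} ms outside the recorded window")
    return idx


def evoked_amplitude(ensemble: TrialEnsemble, onset: float, duration: float,
                     column: int = 0, trial: int = 0) -> float:
    """Evoked amplitude (Hz): offset sample minus the pre-onset sample.

    The offset sample is the last sample strictly inside the half-open
    stimulus window [onset, onset + duration); the prestimulus reference
    is the sample immediately preceding onset.
    """
    grid = ensemble.protocol.dt * ensemble.protocol.record_every
    rate = ensemble.rate_p[trial, column]
    i_off = _sample_index(ensemble, onset + duration - grid)
    i_pre = _sample_index(ensemble, onset - grid)
    return float(rate[i_off] - rate[i_pre])


def net_evoked_current(ensemble: TrialEnsemble, trial: int = 0,
                       column: int = 0) -> np.ndarray:
    """|E| - |I| on the pyramidal population over the recorded window.

    E collects the excitatory synaptic currents (recurrent plus
    long-range plus stimulus-borne) and I the inhibitory current, both
    evaluated from the recorded state trajectory.  Requires
    ``record_state=True`` in the protocol.
    """
    if ensemble.state is None:
        raise ValueError("net_evoked_current needs a state-recorded ensemble")
    net = ensemble.net
    syn, sc = net.params.synapse, net.scaling
    x = ensemble.state[trial, column]  # (NVAR, n_samples)
    v_p = x[IVP]
    s_pp = x[syn_index("pp")[0]]
    s_pi = x[syn_index("pi")[0]]
    s_px = x[syn_index("px")[0]]
    s_pu = x[syn_index("pu")[0]]
    exc = (np.asarray(sc.beta_intra) * syn.g_ampa * s_pp
           + np.asarray(sc.beta_inter) * syn.g_ampa * (s_px + s_pu)) * (v_p - syn.e_ampa)
    inh = np.asarray(sc.beta_gaba_p) * syn.g_gaba * s_pi * (v_p - syn.e_gaba)
    return np.abs(exc) - np.abs(inh)


def deterministic_evoked(net: NetworkConfig, x0: np.ndarray, intensity: float,
                         stim: StimulusProtocol | None = None,
                         settle: float = 500.0, post: float = 400.0,
                         dt: float = 0.1, record_every: int = 10) -> tuple[TrialEnsemble, StimulusProtocol]:
    """One noise-free stimulated trial from a fixed point.

    The run starts at ``x0`` (a calibrated or solved equilibrium), waits
    ``settle`` ms, delivers the boxcar, and records ``post`` ms beyond
    offset.  Returns the recorded trial (with state) and the concrete
    stimulus protocol used.
    """
    if stim is None:
        stim = StimulusProtocol()
    stim = replace(stim, onset=settle, onset_mode="fixed", intensity=float(intensity))
    total = settle + stim.duration + post
    proto = SimProtocol(dt=dt, total_duration=total, discard=0.0, n_trials=1,
                        seed=0, noise_on=False, record_every=record_every,
                        record_state=True)
    ens = run_ensemble(net, proto, stim=stim, x0=x0)
    return ens, stim


def run_stimulus_battery(net: NetworkConfig, stim: StimulusProtocol,
                         sim: SimProtocol, x0: np.ndarray | None = None,
                         noise: bool | None = None) -> EvokedSummary:
    """Evoked readouts for every intensity of the battery.

    Deterministic mode (noise False): one noise-free trial per intensity
    from the fixed point ``x0``, yielding amplitudes and net evoked
    currents at offset.  Stochastic mode (noise True): a full ensemble
    per intensity with per-trial onsets, recording the per-trial rate at
    the offset sample and at the prestimulus lag for both columns --
    the inputs of the information metrics.
    """
    if noise is None:
        noise = sim.noise_on
    grid = sim.dt * sim.record_every
    summary = EvokedSummary(deterministic=not noise)
    if not noise:
        if x0 is None:
            raise ValueError("deterministic batteries start from a fixed point x0")
        for intensity in stim.intensities:
            ens, used = deterministic_evoked(net, x0, intensity, stim=stim,
                                             dt=sim.dt, record_every=sim.record_every)
            nc = net.n_columns
            for col in range(nc):
                amp = evoked_amplitude(ens, used.onset, used.duration, column=col)
                summary.amplitude[(intensity, col)] = amp
                trace = net_evoked_current(ens, column=col)
                i_off = _sample_index(ens, used.onset + used.duration - grid)
                i_pre = _sample_index(ens, used.onset - grid)
                summary.net_current[(intensity, col)] = float(trace[i_off])
                summary.baseline_net_current[col] = float(trace[i_pre])
        return summary

    for intensity in stim.intensities:
        stim_i = replace(stim, intensity=float(intensity), onset_mode="random")
        ens = run_ensemble(net, sim, stim=stim_i, x0=x0)
        rate = ens.rate_p  # (nt, ncol, nrec)
        nt, nc, _ = rate.shape
        off = np.empty((nt, nc))
        pre = np.empty((nt, nc))
        for j in range(nt):
            i_off = _sample_index(ens, ens.onsets[j] + stim.duration - grid)
            i_pre = _sample_index(ens, ens.onsets[j] - PRESTIM_LAG)
            off[j] = rate[j, :, i_off]
            pre[j] = rate[j, :, i_pre]
        summary.offset_samples[intensity] = off
        summary.prestim_samples[intensity] = pre
        mean_amp = off.mean(axis=0) - pre.mean(axis=0)
        for col in range(nc):
            summary.amplitude[(intensity, col)] = float(mean_amp[col])
    return summary
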