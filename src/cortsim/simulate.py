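"""Stochastic Heun integration of the network model and trial ensembles.

Noise model
-----------
The fluctuating input is a zero-mean Gaussian drive added to the
within-column excitatory synaptic equations, drawn independently for the
p- and i-targeting equation of each column at every step.  ``noise_std``
(ms^-1) is the intensity of a white (zero-autocorrelation-time) process:
the per-step draw has standard deviation ``noise_std / sqrt(dt)`` with dt
in ms, so the integrated fluctuation is invariant under step refinement
and a 1-ms window of the discretised process carries the stated standard
deviation.  This amplitude is what sustains the noise-induced Up/Down
switching of the NREM regime; the weaker per-step reading (std equal to
``noise_std`` at dt = 0.1 ms) leaves the system parked at its stable
up-state equilibrium.

Each trial draws its own random stream from a spawned seed sequence, so
ensembles are reproducible trial-by-trial and independent of the number
of trials integrated together.  Trials are integrated as one vectorised
array, which makes the wall-clock cost of an ensemble nearly independent
of trial count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .model import (
    NVAR,
    IVP,
    IVI,
    INA,
    SYN_CHANNELS,
    NetworkConfig,
    _Compiled,
    _rhs,
    firing_rate,
    RATE_SCALE,
    syn_index,
)

__all__ = ["SimProtocol", "TrialEnsemble", "heun_step", "run_trial", "run_ensemble"]

_NOISE_CHUNK = 2000  # steps of noise drawn per trial at a time


@dataclass(frozen=True)
class SimProtocol:
    """Integration protocol.

    dt : step (ms)
    total_duration : simulated span per trial (ms)
    discard : initial transient removed before recording (ms)
    n_trials : ensemble size
    seed : root seed for the ensemble
    noise_std : white-noise intensity (ms^-1); per-step std is noise_std/sqrt(dt)
    noise_on : stochastic (True) or deterministic (False) integration
    record_every : record every k-th step (1 = full 0.1 ms resolution)
    record_state : additionally keep the full state trajectory
    """

    dt: float = 0.1
    total_duration: float = 8000.0
    discard: float = 4000.0
    n_trials: int = 500
    seed: int = 0
    noise_std: float = 1.2
    noise_on: bool = True
    record_every: int = 1
    record_state: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.discard >= self.total_duration:
            raise ValueError("discard must be shorter than total_duration")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


@dataclass
class TrialEnsemble:
    """Recorded window of a seeded trial ensemble.

    time is in ms (absolute, starting after the discarded transient);
    v_p / v_i have shape (n_trials, n_columns, n_samples).  Firing rates
    (Hz) are recomputed from the potentials through the memoryless
    sigmoid, so they are not stored twice.
    """

    time: np.ndarray
    v_p: np.ndarray
    v_i: np.ndarray
    net: NetworkConfig
    protocol: SimProtocol
    trial_seeds: list[int] = field(default_factory=list)
    onsets: np.ndarray | None = None  # per-trial stimulus onset (ms), if stimulated
    stim_intensity: float | None = None
    state: np.ndarray | None = None  # (n_trials, n_columns, NVAR, n_samples) if requested

    @property
    def n_trials(self) -> int:
        return self.v_p.shape[0]

    @property
    def sampling_rate(self) -> float:
        """Samples per second of the recorded series."""
        return 1000.0 / (self.protocol.dt * self.protocol.record_every)

    @property
    def rate_p(self) -> np.ndarray:
        return firing_rate(self.v_p, self.net.params.pyramidal)

    @property
    def rate_i(self) -> np.ndarray:
        return firing_rate(self.v_i, self.net.params.inhibitory)

    def pooled(self, which: str = "rate_p", column: int = 0) -> np.ndarray:
        """All samples of one series for one column, pooled across trials."""
        return getattr(self, which)[:, column, :].ravel()


def heun_step(x: np.ndarray, rhs: Callable[[np.ndarray], np.ndarray], dt: float,
              noise_drift: np.ndarray | None = None) -> np.ndarray:
    """One predictor-corrector (Heun) step of dx/dt = rhs(x) + noise_drift.

    The same noise realisation enters the predictor and the corrector, so
    with ``noise_drift=None`` this is the deterministic order-2 Heun
    scheme.  ``noise_drift`` must be shaped like the state (zero where no
    noise applies).
    """
    f0 = np.asarray(rhs(x))
    if noise_drift is not None:
        f0 = f0 + noise_drift
    x_pred = x + dt * f0
    f1 = np.asarray(rhs(x_pred))
    if noise_drift is not None:
        f1 = f1 + noise_drift
    x_next = x + 0.5 * dt * (f0 + f1)
    if not np.all(np.isfinite(x_next)):
        raise FloatingPointError("integration produced non-finite values")
    return x_next


# ---------------------------------------------------------------------------
# internal fused engine
# ---------------------------------------------------------------------------

def _draw_initial(rngs, n_columns: int, active_inter: bool) -> np.ndarray:
    """Uniform initial conditions inside the physiological basin.

    V ~ U(-70, -50) mV, Na ~ U(9, 11) mM, active synaptic responses
    s ~ U(0, 1) with zero derivative; inactive pathways start at rest.
    """
    nt = len(rngs)
    x = np.zeros((n_columns, NVAR, nt))
    for j, rng in enumerate(rngs):
        x[:, IVP, j] = rng.uniform(-70.0, -50.0, n_columns)
        x[:, IVI, j] = rng.uniform(-70.0, -50.0, n_columns)
        x[:, INA, j] = rng.uniform(9.0, 11.0, n_columns)
        for name in ("pp", "ip", "pi", "ii"):
            x[:, syn_index(name)[0], j] = rng.uniform(0.0, 1.0, n_columns)
        if active_inter:
            for name in ("px", "ix"):
                x[:, syn_index(name)[0], j] = rng.uniform(0.0, 1.0, n_columns)
    return x


def _integrate(net: NetworkConfig, protocol: SimProtocol, rngs: Sequence,
               stim=None, x0: np.ndarray | None = None) -> TrialEnsemble:
    c = _Compiled(net)
    dt = protocol.dt
    n_steps = int(round(protocol.total_duration / dt))
    discard_steps = int(round(protocol.discard / dt))
    rec = protocol.record_every
    nt = len(rngs)

    if x0 is None:
        x = _draw_initial(rngs, net.n_columns, active_inter=net.n_columns == 2)
    else:
        x = np.array(x0, dtype=float)
        if x.ndim == 2:
            x = np.repeat(x[:, :, None], nt, axis=2)

    # per-trial stimulus windows on the step grid
    if stim is not None:
        onsets = stim.draw_onsets(protocol, rngs)
        onset_steps = np.round(onsets / dt).astype(int)
        offset_steps = onset_steps + int(round(stim.duration / dt))
        stim_ms = stim.intensity * RATE_SCALE if stim.intensity is not None else 0.0
    else:
        onsets = None

    rec_idx = np.arange(discard_steps, n_steps, rec)
    n_rec = len(rec_idx)
    v_p = np.empty((nt, net.n_columns, n_rec))
    v_i = np.empty((nt, net.n_columns, n_rec))
    full = np.empty((nt, net.n_columns, NVAR, n_rec)) if protocol.record_state else None

    sigma = protocol.noise_std / np.sqrt(dt) if protocol.noise_on else 0.0
    dx0 = np.empty_like(x)
    dx1 = np.empty_like(x)
    noise = None
    k_rec = 0
    for step in range(n_steps):
        if protocol.noise_on:
            j = step % _NOISE_CHUNK
            if j == 0:
                n_chunk = min(_NOISE_CHUNK, n_steps - step)
                chunk = np.empty((n_chunk, net.n_columns, 2, nt))
                for t, rng in enumerate(rngs):
                    chunk[:, :, :, t] = sigma * rng.standard_normal((n_chunk, net.n_columns, 2))
            noise = chunk[j]

        if stim is not None:
            active = (onset_steps <= step) & (step < offset_steps)
            stim_now = stim_ms * active  # (nt,) broadcasts across trials
        else:
            stim_now = 0.0

        _rhs(x, c, noise, stim_now, dx0)
        x_pred = x + dt * dx0
        _rhs(x_pred, c, noise, stim_now, dx1)
        x += 0.5 * dt * (dx0 + dx1)

        # record the state at the *end* of steps landing on the grid
        if step + 1 - discard_steps >= 0 and (step + 1 - discard_steps) % rec == 0 and k_rec < n_rec:
            v_p[:, :, k_rec] = x[:, IVP].T
            v_i[:, :, k_rec] = x[:, IVI].T
            if full is not None:
                full[:, :, :, k_rec] = np.transpose(x, (2, 0, 1))
            k_rec += 1

    if not np.all(np.isfinite(x)):
        bad = [i for i in range(nt) if not np.all(np.isfinite(x[:, :, i]))]
        raise FloatingPointError(f"integration diverged in trials {bad}")

    time = rec_idx * dt  # first record falls at the end of the discard window
    return TrialEnsemble(
        time=time,
        v_p=v_p,
        v_i=v_i,
        net=net,
        protocol=protocol,
        onsets=onsets,
        stim_intensity=None if stim is None else stim.intensity,
        state=full,
    )


def run_ensemble(net: NetworkConfig, protocol: SimProtocol, stim=None,
                 x0: np.ndarray | None = None) -> TrialEnsemble:
    """Integrate ``protocol.n_trials`` independent trials.

    Per-trial random streams are spawned from ``protocol.seed`` with a
    seed sequence, so the i-th trial of an ensemble equals a single-trial
    run with the i-th spawned sequence regardless of ensemble size.
    ``x0`` optionally fixes the initial state (one state shared by all
    trials, e.g. a calibrated fixed point) instead of random initials.
    """
    ss = np.random.SeedSequence(protocol.seed)
    children = ss.spawn(protocol.n_trials)
    rngs = [np.random.default_rng(child) for child in children]
    ens = _integrate(net, protocol, rngs, stim=stim, x0=x0)
    ens.trial_seeds = [int(child.entropy) for child in children]
    return ens


def run_trial(net: NetworkConfig, protocol: SimProtocol, stim=None,
              x0: np.ndarray | None = None) -> TrialEnsemble:
    """Single-trial convenience wrapper (an ensemble with n_trials = 1)."""
    return run_ensemble(net, replace(protocol, n_trials=1), stim=stim, x0=x0)


# ---------------------------------------------------------------------------
# ensemble persistence: compressed array container + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: TrialEnsemble, path) -> None:
    """Write an ensemble to ``<path>.npz`` with a ``<path>.json`` sidecar.

    The sidecar carries the full network and protocol configuration plus
    per-trial seeds, so a saved ensemble is reproducible from metadata
    alone.
    """
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    arrays = {"time": ensemble.time, "v_p": ensemble.v_p, "v_i": ensemble.v_i}
    if ensemble.onsets is not None:
        arrays["onsets"] = ensemble.onsets
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "net": ensemble.net.to_dict(),
        "protocol": asdict(ensemble.protocol),
        "trial_seeds": ensemble.trial_seeds,
        "stim_intensity": ensemble.stim_intensity,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_ensemble(path) -> TrialEnsemble:
    """Read an ensemble written by :func:`save_ensemble`."""
    import json
    from pathlib import Path

    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    proto_doc = dict(meta["protocol"])
    return TrialEnsemble(
        time=data["time"],
        v_p=data["v_p"],
        v_i=data["v_i"],
        net=NetworkConfig.from_dict(meta["net"]),
        protocol=SimProtocol(**{k: proto_doc[k] for k in SimProtocol.__dataclass_fields__}),
        trial_seeds=list(meta.get("trial_seeds", [])),
        onsets=data["onsets"] if "onsets" in data else None,
        stim_intensity=meta.get("stim_intensity"),
    )
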