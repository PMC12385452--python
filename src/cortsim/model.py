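"""Core neural mass model of one or two coupled cortical columns.

The model describes a cortical column as a pair of interacting neural
populations -- pyramidal (p) and inhibitory (i) -- whose mean membrane
potentials evolve under leak, AMPA-ergic, GABA-ergic and (pyramidal only)
sodium-gated potassium currents.  Population firing rates are a sigmoid
function of the membrane potential, and synaptic responses follow
critically damped second-order (alpha-function) kinetics driven by
presynaptic rates.  Two columns may be coupled symmetrically through
excitatory synapses from each pyramidal population onto both populations
of the other column.  An external stimulus enters through the same kind
of long-range excitatory pathway.

Scaling factors model synaptic homeostasis across the sleep-wake cycle:
``beta_intra`` upscales recurrent (within-column) excitation,
``beta_inter`` upscales long-range (between-column and stimulus-carrying)
excitation, and ``beta_gaba_p`` / ``beta_gaba_i`` upscale inhibition onto
each population so that the wake fixed point stays pinned to the NREM
Up-state potentials (see :mod:`cortsim.calibrate`).

Units
-----
Time is in ms, potentials in mV, sodium in mM.  Firing rates are
reported in Hz at the API surface, but all synaptic drives and sodium
influx use rates in ms^-1, which keeps the drive term commensurate with
the printed noise standard deviation (ms^-1) and the sodium influx gain
(mM.ms).  Currents are in the model's mixed units (gain x response x mV);
no attempt is made to re-dimensionalise them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import yaml

__all__ = [
    "PopulationParams",
    "SynapseParams",
    "AdaptationParams",
    "Connectivity",
    "ScalingConfig",
    "ModelParams",
    "NetworkConfig",
    "ColumnState",
    "firing_rate",
    "leak_current",
    "synaptic_current",
    "kna_gate",
    "kna_current",
    "sodium_pump",
    "synaptic_kinetics_rhs",
    "network_rhs",
    "state_array",
    "NVAR",
    "IVP",
    "IVI",
    "INA",
    "SYN_CHANNELS",
    "syn_index",
]

# Hz -> ms^-1: internal rate unit used in synaptic drives and sodium influx.
RATE_SCALE = 1.0e-3

# Sigmoid slope constant: the hyperbolic form below is the logistic
# Qmax / (1 + exp(-pi (V - theta) / (sqrt(3) sigma))) rewritten with tanh.
_SIG = np.pi / (2.0 * np.sqrt(3.0))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Sigmoid rate function and membrane constants of one population.

    qmax : maximal firing rate (Hz)
    theta : potential of half-maximal rate (mV)
    sigma : inverse-gain scale of the sigmoid (mV)
    tau : membrane time constant (ms)
    e_leak : leak reversal potential (mV)
    """

    qmax: float
    theta: float
    sigma: float
    tau: float
    e_leak: float

    def __post_init__(self) -> None:
        if self.qmax <= 0 or self.sigma <= 0 or self.tau <= 0:
            raise ValueError("qmax, sigma and tau must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic gains, reversal potentials and response rate constants.

    The excitatory/inhibitory gains are dimensionless multipliers of the
    synaptic response; gamma_p / gamma_i (ms^-1) set the alpha-function
    rise time (peak at 1/gamma) of excitatory and inhibitory synapses.
    """

    g_ampa: float = 1.0
    g_gaba: float = 1.0
    e_ampa: float = 0.0
    e_gaba: float = -70.0
    gamma_p: float = 70.0e-3
    gamma_i: float = 58.6e-3

    def __post_init__(self) -> None:
        if self.gamma_p <= 0 or self.gamma_i <= 0:
            raise ValueError("synaptic rate constants must be positive")
        if self.e_gaba >= self.e_ampa:
            raise ValueError("inhibitory reversal must lie below excitatory reversal")


@dataclass(frozen=True)
class AdaptationParams:
    """Sodium-gated potassium adaptation of the pyramidal population.

    g_kna : channel conductance (mS/cm^2)
    e_k : potassium reversal (mV)
    cm : membrane capacitance (uF/cm^2)
    tau_na : sodium extrusion time constant (ms)
    alpha_na : sodium influx per unit firing rate (mM.ms)
    r_pump : pump strength (mM)
    na_eq : equilibrium sodium concentration (mM)
    """

    g_kna: float = 1.9
    e_k: float = -100.0
    cm: float = 1.0
    tau_na: float = 1.7
    alpha_na: float = 2.0
    r_pump: float = 0.09
    na_eq: float = 9.5

    def __post_init__(self) -> None:
        if min(self.g_kna, self.cm, self.tau_na, self.alpha_na, self.r_pump, self.na_eq) <= 0:
            raise ValueError("adaptation constants must be positive")
        if self.e_k >= 0:
            raise ValueError("potassium reversal must be negative")


@dataclass(frozen=True)
class Connectivity:
    """Mean synapse counts.

    n_pp .. n_ii are within-column counts (presynaptic index second:
    n_pi is the number of inhibitory synapses onto the pyramidal
    population).  n_pp_x / n_ip_x are the between-column counts and
    n_pp_stim / n_ip_stim the counts of the stimulus pathway.
    """

    n_pp: int = 144
    n_ip: int = 36
    n_pi: int = 160
    n_ii: int = 40
    n_pp_x: int = 16
    n_ip_x: int = 4
    n_pp_stim: int = 16
    n_ip_stim: int = 4

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0 or int(value) != value:
                raise ValueError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class ScalingConfig:
    """Synaptic upscaling factors (all unitless, NREM baseline = 1).

    ``beta_gaba_p`` / ``beta_gaba_i`` may be arrays to sweep many
    calibrated configurations across the trial axis of one simulation.
    """

    beta_intra: Any = 1.0
    beta_inter: Any = 1.0
    beta_gaba_p: Any = 1.0
    beta_gaba_i: Any = 1.0


@dataclass(frozen=True)
class ModelParams:
    """All biophysical constants of one cortical column."""

    pyramidal: PopulationParams = field(
        default_factory=lambda: PopulationParams(30.0, -58.5, 6.7, 30.0, -66.0)
    )
    inhibitory: PopulationParams = field(
        default_factory=lambda: PopulationParams(60.0, -58.5, 6.0, 30.0, -64.0)
    )
    synapse: SynapseParams = field(default_factory=SynapseParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    # The leak gain is not printed with the other conductances; it defaults
    # to 1 under the same dimensionless-gain convention as g_ampa / g_gaba.
    g_leak: float = 1.0


@dataclass(frozen=True)
class NetworkConfig:
    """One or two identical, symmetrically coupled cortical columns."""

    n_columns: int = 1
    params: ModelParams = field(default_factory=ModelParams)
    connectivity: Connectivity = field(default_factory=Connectivity)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)

    def __post_init__(self) -> None:
        if self.n_columns not in (1, 2):
            raise ValueError("n_columns must be 1 or 2")

    def with_scaling(self, **kwargs: Any) -> "NetworkConfig":
        return replace(self, scaling=replace(self.scaling, **kwargs))

    # -- flat config document -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkConfig":
        p = doc.get("params", {})
        params = ModelParams(
            pyramidal=PopulationParams(**p["pyramidal"]) if "pyramidal" in p else ModelParams().pyramidal,
            inhibitory=PopulationParams(**p["inhibitory"]) if "inhibitory" in p else ModelParams().inhibitory,
            synapse=SynapseParams(**p.get("synapse", {})),
            adaptation=AdaptationParams(**p.get("adaptation", {})),
            g_leak=p.get("g_leak", 1.0),
        )
        return cls(
            n_columns=doc.get("n_columns", 1),
            params=params,
            connectivity=Connectivity(**doc.get("connectivity", {})),
            scaling=ScalingConfig(**doc.get("scaling", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

IVP, IVI, INA = 0, 1, 2

#: synaptic channels of one column, in state order.  First letter is the
#: postsynaptic population; the second names the source: p/i within the
#: column, x the other column's pyramidal population, u the (unmodeled)
#: upstream stimulus population.
SYN_CHANNELS = ("pp", "ip", "pi", "ii", "px", "ix", "pu", "iu")

NVAR = 3 + 2 * len(SYN_CHANNELS)


def syn_index(channel: str) -> tuple[int, int]:
    """Indices (s, ds/dt) of a synaptic channel in the state vector."""
    c = SYN_CHANNELS.index(channel)
    return 3 + 2 * c, 4 + 2 * c


_IS = {name: 3 + 2 * c for c, name in enumerate(SYN_CHANNELS)}
_ISD = {name: 4 + 2 * c for c, name in enumerate(SYN_CHANNELS)}


@dataclass
class ColumnState:
    """Convenience view of one column's instantaneous state.

    The simulator itself works on plain arrays of shape
    ``(n_columns, NVAR, ...)``; this wrapper is for inspection and for
    building initial conditions by hand.
    """

    v_p: float
    v_i: float
    na: float
    s: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in SYN_CHANNELS})
    s_dot: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in SYN_CHANNELS})

    def to_array(self) -> np.ndarray:
        x = np.empty(NVAR)
        x[IVP], x[IVI], x[INA] = self.v_p, self.v_i, self.na
        for c in SYN_CHANNELS:
            x[_IS[c]] = self.s.get(c, 0.0)
            x[_ISD[c]] = self.s_dot.get(c, 0.0)
        return x

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ColumnState":
        return cls(
            v_p=float(x[IVP]),
            v_i=float(x[IVI]),
            na=float(x[INA]),
            s={c: float(x[_IS[c]]) for c in SYN_CHANNELS},
            s_dot={c: float(x[_ISD[c]]) for c in SYN_CHANNELS},
        )


def state_array(n_columns: int, n_trials: int | None = None) -> np.ndarray:
    """Zero-initialised state array of shape (n_columns, NVAR[, n_trials])."""
    shape = (n_columns, NVAR) if n_trials is None else (n_columns, NVAR, n_trials)
    return np.zeros(shape)


# ---------------------------------------------------------------------------
# elementary model functions
# ---------------------------------------------------------------------------

def firing_rate(v, pop: PopulationParams):
    """Population firing rate (Hz) as a sigmoid of membrane potential (mV).

    Q(V) = Qmax/2 (1 + tanh(pi (V - theta) / (2 sqrt(3) sigma))); bounded
    in (0, Qmax), equal to Qmax/2 at V = theta, strictly increasing.
    """
    return 0.5 * pop.qmax * (1.0 + np.tanh(_SIG * (np.asarray(v) - pop.theta) / pop.sigma))


def leak_current(v, pop: PopulationParams, g_leak: float = 1.0):
    """Leak current g_L (V - E_L); zero exactly at the leak reversal."""
    return g_leak * (np.asarray(v) - pop.e_leak)


def synaptic_current(v, s, beta, g, e_rev):
    """Synaptic current beta g s (V - E_rev) for one channel."""
    return beta * g * np.asarray(s) * (np.asarray(v) - e_rev)


def kna_gate(na):
    """Sodium gating factor 0.37 / (1 + (38.7 / [Na])^3.5), in (0, 0.37)."""
    na = np.asarray(na, dtype=float)
    if np.any(na <= 0):
        raise ValueError("sodium concentration must be positive")
    return 0.37 / (1.0 + (38.7 / na) ** 3.5)


def kna_current(v_p, na, adapt: AdaptationParams, tau_p: float):
    """Sodium-gated potassium current on the pyramidal population.

    I_KNa = (tau_p / C_m) g_KNa w([Na]) (V_p - E_K) with the gating factor
    w increasing in sodium; provides the slow activity-dependent
    adaptation that terminates Up states.
    """
    return (tau_p / adapt.cm) * adapt.g_kna * kna_gate(na) * (np.asarray(v_p) - adapt.e_k)


def sodium_pump(na, adapt: AdaptationParams):
    """Sodium extrusion rate (mM), zero at equilibrium, increasing in [Na].

    Na_pump = R_pump ([Na]^3/([Na]^3 + 15^3) - [Na]_eq^3/([Na]_eq^3 + 15^3)).
    """
    na = np.asarray(na, dtype=float)
    if np.any(na <= 0):
        raise ValueError("sodium concentration must be positive")
    na3 = na**3
    eq3 = adapt.na_eq**3
    return adapt.r_pump * (na3 / (na3 + 3375.0) - eq3 / (eq3 + 3375.0))


def synaptic_kinetics_rhs(s, s_dot, drive, gamma):
    """Second-order critically damped synaptic kinetics.

    Returns (ds/dt, d2s/dt2) with d2s/dt2 = gamma^2 (drive - s) -
    2 gamma ds/dt.  The impulse response is the alpha function
    gamma^2 t exp(-gamma t), peaking at t = 1/gamma; a constant drive D
    relaxes to the fixed point s = D, ds/dt = 0.
    """
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("gamma must be positive")
    s_ddot = gamma**2 * (np.asarray(drive) - np.asarray(s)) - 2.0 * gamma * np.asarray(s_dot)
    return np.asarray(s_dot), s_ddot


# ---------------------------------------------------------------------------
# full network right-hand side
# ---------------------------------------------------------------------------

class _Compiled:
    """Scalar (or per-trial array) constants extracted from a NetworkConfig.

    Pulling every attribute access out of the integration loop keeps the
    per-step cost down to plain numpy elementwise work.
    """

    __slots__ = (
        "n_columns", "qh_p", "qh_i", "kp", "ki", "theta_p", "theta_i",
        "tau_p", "tau_i", "gl", "el_p", "el_i", "g_ampa", "g_gaba",
        "e_ampa", "e_gaba", "gamma_p", "gamma_i", "kna_fac", "e_k",
        "tau_na", "alpha_na", "r_pump", "pump_eq",
        "n_pp", "n_ip", "n_pi", "n_ii", "n_pp_x", "n_ip_x", "n_pp_u", "n_ip_u",
        "b_intra", "b_inter", "b_gaba_p", "b_gaba_i",
    )

    def __init__(self, net: NetworkConfig):
        p, i = net.params.pyramidal, net.params.inhibitory
        syn, ad, con, sc = net.params.synapse, net.params.adaptation, net.connectivity, net.scaling
        self.n_columns = net.n_columns
        self.qh_p = 0.5 * p.qmax * RATE_SCALE  # half of qmax in ms^-1
        self.qh_i = 0.5 * i.qmax * RATE_SCALE
        self.kp = _SIG / p.sigma
        self.ki = _SIG / i.sigma
        self.theta_p, self.theta_i = p.theta, i.theta
        self.tau_p, self.tau_i = p.tau, i.tau
        self.gl = net.params.g_leak
        self.el_p, self.el_i = p.e_leak, i.e_leak
        self.g_ampa, self.g_gaba = syn.g_ampa, syn.g_gaba
        self.e_ampa, self.e_gaba = syn.e_ampa, syn.e_gaba
        self.gamma_p, self.gamma_i = syn.gamma_p, syn.gamma_i
        self.kna_fac = p.tau / ad.cm * ad.g_kna
        self.e_k = ad.e_k
        self.tau_na, self.alpha_na, self.r_pump = ad.tau_na, ad.alpha_na, ad.r_pump
        self.pump_eq = ad.na_eq**3 / (ad.na_eq**3 + 3375.0)
        self.n_pp, self.n_ip, self.n_pi, self.n_ii = con.n_pp, con.n_ip, con.n_pi, con.n_ii
        self.n_pp_x, self.n_ip_x = con.n_pp_x, con.n_ip_x
        self.n_pp_u, self.n_ip_u = con.n_pp_stim, con.n_ip_stim
        self.b_intra = np.asarray(sc.beta_intra)
        self.b_inter = np.asarray(sc.beta_inter)
        self.b_gaba_p = np.asarray(sc.beta_gaba_p)
        self.b_gaba_i = np.asarray(sc.beta_gaba_i)


def _rhs(x: np.ndarray, c: _Compiled, noise, stim_ms, out: np.ndarray) -> np.ndarray:
    """Time derivative of the full network state.

    x, out : (n_columns, NVAR, ...) state and derivative buffers.
    noise : None or (n_columns, 2, ...) drive fluctuation (ms^-1) added to
        the within-column excitatory drives of the p- and i-targeting
        synapse equations.
    stim_ms : presynaptic stimulus rate (ms^-1); enters column 0 only.
    """
    v_p, v_i, na = x[:, IVP], x[:, IVI], x[:, INA]

    q_p = c.qh_p * (1.0 + np.tanh(c.kp * (v_p - c.theta_p)))  # ms^-1
    q_i = c.qh_i * (1.0 + np.tanh(c.ki * (v_i - c.theta_i)))

    # --- membrane potentials ---
    s_pp, s_pi = x[:, _IS["pp"]], x[:, _IS["pi"]]
    s_ip, s_ii = x[:, _IS["ip"]], x[:, _IS["ii"]]
    s_px, s_ix = x[:, _IS["px"]], x[:, _IS["ix"]]
    s_pu, s_iu = x[:, _IS["pu"]], x[:, _IS["iu"]]

    gate = 0.37 / (1.0 + (38.7 / na) ** 3.5)
    i_kna = c.kna_fac * gate * (v_p - c.e_k)
    out[:, IVP] = -(
        c.gl * (v_p - c.el_p)
        + c.b_intra * c.g_ampa * s_pp * (v_p - c.e_ampa)
        + c.b_gaba_p * c.g_gaba * s_pi * (v_p - c.e_gaba)
        + i_kna
        + c.b_inter * c.g_ampa * (s_px + s_pu) * (v_p - c.e_ampa)
    ) / c.tau_p
    out[:, IVI] = -(
        c.gl * (v_i - c.el_i)
        + c.b_intra * c.g_ampa * s_ip * (v_i - c.e_ampa)
        + c.b_gaba_i * c.g_gaba * s_ii * (v_i - c.e_gaba)
        + c.b_inter * c.g_ampa * (s_ix + s_iu) * (v_i - c.e_ampa)
    ) / c.tau_i

    # --- sodium ---
    na3 = na**3
    pump = c.r_pump * (na3 / (na3 + 3375.0) - c.pump_eq)
    out[:, INA] = (c.alpha_na * q_p - pump) / c.tau_na

    # --- synaptic kinetics ---
    if c.n_columns == 2:
        q_p_other = q_p[::-1]
    else:
        q_p_other = 0.0
    if noise is None:
        drive_pp = c.n_pp * q_p
        drive_ip = c.n_ip * q_p
    else:
        drive_pp = c.n_pp * q_p + noise[:, 0]
        drive_ip = c.n_ip * q_p + noise[:, 1]

    gp2, gi2 = c.gamma_p**2, c.gamma_i**2
    for name, drive, g, g2 in (
        ("pp", drive_pp, c.gamma_p, gp2),
        ("ip", drive_ip, c.gamma_p, gp2),
        ("pi", c.n_pi * q_i, c.gamma_i, gi2),
        ("ii", c.n_ii * q_i, c.gamma_i, gi2),
        ("px", c.n_pp_x * q_p_other, c.gamma_p, gp2),
        ("ix", c.n_ip_x * q_p_other, c.gamma_p, gp2),
    ):
        s = x[:, _IS[name]]
        sd = x[:, _ISD[name]]
        out[:, _IS[name]] = sd
        out[:, _ISD[name]] = g2 * (drive - s) - 2.0 * g * sd

    # stimulus pathway: noise-free drive into column 0 only
    for name, count in (("pu", c.n_pp_u), ("iu", c.n_ip_u)):
        s = x[:, _IS[name]]
        sd = x[:, _ISD[name]]
        out[:, _IS[name]] = sd
        drive = np.zeros_like(s)
        drive[0] = count * stim_ms
        out[:, _ISD[name]] = gp2 * (drive - s) - 2.0 * c.gamma_p * sd
    return out


def network_rhs(state: np.ndarray, net: NetworkConfig, noise=None, stim_rate: float = 0.0):
    """Deterministic right-hand side of the network ODE/SDE drift.

    Parameters
    ----------
    state : array, shape (n_columns, NVAR[, n_trials])
        Instantaneous network state.
    net : NetworkConfig
    noise : optional array (n_columns, 2[, n_trials])
        Fluctuation (ms^-1) added to the within-column excitatory synaptic
        drives (first the p-targeting, then the i-targeting equation).
    stim_rate : float
        Stimulus presynaptic rate in Hz, delivered to column 0.

    Returns the state derivative (per ms), same shape as ``state``.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    if state.shape[0] != net.n_columns or state.shape[1] != NVAR:
        raise ValueError(f"state must have shape ({net.n_columns}, {NVAR}, ...)")
    if stim_rate < 0:
        raise ValueError("stimulus rate must be non-negative")
    c = _Compiled(net)
    out = np.empty_like(state)
    return _rhs(state, c, noise, stim_rate * RATE_SCALE, out)
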