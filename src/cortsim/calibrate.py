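"""Excitation-inhibition balance calibration.

During NREM-like activity (all scaling factors at 1) the firing rate of
each population alternates between a silent Down mode and an active Up
mode, producing a bimodal pooled rate distribution.  Wake-like
configurations are built by upscaling excitation (beta_intra /
beta_inter) and solving for the inhibitory scaling factors
(beta_gaba_p / beta_gaba_i) that place the noise-free wake fixed point
exactly at the NREM Up-state potentials.  At that fixed point every
synaptic response equals its steady drive ``s* = N Q(V*)`` and sodium
sits at the equilibrium of influx and pump, so each population's current
balance is linear in its inhibitory scaling factor and solves in closed
form.

Up-state targets are extracted in rate space: the active mode of the
pooled firing-rate distribution is located per population and mapped to
a potential through the inverse sigmoid.  (The pooled membrane-potential
distribution has a broad hyperpolarised tail rather than a clean second
mode, because the sigmoid compresses all Down-state potentials into
near-zero rates; the rate distribution is where the bimodality is
unambiguous.)

For the two-column model at the NREM baseline (beta_intra = beta_inter
= 1) there is no separate wake fixed point to pin; there the inhibitory
factors are chosen so that the coupled system's noise-free equilibrium
coincides with the single column's NREM equilibrium, i.e. the
inter-column excitation is exactly compensated and the coupled columns
inherit the uncoupled NREM steady state (see
:func:`nrem_coupled_calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq, fsolve
from scipy.signal import find_peaks

from .model import (
    INA,
    IVI,
    IVP,
    RATE_SCALE,
    _SIG,
    AdaptationParams,
    NetworkConfig,
    PopulationParams,
    firing_rate,
    kna_current,
    network_rhs,
    sodium_pump,
    state_array,
    syn_index,
)

__all__ = [
    "UpStateTargets",
    "CalibrationResult",
    "BimodalityError",
    "active_mode",
    "extract_up_state_potentials",
    "inverse_firing_rate",
    "steady_state_sodium",
    "solve_beta_gaba",
    "fixed_point_state",
    "find_fixed_point",
    "calibration_table",
    "nrem_coupled_calibration",
]


@dataclass(frozen=True)
class UpStateTargets:
    """Up-state (active-mode) potentials of the two populations (mV)."""

    v_p_star: float
    v_i_star: float
    q_p_star: float | None = None  # rate-space modes (Hz), when extracted
    q_i_star: float | None = None
    bin_width: float = 0.25
    n_trials: int = 0


@dataclass(frozen=True)
class CalibrationResult:
    """Inhibitory scaling factors pinning a fixed point to the targets."""

    beta_gaba_p: float
    beta_gaba_i: float
    na_star: float
    residual: float


class BimodalityError(ValueError):
    """Raised when a pooled distribution has no separated second mode."""


def active_mode(samples, bin_width: float = 0.25, smooth: float = 0.0,
                min_prominence_frac: float = 0.05) -> float:
    """Location of the higher mode of a bimodal sample distribution.

    Histograms the pooled samples at ``bin_width``, optionally smooths the
    counts with a Gaussian kernel of standard deviation ``smooth`` (in
    sample units), finds local maxima with prominence at least
    ``min_prominence_frac`` of the tallest bin, keeps the two most
    prominent, and returns the centre of the upper one with parabolic
    sub-bin refinement.  Raises :class:`BimodalityError` when fewer than
    two such maxima exist.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty sample set")
    lo, hi = samples.min(), samples.max()
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    dens = counts.astype(float)
    if smooth > 0:
        dens = gaussian_filter1d(dens, smooth / bin_width)
    # pad so maxima in the first/last bin are detectable
    padded = np.concatenate(([0.0], dens, [0.0]))
    peaks, props = find_peaks(padded, prominence=min_prominence_frac * dens.max())
    peaks = peaks - 1
    if len(peaks) < 2:
        raise BimodalityError(
            f"expected a bimodal distribution, found {len(peaks)} mode(s)"
        )
    order = np.argsort(props["prominences"])[::-1]
    j = int(np.sort(peaks[order[:2]])[-1])
    centre = 0.5 * (edges[j] + edges[j + 1])
    if 0 < j < len(dens) - 1:
        y0, y1, y2 = dens[j - 1], dens[j], dens[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            centre += 0.5 * (y0 - y2) / denom * bin_width
    return float(centre)


def inverse_firing_rate(q, pop: PopulationParams) -> float:
    """Membrane potential (mV) at which the sigmoid attains rate q (Hz)."""
    q = float(q)
    if not 0.0 < q < pop.qmax:
        raise ValueError("rate must lie strictly inside (0, qmax)")
    return pop.theta + np.arctanh(2.0 * q / pop.qmax - 1.0) * pop.sigma / _SIG


def extract_up_state_potentials(ensemble, column: int = 0,
                                bin_width_hz: float = 0.25,
                                smooth_hz: float = 1.0) -> UpStateTargets:
    """Up-state potentials of both populations from an NREM ensemble.

    Pools post-transient firing-rate samples across trials, locates the
    active (higher-rate) mode of each population's bimodal distribution,
    and maps it to a membrane potential through the inverse sigmoid.
    Raises :class:`BimodalityError` on ensembles without a silent mode
    (e.g. calibrated wake configurations).
    """
    q_p = active_mode(ensemble.pooled("rate_p", column), bin_width_hz, smooth_hz)
    q_i = active_mode(ensemble.pooled("rate_i", column), bin_width_hz, smooth_hz)
    p, i = ensemble.net.params.pyramidal, ensemble.net.params.inhibitory
    return UpStateTargets(
        v_p_star=inverse_firing_rate(q_p, p),
        v_i_star=inverse_firing_rate(q_i, i),
        q_p_star=q_p,
        q_i_star=q_i,
        bin_width=bin_width_hz,
        n_trials=ensemble.n_trials,
    )


def steady_state_sodium(v_p: float, adapt: AdaptationParams,
                        pop: PopulationParams | None = None) -> float:
    """Sodium concentration balancing influx and pump at a fixed potential.

    Solves alpha_Na Q_p(V_p) = Na_pump([Na]) by bracketed root finding;
    the root is unique because the pump is strictly increasing.
    """
    if pop is None:
        pop = PopulationParams(30.0, -58.5, 6.7, 30.0, -66.0)
    q = float(firing_rate(v_p, pop)) * RATE_SCALE
    influx = adapt.alpha_na * q

    def f(na):
        return influx - float(sodium_pump(na, adapt))

    lo = adapt.na_eq
    if abs(f(lo)) < 1e-14:
        return lo
    hi = 38.0
    while f(hi) > 0:
        hi *= 1.5
        if hi > 1e4:
            raise RuntimeError("failed to bracket the sodium steady state")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _steady_drives(net: NetworkConfig, targets: UpStateTargets) -> dict[str, float]:
    """Steady synaptic responses s* = N Q(V*) (ms^-1) at the targets."""
    p, i = net.params.pyramidal, net.params.inhibitory
    con = net.connectivity
    q_p = float(firing_rate(targets.v_p_star, p)) * RATE_SCALE
    q_i = float(firing_rate(targets.v_i_star, i)) * RATE_SCALE
    s = {
        "pp": con.n_pp * q_p,
        "ip": con.n_ip * q_p,
        "pi": con.n_pi * q_i,
        "ii": con.n_ii * q_i,
        "px": 0.0,
        "ix": 0.0,
        "pu": 0.0,
        "iu": 0.0,
    }
    if net.n_columns == 2:
        # symmetric fixed point: the other column sits at the same targets
        s["px"] = con.n_pp_x * q_p
        s["ix"] = con.n_ip_x * q_p
    return s


def solve_beta_gaba(targets: UpStateTargets, beta_intra: float, beta_inter: float,
                    net: NetworkConfig, residual_tol: float = 1e-8) -> CalibrationResult:
    """Closed-form inhibitory scaling factors for one scaling configuration.

    At the noise-free fixed point pinned to the targets the pyramidal and
    inhibitory current balances are each linear in their inhibitory
    scaling factor:

        beta_gaba_p = -(I_L + beta_intra I_AMPA + beta_inter I_AMPA,x
                        + I_KNa) / I_GABA_unit

    evaluated at (V_p*, V_i*, Na*), and analogously for the inhibitory
    population (which carries no adaptation current).  Inter-column terms
    appear only in the two-column configuration, whose symmetric fixed
    point places both columns at the same targets.  The returned residual
    is the max-norm of the full network derivative at the implied fixed
    point, which is zero up to round-off by construction.
    """
    if beta_intra < 0 or beta_inter < 0:
        raise ValueError("scaling factors must be non-negative")
    p, i = net.params.pyramidal, net.params.inhibitory
    syn, ad = net.params.synapse, net.params.adaptation
    gl = net.params.g_leak
    u, v = targets.v_p_star, targets.v_i_star
    s = _steady_drives(net, targets)
    na_star = steady_state_sodium(u, ad, pop=p)

    i_kna = float(kna_current(u, na_star, ad, p.tau))
    exc_p = syn.g_ampa * (u - syn.e_ampa)
    exc_i = syn.g_ampa * (v - syn.e_ampa)
    gaba_unit_p = syn.g_gaba * s["pi"] * (u - syn.e_gaba)
    gaba_unit_i = syn.g_gaba * s["ii"] * (v - syn.e_gaba)
    if gaba_unit_p == 0 or gaba_unit_i == 0:
        raise ValueError("inhibitory drive vanishes at the targets")

    beta_p = -(
        gl * (u - p.e_leak)
        + beta_intra * s["pp"] * exc_p
        + beta_inter * s["px"] * exc_p
        + i_kna
    ) / gaba_unit_p
    beta_i = -(
        gl * (v - i.e_leak)
        + beta_intra * s["ip"] * exc_i
        + beta_inter * s["ix"] * exc_i
    ) / gaba_unit_i
    if beta_p <= 0 or beta_i <= 0:
        raise RuntimeError("calibration produced a non-positive inhibitory factor")

    calibrated = net.with_scaling(
        beta_intra=beta_intra, beta_inter=beta_inter,
        beta_gaba_p=float(beta_p), beta_gaba_i=float(beta_i),
    )
    x_star = fixed_point_state(calibrated, targets, na_star=na_star)
    residual = float(np.max(np.abs(network_rhs(x_star, calibrated))))
    if residual > residual_tol:
        raise RuntimeError(f"fixed-point residual {residual:.3e} above tolerance")
    return CalibrationResult(
        beta_gaba_p=float(beta_p), beta_gaba_i=float(beta_i),
        na_star=na_star, residual=residual,
    )


def fixed_point_state(net: NetworkConfig, targets: UpStateTargets,
                      na_star: float | None = None) -> np.ndarray:
    """Full state array at the fixed point implied by the targets.

    Both columns (if two) sit at the same potentials; every synaptic
    response equals its steady drive with zero derivative.  The state is
    an exact equilibrium only when ``net.scaling`` carries factors from
    :func:`solve_beta_gaba` for the same targets.
    """
    if na_star is None:
        na_star = steady_state_sodium(targets.v_p_star, net.params.adaptation,
                                      pop=net.params.pyramidal)
    s = _steady_drives(net, targets)
    x = state_array(net.n_columns)
    x[:, IVP] = targets.v_p_star
    x[:, IVI] = targets.v_i_star
    x[:, INA] = na_star
    for name, value in s.items():
        x[:, syn_index(name)[0]] = value
    return x


def find_fixed_point(net: NetworkConfig,
                     guess: tuple[float, float] = (-57.0, -55.0)) -> np.ndarray:
    """Noise-free equilibrium of the network by 2-D root finding.

    Reduces the system to the two potentials (shared by both columns at a
    symmetric equilibrium): synaptic responses are slaved to their steady
    drives and sodium to its steady state, leaving the two membrane
    balance equations.  Used for the NREM deterministic baseline, where
    no calibration pins the equilibrium analytically.
    """

    def residual(uv):
        t = UpStateTargets(v_p_star=float(uv[0]), v_i_star=float(uv[1]))
        x = fixed_point_state(net, t)
        dx = network_rhs(x, net)
        return [float(dx[0, IVP]), float(dx[0, IVI])]

    sol, info, ok, msg = fsolve(residual, list(guess), full_output=True, xtol=1e-13)
    if ok != 1:
        raise RuntimeError(f"fixed-point search failed: {msg}")
    t = UpStateTargets(v_p_star=float(sol[0]), v_i_star=float(sol[1]))
    return fixed_point_state(net, t)


def nrem_coupled_calibration(net: NetworkConfig,
                             guess: tuple[float, float] = (-57.0, -55.0)) -> CalibrationResult:
    """Inhibitory factors keeping the coupled columns at the NREM baseline.

    At beta_intra = beta_inter = 1 the NREM state is oscillatory, so
    there is no wake fixed point to pin to Up-state modes.  Instead the
    inter-column excitation is compensated exactly at steady state: the
    factors solve the symmetric two-column balance with targets at the
    *single column's* noise-free NREM equilibrium, so the coupled system
    inherits the uncoupled NREM steady state (and with it the NREM
    regime's dynamics).
    """
    if net.n_columns != 2:
        raise ValueError("requires a two-column configuration")
    single = NetworkConfig(
        n_columns=1, params=net.params, connectivity=net.connectivity,
    )
    x_eq = find_fixed_point(single, guess=guess)
    targets = UpStateTargets(v_p_star=float(x_eq[0, IVP]), v_i_star=float(x_eq[0, IVI]))
    return solve_beta_gaba(targets, 1.0, 1.0, net)


def calibration_table(targets: UpStateTargets, configs, net: NetworkConfig) -> dict:
    """Calibrate a grid of (beta_intra, beta_inter) configurations.

    Returns a JSON-ready mapping keyed by ``"intra=<a>,inter=<b>"``.  The
    two-column NREM baseline (both factors at 1) is dispatched to
    :func:`nrem_coupled_calibration`; every other cell uses the
    closed-form Up-state solve.
    """
    out = {}
    for beta_intra, beta_inter in configs:
        if net.n_columns == 2 and beta_intra == 1 and beta_inter == 1:
            res = nrem_coupled_calibration(net)
        else:
            res = solve_beta_gaba(targets, beta_intra, beta_inter, net)
        out[f"intra={beta_intra:g},inter={beta_inter:g}"] = {
            "n_columns": net.n_columns,
            "beta_intra": beta_intra,
            "beta_inter": beta_inter,
            "beta_gaba_p": res.beta_gaba_p,
            "beta_gaba_i": res.beta_gaba_i,
            "na_star": res.na_star,
            "residual": res.residual,
        }
    return out
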