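"""Exact stochastic simulation of single-photon responses (quantum bumps).

Discrete species follow the Gillespie stochastic simulation algorithm.
Calcium is the one fast, high-copy variable and is treated as a continuous
concentration obeying

    dCa/dt = k_ca_in * C_open * ca_ext - gamma_ca * (Ca - ca_eq),

integrated exactly (the ODE is linear at fixed open-channel count) between
discrete events.  While calcium is moving, the event clock is advanced in
micro-steps of at most ``micro_dt`` so that Ca-dependent propensities are
refreshed; within each micro-step propensities are constant and the next
event time is sampled from the exact exponential law, so a network with no
calcium coupling reduces to the textbook exact SSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .kinetics import ParameterSet, ReactionNetwork

__all__ = [
    "QBTrace",
    "QBEnsemble",
    "CompiledNetwork",
    "compile_network",
    "simulate_qb",
    "simulate_ensemble",
    "derive_seed",
]

DEFAULT_T_MAX = 500.0  # ms; generous tail for long-latency bumps
DEFAULT_DT_RECORD = 0.5  # ms
DEFAULT_MICRO_DT = 0.01  # ms cap on propensity-refresh interval while Ca moves

_SEED_MASK = 0x7FFFFFFF


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-trial / per-vertex seed: base XOR a multiplicative hash."""
    h = ((index + 1) * 2654435761) & 0xFFFFFFFF
    return (base_seed ^ h) & _SEED_MASK


@dataclass(frozen=True)
class QBTrace:
    """One simulated single-photon response sampled on a regular grid."""

    time_ms: np.ndarray
    open_channels: np.ndarray
    ca: np.ndarray
    n_events: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.open_channels < 0) or np.any(self.ca < 0):
            raise ValueError("trace contains negative counts or concentrations")

    def to_tsv(self, path) -> None:
        arr = np.column_stack([self.time_ms, self.open_channels, self.ca])
        np.savetxt(
            path, arr, delimiter="\t", header="time_ms\topen_channels\tCa",
            comments="", fmt=["%.3f", "%d", "%.6g"],
        )


@dataclass(frozen=True)
class QBEnsemble:
    """Trials of the same genotype on a shared time grid.

    ``open_channels`` is (n_trials, n_times); ``ca`` likewise (float32).
    ``decay_times`` holds the time of the last discrete event of each trial
    (used by distributional oracles on reduced networks).
    """

    time_ms: np.ndarray
    open_channels: np.ndarray
    ca: np.ndarray
    params: ParameterSet
    seeds: np.ndarray
    decay_times: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.open_channels.shape[0]

    def trace(self, i: int) -> QBTrace:
        return QBTrace(
            self.time_ms,
            self.open_channels[i].astype(np.int64),
            self.ca[i].astype(float),
            n_events=-1,
            seed=int(self.seeds[i]),
        )


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array view of a ReactionNetwork consumed by the jitted kernel."""

    stoich: np.ndarray          # (R, S) int64
    reactant_idx: np.ndarray    # (R, 2) int64, -1 padding
    reactant_ord: np.ndarray    # (R, 2) int64
    rate: np.ndarray            # (R,) float64
    hill_sp: np.ndarray         # (R,) int64, -1 if no activator Hill factor
    hill_K: np.ndarray
    hill_m: np.ndarray
    ca_lin: np.ndarray          # (R,) int8
    fb_tag: np.ndarray          # (R,) int8: 0 none, 1 fp, 2 fn
    fb_const: np.ndarray        # (kp, mp, gain_p, kn, mn, gain_n)
    ca_const: np.ndarray        # (influx_per_open, gamma_ca, ca_eq)
    bstar_idx: int
    c_open_idx: int
    init_counts: np.ndarray


def compile_network(
    network: ReactionNetwork, init_counts: np.ndarray | None = None
) -> CompiledNetwork:
    """Pack a declarative network into the flat arrays the kernel consumes.

    Reduced networks (e.g. a single decay reaction used as a distributional
    oracle) may omit the calcium constants and the phototransduction species;
    calcium then stays frozen at zero and feedback multipliers at one.
    ``init_counts`` overrides the resting initial state.
    """
    n_r, n_s = len(network.reactions), len(network.species)
    stoich = np.zeros((n_r, n_s), dtype=np.int64)
    reactant_idx = np.full((n_r, 2), -1, dtype=np.int64)
    reactant_ord = np.zeros((n_r, 2), dtype=np.int64)
    rate = np.empty(n_r)
    hill_sp = np.full(n_r, -1, dtype=np.int64)
    hill_K = np.ones(n_r)
    hill_m = np.ones(n_r)
    ca_lin = np.zeros(n_r, dtype=np.int8)
    fb_tag = np.zeros(n_r, dtype=np.int8)
    fb = network.feedback
    for r, rxn in enumerate(network.reactions):
        for sp, delta in rxn.stoich.items():
            stoich[r, network.species_index(sp)] = delta
        for j, (sp, order) in enumerate(rxn.reactants):
            reactant_idx[r, j] = network.species_index(sp)
            reactant_ord[r, j] = order
        rate[r] = network.params[rxn.rate_key]
        if rxn.activator_hill is not None:
            sp, k_key, m_key = rxn.activator_hill
            hill_sp[r] = network.species_index(sp)
            hill_K[r] = network.params[k_key]
            hill_m[r] = network.params[m_key]
        ca_lin[r] = 1 if rxn.ca_linear else 0
        if rxn.feedback == "fp" and rxn.name in fb.modulates.get("fp", ()):
            fb_tag[r] = 1
        elif rxn.feedback == "fn" and rxn.name in fb.modulates.get("fn", ()):
            fb_tag[r] = 2
    p = network.params
    if all(k in p for k in ("k_ca_in", "ca_ext", "gamma_ca", "ca_eq")):
        ca_const = np.array([p["k_ca_in"] * p["ca_ext"], p["gamma_ca"], p["ca_eq"]])
    else:
        ca_const = np.array([0.0, 1.0, 0.0])  # calcium decoupled
    bstar_idx = (
        network.species_index("Bstar") if "Bstar" in network.species else 0
    )
    c_open_idx = (
        network.species_index("C_open") if "C_open" in network.species else 0
    )
    if init_counts is None:
        init_counts = network.initial_state()
    return CompiledNetwork(
        stoich=stoich,
        reactant_idx=reactant_idx,
        reactant_ord=reactant_ord,
        rate=rate,
        hill_sp=hill_sp,
        hill_K=hill_K,
        hill_m=hill_m,
        ca_lin=ca_lin,
        fb_tag=fb_tag,
        fb_const=np.array([fb.K_p, fb.m_p, fb.gain_p, fb.K_n, fb.m_n, fb.gain_n]),
        ca_const=ca_const,
        bstar_idx=bstar_idx,
        c_open_idx=c_open_idx,
        init_counts=np.asarray(init_counts, dtype=np.int64),
    )


@njit(cache=True)
def _hill(x, K, m):
    if x <= 0.0:
        return 0.0
    xm = x**m
    return xm / (xm + K**m)


@njit(cache=True)
def _ca_after(ca, dt, c_open, influx, gamma, ca_eq):
    # exact solution of dCa/dt = influx*c_open - gamma*(Ca - ca_eq) at fixed c_open
    target = ca_eq + influx * c_open / gamma
    return target + (ca - target) * np.exp(-gamma * dt)


@njit(cache=True)
def _ssa_trace(
    stoich, reactant_idx, reactant_ord, rate, hill_sp, hill_K, hill_m,
    ca_lin, fb_tag, fb_const, ca_const, bstar_idx, c_open_idx,
    init_counts, ca0, t_max, dt_record, micro_dt, seed,
    open_rec, ca_rec,
):
    np.random.seed(seed)
    n_r = stoich.shape[0]
    counts = init_counts.copy()
    ca = ca0
    influx, gamma, ca_eq = ca_const[0], ca_const[1], ca_const[2]
    kp, mp, gain_p, kn, mn, gain_n = (
        fb_const[0], fb_const[1], fb_const[2], fb_const[3], fb_const[4], fb_const[5],
    )
    t = 0.0
    n_events = 0
    t_last = 0.0
    rec_i = 0
    n_rec = open_rec.shape[0]
    # record t = 0
    open_rec[0] = counts[c_open_idx]
    ca_rec[0] = ca
    rec_i = 1
    a = np.empty(n_r)
    ca_tol = 1e-6 * (ca_eq if ca_eq > 0 else 1.0) + 1e-12
    while t < t_max:
        fp_mult = 1.0 + gain_p * _hill(ca, kp, mp)
        fn_mult = 1.0 + gain_n * _hill(float(counts[bstar_idx]), kn, mn)
        a0 = 0.0
        for r in range(n_r):
            x = rate[r]
            for j in range(2):
                si = reactant_idx[r, j]
                if si >= 0:
                    n = counts[si]
                    order = reactant_ord[r, j]
                    for q in range(order):
                        x *= max(n - q, 0)
                    if order == 2:
                        x *= 0.5
            if hill_sp[r] >= 0:
                x *= _hill(float(counts[hill_sp[r]]), hill_K[r], hill_m[r])
            if ca_lin[r] == 1:
                x *= ca
            if fb_tag[r] == 1:
                x *= fp_mult
            elif fb_tag[r] == 2:
                x *= fn_mult
            a[r] = x
            a0 += x
        c_open = counts[c_open_idx]
        ca_moving = c_open > 0 or abs(ca - ca_eq) > ca_tol
        h_cap = micro_dt if ca_moving else (t_max - t)
        if a0 > 0.0:
            tau = -np.log(np.random.random()) / a0
        else:
            tau = np.inf
        fire = tau <= h_cap
        step = tau if fire else h_cap
        if t + step > t_max:
            step = t_max - t
            fire = False
        # flush recording grid points inside (t, t+step]
        while rec_i < n_rec and rec_i * dt_record <= t + step + 1e-12:
            tg = rec_i * dt_record
            open_rec[rec_i] = c_open
            ca_rec[rec_i] = _ca_after(ca, tg - t, c_open, influx, gamma, ca_eq)
            rec_i += 1
        ca = _ca_after(ca, step, c_open, influx, gamma, ca_eq)
        t += step
        if fire:
            u = np.random.random() * a0
            acc = 0.0
            rxn = n_r - 1
            for r in range(n_r):
                acc += a[r]
                if u <= acc:
                    rxn = r
                    break
            for s in range(stoich.shape[1]):
                counts[s] += stoich[rxn, s]
            n_events += 1
            t_last = t
    while rec_i < n_rec:
        open_rec[rec_i] = counts[c_open_idx]
        ca_rec[rec_i] = ca
        rec_i += 1
    return n_events, t_last


def _run_one(compiled: CompiledNetwork, seed: int, t_max: float, dt_record: float,
             micro_dt: float):
    n_rec = int(np.floor(t_max / dt_record + 1e-9)) + 1
    open_rec = np.zeros(n_rec, dtype=np.int64)
    ca_rec = np.zeros(n_rec)
    n_events, t_last = _ssa_trace(
        compiled.stoich, compiled.reactant_idx, compiled.reactant_ord,
        compiled.rate, compiled.hill_sp, compiled.hill_K, compiled.hill_m,
        compiled.ca_lin, compiled.fb_tag, compiled.fb_const, compiled.ca_const,
        compiled.bstar_idx, compiled.c_open_idx, compiled.init_counts,
        compiled.ca_const[2], t_max, dt_record, micro_dt, seed,
        open_rec, ca_rec,
    )
    return open_rec, ca_rec, n_events, t_last


def simulate_qb(
    network: ReactionNetwork | CompiledNetwork,
    seed: int,
    t_max: float = DEFAULT_T_MAX,
    dt_record: float = DEFAULT_DT_RECORD,
    micro_dt: float = DEFAULT_MICRO_DT,
) -> QBTrace:
    """Simulate one quantum bump from a single activated metarhodopsin.

    The initial state is one M*, resting pools, calcium at its intracellular
    equilibrium.  A fixed seed yields a bit-identical trace.
    """
    if t_max <= 0 or dt_record <= 0 or micro_dt <= 0:
        raise ValueError("t_max, dt_record and micro_dt must be positive")
    compiled = network if isinstance(network, CompiledNetwork) else compile_network(network)
    open_rec, ca_rec, n_events, _ = _run_one(
        compiled, int(seed) & _SEED_MASK, t_max, dt_record, micro_dt
    )
    time_ms = np.arange(open_rec.size) * dt_record
    return QBTrace(time_ms, open_rec, ca_rec, n_events, int(seed) & _SEED_MASK)


def simulate_ensemble(
    network: ReactionNetwork | CompiledNetwork,
    n_trials: int,
    base_seed: int,
    t_max: float = DEFAULT_T_MAX,
    dt_record: float = DEFAULT_DT_RECORD,
    micro_dt: float = DEFAULT_MICRO_DT,
    params: ParameterSet | None = None,
) -> QBEnsemble:
    """Independent quantum-bump trials with seeds derived from ``base_seed``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(network, CompiledNetwork):
        compiled = network
        if params is None:
            raise ValueError("params must be given when passing a CompiledNetwork")
    else:
        compiled = compile_network(network)
        params = network.params
    n_rec = int(np.floor(t_max / dt_record + 1e-9)) + 1
    open_all = np.empty((n_trials, n_rec), dtype=np.int32)
    ca_all = np.empty((n_trials, n_rec), dtype=np.float32)
    seeds = np.empty(n_trials, dtype=np.int64)
    decay_times = np.empty(n_trials)
    for i in range(n_trials):
        seeds[i] = derive_seed(base_seed, i)
        open_rec, ca_rec, _, t_last = _run_one(
            compiled, int(seeds[i]), t_max, dt_record, micro_dt
        )
        open_all[i] = open_rec
        ca_all[i] = ca_rec
        decay_times[i] = t_last
    time_ms = np.arange(n_rec) * dt_record
    return QBEnsemble(time_ms, open_all, ca_all, params, seeds, decay_times)
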