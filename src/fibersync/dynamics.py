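"""Admissible in-degree coupled neuron ODE models.

Three interaction types, mapped onto a network's in-edges (column convention:
the input of neuron i is the i-th column of the adjacency, i.e. the coupling
sums over in-edges with multiplicity):

``gap``    electrical coupling,  dV_i = f(V_i) - a_gap * sum_j A_ji (V_i - V_j)
``chem1``  graded synapse,       dV_i = f(V_i) - a_chem * sum_j A_ji Phi(V_j) (V_i - V_s,j)
``chem2``  synaptic variable,    dV_i = f(V_i) - a_chem * sum_j A_ji s_j (V_i - V_s,j)
                                 ds_i = a_r Phi(V_i)(1 - s_i) - a_d s_i

with leak f(V) = -a_leak (V - V_rest) and sigmoid Phi centered on the
per-neuron threshold voltage.  The threshold is the equilibrium of the
steady-state linear system with Phi = 0.5 (and s = s_eq for chem2), so any
fiber-symmetric stimulus admits an exactly fiber-synchronous solution.

Units: membrane potential in mV, time in s, currents in pA with membrane
capacitance C = 1 pF absorbed into alpha_ext = 1/C (so 1 pA shifts dV/dt by
1 V/s = 1000 mV/s); the sigmoid steepness gamma is quoted in 1/V as in the
electrophysiology literature and converted internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .graphs import NeuronNetwork
from .partitioning import Partition

__all__ = [
    "ModelParams",
    "Stimulus",
    "SimulationResult",
    "MODELS",
    "rhs",
    "threshold_voltage",
    "build_stimulus",
    "integrate",
]

MODELS = ("gap", "chem1", "chem2")
MV_PER_V = 1000.0  # 1 pA / 1 pF = 1 V/s expressed in mV/s


class ConfigurationError(ValueError):
    """Model applied to an incompatible network (e.g. gap on asymmetric)."""


class DivergenceError(RuntimeError):
    def __init__(self, step: int, t: float):
        self.step = step
        super().__init__(f"non-finite state at step {step} (t = {t:.6g} s)")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and potentials shared by all neurons.

    alpha_leak [1/s] membrane leak rate; alpha_gap, alpha_chem [1/s] coupling
    rates; alpha_ext [1/pF] inverse capacitance; V_rest [mV] resting
    potential; gamma [1/V] sigmoid steepness; a_r, a_d [1/s] synaptic rise
    and decay rates; V_exc / V_inh [mV] excitatory and inhibitory reversal
    potentials.  All chemical edges are excitatory unless the edge carries an
    inhibitory sign or the presynaptic neuron is listed in
    ``inhibitory_neurons``.
    """

    alpha_leak: float = 10.0
    alpha_gap: float = 100.0
    alpha_chem: float = 100.0
    alpha_ext: float = 1.0
    V_rest: float = -37.0
    gamma: float = 125.0
    a_r: float = 1.0
    a_d: float = 5.0
    V_exc: float = 0.0
    V_inh: float = -70.0
    inhibitory_neurons: Tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("alpha_leak", "alpha_gap", "alpha_chem", "a_r", "a_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def s_eq(self) -> float:
        """Equilibrium synaptic activity with the sigmoid at 0.5."""
        return self.a_r / (self.a_r + 2.0 * self.a_d)

    @property
    def gamma_mV(self) -> float:
        return self.gamma / 1000.0

    @staticmethod
    def gamma_from_sigmoid_range(span_mV: float = 36.0) -> float:
        """Steepness [1/V] for a 0.1 -> 0.9 sigmoid swing over ``span_mV``."""
        return 2.0 * math.log(0.9 / 0.1) / (span_mV / 1000.0)


@dataclass(frozen=True)
class Stimulus:
    """External current I(t) = I_drive + I_osc sin(2 pi f t) + I_noise(t).

    The noise term is a Gaussian random walk min-max rescaled into
    [-noise_scale, +noise_scale] per run.  When ``shared_across_fiber`` is
    set, nodes of the same fiber see one common noise path, preserving the
    input symmetry of the balanced coloring.
    """

    targets: Tuple[str, ...]
    I_drive: float = 0.0
    I_osc: float = 0.0
    f: float = 0.0
    noise_scale: float = 0.0
    shared_across_fiber: bool = True
    partition: Optional[Partition] = None

    @property
    def max_amplitude(self) -> float:
        return abs(self.I_drive) + abs(self.I_osc) + abs(self.noise_scale)

    def deterministic(self, t) -> float:
        return self.I_drive + self.I_osc * np.sin(2.0 * np.pi * self.f * t)


@dataclass
class SimulationResult:
    """Trajectories on a uniform grid, aligned with ``nodes`` order."""

    t: np.ndarray
    V: np.ndarray                     # (n_samples, n) in mV
    nodes: List[str]
    model: str
    dt: float
    s: Optional[np.ndarray] = None    # (n_samples, n), chem2 only
    stim_record: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def voltage(self, node: str) -> np.ndarray:
        return self.V[:, self.nodes.index(node)]

    def window(self, last_seconds: float) -> slice:
        t0 = self.t[-1] - last_seconds
        start = int(np.searchsorted(self.t, t0 - 1e-12))
        return slice(start, len(self.t))


def build_stimulus(part: Optional[Partition], targets: Iterable[str],
                   I_drive: float = 0.0, I_osc: float = 0.0, f: float = 0.0,
                   noise_scale: float = 0.0, seed: int = 0,
                   shared_across_fiber: bool = True) -> Stimulus:
    """Construct a stimulus, warning when it would break fiber symmetry."""
    targets = tuple(sorted(str(t) for t in targets))
    if part is not None and shared_across_fiber:
        hit = {part.cell_of(t) for t in targets if t in part.mapping}
        for cell_id in hit:
            members = set(part.cells_by_id[cell_id])
            if not members.issubset(targets):
                warnings.warn(
                    f"stimulus targets only part of fiber {cell_id!r}; this "
                    f"breaks the input symmetry of the balanced coloring",
                    stacklevel=2)
    return Stimulus(targets=targets, I_drive=I_drive, I_osc=I_osc, f=f,
                    noise_scale=noise_scale,
                    shared_across_fiber=shared_across_fiber, partition=part)


# ---------------------------------------------------------------------------
# model assembly


def _in_adjacency(net: NeuronNetwork, order: Sequence[str]) -> np.ndarray:
    """M[i, j] = multiplicity of j -> i (the i-th row collects i's inputs)."""
    return net.adjacency_matrix(order=list(order)).T


def _reversal_matrix(net: NeuronNetwork, order: Sequence[str],
                     params: ModelParams) -> np.ndarray:
    """V_rev[i, j]: reversal potential seen by i from presynaptic j (mV)."""
    n = len(order)
    rev = np.full((n, n), params.V_exc)
    inh = set(params.inhibitory_neurons)
    for jj, j in enumerate(order):
        if j in inh:
            rev[:, jj] = params.V_inh
    for (tail, head), sign in net.edge_sign.items():
        if sign < 0 and tail in order and head in order:
            rev[order.index(head), order.index(tail)] = params.V_inh
    return rev


def _check_model(model: str, net: NeuronNetwork) -> None:
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; one of {MODELS}")
    if model == "gap":
        a = net.adjacency_matrix()
        if not np.allclose(a, a.T):
            raise ConfigurationError(
                "gap model requires a symmetric (undirected) edge set")


def threshold_voltage(net: NeuronNetwork, params: ModelParams, model: str,
                      I_drive: Union[float, Dict[str, float], np.ndarray] = 0.0
                      ) -> np.ndarray:
    """Equilibrium (threshold) voltages from the linearized steady state.

    Sets the model equations to zero with the sigmoid frozen at 0.5 (and the
    synaptic variable at s_eq for chem2) and solves the resulting n x n
    linear system with I_ext = I_drive.  For an isolated neuron this reduces
    to V_rest + 1000 * alpha_ext * I / alpha_leak (mV, I in pA).
    """
    _check_model(model, net)
    order = net.nodes
    n = len(order)
    M = _in_adjacency(net, order)
    if isinstance(I_drive, dict):
        I = np.array([I_drive.get(u, 0.0) for u in order])
    else:
        I = np.broadcast_to(np.asarray(I_drive, dtype=float), (n,)).copy()
    ext = MV_PER_V * params.alpha_ext * I

    A = np.zeros((n, n))
    b = np.full(n, params.alpha_leak * params.V_rest) + ext
    indeg = M.sum(axis=1)
    if model == "gap":
        A += np.diag(params.alpha_leak + params.alpha_gap * indeg)
        A -= params.alpha_gap * M
    else:
        c = 0.5 if model == "chem1" else params.s_eq
        rev = _reversal_matrix(net, order, params)
        A += np.diag(params.alpha_leak + c * params.alpha_chem * indeg)
        b += c * params.alpha_chem * (M * rev).sum(axis=1)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"steady-state system singular or ill-conditioned "
            f"(cond = {cond:.3g})")
    return np.linalg.solve(A, b)


def rhs(model: str, state: np.ndarray, t: float, net: NeuronNetwork,
        params: ModelParams, stim: Optional[Union[Stimulus, Sequence[Stimulus]]] = None,
        V_threshold: Optional[np.ndarray] = None,
        noise: Optional[np.ndarray] = None) -> np.ndarray:
    """Time derivative of the state vector.

    ``state`` has dimension n for gap/chem1 and 2n for chem2 (voltages then
    synaptic variables).  ``noise`` is the per-node noise current (pA) held
    constant over the current step.
    """
    _check_model(model, net)
    order = net.nodes
    n = len(order)
    M = _in_adjacency(net, order)
    stims = _as_stim_list(stim)
    if V_threshold is None:
        drive = _drive_vector(order, stims)
        V_threshold = threshold_voltage(net, params, model, drive)
    I = _current_vector(order, stims, t, noise)
    return _rhs_core(model, state, net=None, M=M,
                     rev=_reversal_matrix(net, order, params),
                     params=params, V_th=np.asarray(V_threshold), I=I)


def _as_stim_list(stim) -> List[Stimulus]:
    if stim is None:
        return []
    if isinstance(stim, Stimulus):
        return [stim]
    return list(stim)


def _drive_vector(order: Sequence[str], stims: List[Stimulus]) -> np.ndarray:
    I = np.zeros(len(order))
    for st in stims:
        for tgt in st.targets:
            if tgt in order:
                I[list(order).index(tgt)] += st.I_drive
    return I


def _current_vector(order: Sequence[str], stims: List[Stimulus], t: float,
                    noise: Optional[np.ndarray]) -> np.ndarray:
    I = np.zeros(len(order))
    for st in stims:
        det = st.deterministic(t)
        for tgt in st.targets:
            if tgt in order:
                I[list(order).index(tgt)] += det
    if noise is not None:
        I = I + noise
    return I


def _sigmoid(V: np.ndarray, V_th: np.ndarray, gamma_mV: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-gamma_mV * (V - V_th)))


def _rhs_core(model: str, state: np.ndarray, net, M: np.ndarray,
              rev: np.ndarray, params: ModelParams, V_th: np.ndarray,
              I: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    ext = MV_PER_V * params.alpha_ext * I
    if model == "gap":
        V = state
        indeg = M.sum(axis=1)
        dV = (-params.alpha_leak * (V - params.V_rest)
              - params.alpha_gap * (indeg * V - M @ V) + ext)
        return dV
    if model == "chem1":
        V = state
        phi = _sigmoid(V, V_th, params.gamma_mV)
        dV = (-params.alpha_leak * (V - params.V_rest)
              - params.alpha_chem * (V * (M @ phi) - (M * rev) @ phi) + ext)
        return dV
    V, s = state[:n], state[n:]
    phi = _sigmoid(V, V_th, params.gamma_mV)
    dV = (-params.alpha_leak * (V - params.V_rest)
          - params.alpha_chem * (V * (M @ s) - (M * rev) @ s) + ext)
    ds = params.a_r * phi * (1.0 - s) - params.a_d * s
    return np.concatenate([dV, ds])


# ---------------------------------------------------------------------------
# integration


def _noise_paths(stims: List[Stimulus], order: Sequence[str],
                 n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-node noise current per step: rescaled Gaussian random walks.

    One shared path per targeted fiber when the sharing flag is set (and a
    partition is attached), otherwise one independent path per target node.
    """
    paths = np.zeros((n_steps, len(order)))
    idx = {u: i for i, u in enumerate(order)}
    for st in stims:
        if st.noise_scale == 0:
            continue
        groups: Dict[str, List[str]] = {}
        if st.shared_across_fiber and st.partition is not None:
            for tgt in st.targets:
                groups.setdefault(st.partition.cell_of(tgt), []).append(tgt)
        else:
            for tgt in st.targets:
                groups[tgt] = [tgt]
        for members in groups.values():
            walk = np.cumsum(rng.standard_normal(n_steps))
            span = walk.max() - walk.min()
            if span > 0:
                walk = (walk - walk.min()) / span * 2.0 - 1.0
            walk = walk * st.noise_scale
            for tgt in members:
                if tgt in idx:
                    paths[:, idx[tgt]] += walk
    return paths


def integrate(model: str, net: NeuronNetwork, params: ModelParams,
              stim: Optional[Union[Stimulus, Sequence[Stimulus]]] = None,
              initial_state: Optional[np.ndarray] = None,
              T: float = 5.0, dt: float = 1e-4, seed: int = 0,
              record_every: int = 1) -> SimulationResult:
    """Integrate the model with classic RK4 (dt default 0.1 ms).

    With noise the scheme is the stochastic RK variant in which the random
    walk stimulus is updated once per step (piecewise constant across the
    four stages); runs are bit-reproducible for a fixed seed.  Raises
    :class:`DivergenceError` on the first non-finite state.
    """
    _check_model(model, net)
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    order = net.nodes
    n = len(order)
    M = _in_adjacency(net, order)
    rev = _reversal_matrix(net, order, params)
    stims = _as_stim_list(stim)
    V_th = threshold_voltage(net, params, model, _drive_vector(order, stims))

    dim = 2 * n if model == "chem2" else n
    if initial_state is None:
        V0 = np.full(n, params.V_rest)
        initial_state = (np.concatenate([V0, np.full(n, params.s_eq)])
                         if model == "chem2" else V0)
    state = np.asarray(initial_state, dtype=float).copy()
    if state.shape != (dim,):
        raise ValueError(f"initial state must have shape ({dim},)")

    n_steps = int(round(T / dt))
    rng = np.random.default_rng(seed)
    noise = _noise_paths(stims, order, n_steps, rng)

    # deterministic part of the stimulus, evaluated at stage times
    tgt_idx: List[Tuple[Stimulus, np.ndarray]] = []
    for st in stims:
        sel = np.array([i for i, u in enumerate(order) if u in st.targets],
                       dtype=int)
        if sel.size:
            tgt_idx.append((st, sel))

    def current(t: float, k: int) -> np.ndarray:
        I = noise[k].copy()
        for st, sel in tgt_idx:
            I[sel] += st.deterministic(t)
        return I

    def f(t: float, y: np.ndarray, k: int) -> np.ndarray:
        return _rhs_core(model, y, None, M, rev, params, V_th, current(t, k))

    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    V_out = np.empty((n_rec, n))
    s_out = np.empty((n_rec, n)) if model == "chem2" else None
    stim_out = np.empty((n_rec, n))
    rec = 0

    def record(k: int, t: float) -> None:
        nonlocal rec
        t_out[rec] = t
        V_out[rec] = state[:n]
        if s_out is not None:
            s_out[rec] = state[n:]
        stim_out[rec] = current(t, min(k, n_steps - 1))
        rec += 1

    record(0, 0.0)
    t = 0.0
    for k in range(n_steps):
        k1 = f(t, state, k)
        k2 = f(t + dt / 2, state + dt / 2 * k1, k)
        k3 = f(t + dt / 2, state + dt / 2 * k2, k)
        k4 = f(t + dt, state + dt * k3, k)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (k + 1) * dt
        if not np.all(np.isfinite(state)):
            raise DivergenceError(k + 1, t)
        if (k + 1) % record_every == 0:
            record(k + 1, t)

    return SimulationResult(t=t_out[:rec], V=V_out[:rec], nodes=list(order),
                            model=model, dt=dt,
                            s=s_out[:rec] if s_out is not None else None,
                            stim_record=stim_out[:rec], seed=seed)
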