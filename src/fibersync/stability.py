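"""Linear stability of the fiber-synchronous equilibrium.

The Jacobian of each model is evaluated at the threshold equilibrium (where
the sigmoid is exactly 0.5 and, for the synaptic-variable model, s = s_eq).
The gap-junction Jacobian -a_leak I - a_gap L is independent of the external
stimulus, so that model is stable under any drive; the chemical models feel
the stimulus indirectly through the equilibrium voltages sitting in the
off-diagonal terms, and large enough drives push an eigenvalue across zero —
the onset of the left/right voltage bifurcation seen in simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (ModelParams, MV_PER_V, _check_model, _in_adjacency,
                       _reversal_matrix, _sigmoid, threshold_voltage)
from .graphs import NeuronNetwork

__all__ = ["StabilityReport", "jacobian", "sweep_instability"]

EIG_TOL = 1e-9  # "positive" means real part above this


@dataclass
class StabilityReport:
    """Leading-eigenvalue sweep over external stimulus strength."""

    model: str
    targets: Tuple[str, ...]
    grid: np.ndarray                    # pA, sorted
    leading: np.ndarray                 # max real part per grid point
    mode_node: List[str]                # node dominating the leading mode
    threshold_pos: Optional[float]      # smallest I > 0 with instability
    threshold_neg: Optional[float]      # largest I < 0 (closest to 0)

    def threshold(self, sign: int = +1) -> Optional[float]:
        return self.threshold_pos if sign > 0 else self.threshold_neg


def jacobian(model: str, net: NeuronNetwork, params: ModelParams,
             V_threshold: np.ndarray,
             s: Optional[np.ndarray] = None) -> np.ndarray:
    """Jacobian at the given voltages (typically the threshold equilibrium).

    Shapes: n x n for gap/chem1, 2n x 2n for chem2 with state layout
    (voltages, synaptic variables).  The chem2 s defaults to s_eq.
    """
    _check_model(model, net)
    order = net.nodes
    n = len(order)
    M = _in_adjacency(net, order)
    V = np.asarray(V_threshold, dtype=float)
    if V.shape != (n,):
        raise ValueError(f"V_threshold must have shape ({n},)")
    if model == "gap":
        indeg = M.sum(axis=1)
        lap = np.diag(indeg) - M
        return -params.alpha_leak * np.eye(n) - params.alpha_gap * lap
    rev = _reversal_matrix(net, order, params)
    g = params.gamma_mV
    phi = np.full(n, 0.5)  # sigmoid value at the threshold equilibrium
    dphi = g * phi * (1.0 - phi)
    if model == "chem1":
        J = np.diag(-params.alpha_leak - params.alpha_chem * (M @ phi))
        J += -params.alpha_chem * M * dphi[None, :] * (V[:, None] - rev)
        return J
    s = np.full(n, params.s_eq) if s is None else np.asarray(s, dtype=float)
    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = np.diag(-params.alpha_leak - params.alpha_chem * (M @ s))
    J[:n, n:] = -params.alpha_chem * M * (V[:, None] - rev)
    J[n:, :n] = np.diag(params.a_r * dphi * (1.0 - s))
    J[n:, n:] = np.diag(-params.a_r * phi - params.a_d)
    return J


def _leading(model: str, net: NeuronNetwork, params: ModelParams,
             targets: Sequence[str], I: float) -> Tuple[float, str]:
    drive = {t: I for t in targets}
    V_th = threshold_voltage(net, params, model, drive)
    J = jacobian(model, net, params, V_th)
    vals, vecs = np.linalg.eig(J)
    i = int(np.argmax(vals.real))
    n = net.n
    comp = np.abs(vecs[:n, i]) if J.shape[0] > n else np.abs(vecs[:, i])
    return float(vals.real[i]), net.nodes[int(np.argmax(comp))]


def sweep_instability(model: str, net: NeuronNetwork, params: ModelParams,
                      targets: Sequence[str],
                      I_range: Tuple[float, float] = (0.0, 500.0),
                      step: float = 1.0,
                      refine_to: float = 0.01) -> StabilityReport:
    """Find the stimulus strength at which the first positive eigenvalue
    emerges.

    The grid is swept on both signs of ``I_range`` (mirrored); the first
    crossing on each side is refined by bisection to ``refine_to`` pA.  The
    gap model never crosses: its Jacobian does not depend on the stimulus.
    """
    targets = tuple(sorted(str(t) for t in targets))
    lo, hi = sorted(I_range)
    pos_grid = np.arange(0.0, max(hi, 0.0) + step / 2, step)
    neg_grid = (-np.arange(step, abs(min(lo, 0.0)) + step / 2, step)
                if lo < 0 else np.array([]))
    grid = np.sort(np.concatenate([neg_grid, pos_grid]))
    lead_at: Dict[float, float] = {}
    mode_at: Dict[float, str] = {}
    for I in grid:
        lam, node = _leading(model, net, params, targets, float(I))
        lead_at[float(I)] = lam
        mode_at[float(I)] = node

    def refine(a: float, b: float) -> float:
        fa, _ = _leading(model, net, params, targets, a)
        while abs(b - a) > refine_to:
            m = 0.5 * (a + b)
            fm, _ = _leading(model, net, params, targets, m)
            if (fm > EIG_TOL) == (fa > EIG_TOL):
                a, fa = m, fm
            else:
                b = m
        return 0.5 * (a + b)

    thr_pos = thr_neg = None
    outward_pos = sorted(g for g in lead_at if g >= 0)
    for a, b in zip(outward_pos[:-1], outward_pos[1:]):
        if lead_at[a] <= EIG_TOL < lead_at[b]:
            thr_pos = refine(a, b)
            break
    outward_neg = sorted((g for g in lead_at if g <= 0), reverse=True)
    for a, b in zip(outward_neg[:-1], outward_neg[1:]):
        if lead_at[a] <= EIG_TOL < lead_at[b]:
            thr_neg = refine(a, b)
            break
    leading = np.array([lead_at[float(g)] for g in grid])
    mode = [mode_at[float(g)] for g in grid]
    return StabilityReport(model=model, targets=targets, grid=grid,
                           leading=leading, mode_node=mode,
                           threshold_pos=thr_pos, threshold_neg=thr_neg)
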