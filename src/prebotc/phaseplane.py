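"""Fast-slow geometry of the reduced model in the (V, h_NaP)-plane.

Setting the voltage equation's right-hand side to zero and solving for the
slow variable gives the V-nullcline

    h(V) = -[gbar_L (V - E_L) + drive * gbar_SynE (V - E_SynE)]
           / [gbar_NaP * m_inf(V) * (V - E_Na)],

a cubic-shaped curve whose folds ("knees") gate activation: a silent unit
activates when its h rises above the left knee (the local maximum of h along
the curve), and an active unit shuts off at the right knee (the local
minimum).  Synaptic input enters as the frozen scalar ``drive`` =
sum_j w * f(V_j); excitation lowers the nullcline and its knees (fast
threshold modulation), which is how a silent low-excitability unit gets
recruited.  The h-nullcline is simply h = h_inf(V).

The intersection of the two nullclines is the unit's fixed point; its branch
position classifies the uncoupled mode: left branch -> silence, middle branch
-> bursting (unstable focus surrounded by a relaxation orbit), right branch
-> tonic depolarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .reduced import ReducedNeuronParams, h_nap_inf, m_nap_inf, tau_h_nap

__all__ = [
    "NullclineCurve",
    "KneePoint",
    "FixedPoint",
    "v_nullcline_h",
    "v_nullcline",
    "h_nullcline",
    "find_knees",
    "fixed_points",
    "classify_excitability",
    "curve_of_knees",
]

#: Default voltage window for nullcline work (away from the V = E_Na pole).
V_LO, V_HI = -75.0, 20.0


@dataclass
class NullclineCurve:
    """Sampled nullcline with the context it was computed under."""

    V: np.ndarray
    h: np.ndarray
    kind: str  # "V" or "h"
    E_L: float | None = None
    input_drive: float = 0.0

    def branch_labels(self, params: ReducedNeuronParams) -> np.ndarray:
        """'left' / 'middle' / 'right' per sample (V-nullclines only)."""
        if self.kind != "V":
            raise ValueError("branches are defined for the V-nullcline")
        knees = find_knees(params, E_L=self.E_L, input_drive=self.input_drive)
        labels = np.full(len(self.V), "middle", dtype=object)
        if knees["left"] is not None:
            labels[self.V < knees["left"].V] = "left"
        if knees["right"] is not None:
            labels[self.V > knees["right"].V] = "right"
        return labels


@dataclass(frozen=True)
class KneePoint:
    """Fold of the V-nullcline: 'left' = local max of h, 'right' = local min."""

    kind: str
    V: float
    h: float
    input_drive: float


@dataclass(frozen=True)
class FixedPoint:
    V: float
    h: float
    branch: str  # left / middle / right
    stable: bool
    mode: str  # silence / bursting / tonic


def v_nullcline_h(
    V,
    params: ReducedNeuronParams,
    E_L: float | None = None,
    input_drive: float = 0.0,
):
    """h-coordinate of the V-nullcline at voltage(s) V (closed form)."""
    e_l = params.E_L if E_L is None else E_L
    V = np.asarray(V, dtype=float)
    if np.any(V == params.E_Na):
        raise ValueError("V grid must exclude the singularity at V = E_Na")
    num = params.gbar_L * (V - e_l) + input_drive * params.gbar_SynE * (V - params.E_SynE)
    den = params.gbar_NaP * np.asarray(m_nap_inf(V, params)) * (V - params.E_Na)
    out = -num / den
    return out if out.ndim else float(out)


def v_nullcline(
    params: ReducedNeuronParams,
    E_L: float | None = None,
    input_drive: float = 0.0,
    V_grid: np.ndarray | None = None,
) -> NullclineCurve:
    if V_grid is None:
        V_grid = np.linspace(V_LO, V_HI, 1901)
    h = v_nullcline_h(V_grid, params, E_L=E_L, input_drive=input_drive)
    return NullclineCurve(V=np.asarray(V_grid, float), h=np.asarray(h), kind="V",
                          E_L=params.E_L if E_L is None else E_L,
                          input_drive=input_drive)


def h_nullcline(
    params: ReducedNeuronParams, V_grid: np.ndarray | None = None
) -> NullclineCurve:
    if V_grid is None:
        V_grid = np.linspace(V_LO, V_HI, 1901)
    return NullclineCurve(V=np.asarray(V_grid, float),
                          h=np.asarray(h_nap_inf(V_grid, params)), kind="h")


def find_knees(
    params: ReducedNeuronParams,
    E_L: float | None = None,
    input_drive: float = 0.0,
    V_window: tuple[float, float] = (V_LO, 5.0),
    tol: float = 1e-10,
) -> dict[str, KneePoint | None]:
    """Locate the left (max-h) and right (min-h) folds of the V-nullcline.

    Scans a fine grid for interior extrema and refines each by bounded scalar
    optimization.  Returns ``{"left": ..., "right": ...}`` with None entries
    when the curve is monotone (no folds) over the window.
    """
    e_l = params.E_L if E_L is None else E_L
    lo = max(V_window[0], e_l + 1e-6)  # h crosses zero at V = E_L when drive = 0
    grid = np.linspace(lo, V_window[1], 2001)
    h = np.asarray(v_nullcline_h(grid, params, E_L=e_l, input_drive=input_drive))

    def refine(idx: int, sign: float) -> KneePoint:
        a, b = grid[max(idx - 1, 0)], grid[min(idx + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda v: sign * v_nullcline_h(v, params, E_L=e_l, input_drive=input_drive),
            bounds=(a, b), method="bounded",
            options={"xatol": tol},
        )
        return KneePoint(kind="left" if sign < 0 else "right",
                         V=float(res.x),
                         h=float(v_nullcline_h(res.x, params, E_L=e_l,
                                               input_drive=input_drive)),
                         input_drive=input_drive)

    dh = np.diff(h)
    maxima = np.flatnonzero((dh[:-1] > 0) & (dh[1:] <= 0)) + 1
    minima = np.flatnonzero((dh[:-1] < 0) & (dh[1:] >= 0)) + 1
    left = refine(int(maxima[0]), -1.0) if len(maxima) else None
    right = None
    if len(minima):
        after = minima[minima > (maxima[0] if len(maxima) else -1)]
        if len(after):
            right = refine(int(after[0]), +1.0)
    return {"left": left, "right": right}


def fixed_points(
    params: ReducedNeuronParams,
    E_L: float | None = None,
    input_drive: float = 0.0,
    tol: float = 1e-10,
) -> list[FixedPoint]:
    """Intersections of the V- and h-nullclines, with branch and stability.

    Stability is assessed from the trace/determinant of the local Jacobian
    (numerical differentiation); the branch position determines the implied
    uncoupled firing mode.
    """
    e_l = params.E_L if E_L is None else E_L

    def gap(v: float) -> float:
        return v_nullcline_h(v, params, E_L=e_l, input_drive=input_drive) - h_nap_inf(v, params)

    lo = max(V_LO, e_l + 1e-6)
    grid = np.linspace(lo, 5.0, 4001)
    vals = np.array([gap(v) for v in grid])
    roots = []
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    for i in sign_change:
        roots.append(brentq(gap, grid[i], grid[i + 1], xtol=tol))

    knees = find_knees(params, E_L=e_l, input_drive=input_drive)
    out = []
    for v in roots:
        h = float(h_nap_inf(v, params))
        if knees["left"] is not None and v < knees["left"].V:
            branch = "left"
        elif knees["right"] is not None and v > knees["right"].V:
            branch = "right"
        elif knees["left"] is None and knees["right"] is None:
            branch = "left" if v < params.V_min else "right"
        else:
            branch = "middle"
        stable = _is_stable(v, h, params, e_l, input_drive)
        mode = {"left": "silence", "middle": "bursting", "right": "tonic"}[branch]
        if stable:
            # near the cusp where the folds merge, branch labels are ambiguous;
            # a stable point is silence or tonic by its depolarization level
            f_fp = max(0.0, min(1.0, (v - params.V_min) / (params.V_max - params.V_min)))
            mode = "tonic" if f_fp > 0.05 else "silence"
        out.append(FixedPoint(V=float(v), h=h, branch=branch, stable=stable, mode=mode))
    return out


def _is_stable(
    v: float, h: float, params: ReducedNeuronParams, e_l: float, drive: float,
    eps: float = 1e-6,
) -> bool:
    def rhs(vv: float, hh: float) -> tuple[float, float]:
        i_nap = params.gbar_NaP * m_nap_inf(vv, params) * hh * (vv - params.E_Na)
        i_l = params.gbar_L * (vv - e_l)
        i_syn = drive * params.gbar_SynE * (vv - params.E_SynE)
        dv = -(i_nap + i_l + i_syn) / params.C
        dh = (h_nap_inf(vv, params) - hh) / tau_h_nap(vv, params)
        return dv, dh

    fv_p, gv_p = rhs(v + eps, h)
    fv_m, gv_m = rhs(v - eps, h)
    fh_p, gh_p = rhs(v, h + eps)
    fh_m, gh_m = rhs(v, h - eps)
    a = (fv_p - fv_m) / (2 * eps)
    b = (fh_p - fh_m) / (2 * eps)
    c = (gv_p - gv_m) / (2 * eps)
    d = (gh_p - gh_m) / (2 * eps)
    trace, det = a + d, a * d - b * c
    return trace < 0 and det > 0


def classify_excitability(
    E_L: float,
    params: ReducedNeuronParams | None = None,
    input_drive: float = 0.0,
) -> str:
    """Uncoupled firing mode ('silence'/'bursting'/'tonic') from fixed-point
    branch position; with several intersections the stability analysis picks
    the governing one (a stable node wins over branch ambiguity)."""
    p = params or ReducedNeuronParams()
    fps = fixed_points(p, E_L=E_L, input_drive=input_drive)
    if not fps:
        return "silence"
    if len(fps) == 1:
        return fps[0].mode
    stable = [fp for fp in fps if fp.stable]
    if stable:
        # the slow flow converges to a stable point: silence or tonic by branch
        return stable[0].mode
    return "bursting"


def knee_activation_check(
    traj,
    neuron: int,
    active_threshold: float = 0.05,
) -> list[dict]:
    """Event-by-event test of the knee-crossing activation rule.

    For each network burst event, the unit ``neuron`` is predicted to
    activate iff, at some moment of the event while it is still inactive,
    its slow variable h exceeds the left-knee h of its V-nullcline at the
    instantaneous synaptic drive it receives.  Returns one dict per network
    event (excluding events the unit itself initiates) with keys
    ``predicted``, ``actual``, ``onset``.
    """
    from .reduced import detect_cycles  # local import to avoid a cycle

    net = traj.network
    params = net.neurons[neuron]
    e_l = params.E_L
    per_neuron, events = detect_cycles(traj, active_threshold)
    w = net.w
    max_drive = w * (net.n - 1)
    drive_grid = np.linspace(0.0, max_drive * 1.05 + 1e-9, 60)
    knee_h = np.array(
        [
            k.h if (k := find_knees(params, E_L=e_l, input_drive=float(d))["left"])
            is not None else -np.inf
            for d in drive_grid
        ]
    )
    others = [j for j in range(net.n) if j != neuron]
    results = []
    for ev in events:
        sel = (traj.t >= ev.onset) & (traj.t <= ev.offset)
        if not sel.any():
            continue
        f_self = traj.f[sel, neuron]
        drive = w * traj.f[sel][:, others].sum(axis=1)
        if drive.max() <= 0:
            continue  # event initiated by this unit alone
        h_self = traj.h[sel, neuron]
        inactive = f_self <= active_threshold
        knees = np.interp(drive, drive_grid, knee_h)
        predicted = bool(np.any(inactive & (h_self > knees)))
        actual = bool(np.any(f_self > active_threshold))
        results.append({"onset": ev.onset, "predicted": predicted, "actual": actual})
    return results


def curve_of_knees(
    input_grid: np.ndarray,
    params: ReducedNeuronParams | None = None,
    E_L: float | None = None,
    kind: str = "left",
) -> np.ndarray:
    """h-coordinate of a knee as a function of synaptic drive.

    Returns an array of shape (len(input_grid), 2): columns (drive, h_knee).
    Used to overlay simulated (input_i, h_i) trajectories and read off where
    activation succeeds (trajectory above the curve) or fails.
    """
    p = params or ReducedNeuronParams()
    rows = []
    for drive in np.asarray(input_grid, dtype=float):
        knees = find_knees(p, E_L=E_L, input_drive=float(drive))
        k = knees[kind]
        rows.append((float(drive), np.nan if k is None else k.h))
    return np.array(rows)
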