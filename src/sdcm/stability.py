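"""Local stability analysis of the deterministic skeleton.

Equilibria and their classification, linearised perturbation dynamics, and
the decomposition of local stability into a frame of reference that moves
with the flow.  For a two-dimensional flow f(x) with Jacobian J, rotating
the perturbation into the frame whose first axis is aligned with f gives

    d/dt (dx*) = J* dx*,   J* = U J U^-1 + (dU/dt) U^-1 ,

where J* has the structure

    J* = [[lambda_ff,   lambda_perp_f],
          [0,           lambda_perp_perp]] :

the entry coupling tangential perturbations into transverse motion is
identically zero (a perturbation along the flow is a time shift of the same
orbit and never leaves it), while transverse perturbations feed back onto
the tangential motion with rate lambda_perp_f (phase advance/retard).  The
transverse exponent lambda_perp_perp is the local rate of divergence normal
to the flow; its sign partitions state space into regions where noise is
amplified away from, or damped back onto, the deterministic path.  Because
(dU/dt)U^-1 is antisymmetric, trace(J*) = trace(J) everywhere.

J* is built constructively from the rotation to the flow frame; the
structural claims (zero coupling entry, trace preservation) are verified by
the test battery rather than transcribed from a printed coefficient table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import neural_flow, neural_jacobian

__all__ = [
    "EquilibriumPoint",
    "MovingFrameStability",
    "ZeroFlowError",
    "find_equilibria",
    "perturbation_dynamics",
    "moving_frame_matrix",
    "transverse_exponent_map",
    "neural_flow_field",
]

ROOT_TOL = 1e-9
DEDUP_RADIUS = 1e-6


class ZeroFlowError(ValueError):
    """The moving frame is undefined where the flow vanishes."""


@dataclass
class EquilibriumPoint:
    location: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str

    @property
    def stable(self):
        return bool(np.all(self.eigenvalues.real < 0))


@dataclass
class MovingFrameStability:
    """The three exponents of the 2-D moving-frame stability matrix (1/s)."""

    lambda_ff: float
    lambda_perp_perp: float
    lambda_perp_f: float
    #: tangential-to-transverse coupling; structurally zero
    lambda_f_perp: float = 0.0

    @property
    def matrix(self):
        return np.array([
            [self.lambda_ff, self.lambda_perp_f],
            [self.lambda_f_perp, self.lambda_perp_perp],
        ])


def _classify(eigenvalues):
    re = eigenvalues.real
    im = eigenvalues.imag
    tol = 1e-9 * max(1.0, float(np.abs(eigenvalues).max()))
    if np.any(re > tol) and np.any(re < -tol):
        return "saddle"
    complex_pair = bool(np.any(np.abs(im) > tol))
    if np.all(np.abs(re) <= tol):
        return "center-like"
    if np.all(re < tol):
        return "stable spiral" if complex_pair else "stable node"
    return "unstable spiral" if complex_pair else "unstable node"


def find_equilibria(flow, jacobian, search_box, n_starts=200, seed=0):
    """Multi-start root search for equilibria of ``flow`` inside a box.

    Parameters
    ----------
    flow, jacobian : callables mapping a state vector to the flow / Jacobian.
    search_box : sequence of (lo, hi) pairs, one per dimension.
    n_starts : number of random starting points (deterministic given seed).

    Returns
    -------
    list of EquilibriumPoint, deduplicated (pairwise distance larger than
    ten times the root tolerance) and sorted by norm of the location.  An
    empty list (no roots) is a valid result, not an error.
    """
    box = np.asarray(search_box, dtype=float)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(box[:, 0], box[:, 1], size=(n_starts, box.shape[0]))
    # clamp the solver's exploration to a margin around the box so that
    # flows with singular far fields cannot feed non-finite values back
    lo = box[:, 0] - (box[:, 1] - box[:, 0])
    hi = box[:, 1] + (box[:, 1] - box[:, 0])

    def safe_flow(x):
        x = np.clip(np.nan_to_num(x), lo, hi)
        return np.nan_to_num(np.asarray(flow(x), dtype=float),
                             nan=1e6, posinf=1e6, neginf=-1e6)

    def safe_jac(x):
        x = np.clip(np.nan_to_num(x), lo, hi)
        return np.nan_to_num(np.asarray(jacobian(x), dtype=float),
                             nan=1e6, posinf=1e6, neginf=-1e6)

    roots = []
    for x0 in starts:
        sol = root(safe_flow, x0, jac=safe_jac, tol=1e-12)
        if not sol.success:
            continue
        x = sol.x
        if np.linalg.norm(np.asarray(flow(x), dtype=float)) > ROOT_TOL:
            continue
        if np.any(x < box[:, 0] - 1e-6) or np.any(x > box[:, 1] + 1e-6):
            continue
        if any(np.linalg.norm(x - r) <= 10 * DEDUP_RADIUS for r in roots):
            continue
        roots.append(x)
    out = []
    for x in roots:
        J = np.asarray(jacobian(x), dtype=float)
        ev = np.linalg.eigvals(J)
        out.append(EquilibriumPoint(location=x, jacobian=J, eigenvalues=ev,
                                    classification=_classify(ev)))
    out.sort(key=lambda e: float(np.linalg.norm(e.location)))
    return out


def perturbation_dynamics(jacobian_at_path, delta_x0, times):
    """Integrate the linearised perturbation equation d(dx)/dt = J(t) dx.

    ``jacobian_at_path`` is an array (T, n, n) of Jacobians on the time grid
    ``times`` (piecewise-linearly interpolated), or a callable J(t).
    Returns the perturbation trajectory as an array (T, n).
    """
    times = np.asarray(times, dtype=float)
    delta_x0 = np.asarray(delta_x0, dtype=float)
    if callable(jacobian_at_path):
        J_of_t = jacobian_at_path
    else:
        Js = np.asarray(jacobian_at_path, dtype=float)
        if Js.shape[0] != times.size:
            raise ValueError("Jacobian array must match the time grid")

        def J_of_t(t):
            i = np.searchsorted(times, t, side="right") - 1
            i = min(max(i, 0), times.size - 2)
            w = (t - times[i]) / (times[i + 1] - times[i]) if times.size > 1 else 0.0
            return (1 - w) * Js[i] + w * Js[i + 1]

    if np.all(delta_x0 == 0):
        return np.zeros((times.size, delta_x0.size))
    sol = solve_ivp(
        lambda t, v: J_of_t(t) @ v,
        (times[0], times[-1]),
        delta_x0,
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
        max_step=(times[-1] - times[0]) / max(times.size - 1, 1),
    )
    return sol.y.T


def moving_frame_matrix(J, f, df_dt=None):
    """Moving-frame stability exponents for a 2-D system.

    Parameters
    ----------
    J : (2, 2) Jacobian at the current state.
    f : (2,) flow vector there (must be non-zero).
    df_dt : (2,) time derivative of the flow along the path; along a
        deterministic trajectory this is J f, which is used when omitted.

    Returns
    -------
    MovingFrameStability
    """
    J = np.asarray(J, dtype=float)
    f = np.asarray(f, dtype=float)
    if J.shape != (2, 2) or f.shape != (2,):
        raise ValueError("moving_frame_matrix is defined for 2-D systems")
    nf = float(np.hypot(f[0], f[1]))
    if nf == 0.0:
        raise ZeroFlowError("flow vanishes; the moving frame is undefined")
    u_f = f / nf
    u_p = np.array([-u_f[1], u_f[0]])
    Jf = J @ f
    if df_dt is None:
        df_dt = Jf
    df_dt = np.asarray(df_dt, dtype=float)
    # rotation rate of the frame: phi_dot = (f x f_dot)/|f|^2
    phi_dot = (u_p @ df_dt) / nf
    l_ff = u_f @ (J @ u_f)
    l_pp = u_p @ (J @ u_p)
    l_pf = u_f @ (J @ u_p) + phi_dot   # transverse -> tangential (phase resetting)
    l_fp = (u_p @ Jf) / nf - phi_dot   # tangential -> transverse; exactly 0 on paths
    return MovingFrameStability(
        lambda_ff=float(l_ff),
        lambda_perp_perp=float(l_pp),
        lambda_perp_f=float(l_pf),
        lambda_f_perp=float(l_fp),
    )


def neural_flow_field(spec, u=None):
    """(flow, jacobian) callables for the neural subsystem of a spec at a
    fixed input value (defaults to zero input)."""
    if u is None:
        u = np.zeros(spec.n_inputs)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    conn = spec.connectivity

    def flow(x):
        return neural_flow(np.asarray(x, dtype=float), u, conn)

    def jac(x):
        return neural_jacobian(np.asarray(x, dtype=float), u, conn)

    return flow, jac


def transverse_exponent_map(spec, grid_x1, grid_x2, u=None, flow_floor=1e-6):
    """Evaluate the moving-frame exponents over a 2-D state grid.

    On a grid there is no path, so the frame rotation rate is taken from the
    local field via f_dot = J f (recorded in the metadata).  Nodes where the
    flow magnitude is below ``flow_floor`` are skipped and flagged NaN.

    Returns a dict with the coordinate grids, the three exponent fields, the
    lambda_perp_perp <= 0 level-set mask, and metadata.
    """
    if spec.n_regions != 2:
        raise ValueError("the exponent map is defined for two-region systems")
    flow, jac = neural_flow_field(spec, u)
    g1 = np.asarray(grid_x1, dtype=float)
    g2 = np.asarray(grid_x2, dtype=float)
    shape = (g1.size, g2.size)
    l_ff = np.full(shape, np.nan)
    l_pp = np.full(shape, np.nan)
    l_pf = np.full(shape, np.nan)
    skipped = np.zeros(shape, dtype=bool)
    for i, x1 in enumerate(g1):
        for j, x2 in enumerate(g2):
            x = np.array([x1, x2])
            fx = flow(x)
            if np.hypot(fx[0], fx[1]) < flow_floor:
                skipped[i, j] = True
                continue
            mf = moving_frame_matrix(jac(x), fx)
            l_ff[i, j] = mf.lambda_ff
            l_pp[i, j] = mf.lambda_perp_perp
            l_pf[i, j] = mf.lambda_perp_f
    return {
        "x1": g1,
        "x2": g2,
        "lambda_ff": l_ff,
        "lambda_perp_perp": l_pp,
        "lambda_perp_f": l_pf,
        "stable_mask": l_pp <= 0,
        "skipped": skipped,
        "metadata": {"frame_rotation": "local field, f_dot = J f",
                     "flow_floor": flow_floor},
    }
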