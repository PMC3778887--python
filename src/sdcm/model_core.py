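"""Generative model for DCM of fMRI: neural dynamics, hemodynamics and the BOLD observer.

The model couples a network of brain regions through a bilinear-plus-gating
neural evolution function,

    dx/dt = A x + sum_i u_i B^(i) x + C u + sum_j x_j D^(j) x ,

to a regional balloon/Windkessel hemodynamic cascade observed through a
three-compartment BOLD signal equation.  The hemodynamic states (vasodilatory
signal, blood inflow, venous volume, deoxyhemoglobin content) are stored in
log-transformed coordinates, so that the physical quantities stay positive
while the state vector is unconstrained.

All connectivity matrices carry binary *masks* declaring which entries are
free parameters; masked-out entries are structurally zero and never enter the
packed parameter vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NeuralConnectivity",
    "HemodynamicParams",
    "NoiseSpec",
    "PriorSet",
    "BasisSet",
    "DCMSpec",
    "InputCourse",
    "ParameterIndex",
    "neural_flow",
    "neural_jacobian",
    "hemodynamic_flow",
    "hemodynamic_jacobian",
    "bold_observation",
    "bold_gradient",
    "attach_basis",
    "make_basis_values",
    "pack_parameters",
    "unpack_parameters",
]

#: names of hemodynamic parameters that enter the state evolution
HEMO_DYNAMIC_NAMES = ("kappa_s", "kappa_f", "tau_0", "alpha", "E_0")
#: names of parameters that only enter the BOLD observer
HEMO_OBSERVER_NAMES = ("V_0", "nu_0", "TE", "r_0", "epsilon_0")
HEMO_PARAM_NAMES = HEMO_DYNAMIC_NAMES + HEMO_OBSERVER_NAMES


class SpecificationError(ValueError):
    """Raised when a model specification is internally inconsistent."""


def _as_matrix(x, shape, name):
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise SpecificationError(f"{name} must have shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise SpecificationError(f"{name} contains non-finite entries")
    return a


@dataclass
class NeuralConnectivity:
    """Coupling matrices of the neural evolution function.

    Parameters
    ----------
    A : (n, n) array
        Fixed (endogenous) coupling rates, per second.
    B : list of (n, n) arrays
        Input-dependent modulation of coupling, one matrix per input channel.
    C : (n, m) array
        Driving-input gains.
    D : list of (n, n) arrays
        State-dependent gating, one matrix per (gating) region.
    basis_coefficients : (n, K) array, optional
        Projection coefficients of modelled neural fluctuations onto an
        attached temporal basis set (augmented deterministic DCM).

    Each matrix has a companion binary mask (``A_mask`` etc.) selecting which
    entries are free parameters.  Entries whose mask is zero are fixed
    constants that never enter the packed parameter vector; when that
    constant is zero (the usual case) the connection is structurally absent,
    not "estimated at zero".
    """

    A: np.ndarray
    B: list = field(default_factory=list)
    C: np.ndarray | None = None
    D: list = field(default_factory=list)
    basis_coefficients: np.ndarray | None = None
    A_mask: np.ndarray | None = None
    B_masks: list | None = None
    C_mask: np.ndarray | None = None
    D_masks: list | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        _as_matrix(self.A, (n, n), "A")
        if self.C is None:
            self.C = np.zeros((n, 1))
        self.C = np.asarray(self.C, dtype=float)
        m = self.C.shape[1]
        _as_matrix(self.C, (n, m), "C")
        self.B = [_as_matrix(b, (n, n), f"B[{i}]") for i, b in enumerate(self.B)]
        if self.B and len(self.B) != m:
            raise SpecificationError(
                f"B must have one matrix per input channel ({m}), got {len(self.B)}"
            )
        self.D = [_as_matrix(d, (n, n), f"D[{j}]") for j, d in enumerate(self.D)]
        if self.D and len(self.D) != n:
            raise SpecificationError(
                f"D must have one matrix per region ({n}), got {len(self.D)}"
            )
        if self.A_mask is None:
            self.A_mask = (self.A != 0).astype(int)
        self.A_mask = np.asarray(self.A_mask, dtype=int)
        if self.C_mask is None:
            self.C_mask = (self.C != 0).astype(int)
        self.C_mask = np.asarray(self.C_mask, dtype=int)
        if self.B_masks is None:
            self.B_masks = [(b != 0).astype(int) for b in self.B]
        if self.D_masks is None:
            self.D_masks = [(d != 0).astype(int) for d in self.D]
        for _, mask, name in self._mask_pairs():
            if not np.isin(np.asarray(mask), (0, 1)).all():
                raise SpecificationError(f"{name} mask must be binary")

    def _mask_pairs(self):
        pairs = [(self.A, self.A_mask, "A"), (self.C, self.C_mask, "C")]
        pairs += [(b, mk, f"B[{i}]") for i, (b, mk) in enumerate(zip(self.B, self.B_masks))]
        pairs += [(d, mk, f"D[{j}]") for j, (d, mk) in enumerate(zip(self.D, self.D_masks))]
        return pairs

    @property
    def n_regions(self):
        return self.A.shape[0]

    @property
    def n_inputs(self):
        return self.C.shape[1]

    def copy(self):
        return NeuralConnectivity(
            A=self.A.copy(),
            B=[b.copy() for b in self.B],
            C=self.C.copy(),
            D=[d.copy() for d in self.D],
            basis_coefficients=None
            if self.basis_coefficients is None
            else self.basis_coefficients.copy(),
            A_mask=self.A_mask.copy(),
            B_masks=[m.copy() for m in self.B_masks],
            C_mask=self.C_mask.copy(),
            D_masks=[m.copy() for m in self.D_masks],
        )


@dataclass
class HemodynamicParams:
    """Balloon/Windkessel constants.  Defaults are the standard values used
    throughout (rates in 1/s, times in s, the rest dimensionless)."""

    kappa_s: float = 0.65   # vasodilatory signal decay rate
    kappa_f: float = 0.41   # vasodilatory signal feedback rate
    tau_0: float = 2.0      # mean transit time
    alpha: float = 0.32     # vessel stiffness (Grubb exponent)
    E_0: float = 0.34       # resting oxygen extraction fraction
    V_0: float = 4.0        # resting venous volume fraction (percent units)
    nu_0: float = 40.3      # frequency offset of deoxygenated blood
    TE: float = 0.04        # echo time
    r_0: float = 25.0       # intravascular relaxation rate
    epsilon_0: float = 1.0  # intra/extra-vascular signal ratio

    def __post_init__(self):
        for name in HEMO_PARAM_NAMES:
            v = float(getattr(self, name))
            setattr(self, name, v)
            if name == "epsilon_0":
                if v < 0:
                    raise SpecificationError("epsilon_0 must be >= 0")
            elif v <= 0:
                raise SpecificationError(f"{name} must be strictly positive")

    def as_array(self):
        return np.array([getattr(self, k) for k in HEMO_PARAM_NAMES])

    def copy(self):
        return HemodynamicParams(**{k: getattr(self, k) for k in HEMO_PARAM_NAMES})


@dataclass
class NoiseSpec:
    """Noise model: hyperpriors on precisions, and the neural/hemodynamic
    variance partition.

    ``state_noise_prior`` is a shape/rate Gamma hyperprior on the precision of
    neural state noise.  The default Ga(1, 0.1) places 95% prior mass on state
    noise variance above 1/30 (P(precision < 30) = 1 - exp(-3)).  The
    measurement-noise prior defaults to the Jeffreys limit, encoded as a
    conjugate Gamma with shape = rate = 1e-8.  ``neural_to_hemo_variance_ratio``
    fixes the hemodynamic state-noise variance at 1/ratio times the neural
    one, which penalises explanations of BOLD changes in terms of hemodynamic
    (rather than neuronal) fluctuations.
    """

    state_noise_prior: tuple = (1.0, 0.1)
    neural_to_hemo_variance_ratio: float = 100.0
    measurement_noise_prior: tuple = (1e-8, 1e-8)
    stochastic: bool = False

    def __post_init__(self):
        a, b = self.state_noise_prior
        if a < 0 or b < 0:
            raise SpecificationError("Gamma hyperprior shape/rate must be >= 0")
        a, b = self.measurement_noise_prior
        if a < 0 or b < 0:
            raise SpecificationError("Gamma hyperprior shape/rate must be >= 0")
        if self.neural_to_hemo_variance_ratio <= 0:
            raise SpecificationError("neural_to_hemo_variance_ratio must be > 0")

    def copy(self):
        return NoiseSpec(
            state_noise_prior=tuple(self.state_noise_prior),
            neural_to_hemo_variance_ratio=self.neural_to_hemo_variance_ratio,
            measurement_noise_prior=tuple(self.measurement_noise_prior),
            stochastic=self.stochastic,
        )


@dataclass
class PriorSet:
    """Priors over evolution and hemodynamic parameters plus the noise model.

    Evolution parameters (free A/B/C/D entries and basis coefficients) share
    an i.i.d. zero-mean shrinkage prior of variance ``evolution_variance``
    (default 0.1).  Hemodynamic parameters are parameterised as log-scaling
    factors of their default values with prior N(0, hemodynamic_variance);
    variance 0 (the default) fixes them at the defaults, while 1e-2 is the
    conventional "empirical" setting that lets hemodynamics deviate from
    their canonical form.
    """

    evolution_variance: float = 0.1
    evolution_mean: np.ndarray | None = None
    hemodynamic_variance: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if self.evolution_variance <= 0:
            raise SpecificationError("evolution prior variance must be > 0")
        if self.hemodynamic_variance < 0:
            raise SpecificationError("hemodynamic prior variance must be >= 0")

    def copy(self):
        return PriorSet(
            evolution_variance=self.evolution_variance,
            evolution_mean=None if self.evolution_mean is None else np.array(self.evolution_mean),
            hemodynamic_variance=self.hemodynamic_variance,
            noise=self.noise.copy(),
        )


@dataclass
class BasisSet:
    """Temporal basis set used to model neural fluctuations within a
    deterministic DCM (kind 'fourier' or 'rbf'), or 'none'."""

    kind: str = "none"
    K: int = 0
    times: np.ndarray | None = None
    sampled_values: np.ndarray | None = None  # (K, T)

    def __post_init__(self):
        if self.kind not in ("none", "fourier", "rbf"):
            raise SpecificationError(f"unknown basis kind {self.kind!r}")
        if (self.K == 0) != (self.kind == "none"):
            raise SpecificationError("K must be 0 iff kind is 'none'")
        if self.sampled_values is not None:
            self.sampled_values = np.asarray(self.sampled_values, dtype=float)
            if not np.all(np.isfinite(self.sampled_values)):
                raise SpecificationError("basis values must be finite")
            if self.sampled_values.shape[0] != self.K:
                raise SpecificationError("sampled_values must have K rows")

    def copy(self):
        return BasisSet(
            kind=self.kind,
            K=self.K,
            times=None if self.times is None else np.array(self.times),
            sampled_values=None
            if self.sampled_values is None
            else self.sampled_values.copy(),
        )


@dataclass
class DCMSpec:
    """Complete description of one generative model."""

    connectivity: NeuralConnectivity
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    priors: PriorSet = field(default_factory=PriorSet)
    basis: BasisSet = field(default_factory=BasisSet)
    label: str = "dcm"
    family_tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.basis.K > 0:
            cb = self.connectivity.basis_coefficients
            if cb is None:
                self.connectivity.basis_coefficients = np.zeros(
                    (self.n_regions, self.basis.K)
                )
            elif cb.shape != (self.n_regions, self.basis.K):
                raise SpecificationError("basis_coefficients shape mismatch")
        elif self.connectivity.basis_coefficients is not None:
            raise SpecificationError("basis_coefficients present without a basis set")

    @property
    def n_regions(self):
        return self.connectivity.n_regions

    @property
    def n_inputs(self):
        return self.connectivity.n_inputs

    def copy(self):
        return DCMSpec(
            connectivity=self.connectivity.copy(),
            hemo=self.hemo.copy(),
            priors=self.priors.copy(),
            basis=self.basis.copy(),
            label=self.label,
            family_tags=dict(self.family_tags),
        )


@dataclass
class InputCourse:
    """Exogenous inputs on a uniform time grid.

    ``u`` holds the controlled experimental inputs (m x T).  ``delta_u``
    optionally holds per-region neural fluctuations (n x T) that perturb the
    hidden states of every node directly, in addition to the routed input.
    """

    times: np.ndarray
    u: np.ndarray
    delta_u: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.u.shape[1] != self.times.size:
            raise SpecificationError("u must have one column per time point")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise SpecificationError("times must be strictly increasing with constant step")
        if not np.all(np.isfinite(self.u)):
            raise SpecificationError("u must be finite")
        if self.delta_u is not None:
            self.delta_u = np.atleast_2d(np.asarray(self.delta_u, dtype=float))
            if self.delta_u.shape[1] != self.times.size:
                raise SpecificationError("delta_u must share the input time grid")

    @property
    def step(self):
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def copy(self):
        return InputCourse(
            times=self.times.copy(),
            u=self.u.copy(),
            delta_u=None if self.delta_u is None else self.delta_u.copy(),
        )


# ---------------------------------------------------------------------------
# evolution, observation and their derivatives
# ---------------------------------------------------------------------------

def neural_flow(x_n, u, conn, basis_values=None, delta=None):
    """Rate of change of the neural states.

    Parameters
    ----------
    x_n : (n,) array
    u : (m,) array
    conn : NeuralConnectivity
    basis_values : (K,) array, optional
        Basis functions evaluated at the current time; multiplied by the
        basis coefficients when the spec carries an augmented basis set.
    delta : (n,) array, optional
        Instantaneous neural fluctuation added directly to each region.
    """
    x_n = np.asarray(x_n, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    n = conn.n_regions
    if x_n.shape != (n,):
        raise SpecificationError(f"x_n must have shape ({n},)")
    if u.shape != (conn.n_inputs,):
        raise SpecificationError(f"u must have shape ({conn.n_inputs},)")
    dx = conn.A @ x_n + conn.C @ u
    for i, Bi in enumerate(conn.B):
        dx += u[i] * (Bi @ x_n)
    for j, Dj in enumerate(conn.D):
        dx += x_n[j] * (Dj @ x_n)
    if basis_values is not None:
        cb = conn.basis_coefficients
        if cb is None:
            raise SpecificationError("basis values supplied but no coefficients attached")
        dx += cb @ np.asarray(basis_values, dtype=float)
    if delta is not None:
        dx = dx + delta
    return dx


def neural_jacobian(x_n, u, conn):
    """Analytic Jacobian of :func:`neural_flow` with respect to the states.

    With gating, the Jacobian depends on where you are in state space:
    J = A + sum_i u_i B^(i) + sum_j x_j D^(j) + sum_j (D^(j) x) e_j^T.
    Without gating (all D zero) it is constant over state space.
    """
    x_n = np.asarray(x_n, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    n = conn.n_regions
    if x_n.shape != (n,) or u.shape != (conn.n_inputs,):
        raise SpecificationError("dimension mismatch in neural_jacobian")
    J = conn.A.copy()
    for i, Bi in enumerate(conn.B):
        J += u[i] * Bi
    for j, Dj in enumerate(conn.D):
        J += x_n[j] * Dj
        J[:, j] += Dj @ x_n
    return J


def hemodynamic_flow(x_h, x_n_i, hemo):
    """Balloon-model derivatives for one region.

    States are ``x_h = (s, log f, log v, log q)``: vasodilatory signal,
    log blood inflow, log venous volume, log deoxyhemoglobin content.
    """
    x_h = np.asarray(x_h, dtype=float)
    if not np.all(np.isfinite(x_h)):
        raise FloatingPointError("non-finite hemodynamic state")
    s, lf, lv, lq = x_h
    with np.errstate(over="ignore"):
        ef = np.exp(lf)
        a = hemo.alpha
        ds = x_n_i - hemo.kappa_s * s - hemo.kappa_f * (ef - 1.0)
        dlf = s * np.exp(-lf)
        dlv = (ef - np.exp(lv / a)) * np.exp(-lv) / hemo.tau_0
        E = 1.0 - (1.0 - hemo.E_0) ** np.exp(-lf)
        dlq = (np.exp(lf - lq) * E / hemo.E_0 - np.exp((1.0 - a) * lv / a)) / hemo.tau_0
    return np.array([ds, dlf, dlv, dlq])


def hemodynamic_jacobian(x_h, hemo):
    """Analytic Jacobian of :func:`hemodynamic_flow` w.r.t. the four
    hemodynamic states (the derivative w.r.t. the neural drive is e_1)."""
    s, lf, lv, lq = np.asarray(x_h, dtype=float)
    a = hemo.alpha
    with np.errstate(over="ignore"):
        ef = np.exp(lf)
        J = np.zeros((4, 4))
        # ds/d(.)
        J[0, 0] = -hemo.kappa_s
        J[0, 1] = -hemo.kappa_f * ef
        # dlf/d(.)
        J[1, 0] = np.exp(-lf)
        J[1, 1] = -s * np.exp(-lf)
        # dlv/d(.)
        J[2, 1] = ef * np.exp(-lv) / hemo.tau_0
        J[2, 2] = (
            -(1.0 / a) * np.exp(lv / a) * np.exp(-lv)
            - (ef - np.exp(lv / a)) * np.exp(-lv)
        ) / hemo.tau_0
        # dlq/d(.)
        one_minus = 1.0 - hemo.E_0
        E = 1.0 - one_minus ** np.exp(-lf)
        dE_dlf = one_minus ** np.exp(-lf) * math.log(one_minus) * np.exp(-lf)
        J[3, 1] = (np.exp(lf - lq) * (E + dE_dlf) / hemo.E_0) / hemo.tau_0
        J[3, 2] = -((1.0 - a) / a) * np.exp((1.0 - a) * lv / a) / hemo.tau_0
        J[3, 3] = -np.exp(lf - lq) * E / hemo.E_0 / hemo.tau_0
    return J


def bold_observation(x_h, hemo):
    """Three-compartment BOLD signal from one region's hemodynamic states.

    y = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ] with q = exp(x4),
    v = exp(x3), k1 = 4.3 nu0 E0 TE, k2 = eps0 r0 E0 TE, k3 = 1 - eps0.
    """
    x_h = np.asarray(x_h, dtype=float)
    lv, lq = x_h[2], x_h[3]
    k1 = 4.3 * hemo.nu_0 * hemo.E_0 * hemo.TE
    k2 = hemo.epsilon_0 * hemo.r_0 * hemo.E_0 * hemo.TE
    k3 = 1.0 - hemo.epsilon_0
    return hemo.V_0 * (
        k1 * (1.0 - math.exp(lq))
        + k2 * (1.0 - math.exp(lq - lv))
        + k3 * (1.0 - math.exp(lv))
    )


def bold_gradient(x_h, hemo):
    """Gradient of :func:`bold_observation` w.r.t. the four hemodynamic states."""
    x_h = np.asarray(x_h, dtype=float)
    lv, lq = x_h[2], x_h[3]
    k1 = 4.3 * hemo.nu_0 * hemo.E_0 * hemo.TE
    k2 = hemo.epsilon_0 * hemo.r_0 * hemo.E_0 * hemo.TE
    k3 = 1.0 - hemo.epsilon_0
    g = np.zeros(4)
    g[2] = hemo.V_0 * (k2 * math.exp(lq - lv) - k3 * math.exp(lv))
    g[3] = hemo.V_0 * (-k1 * math.exp(lq) - k2 * math.exp(lq - lv))
    return g


# ---------------------------------------------------------------------------
# temporal basis sets
# ---------------------------------------------------------------------------

def make_basis_values(kind, K, session_length, TR):
    """Sample K basis functions on the scan grid t = 0, TR, ..., < session_length.

    Fourier: sine/cosine pairs up to order K/2 on the session (orthogonal on
    the grid).  RBF: K evenly spaced Gaussian bumps whose width equals the
    spacing between centres.
    """
    times = np.arange(0.0, session_length, TR)
    T = times.size
    if kind == "none" or K == 0:
        return times, np.zeros((0, T))
    if kind == "fourier":
        if K % 2:
            logger.warning("Fourier basis needs an even K; rounding %d down to %d", K, K - 1)
            K -= 1
        rows = []
        L = session_length
        for order in range(1, K // 2 + 1):
            w = 2.0 * np.pi * order / L
            rows.append(np.sin(w * times))
            rows.append(np.cos(w * times))
        return times, np.vstack(rows)
    if kind == "rbf":
        centres = (np.arange(K) + 0.5) * session_length / K
        width = session_length / K
        vals = np.exp(-0.5 * ((times[None, :] - centres[:, None]) / width) ** 2)
        return times, vals
    raise SpecificationError(f"unknown basis kind {kind!r}")


def attach_basis(spec, kind, K, session_length, TR):
    """Return a copy of ``spec`` augmented with a temporal basis set.

    Adds n_regions x K free coefficients sharing the evolution shrinkage
    prior.  ``K = 0`` (or kind 'none') returns an unchanged copy.
    """
    if kind == "none" or K == 0:
        out = spec.copy()
        out.basis = BasisSet()
        out.connectivity.basis_coefficients = None
        return out
    times, vals = make_basis_values(kind, K, session_length, TR)
    K_eff = vals.shape[0]
    out = spec.copy()
    out.basis = BasisSet(kind=kind, K=K_eff, times=times, sampled_values=vals)
    out.connectivity.basis_coefficients = np.zeros((spec.n_regions, K_eff))
    return out


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

@dataclass
class ParameterIndex:
    """Index map produced by :func:`pack_parameters`.

    ``entries`` is a list of (block, coords) pairs, one per element of the
    packed vector, where block is one of 'A', 'B', 'C', 'D', 'basis', 'hemo'.
    """

    entries: list
    n_evolution: int
    n_hemo: int

    def __len__(self):
        return len(self.entries)

    @property
    def names(self):
        out = []
        for block, coords in self.entries:
            if block in ("A", "C"):
                out.append(f"{block}[{coords[0]},{coords[1]}]")
            elif block in ("B", "D"):
                out.append(f"{block}{coords[0]}[{coords[1]},{coords[2]}]")
            elif block == "basis":
                out.append(f"c[{coords[0]},{coords[1]}]")
            else:
                out.append(f"hemo:{coords}")
        return out


def pack_parameters(spec):
    """Flatten the free parameters of a spec into a vector.

    Only entries whose mask is set appear; order is A (row-major), then each
    B, C, each D, basis coefficients, then free hemodynamic parameters
    (present only when the hemodynamic prior variance is non-zero, stored as
    log-scaling factors relative to the defaults, i.e. 0 at the default).
    """
    conn = spec.connectivity
    vec, entries = [], []
    for r, c in np.argwhere(conn.A_mask):
        vec.append(conn.A[r, c])
        entries.append(("A", (int(r), int(c))))
    for i, (Bi, mask) in enumerate(zip(conn.B, conn.B_masks)):
        for r, c in np.argwhere(mask):
            vec.append(Bi[r, c])
            entries.append(("B", (i, int(r), int(c))))
    for r, c in np.argwhere(conn.C_mask):
        vec.append(conn.C[r, c])
        entries.append(("C", (int(r), int(c))))
    for j, (Dj, mask) in enumerate(zip(conn.D, conn.D_masks)):
        for r, c in np.argwhere(mask):
            vec.append(Dj[r, c])
            entries.append(("D", (j, int(r), int(c))))
    if conn.basis_coefficients is not None:
        n, K = conn.basis_coefficients.shape
        for r in range(n):
            for k in range(K):
                vec.append(conn.basis_coefficients[r, k])
                entries.append(("basis", (r, k)))
    n_evo = len(vec)
    n_hemo = 0
    if spec.priors.hemodynamic_variance > 0:
        defaults = HemodynamicParams()
        for name in HEMO_PARAM_NAMES:
            val = getattr(spec.hemo, name)
            ref = getattr(defaults, name)
            if ref > 0:
                vec.append(math.log(val / ref))
                entries.append(("hemo", name))
                n_hemo += 1
    return np.array(vec, dtype=float), ParameterIndex(entries, n_evo, n_hemo)


def unpack_parameters(vector, index_map, template):
    """Inverse of :func:`pack_parameters`: write a vector back into a copy of
    ``template`` (a DCMSpec)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(index_map),):
        raise SpecificationError(
            f"vector length {vector.shape} does not match index map ({len(index_map)})"
        )
    spec = template.copy()
    conn = spec.connectivity
    defaults = HemodynamicParams()
    for val, (block, coords) in zip(vector, index_map.entries):
        if block == "A":
            conn.A[coords] = val
        elif block == "B":
            conn.B[coords[0]][coords[1], coords[2]] = val
        elif block == "C":
            conn.C[coords] = val
        elif block == "D":
            conn.D[coords[0]][coords[1], coords[2]] = val
        elif block == "basis":
            conn.basis_coefficients[coords] = val
        elif block == "hemo":
            setattr(spec.hemo, coords, getattr(defaults, coords) * math.exp(val))
        else:  # pragma: no cover
            raise SpecificationError(f"unknown block {block!r}")
    return spec


def prior_moments(spec, index_map):
    """Prior mean and (diagonal) variance for a packed parameter vector."""
    n = len(index_map)
    mean = np.zeros(n)
    if spec.priors.evolution_mean is not None:
        em = np.asarray(spec.priors.evolution_mean, dtype=float)
        mean[: index_map.n_evolution] = em
    var = np.full(n, spec.priors.evolution_variance)
    if index_map.n_hemo:
        var[index_map.n_evolution:] = spec.priors.hemodynamic_variance
    return mean, var
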