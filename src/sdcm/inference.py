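"""Variational Bayesian inversion under the Laplace approximation.

Both deterministic and stochastic DCM are inverted as Gaussian-prior
nonlinear regression problems,

    y = g(theta) + eps,   theta ~ N(m0, V0),   eps ~ N(0, 1/lambda_eps I),

where g integrates the generative model and theta collects the free
evolution (and optionally hemodynamic) parameters.  For stochastic DCM the
parameter vector is augmented with per-scan neural innovations w: the
Wiener state noise accumulated over each repetition time is lumped into an
impulse on the neural states at the scan boundary, with conjugate prior
w ~ N(0, TR / lambda_w) per region and scan.  This turns state estimation
into a batch Gaussian smoothing problem solved jointly with the parameters:
the posterior state trajectory at any time is conditioned on the entire
session (which subsumes the fixed-lag requirement that the estimate at time
t see data up to t + lag; the ``lag`` setting is retained as metadata).
As the state-noise precision grows the innovations shrink to zero and the
scheme reduces exactly to deterministic DCM.

The approximate posterior factorises as q(theta, w) q(lambda_eps)
q(lambda_w) with a joint Gaussian over (theta, w) and Gamma factors over
the precisions.  Iteration alternates Levenberg-damped Gauss-Newton steps
on the Gaussian mean, a closed-form covariance, and conjugate Gamma
updates; the free energy

    F = <ln p(y|theta)> + <ln p(theta)> - <ln q> (+ precision terms)

is evaluated in closed form under a local quadratic expansion of g (exact
for linear g, which is what makes F match the analytic log evidence on
conjugate linear-Gaussian problems).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, digamma

from . import _forward
from .model_core import (
    SpecificationError,
    pack_parameters,
    prior_moments,
    unpack_parameters,
)
from .simulator import _hold

logger = logging.getLogger(__name__)

__all__ = [
    "InversionSettings",
    "Posterior",
    "VariationalProblem",
    "free_energy",
    "invert_deterministic",
    "invert_stochastic",
    "posterior_correlation",
]


@dataclass
class InversionSettings:
    """Numerical settings of the variational inversion.

    ``lag`` (s) is the minimum look-ahead the state estimates must be
    conditioned on; the batch smoother conditions on the full session, which
    always satisfies it.  ``dt`` is the inversion micro-step (default TR/8;
    the Heun drift step keeps the discretisation error well below the noise
    floor at that resolution).
    """

    lag: float = 16.0
    max_iter: int = 64
    tol: float = 1e-4
    dt: float | None = None
    seed: int = 0
    init_self_inhibition: float = -0.5
    max_step_halvings: int = 8

    def validate(self, TR):
        if self.lag < 0:
            raise SpecificationError("lag must be >= 0")
        k = self.lag / TR
        if abs(k - round(k)) > 1e-9:
            raise SpecificationError("lag must be a multiple of TR")
        if self.tol <= 0:
            raise SpecificationError("tolerance must be > 0")


@dataclass
class Posterior:
    """Approximate posterior from variational Laplace."""

    mu: np.ndarray
    Sigma: np.ndarray
    param_names: list
    index_map: object
    free_energy: float
    trace: list
    converged: bool
    lambda_eps_posterior: tuple          # Gamma (shape, rate) or ("fixed", value)
    lambda_state_posterior: tuple | None = None
    n_evolution: int = 0
    w_mean: np.ndarray | None = None     # (n, T) innovations (sDCM)
    states: dict | None = None           # times, x_n mean/var at scan times
    metadata: dict = field(default_factory=dict)

    @property
    def theta(self):
        """Posterior mean over model (non-innovation) parameters."""
        return self.mu[: self.n_evolution]

    @property
    def theta_sd(self):
        return np.sqrt(np.diag(self.Sigma)[: self.n_evolution])

    @property
    def lambda_eps_mean(self):
        a, b = self.lambda_eps_posterior
        return a / b if a != "fixed" else b

    @property
    def lambda_state_mean(self):
        if self.lambda_state_posterior is None:
            return None
        a, b = self.lambda_state_posterior
        return a / b

    def spec_at_posterior(self, template):
        return unpack_parameters(self.theta, self.index_map, template)


class VariationalProblem:
    """A Gaussian-prior nonlinear regression problem.

    Parameters
    ----------
    forward : callable(theta, want_sens) -> (yhat, G) or None on divergence.
        ``G`` may be None when ``want_sens`` is False.
    y : (N,) observations.
    m0, v0 : prior mean and variance (diagonal) of the plain parameter block.
    noise_eps : ("fixed", precision) or ("gamma", shape, rate).
    n_w : size of the innovation block appended after the plain block.
    w_scale : per-innovation variance scale c (prior var = c / lambda_w).
    state_prior : Gamma (shape, rate) hyperprior on lambda_w.
    """

    def __init__(self, forward, y, m0, v0, noise_eps=("gamma", 1e-8, 1e-8),
                 n_w=0, w_scale=None, state_prior=(1.0, 0.1), names=None):
        self.forward = forward
        self.y = np.asarray(y, dtype=float).ravel()
        self.m0 = np.asarray(m0, dtype=float)
        self.v0 = np.asarray(v0, dtype=float)
        if np.any(self.v0 <= 0):
            raise SpecificationError("prior variances must be positive")
        self.noise_eps = noise_eps
        self.n_w = int(n_w)
        self.n_plain = self.m0.size
        self.P = self.n_plain + self.n_w
        if self.n_w:
            self.w_scale = np.asarray(w_scale, dtype=float)
        else:
            self.w_scale = np.zeros(0)
        self.state_prior = state_prior
        self.names = names or [f"p{i}" for i in range(self.n_plain)]

    # -- prior precision given the current state-noise estimate ------------
    def prior_precision(self, lam_w_mean):
        P0 = np.empty(self.P)
        P0[: self.n_plain] = 1.0 / self.v0
        if self.n_w:
            P0[self.n_plain:] = lam_w_mean / self.w_scale
        return P0

    def prior_mean(self):
        m = np.zeros(self.P)
        m[: self.n_plain] = self.m0
        return m


def _gamma_moments(a, b):
    return a / b, digamma(a) - math.log(b)


def _gamma_terms(a, b, a0, b0):
    """E_q[ln p(lambda)] - E_q[ln q(lambda)] for Gamma q and prior."""
    E, Eln = _gamma_moments(a, b)
    lp = a0 * math.log(b0) - gammaln(a0) + (a0 - 1.0) * Eln - b0 * E
    lq = a * math.log(b) - gammaln(a) + (a - 1.0) * Eln - b * E
    return lp - lq


def free_energy(mu, Sigma, problem, lam_eps=None, lam_w=None, forward_out=None):
    """Variational free energy of a Gaussian posterior q = N(mu, Sigma).

    ``lam_eps`` is ("fixed", precision) or Gamma (shape, rate) posterior
    over the measurement precision (defaults to the problem's fixed noise if
    it has one).  ``lam_w`` is the Gamma posterior over the state-noise
    precision when the problem has an innovation block.  ``forward_out`` may
    carry a precomputed (yhat, G) pair at ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    P = mu.size
    if forward_out is None:
        forward_out = problem.forward(mu, True)
        if forward_out is None:
            return -np.inf
    yhat, G = forward_out
    r = problem.y - yhat
    N = r.size

    if lam_eps is None:
        lam_eps = problem.noise_eps
        if lam_eps[0] != "fixed":
            raise ValueError("lam_eps posterior required for Gamma noise")
    if lam_eps[0] == "fixed":
        E_le, Eln_le = lam_eps[1], math.log(lam_eps[1])
        gamma_eps_term = 0.0
    else:
        a, b = lam_eps
        E_le, Eln_le = _gamma_moments(a, b)
        a0, b0 = problem.noise_eps[1], problem.noise_eps[2]
        gamma_eps_term = _gamma_terms(a, b, a0, b0)

    GS = G @ Sigma
    tr_GSG = float(np.sum(GS * G))
    F = 0.5 * N * (Eln_le - math.log(2 * math.pi))
    F -= 0.5 * E_le * (float(r @ r) + tr_GSG)

    dvar = np.diag(Sigma)
    npl = problem.n_plain
    d = mu[:npl] - problem.m0
    F -= 0.5 * np.sum(np.log(2 * math.pi * problem.v0))
    F -= 0.5 * float(np.sum((d * d + dvar[:npl]) / problem.v0))

    gamma_w_term = 0.0
    if problem.n_w:
        if lam_w is None:
            raise ValueError("lam_w posterior required for the innovation block")
        aw, bw = lam_w
        E_lw, Eln_lw = _gamma_moments(aw, bw)
        wm = mu[npl:]
        F += 0.5 * problem.n_w * (Eln_lw - math.log(2 * math.pi))
        F -= 0.5 * float(np.sum(np.log(problem.w_scale)))
        F -= 0.5 * E_lw * float(np.sum((wm * wm + dvar[npl:]) / problem.w_scale))
        a0w, b0w = problem.state_prior
        gamma_w_term = _gamma_terms(aw, bw, a0w, b0w)

    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        jitter = 1e-8 * float(np.trace(Sigma)) / max(P, 1)
        sign, logdet = np.linalg.slogdet(Sigma + jitter * np.eye(P))
    F += 0.5 * (P * (1.0 + math.log(2 * math.pi)) + logdet)
    F += gamma_eps_term + gamma_w_term
    return float(F)


def _vb_invert(problem, settings, mu_init=None):
    """Levenberg-damped Gauss-Newton maximisation of the free energy."""
    y = problem.y
    N = y.size
    npl = problem.n_plain

    if problem.noise_eps[0] == "fixed":
        lam_eps = ("fixed", problem.noise_eps[1])
        E_le = problem.noise_eps[1]
    else:
        a0, b0 = problem.noise_eps[1], problem.noise_eps[2]
        var0 = max(float(np.var(y)), 1e-12)
        lam_eps = (a0 + 0.5 * N, b0 + 0.5 * N * var0)
        E_le = lam_eps[0] / lam_eps[1]

    lam_w = None
    E_lw = 0.0
    if problem.n_w:
        a0w, b0w = problem.state_prior
        lam_w = (a0w, b0w)
        E_lw = a0w / b0w

    mu = problem.prior_mean() if mu_init is None else np.array(mu_init, dtype=float)

    def objective(theta, fw=None):
        fw = problem.forward(theta, False) if fw is None else fw
        if fw is None:
            return -np.inf
        r = y - fw[0]
        U = -0.5 * E_le * float(r @ r)
        d = theta[:npl] - problem.m0
        U -= 0.5 * float(np.sum(d * d / problem.v0))
        if problem.n_w:
            wm = theta[npl:]
            U -= 0.5 * E_lw * float(np.sum(wm * wm / problem.w_scale))
        return U

    trace = []
    converged = False
    nu = 1e-3
    best = None
    Sigma = None
    fw_mu = None
    damped = False
    for it in range(settings.max_iter):
        fw_mu = problem.forward(mu, True)
        if fw_mu is None:
            raise RuntimeError("forward model diverged at the current posterior mean")
        yhat, G = fw_mu
        r = y - yhat
        P0 = problem.prior_precision(E_lw)
        H = E_le * (G.T @ G)
        H[np.diag_indices_from(H)] += P0
        grad = E_le * (G.T @ r) - P0 * (mu - problem.prior_mean())

        U_cur = objective(mu, fw_mu)
        accepted = False
        for _ in range(settings.max_step_halvings):
            Hd = H.copy()
            Hd[np.diag_indices_from(Hd)] *= (1.0 + nu)
            try:
                step = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                nu *= 10.0
                damped = True
                continue
            cand = mu + step
            U_cand = objective(cand)
            if U_cand > U_cur:
                mu = cand
                nu = max(nu / 3.0, 1e-9)
                accepted = True
                break
            nu *= 8.0
            damped = True
        if accepted:
            fw_mu = problem.forward(mu, True)
            yhat, G = fw_mu
            r = y - yhat
            H = E_le * (G.T @ G)
            H[np.diag_indices_from(H)] += P0

        Sigma = np.linalg.inv(H)
        Sigma = 0.5 * (Sigma + Sigma.T)

        # conjugate precision updates
        GS = G @ Sigma
        tr_GSG = float(np.sum(GS * G))
        if problem.noise_eps[0] != "fixed":
            a0, b0 = problem.noise_eps[1], problem.noise_eps[2]
            lam_eps = (a0 + 0.5 * N, b0 + 0.5 * (float(r @ r) + tr_GSG))
            E_le = lam_eps[0] / lam_eps[1]
        if problem.n_w:
            a0w, b0w = problem.state_prior
            wm = mu[npl:]
            wv = np.diag(Sigma)[npl:]
            lam_w = (a0w + 0.5 * problem.n_w,
                     b0w + 0.5 * float(np.sum((wm * wm + wv) / problem.w_scale)))
            E_lw = lam_w[0] / lam_w[1]

        F = free_energy(mu, Sigma, problem, lam_eps=lam_eps, lam_w=lam_w,
                        forward_out=fw_mu)
        if trace and F < trace[-1] - 1e-9 * max(1.0, abs(trace[-1])):
            # a decrease signals that the interleaved updates have reached
            # the resolution of the local quadratic expansion: revert to the
            # best iterate and stop
            converged = True
            break
        trace.append(F)
        if best is None or F >= best[0]:
            best = (F, mu.copy(), Sigma.copy(), lam_eps, lam_w)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-1]))
            if rel < settings.tol:
                converged = True
                break

    F, mu, Sigma, lam_eps, lam_w = best
    if damped:
        logger.info("Levenberg damping engaged during inversion")
    return Posterior(
        mu=mu,
        Sigma=Sigma,
        param_names=list(problem.names) + [f"w{i}" for i in range(problem.n_w)],
        index_map=None,
        free_energy=F,
        trace=trace,
        converged=converged,
        lambda_eps_posterior=lam_eps,
        lambda_state_posterior=lam_w,
        n_evolution=npl,
        metadata={"damped": damped},
    )


# ---------------------------------------------------------------------------
# DCM-specific problem assembly
# ---------------------------------------------------------------------------

def _conn_arrays(spec):
    conn = spec.connectivity
    n, m = conn.n_regions, conn.n_inputs
    Bst = np.array(conn.B) if conn.B else np.zeros((0, n, n))
    Dst = np.array(conn.D) if conn.D else np.zeros((0, n, n))
    Cb = (conn.basis_coefficients if conn.basis_coefficients is not None
          else np.zeros((n, 0)))
    return conn.A.copy(), Bst, conn.C.copy(), Dst, Cb.copy()


def _param_coding(index_map):
    pb, pi, pj, pk = [], [], [], []
    for block, coords in index_map.entries[: index_map.n_evolution]:
        if block == "A":
            pb.append(0); pi.append(coords[0]); pj.append(coords[1]); pk.append(0)
        elif block == "B":
            pb.append(1); pi.append(coords[0]); pj.append(coords[1]); pk.append(coords[2])
        elif block == "C":
            pb.append(2); pi.append(coords[0]); pj.append(coords[1]); pk.append(0)
        elif block == "D":
            pb.append(3); pi.append(coords[0]); pj.append(coords[1]); pk.append(coords[2])
        elif block == "basis":
            pb.append(4); pi.append(coords[0]); pj.append(coords[1]); pk.append(0)
    return (np.array(pb, dtype=np.int64), np.array(pi, dtype=np.int64),
            np.array(pj, dtype=np.int64), np.array(pk, dtype=np.int64))


class _DCMForward:
    """Forward map theta -> BOLD for a spec, using the compiled kernel.

    Free hemodynamic parameters (empirical mode) are handled by finite
    differences around the kernel pass.
    """

    def __init__(self, spec, input_course, TR, dt, n_scan, stochastic):
        self.template = spec.copy()
        _, self.index_map = pack_parameters(spec)
        self.n = spec.n_regions
        self.TR = TR
        self.dt = dt
        self.sub = int(round(TR / dt))
        self.n_scan = n_scan
        n_micro = self.sub * n_scan
        grid = np.arange(n_micro) * dt
        self.u = np.ascontiguousarray(_hold(input_course.u, input_course.times, grid))
        if spec.basis.K > 0:
            self.ub = np.ascontiguousarray(
                _hold(spec.basis.sampled_values, spec.basis.times, grid))
        else:
            self.ub = np.zeros((0, n_micro))
        self.delta = np.zeros((self.n, n_micro))
        self.coding = _param_coding(self.index_map)
        self.stochastic = stochastic
        self.n_w = self.n * n_scan if stochastic else 0
        self.n_evo = self.index_map.n_evolution
        self.n_hemo = self.index_map.n_hemo
        self.fd_step = 1e-4

    def _split(self, theta):
        evo = theta[: self.n_evo + self.n_hemo]
        w = theta[self.n_evo + self.n_hemo:]
        spec = unpack_parameters(evo, self.index_map, self.template)
        return spec, w

    def _kernel(self, spec, w, want_sens, want_state_sens=False):
        A, Bst, C, Dst, Cb = _conn_arrays(spec)
        hp = spec.hemo.as_array()
        w_mat = (w.reshape(self.n_scan, self.n).T if self.stochastic
                 else np.zeros((self.n, 0)))
        w_arg = np.ascontiguousarray(w_mat) if self.stochastic else np.zeros((self.n, 1))
        pb, pi, pj, pk = self.coding
        return _forward.forward_sens(
            self.n, self.dt, self.sub, self.n_scan,
            A, Bst, C, Dst, Cb,
            self.u, self.ub, self.delta, hp, w_arg,
            pb, pi, pj, pk,
            self.stochastic, want_sens, want_state_sens,
        )

    def __call__(self, theta, want_sens):
        spec, w = self._split(theta)
        out = self._kernel(spec, w, want_sens)
        status, y, G, _, _, _ = out
        if status >= 0:
            return None
        yflat = y.T.ravel()   # scan-major: row = scan * n + region
        if not want_sens:
            return yflat, None
        if self.n_hemo:
            G = self._augment_hemo(theta, spec, w, yflat, G)
        return yflat, G

    def _augment_hemo(self, theta, spec, w, y0, G_evo):
        """Insert finite-difference columns for free hemodynamic parameters
        between the evolution block and the innovation block."""
        cols = []
        for h in range(self.n_hemo):
            th = theta.copy()
            th[self.n_evo + h] += self.fd_step
            spec_h, _ = self._split(th)
            out = self._kernel(spec_h, w, False)
            if out[0] >= 0:
                return None
            cols.append((out[1].T.ravel() - y0) / self.fd_step)
        Gh = np.column_stack(cols)
        return np.hstack([G_evo[:, : self.n_evo], Gh, G_evo[:, self.n_evo:]])

    def state_estimates(self, theta, Sigma):
        """Posterior neural-state means and marginal variances at scan times."""
        spec, w = self._split(theta)
        status, y, G, xn, xh, Sxn = self._kernel(spec, w, True, True)
        if status >= 0:
            return None
        if self.n_hemo:
            # state sensitivities ignore hemodynamic-parameter uncertainty
            keep = np.r_[np.arange(self.n_evo),
                         np.arange(self.n_evo + self.n_hemo, Sigma.shape[0])]
            Sigma = Sigma[np.ix_(keep, keep)]
        var = np.einsum("krp,pq,krq->kr", Sxn, Sigma, Sxn)
        times = (np.arange(self.n_scan) + 1) * self.TR
        return {
            "times": times,
            "x_n_mean": xn,
            "x_n_var": np.maximum(var.T, 0.0),
            "x_h_mean": xh,
            "y_pred": y,
        }


def _initial_mean(problem, index_map, settings):
    """Initial expansion point: prior mean with the free self-connections
    set to a stabilising negative value.  If the forward model diverges
    there (e.g. a fixed baseline drive meeting weak initial coupling),
    progressively stronger self-inhibition is tried."""
    diag_idx = [i for i, (block, coords)
                in enumerate(index_map.entries[: index_map.n_evolution])
                if block == "A" and coords[0] == coords[1]]
    base = np.zeros(problem.P)
    base[: problem.n_plain] = problem.m0
    candidates = [settings.init_self_inhibition, -1.0, -2.0, -3.0, -5.0]
    for self_inh in candidates:
        mu = base.copy()
        for i in diag_idx:
            if problem.m0[i] == 0.0:
                mu[i] = self_inh
        if problem.forward(mu, False) is not None:
            return mu
    raise RuntimeError("no feasible initial expansion point found")


def _make_problem(spec, y, input_course, TR, settings, stochastic):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_scan = y.shape[1]
    if y.shape[0] != spec.n_regions:
        raise SpecificationError("y must have one row per region")
    dt = settings.dt if settings.dt is not None else TR / 8.0
    if abs(TR / dt - round(TR / dt)) > 1e-9:
        raise SpecificationError("inversion micro-step must divide TR")
    settings.validate(TR)
    fwd = _DCMForward(spec, input_course, TR, dt, n_scan, stochastic)
    m0, v0 = prior_moments(spec, fwd.index_map)
    noise = spec.priors.noise
    problem = VariationalProblem(
        forward=fwd,
        y=y.T.ravel(),
        m0=m0,
        v0=v0,
        noise_eps=("gamma",) + tuple(noise.measurement_noise_prior),
        n_w=fwd.n_w,
        w_scale=np.full(fwd.n_w, TR) if stochastic else None,
        state_prior=tuple(noise.state_noise_prior),
        names=fwd.index_map.names,
    )
    return problem, fwd


def invert_deterministic(spec, y, input_course, TR, settings=None):
    """Invert a deterministic DCM: posterior over free parameters, Gamma
    posterior over measurement precision, and the free energy."""
    settings = settings or InversionSettings()
    problem, fwd = _make_problem(spec, y, input_course, TR, settings, False)
    mu0 = _initial_mean(problem, fwd.index_map, settings)
    post = _vb_invert(problem, settings, mu_init=mu0)
    post.index_map = fwd.index_map
    post.states = fwd.state_estimates(post.mu, post.Sigma)
    post.metadata.update({"stochastic": False, "dt": fwd.dt, "TR": TR})
    return post


def invert_stochastic(spec, y, input_course, TR, settings=None):
    """Invert a stochastic DCM.

    The innovation block holds one neural impulse per region and scan with
    prior variance TR / lambda_w; lambda_w carries the Gamma hyperprior from
    the noise spec, and the hemodynamic state-noise variance is tied to the
    neural one through the fixed neural-to-hemodynamic ratio (hemodynamic
    innovations are not separately estimated: the ratio of 100 makes their
    prior contribution negligible).  Returns a posterior that includes the
    smoothed neural state trajectories.
    """
    settings = settings or InversionSettings()
    if not spec.priors.noise.stochastic:
        spec = spec.copy()
        spec.priors.noise.stochastic = True
    problem, fwd = _make_problem(spec, y, input_course, TR, settings, True)
    mu0 = _initial_mean(problem, fwd.index_map, settings)
    post = _vb_invert(problem, settings, mu_init=mu0)
    post.index_map = fwd.index_map
    post.w_mean = post.mu[problem.n_plain:].reshape(fwd.n_scan, fwd.n).T
    post.states = fwd.state_estimates(post.mu, post.Sigma)
    post.metadata.update({"stochastic": True, "dt": fwd.dt, "TR": TR,
                          "lag": settings.lag,
                          "lag_note": "batch smoother; conditioning exceeds lag"})
    return post


def posterior_correlation(posterior, include_w=False):
    """Posterior correlation matrix over the model parameters.

    Off-diagonal entries near zero indicate uniquely identifiable
    parameters.  Zero-variance parameters get zero correlation and a flag.
    """
    Sigma = posterior.Sigma if hasattr(posterior, "Sigma") else np.asarray(posterior)
    if hasattr(posterior, "n_evolution") and not include_w:
        k = posterior.n_evolution
        Sigma = Sigma[:k, :k]
    sd = np.sqrt(np.diag(Sigma))
    zero = sd == 0
    denom = np.outer(sd, sd)
    denom[denom == 0] = np.inf
    corr = Sigma / denom
    corr[np.diag_indices_from(corr)] = np.where(zero, 0.0, 1.0)
    if np.any(zero):
        logger.warning("zero-variance parameters in correlation matrix: %s",
                       np.where(zero)[0])
    return corr
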