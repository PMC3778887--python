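"""Integration of the stochastic neural-hemodynamic system and fixture networks.

The coupled system is integrated at a micro-time step ``dt`` (default
TR/16) by an Euler-Maruyama scheme whose drift part uses a Heun
(second-order) step -- the additive noise keeps the usual Euler-Maruyama
form while the deterministic skeleton gains an order of accuracy.  Neural
states receive Gaussian increments of
variance ``state_noise_var * dt``; hemodynamic states receive increments a
factor ``neural_to_hemo_variance_ratio`` (default 100) smaller.  BOLD is
read out through the observer at every TR and measurement noise is added at
a calibrated signal-to-noise ratio.

The fixture registry provides the small networks used throughout the test
battery (a stable linear inhibitory pair, a gated limit-cycle pair, mediated
and direct three-region variants, and an epilepsy-style three-node network
with block inputs).  Connection strengths are chosen, not measured: they are
picked to realise the intended qualitative regimes (stability, limit cycle,
mediation) and are fixed here once and for all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    DCMSpec,
    InputCourse,
    NeuralConnectivity,
    SpecificationError,
)

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SimulationBlowupError",
    "DegenerateSignalError",
    "integrate",
    "add_measurement_noise",
    "make_fluctuations",
    "fixture_network",
    "FIXTURE_NAMES",
]

STATE_CAP = 1e6


class SimulationBlowupError(RuntimeError):
    def __init__(self, t):
        self.t = t
        super().__init__(f"simulation diverged (|state| > {STATE_CAP:g}) at t = {t:.3f} s")


class DegenerateSignalError(ValueError):
    pass


@dataclass
class SimulationSettings:
    """Session geometry and noise levels for one simulated run."""

    TR: float = 1.0
    duration: float = 600.0
    dt: float | None = None          # micro-step; default TR/16
    snr_db: float = math.inf         # measurement SNR target
    state_noise_var: float = 0.0     # neural state-noise variance (per unit time)
    seed: int = 0

    def __post_init__(self):
        if self.dt is None:
            self.dt = self.TR / 16.0
        steps = self.TR / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise SpecificationError("dt must divide TR")
        scans = self.duration / self.TR
        if abs(scans - round(scans)) > 1e-9:
            raise SpecificationError("duration must be a whole number of TRs")
        if not (math.isfinite(self.snr_db) or self.snr_db == math.inf):
            raise SpecificationError("snr_db must be finite or +inf")
        if self.state_noise_var < 0:
            raise SpecificationError("state_noise_var must be >= 0")


@dataclass
class Trajectory:
    """One simulated session: micro-time states plus scan-time observations."""

    times_micro: np.ndarray
    x_n: np.ndarray          # (n, T_micro)
    x_h: np.ndarray          # (4n, T_micro), region-major (s, log f, log v, log q)
    times_scan: np.ndarray
    y_clean: np.ndarray      # (n, T_scan)
    y: np.ndarray            # (n, T_scan)
    eps: np.ndarray          # (n, T_scan) realized measurement noise
    state_noise: np.ndarray  # (n, T_micro) realized neural increments (unscaled by dt)
    hemo_noise: np.ndarray   # (4n, T_micro)
    seed: int | None = None
    settings: SimulationSettings | None = None


def _hold(values, src_times, dst_times):
    """Zero-order hold of a (k, T_src) series onto a finer grid."""
    if values is None:
        return None
    src_times = np.asarray(src_times)
    idx = np.searchsorted(src_times, dst_times + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, values.shape[1] - 1)
    return values[:, idx]


def _drift(z, n, conn, u_t, basis_t, delta_t, hp):
    """Time derivative of the stacked state z = (x_n, x_h region-major)."""
    x_n = z[:n]
    H = z[n:].reshape(n, 4)
    dx = conn.A @ x_n + conn.C @ u_t
    for i, Bi in enumerate(conn.B):
        if u_t[i] != 0.0:
            dx += u_t[i] * (Bi @ x_n)
    for j, Dj in enumerate(conn.D):
        if x_n[j] != 0.0:
            dx += x_n[j] * (Dj @ x_n)
    if basis_t is not None:
        dx += conn.basis_coefficients @ basis_t
    if delta_t is not None:
        dx = dx + delta_t
    s, lf, lv, lq = H[:, 0], H[:, 1], H[:, 2], H[:, 3]
    ef = np.exp(lf)
    a = hp.alpha
    dH = np.empty_like(H)
    dH[:, 0] = x_n - hp.kappa_s * s - hp.kappa_f * (ef - 1.0)
    dH[:, 1] = s / ef
    dH[:, 2] = (ef - np.exp(lv / a)) * np.exp(-lv) / hp.tau_0
    E = 1.0 - (1.0 - hp.E_0) ** np.exp(-lf)
    dH[:, 3] = (np.exp(lf - lq) * E / hp.E_0 - np.exp((1.0 - a) * lv / a)) / hp.tau_0
    return np.concatenate([dx, dH.ravel()])


def _bold_all(z, n, hp):
    H = z[n:].reshape(n, 4)
    lv, lq = H[:, 2], H[:, 3]
    k1 = 4.3 * hp.nu_0 * hp.E_0 * hp.TE
    k2 = hp.epsilon_0 * hp.r_0 * hp.E_0 * hp.TE
    k3 = 1.0 - hp.epsilon_0
    return hp.V_0 * (
        k1 * (1.0 - np.exp(lq)) + k2 * (1.0 - np.exp(lq - lv)) + k3 * (1.0 - np.exp(lv))
    )


def integrate(spec, input_course, settings, replay=None):
    """Integrate one session by Euler-Maruyama from x(0) = 0.

    Parameters
    ----------
    spec : DCMSpec
    input_course : InputCourse
    settings : SimulationSettings
    replay : (state_noise, hemo_noise, eps) tuple, optional
        Previously realized noise draws; when given, the trajectory is
        reproduced deterministically from them (same shapes as stored on
        :class:`Trajectory`).

    Notes
    -----
    The state-noise increments have variance ``state_noise_var * dt`` on the
    neural states and ``state_noise_var / ratio * dt`` on the hemodynamic
    states, where the ratio comes from the noise spec (default 100).  With
    ``state_noise_var = 0`` (or ``stochastic = False``) the path is the
    deterministic solution of the drift.
    """
    n = spec.n_regions
    conn = spec.connectivity
    hp = spec.hemo
    dt = settings.dt
    n_micro = int(round(settings.duration / dt))
    times_micro = (np.arange(n_micro) + 1) * dt
    sub = int(round(settings.TR / dt))
    n_scan = n_micro // sub
    times_scan = (np.arange(n_scan) + 1) * settings.TR

    grid = np.arange(n_micro) * dt  # left edge of each micro interval
    u_micro = _hold(input_course.u, input_course.times, grid)
    delta_micro = _hold(input_course.delta_u, input_course.times, grid)
    basis_micro = None
    if spec.basis.K > 0:
        basis_micro = _hold(spec.basis.sampled_values, spec.basis.times, grid)

    stochastic = spec.priors.noise.stochastic and settings.state_noise_var > 0
    rng = np.random.default_rng(settings.seed)
    if replay is not None:
        w_n, w_h, eps = replay
        w_n = np.asarray(w_n, dtype=float)
        w_h = np.asarray(w_h, dtype=float)
    elif stochastic:
        ratio = spec.priors.noise.neural_to_hemo_variance_ratio
        sd_n = math.sqrt(settings.state_noise_var * dt)
        sd_h = math.sqrt(settings.state_noise_var / ratio * dt)
        w_n = sd_n * rng.standard_normal((n, n_micro))
        w_h = sd_h * rng.standard_normal((4 * n, n_micro))
        eps = None
    else:
        w_n = np.zeros((n, n_micro))
        w_h = np.zeros((4 * n, n_micro))
        eps = None

    z = np.zeros(5 * n)
    x_n = np.empty((n, n_micro))
    x_h = np.empty((4 * n, n_micro))
    for k in range(n_micro):
        u_t = u_micro[:, k]
        basis_t = basis_micro[:, k] if basis_micro is not None else None
        delta_t = delta_micro[:, k] if delta_micro is not None else None
        # Heun (second-order) drift step with additive Euler-Maruyama noise
        f0 = _drift(z, n, conn, u_t, basis_t, delta_t, hp)
        z_pred = z + dt * f0
        f1 = _drift(z_pred, n, conn, u_t, basis_t, delta_t, hp)
        z = z + 0.5 * dt * (f0 + f1)
        z[:n] += w_n[:, k]
        z[n:] += w_h[:, k]
        if np.max(np.abs(z)) > STATE_CAP:
            raise SimulationBlowupError(times_micro[k])
        x_n[:, k] = z[:n]
        x_h[:, k] = z[n:]

    scan_idx = sub * np.arange(1, n_scan + 1) - 1
    y_clean = np.empty((n, n_scan))
    for j, k in enumerate(scan_idx):
        y_clean[:, j] = _bold_all(np.concatenate([x_n[:, k], x_h[:, k]]), n, hp)

    if replay is not None and eps is not None:
        y = y_clean + eps
    elif math.isinf(settings.snr_db):
        eps = np.zeros_like(y_clean)
        y = y_clean.copy()
    else:
        y, eps = _add_noise_draws(y_clean, settings.snr_db, rng)

    return Trajectory(
        times_micro=times_micro,
        x_n=x_n,
        x_h=x_h,
        times_scan=times_scan,
        y_clean=y_clean,
        y=y,
        eps=eps if eps is not None else np.zeros_like(y_clean),
        state_noise=w_n,
        hemo_noise=w_h,
        seed=settings.seed,
        settings=settings,
    )


def _add_noise_draws(y_clean, snr_db, rng):
    power = float(np.mean(y_clean**2))
    if power == 0.0:
        raise DegenerateSignalError("cannot set a finite SNR on an all-zero signal")
    target_var = power * 10.0 ** (-snr_db / 10.0)
    eps = rng.standard_normal(y_clean.shape)
    eps *= math.sqrt(target_var / np.mean(eps**2))
    y = y_clean + eps
    # store the realized noise as the exact float difference so that
    # y - y_clean == eps holds bit-for-bit
    return y, y - y_clean


def add_measurement_noise(y_clean, snr_db, seed):
    """Add i.i.d. Gaussian noise at the target SNR (dB), pooled over regions
    and time.  The draws are rescaled so the realized
    10 log10(<g^2>/<eps^2>) equals the target essentially exactly."""
    y_clean = np.atleast_2d(np.asarray(y_clean, dtype=float))
    if math.isinf(snr_db):
        return y_clean.copy()
    y, _ = _add_noise_draws(y_clean, snr_db, np.random.default_rng(seed))
    return y


def make_fluctuations(input_course, n_regions, snr_db=10.0, n_sinusoids=8, seed=0,
                      reference_channels=None):
    """Attach random neural fluctuations Delta-u to an input course.

    Delta-u is, per region, a random mixture of ``n_sinusoids`` sinusoids
    (frequencies drawn from 0.01-0.1 Hz, random phases) and white noise with
    an equal power split, rescaled so that the pooled state SNR
    10 log10(<u^2>/<Du^2>) hits the target.  ``n_sinusoids = 0`` gives pure
    white noise at the target power.

    ``reference_channels`` selects which input channels define the reference
    power <u^2>.  By default all channels with non-zero temporal variance are
    used: constant channels are baseline drives, not experimental stimuli,
    and do not count towards the reference power (if every channel is
    constant, all are used).
    """
    u_ref = input_course.u
    if reference_channels is not None:
        u_ref = u_ref[list(np.atleast_1d(reference_channels))]
    else:
        varying = u_ref.std(axis=1) > 0
        if varying.any():
            u_ref = u_ref[varying]
    u_power = float(np.mean(u_ref**2))
    if u_power == 0.0:
        raise DegenerateSignalError("input course has zero power")
    t = input_course.times
    T = t.size
    rng = np.random.default_rng(seed)
    target = u_power * 10.0 ** (-snr_db / 10.0)
    delta = np.zeros((n_regions, T))
    for r in range(n_regions):
        parts = []
        if n_sinusoids > 0:
            freqs = rng.uniform(0.01, 0.1, n_sinusoids)
            phases = rng.uniform(0, 2 * np.pi, n_sinusoids)
            amps = rng.uniform(0.5, 1.0, n_sinusoids)
            sin_part = np.zeros(T)
            for f, p, a in zip(freqs, phases, amps):
                sin_part += a * np.sin(2 * np.pi * f * t + p)
            sin_part *= math.sqrt((target / 2.0) / np.mean(sin_part**2))
            parts.append(sin_part)
        white = rng.standard_normal(T)
        w_target = target / 2.0 if n_sinusoids > 0 else target
        white *= math.sqrt(w_target / np.mean(white**2))
        parts.append(white)
        delta[r] = sum(parts)
    # exact pooled rescale
    delta *= math.sqrt(target / np.mean(delta**2))
    out = input_course.copy()
    out.delta_u = delta
    return out


# ---------------------------------------------------------------------------
# fixture networks
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "linear_2r",
    "lotka_volterra_2r",
    "mediated_3r",
    "direct_3r",
    "gating_2r_limit_cycle",
    "epilepsy_3r",
)

# Gated two-region system with a stable limit cycle (provenance: chosen by
# numerical search over the gating family, then frozen).  The raw system has
# an unstable spiral at the origin inside the cycle and a saddle outside it;
# because the balloon model tolerates only mild sustained deactivation, the
# operating point is translated into positive territory by a constant
# baseline drive delivered through a tonic input channel.  The translated
# quadratic system is again exactly of A/C/D form:
#   A' = A - sum_j x0_j D^(j) - sum_j (D^(j) x0) e_j^T,  c0 = f(-x0),
# with x0 = (0.55, 0.55) the translation.  Its limit cycle spans roughly
# x in [0.06, 1.27] x [0.07, 1.37]; the unstable spiral sits at x0 and the
# saddle at (2.12, 3.79).
_LC_D1 = np.array([[0.5, 0.13], [0.23, -0.53]])
_LC_D2 = np.array([[-1.0, 0.69], [0.44, -0.22]])
_LC_A = np.array([[-0.0115, -1.5605], [1.0765, 0.3515]])  # translated A'
_LC_C0 = np.array([0.7678, -0.7612])                      # baseline drive c0


def _boxcar_input(duration, step, amplitude=0.5, period=120.0, on=60.0):
    """One boxcar per `period` seconds, each `on` seconds long, into channel 1."""
    t = np.arange(0.0, duration, step)
    u = (amplitude * ((t % period) < on)).astype(float)[None, :]
    return InputCourse(times=t, u=u)


def fixture_network(name):
    """Return (DCMSpec, InputCourse, SimulationSettings) for a named fixture."""
    if name == "linear_2r":
        # Coupling strengths are plausible draws under the shrinkage prior
        # (sd ~ 0.32) and keep the deactivated node well above the balloon
        # model's sustained-deactivation limit (~ -kappa_f).
        conn = NeuralConnectivity(
            A=np.array([[-0.55, -0.25], [-0.25, -0.55]]),
            C=np.array([[0.6], [0.0]]),
            A_mask=np.ones((2, 2), dtype=int),
            C_mask=np.array([[1], [0]]),
        )
        spec = DCMSpec(connectivity=conn, label="linear_2r",
                       family_tags={"NL": "linear"})
        settings = SimulationSettings(TR=1.0, duration=600.0)
        return spec, _boxcar_input(600.0, 1.0, amplitude=0.2), settings
    if name == "lotka_volterra_2r":
        # channel 1: experimental boxcar into region 1; channel 2: constant
        # baseline drive realising the translated operating point (fixed).
        conn = NeuralConnectivity(
            A=_LC_A.copy(),
            C=np.column_stack([[0.5, 0.0], _LC_C0]),
            D=[_LC_D1.copy(), _LC_D2.copy()],
            A_mask=np.ones((2, 2), dtype=int),
            C_mask=np.array([[1, 0], [0, 0]]),
            D_masks=[np.ones((2, 2), dtype=int), np.ones((2, 2), dtype=int)],
        )
        spec = DCMSpec(connectivity=conn, label="lotka_volterra_2r",
                       family_tags={"NL": "nonlinear"})
        inp = _boxcar_input(600.0, 1.0, amplitude=0.2)
        inp.u = np.vstack([inp.u, np.ones_like(inp.u[0])[None, :]])
        settings = SimulationSettings(TR=1.0, duration=600.0)
        return spec, inp, settings
    if name in ("mediated_3r", "direct_3r"):
        # prior-plausible strengths; the direct links are kept weak so the
        # slow network mode stays well damped (sustained fluctuations would
        # otherwise drive deactivations the hemodynamics cannot follow)
        A = np.array([
            [-0.8, 0.3, 0.0],
            [0.3, -0.8, 0.3],
            [0.0, 0.3, -0.8],
        ])
        mask = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        if name == "direct_3r":
            A[0, 2] = 0.15
            A[2, 0] = 0.15
            mask = np.ones((3, 3), dtype=int)
        conn = NeuralConnectivity(
            A=A,
            C=np.array([[1.0], [0.0], [0.0]]),
            A_mask=mask,
            C_mask=np.array([[1], [0], [0]]),
        )
        spec = DCMSpec(connectivity=conn, label=name,
                       family_tags={"network": "A" if name == "mediated_3r" else "B"})
        settings = SimulationSettings(TR=1.0, duration=600.0)
        return spec, _boxcar_input(600.0, 1.0, amplitude=0.3), settings
    if name == "gating_2r_limit_cycle":
        # almost-full gating with a tonic input of unit magnitude; the tonic
        # drive realises the translated limit-cycle operating point.
        conn = NeuralConnectivity(
            A=_LC_A.copy(),
            C=_LC_C0.reshape(2, 1).copy(),
            D=[_LC_D1.copy(), _LC_D2.copy()],
            A_mask=np.ones((2, 2), dtype=int),
            C_mask=np.array([[1], [1]]),
            D_masks=[np.ones((2, 2), dtype=int), np.ones((2, 2), dtype=int)],
        )
        spec = DCMSpec(connectivity=conn, label="gating_2r_limit_cycle",
                       family_tags={"NL": "nonlinear"})
        t = np.arange(0.0, 600.0, 1.0)
        inp = InputCourse(times=t, u=np.ones((1, t.size)))  # tonic drive
        settings = SimulationSettings(TR=1.0, duration=600.0)
        return spec, inp, settings
    if name == "epilepsy_3r":
        conn = NeuralConnectivity(
            A=np.array([
                [-1.0, 0.2, 0.2],
                [0.2, -1.0, 0.2],
                [0.2, 0.2, -1.0],
            ]),
            C=np.array([[1.0], [0.0], [0.0]]),
            A_mask=np.ones((3, 3), dtype=int),
            C_mask=np.array([[1], [0], [0]]),
        )
        spec = DCMSpec(connectivity=conn, label="epilepsy_3r",
                       family_tags={"regions": "thalamus,pfc,precuneus"})
        # two GSW-style blocks of 30 s within a 10-min session sampled at TR = 3 s
        t = np.arange(0.0, 600.0, 3.0)
        u = (((t >= 120.0) & (t < 150.0)) | ((t >= 360.0) & (t < 390.0))).astype(float)
        inp = InputCourse(times=t, u=u[None, :])
        settings = SimulationSettings(TR=3.0, duration=600.0)
        return spec, inp, settings
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
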