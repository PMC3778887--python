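"""Model/results facade in the style of statsmodels.

``DCM`` wraps region-wise BOLD observations, the exogenous input course and
a model specification; ``fit`` runs variational Laplace and returns a
``DCMResults`` carrying the posterior moments, precision posteriors,
free energy and a ``summary()`` table.  Simulation and plotting hang off
these two objects; the functional interfaces in :mod:`sdcm.inference` and
:mod:`sdcm.simulator` remain available underneath.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .inference import (
    InversionSettings,
    invert_deterministic,
    invert_stochastic,
    posterior_correlation,
)
from .model_core import DCMSpec, InputCourse, pack_parameters
from .simulator import SimulationSettings, fixture_network, integrate

__all__ = ["DCM", "DCMResults"]


class DCM:
    """A dynamic causal model bound to one session of data.

    Parameters
    ----------
    endog : (n_regions, T) array or DataFrame (T x n_regions)
        Region-wise BOLD time series.
    inputs : InputCourse
    spec : DCMSpec
    tr : float
        Repetition time (s).
    """

    def __init__(self, endog, inputs, spec, tr):
        if isinstance(endog, pd.DataFrame):
            self.region_names = list(endog.columns)
            endog = endog.to_numpy().T
        else:
            endog = np.atleast_2d(np.asarray(endog, dtype=float))
            self.region_names = [f"region{r+1}" for r in range(endog.shape[0])]
        if endog.shape[0] != spec.n_regions:
            raise ValueError("endog must have one series per region")
        self.endog = endog
        self.inputs = inputs
        self.spec = spec
        self.tr = float(tr)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_fixture(cls, name, snr_db=math.inf, state_noise_var=0.0, seed=0,
                     fluctuations=False):
        """Simulate a named fixture network and bind the model to it.

        The returned model remembers the generating trajectory under
        ``.ground_truth`` (simulated sessions only).
        """
        from .simulator import make_fluctuations
        spec, inp, settings = fixture_network(name)
        settings = SimulationSettings(
            TR=settings.TR, duration=settings.duration,
            snr_db=snr_db, state_noise_var=state_noise_var, seed=seed)
        if fluctuations:
            inp = make_fluctuations(inp, spec.n_regions, snr_db=10.0, seed=seed)
        gen = spec.copy()
        if state_noise_var > 0:
            gen.priors.noise.stochastic = True
        traj = integrate(gen, inp, settings)
        model = cls(traj.y, inp, spec, settings.TR)
        model.ground_truth = traj
        return model

    @classmethod
    def from_files(cls, model_path, bold_path, input_path):
        from .io import load_model_config, read_timeseries
        spec = load_model_config(model_path)
        bold, meta = read_timeseries(bold_path)
        u, umeta = read_timeseries(input_path)
        inp = InputCourse(times=umeta["times"], u=u)
        return cls(bold, inp, spec, meta["step"])

    # -- estimation ---------------------------------------------------------
    def fit(self, method=None, settings=None, **kwargs):
        """Invert the model.

        ``method`` is 'stochastic' or 'deterministic'; by default it follows
        the spec's noise flag.  Extra keyword arguments populate the
        InversionSettings (lag, max_iter, tol, dt, seed).
        """
        if settings is None:
            settings = InversionSettings(**kwargs)
        if method is None:
            method = ("stochastic" if self.spec.priors.noise.stochastic
                      else "deterministic")
        if method == "stochastic":
            post = invert_stochastic(self.spec, self.endog, self.inputs,
                                     self.tr, settings)
        elif method == "deterministic":
            post = invert_deterministic(self.spec, self.endog, self.inputs,
                                        self.tr, settings)
        else:
            raise ValueError("method must be 'stochastic' or 'deterministic'")
        return DCMResults(self, post, method)

    # -- simulation ---------------------------------------------------------
    def simulate(self, snr_db=math.inf, state_noise_var=0.0, seed=0):
        settings = SimulationSettings(
            TR=self.tr, duration=self.endog.shape[1] * self.tr,
            snr_db=snr_db, state_noise_var=state_noise_var, seed=seed)
        spec = self.spec.copy()
        if state_noise_var > 0:
            spec.priors.noise.stochastic = True
        return integrate(spec, self.inputs, settings)


class DCMResults:
    """Estimation results: posterior moments, precisions and diagnostics."""

    def __init__(self, model, posterior, method):
        self.model = model
        self.posterior = posterior
        self.method = method

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def params(self):
        names = self.posterior.param_names[: self.posterior.n_evolution]
        return pd.Series(self.posterior.theta, index=names)

    @property
    def bse(self):
        names = self.posterior.param_names[: self.posterior.n_evolution]
        return pd.Series(self.posterior.theta_sd, index=names)

    def cov_params(self):
        k = self.posterior.n_evolution
        names = self.posterior.param_names[:k]
        return pd.DataFrame(self.posterior.Sigma[:k, :k], index=names,
                            columns=names)

    def corr_params(self):
        k = self.posterior.n_evolution
        names = self.posterior.param_names[:k]
        return pd.DataFrame(posterior_correlation(self.posterior),
                            index=names, columns=names)

    @property
    def free_energy(self):
        return self.posterior.free_energy

    @property
    def converged(self):
        return self.posterior.converged

    @property
    def states(self):
        return self.posterior.states

    def spec_at_posterior(self):
        return self.posterior.spec_at_posterior(self.model.spec)

    def summary(self):
        """Plain-text summary of the inversion."""
        post = self.posterior
        lines = []
        lines.append(f"Dynamic causal model ({self.method}) — "
                     f"{self.model.spec.label}")
        lines.append(f"regions: {self.model.spec.n_regions}   "
                     f"scans: {self.model.endog.shape[1]}   "
                     f"TR: {self.model.tr:g} s")
        lines.append(f"free energy: {post.free_energy:.3f}   "
                     f"iterations: {len(post.trace)}   "
                     f"converged: {post.converged}")
        a, b = post.lambda_eps_posterior
        lines.append(f"measurement precision (posterior mean): {a / b:.4g}")
        if post.lambda_state_posterior is not None:
            aw, bw = post.lambda_state_posterior
            lines.append(f"state-noise precision (posterior mean): {aw / bw:.4g}")
        lines.append("")
        lines.append(f"{'parameter':<14s}{'mean':>10s}{'sd':>10s}")
        for name, m, s in zip(self.params.index, self.params, self.bse):
            lines.append(f"{name:<14s}{m:>10.4f}{s:>10.4f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs predicted BOLD per region (diagnostic plot)."""
        import matplotlib.pyplot as plt
        st = self.posterior.states
        n = self.model.endog.shape[0]
        if ax is None:
            _, ax = plt.subplots(n, 1, sharex=True, squeeze=False)
            ax = ax[:, 0]
        times = st["times"]
        for r in range(n):
            ax[r].plot(times, self.model.endog[r], ".", ms=2, label="observed")
            ax[r].plot(times, st["y_pred"][r], "-", label="predicted")
            ax[r].set_ylabel(self.model.region_names[r])
        ax[0].legend(loc="best", fontsize="small")
        ax[-1].set_xlabel("time (s)")
        return ax
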