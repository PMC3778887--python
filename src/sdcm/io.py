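"""Readers, writers and configuration for time series, model specs and
posterior archives.

Time series travel as TSV (first column ``time`` in seconds, one column per
region); model specifications as YAML with an explicit schema version.
Posterior archives pair a keyed binary container (``.npz``) with a JSON
manifest so that runs can be replayed and compared exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    BasisSet,
    DCMSpec,
    HemodynamicParams,
    InputCourse,
    NeuralConnectivity,
    NoiseSpec,
    PriorSet,
    HEMO_PARAM_NAMES,
)

__all__ = [
    "ParseError",
    "ConfigError",
    "read_timeseries",
    "write_timeseries",
    "load_model_config",
    "save_model_config",
    "SessionBundle",
    "save_session",
    "load_session",
    "save_posterior",
    "load_posterior",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    pass


class ConfigError(ValueError):
    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid model config:\n" +
                         "\n".join(f"  - {v}" for v in self.violations))


def read_timeseries(path):
    """Read a TSV time-series file.

    Returns (matrix, metadata): matrix is (n_series, T); metadata carries
    the column names, the time vector and the (validated constant) step.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if not cols or cols[0].strip().lower() != "time":
        raise ParseError(f"{path}:1: first header column must be 'time'")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable TSV ({exc})") from exc
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0]) + 2
        raise ParseError(f"{path}:{bad}: ragged or incomplete row")
    try:
        values = df.to_numpy(dtype=float)  # dot-decimal only, locale-proof
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry ({exc})") from exc
    times = values[:, 0]
    dt = np.diff(times)
    if times.size > 1:
        if np.any(dt <= 0):
            row = int(np.where(dt <= 0)[0][0]) + 3
            raise ParseError(f"{path}:{row}: time column must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            row = int(np.where(~np.isclose(dt, dt[0], rtol=1e-9, atol=1e-12))[0][0]) + 3
            raise ParseError(f"{path}:{row}: non-uniform time step")
    meta = {
        "names": cols[1:],
        "times": times,
        "step": float(dt[0]) if times.size > 1 else 0.0,
    }
    return values[:, 1:].T.copy(), meta


def write_timeseries(matrix, times, names, path):
    """Write a (n_series, T) matrix as TSV at 17 significant digits (exact
    round-trip for doubles)."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    times = np.asarray(times, dtype=float)
    if matrix.shape[1] != times.size:
        raise ValueError("matrix/time length mismatch")
    if len(names) != matrix.shape[0]:
        raise ValueError("one name per series required")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(names) + "\n")
        for k in range(times.size):
            row = [f"{times[k]:.17g}"] + [f"{matrix[r, k]:.17g}"
                                          for r in range(matrix.shape[0])]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"schema_version", "label", "regions", "inputs", "connectivity",
             "priors", "hemodynamics", "basis", "family_tags"}
_CONN_KEYS = {"A", "A_mask", "B", "B_masks", "C", "C_mask", "D", "D_masks"}
_PRIOR_KEYS = {"evolution_variance", "evolution_mean", "hemodynamic_variance",
               "noise"}
_NOISE_KEYS = {"stochastic", "state_noise_prior", "measurement_noise_prior",
               "neural_to_hemo_variance_ratio"}


def _check_matrix(value, shape, name, violations):
    try:
        arr = np.asarray(value, dtype=float)
    except Exception:
        violations.append(f"{name}: not numeric")
        return None
    if arr.shape != shape:
        violations.append(f"{name}: expected shape {shape}, got {arr.shape}")
        return None
    return arr


def load_model_config(path):
    """Load and validate a YAML model config; every violation found is
    reported (not just the first)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    violations = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError([
            f"unsupported schema version {version!r} (this build reads "
            f"version {SCHEMA_VERSION})"])
    for key in raw:
        if key not in _TOP_KEYS:
            violations.append(f"unknown top-level key {key!r}")
    n = raw.get("regions")
    m = raw.get("inputs")
    if not isinstance(n, int) or n < 1:
        violations.append("regions: must be a positive integer")
    if not isinstance(m, int) or m < 1:
        violations.append("inputs: must be a positive integer")
    conn_raw = raw.get("connectivity")
    if not isinstance(conn_raw, dict):
        violations.append("connectivity: missing or not a mapping")
        conn_raw = {}
    for key in conn_raw:
        if key not in _CONN_KEYS:
            violations.append(f"connectivity: unknown key {key!r}")
    conn_kwargs = {}
    if isinstance(n, int) and isinstance(m, int):
        A = _check_matrix(conn_raw.get("A"), (n, n), "connectivity.A", violations)
        C = _check_matrix(conn_raw.get("C", np.zeros((n, m)).tolist()),
                          (n, m), "connectivity.C", violations)
        conn_kwargs["A"], conn_kwargs["C"] = A, C
        for key, shape_n in (("A_mask", (n, n)), ("C_mask", (n, m))):
            if key in conn_raw:
                conn_kwargs[key] = _check_matrix(conn_raw[key], shape_n,
                                                 f"connectivity.{key}", violations)
        for key, count in (("B", m), ("D", n)):
            if key in conn_raw:
                mats = conn_raw[key]
                if not isinstance(mats, list) or (mats and len(mats) != count):
                    violations.append(
                        f"connectivity.{key}: expected a list of {count} matrices")
                else:
                    conn_kwargs[key] = [
                        _check_matrix(mi, (n, n), f"connectivity.{key}[{i}]",
                                      violations)
                        for i, mi in enumerate(mats)]
            mk = key + "_masks"
            if mk in conn_raw:
                conn_kwargs[mk] = [
                    _check_matrix(mi, (n, n), f"connectivity.{mk}[{i}]", violations)
                    for i, mi in enumerate(conn_raw[mk])]
    priors_raw = raw.get("priors", {}) or {}
    for key in priors_raw:
        if key not in _PRIOR_KEYS:
            violations.append(f"priors: unknown key {key!r}")
    noise_raw = priors_raw.get("noise", {}) or {}
    for key in noise_raw:
        if key not in _NOISE_KEYS:
            violations.append(f"priors.noise: unknown key {key!r}")
    hemo_raw = raw.get("hemodynamics", {}) or {}
    for key in hemo_raw:
        if key not in HEMO_PARAM_NAMES:
            violations.append(f"hemodynamics: unknown parameter {key!r}")
    basis_raw = raw.get("basis", {}) or {}
    if basis_raw.get("kind", "none") != "none":
        violations.append("basis: configs carry kind 'none'; attach basis sets "
                          "programmatically (they depend on the session grid)")
    if violations or any(v is None for v in conn_kwargs.values()):
        raise ConfigError(violations or ["connectivity matrices unreadable"])
    try:
        conn = NeuralConnectivity(**conn_kwargs)
        noise = NoiseSpec(
            stochastic=bool(noise_raw.get("stochastic", False)),
            state_noise_prior=tuple(noise_raw.get("state_noise_prior", (1.0, 0.1))),
            measurement_noise_prior=tuple(
                noise_raw.get("measurement_noise_prior", (1e-8, 1e-8))),
            neural_to_hemo_variance_ratio=float(
                noise_raw.get("neural_to_hemo_variance_ratio", 100.0)),
        )
        priors = PriorSet(
            evolution_variance=float(priors_raw.get("evolution_variance", 0.1)),
            evolution_mean=priors_raw.get("evolution_mean"),
            hemodynamic_variance=float(priors_raw.get("hemodynamic_variance", 0.0)),
            noise=noise,
        )
        hemo = HemodynamicParams(**{k: float(v) for k, v in hemo_raw.items()})
        spec = DCMSpec(connectivity=conn, hemo=hemo, priors=priors,
                       basis=BasisSet(),
                       label=str(raw.get("label", "dcm")),
                       family_tags=dict(raw.get("family_tags", {}) or {}))
    except Exception as exc:
        raise ConfigError([str(exc)]) from exc
    if spec.n_regions != n or spec.n_inputs != m:
        raise ConfigError(["declared regions/inputs do not match matrices"])
    return spec


def save_model_config(spec, path):
    conn = spec.connectivity
    doc = {
        "schema_version": SCHEMA_VERSION,
        "label": spec.label,
        "regions": int(spec.n_regions),
        "inputs": int(spec.n_inputs),
        "connectivity": {
            "A": conn.A.tolist(),
            "A_mask": conn.A_mask.tolist(),
            "C": conn.C.tolist(),
            "C_mask": conn.C_mask.tolist(),
        },
        "priors": {
            "evolution_variance": float(spec.priors.evolution_variance),
            "hemodynamic_variance": float(spec.priors.hemodynamic_variance),
            "noise": {
                "stochastic": bool(spec.priors.noise.stochastic),
                "state_noise_prior": [float(v) for v in
                                      spec.priors.noise.state_noise_prior],
                "measurement_noise_prior": [
                    float(v) for v in spec.priors.noise.measurement_noise_prior],
                "neural_to_hemo_variance_ratio": float(
                    spec.priors.noise.neural_to_hemo_variance_ratio),
            },
        },
        "hemodynamics": {k: float(getattr(spec.hemo, k))
                         for k in HEMO_PARAM_NAMES},
        "basis": {"kind": "none", "K": 0},
        "family_tags": dict(spec.family_tags),
    }
    if conn.B:
        doc["connectivity"]["B"] = [b.tolist() for b in conn.B]
        doc["connectivity"]["B_masks"] = [np.asarray(mk).tolist()
                                          for mk in conn.B_masks]
    if conn.D:
        doc["connectivity"]["D"] = [d.tolist() for d in conn.D]
        doc["connectivity"]["D_masks"] = [np.asarray(mk).tolist()
                                          for mk in conn.D_masks]
    if spec.priors.evolution_mean is not None:
        doc["priors"]["evolution_mean"] = np.asarray(
            spec.priors.evolution_mean, dtype=float).tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# session bundles and posterior archives
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    bold: np.ndarray          # (n, T_scan)
    TR: float
    input_course: InputCourse
    spec: DCMSpec
    trajectory: object | None = None
    provenance: dict = field(default_factory=dict)


def _config_hash(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def save_session(bundle, outdir):
    """Write a session to a directory: BOLD + input TSVs, model YAML and a
    provenance block sufficient for exact replay of simulated bundles."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    n = bundle.bold.shape[0]
    times = (np.arange(bundle.bold.shape[1]) + 1) * bundle.TR
    write_timeseries(bundle.bold, times,
                     [f"region{r+1}" for r in range(n)], out / "bold.tsv")
    inp = bundle.input_course
    write_timeseries(inp.u, inp.times,
                     [f"u{i+1}" for i in range(inp.u.shape[0])],
                     out / "input.tsv")
    if inp.delta_u is not None:
        write_timeseries(inp.delta_u, inp.times,
                         [f"delta{r+1}" for r in range(inp.delta_u.shape[0])],
                         out / "fluctuations.tsv")
    save_model_config(bundle.spec, out / "model.yaml")
    prov = dict(bundle.provenance)
    prov.update({"TR": bundle.TR, "config_sha256": _config_hash(out / "model.yaml")})
    traj = bundle.trajectory
    if traj is not None:
        np.savez(out / "trajectory.npz",
                 times_micro=traj.times_micro, x_n=traj.x_n, x_h=traj.x_h,
                 times_scan=traj.times_scan, y_clean=traj.y_clean, y=traj.y,
                 eps=traj.eps, state_noise=traj.state_noise,
                 hemo_noise=traj.hemo_noise)
        prov["seed"] = traj.seed
        if traj.settings is not None:
            prov["settings"] = {
                "TR": traj.settings.TR, "duration": traj.settings.duration,
                "dt": traj.settings.dt,
                "snr_db": (traj.settings.snr_db
                           if math.isfinite(traj.settings.snr_db) else "inf"),
                "state_noise_var": traj.settings.state_noise_var,
                "seed": traj.settings.seed,
            }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))


def load_session(path):
    path = Path(path)
    bold, meta = read_timeseries(path / "bold.tsv")
    u, umeta = read_timeseries(path / "input.tsv")
    delta = None
    if (path / "fluctuations.tsv").exists():
        delta, _ = read_timeseries(path / "fluctuations.tsv")
    inp = InputCourse(times=umeta["times"], u=u, delta_u=delta)
    spec = load_model_config(path / "model.yaml")
    prov = json.loads((path / "provenance.json").read_text())
    TR = float(prov["TR"])
    return SessionBundle(bold=bold, TR=TR, input_course=inp, spec=spec,
                         provenance=prov)


def save_posterior(post, outdir):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {"mu": post.mu, "Sigma": post.Sigma,
              "trace": np.asarray(post.trace)}
    if post.w_mean is not None:
        arrays["w_mean"] = post.w_mean
    if post.states is not None:
        for key in ("times", "x_n_mean", "x_n_var"):
            arrays[f"states_{key}"] = post.states[key]
    np.savez(out / "posterior.npz", **arrays)
    manifest = {
        "free_energy": post.free_energy,
        "converged": bool(post.converged),
        "n_evolution": int(post.n_evolution),
        "param_names": post.param_names[: post.n_evolution],
        "lambda_eps_posterior": list(post.lambda_eps_posterior),
        "lambda_state_posterior": (list(post.lambda_state_posterior)
                                   if post.lambda_state_posterior else None),
        "metadata": {k: v for k, v in post.metadata.items()
                     if isinstance(v, (str, int, float, bool))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_posterior(path):
    from .inference import Posterior
    path = Path(path)
    data = np.load(path / "posterior.npz")
    manifest = json.loads((path / "manifest.json").read_text())
    states = None
    if "states_times" in data:
        states = {"times": data["states_times"],
                  "x_n_mean": data["states_x_n_mean"],
                  "x_n_var": data["states_x_n_var"]}
    lam_state = manifest["lambda_state_posterior"]
    return Posterior(
        mu=data["mu"], Sigma=data["Sigma"],
        param_names=list(manifest["param_names"]),
        index_map=None,
        free_energy=float(manifest["free_energy"]),
        trace=list(data["trace"]),
        converged=bool(manifest["converged"]),
        lambda_eps_posterior=tuple(manifest["lambda_eps_posterior"]),
        lambda_state_posterior=tuple(lam_state) if lam_state else None,
        n_evolution=int(manifest["n_evolution"]),
        w_mean=data["w_mean"] if "w_mean" in data else None,
        states=states,
        metadata=dict(manifest.get("metadata", {})),
    )
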