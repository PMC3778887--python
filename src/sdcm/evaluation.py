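"""Monte-Carlo evaluation machinery: estimation metrics, model comparison,
factorial study designs and the epilepsy-style model space.

Two metrics summarise estimation quality for a group of variables
(parameters, neural states, or inputs):

    MSE = (1/n) sum_i (truth_i - estimate_i)^2
    MCB = (1/n) sum_i [ (truth_i - mu_i)^2 - Sigma_ii ]

The posterior variance is the *expected* squared estimation error under a
well-specified model, so MCB > 0 means the scheme is overconfident and
MCB < 0 underconfident.  Model comparison uses the log-Bayes factor
LBF_AB = F_A - F_B (free-energy approximation to the log evidence ratio);
positive values favour model A.

The two study designs mirror a 2 (SNR) x 2 (nonlinearity) x 2 (fluctuations)
accuracy design analysed under a 2 (DCM type) x 3 (basis set) model grid,
and a 2 (network) x 2 (fluctuations) discrimination design analysed under a
2 (network) x 2 (DCM type) grid.  Reduced-scale presets (fewer repetitions,
shorter sessions) ship alongside the full designs so the whole pipeline can
be exercised at desk scale; per-session seeds are derived from the cell
labels, so execution order never changes any record.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import InversionSettings, invert_deterministic, invert_stochastic
from .model_core import (
    DCMSpec,
    NeuralConnectivity,
    NoiseSpec,
    PriorSet,
    attach_basis,
    pack_parameters,
)
from .simulator import (
    SimulationSettings,
    add_measurement_noise,
    fixture_network,
    integrate,
    make_fluctuations,
)

__all__ = [
    "mse",
    "mcb",
    "lbf",
    "MonteCarloDesign",
    "accuracy_design",
    "discrimination_design",
    "run_accuracy_study",
    "run_discrimination_study",
    "build_epilepsy_model_space",
    "ModelSpace",
    "summarize_effects",
]


def mse(theta_true, theta_hat):
    """Mean squared error between simulated and estimated variables."""
    t = np.asarray(theta_true, dtype=float).ravel()
    h = np.asarray(theta_hat, dtype=float).ravel()
    if t.shape != h.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {h.shape}")
    if t.size == 0:
        raise ValueError("empty variable group")
    return float(np.mean((t - h) ** 2))


def mcb(theta_true, mu, sigma_diag):
    """Mean confidence bias: squared error minus posterior variance,
    averaged over the group.  Positive = overconfident."""
    t = np.asarray(theta_true, dtype=float).ravel()
    m = np.asarray(mu, dtype=float).ravel()
    v = np.asarray(sigma_diag, dtype=float).ravel()
    if not (t.shape == m.shape == v.shape):
        raise ValueError("length mismatch in mcb")
    if np.any(v < 0):
        raise ValueError("posterior variances must be >= 0")
    return float(np.mean((t - m) ** 2 - v))


def lbf(F_A, F_B):
    """Log-Bayes factor of model A over model B from their free energies."""
    if not (np.isfinite(F_A) and np.isfinite(F_B)):
        raise ValueError("free energies must be finite")
    return float(F_A - F_B)


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloDesign:
    """Factorial data-generation design.

    ``factors`` maps factor names to level lists (data-generation factors
    only); total sessions = repetitions x product of level counts.
    """

    factors: dict
    repetitions: int
    base_seed: int = 0
    duration: float = 600.0
    TR: float = 1.0

    @property
    def n_sessions(self):
        n = self.repetitions
        for levels in self.factors.values():
            n *= len(levels)
        return n

    def sessions(self):
        """Deterministic enumeration of (cell dict, rep, seed)."""
        cells = [{}]
        for name, levels in self.factors.items():
            cells = [dict(c, **{name: lv}) for c in cells for lv in levels]
        out = []
        for cell in cells:
            for rep in range(self.repetitions):
                out.append((cell, rep, self.session_seed(cell, rep)))
        return out

    def session_seed(self, cell, rep):
        key = "|".join(f"{k}={cell[k]}" for k in sorted(cell)) + f"|rep={rep}"
        return (zlib.crc32(key.encode()) ^ (self.base_seed * 2654435761)) % (2**31)


def accuracy_design(preset="full", base_seed=0):
    """The estimation-accuracy design: SNR x nonlinearity x fluctuations.

    The full design has 2 x 2 x 2 cells x 24 repetitions = 192 sessions of
    10 minutes at TR = 1 s.  The reduced preset keeps two informative cells
    and 2 repetitions of 5-minute sessions for desk-scale runs.
    """
    if preset == "full":
        return MonteCarloDesign(
            factors={"snr_db": [1.0, 10.0], "NL": ["linear", "nonlinear"],
                     "du": [False, True]},
            repetitions=24, base_seed=base_seed, duration=600.0, TR=1.0)
    if preset == "reduced":
        return MonteCarloDesign(
            factors={"snr_db": [10.0], "NL": ["linear", "nonlinear"],
                     "du": [True]},
            repetitions=2, base_seed=base_seed, duration=300.0, TR=1.0)
    raise KeyError(f"unknown preset {preset!r}")


def discrimination_design(preset="full", base_seed=0):
    """The mediated-vs-direct discrimination design at 1 dB SNR."""
    if preset == "full":
        return MonteCarloDesign(
            factors={"network": ["A", "B"], "du": [False, True]},
            repetitions=24, base_seed=base_seed, duration=600.0, TR=1.0)
    if preset == "reduced":
        return MonteCarloDesign(
            factors={"network": ["A"], "du": [True]},
            repetitions=8, base_seed=base_seed, duration=300.0, TR=1.0)
    raise KeyError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# study execution
# ---------------------------------------------------------------------------

def _session_inputs(fixture, cell, design, seed):
    spec, inp, settings = fixture_network(fixture)
    n_scan = int(round(design.duration / design.TR))
    inp = inp.copy()
    keep = inp.times < design.duration - 1e-9
    inp.times = inp.times[keep]
    inp.u = inp.u[:, keep]
    settings = SimulationSettings(TR=design.TR, duration=design.duration,
                                  snr_db=cell.get("snr_db", math.inf),
                                  seed=seed)
    if cell.get("du", False):
        inp = make_fluctuations(inp, spec.n_regions, snr_db=10.0, seed=seed)
    return spec, inp, settings, n_scan


def _drive_rows(spec_inv, index_map, u_scan, ub_scan, n_scan, n, n_w, TR):
    """Linear maps from the packed parameter vector to the per-region input
    drive at each scan (known input + modelled fluctuations)."""
    P = len(index_map) + n_w
    rows = np.zeros((n_scan * n, P))
    for p, (block, coords) in enumerate(index_map.entries):
        if block == "C":
            r, i = coords
            rows[r::n, p] = u_scan[i]
        elif block == "basis":
            r, k = coords
            rows[r::n, p] = ub_scan[k]
    if n_w:
        base = len(index_map)
        for k in range(n_scan):
            for r in range(n):
                rows[k * n + r, base + k * n + r] = 1.0 / TR
    return rows


def _true_drive(spec, inp, times_scan):
    from .simulator import _hold
    u_scan = _hold(inp.u, inp.times, times_scan)
    drive = spec.connectivity.C @ u_scan
    if inp.delta_u is not None:
        drive = drive + _hold(inp.delta_u, inp.times, times_scan)
    return drive


ANALYSES_FULL = [(t, b) for t in ("stochastic", "deterministic")
                 for b in ("none", "fourier", "rbf")]


def run_accuracy_study(design, analyses=None, basis_K=32,
                       inversion=None, progress=False):
    """Simulate every session of the design and invert it under each
    analysis cell (DCM type x basis set); returns one record per analysis.

    Individual inversion failures are recorded (status column) rather than
    raised.
    """
    analyses = analyses if analyses is not None else ANALYSES_FULL
    inversion = inversion or InversionSettings(dt=design.TR / 8.0)
    records = []
    for cell, rep, seed in design.sessions():
        fixture = "linear_2r" if cell["NL"] == "linear" else "lotka_volterra_2r"
        spec, inp, settings, n_scan = _session_inputs(fixture, cell, design, seed)
        spec_gen = spec.copy()
        spec_gen.priors.noise.stochastic = False
        try:
            traj = integrate(spec_gen, inp, settings)
        except Exception as exc:   # noqa: BLE001 - recorded, not fatal
            for dcm_type, basis in analyses:
                records.append(_failed_record(cell, rep, seed, dcm_type, basis,
                                              f"simulation: {exc}"))
            continue
        theta_true, imap_true = pack_parameters(spec_gen)
        sub = int(round(design.TR / settings.dt))
        xn_true = traj.x_n[:, sub - 1::sub]
        drive_true = _true_drive(spec_gen, inp, traj.times_scan)
        for dcm_type, basis in analyses:
            rec = _analyse_session(
                spec_gen, traj, inp, design, cell, rep, seed,
                dcm_type, basis, basis_K, inversion,
                theta_true, xn_true, drive_true)
            records.append(rec)
            if progress:
                print(f"cell={cell} rep={rep} {dcm_type}/{basis}: {rec['status']}")
    return pd.DataFrame.from_records(records)


def _failed_record(cell, rep, seed, dcm_type, basis, reason):
    rec = dict(cell)
    rec.update({"rep": rep, "seed": seed, "dcm_type": dcm_type, "basis": basis,
                "status": reason})
    for g in ("params", "states", "input"):
        rec[f"mse_{g}"] = np.nan
        rec[f"mcb_{g}"] = np.nan
    rec["F"] = np.nan
    rec["converged"] = False
    return rec


def _analyse_session(spec_gen, traj, inp, design, cell, rep, seed,
                     dcm_type, basis, basis_K, inversion,
                     theta_true, xn_true, drive_true):
    from .simulator import _hold
    n = spec_gen.n_regions
    spec_inv = spec_gen.copy()
    spec_inv.priors.noise.stochastic = dcm_type == "stochastic"
    if basis != "none":
        spec_inv = attach_basis(spec_inv, basis, basis_K, design.duration, design.TR)
    try:
        if dcm_type == "stochastic":
            post = invert_stochastic(spec_inv, traj.y, inp, design.TR, inversion)
        else:
            post = invert_deterministic(spec_inv, traj.y, inp, design.TR, inversion)
    except Exception as exc:   # noqa: BLE001
        return _failed_record(cell, rep, seed, dcm_type, basis, f"inversion: {exc}")

    rec = dict(cell)
    rec.update({"rep": rep, "seed": seed, "dcm_type": dcm_type, "basis": basis,
                "status": "ok", "F": post.free_energy,
                "converged": post.converged})
    # parameters: compare the shared (generating) free parameters only
    n_shared = theta_true.size
    mu_th = post.theta[:n_shared]
    var_th = np.diag(post.Sigma)[:n_shared]
    rec["mse_params"] = mse(theta_true, mu_th)
    rec["mcb_params"] = mcb(theta_true, mu_th, var_th)
    # neural states at scan times
    st = post.states
    rec["mse_states"] = mse(xn_true, st["x_n_mean"])
    rec["mcb_states"] = mcb(xn_true.ravel(), st["x_n_mean"].ravel(),
                            st["x_n_var"].ravel())
    # region-wise input drive (known input + modelled fluctuations)
    n_scan = st["x_n_mean"].shape[1]
    u_scan = _hold(inp.u, inp.times, st["times"])
    if spec_inv.basis.K > 0:
        ub_scan = _hold(spec_inv.basis.sampled_values, spec_inv.basis.times,
                        st["times"])
    else:
        ub_scan = np.zeros((0, n_scan))
    n_w = (n * n_scan) if dcm_type == "stochastic" else 0
    L = _drive_rows(spec_inv, post.index_map, u_scan, ub_scan, n_scan, n,
                    n_w, design.TR)
    drive_mu = L @ post.mu
    drive_var = np.einsum("ip,pq,iq->i", L, post.Sigma, L)
    rec["mse_input"] = mse(drive_true.T.ravel(), drive_mu)
    rec["mcb_input"] = mcb(drive_true.T.ravel(), drive_mu,
                           np.maximum(drive_var, 0.0))
    return rec


def run_discrimination_study(design, inversion=None, snr_db=1.0, progress=False):
    """Simulate mediated/direct sessions and invert each under both network
    structures and both DCM types; records LBF_AB per session and type."""
    inversion = inversion or InversionSettings(dt=design.TR / 8.0)
    spec_A = fixture_network("mediated_3r")[0]
    spec_B = fixture_network("direct_3r")[0]
    records = []
    for cell, rep, seed in design.sessions():
        gen_name = "mediated_3r" if cell["network"] == "A" else "direct_3r"
        cell_sim = dict(cell, snr_db=cell.get("snr_db", snr_db))
        spec, inp, settings, _ = _session_inputs(gen_name, cell_sim, design, seed)
        try:
            traj = integrate(spec, inp, settings)
        except Exception as exc:   # noqa: BLE001
            records.append({**cell, "rep": rep, "seed": seed,
                            "dcm_type": "both", "status": f"simulation: {exc}",
                            "F_A": np.nan, "F_B": np.nan, "LBF_AB": np.nan})
            continue
        for dcm_type in ("stochastic", "deterministic"):
            Fs = {}
            status = "ok"
            for label, base in (("A", spec_A), ("B", spec_B)):
                m = base.copy()
                m.priors.noise.stochastic = dcm_type == "stochastic"
                try:
                    if dcm_type == "stochastic":
                        post = invert_stochastic(m, traj.y, inp, design.TR, inversion)
                    else:
                        post = invert_deterministic(m, traj.y, inp, design.TR, inversion)
                    Fs[label] = post.free_energy
                except Exception as exc:   # noqa: BLE001
                    status = f"inversion {label}: {exc}"
                    Fs[label] = np.nan
            rec = {**cell, "rep": rep, "seed": seed, "dcm_type": dcm_type,
                   "status": status, "F_A": Fs["A"], "F_B": Fs["B"]}
            rec["LBF_AB"] = (lbf(Fs["A"], Fs["B"])
                             if np.isfinite(Fs["A"]) and np.isfinite(Fs["B"])
                             else np.nan)
            records.append(rec)
            if progress:
                print(f"cell={cell} rep={rep} {dcm_type}: LBF={rec['LBF_AB']}")
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# epilepsy-style model space
# ---------------------------------------------------------------------------

@dataclass
class ModelSpace:
    specs: list
    reference_index: int = 0

    def __len__(self):
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def labels(self):
        return [s.label for s in self.specs]


# which cortico-thalamic connections each B-family variant lets GSW modulate;
# entries are (target, source) with region order (thalamus, cortex1, cortex2)
_B_FAMILIES = {
    "B:ff": [(1, 0), (2, 0)],                 # thalamo-cortical (feedforward)
    "B:fb": [(0, 1), (0, 2)],                 # cortico-thalamic (feedback)
    "B:intra": [(0, 0)],                      # intrathalamic self-modulation
    "B:all": [(1, 0), (2, 0), (0, 1), (0, 2), (0, 0)],
}
_C_FAMILIES = {
    "C:thal": [0],
    "C:pfc": [1],
    "C:prec": [2],
    "C:all": [0, 1, 2],
}


def build_epilepsy_model_space(region_names=("thalamus", "pfc", "precuneus"),
                               a_strength=0.2, self_inhibition=-0.8):
    """Factorial model space for a three-node spike-and-wave network.

    9 GSW-effect variants (4 driving-input placements, 4 modulatory
    connection sets, 1 null) x gating {on, off} x DCM type {stochastic,
    deterministic} = 36 models, all with full reciprocal endogenous
    connectivity.  Region order is (thalamus, cortex, cortex); the gating
    variants let thalamic activity modulate the thalamus's afferent
    connections.
    """
    if len(region_names) != 3:
        raise ValueError("the model space is defined for exactly 3 regions")
    n = 3
    A = np.full((n, n), a_strength)
    np.fill_diagonal(A, self_inhibition)
    gsw_effects = (list(_C_FAMILIES) + list(_B_FAMILIES) + ["null"])
    specs = []
    for gsw in gsw_effects:
        for gating in ("off", "on"):
            for dcm_type in ("deterministic", "stochastic"):
                C = np.zeros((n, 1))
                C_mask = np.zeros((n, 1), dtype=int)
                B = []
                B_masks = None
                D = []
                D_masks = None
                if gsw in _C_FAMILIES:
                    C_mask[_C_FAMILIES[gsw], 0] = 1
                    C[_C_FAMILIES[gsw], 0] = 0.5
                if gsw in _B_FAMILIES:
                    Bm = np.zeros((n, n))
                    mask = np.zeros((n, n), dtype=int)
                    for (r, c) in _B_FAMILIES[gsw]:
                        mask[r, c] = 1
                    B = [Bm]
                    B_masks = [mask]
                if gating == "on":
                    D = [np.zeros((n, n)) for _ in range(n)]
                    D_masks = [np.zeros((n, n), dtype=int) for _ in range(n)]
                    # thalamus gates its own afferents from both cortices
                    D_masks[0][0, 1] = 1
                    D_masks[0][0, 2] = 1
                conn = NeuralConnectivity(
                    A=A.copy(), B=B, C=C, D=D,
                    A_mask=np.ones((n, n), dtype=int),
                    B_masks=B_masks, C_mask=C_mask, D_masks=D_masks)
                priors = PriorSet(
                    hemodynamic_variance=1e-2,   # empirical-style mode
                    noise=NoiseSpec(stochastic=(dcm_type == "stochastic")))
                label = f"{gsw}|D:{gating}|{dcm_type[0]}DCM"
                specs.append(DCMSpec(
                    connectivity=conn, priors=priors, label=label,
                    family_tags={"gsw_effect": gsw, "gating": gating,
                                 "dcm_type": dcm_type,
                                 "regions": ",".join(region_names)}))
    ref = next(i for i, s in enumerate(specs)
               if s.family_tags["gsw_effect"] == "null"
               and s.family_tags["gating"] == "off"
               and s.family_tags["dcm_type"] == "stochastic")
    return ModelSpace(specs=specs, reference_index=ref)


# ---------------------------------------------------------------------------
# factorial summaries
# ---------------------------------------------------------------------------

def summarize_effects(table, response, factors, blocking="rep"):
    """Ordinary-least-squares factorial summary with a blocking factor.

    Fits response = cell effect (full factorial) + blocking effect
    (sum-to-zero) and returns the per-cell adjusted means with standard
    errors plus main-effect estimates (level mean of adjusted cell means,
    relative to the grand mean).

    Missing responses are dropped with a warning flag; empty cells are
    reported in the output.
    """
    df = pd.DataFrame(table).copy()
    ok = df[response].notna()
    n_missing = int((~ok).sum())
    df = df[ok]
    if df.empty:
        raise ValueError("no usable rows")
    cell_key = df[list(factors)].astype(str).agg("|".join, axis=1)
    cells = sorted(cell_key.unique())
    reps = sorted(df[blocking].unique())
    X_cell = np.column_stack([(cell_key == c).to_numpy(float) for c in cells])
    # sum-to-zero blocking contrasts (last rep is -1 on all columns)
    X_rep = np.zeros((len(df), len(reps) - 1))
    rep_vals = df[blocking].to_numpy()
    for j, rv in enumerate(reps[:-1]):
        X_rep[rep_vals == rv, j] = 1.0
    X_rep[rep_vals == reps[-1], :] = -1.0
    X = np.hstack([X_cell, X_rep])
    y = df[response].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(df) - np.linalg.matrix_rank(X), 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv)[: len(cells)] * s2, 0.0))

    cell_means = pd.DataFrame({
        "cell": cells,
        "adjusted_mean": beta[: len(cells)],
        "se": se,
    })
    grand = float(np.mean(beta[: len(cells)]))
    effects = {}
    cell_levels = [c.split("|") for c in cells]
    for fi, f in enumerate(factors):
        levels = sorted({cl[fi] for cl in cell_levels})
        rows = []
        for lv in levels:
            sel = [i for i, cl in enumerate(cell_levels) if cl[fi] == lv]
            w = np.zeros(X.shape[1])
            w[sel] = 1.0 / len(sel)
            est = float(w[: len(cells)] @ beta[: len(cells)]) - grand
            var = float(w @ XtX_inv @ w) * s2
            rows.append({"level": lv, "effect": est, "se": math.sqrt(max(var, 0))})
        effects[f] = pd.DataFrame(rows)
    empty = [c for c in cells if (cell_key == c).sum() == 0]
    return {"cell_means": cell_means, "effects": effects,
            "grand_mean": grand, "sigma2": s2,
            "n_missing": n_missing, "empty_cells": empty}
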