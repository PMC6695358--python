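"""The four drug experiments as precision-parameter sweeps.

Each synthetic pharmacological manipulation is a sweep of one precision over
a grid, with all others at their defaults, running seeded trials of the
delayed saccade task and aggregating kinematic and decision metrics:

* GABA (``pi_motor``): inverse dose-response of saccadic peak velocity;
  overshoot when depleted, slow broken saccades when in excess.
* acetylcholine (``zeta``): peak velocity rises and saturates with likelihood
  precision; depletion gives hypometric saccades and inappropriate ones.
* dopamine (``gamma = 1/beta``): choice accuracy collapses to chance as the
  policy precision is depleted; simulated dopaminergic firing (the
  iteration-indexed gamma trace) flattens at high precision.
* noradrenaline (``omega``): delay-period persistence of the target belief
  grows with transition precision while task performance is preserved.

Also here: the omega x gamma interaction experiment, the belief-raster
extraction behind the working-memory figures, and synthetic parameter
recovery of gamma from observed choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import GenerativeModel, Precisions, action_marginal, update_precision
from .plant import PlantParams
from .task import TaskConfig, build_model, replay_functionals, run_trial

DEFAULT_GABA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_ACH_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
DEFAULT_DA_BETA_GRID = (64.0, 16.0, 4.0, 1.0, 0.25)   # gamma = 1/beta, ascending
DEFAULT_NA_GRID = (0.5, 1.0, 2.0, 4.0)


def trial_rng(master_seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-trial RNG: the trial/grid indices are mixed into the
    seed sequence, so changing n_trials never perturbs earlier trials."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *stream])


@dataclass
class DoseResponseTable:
    """Per-grid-value summary statistics for one precision sweep."""

    parameter: str
    values: np.ndarray
    frame: pd.DataFrame
    n_trials: int
    seed: int

    def __getitem__(self, column: str) -> np.ndarray:
        return self.frame[column].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.9g")


@dataclass
class RasterData:
    """Belief-derived firing rates for the remembered target location.

    rows = target state x represented time (grouped by represented time),
    columns = observation epochs; entries are Bayesian-model-average
    posterior probabilities, so each (represented time, epoch) block of four
    rows sums to one.  Extracted from a deterministic canonical trial
    (greedy action selection), as in single-trial raster figures.
    """

    omega: float
    matrix: np.ndarray
    true_target: int
    persistence: float
    correct: bool


def _aggregate(results, param: str, value: float, n_trials: int, seed: int) -> dict:
    go = results[0].go_segment

    def sacc_from_go(r):
        start = r.trajectory.segment_bounds[go]
        return sum(1 for i, _ in r.metrics.events if i >= start)

    return {
        "parameter": param,
        "value": value,
        "peak_velocity": float(np.mean([r.metrics.peak_velocity for r in results])),
        "amplitude": float(np.mean([r.metrics.amplitude for r in results])),
        "accuracy": float(np.mean([r.correct for r in results])),
        "endpoint_error": float(np.mean([r.metrics.endpoint_error for r in results])),
        "inappropriate_rate": float(np.mean([r.n_inappropriate for r in results])),
        "persistence": float(np.mean([r.persistence_index for r in results])),
        "overshoot_rate": float(np.mean([r.metrics.overshoot for r in results])),
        "saccades_to_arrival": float(np.mean([sacc_from_go(r) for r in results])),
        "n_trials": n_trials,
        "seed": seed,
    }


def _sweep(param: str, grid, n_trials: int, seed: int,
           model: GenerativeModel | None = None,
           config: TaskConfig | None = None,
           plant: PlantParams | None = None,
           base: Precisions | None = None,
           collect=None) -> DoseResponseTable:
    grid = np.asarray(grid, dtype=float)
    model = model if model is not None else build_model(config)
    base = base or Precisions()
    rows, extras = [], []
    for gi, value in enumerate(grid):
        prec = replace(base, **{param: float(value)})
        results = [run_trial(model, prec, true_target=i % 4,
                             seed=trial_rng(seed, gi, i),
                             config=config, plant=plant)
                   for i in range(n_trials)]
        rows.append(_aggregate(results, param, float(value), n_trials, seed))
        if collect is not None:
            extras.append(collect(results, float(value)))
    table = DoseResponseTable(parameter=param, values=grid,
                              frame=pd.DataFrame(rows), n_trials=n_trials,
                              seed=seed)
    return (table, extras) if collect is not None else table


def sweep_gaba(pi_grid=DEFAULT_GABA_GRID, n_trials: int = 20, seed: int = 0,
               **kw) -> DoseResponseTable:
    """Vary the motor-prior precision (synthetic GABAergic collicular gain)."""
    pi_grid = np.asarray(pi_grid, dtype=float)
    if np.any(pi_grid <= 0) or np.any(np.diff(pi_grid) <= 0):
        raise ValueError("pi_grid must be positive and sorted ascending")
    return _sweep("pi_motor", pi_grid, n_trials, seed, **kw)


def sweep_ach(zeta_grid=DEFAULT_ACH_GRID, n_trials: int = 50, seed: int = 0,
              **kw) -> DoseResponseTable:
    """Vary the likelihood precision (synthetic cholinergic modulation)."""
    zeta_grid = np.asarray(zeta_grid, dtype=float)
    if np.any(zeta_grid < 0) or np.any(np.diff(zeta_grid) <= 0):
        raise ValueError("zeta_grid must be non-negative and sorted ascending")
    return _sweep("zeta", zeta_grid, n_trials, seed, **kw)


def sweep_dopamine(beta_grid=DEFAULT_DA_BETA_GRID, n_trials: int = 200,
                   seed: int = 0, **kw) -> tuple[DoseResponseTable, np.ndarray]:
    """Vary the policy precision gamma = 1/beta (synthetic dopamine).

    Returns the dose-response table (rows ascending in gamma) and the mean
    simulated dopaminergic firing trace per gamma: the iteration-indexed
    expected precision, ``n_gamma x (T * n_iterations)``.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid <= 0):
        raise ValueError("beta_grid must be positive")

    def collect(results, value):
        return np.mean([r.gamma_trace for r in results], axis=0)

    table, traces = _sweep("beta", beta_grid, n_trials, seed, collect=collect, **kw)
    table.frame["gamma"] = 1.0 / table.frame["value"]
    return table, np.asarray(traces)


def sweep_noradrenaline(omega_grid=DEFAULT_NA_GRID, n_trials: int = 100,
                        seed: int = 0, model: GenerativeModel | None = None,
                        config: TaskConfig | None = None,
                        **kw) -> tuple[DoseResponseTable, list[RasterData]]:
    """Vary the transition precision (synthetic noradrenaline).

    Returns the dose-response table and one canonical-trial raster per omega.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid < 0) or np.any(np.diff(omega_grid) <= 0):
        raise ValueError("omega_grid must be non-negative and sorted ascending")
    model = model if model is not None else build_model(config)
    table = _sweep("omega", omega_grid, n_trials, seed, model=model,
                   config=config, **kw)
    rasters = []
    for value in omega_grid:
        r = run_trial(model, Precisions(omega=float(value)), true_target=0,
                      seed=trial_rng(seed, 999), config=config,
                      policy_mode="greedy")
        rasters.append(RasterData(omega=float(value), matrix=r.target_raster(),
                                  true_target=r.true_target,
                                  persistence=r.persistence_index,
                                  correct=r.correct))
    return table, rasters


def chance_level(n_trials: int = 200, seed: int = 0,
                 model: GenerativeModel | None = None,
                 config: TaskConfig | None = None) -> tuple[float, float]:
    """Empirical chance accuracy under a forced-uniform policy posterior.

    Returns (accuracy, binomial SE).  Computed by simulation rather than
    assumed 1/4, because mistimed (premature) saccades also forfeit trials.
    """
    model = model if model is not None else build_model(config)
    hits = [run_trial(model, Precisions(), true_target=i % 4,
                      seed=trial_rng(seed, 0, i), config=config,
                      policy_mode="uniform").correct
            for i in range(n_trials)]
    p = float(np.mean(hits))
    return p, float(np.sqrt(p * (1 - p) / n_trials))


def interaction_grid(omega_grid=(0.5, 4.0), beta_grid=(4.0, 0.5),
                     n_trials: int = 500, seed: int = 0,
                     model: GenerativeModel | None = None,
                     config: TaskConfig | None = None) -> pd.DataFrame:
    """Accuracy on the omega x gamma grid (noradrenaline x dopamine).

    The directional hypothesis: under transition-precision blockade (low
    omega) task performance is more sensitive to policy-precision (dopamine)
    depletion, because deep policies inferred from the cue can no longer
    compensate for degraded memories.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if omega_grid.size < 2 or beta_grid.size < 2:
        raise ValueError("both grids need at least 2 values")
    model = model if model is not None else build_model(config)
    rows = []
    for oi, om in enumerate(omega_grid):
        for bi, be in enumerate(beta_grid):
            prec = Precisions(omega=float(om), beta=float(be))
            hits = [run_trial(model, prec, true_target=i % 4,
                              seed=trial_rng(seed, oi, bi, i),
                              config=config).correct
                    for i in range(n_trials)]
            p = float(np.mean(hits))
            rows.append({"omega": float(om), "beta": float(be),
                         "gamma": 1.0 / float(be), "accuracy": p,
                         "se": float(np.sqrt(p * (1 - p) / n_trials)),
                         "n_trials": n_trials, "seed": seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    estimate_beta: float
    estimate_gamma: float
    candidates_beta: np.ndarray
    log_likelihood: np.ndarray
    flat: bool
    n_trials: int


def fit_gamma(trials: list, model: GenerativeModel,
              beta_candidates=DEFAULT_DA_BETA_GRID,
              precisions: Precisions | None = None,
              config: TaskConfig | None = None) -> GammaFit:
    """Grid maximum likelihood for the policy precision from observed choices.

    ``trials`` holds (outcomes, actions) pairs as recorded by
    :func:`oculopharm.task.run_trial` (``TrialResult.outcomes`` /
    ``.actions``).  State inference does not depend on gamma, so the
    per-epoch (F, G) functionals are computed once per distinct trial
    history and the gamma-dependent policy/action likelihood is evaluated on
    top for every candidate.
    """
    if len(trials) == 0:
        raise ValueError("no trials to fit")
    base = precisions or Precisions()
    cfg = config or TaskConfig()
    beta_candidates = np.asarray(beta_candidates, dtype=float)
    n_controls = model.B[model.controllable_factor].shape[2]

    cache: dict = {}
    loglik = np.zeros(beta_candidates.size)
    for outcomes, actions in trials:
        key = tuple(map(tuple, outcomes))
        if key not in cache:
            cache[key] = replay_functionals(model, list(outcomes),
                                            base.zeta, base.omega)
        funcs = cache[key]
        for ci, beta0 in enumerate(beta_candidates):
            beta_carry = beta0
            for t, a in enumerate(actions):
                F, G = funcs[t]
                pu = update_precision(beta0, G, F, beta_init=beta_carry)
                beta_carry = pu.beta
                marg = action_marginal(pu.pi_posterior, model.policies, t,
                                       n_controls)
                loglik[ci] += np.log(max(marg[a], 1e-300))
    best = int(np.argmax(loglik))
    flat = bool(loglik.max() - loglik.min() < 1e-9)
    return GammaFit(estimate_beta=float(beta_candidates[best]),
                    estimate_gamma=1.0 / float(beta_candidates[best]),
                    candidates_beta=beta_candidates, log_likelihood=loglik,
                    flat=flat, n_trials=len(trials))


def recover_gamma(beta_true: float, m: int, seed: int = 0,
                  beta_candidates=DEFAULT_DA_BETA_GRID,
                  model: GenerativeModel | None = None,
                  config: TaskConfig | None = None) -> GammaFit:
    """Generate ``m`` trials at a known policy precision and re-estimate it."""
    model = model if model is not None else build_model(config)
    prec = Precisions(beta=float(beta_true))
    data = []
    for i in range(m):
        r = run_trial(model, prec, true_target=i % 4,
                      seed=trial_rng(seed, 7, i), config=config)
        data.append((r.outcomes, r.actions))
    return fit_gamma(data, model, beta_candidates, config=config)
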