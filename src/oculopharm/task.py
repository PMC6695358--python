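"""The delayed oculomotor task: model construction and single trials.

A trial has four discrete epochs of 250 ms each — cue, delay, go, feedback.
The subject fixates a central cross while a peripheral target flashes (cue),
holds fixation while the cross is red (delay), saccades to the remembered
location when the cross turns blue (go), and receives feedback.  Three
hidden-state factors generate outcomes: the controllable fixation location
(5 states), the static target location (4 states) and the deterministic
trial stage.  Four outcome modalities: target cue (4 directions + none),
cross colour (blue/red), feedback (null/correct/incorrect) and
proprioception (5 locations).

Each epoch of the discrete loop hands a Bayesian-model-average attracting
point to the continuous plant, and the realised endpoint returns as the next
proprioceptive outcome — the closed loop between deciding where to look and
implementing the movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .bridge import LocationMap, outcome_to_target, sample_proprioceptive_outcome
from .engine import (GenerativeModel, Precisions, action_marginal,
                     expected_free_energy_batch, infer_states_batch,
                     update_precision)
from .plant import (ContinuousFilterState, ContinuousTrajectory, PlantParams,
                    SaccadeMetrics, detect_saccades, integrate_segment)

# outcome-index conventions
CUE_NONE = 4            # target-cue modality: 0..3 = directions, 4 = none
COLOUR_BLUE, COLOUR_RED = 0, 1
FB_NULL, FB_CORRECT, FB_INCORRECT = 0, 1, 2
FIX_CROSS = 0           # fixation-location state 0 = the central cross

MODALITIES = ["target_cue", "cross_colour", "feedback", "proprioception"]
FACTORS = ["fixation_location", "target_location", "trial_stage"]


@dataclass
class TaskConfig:
    """Task geometry, trial structure and model softnesses.

    n_delay_steps extends the delay period (each extra step adds a 250 ms
    epoch); the default single step gives the four-epoch trial.
    """

    eccentricity_deg: float = 8.0
    n_delay_steps: int = 1
    c_pref: float = 4.0          # preference magnitude for 'correct', nats
    p_cue: float = 0.99         # cue-likelihood mass on the true direction
    p_proprio: float = 0.95      # proprioceptive-likelihood mass on the true location
    p_feedback: float = 0.995    # feedback-likelihood mass on the designated outcome
    target_stickiness: float = 0.9   # agent's belief that the target persists
    obs_precision: float = 4.0   # ascending endpoint->outcome sharpness, deg^-2

    def __post_init__(self) -> None:
        if self.eccentricity_deg <= 0:
            raise ValueError("eccentricity_deg must be positive")
        if self.n_delay_steps < 1:
            raise ValueError("n_delay_steps must be >= 1")
        if not (0.5 < self.p_cue <= 1.0):
            raise ValueError("p_cue must lie in (0.5, 1]")
        if not (0.5 < self.p_proprio <= 1.0):
            raise ValueError("p_proprio must lie in (0.5, 1]")
        if not (0.5 < self.p_feedback <= 1.0):
            raise ValueError("p_feedback must lie in (0.5, 1]")
        if not (0.25 < self.target_stickiness <= 1.0):
            raise ValueError("target_stickiness must lie in (0.25, 1]")

    @property
    def stages(self) -> list[str]:
        return ["cue"] + ["delay"] * self.n_delay_steps + ["go", "feedback"]

    @property
    def T(self) -> int:
        return len(self.stages)

    @property
    def go_step(self) -> int:
        return self.stages.index("go")

    def locmap(self) -> LocationMap:
        return LocationMap(eccentricity=self.eccentricity_deg)


def build_model(config: TaskConfig | None = None) -> GenerativeModel:
    """Construct the agent's generative model of the delayed saccade task.

    The cue likelihood and the target-persistence transition carry mild base
    softness (``p_cue``, ``target_stickiness``): the precision operator is a
    pure inverse temperature, so a strictly one-hot mapping would be a fixed
    point at every positive precision and the cholinergic/noradrenergic
    manipulations would have nothing to act on.  The generative *process*
    (``TrialProcess``) keeps the target perfectly static and the cue
    deterministic.
    """
    cfg = config or TaskConfig()
    T = cfg.T
    n_fix, n_targ, n_stage = 5, 4, T
    stages = cfg.stages

    # --- likelihoods -------------------------------------------------------
    A_cue = np.zeros((5, n_fix, n_targ, n_stage))
    for s, name in enumerate(stages):
        if name == "cue":
            for tg in range(n_targ):
                A_cue[:, :, tg, s] = (1.0 - cfg.p_cue) / 4.0
                A_cue[tg, :, tg, s] = cfg.p_cue
        else:
            A_cue[CUE_NONE, :, :, s] = 1.0

    A_colour = np.zeros((2, n_fix, n_targ, n_stage))
    for s, name in enumerate(stages):
        A_colour[COLOUR_RED if name == "delay" else COLOUR_BLUE, :, :, s] = 1.0

    # feedback softness is what lets the likelihood precision modulate the
    # perceived risk of a mistimed saccade: as zeta falls the predicted
    # consequences of moving during the delay blur into those of waiting
    A_feedback = np.full((3, n_fix, n_targ, n_stage), (1.0 - cfg.p_feedback) / 2.0)
    for s, name in enumerate(stages):
        for fx in range(n_fix):
            for tg in range(n_targ):
                if name == "cue":
                    o = FB_NULL
                elif name == "delay":
                    o = FB_NULL if fx == FIX_CROSS else FB_INCORRECT
                else:  # go, feedback: correct iff fixating the target
                    o = FB_CORRECT if fx == tg + 1 else FB_INCORRECT
                A_feedback[o, fx, tg, s] = cfg.p_feedback

    # proprioception reports the fixation location; the agent's mapping has a
    # little base softness so that the likelihood precision can sharpen or
    # flatten the predictive distribution over saccadic locations
    A_proprio = np.full((5, n_fix, n_targ, n_stage), (1.0 - cfg.p_proprio) / 4.0)
    for fx in range(n_fix):
        A_proprio[fx, fx, :, :] = cfg.p_proprio

    # --- transitions -------------------------------------------------------
    B_fix = np.zeros((n_fix, n_fix, n_fix))   # action = destination location
    for a in range(n_fix):
        B_fix[a, :, a] = 1.0

    st = cfg.target_stickiness
    B_targ = np.full((n_targ, n_targ, 1), (1.0 - st) / (n_targ - 1))
    np.fill_diagonal(B_targ[:, :, 0], st)

    B_stage = np.zeros((n_stage, n_stage, 1))
    for s in range(n_stage):
        B_stage[min(s + 1, n_stage - 1), s, 0] = 1.0

    # --- preferences and priors -------------------------------------------
    C = [np.zeros(5), np.zeros(2),
         np.array([0.0, cfg.c_pref, -cfg.c_pref]), np.zeros(5)]
    D = [np.eye(n_fix)[FIX_CROSS], np.full(n_targ, 0.25), np.eye(n_stage)[0]]

    # deep policies: every action sequence over the T-1 transitions
    grids = np.meshgrid(*([np.arange(n_fix)] * (T - 1)), indexing="ij")
    policies = np.stack([g.ravel() for g in grids], axis=1)

    return GenerativeModel(A=[A_cue, A_colour, A_feedback, A_proprio],
                           B=[B_fix, B_targ, B_stage],
                           C=C, D=D, policies=policies, T=T,
                           controllable_factor=0,
                           factor_names=list(FACTORS),
                           modality_names=list(MODALITIES))


class TrialProcess:
    """Generative process (the true world) for one trial.

    The target is perfectly static; the cue is deterministic; a premature
    fixation change during any delay epoch latches, so feedback at the go and
    feedback stages reads 'incorrect' even if the eye later returns.
    """

    def __init__(self, config: TaskConfig, true_target: int):
        if not 0 <= true_target < 4:
            raise ValueError("true_target must be one of the 4 peripheral locations")
        self.cfg = config
        self.true_target = true_target
        self.premature = False

    def outcomes(self, step: int, fix_state: int) -> tuple[int, int, int, int]:
        stage = self.cfg.stages[step]
        if stage == "delay" and fix_state != FIX_CROSS:
            self.premature = True
        cue = self.true_target if stage == "cue" else CUE_NONE
        colour = COLOUR_RED if stage == "delay" else COLOUR_BLUE
        if stage == "cue":
            fb = FB_NULL
        elif stage == "delay":
            fb = FB_INCORRECT if fix_state != FIX_CROSS else FB_NULL
        else:
            on_target = fix_state == self.true_target + 1
            fb = FB_CORRECT if (on_target and not self.premature) else FB_INCORRECT
        return cue, colour, fb, fix_state


@dataclass
class TrialResult:
    """Everything one simulated trial produced."""

    true_target: int
    actions: list[int]
    outcomes: list[tuple[int, int, int, int]]
    fix_states: list[int]
    correct: bool
    premature: bool
    saccade_steps: list[int]
    go_segment: int
    # belief/evaluation history
    bma_beliefs: list[list[np.ndarray]]      # per epoch, per factor: (T, ns)
    policy_posteriors: list[np.ndarray]      # per epoch: (P,)
    policy_priors: list[np.ndarray]
    F_history: list[np.ndarray]
    G_history: list[np.ndarray]
    gamma_trace: np.ndarray                  # concatenated over epochs
    final_beliefs: list[np.ndarray] | None   # per-policy beliefs, last epoch
    # continuous level
    trajectory: ContinuousTrajectory
    segment_metrics: list[SaccadeMetrics]
    metrics: SaccadeMetrics
    eta_history: list[np.ndarray]

    @property
    def n_inappropriate(self) -> int:
        """Saccade events outside the go segment, plus extras within it."""
        n = 0
        for i, m in enumerate(self.segment_metrics):
            n += m.n_saccades - 1 if i == self.go_segment else m.n_saccades
        return max(n, 0)

    def target_raster(self) -> np.ndarray:
        """Belief-derived firing rates for the remembered target location.

        Rows: target state x represented time (grouped by represented time);
        columns: observation epochs.  Entry = Bayesian-model-average posterior
        probability, so each (represented time, epoch) block sums to 1 over
        the four target states.
        """
        T = len(self.bma_beliefs)
        n_targ = self.bma_beliefs[0][1].shape[1]
        raster = np.zeros((T * n_targ, T))
        for epoch, bma in enumerate(self.bma_beliefs):
            for tau in range(T):
                raster[tau * n_targ:(tau + 1) * n_targ, epoch] = bma[1][tau]
        return raster

    @property
    def persistence_index(self) -> float:
        """Delay-period maintenance: posterior probability of the true target
        at the final represented time, read out at the last delay epoch.

        Read any later and the response-stage feedback observation pins the
        target belief regardless of transition precision, so the index would
        measure the feedback channel rather than working memory.
        """
        return float(self.bma_beliefs[self.go_segment - 1][1][-1, self.true_target])

    def to_dict(self) -> dict:
        return {
            "true_target": self.true_target,
            "actions": self.actions,
            "outcomes": [list(o) for o in self.outcomes],
            "fix_states": self.fix_states,
            "correct": self.correct,
            "premature": self.premature,
            "saccade_steps": self.saccade_steps,
            "go_segment": self.go_segment,
            "persistence_index": self.persistence_index,
            "metrics": self.metrics.to_dict(),
            "gamma_trace": self.gamma_trace.tolist(),
        }


def run_trial(model: GenerativeModel,
              precisions: Precisions | None = None,
              true_target: int = 0,
              seed: int | np.random.Generator = 0,
              config: TaskConfig | None = None,
              plant: PlantParams | None = None,
              *,
              policy_mode: str = "sample",
              keep_final_beliefs: bool = False) -> TrialResult:
    """Simulate one full trial through engine, bridge and plant.

    policy_mode: 'sample' (default) draws actions from the policy-marginal
    action distribution; 'greedy' takes its argmax (the deterministic
    canonical trial used for raster figures); 'uniform' forces a uniform
    policy posterior (the chance-level oracle).
    """
    cfg = config or TaskConfig()
    prec = precisions or Precisions()
    plant = plant or PlantParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locmap = cfg.locmap()
    T = model.T
    cf = model.controllable_factor
    n_controls = model.B[cf].shape[2]

    # omega acts on the target-location factor's transitions (factor 1):
    # the environment dynamics the synthetic noradrenaline is confident about
    model_w = model.weighted(prec.zeta, prec.omega, omega_factors=[1])

    process = TrialProcess(cfg, true_target)
    eye = ContinuousFilterState.at_rest(locmap.coords[FIX_CROSS])

    outcomes: list[tuple[int, int, int, int]] = []
    actions: list[int] = []
    fix_states: list[int] = []
    bma_hist, pi_hist, prior_hist, F_hist, G_hist, eta_hist = [], [], [], [], [], []
    gamma_bits = []
    seg_metrics: list[SaccadeMetrics] = []
    traj: ContinuousTrajectory | None = None
    beta_carry = prec.beta
    final_beliefs = None

    fix_state = FIX_CROSS
    for t in range(T):
        fix_states.append(fix_state)
        outcomes.append(process.outcomes(t, fix_state))

        res = infer_states_batch(model_w, outcomes, weighted=True)
        G = expected_free_energy_batch(model_w, res.beliefs, t)
        pu = update_precision(prec.beta, G, res.F, beta_init=beta_carry)
        beta_carry = pu.beta
        gamma_bits.append(pu.gamma_trace)
        if policy_mode == "uniform":
            pi_post = np.full(model.n_policies, 1.0 / model.n_policies)
        else:
            pi_post = pu.pi_posterior
        pi_hist.append(pi_post)
        prior_hist.append(pu.pi_prior)
        F_hist.append(res.F)
        G_hist.append(G)
        bma_hist.append([np.einsum("p,ptn->tn", pi_post, q) for q in res.beliefs])
        if keep_final_beliefs and t == T - 1:
            final_beliefs = res.beliefs

        if t == 0:
            # epoch 0 renders as a 250 ms hold at the current fixation
            seg, eye = integrate_segment(eye, eye.eye, prec.pi_motor, plant)
            traj = seg
            seg_metrics.append(detect_saccades(seg, eye.eye))
        if t < T - 1:
            if policy_mode == "greedy":
                marg = action_marginal(pi_post, model.policies, t, n_controls)
                a = int(np.argmax(marg))
            else:
                a = engine.sample_action(pi_post, model.policies, t, n_controls, rng)
            actions.append(a)
            # predictive proprioception at the next epoch, averaged over the
            # policies consistent with the selected action
            consistent = model.policies[:, t] == a
            w = pi_post * consistent
            w = w / w.sum() if w.sum() > 0 else consistent / consistent.sum()
            A_prop = model_w.A[3]
            pred = np.zeros(A_prop.shape[0])
            for f_idx in np.nonzero(w)[0]:
                q_next = [res.beliefs[f][f_idx, t + 1] for f in range(model.n_factors)]
                pred += w[f_idx] * np.einsum("oijk,i,j,k->o", A_prop, *q_next)
            pred = pred / pred.sum()
            eta = outcome_to_target(pred, locmap)
            eta_hist.append(eta)
            target_xy = locmap.coords[process.true_target + 1]
            seg, eye = integrate_segment(eye, eta, prec.pi_motor, plant)
            traj = traj.append(seg)
            seg_metrics.append(detect_saccades(seg, target_xy))
            fix_state = sample_proprioceptive_outcome(eye.eye, locmap,
                                                      cfg.obs_precision)

    target_xy = locmap.coords[true_target + 1]
    metrics = detect_saccades(traj, target_xy)
    saccade_steps = [t for t in range(1, T) if fix_states[t] != fix_states[t - 1]]
    correct = (fix_states[-1] == true_target + 1) and not process.premature
    return TrialResult(true_target=true_target, actions=actions,
                       outcomes=outcomes, fix_states=fix_states,
                       correct=correct, premature=process.premature,
                       saccade_steps=saccade_steps, go_segment=cfg.go_step,
                       bma_beliefs=bma_hist, policy_posteriors=pi_hist,
                       policy_priors=prior_hist, F_history=F_hist,
                       G_history=G_hist,
                       gamma_trace=np.concatenate(gamma_bits),
                       final_beliefs=final_beliefs,
                       trajectory=traj, segment_metrics=seg_metrics,
                       metrics=metrics, eta_history=eta_hist)


def replay_functionals(model: GenerativeModel,
                       outcomes: list[tuple[int, ...]],
                       zeta: float, omega: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-epoch (F, G) for a recorded outcome history.

    State inference is independent of the policy precision, so these
    functionals can be computed once per trial and reused for every gamma
    candidate when fitting (see :func:`oculopharm.pharm.fit_gamma`).
    """
    model_w = model.weighted(zeta, omega, omega_factors=[1])
    out = []
    for t in range(len(outcomes)):
        res = infer_states_batch(model_w, outcomes[:t + 1], weighted=True)
        G = expected_free_energy_batch(model_w, res.beliefs, t)
        out.append((res.F, G))
    return out
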