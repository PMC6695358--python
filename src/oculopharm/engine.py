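"""Discrete active-inference machinery.

A factorised categorical generative model — likelihoods ``A``, transitions
``B``, log-preferences ``C``, initial priors ``D`` and an enumerated set of
temporally deep policies — is evaluated by variational (mean-field) inference.
Neuromodulatory precisions enter as inverse-temperature exponents on the
probability arrays (``zeta`` on likelihoods, ``omega`` on transitions), as the
inverse temperature ``gamma = 1/beta`` of the softmax over policies, and as
the gain ``pi_motor`` of the continuous motor plant (used elsewhere).

Conventions
-----------
* A likelihood array for modality ``m`` has shape ``(n_outcomes_m, *n_states)``
  where ``n_states`` are the cardinalities of all hidden-state factors.
* A transition array for factor ``f`` has shape ``(n_next, n_prev, n_controls)``.
* Policies are integer arrays of shape ``(n_policies, T - 1)`` holding the
  control index of the single controllable factor at each transition.
* All categorical distributions are normalised to 1 within 1e-9; probabilities
  are floored at :data:`P_FLOOR` before logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

P_FLOOR = 1e-16
#: lower clip for the inverse policy precision (beta) during updates
BETA_FLOOR = 1.0 / 64.0


# ---------------------------------------------------------------------------
# small categorical utilities
# ---------------------------------------------------------------------------

def normalise(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Normalise a non-negative array to sum to one along ``axis``."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=axis, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot normalise a distribution with non-positive mass")
    return x / s


def safe_log(x: np.ndarray) -> np.ndarray:
    """Log with the probability floor applied first."""
    return np.log(np.maximum(x, P_FLOOR))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def assert_categorical(p: np.ndarray, axis: int = 0, tol: float = 1e-9) -> None:
    p = np.asarray(p)
    if np.any(p < -tol):
        raise ValueError("negative probability entry")
    if not np.allclose(p.sum(axis=axis), 1.0, atol=tol):
        raise ValueError("distribution does not sum to one")


def apply_precision(dist_array: np.ndarray, precision: float, axis: int = 0) -> np.ndarray:
    """Raise each categorical column to a power and renormalise.

    This is the inverse-temperature (precision) operator: ``precision = 1``
    leaves the array unchanged, ``0`` flattens every column to uniform, and
    ``precision -> inf`` drives each column to a one-hot at its argmax (ties
    broken by the lowest index, which is what renormalised equal maxima give
    under argmax downstream).

    Zero entries are floored at :data:`P_FLOOR` before the log so that a
    strictly positive distribution is returned for any finite precision;
    a one-hot column is therefore (numerically) a fixed point for every
    positive precision.
    """
    if precision < 0:
        raise ValueError(f"precision must be non-negative, got {precision}")
    arr = np.asarray(dist_array, dtype=float)
    logp = safe_log(arr)
    out = np.exp(precision * (logp - logp.max(axis=axis, keepdims=True)))
    return normalise(out, axis=axis)


# ---------------------------------------------------------------------------
# generative model container
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """Factorised categorical generative model over ``T`` time-steps.

    Parameters
    ----------
    A : per-modality likelihood arrays, shape ``(No_m, *Ns)``.
    B : per-factor transition arrays, shape ``(Ns_f, Ns_f, Nu_f)``.
    C : per-modality log-preference vectors, shape ``(No_m,)`` (time-constant).
    D : per-factor initial priors.
    policies : ``(P, T-1)`` control indices for the controllable factor.
    controllable_factor : index of the factor the policies act on.
    """

    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    policies: np.ndarray
    T: int
    controllable_factor: int = 0
    factor_names: list[str] = field(default_factory=list)
    modality_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        self.C = [np.asarray(c, dtype=float) for c in self.C]
        self.D = [np.asarray(d, dtype=float) for d in self.D]
        self.policies = np.asarray(self.policies, dtype=int)
        for a in self.A:
            assert_categorical(a.reshape(a.shape[0], -1), axis=0)
        for b in self.B:
            assert_categorical(b, axis=0)
        for d in self.D:
            assert_categorical(d, axis=0)
        if self.policies.ndim != 2 or self.policies.shape[1] != self.T - 1:
            raise ValueError("policies must have shape (n_policies, T-1)")

    @property
    def n_factors(self) -> int:
        return len(self.B)

    @property
    def n_modalities(self) -> int:
        return len(self.A)

    @property
    def state_sizes(self) -> tuple[int, ...]:
        return tuple(b.shape[0] for b in self.B)

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    def weighted(self, zeta: float, omega: float,
                 omega_factors: Sequence[int] | None = None) -> "GenerativeModel":
        """Return a copy with precision-weighted likelihoods and transitions.

        ``zeta`` is applied to every modality. ``omega`` is applied to the
        transition arrays of the factors listed in ``omega_factors`` (all
        factors when ``None``).
        """
        A = [apply_precision(a.reshape(a.shape[0], -1), zeta).reshape(a.shape)
             for a in self.A]
        if omega_factors is None:
            omega_factors = range(self.n_factors)
        omega_factors = set(omega_factors)
        B = [apply_precision(b, omega) if f in omega_factors else b.copy()
             for f, b in enumerate(self.B)]
        return GenerativeModel(A=A, B=B, C=[c.copy() for c in self.C],
                               D=[d.copy() for d in self.D],
                               policies=self.policies.copy(), T=self.T,
                               controllable_factor=self.controllable_factor,
                               factor_names=list(self.factor_names),
                               modality_names=list(self.modality_names))

    # -- JSON round trip -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "T": self.T,
            "controllable_factor": self.controllable_factor,
            "factor_names": self.factor_names,
            "modality_names": self.modality_names,
            "A": [a.tolist() for a in self.A],
            "B": [b.tolist() for b in self.B],
            "C": [c.tolist() for c in self.C],
            "D": [d.tolist() for d in self.D],
            "policies": self.policies.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeModel":
        p = json.loads(text)
        return cls(A=[np.array(a) for a in p["A"]],
                   B=[np.array(b) for b in p["B"]],
                   C=[np.array(c) for c in p["C"]],
                   D=[np.array(d) for d in p["D"]],
                   policies=np.array(p["policies"]), T=p["T"],
                   controllable_factor=p["controllable_factor"],
                   factor_names=p["factor_names"],
                   modality_names=p["modality_names"])


@dataclass
class Precisions:
    """The four neuromodulatory precision parameters.

    zeta      -- likelihood (sensory) precision, >= 0; synthetic acetylcholine.
    omega     -- transition precision, >= 0; synthetic noradrenaline.
    beta      -- inverse policy precision, > 0 (gamma = 1/beta); synthetic
                 dopamine acts as gamma.
    pi_motor  -- precision of the stationarity (fixation) prior in the
                 continuous plant, > 0; synthetic GABAergic collicular gain.
    """

    zeta: float = 1.0
    omega: float = 4.0
    beta: float = 0.5
    pi_motor: float = 1.0

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.pi_motor <= 0:
            raise ValueError("pi_motor must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 / self.beta


# ---------------------------------------------------------------------------
# variational state inference
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    """Posterior beliefs for a batch of policies.

    beliefs  -- per factor, array ``(P, T, Ns_f)``.
    F        -- variational free energy per policy, shape ``(P,)``.
    F_trace  -- free energy after each sweep (only when ``track_F``).
    converged -- False if the fixed-point iteration hit ``max_iter``.
    """

    beliefs: list[np.ndarray]
    F: np.ndarray
    F_trace: np.ndarray | None
    converged: bool


def _policy_B(B: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """Per-policy transition matrices ``(P, ns, ns)`` for one transition."""
    return np.moveaxis(B[:, :, actions], 2, 0)


def _chain_smooth(prior: np.ndarray, trans: np.ndarray, log_ev: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Batched exact forward-backward smoothing of a categorical chain.

    prior  -- (P, n) initial distribution
    trans  -- (T-1, P, n, n) transition matrices (next, prev)
    log_ev -- (P, T, n) local log-evidence (zero where unobserved)

    Returns unary marginals ``q`` (P, T, n) and pairwise marginals ``xi``
    (T-1, P, n, n) with ``xi[tau]`` over (s_{tau+1}, s_tau).
    """
    P, T, n = log_ev.shape
    ev = np.exp(log_ev - log_ev.max(axis=2, keepdims=True))
    alpha = np.empty((T, P, n))
    a = prior * ev[:, 0]
    alpha[0] = a / a.sum(axis=1, keepdims=True)
    for tau in range(1, T):
        a = np.einsum("pij,pj->pi", trans[tau - 1], alpha[tau - 1]) * ev[:, tau]
        alpha[tau] = a / a.sum(axis=1, keepdims=True)
    beta = np.ones((T, P, n))
    for tau in range(T - 2, -1, -1):
        b = np.einsum("pij,pi->pj", trans[tau], beta[tau + 1] * ev[:, tau + 1])
        beta[tau] = b / b.max(axis=1, keepdims=True)
    q = alpha * beta
    q = q / q.sum(axis=2, keepdims=True)
    xi = np.empty((T - 1, P, n, n))
    for tau in range(T - 1):
        x = trans[tau] * (beta[tau + 1] * ev[:, tau + 1])[:, :, None] \
            * alpha[tau][:, None, :]
        xi[tau] = x / x.reshape(P, -1).sum(axis=1)[:, None, None]
    return np.moveaxis(q, 0, 1), xi


def infer_states_batch(model: GenerativeModel,
                       outcomes: Sequence[Sequence[int]],
                       precisions: Precisions | None = None,
                       *,
                       weighted: bool = False,
                       max_iter: int = 16,
                       tol: float = 1e-4,
                       track_F: bool = False) -> InferenceResult:
    """Structured variational smoothing over hidden states, for every policy.

    ``outcomes`` is a list of per-step outcome index tuples observed so far
    (length ``t <= T``).  Beliefs span the full horizon ``T``; steps beyond
    ``t`` carry no likelihood term and converge to the policy-conditioned
    prior propagation.

    The variational posterior factorises across hidden-state factors but
    keeps each factor's temporal chain intact: one update sweeps a factor's
    whole chain with exact forward-backward smoothing under the expected
    log-likelihood messages from the other factors.  Each sweep is an exact
    block-coordinate-descent step on the structured free energy, so ``F`` is
    non-increasing over sweeps (up to numerical tolerance), and for a
    single-factor model the result is exact Bayesian smoothing.
    """
    if precisions is not None and not weighted:
        model = model.weighted(precisions.zeta, precisions.omega)
    T, nf, P = model.T, model.n_factors, model.n_policies
    sizes = model.state_sizes
    t_obs = len(outcomes)
    cf = model.controllable_factor

    lnD = [safe_log(d) for d in model.D]

    # joint observed log-likelihood tensor per observed step: shape (*sizes)
    L = []
    for tau in range(t_obs):
        Ltau = np.zeros(sizes)
        for m, a in enumerate(model.A):
            Ltau = Ltau + safe_log(a[outcomes[tau][m]])
        L.append(Ltau)

    # transition stacks per factor: (T-1, P, ns, ns)
    trans = []
    for f in range(nf):
        if f == cf:
            trans.append(np.stack([_policy_B(model.B[f], model.policies[:, tau])
                                   for tau in range(T - 1)]))
        else:
            b = np.broadcast_to(model.B[f][:, :, 0], (P,) + model.B[f].shape[:2])
            trans.append(np.stack([b] * (T - 1)))
    ln_trans = [safe_log(tr) for tr in trans]

    q = [np.full((P, T, s), 1.0 / s) for s in sizes]
    xi = [None] * nf
    all_f = list(range(nf))

    def likelihood_term(tau: int, f: int) -> np.ndarray:
        """E_{q(other factors)}[ln p(o_tau | s)] as a (P, ns_f) array."""
        out = np.broadcast_to(L[tau], (P,) + sizes).copy()
        # contract the other factors' axes, highest index first so the
        # remaining axis positions stay valid
        for g in sorted((g for g in all_f if g != f), reverse=True):
            ax = 1 + g
            out = np.einsum(out, list(range(out.ndim)),
                            q[g][:, tau, :], [0, ax],
                            [i for i in range(out.ndim) if i != ax])
        return out

    def free_energy() -> np.ndarray:
        F = np.zeros(P)
        for f in all_f:
            qi, xif = q[f], xi[f]
            # E[ln q] for a chain: q0 ln q0 + sum_links xi (ln xi - ln q_prev)
            F += np.sum(qi[:, 0] * safe_log(qi[:, 0]), axis=1)
            for tau in range(1, T):
                F += np.sum(xif[tau - 1] * safe_log(xif[tau - 1]), axis=(1, 2))
                F -= np.sum(qi[:, tau - 1] * safe_log(qi[:, tau - 1]), axis=1)
                F -= np.einsum("pij,pij->p", xif[tau - 1], ln_trans[f][tau - 1])
            F -= qi[:, 0, :] @ lnD[f]
        for tau in range(t_obs):
            out = np.broadcast_to(L[tau], (P,) + sizes).copy()
            for g in all_f:
                out = np.einsum(out, list(range(out.ndim)),
                                q[g][:, tau, :], [0, 1],
                                [0] + list(range(2, out.ndim)))
            F -= out.reshape(P)
        return F

    F_hist = []
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for f in all_f:
            log_ev = np.zeros((P, T, sizes[f]))
            for tau in range(t_obs):
                log_ev[:, tau, :] = likelihood_term(tau, f)
            prior = np.broadcast_to(np.exp(lnD[f]), (P, sizes[f]))
            new_q, new_xi = _chain_smooth(prior, trans[f], log_ev)
            delta = max(delta, float(np.abs(new_q - q[f]).max()))
            q[f], xi[f] = new_q, new_xi
        if track_F:
            F_hist.append(free_energy())
        if delta < tol:
            converged = True
            break

    F = F_hist[-1] if (track_F and F_hist) else free_energy()
    return InferenceResult(beliefs=q, F=F,
                          F_trace=np.array(F_hist) if track_F else None,
                          converged=converged)


def infer_states(model: GenerativeModel,
                 outcomes: Sequence[Sequence[int]],
                 policy: Sequence[int],
                 precisions: Precisions | None = None,
                 **kw) -> tuple[list[np.ndarray], float, bool]:
    """Single-policy convenience wrapper around :func:`infer_states_batch`.

    Returns (per-factor ``(T, Ns_f)`` beliefs, free energy F, converged flag).
    """
    sub = GenerativeModel(A=model.A, B=model.B, C=model.C, D=model.D,
                          policies=np.asarray(policy, dtype=int)[None, :],
                          T=model.T, controllable_factor=model.controllable_factor,
                          factor_names=model.factor_names,
                          modality_names=model.modality_names)
    res = infer_states_batch(sub, outcomes, precisions, **kw)
    return [b[0] for b in res.beliefs], float(res.F[0]), res.converged


# ---------------------------------------------------------------------------
# expected free energy, policy posterior, precision dynamics
# ---------------------------------------------------------------------------

def outcome_ambiguity(A: np.ndarray) -> np.ndarray:
    """Conditional outcome entropy ``H[p(o|s)]`` per joint state."""
    return -(A * safe_log(A)).sum(axis=0)


def expected_free_energy_batch(model: GenerativeModel,
                               beliefs: list[np.ndarray],
                               current_step: int) -> np.ndarray:
    """Expected free energy ``G`` per policy, summed over future steps.

    ``G = risk + ambiguity`` with risk the KL divergence from the predicted
    outcome distribution to the preference distribution ``softmax(C)`` and
    ambiguity the expected conditional entropy of the likelihood mapping.
    Lower is better.  Steps ``current_step+1 .. T-1`` (0-based) contribute.
    """
    T, P = model.T, model.n_policies
    sizes = model.state_sizes
    G = np.zeros(P)
    pref = [safe_log(softmax(c)) for c in model.C]
    amb = [outcome_ambiguity(a) for a in model.A]
    for tau in range(current_step + 1, T):
        for m, a in enumerate(model.A):
            # predicted outcomes: contract A with each factor's beliefs at tau
            pred = np.broadcast_to(a, (P,) + a.shape).copy()
            amb_m = np.broadcast_to(amb[m], (P,) + amb[m].shape).copy()
            for f in range(model.n_factors):
                pred = np.einsum(pred, list(range(pred.ndim)),
                                 beliefs[f][:, tau, :], [0, 2],
                                 [0, 1] + list(range(3, pred.ndim)))
                amb_m = np.einsum(amb_m, list(range(amb_m.ndim)),
                                  beliefs[f][:, tau, :], [0, 1],
                                  [0] + list(range(2, amb_m.ndim)))
            pred = pred.reshape(P, a.shape[0])
            G += np.sum(pred * (safe_log(pred) - pref[m]), axis=1)
            G += amb_m.reshape(P)
    return G


def expected_free_energy(model: GenerativeModel,
                         policy: Sequence[int],
                         beliefs: list[np.ndarray],
                         current_step: int = 0) -> float:
    """Single-policy G; ``beliefs`` are per-factor ``(T, Ns_f)`` arrays."""
    sub = GenerativeModel(A=model.A, B=model.B, C=model.C, D=model.D,
                          policies=np.asarray(policy, dtype=int)[None, :],
                          T=model.T, controllable_factor=model.controllable_factor)
    b = [x[None, ...] for x in beliefs]
    return float(expected_free_energy_batch(sub, b, current_step)[0])


def policy_posterior(F: np.ndarray, G: np.ndarray,
                     gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Prior and posterior over policies.

    prior = softmax(-gamma*G); posterior = softmax(-gamma*G - F).  Both are
    invariant to adding a constant to G or to F.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape != G.shape:
        raise ValueError("F and G must have the same length")
    prior = softmax(-gamma * G)
    post = softmax(-gamma * G - F)
    return post, prior


@dataclass
class PrecisionUpdate:
    beta: float
    gamma_trace: np.ndarray
    clipped: bool
    pi_posterior: np.ndarray
    pi_prior: np.ndarray


def update_precision(beta_prior: float, G: np.ndarray, F: np.ndarray,
                     *, beta_init: float | None = None,
                     n_iter: int = 16) -> PrecisionUpdate:
    """Iterate the policy-precision (simulated dopamine) update.

    Fixed point: ``beta = beta_prior + (pi_post - pi_prior) . G`` where the
    policy distributions themselves depend on ``gamma = 1/beta``.  Each
    variational iteration takes a damped Newton-style half-step toward the
    fixed point and appends ``gamma`` to the trace; ``beta`` is clipped at
    1/64.  With ``pi_post == pi_prior`` (e.g. F constant) beta relaxes to the
    prior and the trace is flat.
    """
    if beta_prior <= 0:
        raise ValueError("beta_prior must be positive")
    beta = beta_prior if beta_init is None else beta_init
    trace = []
    clipped = False
    post = prior = None
    for _ in range(n_iter):
        gamma = 1.0 / beta
        post, prior = policy_posterior(F, G, gamma)
        target = beta_prior + float((post - prior) @ G)
        beta = beta - (beta - target) / 2.0
        if beta < BETA_FLOOR:
            beta = BETA_FLOOR
            clipped = True
        trace.append(1.0 / beta)
    return PrecisionUpdate(beta=beta, gamma_trace=np.array(trace),
                           clipped=clipped, pi_posterior=post, pi_prior=prior)


def action_marginal(pi_posterior: np.ndarray, policies: np.ndarray,
                    step: int, n_controls: int) -> np.ndarray:
    """Marginal distribution over the next control at ``step`` (0-based)."""
    pi_posterior = np.asarray(pi_posterior, dtype=float)
    marg = np.zeros(n_controls)
    np.add.at(marg, policies[:, step], pi_posterior)
    return normalise(marg)


def sample_action(pi_posterior: np.ndarray, policies: np.ndarray, step: int,
                  n_controls: int, rng: np.random.Generator) -> int:
    """Sample the next control from the policy-marginal action distribution."""
    marg = action_marginal(pi_posterior, policies, step, n_controls)
    return int(rng.choice(n_controls, p=marg))
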