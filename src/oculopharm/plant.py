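"""Continuous saccade generator.

Each discrete 250 ms epoch launches a small Bayesian-filter-style attractor:
the believed eye position ``mu`` is drawn toward the attracting (equilibrium)
point ``eta`` supplied by the categorical level, while a competing
stationarity (fixation) prior with precision ``pi_motor`` — the synthetic
GABAergic nigro-collicular gain — resists belief updating.  The true eye
follows the belief through a fast first-order proprioceptive reflex.

The reduction used here is a linear second-order filter per axis::

    mu_ddot = k_eff (eta - mu) - lambda_eff mu_dot
    eye_dot = (mu - eye) / tau_reflex

with the stationarity prior entering as precision-weighted averaging of the
competing flows:

    k_eff      = k * p_target / (p_target + pi_motor)
    lambda_eff = lambda0 + c_lambda * pi_motor

High ``pi_motor`` therefore yields slow, hypometric ("broken") saccades; low
``pi_motor`` an underdamped overshoot with a higher peak velocity.  The
linear time-invariant system is integrated exactly with a matrix-exponential
propagator at the sampling step ``dt``, so the trajectory is independent of
``dt`` up to sampling resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm


@dataclass
class PlantParams:
    """Attractor-filter constants (degrees, seconds)."""

    k: float = 90000.0          # stiffness of the target-attraction flow, s^-2
    p_target: float = 1.0       # precision of the target-attraction prior
    lambda0: float = 174.0      # baseline damping, s^-1
    c_lambda: float = 271.0     # damping added per unit of pi_motor, s^-1
    tau_reflex: float = 0.002   # proprioceptive reflex lag, s
    dt: float = 0.001           # sampling step, s
    segment_duration: float = 0.25  # one discrete epoch, s

    def k_eff(self, pi_motor: float) -> float:
        return self.k * self.p_target / (self.p_target + pi_motor)

    def lambda_eff(self, pi_motor: float) -> float:
        return self.lambda0 + self.c_lambda * pi_motor


@dataclass
class ContinuousFilterState:
    """Believed and true 2-D eye state at a segment boundary."""

    mu: np.ndarray       # believed position, deg
    mu_dot: np.ndarray   # believed velocity, deg/s
    eye: np.ndarray      # true position, deg

    @classmethod
    def at_rest(cls, position) -> "ContinuousFilterState":
        p = np.asarray(position, dtype=float)
        return cls(mu=p.copy(), mu_dot=np.zeros(2), eye=p.copy())


@dataclass
class ContinuousTrajectory:
    """Uniformly sampled 2-D eye trajectory, possibly spanning segments."""

    times: np.ndarray       # s
    positions: np.ndarray   # (n, 2) deg
    velocities: np.ndarray  # (n, 2) deg/s
    segment_bounds: list[int] = field(default_factory=list)  # start indices

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)

    def append(self, other: "ContinuousTrajectory") -> "ContinuousTrajectory":
        """Concatenate, dropping the other's duplicate boundary sample so a
        stitched T-segment trajectory spans exactly T x segment_duration."""
        n0 = len(self.times)
        return ContinuousTrajectory(
            times=np.concatenate([self.times, other.times[1:] + self.times[-1]]),
            positions=np.vstack([self.positions, other.positions[1:]]),
            velocities=np.vstack([self.velocities, other.velocities[1:]]),
            segment_bounds=self.segment_bounds + [n0 + b for b in other.segment_bounds],
        )

    def to_frame(self):
        """Trajectory as a pandas DataFrame (CSV-ready)."""
        import pandas as pd

        seg = np.zeros(len(self.times), dtype=int)
        for i, b in enumerate(self.segment_bounds):
            seg[b:] = i
        return pd.DataFrame({
            "time_s": self.times,
            "x_deg": self.positions[:, 0],
            "y_deg": self.positions[:, 1],
            "vx_deg_s": self.velocities[:, 0],
            "vy_deg_s": self.velocities[:, 1],
            "segment_index": seg,
        })


@dataclass
class SaccadeMetrics:
    peak_velocity: float       # deg/s
    amplitude: float           # deg, net displacement over the largest event
    endpoint_error: float      # deg, distance from final sample to target
    n_saccades: int
    overshoot: bool
    latency: float             # s, onset of the first event (nan if none)
    events: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"peak_velocity": self.peak_velocity, "amplitude": self.amplitude,
                "endpoint_error": self.endpoint_error, "n_saccades": self.n_saccades,
                "overshoot": self.overshoot, "latency": self.latency}


def _propagator(params: PlantParams, pi_motor: float) -> np.ndarray:
    """Exact one-step propagator for the augmented state [mu, mu_dot, eye, eta]."""
    k = params.k_eff(pi_motor)
    lam = params.lambda_eff(pi_motor)
    a = 1.0 / params.tau_reflex
    M = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-k, -lam, 0.0, k],
        [a, 0.0, -a, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return expm(M * params.dt)


def integrate_segment(state: ContinuousFilterState,
                      eta,
                      pi_motor: float,
                      params: PlantParams | None = None,
                      duration: float | None = None,
                      *,
                      reset_belief: bool = True,
                      ) -> tuple[ContinuousTrajectory, ContinuousFilterState]:
    """Integrate one continuous epoch toward the attracting point ``eta``.

    With ``reset_belief`` (the default) the filter re-initialises its belief
    at the current (proprioceptively sensed) eye position with zero velocity,
    as each discrete epoch launches a fresh continuous inference.  Velocity
    reported is the true eye velocity ``(mu - eye)/tau_reflex``.
    """
    params = params or PlantParams()
    if pi_motor <= 0:
        raise ValueError("pi_motor must be positive")
    duration = params.segment_duration if duration is None else duration
    n = round(duration / params.dt)
    if abs(n * params.dt - duration) > 1e-9:
        raise ValueError("duration must be an integer number of dt steps")
    # sampling-adequacy guard (the propagator itself is exact)
    if params.dt ** 2 * params.k_eff(pi_motor) >= 2.0:
        raise ValueError("dt too large to resolve the attractor dynamics")

    eta = np.asarray(eta, dtype=float)
    if reset_belief:
        state = ContinuousFilterState(mu=state.eye.copy(), mu_dot=np.zeros(2),
                                      eye=state.eye.copy())
    P = _propagator(params, pi_motor)
    # per-axis augmented state columns: rows = [mu, mu_dot, eye, eta], cols = x,y
    X = np.vstack([state.mu, state.mu_dot, state.eye, eta])
    a = 1.0 / params.tau_reflex

    pos = np.empty((n + 1, 2))
    vel = np.empty((n + 1, 2))
    pos[0] = X[2]
    vel[0] = a * (X[0] - X[2])
    for i in range(1, n + 1):
        X = P @ X
        pos[i] = X[2]
        vel[i] = a * (X[0] - X[2])
    times = np.arange(n + 1) * params.dt
    traj = ContinuousTrajectory(times=times, positions=pos, velocities=vel,
                                segment_bounds=[0])
    final = ContinuousFilterState(mu=X[0].copy(), mu_dot=X[1].copy(), eye=X[2].copy())
    return traj, final


def detect_saccades(traj: ContinuousTrajectory,
                    target=None,
                    *,
                    v_threshold: float = 5.0,
                    min_amplitude: float = 0.5,
                    min_duration: float = 0.005) -> SaccadeMetrics:
    """Extract saccade events and kinematic metrics from a trajectory.

    Events are maximal runs with speed above ``v_threshold`` that also pass
    minimum-amplitude and minimum-duration filters (drift suppression).
    ``overshoot`` flags a sign reversal of the target-ward displacement
    component after the first crossing of the target (requires ``target``).
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    speed = traj.speed
    dt = traj.times[1] - traj.times[0] if len(traj.times) > 1 else 0.0
    above = speed > v_threshold
    events: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            amp = float(np.linalg.norm(traj.positions[j] - traj.positions[i]))
            if amp >= min_amplitude and (j - i) * dt >= min_duration:
                events.append((i, j))
            i = j + 1
        else:
            i += 1

    peak = float(speed.max())
    if events:
        amps = [float(np.linalg.norm(traj.positions[j] - traj.positions[i]))
                for i, j in events]
        amplitude = max(amps)
        latency = float(traj.times[events[0][0]])
    else:
        amplitude = 0.0
        latency = float("nan")

    overshoot = False
    endpoint_error = float("nan")
    if target is not None:
        target = np.asarray(target, dtype=float)
        endpoint_error = float(np.linalg.norm(traj.positions[-1] - target))
        start = traj.positions[0]
        d = target - start
        dist = np.linalg.norm(d)
        if dist > 1e-9:
            u = d / dist
            proj = (traj.positions - start) @ u
            crossed = np.nonzero(proj > dist + 1e-6)[0]
            overshoot = crossed.size > 0
    return SaccadeMetrics(peak_velocity=peak, amplitude=amplitude,
                          endpoint_error=endpoint_error, n_saccades=len(events),
                          overshoot=overshoot, latency=latency, events=events)
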