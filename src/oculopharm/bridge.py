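"""Coupling between the categorical and continuous levels.

Descending: the posterior-predictive distribution over discrete locations
becomes a single continuous attracting point — the probability-weighted
(Bayesian model average) mixture of the location coordinates.  Ascending: a
realised trajectory endpoint is converted back into categorical
proprioceptive evidence by a squared-distance softmax over locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import assert_categorical, normalise, softmax


@dataclass
class LocationMap:
    """Named discrete locations with 2-D coordinates in degrees.

    Default geometry: fixation cross at the origin with four peripheral
    targets at the cardinal directions, eccentricity 8 degrees.  The
    peripheral targets are symmetric about fixation, so a uniform mixture
    over them lands on the fixation point.
    """

    names: list[str] = field(default_factory=lambda: ["fixation", "up", "down", "left", "right"])
    coords: np.ndarray = None
    eccentricity: float = 8.0

    def __post_init__(self) -> None:
        if self.coords is None:
            e = self.eccentricity
            self.coords = np.array([[0.0, 0.0], [0.0, e], [0.0, -e], [-e, 0.0], [e, 0.0]])
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("coords must be (n_locations, 2)")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def peripheral(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n != "fixation"]


def outcome_to_target(predictive: np.ndarray, locmap: LocationMap) -> np.ndarray:
    """Attracting point: probability-weighted average of location coordinates."""
    predictive = np.asarray(predictive, dtype=float)
    if predictive.shape != (len(locmap),):
        raise ValueError("predictive dimension does not match the location map")
    assert_categorical(predictive, axis=0, tol=1e-6)
    return predictive @ locmap.coords


def endpoint_to_outcome(endpoint, locmap: LocationMap,
                        obs_precision: float = 4.0) -> np.ndarray:
    """Categorical proprioceptive evidence from a continuous endpoint.

    ``softmax(-0.5 * obs_precision * d^2)`` over locations; at high precision
    this recovers the identity mapping (the nearest location) whenever the
    eye lands on a target.
    """
    if obs_precision <= 0:
        raise ValueError("obs_precision must be positive")
    endpoint = np.asarray(endpoint, dtype=float)
    d2 = np.sum((locmap.coords - endpoint) ** 2, axis=1)
    return softmax(-0.5 * obs_precision * d2)


def sample_proprioceptive_outcome(endpoint, locmap: LocationMap,
                                  obs_precision: float = 4.0) -> int:
    """The discrete proprioceptive outcome fed back to the categorical level.

    At default precisions this is the distribution's argmax (nearest
    location); the full distribution remains available for diagnostics via
    :func:`endpoint_to_outcome`.
    """
    return int(np.argmax(endpoint_to_outcome(endpoint, locmap, obs_precision)))
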