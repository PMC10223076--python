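"""Constant-velocity Kalman filter over the 8-dimensional box state.

The state is (cx, cy, gamma, h, and their per-frame velocities), where
(cx, cy) is the box center, gamma = width/height is the aspect ratio, and h
is the box height in pixels. Observations are the first four components,
taken directly from a detection box. Process and measurement noise scale
with the box height (DeepSort convention): position-like standard
deviations use weight 1/20, velocity-like ones 1/160; the unitless aspect
ratio gets a small fixed standard deviation instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geometry import BoundingBox

__all__ = [
    "KalmanState",
    "KalmanFilter",
    "box_to_measurement",
    "measurement_to_box",
]

STD_WEIGHT_POSITION = 1.0 / 20.0
STD_WEIGHT_VELOCITY = 1.0 / 160.0
# gamma is unitless; a height-scaled std would be meaningless for it
STD_ASPECT = 1e-2
STD_ASPECT_VELOCITY = 1e-5
STD_ASPECT_MEASUREMENT = 1e-1

NDIM = 4


@dataclass
class KalmanState:
    """Gaussian state estimate: 8-vector mean and 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (2 * NDIM,):
            raise ValueError("mean must be an 8-vector")
        if self.covariance.shape != (2 * NDIM, 2 * NDIM):
            raise ValueError("covariance must be 8x8")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")


def box_to_measurement(box: BoundingBox) -> np.ndarray:
    """Box -> (cx, cy, aspect ratio w/h, height)."""
    return np.array(
        [box.x + box.width / 2.0, box.y + box.height / 2.0,
         box.width / box.height, box.height]
    )


def measurement_to_box(z: np.ndarray) -> BoundingBox:
    """Inverse of :func:`box_to_measurement`."""
    cx, cy, gamma, h = np.asarray(z, dtype=float)
    w = gamma * h
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


class KalmanFilter:
    """Constant-velocity filter with height-scaled noise, unit frame time."""

    def __init__(self):
        self._F = np.eye(2 * NDIM)
        self._F[:NDIM, NDIM:] = np.eye(NDIM)  # position += velocity
        self._H = np.eye(NDIM, 2 * NDIM)

    # -- noise models -------------------------------------------------------

    @staticmethod
    def _process_std(h: float) -> np.ndarray:
        return np.array(
            [STD_WEIGHT_POSITION * h, STD_WEIGHT_POSITION * h, STD_ASPECT,
             STD_WEIGHT_POSITION * h,
             STD_WEIGHT_VELOCITY * h, STD_WEIGHT_VELOCITY * h,
             STD_ASPECT_VELOCITY, STD_WEIGHT_VELOCITY * h]
        )

    @staticmethod
    def _measurement_std(h: float) -> np.ndarray:
        return np.array(
            [STD_WEIGHT_POSITION * h, STD_WEIGHT_POSITION * h,
             STD_ASPECT_MEASUREMENT, STD_WEIGHT_POSITION * h]
        )

    # -- filter steps -------------------------------------------------------

    def initiate(self, z: np.ndarray) -> KalmanState:
        """Start a track from a first measurement with zero velocity and a
        diagonal, height-scaled covariance."""
        z = np.asarray(z, dtype=float)
        mean = np.concatenate([z, np.zeros(NDIM)])
        h = z[3]
        std = np.array(
            [2 * STD_WEIGHT_POSITION * h, 2 * STD_WEIGHT_POSITION * h, STD_ASPECT,
             2 * STD_WEIGHT_POSITION * h,
             10 * STD_WEIGHT_VELOCITY * h, 10 * STD_WEIGHT_VELOCITY * h,
             STD_ASPECT_VELOCITY, 10 * STD_WEIGHT_VELOCITY * h]
        )
        return KalmanState(mean, np.diag(std ** 2))

    def predict(self, state: KalmanState) -> KalmanState:
        """Advance one frame: x <- F x, P <- F P F^T + Q."""
        std = self._process_std(state.mean[3])
        Q = np.diag(std ** 2)
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + Q
        return KalmanState(mean, (cov + cov.T) / 2.0)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Project into measurement space: returns (Hx, S = H P H^T + R)."""
        std = self._measurement_std(state.mean[3])
        R = np.diag(std ** 2)
        mean = self._H @ state.mean
        S = self._H @ state.covariance @ self._H.T + R
        return mean, S

    def update(self, state: KalmanState, z: np.ndarray) -> KalmanState:
        """Condition on a measurement of the first four state components."""
        z = np.asarray(z, dtype=float)
        projected_mean, S = self.project(state)
        try:
            chol, lower = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise FloatingPointError("innovation covariance not positive definite") from exc
        K = scipy.linalg.cho_solve(
            (chol, lower), (state.covariance @ self._H.T).T, check_finite=False
        ).T
        mean = state.mean + K @ (z - projected_mean)
        cov = state.covariance - K @ S @ K.T
        return KalmanState(mean, (cov + cov.T) / 2.0)

    def gating_distance(self, state: KalmanState, measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of measurement(s) from the projected
        state, d = (z - Hx)^T S^{-1} (z - Hx). Accepts a 4-vector or an
        (n, 4) stack; returns a scalar array of matching leading shape."""
        measurements = np.atleast_2d(np.asarray(measurements, dtype=float))
        projected_mean, S = self.project(state)
        try:
            chol = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("singular innovation covariance") from exc
        resid = measurements - projected_mean
        y = scipy.linalg.solve_triangular(
            chol, resid.T, lower=True, check_finite=False
        )
        return np.sum(y * y, axis=0)
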