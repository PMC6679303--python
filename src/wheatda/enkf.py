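"""Ensemble Kalman filter with perturbed observations.

Implements the classic stochastic EnKF over an arbitrary state dimension:
forecast of every member through the (possibly nonlinear) model operator
with additive Gaussian process noise, ensemble mean and covariance with the
1/(Ne-1) divisor, Gaussian perturbation of the observation for every
member, the gain K = Pf H^T (H Pf H^T + R)^-1, and the member update
x_a = x_f + K (y_pert - H x_f). H is a selection (identity-row) matrix:
observed variables are model states observed directly.

Observation-perturbation sampling comes in two flavours:

* ``"second_order"`` (default) — perturbations are centred, decorrelated
  from the forecast anomalies and rescaled so their sample covariance is
  exactly R (second-order-exact sampling, cf. Pham 2001). The posterior
  sample covariance is then exactly (I - KH) Pf, so the analysis contracts
  the ensemble variance of every observed variable at every event — a
  property the raw scheme only satisfies in expectation.
* ``"raw"`` — independent N(0, R) draws, the textbook perturbed-observation
  scheme.

All randomness flows through explicit seeds or numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StateVector",
    "EnsembleMatrix",
    "ObservationVector",
    "ensemble_stats",
    "forecast",
    "perturb_observations",
    "selection_matrix",
    "kalman_gain",
    "analysis",
]

_COV_SYM_TOL = 1e-12


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class StateVector:
    """Ordered real state vector with variable names."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.ndim != 1 or v.size != len(self.labels):
            raise ValueError("values must be 1-D with one entry per label")
        if not np.all(np.isfinite(v)):
            raise ValueError("state vector entries must be finite")


@dataclass
class EnsembleMatrix:
    """Ne members stacked as rows of an (Ne, n) matrix."""

    data: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(self.labels)
        if self.data.shape[0] < 2:
            raise ValueError("an ensemble needs at least two members")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("member dimension does not match labels")

    @property
    def n_members(self) -> int:
        return self.data.shape[0]

    @property
    def members(self) -> list[StateVector]:
        return [StateVector(row, self.labels) for row in self.data]


@dataclass
class ObservationVector:
    """m observed values with a diagonal error covariance R."""

    values: np.ndarray
    labels: tuple[str, ...]
    r_diag: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        self.r_diag = np.atleast_1d(np.asarray(self.r_diag, dtype=float))
        self.labels = tuple(self.labels)
        if not (self.values.size == self.r_diag.size == len(self.labels) >= 1):
            raise ValueError("values, labels and r_diag sizes must agree (m >= 1)")
        if np.any(self.r_diag < 0):
            raise ValueError("observation variances must be non-negative")


def ensemble_stats(ensemble: EnsembleMatrix) -> tuple[StateVector, np.ndarray]:
    """Ensemble mean and sample covariance (1/(Ne-1) divisor).

    The returned covariance is symmetrised to remove floating-point
    asymmetry; with Ne >= 2 it is positive semidefinite by construction.
    """
    x = ensemble.data
    mean = x.mean(axis=0)
    anom = x - mean
    cov = anom.T @ anom / (x.shape[0] - 1)
    cov = 0.5 * (cov + cov.T)
    return StateVector(mean, ensemble.labels), cov


def _check_psd(q: np.ndarray, name: str) -> None:
    q = np.asarray(q, dtype=float)
    if q.shape[0] != q.shape[1] or np.abs(q - q.T).max() > 1e-8:
        raise ValueError(f"{name} must be a symmetric square matrix")
    w = np.linalg.eigvalsh(q)
    tr = max(np.trace(q), 1.0)
    if w.min() < -1e-10 * tr:
        raise ValueError(f"{name} is not positive semidefinite")


def forecast(ensemble: EnsembleMatrix,
             step: Callable[[np.ndarray], np.ndarray],
             Q: np.ndarray | None = None,
             rng_seed=None,
             noise_mode: str = "raw") -> EnsembleMatrix:
    """Propagate every member through ``step`` and add N(0, Q) model noise.

    With Q None or zero the forecast is pure model propagation.
    ``noise_mode="second_order"`` centres the noise sample and scales it to
    have sample covariance exactly Q.
    """
    prop = np.asarray([np.asarray(step(row), dtype=float)
                       for row in ensemble.data])
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        if np.any(Q != 0.0):
            _check_psd(Q, "Q")
            rng = _rng(rng_seed)
            ne = prop.shape[0]
            if noise_mode == "second_order":
                noise = _second_order_sample(rng, ne, Q, decorrelate=prop)
            else:
                noise = rng.multivariate_normal(
                    np.zeros(Q.shape[0]), Q, size=ne, method="eigh")
            prop = prop + noise
    return EnsembleMatrix(prop, ensemble.labels)


def perturb_observations(obs: ObservationVector, Ne: int,
                         rng_seed=None) -> np.ndarray:
    """Ne independent replicates y + v_i, v_i ~ N(0, R) (raw scheme)."""
    if Ne < 2:
        raise ValueError("need Ne >= 2 replicates")
    rng = _rng(rng_seed)
    sd = np.sqrt(obs.r_diag)
    return obs.values + rng.standard_normal((Ne, obs.values.size)) * sd


def _second_order_sample(rng: np.random.Generator, ne: int,
                         cov: np.ndarray,
                         decorrelate: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean sample of size ne with sample covariance exactly ``cov``.

    Optionally decorrelated (sample cross-covariance zero) from the columns
    of ``decorrelate``. Falls back to a raw draw when the ensemble is too
    small for the constraints (ne <= m + rank of the decorrelation basis).
    """
    m = cov.shape[0]
    v = rng.standard_normal((ne, m))
    v -= v.mean(axis=0)
    if decorrelate is not None:
        a = decorrelate - decorrelate.mean(axis=0)
        if np.any(a):
            q, r = np.linalg.qr(a)
            keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())
            q = q[:, keep]
            v -= q @ (q.T @ v)
    c = v.T @ v / (ne - 1)
    try:
        lc = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        # degenerate small-ensemble case: fall back to raw sampling
        return rng.multivariate_normal(np.zeros(m), cov, size=ne, method="eigh")
    # whiten, then colour to the target covariance (eigh handles PSD targets)
    v = np.linalg.solve(lc, v.T).T
    w, u = np.linalg.eigh(0.5 * (cov + cov.T))
    w = np.clip(w, 0.0, None)
    return v @ (u * np.sqrt(w)) @ u.T


def selection_matrix(state_labels: Sequence[str],
                     obs_labels: Sequence[str]) -> np.ndarray:
    """Identity-row observation operator H mapping state to observed space."""
    state_labels = list(state_labels)
    h = np.zeros((len(obs_labels), len(state_labels)))
    for i, lab in enumerate(obs_labels):
        if lab not in state_labels:
            raise KeyError(f"observed variable {lab!r} is not a state variable")
        h[i, state_labels.index(lab)] = 1.0
    return h


def kalman_gain(Pf: np.ndarray, H: np.ndarray, R: np.ndarray) -> np.ndarray:
    """K = Pf H^T (H Pf H^T + R)^-1.

    Raises when the innovation covariance is singular, naming the observed
    variables involved.
    """
    Pf = np.asarray(Pf, dtype=float)
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    s = H @ Pf @ H.T + R
    cond = np.linalg.cond(s)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular innovation covariance for observed component(s) "
            f"{[int(np.argmax(row)) for row in H]}; "
            "observation variance and forecast spread are both ~0")
    # K = Pf H' S^{-1}; S symmetric so solve on the left then transpose
    return np.linalg.solve(s, H @ Pf).T


def analysis(ensemble: EnsembleMatrix, obs: ObservationVector,
             rng_seed=None, perturbation_mode: str = "second_order",
             gain_mask: np.ndarray | None = None) -> EnsembleMatrix:
    """Perturbed-observation analysis step.

    Computes Pf from the ensemble, the gain from Pf, H and R, perturbs the
    observation for every member and applies the member update. Unobserved
    state components move only through the Pf cross-covariances.

    ``gain_mask`` (n x m) optionally localises the update by elementwise
    multiplication of the gain (Schur product); a mask that zeroes the
    cross-variable entries suppresses sampling noise in the small-ensemble
    cross-covariances and lets unobserved variables respond through the
    model dynamics instead.
    """
    _, pf = ensemble_stats(ensemble)
    h = selection_matrix(ensemble.labels, obs.labels)
    r = np.diag(obs.r_diag)
    k = kalman_gain(pf, h, r)
    if gain_mask is not None:
        k = k * np.asarray(gain_mask, dtype=float)
    ne = ensemble.n_members
    hx = ensemble.data @ h.T
    if perturbation_mode == "second_order":
        rng = _rng(rng_seed)
        v = _second_order_sample(rng, ne, r, decorrelate=hx)
        y = obs.values + v
    elif perturbation_mode == "raw":
        y = perturb_observations(obs, ne, rng_seed)
    else:
        raise ValueError(f"unknown perturbation_mode {perturbation_mode!r}")
    new = ensemble.data + (y - hx) @ k.T
    return EnsembleMatrix(new, ensemble.labels)
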