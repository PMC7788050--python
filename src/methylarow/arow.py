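"""Adaptive Regularization of Weight vectors (AROW), diagonal variant.

AROW is an online linear learner that keeps, per feature, a mean weight
``mu`` (the "determination weight" of a CpG site) and a positive confidence
``sigma`` that shrinks as evidence accumulates. For an example ``(x, y)``
with ``y in {+1, -1}`` and margin ``m = y * (mu . x)``, no update happens
when ``m >= 1``; otherwise with regularization parameter ``r > 0``:

    beta  = 1 / (sum_j sigma_j * x_j**2 + r)
    alpha = max(0, 1 - m) * beta
    mu_j    <- mu_j + alpha * y * sigma_j * x_j
    sigma_j <- sigma_j - beta * (sigma_j * x_j)**2

Multiclass classification is one-vs-others: one binary AROW model per cell
type, each updated on every training sample (positive for its own class,
negative otherwise). A sample is predicted as the class whose model gives
the largest linear score ``sum_j mu_j * x_j`` (no bias term); ties break by
the fixed class order.

Missing beta values contribute 0 to dot products and are skipped in
updates (their ``x_j`` is taken as 0).
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import CLASSES, BetaMatrix

_CHECKPOINT_VERSION = 1


@dataclass
class ArowClassState:
    """One binary AROW model: weight mean, diagonal confidence, and r."""

    mu: np.ndarray
    sigma: np.ndarray
    r: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal shape")
        if self.r <= 0:
            raise ValueError(f"regularization parameter r must be > 0, got {self.r}")
        if not (self.sigma > 0).all():
            raise ValueError("all sigma entries must be > 0")


def arow_update_binary(state: ArowClassState, x: np.ndarray, y: int) -> ArowClassState:
    """One AROW update; returns a new state, the input is untouched."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != state.mu.shape:
        raise ValueError(f"feature dimension mismatch: {x.shape} vs {state.mu.shape}")
    if y not in (+1, -1):
        raise ValueError("label must be +1 or -1")
    x = np.nan_to_num(x)
    m = y * float(state.mu @ x)
    if m >= 1.0:
        return replace(state, mu=state.mu.copy(), sigma=state.sigma.copy())
    sx = state.sigma * x
    beta = 1.0 / (float(sx @ x) + state.r)
    alpha = (1.0 - m) * beta
    mu = state.mu + alpha * y * sx
    sigma = state.sigma - beta * sx * sx
    return ArowClassState(mu=mu, sigma=sigma, r=state.r)


class MulticlassArowModel:
    """One-vs-others multiclass AROW over a fixed probe set.

    Weight means and confidences are stored stacked as ``(C, n_features)``
    arrays for fast per-sample updates of all class models at once.
    """

    def __init__(
        self,
        probe_ids: Sequence[str],
        classes: Sequence[str] = CLASSES,
        r: float = 1.0,
        rng_seed: int = 0,
    ) -> None:
        if r <= 0:
            raise ValueError(f"regularization parameter r must be > 0, got {r}")
        if len(set(probe_ids)) != len(probe_ids):
            raise ValueError("duplicate probe ids")
        self.classes: tuple[str, ...] = tuple(classes)
        self.probe_ids: list[str] = list(probe_ids)
        self.feature_index: dict[str, int] = {p: i for i, p in enumerate(self.probe_ids)}
        self.r = float(r)
        self.rng_seed = int(rng_seed)
        self.epoch_count = 0
        n = len(self.probe_ids)
        self.mu = np.zeros((len(self.classes), n), dtype=np.float64)
        self.sigma = np.ones((len(self.classes), n), dtype=np.float64)

    # -- state access -------------------------------------------------------

    def state(self, cls: str) -> ArowClassState:
        """The binary state of one class model (copied arrays)."""
        c = self.classes.index(cls)
        return ArowClassState(self.mu[c].copy(), self.sigma[c].copy(), self.r)

    def set_state(self, cls: str, state: ArowClassState) -> None:
        c = self.classes.index(cls)
        self.mu[c] = state.mu
        self.sigma[c] = state.sigma

    def copy(self) -> "MulticlassArowModel":
        clone = MulticlassArowModel(self.probe_ids, self.classes, self.r, self.rng_seed)
        clone.epoch_count = self.epoch_count
        clone.mu = self.mu.copy()
        clone.sigma = self.sigma.copy()
        return clone

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MulticlassArowModel):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.probe_ids == other.probe_ids
            and self.r == other.r
            and self.rng_seed == other.rng_seed
            and self.epoch_count == other.epoch_count
            and np.array_equal(self.mu, other.mu)
            and np.array_equal(self.sigma, other.sigma)
        )

    # -- prediction ---------------------------------------------------------

    def _feature_vector(self, x: Mapping[str, float] | np.ndarray) -> np.ndarray:
        if isinstance(x, Mapping):
            missing = [p for p in self.probe_ids if p not in x]
            if missing:
                raise KeyError(
                    f"{len(missing)} probes missing from sample, e.g. {missing[:3]}"
                )
            x = np.array([x[p] for p in self.probe_ids], dtype=np.float64)
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (len(self.probe_ids),):
            raise ValueError(
                f"feature vector has shape {x.shape}, expected ({len(self.probe_ids)},)"
            )
        return np.nan_to_num(x)

    def decision_scores(self, x: Mapping[str, float] | np.ndarray) -> dict[str, float]:
        """Linear score per class: sum of methylation rate times weight."""
        xv = self._feature_vector(x)
        scores = self.mu @ xv
        return dict(zip(self.classes, map(float, scores)))

    def predict(self, x: Mapping[str, float] | np.ndarray) -> str:
        """Class with the largest decision score; ties break by class order."""
        xv = self._feature_vector(x)
        return self.classes[int(np.argmax(self.mu @ xv))]

    def predict_matrix(self, X: np.ndarray) -> list[str]:
        """Predict columns of a (n_features, n_samples) matrix at once."""
        scores = self.mu @ np.nan_to_num(np.asarray(X, dtype=np.float64))
        return [self.classes[i] for i in np.argmax(scores, axis=0)]

    # -- training -----------------------------------------------------------

    def _update_sample(self, x: np.ndarray, true_class: str) -> None:
        """Apply the one-vs-others update of all class models, in place."""
        y = np.where(np.array(self.classes) == true_class, 1.0, -1.0)
        m = y * (self.mu @ x)
        live = m < 1.0
        if not live.any():
            return
        sx = self.sigma[live] * x
        beta = 1.0 / (sx @ x + self.r)
        alpha = (1.0 - m[live]) * beta
        self.mu[live] += (alpha * y[live])[:, None] * sx
        self.sigma[live] -= beta[:, None] * sx * sx

    def train_epoch(
        self,
        beta: BetaMatrix | np.ndarray,
        labels: Mapping[str, str] | Sequence[str],
        rng: np.random.Generator,
    ) -> "MulticlassArowModel":
        """One epoch: every training sample presented once, rng-shuffled.

        ``beta`` is either a :class:`BetaMatrix` whose probe set matches the
        model (``labels`` maps sample id to class) or a raw
        ``(n_features, n_samples)`` array (``labels`` a sequence per column).
        Updates happen in place; the model itself is returned.
        """
        if isinstance(beta, BetaMatrix):
            if beta.probe_ids != self.probe_ids:
                raise ValueError("beta matrix probe set differs from model features")
            X = beta.data.to_numpy()
            label_list = []
            for s in beta.sample_ids:
                if s not in labels:  # type: ignore[operator]
                    raise KeyError(f"unlabeled sample {s!r}")
                label_list.append(labels[s])  # type: ignore[index]
        else:
            X = np.asarray(beta, dtype=np.float64)
            label_list = list(labels)  # type: ignore[arg-type]
            if X.shape[1] != len(label_list):
                raise ValueError("one label per sample column required")
        unknown = set(label_list) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside classes: {sorted(unknown)}")
        X = np.nan_to_num(X)
        order = rng.permutation(X.shape[1])
        for j in order:
            self._update_sample(np.ascontiguousarray(X[:, j]), label_list[j])
        self.epoch_count += 1
        return self


def save_checkpoint(model: MulticlassArowModel, path: str | Path) -> None:
    """Serialize a model; round trip through :func:`load_checkpoint` is exact."""
    np.savez_compressed(
        path,
        version=np.int64(_CHECKPOINT_VERSION),
        classes=np.array(model.classes),
        probe_ids=np.array(model.probe_ids),
        mu=model.mu,
        sigma=model.sigma,
        r=np.float64(model.r),
        epoch_count=np.int64(model.epoch_count),
        rng_seed=np.int64(model.rng_seed),
    )


def load_checkpoint(path: str | Path) -> MulticlassArowModel:
    try:
        with np.load(path, allow_pickle=False) as npz:
            required = {"version", "classes", "probe_ids", "mu", "sigma", "r",
                        "epoch_count", "rng_seed"}
            missing = required - set(npz.files)
            if missing:
                raise ValueError(f"checkpoint missing arrays: {sorted(missing)}")
            if int(npz["version"]) != _CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {npz['version']}")
            model = MulticlassArowModel(
                probe_ids=[str(p) for p in npz["probe_ids"]],
                classes=tuple(str(c) for c in npz["classes"]),
                r=float(npz["r"]),
                rng_seed=int(npz["rng_seed"]),
            )
            model.epoch_count = int(npz["epoch_count"])
            model.mu = npz["mu"].astype(np.float64)
            model.sigma = npz["sigma"].astype(np.float64)
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise ValueError(f"cannot load checkpoint {path}: {exc}") from exc
    if model.mu.shape != (len(model.classes), len(model.probe_ids)):
        raise ValueError(f"checkpoint {path}: array shapes inconsistent")
    return model
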