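"""State Predictive Information Bottleneck (SPIB) with a linear encoder.

The model learns a 2-D latent reaction-coordinate space from collective
variable (CV) trajectories. A stochastic linear encoder

    z = W x + b + ε,   ε ~ N(0, diag(exp(log_var)))

maps the (filtered, standardized) CV vector at time t to a 2-D latent point,
and a softmax decoder q(y | z) predicts the metastable-state label at time
t + Δt. Training minimizes

    E[ −log q(y_{t+Δt} | z_t) ]  +  β · KL( p(z|x) ‖ N(0, I) )

by minibatch Adam; after each round every frame is relabeled to
argmax_y q(y | μ(x_t)) with the deterministic mean encoding, emptied states
are dropped, and training stops when the relabeled fraction falls below
``relabel_tol``. The latent dimension is fixed at 2; at convergence the
surviving states are the metastable states resolvable at the chosen lag and
the two latent coordinates are the learnt reaction coordinates.

Transition pairs never cross trajectory boundaries: each of the independent
input trajectories contributes its own (x_t, y_{t+Δt}) pairs.

Feature filtering precedes the model: CVs whose standard deviation over the
concatenated trajectories is ≤ ``threshold_fraction`` (default 0.25) of the
maximum CV standard deviation are dropped, and the survivors z-scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .descriptors import CVTrajectory

LATENT_DIM = 2


def _as_matrix_list(trajs) -> list[np.ndarray]:
    out = []
    for t in trajs:
        v = t.values if isinstance(t, CVTrajectory) else np.asarray(t, float)
        out.append(np.atleast_2d(v))
    return out


class FeatureVarianceFilter(BaseEstimator, TransformerMixin):
    """Keep CVs with std > threshold_fraction × max std; z-score the survivors.

    Statistics are computed on the concatenation of all trajectories passed
    to :meth:`fit`.
    """

    def __init__(self, threshold_fraction: float = 0.25):
        self.threshold_fraction = threshold_fraction

    def fit(self, X, y=None):
        if isinstance(X, (list, tuple)):
            X = np.concatenate(_as_matrix_list(X), axis=0)
        X = np.atleast_2d(np.asarray(X, float))
        self.std_ = X.std(axis=0)
        max_std = self.std_.max()
        if max_std == 0:
            raise ValueError("all CVs are constant; nothing to keep")
        self.keep_mask_ = self.std_ > self.threshold_fraction * max_std
        kept = X[:, self.keep_mask_]
        self.mean_ = kept.mean(axis=0)
        self.scale_ = kept.std(axis=0)
        self.scale_ = np.where(self.scale_ > 0, self.scale_, 1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} CVs, got {X.shape[1]}"
            )
        return (X[:, self.keep_mask_] - self.mean_) / self.scale_


def filter_features(trajs, threshold_fraction: float = 0.25) -> FeatureVarianceFilter:
    """Fit the variance filter on the concatenation of all trajectories."""
    return FeatureVarianceFilter(threshold_fraction).fit(_as_matrix_list(trajs))


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class SPIB(BaseEstimator, TransformerMixin):
    """Linear-encoder SPIB estimator.

    Parameters
    ----------
    lag : int
        Prediction lag Δt in frames; must be shorter than every trajectory.
    beta : float, default 1e-3
        Information-bottleneck trade-off (weight of the KL term against a
        standard-normal prior). Small by default so prediction dominates.
    learning_rate, batch_size, epochs_per_round : Adam settings per round.
    max_rounds : int
        Maximum train/relabel rounds.
    relabel_tol : float
        Stop when the fraction of frames whose label changed in a relabel
        pass falls below this.
    seed : int
        Seeds batching, noise and initialization; identical seeds and data
        give identical results.

    Attributes
    ----------
    weights_, bias_, log_var_ : encoder parameters (2×d, 2, 2).
    decoder_weights_, decoder_bias_ : softmax decoder (k×2, k).
    labels_ : list of per-trajectory refined state labels.
    n_states_ : surviving state count.
    training_log_ : DataFrame (round, loss, n_states, relabeled_fraction).
    """

    def __init__(
        self,
        lag: int = 1,
        beta: float = 1e-3,
        learning_rate: float = 5e-3,
        batch_size: int = 512,
        epochs_per_round: int = 2,
        max_rounds: int = 30,
        relabel_tol: float = 0.005,
        seed: int = 0,
    ):
        self.lag = lag
        self.beta = beta
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs_per_round = epochs_per_round
        self.max_rounds = max_rounds
        self.relabel_tol = relabel_tol
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _encode_mean(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights_.T + self.bias_

    def _decode_logits(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.decoder_weights_.T + self.decoder_bias_

    def _predict_states(self, X: np.ndarray) -> np.ndarray:
        return self._decode_logits(self._encode_mean(X)).argmax(axis=1)

    def _train_round(self, X: np.ndarray, Y: np.ndarray, rng: np.random.Generator,
                     opt: _Adam) -> float:
        n, k = len(X), len(self.decoder_bias_)
        losses = []
        for _ in range(self.epochs_per_round):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], Y[idx]
                B = len(xb)
                mu = xb @ self.weights_.T + self.bias_
                sigma = np.exp(0.5 * self.log_var_)
                eps = rng.standard_normal((B, LATENT_DIM))
                z = mu + sigma * eps
                logits = z @ self.decoder_weights_.T + self.decoder_bias_
                logits -= logits.max(axis=1, keepdims=True)
                expl = np.exp(logits)
                p = expl / expl.sum(axis=1, keepdims=True)
                ce = -np.mean(np.log(p[np.arange(B), yb] + 1e-300))
                var = np.exp(self.log_var_)
                kl = 0.5 * np.mean(np.sum(mu**2, axis=1)) + 0.5 * np.sum(var - self.log_var_ - 1)
                loss = ce + self.beta * kl
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite SPIB loss (ce={ce}, kl={kl}); "
                        "reduce the learning rate or check the inputs"
                    )
                losses.append(loss)

                g_logits = p.copy()
                g_logits[np.arange(B), yb] -= 1.0
                g_logits /= B
                g_dec_w = g_logits.T @ z
                g_dec_b = g_logits.sum(axis=0)
                gz = g_logits @ self.decoder_weights_
                g_mu = gz + self.beta * mu / B
                g_logvar = 0.5 * sigma * (gz * eps).sum(axis=0) + self.beta * 0.5 * (var - 1)
                g_w = g_mu.T @ xb
                g_b = g_mu.sum(axis=0)
                opt.step(
                    [self.weights_, self.bias_, self.log_var_,
                     self.decoder_weights_, self.decoder_bias_],
                    [g_w, g_b, g_logvar, g_dec_w, g_dec_b],
                )
        return float(np.mean(losses))

    # -- public API --------------------------------------------------------

    def fit(self, trajs, initial_labels):
        """Train on filtered/standardized CV trajectories with initial labels.

        ``trajs``: list of (n_i × d) arrays (or CVTrajectory); ``initial_labels``:
        list of matching integer label arrays.
        """
        mats = _as_matrix_list(trajs)
        labels = [np.asarray(l, int).copy() for l in initial_labels]
        if len(mats) != len(labels) or any(len(m) != len(l) for m, l in zip(mats, labels)):
            raise ValueError("trajectories and initial labels must align")
        if self.lag < 1 or any(len(m) <= self.lag for m in mats):
            raise ValueError(
                f"lag {self.lag} must be >= 1 and shorter than every trajectory"
            )
        d = mats[0].shape[1]
        if any(m.shape[1] != d for m in mats):
            raise ValueError("all trajectories must share the CV dimension")

        # remap labels to a dense 0..k-1 range
        uniq = np.unique(np.concatenate(labels))
        remap = {int(s): i for i, s in enumerate(uniq)}
        labels = [np.vectorize(remap.__getitem__)(l) for l in labels]
        k = len(uniq)
        if k < 2:
            warnings.warn("initial labels span a single state; training is degenerate",
                          stacklevel=2)

        rng = np.random.default_rng(self.seed)
        self.weights_ = 0.1 * rng.standard_normal((LATENT_DIM, d))
        self.bias_ = np.zeros(LATENT_DIM)
        self.log_var_ = np.full(LATENT_DIM, -2.0)
        self.decoder_weights_ = 0.1 * rng.standard_normal((k, LATENT_DIM))
        self.decoder_bias_ = np.zeros(k)
        self.n_features_in_ = d

        log_rows = []
        opt = None
        n_total = sum(len(m) for m in mats)
        for rnd in range(self.max_rounds):
            X = np.concatenate([m[: -self.lag] for m in mats], axis=0)
            Y = np.concatenate([l[self.lag :] for l in labels], axis=0)
            if opt is None:
                opt = _Adam(
                    [p.shape for p in (self.weights_, self.bias_, self.log_var_,
                                       self.decoder_weights_, self.decoder_bias_)],
                    self.learning_rate,
                )
            loss = self._train_round(X, Y, rng, opt)

            # relabel every frame with the mean encoding
            new_labels = [self._predict_states(m) for m in mats]
            changed = sum(int(np.sum(nl != ol)) for nl, ol in zip(new_labels, labels))
            frac = changed / n_total

            # drop emptied states and compact the decoder
            survivors = np.unique(np.concatenate(new_labels))
            if len(survivors) < len(self.decoder_bias_):
                remap_s = {int(s): i for i, s in enumerate(survivors)}
                new_labels = [np.vectorize(remap_s.__getitem__)(l) for l in new_labels]
                self.decoder_weights_ = self.decoder_weights_[survivors]
                self.decoder_bias_ = self.decoder_bias_[survivors]
                opt = None  # decoder shape changed; restart optimizer state
            labels = new_labels
            log_rows.append(
                {"round": rnd, "loss": loss, "n_states": len(survivors),
                 "relabeled_fraction": frac}
            )
            if frac < self.relabel_tol:
                break

        self.labels_ = labels
        self.n_states_ = len(self.decoder_bias_)
        self.training_log_ = pd.DataFrame(log_rows)
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic mean encoding μ(x) = W x + b of filtered CV vectors."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self._encode_mean(X)

    def predict(self, X) -> np.ndarray:
        """Most likely state label for each filtered CV vector."""
        X = np.atleast_2d(np.asarray(X, float))
        return self._predict_states(X)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "weights": self.weights_.tolist(),
            "bias": self.bias_.tolist(),
            "log_var": self.log_var_.tolist(),
            "decoder_weights": self.decoder_weights_.tolist(),
            "decoder_bias": self.decoder_bias_.tolist(),
            "n_states": self.n_states_,
            "n_features_in": self.n_features_in_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SPIB":
        model = cls(**d["params"])
        model.weights_ = np.asarray(d["weights"], float)
        model.bias_ = np.asarray(d["bias"], float)
        model.log_var_ = np.asarray(d["log_var"], float)
        model.decoder_weights_ = np.asarray(d["decoder_weights"], float)
        model.decoder_bias_ = np.asarray(d["decoder_bias"], float)
        model.n_states_ = int(d["n_states"])
        model.n_features_in_ = int(d["n_features_in"])
        return model


@dataclass
class SpibModel:
    """Bundle of the fitted feature filter and SPIB encoder/decoder."""

    spib: SPIB
    feature_filter: FeatureVarianceFilter

    def save(self, path: str | Path) -> None:
        payload = {
            "spib": self.spib.to_dict(),
            "filter": {
                "threshold_fraction": self.feature_filter.threshold_fraction,
                "std": self.feature_filter.std_.tolist(),
                "keep_mask": self.feature_filter.keep_mask_.tolist(),
                "mean": self.feature_filter.mean_.tolist(),
                "scale": self.feature_filter.scale_.tolist(),
                "n_features_in": self.feature_filter.n_features_in_,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SpibModel":
        payload = json.loads(Path(path).read_text())
        filt = FeatureVarianceFilter(payload["filter"]["threshold_fraction"])
        filt.std_ = np.asarray(payload["filter"]["std"], float)
        filt.keep_mask_ = np.asarray(payload["filter"]["keep_mask"], bool)
        filt.mean_ = np.asarray(payload["filter"]["mean"], float)
        filt.scale_ = np.asarray(payload["filter"]["scale"], float)
        filt.n_features_in_ = int(payload["filter"]["n_features_in"])
        return cls(spib=SPIB.from_dict(payload["spib"]), feature_filter=filt)


def train_spib(
    trajs,
    initial_labels,
    lag: int,
    feature_filter: FeatureVarianceFilter | None = None,
    **config,
) -> SpibModel:
    """Filter features, then fit the SPIB estimator; returns the bundle."""
    mats = _as_matrix_list(trajs)
    if feature_filter is None:
        feature_filter = filter_features(mats)
    filtered = [feature_filter.transform(m) for m in mats]
    spib = SPIB(lag=lag, **config).fit(filtered, initial_labels)
    return SpibModel(spib=spib, feature_filter=feature_filter)


def project(model: SpibModel | SPIB, feature_filter: FeatureVarianceFilter | None,
            points) -> np.ndarray:
    """Project raw CV vectors to (σ1, σ2) with the deterministic mean encoder."""
    if isinstance(model, SpibModel):
        feature_filter = model.feature_filter
        model = model.spib
    pts = points.values if isinstance(points, CVTrajectory) else np.atleast_2d(np.asarray(points, float))
    if feature_filter is not None:
        pts = feature_filter.transform(pts)
    return model.transform(pts)


def screen_lags(
    trajs,
    initial_labels,
    lags: Sequence[int],
    physical_features: dict[str, np.ndarray] | None = None,
    feature_filter: FeatureVarianceFilter | None = None,
    **config,
) -> pd.DataFrame:
    """Train one SPIB per lag and tabulate diagnostics.

    Reports per lag: surviving state count, final training loss, and the
    absolute Pearson correlation of each latent coordinate with each supplied
    physical feature (concatenated over trajectories, e.g. the A-loop
    distance or Dunbrack D1/D2). Lag selection is left to the user. A failing
    lag yields a row flagged failed without aborting the rest.
    """
    mats = _as_matrix_list(trajs)
    if feature_filter is None:
        feature_filter = filter_features(mats)
    rows = []
    for lag in lags:
        row: dict = {"lag": lag, "failed": False}
        try:
            model = train_spib(mats, initial_labels, lag,
                               feature_filter=feature_filter, **config)
            spib = model.spib
            row["n_final_states"] = spib.n_states_
            row["loss"] = float(spib.training_log_["loss"].iloc[-1])
            if physical_features:
                latent = np.concatenate(
                    [project(model, None, m) for m in mats], axis=0
                )
                for name, feat in physical_features.items():
                    feat = np.asarray(feat, float)
                    for j in range(LATENT_DIM):
                        r = np.corrcoef(latent[:, j], feat)[0, 1]
                        row[f"abs_r_sigma{j + 1}_{name}"] = abs(float(r))
        except Exception as exc:
            row.update({"failed": True, "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_projection(path: str | Path, ids: Sequence[str], latent: np.ndarray) -> None:
    pd.DataFrame(
        {"id": list(ids), "sigma1": latent[:, 0], "sigma2": latent[:, 1]}
    ).to_csv(path, sep="\t", index=False)
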