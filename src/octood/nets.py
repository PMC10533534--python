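"""Compact trainable classifier with interchangeable heads.

The network is a small dense model with an average-pooling stem:

    image (S x S) -> avg-pool (factor p) -> flatten -> whiten (fixed PCA)
        -> dense(h1) -> ReLU
        -> dense(h2) -> ReLU -> dropout
        -> dense(D)                          <- penultimate feature space
        -> dense(n_out)                      <- head logits

Three heads share this trunk:

* ``softmax``       — ``n_out = K`` class logits, softmax probabilities;
* ``dirichlet``     — ``n_out = K``; a softplus turns the raw outputs into
  non-negative per-class *evidence* ``e_k``; the induced Dirichlet has
  ``alpha_k = e_k + 1``, total evidence ``S = sum(alpha)``, belief
  ``b_k = e_k / S``, uncertainty ``u = K / S`` and mean class probability
  ``p_k = alpha_k / S``;
* ``reject_bucket`` — ``n_out = K + 1``; the extra output is an abstention
  class trained on exposed outliers.

Forward, backward and input-gradient passes are written out explicitly in
numpy: the model is small enough that hand-derived gradients are both
fast and exactly reproducible, and the input gradient is required by the
ODIN perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DirichletOutput", "CompactNet", "build_model", "extract_features",
           "softmax", "softplus", "HEADS"]

HEADS = ("softmax", "dirichlet", "reject_bucket")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


@dataclass
class DirichletOutput:
    """Dirichlet head output for a batch (or a single sample).

    Satisfies ``u + sum_k b_k = 1`` exactly:
    ``u = K/S`` and ``b_k = e_k/S`` with ``S = sum_k (e_k + 1)``.
    """

    evidence: np.ndarray   # (..., K), >= 0

    @property
    def alpha(self) -> np.ndarray:
        return self.evidence + 1.0

    @property
    def total(self) -> np.ndarray:
        return np.sum(self.alpha, axis=-1)

    @property
    def belief(self) -> np.ndarray:
        return self.evidence / self.total[..., None]

    @property
    def uncertainty(self) -> np.ndarray:
        K = self.evidence.shape[-1]
        return K / self.total

    @property
    def p_hat(self) -> np.ndarray:
        return self.alpha / self.total[..., None]


class CompactNet:
    """Small dense classifier; see module docstring for the layout."""

    def __init__(self, head: str, K: int, D: int = 100,
                 hidden: tuple[int, int] = (128, 96),
                 pool: int = 2, side: int = 64, dropout_rate: float = 0.2,
                 whiten_dim: int = 128, seed: int = 0):
        if head not in HEADS:
            raise ValueError(f"unknown head {head!r}; expected one of {HEADS}")
        if K < 2:
            raise ValueError("K must be >= 2")
        if D < 2:
            raise ValueError("feature dimension D must be >= 2")
        if side % pool != 0:
            raise ValueError(f"side {side} must be divisible by pool factor {pool}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        self.head = head
        self.K = K
        self.D = D
        self.hidden = tuple(hidden)
        self.pool = pool
        self.side = side
        self.dropout_rate = dropout_rate
        self.n_out = K + 1 if head == "reject_bucket" else K
        self.n_pooled = (side // pool) ** 2
        self.whiten_dim = min(whiten_dim, self.n_pooled)
        self.n_in = self.whiten_dim
        self.init_seed = seed
        # whitening front end: placeholder (centered identity slice) until
        # fitted on training images by fit_input_norm
        self.in_mu = np.full(self.n_pooled, 0.5)
        self.in_proj = np.zeros((self.n_pooled, self.whiten_dim))
        self.in_proj[np.arange(self.whiten_dim), np.arange(self.whiten_dim)] = 1.0
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        h1, h2 = self.hidden
        self.params = {
            "W1": he(self.n_in, h1),  "b1": np.zeros(h1),
            "W1b": he(h1, h2),        "b1b": np.zeros(h2),
            "W2": he(h2, self.D),     "b2": np.zeros(self.D),
            "W3": he(self.D, self.n_out), "b3": np.zeros(self.n_out),
        }

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _pooled(self, x: np.ndarray) -> np.ndarray:
        b, s, _ = x.shape
        p = self.pool
        return x.reshape(b, s // p, p, s // p, p).mean(axis=(2, 4)).reshape(b, -1)

    def _stem(self, x: np.ndarray) -> np.ndarray:
        """Average-pool, flatten and apply the fixed whitening projection.

        The projection defaults to a centered identity slice and is
        fitted on training images by :meth:`fit_input_norm`; it is fixed
        (non-trainable) thereafter. Decorrelated unit-variance inputs
        make plain SGD on the dense trunk converge orders of magnitude
        faster than raw, strongly correlated intensities would.
        """
        return (self._pooled(x) - self.in_mu) @ self.in_proj

    def fit_input_norm(self, images: np.ndarray, eps: float = 1e-4) -> None:
        """Fit the whitening front end (PCA to ``whiten_dim`` components,
        eigenvalue floor ``eps``) on training images."""
        flat = self._pooled(images)
        self.in_mu = flat.mean(axis=0)
        centered = flat - self.in_mu
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        lam = (svals ** 2) / len(flat)
        r = min(self.whiten_dim, len(lam))
        proj = np.zeros((self.n_pooled, self.whiten_dim))
        proj[:, :r] = vt[:r].T / np.sqrt(lam[:r] + eps)
        self.in_proj = proj

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        """Run the network; returns a cache dict with ``logits`` and
        ``features`` plus intermediates needed for backprop.

        ``training=True`` activates dropout (an rng is then required if
        the dropout rate is nonzero).
        """
        single = x.ndim == 2
        if single:
            x = x[None]
        P = self.params
        z0 = self._stem(x)
        h1 = z0 @ P["W1"] + P["b1"]
        a1 = np.maximum(h1, 0.0)
        h1b = a1 @ P["W1b"] + P["b1b"]
        a1b = np.maximum(h1b, 0.0)
        if training and self.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode forward with dropout needs an rng")
            mask = (rng.random(a1b.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
        else:
            mask = np.ones_like(a1b)
        d1 = a1b * mask
        # linear penultimate embedding; the nonlinearity lives in the trunk
        a2 = d1 @ P["W2"] + P["b2"]
        logits = a2 @ P["W3"] + P["b3"]
        return {"x": x, "z0": z0, "h1": h1, "a1": a1, "h1b": h1b,
                "mask": mask, "d1": d1, "features": a2, "logits": logits,
                "single": single}

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        """Parameter gradients for a batch loss whose gradient w.r.t. the
        logits is ``dlogits`` (already averaged over the batch)."""
        P = self.params
        a2, d1, z0 = cache["features"], cache["d1"], cache["z0"]
        grads = {}
        grads["W3"] = a2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        da2 = dlogits @ P["W3"].T  # linear embedding layer
        grads["W2"] = d1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        dd1 = da2 @ P["W2"].T
        da1b = dd1 * cache["mask"] * (cache["h1b"] > 0)
        grads["W1b"] = cache["a1"].T @ da1b
        grads["b1b"] = da1b.sum(axis=0)
        da1 = da1b @ P["W1b"].T
        dh1 = da1 * (cache["h1"] > 0)
        grads["W1"] = z0.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        return grads

    def input_gradient(self, cache: dict, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of the same batch loss w.r.t. the input pixels."""
        P = self.params
        da2 = dlogits @ P["W3"].T
        dd1 = da2 @ P["W2"].T
        da1b = dd1 * cache["mask"] * (cache["h1b"] > 0)
        da1 = da1b @ P["W1b"].T
        dh1 = da1 * (cache["h1"] > 0)
        dz0 = dh1 @ P["W1"].T
        dpooled = dz0 @ self.in_proj.T
        b = dpooled.shape[0]
        p, s = self.pool, self.side
        g = dpooled.reshape(b, s // p, s // p)
        # each input pixel contributed 1/p^2 to its pooled cell
        gx = np.repeat(np.repeat(g, p, axis=1), p, axis=2) / (p * p)
        return gx[0] if cache["single"] else gx

    # ------------------------------------------------------------------
    # inference conveniences
    # ------------------------------------------------------------------

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)["logits"]

    def predict_proba(self, x: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities: softmax for softmax/reject-bucket heads,
        Dirichlet mean ``alpha / S`` for the evidential head."""
        out = self.forward(x, training=training, rng=rng)
        if self.head == "dirichlet":
            return DirichletOutput(softplus(out["logits"])).p_hat
        return softmax(out["logits"])

    def dirichlet_output(self, x: np.ndarray) -> DirichletOutput:
        if self.head != "dirichlet":
            raise ValueError("dirichlet_output requires a dirichlet head")
        return DirichletOutput(softplus(self.forward(x)["logits"]))

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    @property
    def config(self) -> dict:
        return {"head": self.head, "K": self.K, "D": self.D,
                "hidden": self.hidden, "pool": self.pool, "side": self.side,
                "dropout_rate": self.dropout_rate,
                "whiten_dim": self.whiten_dim, "seed": self.init_seed}


def build_model(head: str, K: int, D: int = 100, dropout_rate: float = 0.2,
                side: int = 64, hidden: tuple[int, int] = (128, 96),
                pool: int = 2, whiten_dim: int = 128, seed: int = 0) -> CompactNet:
    """Construct a :class:`CompactNet` with the requested head.

    ``head`` is one of ``softmax`` / ``dirichlet`` / ``reject_bucket``;
    the reject-bucket head carries ``K + 1`` outputs.
    """
    return CompactNet(head=head, K=K, D=D, hidden=hidden, pool=pool,
                      side=side, dropout_rate=dropout_rate,
                      whiten_dim=whiten_dim, seed=seed)


def extract_features(model: CompactNet, images: np.ndarray) -> np.ndarray:
    """Penultimate-layer feature vectors (eval mode, deterministic)."""
    out = model.forward(images)
    feats = out["features"]
    return feats[0] if out["single"] else feats
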