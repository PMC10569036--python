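"""Neural network mapping fingerprints to substructure-count vectors.

The model takes, per compound, the standardized 10-solvent
physicochemical fingerprint, the monoisotopic mass, a fixed-length
molecular-formula encoding (counts over the element alphabet) and the
per-formula fragment prior, and outputs a non-negative decimal count for
every substructure in the catalog. Predicted counts are probabilities,
not integers — 0.3 benzene rings means "probably none" — and are
deliberately left unrounded for downstream similarity scoring.

Architecture: 1 input layer, 10 hidden layers of 500 ReLU units, one
dropout layer (rate 0.2 by default), one final hidden layer of 500 units
with an exponential activation, and a linear output layer clamped at 0
at inference. Training minimizes the mean absolute error with the
Adamax optimizer at step size 0.001. Evaluation uses an 80/20
shuffle-split with 5-fold cross-validation, reporting per-fragment
Pearson R^2 and MAE on the held-out portions.

The network is implemented directly on numpy (float32, minibatch
backprop); the architecture is small enough that a framework would add
nothing but weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import ShuffleSplit

from .config import DEFAULT_SOLVENTS, ELEMENT_ALPHABET, log
from .feature_io import parse_formula
from .partition import Fingerprint

HIDDEN_LAYERS = 10
HIDDEN_WIDTH = 500
_EXP_CLIP = 30.0  # exp argument clamp; keeps activations finite


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def encode_formula(formula: str | Mapping[str, int]) -> np.ndarray:
    """Fixed-length element-count vector over the ordered alphabet."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    unknown = set(counts) - set(ELEMENT_ALPHABET)
    if unknown:
        raise ValueError(f"elements outside the supported alphabet: {sorted(unknown)}")
    return np.array([counts.get(el, 0) for el in ELEMENT_ALPHABET], dtype=float)


def assemble_inputs(
    fps: Sequence[Fingerprint],
    masses: Mapping[str, float],
    formulas: Mapping[str, str | Mapping[str, int]],
    priors: Mapping[str, np.ndarray],
    panel: Sequence[str] = DEFAULT_SOLVENTS,
) -> np.ndarray:
    """Stack standardized fingerprints, mass, formula encoding and prior
    into the model's input matrix (one row per compound).

    ``priors`` maps compound_id to a catalog-length vector. Fingerprints
    must be panel-complete: a missing solvent cannot be encoded and the
    compound should first go through read-across imputation.
    """
    rows = []
    for fp in fps:
        if fp.missing:
            raise ValueError(
                f"compound {fp.compound_id} has missing solvents "
                f"{sorted(fp.missing)}; impute the fingerprint first"
            )
        if not fp.standardized:
            raise ValueError(
                f"compound {fp.compound_id}: fingerprint is not standardized"
            )
        cid = fp.compound_id
        rows.append(
            np.concatenate(
                [
                    fp.vector(panel),
                    [float(masses[cid])],
                    encode_formula(formulas[cid]),
                    np.asarray(priors[cid], dtype=float),
                ]
            )
        )
    x = np.asarray(rows, dtype=float)
    if np.isnan(x).any():
        raise ValueError("assembled inputs contain NaN; impute fingerprints first")
    return x


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class FragmentNet:
    """Feed-forward substructure-count regressor (weights in float32)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout_rate: float
    catalog_size: int
    input_size: int
    # column-wise input scaling (training-set statistics)
    x_mean: Optional[np.ndarray] = None
    x_scale: Optional[np.ndarray] = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def layer_spec(self) -> list[str]:
        """Human-readable architecture audit, input to output."""
        spec = ["input"]
        spec += [f"dense({HIDDEN_WIDTH})+relu"] * HIDDEN_LAYERS
        spec += [f"dropout({self.dropout_rate})", f"dense({HIDDEN_WIDTH})+exp",
                 f"dense({self.catalog_size})+linear"]
        return spec

    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return x.astype(np.float32)
        return ((x - self.x_mean) / self.x_scale).astype(np.float32)

    def _forward(
        self, x: np.ndarray, rng: Optional[np.random.Generator] = None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; a generator enables (inverted) dropout for training.

        Returns the raw output and the per-layer cache for backprop.
        """
        cache = []
        a = x
        for i in range(HIDDEN_LAYERS):
            z = a @ self.weights[i] + self.biases[i]
            out = np.maximum(z, 0.0)
            cache.append((a, z))
            a = out
        if rng is not None and self.dropout_rate > 0:
            mask = (
                rng.random(a.shape) >= self.dropout_rate
            ).astype(np.float32) / (1.0 - self.dropout_rate)
        else:
            mask = None
        cache.append(mask)
        if mask is not None:
            a = a * mask
        z = a @ self.weights[HIDDEN_LAYERS] + self.biases[HIDDEN_LAYERS]
        e = np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))
        cache.append((a, z))
        a = e
        out = a @ self.weights[HIDDEN_LAYERS + 1] + self.biases[HIDDEN_LAYERS + 1]
        cache.append((a, None))
        return out, cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass on already-scaled input."""
        out, _ = self._forward(x.astype(np.float32), rng=None)
        return out


def build_model(
    catalog_size: int,
    input_size: int,
    seed: int = 0,
    dropout_rate: float = 0.2,
) -> FragmentNet:
    """Untrained network with seeded He-style initialization.

    The exponential layer is initialized at a smaller scale so its
    activations start near exp(0) = 1 instead of saturating.
    """
    if catalog_size <= 0 or input_size <= 0:
        raise ValueError("catalog_size and input_size must be positive")
    rng = np.random.default_rng(seed)
    sizes = [input_size] + [HIDDEN_WIDTH] * HIDDEN_LAYERS + [HIDDEN_WIDTH, catalog_size]
    weights, biases = [], []
    for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / n_in)
        if i == HIDDEN_LAYERS:  # pre-exponential layer: keep exp(z) ~ 1
            scale *= 0.1
        weights.append((rng.normal(0, scale, (n_in, n_out))).astype(np.float32))
        biases.append(np.zeros(n_out, dtype=np.float32))
    return FragmentNet(
        weights=weights,
        biases=biases,
        dropout_rate=dropout_rate,
        catalog_size=catalog_size,
        input_size=input_size,
    )


# ---------------------------------------------------------------------------
# training (Adamax on MAE)
# ---------------------------------------------------------------------------

@dataclass
class TrainReport:
    """Cross-validation record: per-fold, per-fragment held-out metrics."""

    fold_metrics: list[pd.DataFrame]  # columns: fragment, r2, mae
    n_train: int
    n_test: int
    epochs: int
    seed: int
    folds: int
    test_fraction: float
    loss_history: list[float] = field(default_factory=list)  # returned model

    def mean_test_mae(self) -> pd.Series:
        """Per-fragment MAE averaged over folds."""
        return (
            pd.concat(self.fold_metrics).groupby("fragment", sort=False)["mae"].mean()
        )

    def mean_test_r2(self) -> pd.Series:
        return (
            pd.concat(self.fold_metrics).groupby("fragment", sort=False)["r2"].mean()
        )


class _Adamax:
    """Adamax: Adam variant with an infinity-norm second moment."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc = 1.0 - self.b1**self.t
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m *= self.b1
            m += (1 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p -= (self.lr / bc) * m / (u + self.eps)


def _backward(net: FragmentNet, cache: list, d_out: np.ndarray) -> tuple[list, list]:
    """Gradients of the loss w.r.t. weights and biases."""
    grads_w = [None] * net.n_layers
    grads_b = [None] * net.n_layers
    # output layer (linear)
    a_exp, _ = cache[-1]
    grads_w[-1] = a_exp.T @ d_out
    grads_b[-1] = d_out.sum(axis=0)
    da = d_out @ net.weights[-1].T
    # exponential layer: d/dz exp(z) = exp(z) = a_exp
    a_in, z = cache[-2]
    dz = da * a_exp * (np.abs(z) < _EXP_CLIP)  # zero gradient where clipped
    grads_w[-2] = a_in.T @ dz
    grads_b[-2] = dz.sum(axis=0)
    da = dz @ net.weights[-2].T
    # dropout mask
    mask = cache[HIDDEN_LAYERS]
    if mask is not None:
        da = da * mask
    # ReLU stack
    for i in range(HIDDEN_LAYERS - 1, -1, -1):
        a_in, z = cache[i]
        dz = da * (z > 0)
        grads_w[i] = a_in.T @ dz
        grads_b[i] = dz.sum(axis=0)
        if i > 0:
            da = dz @ net.weights[i].T
    return grads_w, grads_b


def fit(
    net: FragmentNet,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int = 200,
    batch_size: int = 512,
    lr: float = 0.001,
    seed: int = 0,
    scale_inputs: bool = True,
) -> list[float]:
    """Train in place by minibatch Adamax on the mean absolute error.

    Input columns are z-scored with training-set statistics stored on
    the model (constant columns get unit scale). Returns the per-epoch
    training-loss history (MAE on the training set, evaluated without
    dropout at the end of each epoch).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float32)
    if x.shape[1] != net.input_size or y.shape[1] != net.catalog_size:
        raise ValueError("input/target width does not match the model")
    if scale_inputs:
        net.x_mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        net.x_scale = sd
    xs = net._scale(x)
    rng = np.random.default_rng(seed)
    params = net.weights + net.biases
    opt = _Adamax(params, lr=lr)
    n = len(xs)
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = xs[idx], y[idx]
            out, cache = net._forward(xb, rng=rng)
            resid = out - yb
            d_out = np.sign(resid).astype(np.float32) / resid.size
            gw, gb = _backward(net, cache, d_out)
            opt.step(params, gw + gb)
        train_loss = float(np.mean(np.abs(net.forward(xs) - y)))
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}: {train_loss}; "
                "inputs or learning rate likely ill-conditioned"
            )
        history.append(train_loss)
    return history


def predict(net: FragmentNet, x: np.ndarray) -> np.ndarray:
    """Predicted substructure counts: non-negative decimals, unrounded."""
    x = np.asarray(x, dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError(
            "inputs contain NaN (missing fingerprint entries?); run "
            "read-across imputation before predicting"
        )
    if x.ndim == 1:
        x = x[None, :]
    out = net.forward(net._scale(x))
    return np.maximum(out.astype(np.float64), 0.0)


def _per_fragment_metrics(
    pred: np.ndarray, true: np.ndarray, catalog: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for j, frag in enumerate(catalog):
        t, p = true[:, j], pred[:, j]
        mae = float(np.mean(np.abs(p - t)))
        if t.std() == 0 or p.std() == 0:
            r2 = float("nan")
        else:
            r2 = float(stats.pearsonr(t, p)[0] ** 2)
        rows.append({"fragment": frag, "r2": r2, "mae": mae})
    return pd.DataFrame(rows)


def train(
    x: np.ndarray,
    y: np.ndarray,
    catalog: Sequence[str],
    epochs: int = 200,
    seed: int = 0,
    folds: int = 5,
    test_fraction: float = 0.2,
    dropout_rate: float = 0.2,
    batch_size: int = 512,
    lr: float = 0.001,
) -> tuple[FragmentNet, TrainReport]:
    """Train with the 80/20 shuffle-split 5-fold cross-validation protocol.

    Each fold trains a fresh network on its 80% portion and reports
    per-fragment Pearson R^2 and MAE on its 20% held-out portion. The
    returned model is the first fold's network (so the fold-0 metrics
    are honest held-out numbers for it).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 50:
        raise ValueError(f"need >= 50 training examples, got {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("training data contain NaN; impute fingerprints first")
    splitter = ShuffleSplit(
        n_splits=folds, test_size=test_fraction, random_state=seed
    )
    fold_metrics: list[pd.DataFrame] = []
    first_model: Optional[FragmentNet] = None
    first_history: list[float] = []
    n_train = n_test = 0
    for k, (tr, te) in enumerate(splitter.split(x)):
        net = build_model(
            catalog_size=y.shape[1], input_size=x.shape[1],
            seed=seed + k, dropout_rate=dropout_rate,
        )
        history = fit(
            net, x[tr], y[tr], epochs=epochs, batch_size=batch_size,
            lr=lr, seed=seed + k,
        )
        pred = predict(net, x[te])
        fold_metrics.append(_per_fragment_metrics(pred, y[te], catalog))
        log.info(
            "fold %d/%d: test MAE %.4f", k + 1, folds,
            float(np.mean(np.abs(pred - y[te]))),
        )
        if k == 0:
            first_model, first_history = net, history
            n_train, n_test = len(tr), len(te)
    report = TrainReport(
        fold_metrics=fold_metrics,
        n_train=n_train,
        n_test=n_test,
        epochs=epochs,
        seed=seed,
        folds=folds,
        test_fraction=test_fraction,
        loss_history=first_history,
    )
    assert first_model is not None
    return first_model, report


def evaluate_fragments(
    pred: np.ndarray, true: np.ndarray
) -> dict[str, float]:
    """Pearson R^2 and MAE between one predicted and one true fragment
    vector, computed over the fragment axis on unrounded decimals.

    R^2 is undefined (NaN) when either vector has zero variance; the MAE
    is still returned.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("fragment vectors must share the catalog")
    mae = float(np.mean(np.abs(pred - true)))
    if pred.std() == 0 or true.std() == 0:
        return {"r2": float("nan"), "mae": mae}
    r = stats.pearsonr(true, pred)[0]
    return {"r2": float(r**2), "mae": mae}


# ---------------------------------------------------------------------------
# persistence: weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(
    net: FragmentNet,
    path: str | Path,
    catalog: Sequence[str],
    training_config: Optional[dict] = None,
) -> None:
    """Save to a directory: npz weights plus a JSON sidecar holding the
    catalog, element alphabet, input-scaling statistics and training
    config."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays |= {f"b{i}": b for i, b in enumerate(net.biases)}
    np.savez(path / "weights.npz", **arrays)
    sidecar = {
        "catalog": list(catalog),
        "element_alphabet": list(ELEMENT_ALPHABET),
        "input_size": net.input_size,
        "catalog_size": net.catalog_size,
        "dropout_rate": net.dropout_rate,
        "x_mean": None if net.x_mean is None else net.x_mean.tolist(),
        "x_scale": None if net.x_scale is None else net.x_scale.tolist(),
        "training_config": training_config or {},
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> tuple[FragmentNet, list[str]]:
    path = Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    with np.load(path / "weights.npz") as z:
        n = len([k for k in z.files if k.startswith("w")])
        weights = [z[f"w{i}"] for i in range(n)]
        biases = [z[f"b{i}"] for i in range(n)]
    net = FragmentNet(
        weights=weights,
        biases=biases,
        dropout_rate=sidecar["dropout_rate"],
        catalog_size=sidecar["catalog_size"],
        input_size=sidecar["input_size"],
        x_mean=None if sidecar["x_mean"] is None else np.asarray(sidecar["x_mean"]),
        x_scale=None if sidecar["x_scale"] is None else np.asarray(sidecar["x_scale"]),
    )
    return net, sidecar["catalog"]
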