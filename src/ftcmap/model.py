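"""Feedforward tree-cover regressor and post-processing masks.

The regressor maps the twelve phase x band predictors to percent tree cover
with a fully connected network of five hidden ReLU layers (400, 200, 100,
50, 25 neurons) and a linear output. Training uses mean-squared error with
Adam (learning rate 1e-3, batches of 1024, at most 100 epochs) and early
stopping on a 10% validation split; features and the target are z-scored
from the training data. Predictions are clipped to [0, 100].

scikit-learn's MLPRegressor performs the optimisation; predictions are
served by this module's own forward pass on the extracted weights so a
saved model (plain ``.npz``) reproduces predictions bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

#: annual-maximum-NDVI threshold below which pixels are set to 0% tree cover
NDVI_POSTMASK = 0.35
MIN_TRAINING_ROWS = 100

DEFAULT_HIDDEN = (400, 200, 100, 50, 25)

__all__ = [
    "NDVI_POSTMASK",
    "NetworkSpec",
    "TrainedModel",
    "build_network",
    "train",
    "predict",
    "postprocess",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the regressor; hidden widths default to the full network."""

    input_width: int = 12
    hidden_widths: tuple[int, ...] = DEFAULT_HIDDEN
    output_width: int = 1

    def __post_init__(self) -> None:
        if self.input_width < 1 or self.output_width < 1 or not self.hidden_widths:
            raise ValueError("all layer widths must be >= 1")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("all hidden widths must be >= 1")


@dataclass
class Hyper:
    """Training recipe (MSE/Adam defaults)."""

    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 5
    validation_fraction: float = 0.1
    l2: float = 0.0


@dataclass
class TrainedModel:
    """Weights, standardisation parameters and training history of a fitted network."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    seed: int
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    def forward(self, x_std: np.ndarray) -> np.ndarray:
        """Raw (unclipped, unstandardised-output) forward pass on z-scored features."""
        a = x_std
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i < last:
                np.maximum(a, 0.0, out=a)
        return self.y_mean + self.y_sd * a[:, 0]


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> MLPRegressor:
    """Configured (untrained) optimiser for the given architecture.

    Weight matrices are initialised inside the first call to ``fit`` using
    ``seed``, giving shapes (input, h1), (h1, h2), ..., (h_last, 1).
    """
    spec = spec or NetworkSpec()
    return MLPRegressor(
        hidden_layer_sizes=spec.hidden_widths,
        activation="relu",
        solver="adam",
        alpha=Hyper().l2,
        batch_size=Hyper().batch_size,
        learning_rate_init=Hyper().learning_rate,
        max_iter=Hyper().max_epochs,
        shuffle=True,
        random_state=seed,
        early_stopping=True,
        validation_fraction=Hyper().validation_fraction,
        n_iter_no_change=Hyper().patience,
        tol=1e-6,
    )


def train(
    features: np.ndarray,
    targets: np.ndarray,
    spec: NetworkSpec | None = None,
    hyper: Hyper | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the regressor on (features, target %) rows; reproducible under seed.

    Refuses fewer than 100 rows (generate synthetic scenes for more data).
    """
    spec = spec or NetworkSpec()
    hyper = hyper or Hyper()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_width:
        raise ValueError(f"features must be (n, {spec.input_width})")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets row counts differ")
    if X.shape[0] < MIN_TRAINING_ROWS:
        raise ValueError(
            f"need at least {MIN_TRAINING_ROWS} training rows, got {X.shape[0]}; "
            "consider generating synthetic scenes for more data"
        )
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0

    mlp = build_network(spec, seed=seed)
    mlp.set_params(
        alpha=hyper.l2,
        batch_size=min(hyper.batch_size, X.shape[0]),
        learning_rate_init=hyper.learning_rate,
        max_iter=hyper.max_epochs,
        validation_fraction=hyper.validation_fraction,
        n_iter_no_change=hyper.patience,
    )
    mlp.fit((X - x_mean) / x_sd, (y - y_mean) / y_sd)

    return TrainedModel(
        spec=spec,
        weights=[w.astype(float) for w in mlp.coefs_],
        biases=[b.astype(float) for b in mlp.intercepts_],
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        seed=seed,
        loss_curve=np.asarray(mlp.loss_curve_, dtype=float),
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Tree cover (%) clipped to [0, 100]; rows with non-finite features give NaN."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.spec.input_width:
        raise ValueError(f"features must have {model.spec.input_width} columns")
    out = np.full(X.shape[0], np.nan)
    ok = np.isfinite(X).all(axis=1)
    if ok.any():
        raw = model.forward((X[ok] - model.x_mean) / model.x_sd)
        out[ok] = np.clip(raw, 0.0, 100.0)
    return out


def postprocess(
    cover: np.ndarray,
    max_ndvi: np.ndarray,
    landcover: np.ndarray | None = None,
) -> np.ndarray:
    """Final cover grid: sparse-greenness pixels zeroed, water/ice to nodata.

    Pixels whose annual maximum NDVI is strictly below 0.35 cannot sustain
    tree cover and are set to 0%; water and permanent snow/ice become NaN
    (nodata). All other pixels pass through unchanged.
    """
    from .refdata import LC_SNOW_ICE, LC_WATER

    cover = np.asarray(cover, dtype=float)
    max_ndvi = np.asarray(max_ndvi, dtype=float)
    if cover.shape != max_ndvi.shape:
        raise ValueError("cover and max_ndvi grids must be conformable")
    out = cover.copy()
    out[max_ndvi < NDVI_POSTMASK] = 0.0
    if landcover is not None:
        out[np.isin(np.asarray(landcover), [LC_WATER, LC_SNOW_ICE])] = np.nan
    return out


def save_model(model: TrainedModel, path) -> None:
    """Serialise to a plain npz archive (architecture, standardisation, weights)."""
    arrays = {
        "hidden_widths": np.asarray(model.spec.hidden_widths, dtype=int),
        "input_width": np.asarray(model.spec.input_width),
        "x_mean": model.x_mean,
        "x_sd": model.x_sd,
        "y_mean": np.asarray(model.y_mean),
        "y_sd": np.asarray(model.y_sd),
        "seed": np.asarray(model.seed),
        "loss_curve": model.loss_curve,
    }
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; predictions round-trip bit-exactly."""
    with np.load(path) as z:
        spec = NetworkSpec(
            input_width=int(z["input_width"]),
            hidden_widths=tuple(int(w) for w in z["hidden_widths"]),
        )
        n_layers = len(spec.hidden_widths) + 1
        return TrainedModel(
            spec=spec,
            weights=[z[f"w{i}"] for i in range(n_layers)],
            biases=[z[f"b{i}"] for i in range(n_layers)],
            x_mean=z["x_mean"],
            x_sd=z["x_sd"],
            y_mean=float(z["y_mean"]),
            y_sd=float(z["y_sd"]),
            seed=int(z["seed"]),
            loss_curve=z["loss_curve"],
        )
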