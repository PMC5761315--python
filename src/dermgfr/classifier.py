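"""Feed-forward CKD-level classifiers.

Two small fully connected networks map subject records to a 5-way one-hot
CKD level. Network 1 takes five inputs (age, gender, height, weight, serum
creatinine); network 2 takes seven (age, gender, height, weight, the skin
parameter Sp, the mean of the texture features, and entropy) and uses no
creatinine at all — the point being that the texture-derived inputs carry
enough renal information to classify nearly as well as the invasive one.

Both architectures have one hidden layer of five logistic-sigmoid units and
a linear five-unit output:

    y_j = σ(Σ_i x_i W_ij + b_j)         (hidden)
    o_k = Σ_j y_j W_jk + B_k            (output, linear)

Training is full-batch gradient descent on the mean squared error of the
linear outputs against one-hot targets, with z-scored inputs (raw heights
~160 and creatinine ~1–10 differ by two orders of magnitude and would
saturate the sigmoids otherwise) and Xavier-uniform initialization from a
seeded generator. Decoding is argmax, ties broken toward the lower level.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import ValidationError
from .synthetic_data import SubjectRecord

__all__ = [
    "NetworkSpec",
    "TrainedNetwork",
    "ConfusionSummary",
    "NETWORK1_INPUTS",
    "NETWORK2_INPUTS",
    "record_inputs",
    "forward",
    "decode",
    "train",
    "evaluate",
    "save_network",
    "load_network",
]

#: network 1 feature columns: demographics plus serum creatinine.
NETWORK1_INPUTS: tuple[str, ...] = ("age", "gender", "height_cm", "weight_kg", "scr_mg_dl")
#: network 2 feature columns: demographics plus texture-derived values,
#: no creatinine. The seventh input (entropy) is config-selectable.
NETWORK2_INPUTS: tuple[str, ...] = (
    "age", "gender", "height_cm", "weight_kg", "sp", "mean_features", "entropy",
)

N_LEVELS = 5


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes and the fixed activation contract (sigmoid hidden,
    linear output)."""

    n_inputs: int
    n_hidden: int = 5
    n_outputs: int = N_LEVELS

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValidationError("layer sizes must be positive")


@dataclasses.dataclass(frozen=True)
class TrainedNetwork:
    """Weights, biases and the per-feature z-score scaler fitted on the
    training data."""

    spec: NetworkSpec
    w_ih: np.ndarray       # (n_inputs, n_hidden)
    b_h: np.ndarray        # (n_hidden,)
    w_ho: np.ndarray       # (n_hidden, n_outputs)
    b_o: np.ndarray        # (n_outputs,)
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    input_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = self.spec
        expected = {
            "w_ih": (s.n_inputs, s.n_hidden),
            "b_h": (s.n_hidden,),
            "w_ho": (s.n_hidden, s.n_outputs),
            "b_o": (s.n_outputs,),
            "scaler_mean": (s.n_inputs,),
            "scaler_sd": (s.n_inputs,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite parameters")
            object.__setattr__(self, name, arr)


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Binary (normal vs any CKD) confusion of a test set, as percentages
    of the test-set size. The four entries sum to 100 up to rounding."""

    true_positive_pct: float
    true_negative_pct: float
    false_positive_pct: float
    false_negative_pct: float
    n_test: int

    @property
    def accuracy_pct(self) -> float:
        return self.true_positive_pct + self.true_negative_pct


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def record_inputs(
    records: Sequence[SubjectRecord],
    input_names: Sequence[str],
    log_scr: bool = True,
) -> np.ndarray:
    """Stack the named per-record fields into a (n, d) design matrix.

    ``entropy`` is read from the record's texture features; everything else
    is a direct record attribute. Serum creatinine is log-transformed by
    default: it is roughly log-normal across CKD stages (values span
    ~0.5–25 mg/dl) and GFR is a power law in it, so the log makes the stage
    boundaries nearly linear and keeps the z-scored axis from being
    dominated by the end-stage tail.
    """
    rows = []
    for rec in records:
        row = []
        for name in input_names:
            if name == "entropy":
                if rec.features is None:
                    raise ValidationError(f"record {rec.subject_id} has no texture features")
                row.append(rec.features.entropy)
            else:
                val = getattr(rec, name)
                if val is None:
                    raise ValidationError(f"record {rec.subject_id} missing input {name!r}")
                val = float(val)
                if name == "scr_mg_dl" and log_scr:
                    if val <= 0:
                        raise ValidationError(
                            f"record {rec.subject_id}: creatinine must be positive"
                        )
                    val = float(np.log(val))
                row.append(val)
        rows.append(row)
    return np.asarray(rows, dtype=float)


def forward(net: TrainedNetwork, x: np.ndarray) -> np.ndarray:
    """Score vector(s) for one input vector or a batch of rows.

    Applies the stored z-score scaler, then the sigmoid hidden layer and
    linear output layer. Deterministic.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if xb.shape[1] != net.spec.n_inputs:
        raise ValidationError(
            f"input length {xb.shape[1]} != n_inputs {net.spec.n_inputs}"
        )
    z = (xb - net.scaler_mean) / net.scaler_sd
    hidden = _sigmoid(z @ net.w_ih + net.b_h)
    out = hidden @ net.w_ho + net.b_o
    return out[0] if single else out


def decode(outputs: np.ndarray) -> int:
    """One-hot decode a 5-score vector to a CKD level 1–5 (argmax + 1;
    ties go to the lower level with a warning)."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (N_LEVELS,):
        raise ValidationError(f"expected {N_LEVELS} scores, got shape {outputs.shape}")
    if not np.all(np.isfinite(outputs)):
        raise ValidationError("non-finite network output")
    top = outputs.max()
    if (outputs == top).sum() > 1:
        warnings.warn("tied network outputs; decoding to the lower level", stacklevel=2)
    return int(np.argmax(outputs)) + 1


def _one_hot(levels: Sequence[int]) -> np.ndarray:
    t = np.zeros((len(levels), N_LEVELS))
    for i, lv in enumerate(levels):
        if lv not in range(1, 6):
            raise ValidationError(f"level {lv} outside 1..5")
        t[i, lv - 1] = 1.0
    return t


def train(
    spec: NetworkSpec,
    x: np.ndarray,
    levels: Sequence[int],
    seed: int = 0,
    epochs: int = 10000,
    learning_rate: float = 0.5,
    input_names: Sequence[str] = (),
) -> TrainedNetwork:
    """Fit a network by full-batch gradient descent on one-hot MSE.

    Inputs are z-scored by training statistics (constant columns get unit
    scale); weights start Xavier-uniform from a seeded generator, so the
    result is a deterministic function of (data, seed).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != spec.n_inputs:
        raise ValidationError(f"design matrix shape {x.shape} != (n, {spec.n_inputs})")
    levels = list(levels)
    if len(set(levels)) < 2:
        raise ValidationError("training data must contain at least two distinct levels")
    targets = _one_hot(levels)
    n = x.shape[0]

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    z = (x - mean) / sd

    rng = np.random.default_rng(seed)
    lim_ih = np.sqrt(6.0 / (spec.n_inputs + spec.n_hidden))
    lim_ho = np.sqrt(6.0 / (spec.n_hidden + spec.n_outputs))
    w_ih = rng.uniform(-lim_ih, lim_ih, (spec.n_inputs, spec.n_hidden))
    w_ho = rng.uniform(-lim_ho, lim_ho, (spec.n_hidden, spec.n_outputs))
    b_h = np.zeros(spec.n_hidden)
    b_o = np.zeros(spec.n_outputs)

    for _ in range(epochs):
        hidden = _sigmoid(z @ w_ih + b_h)
        out = hidden @ w_ho + b_o
        # d(MSE)/d(out), MSE averaged over samples and output units
        d_out = 2.0 * (out - targets) / (n * spec.n_outputs)
        d_hidden = (d_out @ w_ho.T) * hidden * (1.0 - hidden)
        w_ho -= learning_rate * hidden.T @ d_out
        b_o -= learning_rate * d_out.sum(axis=0)
        w_ih -= learning_rate * z.T @ d_hidden
        b_h -= learning_rate * d_hidden.sum(axis=0)

    return TrainedNetwork(
        spec=spec, w_ih=w_ih, b_h=b_h, w_ho=w_ho, b_o=b_o,
        scaler_mean=mean, scaler_sd=sd, input_names=tuple(input_names),
    )


def training_loss(net: TrainedNetwork, x: np.ndarray, levels: Sequence[int]) -> float:
    """Mean squared error of the linear outputs against one-hot targets."""
    out = forward(net, np.asarray(x, dtype=float))
    return float(np.mean((out - _one_hot(list(levels))) ** 2))


def confusion_from_predictions(
    pred_levels: Sequence[int],
    true_levels: Sequence[int],
) -> ConfusionSummary:
    """Binary confusion of predicted vs true CKD levels.

    Positive = CKD (level 2–5), negative = normal (level 1): a CKD subject
    predicted at any CKD level counts as a true positive even if the exact
    stage is off.
    """
    pred_levels, true_levels = list(pred_levels), list(true_levels)
    if not true_levels:
        raise ValidationError("empty test set")
    if len(pred_levels) != len(true_levels):
        raise ValidationError("predictions and labels disagree in length")
    tp = tn = fp = fn = 0
    for pred, true in zip(pred_levels, true_levels):
        pred_ckd, true_ckd = pred > 1, true > 1
        if true_ckd and pred_ckd:
            tp += 1
        elif not true_ckd and not pred_ckd:
            tn += 1
        elif not true_ckd and pred_ckd:
            fp += 1
        else:
            fn += 1
    pct = 100.0 / len(true_levels)
    return ConfusionSummary(
        true_positive_pct=tp * pct,
        true_negative_pct=tn * pct,
        false_positive_pct=fp * pct,
        false_negative_pct=fn * pct,
        n_test=len(true_levels),
    )


def evaluate(
    net: TrainedNetwork,
    x_test: np.ndarray,
    true_levels: Sequence[int],
) -> ConfusionSummary:
    """Binary (normal vs any CKD) confusion summary of a network on a
    test set."""
    x_test = np.atleast_2d(np.asarray(x_test, dtype=float))
    if x_test.shape[0] == 0:
        raise ValidationError("empty test set")
    if x_test.shape[0] != len(list(true_levels)):
        raise ValidationError("test inputs and labels disagree in length")
    preds = [decode(row) for row in forward(net, x_test)]
    return confusion_from_predictions(preds, true_levels)


def save_network(net: TrainedNetwork, path: str | Path) -> None:
    """Persist a trained network (shapes, arrays, scaler) as JSON."""
    doc = {
        "spec": dataclasses.asdict(net.spec),
        "w_ih": net.w_ih.tolist(),
        "b_h": net.b_h.tolist(),
        "w_ho": net.w_ho.tolist(),
        "b_o": net.b_o.tolist(),
        "scaler_mean": net.scaler_mean.tolist(),
        "scaler_sd": net.scaler_sd.tolist(),
        "input_names": list(net.input_names),
    }
    Path(path).write_text(json.dumps(doc))


def load_network(path: str | Path) -> TrainedNetwork:
    doc = json.loads(Path(path).read_text())
    return TrainedNetwork(
        spec=NetworkSpec(**doc["spec"]),
        w_ih=np.asarray(doc["w_ih"]),
        b_h=np.asarray(doc["b_h"]),
        w_ho=np.asarray(doc["w_ho"]),
        b_o=np.asarray(doc["b_o"]),
        scaler_mean=np.asarray(doc["scaler_mean"]),
        scaler_sd=np.asarray(doc["scaler_sd"]),
        input_names=tuple(doc["input_names"]),
    )
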