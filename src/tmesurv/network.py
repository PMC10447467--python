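"""Multi-task imaging network: TME classification + survival risk from CT.

The model consumes a normalized 5-slice stack centered on the tumor and
produces two coupled outputs:

* ``probs`` — probabilities of the four TME classes (immune/stroma quadrants);
* ``risk``  — a scalar log-hazard, the deep-learning survival score (DLS);
  higher means worse predicted outcome.

Architecture: a shared convolutional backbone embeds each slice into a
d-dimensional feature; two fully connected layers with leaky-ReLU refine the
per-slice features f; a gated-attention module

    A = softmax( w3 ( tanh(w1 f + b1) * sigmoid(w2 f + b2) ) + b3 )

(softmax across the 5 slices, one row per task) pools them into M = A f with
one pooled feature per task. Row 0 of M feeds the TME classification head;
row 1, concatenated with the predicted class probabilities (the biology ->
outcome cascade), feeds the survival head.

Training minimizes the unweighted sum of the mean categorical cross-entropy
over TME classes and the negative Cox log partial likelihood over the batch
(Breslow convention for ties), mirroring how the hazard model is used
downstream.

Two backbones are provided: ``"resnet18"`` — the reference residual
topology whose per-slice feature has the canonical size 256 — and
``"tiny"`` — a 3-conv-block CPU-scale backbone (d = 64) used throughout the
test suite and synthetic experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat

__all__ = [
    "NetworkConfig",
    "MultiTaskNet",
    "loss_tme",
    "loss_cox",
    "total_loss",
    "train",
    "predict",
    "TrainHistory",
]


@dataclass
class NetworkConfig:
    backbone: str = "tiny"                # "resnet18" | "tiny"
    n_slices: int = 5
    input_size: int = 160
    n_tasks: int = 2
    n_classes: int = 4
    leaky_relu_slope: float = 0.01
    seed: int = 0
    learning_rate: float = 1e-3           # reference training recipe uses 1e-5
    batch_size: int = 16
    max_epochs: int = 100
    min_epochs: int = 5
    plateau_tol: float = 1e-4             # relative loss improvement for early stop
    plateau_patience: int = 10
    detach_cascade: bool = False          # block gradients through probs -> risk
    loss_weight_tme: float = 1.0          # Eq-style total loss is the plain sum
    loss_weight_cox: float = 1.0

    @property
    def feature_dim(self) -> int:
        return 256 if self.backbone == "resnet18" else 64


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class Conv2d:
    """3x3-style convolution via im2col; weight layout (Cin*k*k, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        patches = x.pad2d(self.padding).im2col(self.kernel, self.stride)
        _, _, oh, ow, _, _ = patches.shape
        cols = patches.transpose((0, 2, 3, 1, 4, 5)).reshape(b, oh, ow, -1)
        out = cols @ self.w + self.b            # (B, OH, OW, Cout)
        return out.transpose((0, 3, 1, 2))

    def params(self):
        return [self.w, self.b]


class ChannelNorm:
    """Frozen-statistics batch norm: per-channel standardize + learned affine.

    Running statistics are buffers (identity by default); only gamma/beta
    train. Keeps the residual topology faithful without train-time batch
    statistics, which matter little at the cohort sizes used here.
    """

    def __init__(self, channels: int):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        mean = Tensor(self.running_mean.reshape(shape))
        inv = Tensor((1.0 / np.sqrt(self.running_var + 1e-5)).reshape(shape))
        return (x - mean) * inv * self.gamma.reshape(*shape) + self.beta.reshape(*shape)

    def params(self):
        return [self.gamma, self.beta]


def _relu(x: Tensor) -> Tensor:
    return x.leaky_relu(0.0)


def _max_pool(x: Tensor, kernel: int, stride: int, padding: int) -> Tensor:
    b, c, _, _ = x.shape
    patches = x.pad2d(padding).im2col(kernel, stride)
    _, _, oh, ow, _, _ = patches.shape
    return patches.reshape(b, c, oh, ow, kernel * kernel).max_last()


def _avg_pool(x: Tensor, k: int) -> Tensor:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // k, k, w // k, k).mean(axis=5).mean(axis=3)


def _global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=3).mean(axis=2)


class BasicBlock:
    """Two 3x3 convolutions with identity (or projection) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.n1 = ChannelNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.n2 = ChannelNorm(c_out)
        if stride != 1 or c_in != c_out:
            self.proj: Conv2d | None = Conv2d(c_in, c_out, 1, stride, 0, rng)
            self.nproj: ChannelNorm | None = ChannelNorm(c_out)
        else:
            self.proj = None
            self.nproj = None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.n2(self.conv2(_relu(self.n1(self.conv1(x)))))
        shortcut = x if self.proj is None else self.nproj(self.proj(x))
        return _relu(out + shortcut)

    def params(self):
        p = self.conv1.params() + self.n1.params() + self.conv2.params() + self.n2.params()
        if self.proj is not None:
            p += self.proj.params() + self.nproj.params()
        return p


class ResNet18Backbone:
    """Reference backbone: 18-layer residual topology, per-slice feature 256.

    Stem 7x7/2 + max-pool, four stages of two basic blocks (64/128/256/512
    channels), global average pooling, then a linear projection of the
    512-dim embedding to the canonical 256-dim per-slice feature.
    """

    out_dim = 256

    def __init__(self, rng: np.random.Generator):
        self.stem = Conv2d(1, 64, 7, 2, 3, rng)
        self.stem_norm = ChannelNorm(64)
        widths = [64, 128, 256, 512]
        self.blocks: list[BasicBlock] = []
        c_in = 64
        for stage, c_out in enumerate(widths):
            for i in range(2):
                stride = 2 if (stage > 0 and i == 0) else 1
                self.blocks.append(BasicBlock(c_in, c_out, stride, rng))
                c_in = c_out
        self.project = Linear(512, self.out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        out = _max_pool(_relu(self.stem_norm(self.stem(x))), 3, 2, 1)
        for block in self.blocks:
            out = block(out)
        return self.project(_global_avg_pool(out))

    def params(self):
        p = self.stem.params() + self.stem_norm.params()
        for block in self.blocks:
            p += block.params()
        return p + self.project.params()


class TinyBackbone:
    """CPU-scale backbone: tumor-core crop then three strided conv blocks.

    The slice stacks are centroid-centered on the tumor, so the central
    ``core`` x ``core`` window lies inside the lesion for any admissible
    phantom; restricting the receptive field to it reads intra-tumor
    texture without dilution by background or tumor-size variation.
    Rectified conv responses pooled over the core make texture amplitude
    (the class-ordered heterogeneity signal) linearly readable. d = 64.
    """

    out_dim = 64
    core = 24

    def __init__(self, rng: np.random.Generator, slope: float = 0.01):
        self.slope = slope
        self.conv1 = Conv2d(1, 8, 3, 2, 1, rng)
        self.conv2 = Conv2d(8, 16, 3, 2, 1, rng)
        self.conv3 = Conv2d(16, 32, 3, 2, 1, rng)
        self.fc = Linear(32, self.out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if h > self.core and w > self.core:
            y0, x0 = (h - self.core) // 2, (w - self.core) // 2
            x = x[:, :, y0:y0 + self.core, x0:x0 + self.core]
        # fixed affine standardization: soft tissue sits around 0.75 on the
        # [0, 1] window scale; rescaling keeps first-layer activations O(1)
        x = (x - 0.75) * 8.0
        out = self.conv1(x).leaky_relu(self.slope)
        out = self.conv2(out).leaky_relu(self.slope)
        out = self.conv3(out).leaky_relu(self.slope)
        return self.fc(_global_avg_pool(out))

    def params(self):
        return (self.conv1.params() + self.conv2.params()
                + self.conv3.params() + self.fc.params())


# ---------------------------------------------------------------------------
# the multi-task model
# ---------------------------------------------------------------------------

class MultiTaskNet:
    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.backbone == "resnet18":
            self.backbone = ResNet18Backbone(rng)
        elif config.backbone == "tiny":
            self.backbone = TinyBackbone(rng, config.leaky_relu_slope)
        else:
            raise ValueError(f"unknown backbone {config.backbone!r}")
        d = self.backbone.out_dim
        self.refine1 = Linear(d, d, rng)
        self.refine2 = Linear(d, d, rng)
        # gated attention: tanh and sigmoid gates, then an N-output projection
        self.att_v = Linear(d, d, rng)        # (w1, b1)
        self.att_u = Linear(d, d, rng)        # (w2, b2)
        self.att_w = Linear(d, config.n_tasks, rng)  # (w3, b3)
        self.cls_head = Linear(d, config.n_classes, rng)
        self.surv1 = Linear(d + config.n_classes, 32, rng)
        self.surv2 = Linear(32, 1, rng)

    # -- pieces (exposed for inspection and unit testing) ------------------
    def backbone_forward(self, stacks: Tensor) -> Tensor:
        """(B, n_slices, H, W) -> raw per-slice features (B, n_slices, d)."""
        b, s, h, w = stacks.shape
        if s != self.config.n_slices:
            raise ValueError(f"expected {self.config.n_slices} slices, got {s}")
        flat = stacks.reshape(b * s, 1, h, w)
        return self.backbone(flat).reshape(b, s, -1)

    def refine_features(self, raw: Tensor) -> Tensor:
        slope = self.config.leaky_relu_slope
        return self.refine2(self.refine1(raw).leaky_relu(slope)).leaky_relu(slope)

    def attention_pool(self, f: Tensor) -> tuple[Tensor, Tensor]:
        """Gated attention over slices: returns (A, M).

        A has shape (B, n_tasks, n_slices) with rows summing to 1;
        M = A f has shape (B, n_tasks, d).
        """
        gate = self.att_v(f).tanh() * self.att_u(f).sigmoid()
        logits = self.att_w(gate)                       # (B, S, N)
        a = logits.softmax(axis=1).transpose((0, 2, 1))  # (B, N, S)
        b, n, s = a.shape
        d = f.shape[-1]
        m = (a.reshape(b, n, s, 1) * f.reshape(b, 1, s, d)).sum(axis=2)
        return a, m

    def tme_head(self, m_row0: Tensor) -> Tensor:
        return self.cls_head(m_row0).softmax(axis=-1)

    def survival_head(self, m_row1: Tensor, probs: Tensor) -> Tensor:
        z = concat([m_row1, probs], axis=-1)
        h = self.surv1(z).leaky_relu(self.config.leaky_relu_slope)
        return self.surv2(h).reshape(m_row1.shape[0])

    def forward(self, stacks: Tensor) -> dict[str, Tensor]:
        raw = self.backbone_forward(stacks)
        f = self.refine_features(raw)
        a, m = self.attention_pool(f)
        probs = self.tme_head(m[:, 0, :])
        cascade = probs.detach() if self.config.detach_cascade else probs
        risk = self.survival_head(m[:, 1, :], cascade)
        return {"features": f, "attention": a, "pooled": m,
                "probs": probs, "risk": risk}

    def __call__(self, stacks: Tensor) -> dict[str, Tensor]:
        return self.forward(stacks)

    def parameters(self) -> list[Parameter]:
        return (self.backbone.params() + self.refine1.params() + self.refine2.params()
                + self.att_v.params() + self.att_u.params() + self.att_w.params()
                + self.cls_head.params() + self.surv1.params() + self.surv2.params())

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint/parameter count mismatch")
        for i, p in enumerate(params):
            p.data = np.array(arrays[f"p{i}"], dtype=np.float64)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.state_arrays())
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)

    @classmethod
    def load(cls, path) -> "MultiTaskNet":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            config = NetworkConfig(**json.load(fh))
        net = cls(config)
        with np.load(path) as data:
            net.load_state_arrays(dict(data))
        return net


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def loss_tme(y_onehot, y_prob) -> Tensor:
    """Mean categorical cross-entropy over the batch (log clamped at 1e-12)."""
    y = np.asarray(y_onehot.data if isinstance(y_onehot, Tensor) else y_onehot, dtype=float)
    probs = _as_tensor(y_prob)
    return -(Tensor(y) * probs.clip_min(1e-12).log()).sum(axis=-1).mean()


def loss_cox(risk, times, events) -> Tensor:
    """Negative Cox log partial likelihood of the batch.

        - sum_{i: E_i = 1} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]

    Risk sets include the event subject itself; tied event times share risk
    sets (Breslow). Log-sum-exp is max-shifted for stability. Raises if the
    batch has no events (uninformative batch; callers may resample).
    """
    h = _as_tensor(risk)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if h.ndim != 1 or len(times) != h.shape[0] or len(events) != h.shape[0]:
        raise ValueError("risk, times, events must be aligned 1-D")
    if not events.any():
        raise ValueError("uninformative batch: no events")
    event_idx = np.flatnonzero(events)
    risk_matrix = (times[None, :] >= times[event_idx, None]).astype(float)
    shift = float(np.max(h.data))
    exp_h = (h - shift).exp()
    lse = (Tensor(risk_matrix) * exp_h).sum(axis=1).log() + shift
    return -(h[event_idx] - lse).sum()


def total_loss(y_onehot, y_prob, risk, times, events,
               w_tme: float = 1.0, w_cox: float = 1.0) -> Tensor:
    """Joint objective: unit-weighted sum of the two task losses."""
    return w_tme * loss_tme(y_onehot, y_prob) + w_cox * loss_cox(risk, times, events)


def one_hot(labels, n_classes: int = 4) -> np.ndarray:
    """1-based class labels -> one-hot matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels must be in 1..{n_classes}")
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    epoch_loss_tme: list[float] = field(default_factory=list)
    epoch_loss_cox: list[float] = field(default_factory=list)

    @property
    def epoch_total(self) -> list[float]:
        return [a + b for a, b in zip(self.epoch_loss_tme, self.epoch_loss_cox)]


def train(config: NetworkConfig,
          stacks: np.ndarray,
          tme_classes: np.ndarray,
          times: np.ndarray,
          events: np.ndarray,
          augment_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
          ) -> tuple[MultiTaskNet, TrainHistory]:
    """Seeded mini-batch training of the joint objective.

    ``stacks``: (n, n_slices, H, W) in [0, 1]; ``tme_classes``: 1..4;
    ``times``/``events``: the survival outcome. ``augment_fn`` is applied
    per batch (training only). Batches without any event contribute only the
    classification term. Non-finite loss aborts and restores the last
    finite-epoch parameters.
    """
    net = MultiTaskNet(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = stacks.shape[0]
    y_onehot = one_hot(tme_classes, config.n_classes)
    history = TrainHistory()
    best_state = net.state_arrays()
    best_state = {k: v.copy() for k, v in best_state.items()}
    plateau = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        tme_losses, cox_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            batch = stacks[idx]
            if augment_fn is not None:
                batch = np.stack([augment_fn(s, rng) for s in batch])
            out = net.forward(Tensor(batch))
            l_tme = loss_tme(y_onehot[idx], out["probs"])
            if events[idx].any():
                l_cox = loss_cox(out["risk"], times[idx], events[idx])
            else:
                l_cox = Tensor(0.0)
            loss = config.loss_weight_tme * l_tme + config.loss_weight_cox * l_cox
            if not np.isfinite(loss.data):
                net.load_state_arrays(best_state)
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}; restored last finite checkpoint")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tme_losses.append(l_tme.item())
            cox_losses.append(float(l_cox.data))
        history.epoch_loss_tme.append(float(np.mean(tme_losses)))
        history.epoch_loss_cox.append(float(np.mean(cox_losses)))
        best_state = {k: v.copy() for k, v in net.state_arrays().items()}
        # loss-plateau early stopping
        totals = history.epoch_total
        if epoch + 1 >= config.min_epochs and len(totals) >= 2:
            prev, cur = totals[-2], totals[-1]
            rel = (prev - cur) / max(abs(prev), 1e-12)
            plateau = plateau + 1 if rel < config.plateau_tol else 0
            if plateau >= config.plateau_patience:
                break
    return net, history


def predict(net: MultiTaskNet, stacks: np.ndarray,
            batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic eval-mode forward pass.

    Returns (probs (n, 4), risk (n,)); ``risk`` is the DLS.
    """
    probs, risks = [], []
    for start in range(0, stacks.shape[0], batch_size):
        out = net.forward(Tensor(stacks[start:start + batch_size]))
        probs.append(out["probs"].data)
        risks.append(out["risk"].data)
    return np.concatenate(probs), np.concatenate(risks)
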