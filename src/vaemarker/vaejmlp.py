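"""Jointly trained variational autoencoder + MLP classifier.

The model couples a VAE (encoder -> Gaussian latent -> Bernoulli decoder)
with a softmax MLP head that classifies samples from the latent code.  The
encoder outputs the posterior mean mu and log-variance; sampling uses the
reparameterization z = mu + sigma * eps with eps ~ N(0, 1).  Losses:

    L_VAE     = BCE(x, x') + D_KL( N(mu, sigma) || N(0, 1) )
    L_MLP     = CE(y, y')
    L_joint   = lambda * L_VAE + L_MLP

Training runs in three phases: VAE-only (unsupervised), MLP-only with the
encoder and decoder frozen, then joint optimization of the weighted loss.
The classifier consumes the stochastic z during training but the
deterministic mean mu at evaluation and attribution time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import accuracy_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import train_test_split

from . import _nn
from .data_model import LabelVector, ScaledMatrix, ValidationError


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Layer widths of the encoder / decoder / classifier.

    Defaults are the full-scale architecture: encoder hidden widths
    1024-1024-512-128 with a 128-dimensional latent, a mirrored decoder, and
    a 128-64-2 classifier head.  LeakyReLU throughout.
    """

    input_dim: int
    encoder_widths: tuple[int, ...] = (1024, 1024, 512, 128)
    latent_dim: int = 128
    mlp_widths: tuple[int, ...] = (128, 64)
    n_classes: int = 2
    negative_slope: float = 0.01

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_widths))

    @classmethod
    def scaled(cls, input_dim: int) -> "ArchitectureSpec":
        """Shrink widths for small feature sets, keeping the 8:8:4:1 encoder
        ratio with a floor of 8 units, so toy inputs do not allocate
        1024-wide layers."""
        latent = int(np.clip(input_dim // 8, 8, 128))
        return cls(input_dim=input_dim,
                   encoder_widths=(8 * latent, 8 * latent, 4 * latent, latent),
                   latent_dim=latent,
                   mlp_widths=(latent, max(8, latent // 2)))

    def validate(self):
        if self.input_dim < 1:
            raise ValidationError("input_dim must be positive")
        if self.latent_dim < 1 or any(w < 1 for w in self.encoder_widths):
            raise ValidationError("layer widths must be positive")


@dataclasses.dataclass(frozen=True)
class TrainingSchedule:
    """Phase lengths, loss weight, optimizer settings, and split."""

    total_epochs: int = 250
    vae_only_epochs: int = 50
    mlp_only_epochs: int = 50
    joint_epochs: int = 150
    lam: float = 0.001
    lr: float = 1e-3
    weight_decay: float = 0.01  # decoupled L2; stabilizes credit assignment
    input_dropout: float = 0.25  # train-time only; spreads credit over
                                 # redundant informative genes
    batch_size: int = 32
    test_fraction: float = 0.2
    seed: int = 0
    init_seed: int | None = None  # fix weight init across runs; None -> seed

    def validate(self):
        if self.vae_only_epochs + self.mlp_only_epochs + self.joint_epochs \
                != self.total_epochs:
            raise ValidationError(
                f"phase epochs {self.vae_only_epochs}+{self.mlp_only_epochs}"
                f"+{self.joint_epochs} must sum to total {self.total_epochs}")
        if self.lam < 0:
            raise ValidationError("lambda must be non-negative")
        if not (0 < self.test_fraction < 1):
            raise ValidationError("test_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# loss primitives (exposed because their algebra is part of the contract)


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   epsilon: np.ndarray) -> np.ndarray:
    """z = mu + sigma * epsilon, elementwise."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValidationError("sigma must be positive elementwise")
    return np.asarray(mu, float) + sigma * np.asarray(epsilon, float)


def kl_gaussian(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL( N(mu, sigma^2) || N(0, 1) ), summed over latent units
    and averaged over the batch; always >= 0, zero iff mu = 0, sigma = 1."""
    mu = np.atleast_2d(np.asarray(mu, float))
    sigma = np.atleast_2d(np.asarray(sigma, float))
    per = 0.5 * (mu ** 2 + sigma ** 2 - np.log(sigma ** 2) - 1.0)
    return float(per.sum(axis=1).mean())


def vae_loss(x: np.ndarray, x_recon: np.ndarray, mu: np.ndarray,
             sigma: np.ndarray) -> tuple[float, float, float]:
    """(total, bce, kl) with BCE summed over features, averaged over batch."""
    x = np.atleast_2d(np.asarray(x, float))
    xr = np.atleast_2d(np.asarray(x_recon, float))
    if (xr < 0).any() or (xr > 1).any():
        raise ValidationError("reconstruction must lie in [0, 1] "
                              "(decoder must end in a sigmoid)")
    eps = 1e-12
    xr = np.clip(xr, eps, 1 - eps)
    bce = float(-(x * np.log(xr) + (1 - x) * np.log(1 - xr)).sum(axis=1).mean())
    kl = kl_gaussian(mu, sigma)
    return bce + kl, bce, kl


def joint_loss(l_vae: float, l_mlp: float, lam: float) -> float:
    """lambda * L_VAE + L_MLP."""
    if not (np.isfinite(l_vae) and np.isfinite(l_mlp)):
        raise ValidationError("losses must be finite")
    return lam * l_vae + l_mlp


# ---------------------------------------------------------------------------
# network


class _VaeMlpNet:
    """Parameter container with the forward/backward passes of the model."""

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator):
        a = arch.negative_slope
        layers = []
        prev = arch.input_dim
        for w in arch.encoder_widths:
            layers += [_nn.Dense(prev, w, rng), _nn.LeakyReLU(a)]
            prev = w
        self.enc_hidden = _nn.Sequential(layers)
        self.mu_head = _nn.Dense(prev, arch.latent_dim, rng)
        self.logvar_head = _nn.Dense(prev, arch.latent_dim, rng)

        layers = []
        prev = arch.latent_dim
        for w in arch.decoder_widths:
            layers += [_nn.Dense(prev, w, rng), _nn.LeakyReLU(a)]
            prev = w
        layers += [_nn.Dense(prev, arch.input_dim, rng)]  # logits; sigmoid in loss
        self.decoder = _nn.Sequential(layers)

        layers = []
        prev = arch.latent_dim
        for w in arch.mlp_widths:
            layers += [_nn.Dense(prev, w, rng), _nn.LeakyReLU(a)]
            prev = w
        layers += [_nn.Dense(prev, arch.n_classes, rng)]
        self.mlp = _nn.Sequential(layers)
        self.arch = arch

    # parameter groups
    def vae_parameters(self) -> list[_nn.Param]:
        return (self.enc_hidden.parameters() + self.mu_head.parameters()
                + self.logvar_head.parameters() + self.decoder.parameters())

    def mlp_parameters(self) -> list[_nn.Param]:
        return self.mlp.parameters()

    def all_parameters(self) -> list[_nn.Param]:
        return self.vae_parameters() + self.mlp_parameters()

    def encode_params(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.enc_hidden.forward(x)
        return self.mu_head.forward(h), self.logvar_head.forward(h)

    def encode_mu(self, x: np.ndarray) -> np.ndarray:
        return self.encode_params(x)[0]

    def class_logits(self, x: np.ndarray) -> np.ndarray:
        """Deterministic logits through the posterior mean."""
        return self.mlp.forward(self.encode_mu(x))

    def backward_encoder(self, d_mu: np.ndarray, d_logvar: np.ndarray):
        g = self.mu_head.backward(d_mu) + self.logvar_head.backward(d_logvar)
        self.enc_hidden.backward(g)

    def input_gradient(self, x: np.ndarray, class_index: int = 1) -> np.ndarray:
        """d logit[class_index] / dx through the deterministic mu path."""
        h = self.enc_hidden.forward(x)
        mu = self.mu_head.forward(h)
        logits = self.mlp.forward(mu)
        g_logits = np.zeros_like(logits)
        g_logits[:, class_index] = 1.0
        g_mu = self.mlp.backward(g_logits)
        g_h = self.mu_head.backward(g_mu)
        g_x = self.enc_hidden.backward(g_h)
        for p in self.all_parameters():  # inference-only pass
            p.grad[...] = 0.0
        return g_x

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.all_parameters()]


@dataclasses.dataclass
class TrainedVaejmlp:
    """A trained model plus its provenance: traces, split, held-out metrics."""

    arch: ArchitectureSpec
    schedule: TrainingSchedule
    net: _VaeMlpNet
    gene_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    loss_trace: list[dict]
    metrics: dict[str, float]


def stratified_split(labels: LabelVector, test_fraction: float,
                     seed: int) -> tuple[list[str], list[str]]:
    """Class-stratified train/test split of the sample ids."""
    ids = list(labels.sample_ids)
    train, test = train_test_split(ids, test_size=test_fraction,
                                   stratify=labels.labels, random_state=seed)
    return list(train), list(test)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(scaled: ScaledMatrix, labels: LabelVector, arch: ArchitectureSpec,
          sched: TrainingSchedule,
          split: tuple[Sequence[str], Sequence[str]] | None = None
          ) -> TrainedVaejmlp:
    """Run the three-phase schedule and return the trained model.

    ``split`` may carry a precomputed (train_ids, test_ids) pair — e.g. when
    the scaling parameters were fit on that same training partition; otherwise
    a stratified split is drawn from the schedule's seed.
    """
    arch.validate()
    sched.validate()
    labels.require_both_classes()
    if arch.input_dim != len(scaled.gene_ids):
        raise ValidationError(
            f"architecture input_dim {arch.input_dim} != feature count "
            f"{len(scaled.gene_ids)}")

    if split is None:
        train_ids, test_ids = stratified_split(labels, sched.test_fraction,
                                               sched.seed)
    else:
        train_ids, test_ids = list(split[0]), list(split[1])

    x_train = scaled.sample_matrix(train_ids)
    y_train = labels.for_samples(train_ids)
    rng = np.random.default_rng(sched.seed)
    init = sched.init_seed if sched.init_seed is not None else sched.seed
    net = _VaeMlpNet(arch, np.random.default_rng(init))

    wd = sched.weight_decay
    opt_vae = _nn.Adam(net.vae_parameters(), lr=sched.lr, weight_decay=wd)
    opt_mlp = _nn.Adam(net.mlp_parameters(), lr=sched.lr, weight_decay=wd)
    opt_all = _nn.Adam(net.all_parameters(), lr=sched.lr, weight_decay=wd)

    trace: list[dict] = []
    n = x_train.shape[0]
    for epoch in range(sched.total_epochs):
        if epoch < sched.vae_only_epochs:
            phase = "vae"
        elif epoch < sched.vae_only_epochs + sched.mlp_only_epochs:
            phase = "mlp"
        else:
            phase = "joint"
        sums = {"bce": 0.0, "kl": 0.0, "vae": 0.0, "mlp": 0.0, "total": 0.0}
        n_batches = 0
        for idx in _epoch_batches(n, sched.batch_size, rng):
            xb, yb = x_train[idx], y_train[idx]
            b = len(idx)
            if sched.input_dropout > 0:
                # denoising-style corruption of the encoder input only; the
                # reconstruction target remains the clean xb
                keep = 1.0 - sched.input_dropout
                mask = rng.random(xb.shape) < keep
                x_in = xb * mask / keep
            else:
                x_in = xb
            mu, logvar = net.encode_params(x_in)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps

            dec_logits = net.decoder.forward(z)
            bce, g_dec_logits = _nn.bce_with_logits(xb, dec_logits)
            kl = 0.5 * float((mu ** 2 + sigma ** 2 - logvar - 1.0).sum()) / b
            l_vae = bce + kl

            cls_logits = net.mlp.forward(z)
            l_mlp, g_cls_logits = _nn.cross_entropy(cls_logits, yb)

            if phase == "vae":
                w_vae, w_mlp, opt = 1.0, 0.0, opt_vae
            elif phase == "mlp":
                w_vae, w_mlp, opt = 0.0, 1.0, opt_mlp
            else:
                w_vae, w_mlp, opt = sched.lam, 1.0, opt_all
            total = w_vae * l_vae + w_mlp * l_mlp
            if not np.isfinite(total):
                raise TrainingDivergedError(epoch)

            opt.zero_grad()
            dz = np.zeros_like(z)
            if w_vae:
                # scaling the upstream grad scales decoder param grads too
                dz += net.decoder.backward(w_vae * g_dec_logits)
            if w_mlp:
                dz += net.mlp.backward(w_mlp * g_cls_logits)
            if w_vae or (phase == "joint"):
                # reparameterization + closed-form KL gradients
                d_mu = dz + (w_vae / b) * mu
                d_logvar = dz * sigma * eps * 0.5 \
                    + (w_vae * 0.5 / b) * (sigma ** 2 - 1.0)
                if phase != "mlp":
                    net.backward_encoder(d_mu, d_logvar)
            opt.step()

            sums["bce"] += bce
            sums["kl"] += kl
            sums["vae"] += l_vae
            sums["mlp"] += l_mlp
            sums["total"] += total
            n_batches += 1
        trace.append({"epoch": epoch, "phase": phase,
                      **{k: v / n_batches for k, v in sums.items()}})

    model = TrainedVaejmlp(arch, sched, net, scaled.gene_ids,
                           tuple(train_ids), tuple(test_ids), trace, {})
    model.metrics = evaluate(model, scaled, labels, split="test")
    return model


def predict_proba(model: TrainedVaejmlp, scaled: ScaledMatrix,
                  sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """P(tumor) per sample through the deterministic mu path."""
    x = scaled.sample_matrix(sample_ids)
    return _nn.softmax(model.net.class_logits(x))[:, 1]


def evaluate(model: TrainedVaejmlp, scaled: ScaledMatrix, labels: LabelVector,
             split: str = "test") -> dict[str, float]:
    """AUC / accuracy / precision / recall with tumor as the positive class."""
    ids = {"train": model.train_ids, "test": model.test_ids}[split]
    y = labels.for_samples(ids)
    p = predict_proba(model, scaled, ids)
    yhat = (p >= 0.5).astype(int)
    return {
        "auc": float(roc_auc_score(y, p)) if len(set(y)) > 1 else float("nan"),
        "accuracy": float(accuracy_score(y, yhat)),
        "precision": float(precision_score(y, yhat, zero_division=0)),
        "recall": float(recall_score(y, yhat, zero_division=0)),
    }


def encode(model: TrainedVaejmlp, scaled: ScaledMatrix,
           sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Deterministic latent representation (posterior mean), samples x latent."""
    z = model.net.encode_mu(scaled.sample_matrix(sample_ids))
    if not np.isfinite(z).all():
        raise ValidationError("non-finite latent representation")
    return z


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedVaejmlp, path: str | Path):
    """Weights to ``<path>.npz``; architecture/schedule/metrics sidecar JSON."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.all_parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "arch": dataclasses.asdict(model.arch),
        "schedule": dataclasses.asdict(model.schedule),
        "gene_ids": list(model.gene_ids),
        "train_ids": list(model.train_ids),
        "test_ids": list(model.test_ids),
        "metrics": model.metrics,
        "loss_trace": model.loss_trace,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> TrainedVaejmlp:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch_d = sidecar["arch"]
    for key in ("encoder_widths", "mlp_widths"):
        arch_d[key] = tuple(arch_d[key])
    arch = ArchitectureSpec(**arch_d)
    sched = TrainingSchedule(**sidecar["schedule"])
    net = _VaeMlpNet(arch, np.random.default_rng(0))
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(net.all_parameters()):
        p.value[...] = data[f"p{i}"]
    return TrainedVaejmlp(arch, sched, net, tuple(sidecar["gene_ids"]),
                          tuple(sidecar["train_ids"]), tuple(sidecar["test_ids"]),
                          sidecar["loss_trace"], sidecar["metrics"])
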