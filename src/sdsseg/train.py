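"""Training harness: SGD, early stopping, and supervision-scheme comparison.

Three schemes are supported.  ``conventional`` optimizes only the final
head's loss; ``deep_supervision`` supervises every head with all three
regions at constant balancing weights; ``sds`` (selective deep
supervision) gives the shallow auxiliary heads the reduced nested tasks
and decays their weights geometrically per epoch.  All three run the
same forward pass; schemes differ only in which head losses enter the
objective, so ``sds`` with zero auxiliary weights reproduces
``conventional`` step for step, and ``sds`` with the all-region scheme
and no decay reproduces ``deep_supervision``.

Everything is seeded: weight initialization, the train/validation split
and per-epoch shuffling all derive from ``TrainConfig.seed``, so a rerun
with the same configuration gives a bit-identical history.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from . import autograd as ag
from .layers import SGD
from .network import NetworkConfig, SegmentationNet
from .phantom import LabeledVolume
from .preprocess import PreprocessConfig, extract_sample, preprocess_volume
from .supervision import (DEFAULT_SCHEME, FULL_SCHEME, HeadScheme, LossWeights,
                          build_head_targets, nll_loss, total_loss)

SCHEMES = ("conventional", "deep_supervision", "sds")


@dataclass(frozen=True)
class TrainConfig:
    scheme: str = "sds"
    learning_rate: float = 0.001
    momentum: float = 0.0
    batch_size: int = 8
    max_epochs: int = 600
    max_steps: int | None = None          # optional hard cap on SGD steps
    patience: int = 10
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    val_fraction: float = 0.2
    reduction: str = "mean"
    custom_scheme: tuple | None = None    # overrides the per-scheme default
    step_log: str | None = None           # JSONL per-step loss decomposition

    def validate(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")

    def head_scheme(self) -> HeadScheme:
        if self.custom_scheme is not None:
            return HeadScheme(tuple(tuple(h) for h in self.custom_scheme))
        return HeadScheme(FULL_SCHEME if self.scheme == "deep_supervision"
                          else DEFAULT_SCHEME)

    def effective_weights(self) -> LossWeights:
        lw = self.loss_weights
        if self.scheme == "conventional":
            return replace(lw, eta=(0.0, 0.0, 0.0), gamma=1.0)
        if self.scheme == "deep_supervision":
            return replace(lw, gamma=1.0)
        return lw


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    initial_val_loss: float = float("nan")
    stopping_epoch: int = 0
    best_epoch: int = 0
    best_val_loss: float = float("inf")
    final_train_loss: float = float("nan")
    final_val_loss: float = float("nan")


@dataclass
class Sample:
    """A ready-to-train sample: inputs plus per-head class-index targets."""

    image2d: np.ndarray
    patch3d: np.ndarray
    targets: tuple[np.ndarray, ...]
    volume_id: int


def build_dataset(volumes: list[LabeledVolume], pre_cfg: PreprocessConfig,
                  scheme: HeadScheme, val_fraction: float, seed: int
                  ) -> tuple[list[Sample], list[Sample], list[LabeledVolume]]:
    """Preprocess volumes into per-slice samples, split by volume.

    Returns (train samples, validation samples, held-out validation
    volumes in original geometry) — volumes are never split across the
    two sets, so validation measures generalization to unseen phantoms.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(volumes))
    n_val = max(1, int(round(val_fraction * len(volumes)))) if val_fraction > 0 else 0
    val_ids = set(order[:n_val].tolist())
    train, val, val_vols = [], [], []
    for vid, vol in enumerate(volumes):
        prepped, _, _ = preprocess_volume(vol, pre_cfg)
        dest = val if vid in val_ids else train
        if vid in val_ids:
            val_vols.append(vol)
        for n in range(prepped.shape[0]):
            s = extract_sample(prepped, n, pre_cfg)
            targets = build_head_targets(s.label2d, scheme)
            dest.append(Sample(s.image2d, s.patch3d, targets, vid))
    return train, val, val_vols


def _batch(samples: list[Sample]):
    img = np.stack([s.image2d for s in samples])
    patch = np.stack([s.patch3d for s in samples])
    targets = tuple(np.stack([s.targets[h] for s in samples]) for h in range(4))
    return img, patch, targets


def _weight_sq_norm(model: SegmentationNet):
    terms = [ag.tsum(ag.square(p)) for p in model.parameters()]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def _step_loss(model: SegmentationNet, img, patch, targets, weights: LossWeights,
               epoch: int, reduction: str):
    heads = model(img, patch)
    main = nll_loss(heads[3], targets[3], reduction=reduction)
    etas = weights.eta_at(epoch)
    aux = [nll_loss(heads[d], targets[d], reduction=reduction) if etas[d] != 0.0
           else 0.0 for d in range(3)]
    reg = _weight_sq_norm(model) if weights.weight_decay != 0.0 else 0.0
    return total_loss(main, aux, weights, epoch, reg)


def _eval_pass(model: SegmentationNet, samples: list[Sample], batch_size: int,
               reduction: str) -> tuple[float, dict[str, float]]:
    """Validation loss (final head) and per-region Dice at slice level."""
    model.eval()
    losses, n_pix = [], []
    inter = np.zeros(3)
    sums = np.zeros(3)
    for i in range(0, len(samples), batch_size):
        img, patch, targets = _batch(samples[i:i + batch_size])
        heads = model(img, patch)
        losses.append(float(nll_loss(heads[3], targets[3],
                                     reduction=reduction).data))
        n_pix.append(img.shape[0])
        pred = np.argmax(heads[3].data, axis=1)
        ref = targets[3]
        for j, classes in enumerate(((1, 2, 3), (2, 3), (3,))):  # WT, TC, ET
            pm = np.isin(pred, classes)
            rm = np.isin(ref, classes)
            inter[j] += (pm & rm).sum()
            sums[j] += pm.sum() + rm.sum()
    model.train()
    loss = float(np.average(losses, weights=n_pix)) if losses else float("nan")
    dice = {name: (2.0 * inter[j] / sums[j] if sums[j] else 1.0)
            for j, name in enumerate(("dice_wt", "dice_tc", "dice_et"))}
    return loss, dice


def train(model: SegmentationNet, data, cfg: TrainConfig) -> TrainingHistory:
    """Optimize ``model`` with SGD under the configured supervision scheme.

    ``data`` is ``(train_samples, val_samples)``; stops early when the
    validation loss has not improved for ``cfg.patience`` epochs.
    """
    cfg.validate()
    train_samples, val_samples = data
    if not train_samples:
        raise ValueError("empty training set")
    weights = cfg.effective_weights()
    opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    log_fh = open(cfg.step_log, "w") if cfg.step_log else None
    hist = TrainingHistory()
    hist.initial_val_loss, _ = _eval_pass(model, val_samples or train_samples,
                                          cfg.batch_size, cfg.reduction)
    best_state = None
    bad_epochs = 0
    steps = 0
    for epoch in range(cfg.max_epochs):
        order = np.random.default_rng((cfg.seed, 7919, epoch)).permutation(
            len(train_samples))
        epoch_losses = []
        epoch_main = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + cfg.batch_size]]
            img, patch, targets = _batch(batch)
            opt.zero_grad()
            loss, decomp = _step_loss(model, img, patch, targets, weights,
                                      epoch, cfg.reduction)
            if not np.isfinite(float(loss.data)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {steps}: {decomp}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            epoch_main.append(decomp["main"])
            if log_fh is not None:
                import json
                log_fh.write(json.dumps({"epoch": epoch, "step": steps,
                                         "total": float(loss.data), **decomp})
                             + "\n")
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        val_loss, dices = _eval_pass(model, val_samples or train_samples,
                                     cfg.batch_size, cfg.reduction)
        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
               "train_main_loss": float(np.mean(epoch_main)),
               "val_loss": val_loss, "eta": weights.eta_at(epoch), **dices}
        hist.epochs.append(rec)
        if val_loss < hist.best_val_loss - 1e-9:
            hist.best_val_loss = val_loss
            hist.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
        hist.stopping_epoch = epoch + 1
        if bad_epochs >= cfg.patience:
            break
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    hist.final_train_loss = hist.epochs[-1]["train_loss"]
    hist.final_val_loss = hist.epochs[-1]["val_loss"]
    if log_fh is not None:
        log_fh.close()
    if best_state is not None:
        model.load_state_arrays(best_state)
    return hist


def compare_schemes(volumes: list[LabeledVolume], net_cfg: NetworkConfig,
                    pre_cfg: PreprocessConfig, base_cfg: TrainConfig,
                    seeds: list[int]) -> dict[str, list[TrainingHistory]]:
    """Train the three schemes from shared initial weights for each seed."""
    if not seeds:
        raise ValueError("at least one seed is required")
    out: dict[str, list[TrainingHistory]] = {s: [] for s in SCHEMES}
    for seed in seeds:
        for scheme in SCHEMES:
            cfg = replace(base_cfg, scheme=scheme, seed=seed)
            scheme_heads = cfg.head_scheme()
            net = SegmentationNet(dataclasses.replace(
                net_cfg, seed=seed, head_classes=scheme_heads.n_classes()))
            tr, va, _ = build_dataset(volumes, pre_cfg, scheme_heads,
                                      cfg.val_fraction, seed)
            out[scheme].append(train(net, (tr, va), cfg))
    return out


def history_frame(hist: TrainingHistory):
    import pandas as pd

    return pd.DataFrame(hist.epochs)


def plot_learning_curves(histories: dict[str, list[TrainingHistory]], path: str) -> None:
    """Write a per-scheme train/validation loss curve figure (first seed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(histories), figsize=(4 * len(histories), 3),
                             squeeze=False)
    for ax, (scheme, hists) in zip(axes[0], histories.items()):
        h = hists[0]
        ep = [r["epoch"] for r in h.epochs]
        ax.plot(ep, [r["train_loss"] for r in h.epochs], label="train")
        ax.plot(ep, [r["val_loss"] for r in h.epochs], label="validation")
        ax.set_title(scheme)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
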