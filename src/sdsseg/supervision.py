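"""Selective deep supervision: per-head targets and the training objective.

Four output heads are supervised with tasks of increasing difficulty,
exploiting the nesting ET <= TC <= WT of the tumor regions.  Because the
regions overlap, each head's regions are converted into mutually
exclusive classes by hierarchical set difference, so a per-pixel softmax
plus negative log-likelihood is well defined:

    {WT}           -> (background, WT)
    {WT, ET}       -> (background, WT\\ET, ET)
    {WT, TC, ET}   -> (background, WT\\TC, TC\\ET, ET)

The default scheme supervises the two shallowest auxiliary heads with
the reduced tasks and the two deepest outputs with all three regions.
The total objective is

    L = L_main + sum_d eta_d(epoch) * L_d + lambda * (||W||^2 + sum_d ||w_d||^2)

with per-head balancing weights eta_d decayed geometrically per epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor

EPS = 1e-12

#: Region subsets in head order; entry i names head i+1's task.
DEFAULT_SCHEME = (("WT",), ("WT", "ET"), ("WT", "TC", "ET"), ("WT", "TC", "ET"))
FULL_SCHEME = (("WT", "TC", "ET"),) * 4

#: Class layouts per region subset: ordered (name, label-code predicate) pairs.
#: Classes are listed background first, then outside-in.
_LAYOUTS = {
    ("WT",): ("background", "WT"),
    ("WT", "ET"): ("background", "WT-ET", "ET"),
    ("WT", "TC", "ET"): ("background", "WT-TC", "TC-ET", "ET"),
}


@dataclass(frozen=True)
class HeadScheme:
    """Mapping from each of the 4 output heads to its supervised regions."""

    heads: tuple[tuple[str, ...], ...] = DEFAULT_SCHEME

    def __post_init__(self):
        if len(self.heads) != 4:
            raise ValueError("HeadScheme requires exactly 4 heads")
        for h in self.heads:
            if tuple(h) not in _LAYOUTS:
                raise ValueError(f"unsupported region subset {h}; "
                                 f"allowed: {sorted(_LAYOUTS)}")
        order = [len(h) for h in self.heads]
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValueError("head region subsets must be nested (non-decreasing)")
        if len(self.heads[-1]) != 3:
            raise ValueError("the final head must cover all three regions")

    def classes(self, head: int) -> tuple[str, ...]:
        return _LAYOUTS[tuple(self.heads[head])]

    def n_classes(self) -> tuple[int, ...]:
        return tuple(len(self.classes(i)) for i in range(4))


def _class_map(labels: np.ndarray, regions: tuple[str, ...]) -> np.ndarray:
    """Per-pixel class index under the hierarchical set-difference layout."""
    wt = np.isin(labels, (1, 2, 4))
    tc = np.isin(labels, (1, 4))
    et = labels == 4
    out = np.zeros(labels.shape, dtype=np.int64)
    if regions == ("WT",):
        out[wt] = 1
    elif regions == ("WT", "ET"):
        out[wt & ~et] = 1
        out[et] = 2
    elif regions == ("WT", "TC", "ET"):
        out[wt & ~tc] = 1
        out[tc & ~et] = 2
        out[et] = 3
    else:  # pragma: no cover - guarded by HeadScheme
        raise ValueError(f"unsupported region subset {regions}")
    return out


def build_head_targets(label_slice: np.ndarray, scheme: HeadScheme
                       ) -> tuple[np.ndarray, ...]:
    """Four per-pixel class-index maps, one per head, in head order."""
    label_slice = np.asarray(label_slice)
    bad = set(np.unique(label_slice)) - {0, 1, 2, 4}
    if bad:
        raise ValueError(f"unknown label code(s) {sorted(bad)}")
    return tuple(_class_map(label_slice, tuple(r)) for r in scheme.heads)


def label_codes_from_classes(class_map: np.ndarray) -> np.ndarray:
    """Invert the final head's class layout back to BraTS codes {0,2,1,4}."""
    codes = np.array([0, 2, 1, 4], dtype=np.int16)
    return codes[np.asarray(class_map, dtype=np.int64)]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_clamp_warnings = {"count": 0}


def nll_loss(probs, targets: np.ndarray, reduction: str = "mean"):
    """Negative log-likelihood of target classes under per-pixel probabilities.

    ``probs``: Tensor or array (N, C, H, W) of normalized probabilities;
    ``targets``: integer class indices (N, H, W).  Probabilities below
    1e-12 are clamped before the log (counted in a warning counter).
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    probs = ag.as_tensor(probs)
    targets = np.asarray(targets, dtype=np.int64)
    if targets.ndim == probs.ndim - 2:  # allow unbatched (H, W)
        targets = targets[None]
    if probs.ndim == 3:
        probs = ag.reshape(probs, (1,) + probs.shape)
    picked = ag.take_channel(probs, targets)
    n_clamped = int((picked.data < EPS).sum())
    if n_clamped:
        _clamp_warnings["count"] += n_clamped
        warnings.warn(f"clamped {n_clamped} zero-probability target pixels at eps={EPS}")
    neg_log = -ag.log(ag.clamp_min(picked, EPS))
    return neg_log.mean() if reduction == "mean" else neg_log.sum()


def aux_loss(head_probs, head_targets: np.ndarray, d: int,
             reduction: str = "mean"):
    """Auxiliary NLL for supervised hidden layer ``d`` (head index 0..2)."""
    if not 0 <= d <= 2:
        raise ValueError("auxiliary head index must be in {0, 1, 2}")
    return nll_loss(head_probs, head_targets, reduction=reduction)


@dataclass(frozen=True)
class LossWeights:
    """Balancing weights of the SDS objective."""

    eta: tuple[float, ...] = (0.4, 0.3, 0.2)
    gamma: float = 0.95
    weight_decay: float = 1e-4

    def __post_init__(self):
        if any(e < 0 for e in self.eta):
            raise ValueError("eta weights must be non-negative")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")

    def eta_at(self, epoch: int) -> tuple[float, ...]:
        f = self.gamma ** epoch
        return tuple(e * f for e in self.eta)


def total_loss(main, aux, weights: LossWeights, epoch: int,
               weight_sq_norm=0.0):
    """Combine main, auxiliary and regularization terms.

    Accepts floats (returns a float) or autograd Tensors (returns a
    Tensor in the graph).  Terms with zero coefficient are skipped, so
    eta=0, lambda=0 reduces *exactly* to the main loss.  Returns
    ``(total, decomposition)`` where the decomposition maps term names
    to float values summing to the total.
    """
    etas = weights.eta_at(epoch)
    if len(aux) != len(etas):
        raise ValueError(f"expected {len(etas)} auxiliary losses, got {len(aux)}")
    total = main
    decomp = {"main": float(main.data) if isinstance(main, Tensor) else float(main)}
    for d, (e, a) in enumerate(zip(etas, aux)):
        decomp[f"aux{d + 1}"] = e * (float(a.data) if isinstance(a, Tensor) else float(a))
        if e != 0.0:
            total = total + e * a if isinstance(total, Tensor) or isinstance(a, Tensor) \
                else total + e * a
    reg_val = float(weight_sq_norm.data) if isinstance(weight_sq_norm, Tensor) \
        else float(weight_sq_norm)
    decomp["reg"] = weights.weight_decay * reg_val
    if weights.weight_decay != 0.0 and reg_val != 0.0:
        total = total + weights.weight_decay * weight_sq_norm
    decomp["eta"] = etas
    return total, decomp
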