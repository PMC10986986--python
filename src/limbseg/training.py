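"""Training protocol: splits, learning-rate schedule, epoch loop, convergence.

Subjects are split at the subject level (never slice level): one held-out
test subject, then an 80:20 train/validation split of the remaining
originals.  Any augmented subject whose provenance names the test subject
— as fixed or as moving image — is excluded outright, since such a subject
carries the test anatomy.  Training minimises per-pixel multi-class cross
entropy with Adam in mini-batches of 8 slices, under a piecewise-constant
learning rate (1e-3, halved after 30 epochs, 1e-4 after 60) for a fixed
number of epochs.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn.layers import Adam, softmax_channels
from .nn.models import Network, SCUNet, SpatialEncoding, spatial_encoding
from .phantom import PhantomSubject

DEFAULT_LR_STAGES: tuple[tuple[int, float], ...] = ((30, 1e-3), (60, 5e-4), (90, 1e-4))


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 90
    lr_stages: tuple[tuple[int, float], ...] = DEFAULT_LR_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.lr_stages]
        rates = [r for _, r in self.lr_stages]
        if thresholds != sorted(set(thresholds)):
            raise ValueError("lr stage thresholds must be strictly increasing")
        if any(b >= a for a, b in zip(rates, rates[1:])):
            raise ValueError("lr stage rates must be strictly decreasing")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class LossCurve:
    """Per-epoch mean training and validation cross-entropy losses."""

    train: list[float]
    val: list[float]

    def __post_init__(self) -> None:
        t, v = np.asarray(self.train), np.asarray(self.val)
        if len(t) != len(v):
            raise ValueError("train and val curves must have equal length")
        if len(t) and (not np.isfinite(t).all() or not np.isfinite(v).all()):
            raise ValueError("loss values must be finite")
        if len(t) and (t.min() < 0 or v.min() < 0):
            raise ValueError("loss values must be non-negative")


@dataclass(frozen=True)
class SplitPlan:
    test_subject: str
    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    excluded_augmented: tuple[str, ...]


@dataclass(frozen=True)
class SliceSample:
    """One axial slice: 2D image, 2D integer labels, axial-position encoding."""

    image: np.ndarray
    labels: np.ndarray
    position: SpatialEncoding
    subject_id: str = ""


# ---------------------------------------------------------------------------
# Split construction


def _provenance_rows(augmented) -> list[tuple[str, str, str]]:
    rows = []
    for a in augmented:
        if isinstance(a, PhantomSubject):
            if a.provenance is None:
                raise ValueError(f"subject {a.subject_id} has no provenance; not augmented")
            rows.append((a.subject_id, a.provenance[0], a.provenance[1]))
        else:
            sid, fixed, moving = a
            rows.append((str(sid), str(fixed), str(moving)))
    return rows


def make_split(
    originals: Sequence[str],
    augmented,
    test_subject: str,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> SplitPlan:
    """Leave-one-out split with augmented-provenance exclusion.

    ``augmented`` is a sequence of augmented :class:`PhantomSubject` or of
    ``(subject_id, fixed_id, moving_id)`` tuples.  Augmented subjects whose
    provenance names the test subject are excluded; the rest go to the
    validation set only when both parents are validation subjects,
    otherwise to training.
    """
    originals = list(originals)
    if test_subject not in originals:
        raise ValueError(f"test subject {test_subject!r} not among originals")
    if len(originals) < 3:
        raise ValueError("need at least 3 original subjects to form train/val/test")
    rest = [o for o in originals if o != test_subject]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    n_val = max(1, round(val_fraction * len(rest)))
    val = [rest[i] for i in order[:n_val]]
    train = [rest[i] for i in order[n_val:]]

    rows = _provenance_rows(augmented)
    excluded, aug_train, aug_val = [], [], []
    for sid, fixed, moving in rows:
        if test_subject in (fixed, moving):
            excluded.append(sid)
        elif fixed in val and moving in val:
            aug_val.append(sid)
        else:
            aug_train.append(sid)
    return SplitPlan(
        test_subject=test_subject,
        train_subjects=tuple(train + aug_train),
        val_subjects=tuple(val + aug_val),
        excluded_augmented=tuple(excluded),
    )


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant learning rate for a 1-based epoch index."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside 1..{config.epochs}")
    for threshold, rate in config.lr_stages:
        if epoch <= threshold:
            return rate
    return config.lr_stages[-1][1]


# ---------------------------------------------------------------------------
# Slice streams


def slice_stream(
    subjects: Sequence[PhantomSubject],
    nodes: int = 100,
    slice_step: int = 1,
) -> list[SliceSample]:
    """Flatten subjects into per-slice training samples with position encodings.

    ``slice_step`` subsamples the axial axis (every ``slice_step``-th slice),
    a desk-scale cost control; position encodings always reference the full
    slice count so positions stay calibrated.
    """
    samples = []
    for s in subjects:
        nz = s.image.shape[0]
        for z in range(0, nz, slice_step):
            samples.append(
                SliceSample(
                    image=s.image.voxels[z],
                    labels=s.labels.labels[z],
                    position=spatial_encoding(z, nz, nodes),
                    subject_id=s.subject_id,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# Losses


def _cross_entropy_from_logits(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel CE and d(loss)/d(logits) for plain softmax outputs."""
    probs = softmax_channels(logits)
    t = targets[:, None, :, :]
    p_t = np.take_along_axis(probs, t, axis=1)
    loss = float(-np.log(np.clip(p_t, 1e-12, None)).mean())
    npix = targets.size
    dlogits = probs
    np.put_along_axis(dlogits, t, np.take_along_axis(dlogits, t, axis=1) - 1.0, axis=1)
    dlogits /= npix
    return loss, dlogits


def _gated_cross_entropy(
    logits: np.ndarray, gates: np.ndarray, targets: np.ndarray, net: SCUNet
) -> tuple[float, np.ndarray, np.ndarray]:
    """CE on renormalised gate-weighted probabilities, with both gradients.

    The spatial gates multiply the softmax probabilities (background gate
    fixed at 1); the product is renormalised per pixel before taking the
    log-likelihood so the objective stays a proper cross entropy while
    training signal reaches the spatial layer.
    """
    eps = 1e-12
    s = softmax_channels(logits)
    if net.config.include_background_channel:
        gfull = np.concatenate([np.ones((gates.shape[0], 1), dtype=np.float32), gates], axis=1)
    else:
        gfull = gates
    u = s * gfull[:, :, None, None]
    z = u.sum(axis=1, keepdims=True)
    t = targets[:, None, :, :]
    u_t = np.take_along_axis(u, t, axis=1)
    loss = float((-np.log(np.clip(u_t, eps, None)) + np.log(np.clip(z, eps, None))).mean())
    npix = targets.size
    # d loss / d u
    du = np.empty_like(u)
    du[...] = 1.0 / np.clip(z, eps, None)
    np.put_along_axis(
        du, t, np.take_along_axis(du, t, axis=1) - 1.0 / np.clip(u_t, eps, None), axis=1
    )
    du /= npix
    ds = du * gfull[:, :, None, None]
    dg_full = (du * s).sum(axis=(2, 3))
    dgates = dg_full[:, 1:] if net.config.include_background_channel else dg_full
    # softmax backward
    dlogits = s * (ds - (ds * s).sum(axis=1, keepdims=True))
    return loss, dlogits, dgates.astype(np.float32)


def _batch_arrays(samples: Sequence[SliceSample], idx: np.ndarray):
    x = np.stack([samples[i].image for i in idx])[:, None, :, :]
    y = np.stack([samples[i].labels for i in idx]).astype(np.intp)
    pos = np.stack([samples[i].position.vector for i in idx])
    return x, y, pos


def _eval_loss(network: Network, samples: Sequence[SliceSample], batch_size: int) -> float:
    losses, weights = [], []
    for start in range(0, len(samples), batch_size):
        idx = np.arange(start, min(start + batch_size, len(samples)))
        x, y, pos = _batch_arrays(samples, idx)
        if isinstance(network, SCUNet):
            logits, gates = network.forward(x, pos, train=False)
            loss, _, _ = _gated_cross_entropy(logits, gates, y, network)
        else:
            logits = network.forward(x, train=False)
            loss, _ = _cross_entropy_from_logits(logits, y)
        losses.append(loss)
        weights.append(len(idx))
    return float(np.average(losses, weights=weights))


def train_model(
    network: Network,
    train_samples: Sequence[SliceSample],
    val_samples: Sequence[SliceSample],
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[Network, LossCurve]:
    """Mini-batch Adam training of per-pixel cross entropy.

    Returns the trained network and the per-epoch loss curve.  Deterministic
    given ``config.seed`` and fixed thread settings.
    """
    if not train_samples or not val_samples:
        raise ValueError("training and validation streams must be non-empty")
    if not network.config.include_background_channel:
        raise ValueError("training requires the explicit background channel")
    opt = Adam(network.parameters())
    rng = np.random.default_rng(config.seed)
    n = len(train_samples)
    train_curve, val_curve = [], []
    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(epoch, config)
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x, y, pos = _batch_arrays(train_samples, idx)
            opt.zero_grad()
            if isinstance(network, SCUNet):
                logits, gates = network.forward(x, pos, train=True)
                loss, dlogits, dgates = _gated_cross_entropy(logits, gates, y, network)
                network.backward(dlogits, dgates)
            else:
                logits = network.forward(x, train=True)
                loss, dlogits = _cross_entropy_from_logits(logits, y)
                network.backward(dlogits)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.step(lr)
            batch_losses.append(loss)
        train_curve.append(float(np.mean(batch_losses)))
        val_curve.append(_eval_loss(network, val_samples, config.batch_size))
        if verbose:
            print(
                f"epoch {epoch:3d}/{config.epochs}  lr {lr:.4g}  "
                f"train {train_curve[-1]:.4f}  val {val_curve[-1]:.4f}"
            )
    return network, LossCurve(train=train_curve, val=val_curve)


def check_convergence(curve: LossCurve, window: int, tol: float = 0.01) -> bool:
    """Has the validation loss plateaued over the last ``window`` epochs?

    Compares the mean validation loss over the final window against the
    mean over the preceding window; converged when the relative change is
    below ``tol``.
    """
    v = np.asarray(curve.val, dtype=float)
    if window < 1 or 2 * window > len(v):
        raise ValueError(f"window {window} needs a curve of length >= {2 * window}")
    recent = v[-window:].mean()
    previous = v[-2 * window : -window].mean()
    denom = max(abs(previous), 1e-12)
    return bool(abs(recent - previous) / denom < tol)
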