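"""3D conditional GAN for CT-less attenuation correction.

Two translation modes share one architecture family:

* ``indirect`` — NAC reconstruction -> attenuation map (the estimated
  mu-map is then fed back into OS-EM for the actual correction);
  3 encoder levels, no skip connections (the NAC image and the mu-map
  differ too much structurally for identity shortcuts to help).
* ``direct`` — NAC reconstruction -> attenuation-corrected image;
  2 encoder levels with U-Net skip connections.

The generator is a U-Net (3x3x3 conv + batch-norm + LeakyReLU blocks,
2x2x2 max-pool encoder, nearest-neighbour upsampling decoder, 50 % dropout
in the bottleneck, near-non-negative output head clamped to zero at
inference).  A conditional CNN
discriminator sees the input concatenated with the real or generated
target and is trained with cross-entropy; the generator optimizes the
non-saturating adversarial term plus ``lambda_l1`` (default 20) times the
L1 reconstruction loss:

    G* = argmin_G max_D  V_LD(G, D) + lambda * V_L1(G)

Training uses Adam (initial learning rate 0.001, halved on validation
plateau), whole volumes rather than patches, and horizontal/vertical flip
augmentation (3x the training set).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .volume import ValidationError, Volume3D

__all__ = [
    "CganConfig",
    "TrainedGenerator",
    "NormRecord",
    "build_generator",
    "build_discriminator",
    "normalize_unit",
    "augment_flips",
    "train_cgan",
    "predict",
    "ScannerDataset",
    "split_dataset",
    "run_training_regime",
    "RegimeResult",
]

_MODE_DEPTH = {"indirect": 3, "direct": 2}
_MODE_SKIP = {"indirect": False, "direct": True}


@dataclass
class CganConfig:
    """Hyperparameters; defaults follow the clinical training recipe.

    ``encoder_depth`` and ``use_skip`` default per mode (3 layers without
    skips for indirect, 2 with skips for direct); overriding ``use_skip``
    against the mode rule emits a warning.  ``desk_preset`` shrinks the
    network and schedule to CPU test scale.
    """

    mode: str = "indirect"
    encoder_depth: int | None = None
    base_features: int = 48
    use_skip: bool | None = None
    dropout_rate: float = 0.5
    lambda_l1: float = 20.0
    lr_init: float = 1e-3
    max_epochs: int = 400
    batch_size: int = 2
    seed: int = 0
    desk_preset: bool = False
    early_stop_patience: int = 20
    lr_patience: int = 10
    min_delta: float = 1e-5
    #: discriminator learning rate as a fraction of ``lr_init``; a slower
    #: discriminator keeps the adversarial game stable on small cohorts
    disc_lr_fraction: float = 0.25
    #: generator updates use the L1 term alone for this many initial
    #: epochs; engaging the adversarial term once the generator produces
    #: plausible volumes avoids early collapse on sparse targets
    adversarial_warmup_epochs: int = 2

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEPTH:
            raise ValidationError(f"mode must be 'indirect' or 'direct', got {self.mode!r}")
        if self.lambda_l1 <= 0:
            raise ValidationError("lambda_l1 must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.encoder_depth is None:
            self.encoder_depth = _MODE_DEPTH[self.mode]
        if self.use_skip is None:
            self.use_skip = _MODE_SKIP[self.mode]
        elif self.use_skip != _MODE_SKIP[self.mode]:
            warnings.warn(
                f"use_skip={self.use_skip} overrides the {self.mode}-mode convention",
                stacklevel=2,
            )
        if self.desk_preset:
            if self.base_features == 48:
                self.base_features = 8
            if self.max_epochs == 400:
                self.max_epochs = 20

    @classmethod
    def desk(cls, mode: str, **kw) -> "CganConfig":
        return cls(mode=mode, desk_preset=True, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in vars(self)}


# ----------------------------------------------------------------- models

class _ConvBlock(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.conv = nn.Conv3d(c_in, c_out, rng)
        self.bn = nn.BatchNorm3d(c_out)

    def __call__(self, x):
        return nn.leaky_relu(self.bn(self.conv(x)), 0.2)


class Generator(nn.Module):
    """U-Net generator; dropout noise is drawn from ``self.rng``."""

    def __init__(self, cfg: CganConfig, rng: np.random.Generator):
        d, b = cfg.encoder_depth, cfg.base_features
        self.cfg = cfg
        self.rng = rng
        chans = [b * 2**i for i in range(d)]
        self.enc = [
            _ConvBlock(1 if i == 0 else chans[i - 1], chans[i], rng) for i in range(d)
        ]
        self.bottleneck = _ConvBlock(chans[-1], 2 * chans[-1], rng)
        self.dec = []
        up_in = 2 * chans[-1]
        for i in reversed(range(d)):
            c_in = up_in + (chans[i] if cfg.use_skip else 0)
            self.dec.append(_ConvBlock(c_in, chans[i], rng))
            up_in = chans[i]
        self.head = nn.Conv3d(chans[0], 1, rng, kernel=1)
        # small positive bias keeps the ReLU output head live at start
        self.head.bias.data[:] = 0.05

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        d = self.cfg.encoder_depth
        n_spatial = x.shape[2]
        if n_spatial % 2**d:
            raise ValidationError(
                f"matrix size {n_spatial} not divisible by 2^depth={2**d}"
            )
        skips = []
        h = x
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = nn.max_pool2(h)
        h = self.bottleneck(h)
        h = nn.dropout(h, self.cfg.dropout_rate, self.rng, self.training)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = nn.upsample2(h)
            if self.cfg.use_skip:
                h = nn.concat(h, skip, axis=1)
            h = blk(h)
        # near-non-negative output: a tiny negative slope keeps gradients
        # alive in zero regions; inference clamps at exactly zero
        return nn.leaky_relu(self.head(h), 0.01)

    def recalibrate_batchnorm(self, volumes: list[np.ndarray], batch_size: int = 2) -> None:
        """Re-estimate batch-norm running statistics with dropout disabled.

        Training statistics are collected under bottleneck dropout; at
        inference dropout is off, so the activation distributions shift.
        A calibration pass over the training inputs with dropout disabled
        and cumulative-average momentum removes that mismatch.
        """
        bns = [m for m in self.modules() if isinstance(m, nn.BatchNorm3d)]
        saved_dropout = self.cfg.dropout_rate
        self.cfg.dropout_rate = 0.0
        self.set_training(True)
        for bn in bns:
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 0.0
        try:
            for t, start in enumerate(range(0, len(volumes), batch_size), start=1):
                for bn in bns:
                    bn.momentum = 1.0 / t  # cumulative average
                batch = np.stack(volumes[start : start + batch_size])[:, None]
                self(nn.Tensor(batch))
        finally:
            self.cfg.dropout_rate = saved_dropout
            for bn in bns:
                bn.momentum = 0.1
            self.set_training(False)

    def describe(self) -> dict:
        d, b = self.cfg.encoder_depth, self.cfg.base_features
        return {
            "mode": self.cfg.mode,
            "encoder_depth": d,
            "base_features": b,
            "skip_connections": bool(self.cfg.use_skip),
            "n_parameters": self.n_parameters(),
            "blocks": (
                [f"enc{i}: conv3x3x3({blk.conv.weight.shape[1]}->{blk.conv.weight.shape[0]}) "
                 f"+ BN + LeakyReLU + maxpool2" for i, blk in enumerate(self.enc)]
                + [f"bottleneck: conv({self.bottleneck.conv.weight.shape[1]}->"
                   f"{self.bottleneck.conv.weight.shape[0]}) + dropout({self.cfg.dropout_rate})"]
                + [f"dec{i}: upsample2 + "
                   + ("concat(skip) + " if self.cfg.use_skip else "")
                   + f"conv({blk.conv.weight.shape[1]}->{blk.conv.weight.shape[0]})"
                   for i, blk in enumerate(self.dec)]
                + ["head: conv1x1x1 -> ReLU"]
            ),
        }


class Discriminator(nn.Module):
    """Conditional CNN discriminator: 4 strided conv blocks, global mean
    pooling, scalar real/fake logit.

    No normalization layers: real and generated candidates pass through
    in separate batches, so batch statistics would leak the label.
    """

    def __init__(self, cfg: CganConfig, rng: np.random.Generator):
        b = cfg.base_features
        chans = [b, 2 * b, 4 * b, 8 * b]
        self.blocks = []
        c_in = 2  # condition + candidate
        for c in chans:
            self.blocks.append(nn.Conv3d(c_in, c, rng, stride=2))
            c_in = c
        self.fc = nn.Dense(chans[-1], 1, rng)

    def logits(self, condition: nn.Tensor, candidate: nn.Tensor) -> nn.Tensor:
        h = nn.concat(condition, candidate, axis=1)
        for blk in self.blocks:
            h = nn.leaky_relu(blk(h), 0.2)
        return self.fc(nn.global_mean(h))

    def __call__(self, condition: nn.Tensor, candidate: nn.Tensor) -> nn.Tensor:
        return nn.sigmoid(self.logits(condition, candidate))


def build_generator(cfg: CganConfig) -> Generator:
    """Deterministically build the generator from its config (seeded by
    ``cfg.seed``)."""
    return Generator(cfg, np.random.default_rng(cfg.seed))


def build_discriminator(cfg: CganConfig) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng(cfg.seed + 1))


# ------------------------------------------------------------ data plumbing

@dataclass(frozen=True)
class NormRecord:
    """Unit-interval normalization record; ``constant`` flags degenerate
    input (mapped to all zeros)."""

    lo: float
    hi: float
    constant: bool = False

    def apply(self, arr: np.ndarray) -> np.ndarray:
        if self.constant:
            return np.zeros_like(arr)
        return (arr - self.lo) / (self.hi - self.lo)

    def invert(self, arr: np.ndarray) -> np.ndarray:
        if self.constant:
            return np.full_like(arr, self.lo)
        return arr * (self.hi - self.lo) + self.lo


def normalize_unit(vol: Volume3D | np.ndarray) -> tuple[np.ndarray, NormRecord]:
    """Scale a non-negative volume to [0, 1] (min -> 0, max -> 1).

    A constant volume maps to all zeros and is flagged in the record.
    """
    arr = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr), NormRecord(lo, hi, constant=True)
    rec = NormRecord(lo, hi)
    return rec.apply(arr), rec


def _pair_arrays(pair) -> tuple[np.ndarray, np.ndarray]:
    x, y = pair
    x = x.data if isinstance(x, Volume3D) else np.asarray(x)
    y = y.data if isinstance(y, Volume3D) else np.asarray(y)
    return x, y


def augment_flips(pairs: list) -> list:
    """Originals + horizontal (x) flips + vertical (y) flips: 3x the data.

    Inputs and targets of each pair are flipped identically.
    """
    pairs = [_pair_arrays(p) for p in pairs]
    out = list(pairs)
    for axis in (0, 1):
        out.extend((np.flip(x, axis).copy(), np.flip(y, axis).copy()) for x, y in pairs)
    return out


# ---------------------------------------------------------------- training

@dataclass
class TrainedGenerator:
    """A trained translation model plus everything needed for inference.

    ``target_scale`` is the global factor that mapped training targets
    into [0, 1] (indirect mode: the cohort-maximum attenuation
    coefficient); predictions are multiplied back by it.
    """

    mode: str
    generator: Generator
    input_norm: str  # "per_volume_unit" (indirect) or "none" (direct)
    history: pd.DataFrame
    step_history: pd.DataFrame
    config: CganConfig
    train_shape: tuple[int, int, int]
    target_scale: float = 1.0

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.generator.state_arrays())
        sidecar = {
            "mode": self.mode,
            "input_norm": self.input_norm,
            "target_scale": self.target_scale,
            "train_shape": list(self.train_shape),
            "config": {k: v for k, v in self.config.to_dict().items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedGenerator":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = CganConfig(**meta["config"])
        gen = build_generator(cfg)
        gen.load_state_arrays(dict(np.load(path)))
        hist_path = path.with_suffix(".history.csv")
        hist = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        return cls(meta["mode"], gen, meta["input_norm"], hist, pd.DataFrame(),
                   cfg, tuple(meta["train_shape"]), meta.get("target_scale", 1.0))


def _prepare_inputs(arrs: list[np.ndarray], scheme: str) -> list[np.ndarray]:
    if scheme == "per_volume_unit":
        return [normalize_unit(a)[0] for a in arrs]
    return arrs


def train_cgan(
    pairs: list,
    cfg: CganConfig,
    val_pairs: list | None = None,
    seed: int | None = None,
) -> TrainedGenerator:
    """Train the conditional GAN with alternating discriminator/generator
    updates.

    Indirect mode normalizes each input NAC volume to [0, 1] (targets stay
    in cm^-1); direct mode trains on raw counts to keep them invariable.
    Per-step losses are logged with the exact decomposition
    ``g_total = g_adv + lambda_l1 * g_l1``; training aborts on NaN and can
    stop early on a validation-L1 plateau.
    """
    if not pairs:
        raise ValidationError("need at least one training pair")
    seed = cfg.seed if seed is None else seed
    cfg = replace(cfg, seed=seed)
    scheme = "per_volume_unit" if cfg.mode == "indirect" else "none"
    xs, ys = zip(*(_pair_arrays(p) for p in pairs))
    xs = _prepare_inputs(list(xs), scheme)
    ys = list(ys)
    # indirect mode: bring mu targets onto the [0, 1] input scale so the
    # L1 and adversarial terms stay balanced at lambda = 20
    target_scale = 1.0
    if cfg.mode == "indirect":
        target_scale = max(float(y.max()) for y in ys) or 1.0
        ys = [y / target_scale for y in ys]
    shape = xs[0].shape
    if any(x.shape != shape or y.shape != shape for x, y in zip(xs, ys)):
        raise ValidationError("all training volumes must share one grid")

    gen = build_generator(cfg)
    disc = build_discriminator(cfg)
    rng = np.random.default_rng(seed + 2)  # shuffling + dropout
    gen.rng = rng
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_init, clip_norm=10.0)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr_init * cfg.disc_lr_fraction,
                    clip_norm=10.0)

    val_xy = None
    if val_pairs:
        vx, vy = zip(*(_pair_arrays(p) for p in val_pairs))
        val_xy = (_prepare_inputs(list(vx), scheme),
                  [y / target_scale for y in vy])

    lam = cfg.lambda_l1
    epoch_rows, step_rows = [], []
    best_val, best_epoch = np.inf, -1
    lr_wait = 0
    n = len(xs)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_g_total = ep_g_adv = ep_g_l1 = ep_d = 0.0
        n_steps = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = nn.Tensor(np.stack([xs[i] for i in idx])[:, None])
            yb = nn.Tensor(np.stack([ys[i] for i in idx])[:, None])

            fake = gen(xb)

            # discriminator step: real and detached fake pairs in one batch
            cond2 = nn.Tensor(np.concatenate([xb.data, xb.data]))
            cand2 = nn.Tensor(np.concatenate([yb.data, fake.data]))
            targets = np.concatenate([
                np.ones((len(idx), 1)), np.zeros((len(idx), 1))
            ])
            d_loss = nn.bce_with_logits(disc.logits(cond2, cand2), targets)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator step: non-saturating adversarial + lambda * L1
            # (adversarial term zero-weighted during warm-up epochs)
            g_adv = nn.bce_with_logits(disc.logits(xb, fake), 1.0)
            g_l1 = nn.mean_abs_diff(fake, yb)
            warm = epoch < cfg.adversarial_warmup_epochs
            g_total = nn.add(nn.scale(g_adv, 0.0 if warm else 1.0),
                             nn.scale(g_l1, lam))
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard D grads from this pass
            g_total.backward()
            opt_g.step()

            vals = (g_total.item(), g_adv.item(), g_l1.item(), d_loss.item())
            if not all(np.isfinite(v) for v in vals):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: total={vals[0]}, adv={vals[1]}, "
                    f"l1={vals[2]}, d={vals[3]}; lower the learning rate"
                )
            step_rows.append((epoch, 0.0 if warm else 1.0, vals[1], vals[2],
                              lam, vals[0], vals[3]))
            ep_g_total += vals[0]; ep_g_adv += vals[1]
            ep_g_l1 += vals[2]; ep_d += vals[3]
            n_steps += 1

        val_l1 = np.nan
        if val_xy is not None:
            # quick running-stat refresh so validation sees inference conditions
            gen.recalibrate_batchnorm(xs[: min(n, 4)], cfg.batch_size)
            val_l1 = float(np.mean([
                np.abs(_infer(gen, x) - y).mean() for x, y in zip(*val_xy)
            ]))
            gen.set_training(True)
        epoch_rows.append((epoch, ep_g_total / n_steps, ep_g_adv / n_steps,
                           ep_g_l1 / n_steps, ep_d / n_steps, val_l1, opt_g.lr))

        monitor = val_l1 if val_xy is not None else ep_g_l1 / n_steps
        if monitor < best_val - cfg.min_delta:
            best_val, best_epoch = monitor, epoch
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait >= cfg.lr_patience:
                opt_g.lr *= 0.5
                opt_d.lr *= 0.5
                lr_wait = 0
            if epoch - best_epoch >= cfg.early_stop_patience:
                break

    gen.recalibrate_batchnorm(xs, cfg.batch_size)
    history = pd.DataFrame(
        epoch_rows,
        columns=["epoch", "g_total", "g_adv", "g_l1", "d_loss", "val_l1", "lr"],
    )
    steps = pd.DataFrame(
        step_rows,
        columns=["epoch", "adv_weight", "g_adv", "g_l1", "lambda_l1", "g_total",
                 "d_loss"],
    )
    return TrainedGenerator(cfg.mode, gen, scheme, history, steps, cfg, shape,
                            target_scale)


def _infer(gen: Generator, x: np.ndarray) -> np.ndarray:
    out = gen(nn.Tensor(x[None, None]))
    return out.data[0, 0].astype(np.float64)


def predict(model: TrainedGenerator, nac: Volume3D) -> Volume3D:
    """Apply a trained model to a NAC reconstruction.

    Indirect models return a mu-map in cm^-1 (ready for OS-EM); direct
    models return an attenuation-corrected image in count units.
    Inference is deterministic (no dropout, running batch-norm statistics).
    """
    if nac.shape != tuple(model.train_shape):
        raise ValidationError(
            f"input grid {nac.shape} does not match training grid {model.train_shape}"
        )
    model.generator.set_training(False)
    x = nac.data
    if model.input_norm == "per_volume_unit":
        x, _ = normalize_unit(x)
    out = _infer(model.generator, x) * model.target_scale
    unit = "cm^-1" if model.mode == "indirect" else "counts"
    return Volume3D(np.maximum(out, 0.0), nac.voxel_size_cm, unit)


# ----------------------------------------------------------------- regimes

@dataclass
class ScannerDataset:
    """Train/validation/test pairs of one scanner, with subject indices to
    assert split disjointness."""

    name: str
    train: list
    val: list
    test: list
    train_idx: list[int] = field(default_factory=list)
    val_idx: list[int] = field(default_factory=list)
    test_idx: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in (("train_idx", "val_idx"), ("train_idx", "test_idx"),
                     ("val_idx", "test_idx")):
            if set(getattr(self, a)) & set(getattr(self, b)):
                raise ValidationError(f"{a} and {b} overlap in scanner {self.name}")


def split_dataset(name: str, pairs: list, sizes: tuple[int, int, int] = (90, 10, 30)
                  ) -> ScannerDataset:
    """Split subject pairs into train/validation/test (clinical default
    90/10/30)."""
    n_tr, n_va, n_te = sizes
    if len(pairs) < n_tr + n_va + n_te:
        raise ValidationError(
            f"need {n_tr + n_va + n_te} pairs for split {sizes}, got {len(pairs)}"
        )
    idx = list(range(len(pairs)))
    return ScannerDataset(
        name,
        [pairs[i] for i in idx[:n_tr]],
        [pairs[i] for i in idx[n_tr : n_tr + n_va]],
        [pairs[i] for i in idx[n_tr + n_va : n_tr + n_va + n_te]],
        idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va : n_tr + n_va + n_te],
    )


@dataclass
class RegimeResult:
    regime: str
    models: dict[str, TrainedGenerator]
    assignment: dict[str, str]  # scanner name -> model key
    train_sizes: dict[str, int]


def run_training_regime(
    datasets: dict[str, ScannerDataset],
    regime: str,
    cfg: CganConfig,
) -> RegimeResult:
    """Train models under one of the three regimes.

    ``scanner_specific`` trains one model per scanner on its own data;
    ``cross_scanner`` evaluates each scanner's test set with the model
    trained on the *other* scanner; ``ensemble`` merges both training sets
    into one model.  Flip augmentation (3x) is applied in every regime.
    """
    if regime not in ("scanner_specific", "cross_scanner", "ensemble"):
        raise ValidationError(f"unknown regime {regime!r}")
    names = sorted(datasets)
    if len(names) != 2:
        raise ValidationError("exactly two scanner datasets are required")
    models: dict[str, TrainedGenerator] = {}
    assignment: dict[str, str] = {}
    train_sizes: dict[str, int] = {}
    if regime == "ensemble":
        merged = datasets[names[0]].train + datasets[names[1]].train
        merged_val = datasets[names[0]].val + datasets[names[1]].val
        aug = augment_flips(merged)
        models["ensemble"] = train_cgan(aug, cfg, val_pairs=merged_val)
        train_sizes["ensemble"] = len(aug)
        for name in names:
            assignment[name] = "ensemble"
    else:
        for name in names:
            ds = datasets[name]
            aug = augment_flips(ds.train)
            models[name] = train_cgan(aug, cfg, val_pairs=ds.val)
            train_sizes[name] = len(aug)
        for name in names:
            other = names[1] if name == names[0] else names[0]
            assignment[name] = name if regime == "scanner_specific" else other
    return RegimeResult(regime, models, assignment, train_sizes)
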