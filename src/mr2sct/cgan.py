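"""Conditional GAN for MR -> synthetic-CT translation.

A U-Net generator maps a 3-channel MR patch (T1w, T2w, FLAIR, standardized to
[0, 4095]) to a single-channel CT patch; a PatchGAN discriminator scores
(MR, CT) pairs patch-wise. The generator objective is the adversarial binary
cross-entropy plus lambda_L1 times the L1 term; evaluation MAE is the plain
voxel-wise mean absolute error in HU.

Both networks are fully convolutional: a model trained on small patches runs
unchanged on full-size slices at inference time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn
from .errors import DivergenceError
from .preprocess import PatchPair
from .volume import ImageVolume, MultiSequenceVolume

MR_SCALE = 4095.0  # standardized MR range mapped to [-1, 1]


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    out_channels: int = 1
    depth: int = 5
    base_width: int = 64
    norm: bool = True
    hu_min: float = -1024.0
    hu_max: float = 3071.0
    max_width_mult: int = 8

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("generator depth must be >= 2")
        if self.hu_max <= self.hu_min:
            raise ValueError("hu_max must exceed hu_min")

    def width(self, level: int) -> int:
        return self.base_width * min(2**level, self.max_width_mult)

    @property
    def hu_center(self) -> float:
        return (self.hu_max + self.hu_min) / 2.0

    @property
    def hu_halfrange(self) -> float:
        return (self.hu_max - self.hu_min) / 2.0


@dataclass
class DiscriminatorConfig:
    receptive_field: int = 32
    base_width: int = 64
    in_channels: int = 4  # 3 MR condition channels + 1 CT candidate
    max_width_mult: int = 8

    def __post_init__(self):
        if self.receptive_field < 4:
            raise ValueError("receptive field must be >= 4")


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 32
    lambda_l1: float = 100.0
    lr: float = 2e-4
    beta1: float = 0.5
    seed: int = 0
    patch_side: int = 128
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


def desk_profile() -> tuple[GeneratorConfig, DiscriminatorConfig, TrainConfig]:
    """Small test-scale profile: depth-3/width-16 generator, 64 px patches.

    The optimizer runs hotter than the full-scale profile (lr 1e-3, batch 16)
    so the small network actually converges within its 50-epoch budget.
    """
    return (
        GeneratorConfig(depth=3, base_width=16),
        DiscriminatorConfig(receptive_field=32, base_width=16),
        TrainConfig(epochs=50, batch_size=16, lr=1e-3, patch_side=64),
    )


def paper_profile() -> tuple[GeneratorConfig, DiscriminatorConfig, TrainConfig]:
    """Full-scale profile: depth-5/width-64 generator, 128 px patches."""
    return (GeneratorConfig(), DiscriminatorConfig(), TrainConfig())


def hu_from_norm(y: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    return cfg.hu_center + cfg.hu_halfrange * y


def norm_from_hu(hu: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    return np.clip((hu - cfg.hu_center) / cfg.hu_halfrange, -1.0, 1.0)


def norm_from_mr(mr: np.ndarray) -> np.ndarray:
    return mr / (MR_SCALE / 2.0) - 1.0


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class UNetGenerator:
    """Encoder of strided 4x4 convolutions (batch norm except the first level,
    LeakyReLU 0.2), decoder of transposed convolutions (batch norm + ReLU)
    with skip connections, final tanh. Output lives on the normalized [-1, 1]
    scale; :func:`hu_from_norm` converts to Hounsfield units."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        d = cfg.depth
        self.enc_convs, self.enc_bns = [], []
        cin = cfg.in_channels
        for i in range(d):
            self.enc_convs.append(nn.Conv2d(cin, cfg.width(i), 4, 2, 1, rng=rng))
            self.enc_bns.append(nn.BatchNorm2d(cfg.width(i)) if (cfg.norm and i > 0) else None)
            cin = cfg.width(i)
        # decoder block t consumes encoder level (d-1-t); the last block emits
        # the output channel through tanh
        self.dec_convs, self.dec_bns = [], []
        for t in range(d):
            level = d - 1 - t
            in_ch = cfg.width(level) if t == 0 else 2 * cfg.width(level)
            out_ch = cfg.out_channels if level == 0 else cfg.width(level - 1)
            self.dec_convs.append(nn.ConvTranspose2d(in_ch, out_ch, 4, 2, 1, rng=rng))
            self.dec_bns.append(nn.BatchNorm2d(out_ch) if (cfg.norm and level > 0) else None)
        self.tanh = nn.Tanh()

    def param_layers(self):
        layers = list(self.enc_convs) + list(self.dec_convs)
        layers += [bn for bn in self.enc_bns + self.dec_bns if bn is not None]
        return layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels")
        div = 2**self.cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input sides must be divisible by 2^depth={div}, got {x.shape[2:]}"
            )
        d = self.cfg.depth
        self._enc_masks = []
        encs = []
        h = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = conv.forward(h, train)
            if bn is not None:
                h = bn.forward(h, train)
            mask = h > 0
            self._enc_masks.append(mask)
            h = np.where(mask, h, 0.2 * h)
            encs.append(h)
        self._skip_channels = [e.shape[1] for e in encs]
        self._dec_masks = []
        for t, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            level = d - 1 - t
            h = encs[d - 1] if t == 0 else np.concatenate([encs[level], h], axis=1)
            h = conv.forward(h, train)
            if bn is not None:
                h = bn.forward(h, train)
                mask = h > 0
                self._dec_masks.append(mask)
                h = np.where(mask, h, 0.0)
            else:
                self._dec_masks.append(None)
        return self.tanh.forward(h, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        skip_grads: list = [None] * d
        g = self.tanh.backward(dout)
        for t in reversed(range(d)):
            level = d - 1 - t
            conv, bn, mask = self.dec_convs[t], self.dec_bns[t], self._dec_masks[t]
            if bn is not None:
                g = np.where(mask, g, 0.0)
                g = bn.backward(g)
            g = conv.backward(g)  # gradient w.r.t. this block's input
            if t == 0:
                skip_grads[d - 1] = _acc(skip_grads[d - 1], g)
            else:
                cskip = self._skip_channels[level]
                skip_grads[level] = _acc(skip_grads[level], g[:, :cskip])
                g = np.ascontiguousarray(g[:, cskip:])  # w.r.t. block t-1 output
        # encoder chain: total gradient at each level = skip + deeper chain
        g = None
        for i in reversed(range(d)):
            g = skip_grads[i] if g is None else skip_grads[i] + g if skip_grads[i] is not None else g
            mask = self._enc_masks[i]
            g = np.where(mask, g, 0.2 * g)
            if self.enc_bns[i] is not None:
                g = self.enc_bns[i].backward(g)
            g = self.enc_convs[i].backward(g)
        return g


def _acc(a, b):
    if b is None:
        return a
    return b if a is None else a + b


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    """He-initialized U-Net generator (biases zero)."""
    return UNetGenerator(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

def _disc_layer_specs(receptive_field: int) -> list[tuple[int, int]]:
    """(kernel, stride) stack whose per-unit receptive field is closest to the
    requested value: n strided 4x4 convolutions, one unit-stride 4x4, and the
    unit-stride 4x4 output head. n=1/2/3 give fields of 16/34/70 px."""

    def rf(specs):
        r = 1
        for k, s in reversed(specs):
            r = r * s + (k - s)
        return r

    best = None
    for n in range(1, 5):
        specs = [(4, 2)] * n + [(4, 1), (4, 1)]
        err = abs(rf(specs) - receptive_field)
        if best is None or err < best[0]:
            best = (err, specs)
    return best[1]


def receptive_field_of(specs: list[tuple[int, int]]) -> int:
    r = 1
    for k, s in reversed(specs):
        r = r * s + (k - s)
    return r


class PatchDiscriminator:
    """PatchGAN: maps the channel-concatenated (MR condition, CT candidate)
    image to a grid of real/fake logits, one per receptive-field patch."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.layer_specs = _disc_layer_specs(cfg.receptive_field)
        layers: list = []
        cin = cfg.in_channels
        for idx, (k, s) in enumerate(self.layer_specs):
            last = idx == len(self.layer_specs) - 1
            cout = 1 if last else cfg.base_width * min(2**idx, cfg.max_width_mult)
            layers.append(nn.Conv2d(cin, cout, k, s, 1, rng=rng))
            if not last:
                if idx > 0:
                    layers.append(nn.BatchNorm2d(cout))
                layers.append(nn.LeakyReLU(0.2))
            cin = cout
        self.net = nn.Sequential(layers)

    @property
    def receptive_field(self) -> int:
        return receptive_field_of(self.layer_specs)

    def param_layers(self):
        return self.net.param_layers()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if min(x.shape[2], x.shape[3]) < self.receptive_field:
            raise ValueError(
                f"discriminator receptive field {self.receptive_field} exceeds "
                f"input side {min(x.shape[2], x.shape[3])}"
            )
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(rct, sct) -> float:
    """Voxel-wise mean absolute error (1/n) * sum |rCT_i - sCT_i| in HU."""
    a = rct.data if isinstance(rct, ImageVolume) else np.asarray(rct, dtype=float)
    b = sct.data if isinstance(sct, ImageVolume) else np.asarray(sct, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))))


def adversarial_losses(d_scores_real: np.ndarray, d_scores_fake: np.ndarray):
    """(discriminator loss, generator adversarial loss) from logit grids.

    Discriminator: mean of BCE(real -> 1) and BCE(fake -> 0); generator:
    BCE(fake -> 1). Sigmoid BCE with logits throughout.
    """
    loss_r, _ = nn.bce_with_logits(d_scores_real, 1.0)
    loss_f, _ = nn.bce_with_logits(d_scores_fake, 0.0)
    gen_adv, _ = nn.bce_with_logits(d_scores_fake, 1.0)
    return 0.5 * (loss_r + loss_f), gen_adv


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    folds: list
    seed: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_cv_folds(ids: list, k: int, seed: int = 0) -> FoldSplit:
    """Randomly partition dataset IDs into k near-equal disjoint folds."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of ids ({len(ids)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [order[i::k] for i in range(k)]
    return FoldSplit(folds, seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    train_cfg: TrainConfig
    history: pd.DataFrame

    def save(self, path: str) -> None:
        arrays, meta = {}, {"layers": []}
        for net, prefix in ((self.generator, "g"), (self.discriminator, "d")):
            for i, layer in enumerate(net.param_layers()):
                for k, v in layer.params.items():
                    arrays[f"{prefix}{i}_{k}"] = v
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"{prefix}{i}_rmean"] = layer.running_mean
                    arrays[f"{prefix}{i}_rvar"] = layer.running_var
        meta["gen_cfg"] = asdict(self.gen_cfg)
        meta["disc_cfg"] = asdict(self.disc_cfg)
        meta["train_cfg"] = asdict(self.train_cfg)
        meta["history"] = self.history.to_dict(orient="list")
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        gen_cfg = GeneratorConfig(**meta["gen_cfg"])
        disc_cfg = DiscriminatorConfig(**meta["disc_cfg"])
        train_cfg = TrainConfig(**meta["train_cfg"])
        gen = build_generator(gen_cfg, seed=0)
        disc = build_discriminator(disc_cfg, seed=0)
        for net, prefix in ((gen, "g"), (disc, "d")):
            for i, layer in enumerate(net.param_layers()):
                for k in layer.params:
                    layer.params[k][...] = arrays[f"{prefix}{i}_{k}"]
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = arrays[f"{prefix}{i}_rmean"]
                    layer.running_var[...] = arrays[f"{prefix}{i}_rvar"]
        history = pd.DataFrame(meta["history"])
        return cls(gen, disc, gen_cfg, disc_cfg, train_cfg, history)


def _patch_arrays(patches: list[PatchPair], gen_cfg: GeneratorConfig):
    X = np.stack([norm_from_mr(p.mr) for p in patches]).astype(nn.DTYPE)
    Y = np.stack([norm_from_hu(p.ct, gen_cfg)[None] for p in patches]).astype(nn.DTYPE)
    return X, Y


def train_cgan(
    patches: list[PatchPair],
    gen_cfg: GeneratorConfig,
    disc_cfg: DiscriminatorConfig,
    train_cfg: TrainConfig,
    progress: bool = False,
) -> TrainedModel:
    """Alternating discriminator/generator training on MR/CT patch pairs.

    The patch set is split 9:1 (``val_fraction``) into training and validation
    subsets, seeded. Per epoch the history records the discriminator loss, the
    generator adversarial loss and the train/validation L1 in HU. Deterministic
    for a fixed seed.
    """
    if not patches:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(train_cfg.seed)
    gen = UNetGenerator(gen_cfg, rng)
    disc = PatchDiscriminator(disc_cfg, rng)
    X, Y = _patch_arrays(patches, gen_cfg)
    m = len(patches)
    perm = rng.permutation(m)
    n_val = int(round(train_cfg.val_fraction * m)) if m > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("no training samples left after validation split")
    Xtr, Ytr, Xval, Yval = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]

    opt_g = nn.Adam(gen.param_layers(), lr=train_cfg.lr, beta1=train_cfg.beta1)
    opt_d = nn.Adam(disc.param_layers(), lr=train_cfg.lr, beta1=train_cfg.beta1)
    hu_scale = gen_cfg.hu_halfrange
    rows = []
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(Xtr))
        d_losses, g_advs, l1s = [], [], []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            fake = gen.forward(xb, train=True)

            # --- discriminator update ---
            opt_d.zero_grad()
            logits_r = disc.forward(np.concatenate([xb, yb], axis=1), train=True)
            loss_r, dzr = nn.bce_with_logits(logits_r, 1.0)
            disc.backward(0.5 * dzr)
            logits_f = disc.forward(np.concatenate([xb, fake], axis=1), train=True)
            loss_f, dzf = nn.bce_with_logits(logits_f, 0.0)
            disc.backward(0.5 * dzf)
            opt_d.step()
            d_loss = 0.5 * (loss_r + loss_f)

            # --- generator update (adversarial gradient flows through D) ---
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard G-step gradients accumulated in D
            logits_f2 = disc.forward(np.concatenate([xb, fake], axis=1), train=True)
            g_adv, dz = nn.bce_with_logits(logits_f2, 1.0)
            dx_d = disc.backward(dz)
            d_fake = dx_d[:, gen_cfg.in_channels :]
            diff = fake - yb
            g_l1 = float(np.mean(np.abs(diff)))
            d_fake = d_fake + train_cfg.lambda_l1 * np.sign(diff) / diff.size
            gen.backward(d_fake)
            opt_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_adv) and np.isfinite(g_l1)):
                raise DivergenceError(epoch)
            d_losses.append(d_loss)
            g_advs.append(g_adv)
            l1s.append(g_l1)

        val_l1 = np.nan
        if len(Xval):
            preds = []
            for start in range(0, len(Xval), train_cfg.batch_size):
                preds.append(gen.forward(Xval[start : start + train_cfg.batch_size], train=False))
            val_l1 = float(np.mean(np.abs(np.concatenate(preds) - Yval))) * hu_scale
        rows.append(
            {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)),
                "g_adv": float(np.mean(g_advs)),
                "g_l1_train": float(np.mean(l1s)) * hu_scale,
                "g_l1_val": val_l1,
            }
        )
        if progress:  # pragma: no cover - console feedback only
            r = rows[-1]
            print(
                f"epoch {epoch:3d}  d={r['d_loss']:.3f}  adv={r['g_adv']:.3f}  "
                f"L1(train)={r['g_l1_train']:.1f} HU  L1(val)={r['g_l1_val']:.1f} HU"
            )
    return TrainedModel(gen, disc, gen_cfg, disc_cfg, train_cfg, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_sct(model: TrainedModel, mr: MultiSequenceVolume, batch_slices: int = 8) -> ImageVolume:
    """Slice-wise full-size inference; geometry preserved, output in HU.

    Slice sides that are not divisible by 2^depth are reflect-padded to the
    next multiple and cropped back.
    """
    data = np.asarray(mr.data, dtype=float)
    if data.shape[0] != 3:
        raise ValueError("expected a 3-channel MultiSequenceVolume")
    cfg = model.gen_cfg
    div = 2**cfg.depth
    nz, ny, nx = data.shape[1:]
    py = (-ny) % div
    px = (-nx) % div
    x = norm_from_mr(np.moveaxis(data, 0, 1)).astype(nn.DTYPE)  # (z, 3, y, x)
    if py or px:
        x = np.pad(x, ((0, 0), (0, 0), (0, py), (0, px)), mode="reflect")
    outs = []
    for start in range(0, nz, batch_slices):
        y = model.generator.forward(x[start : start + batch_slices], train=False)
        outs.append(y[:, 0, :ny, :nx])
    hu = hu_from_norm(np.concatenate(outs, axis=0), cfg)
    return ImageVolume(hu, mr.spacing, mr.origin)
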