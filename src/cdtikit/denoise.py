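"""Tensor-to-tensor de-noising with adversarial training and ensembling.

The de-noiser maps a 6-channel grid of noisy (reduced-repetition) diffusion
tensor elements to a refined 6-channel grid.  The generator is a U-shaped
network whose blocks restrict self-attention to non-overlapping spatial
windows; it learns a residual correction added to its input, with the final
projection zero-initialized so the untrained network is exactly the
identity.  A spatial patch critic and a Wasserstein objective with gradient
penalty provide the optional adversarial term; bagging over independently
seeded members gives the ensemble.

All networks run on the package's own numpy autodiff engine
(:mod:`cdtikit._autograd`); everything runs in single precision and is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _autograd as ag
from ._autograd import Tensor, Parameter
from .phantom import TensorField
from .tensor_fit import NormalizationSpec, denormalize_tensor, normalize_tensor

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "EnsembleSpec",
    "GENERATOR_PRESETS",
    "TRAIN_PRESETS",
    "build_generator",
    "build_discriminator",
    "count_parameters",
    "wgan_gp_losses",
    "augment_sample",
    "rotation_channel_matrix",
    "split_patients",
    "TrainingSample",
    "Checkpoint",
    "train",
    "ensemble_predict",
    "denoise_field",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """U-shaped windowed-attention generator.

    ``depths`` lists attention-block counts per scale: ``levels`` encoder
    scales followed by one bottleneck entry; the decoder mirrors the encoder.
    Spatial size is preserved; input height/width must be divisible by
    ``window * 2**levels``.
    """

    in_channels: int = 6
    out_channels: int = 6
    base_width: int = 16
    depths: tuple[int, ...] = (1, 1)
    window: int = 8
    levels: int = 1
    heads: int = 2
    mlp_ratio: float = 2.0
    residual: bool = True

    def __post_init__(self) -> None:
        if len(self.depths) != self.levels + 1:
            raise ValueError("depths must list levels encoder scales + bottleneck")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Patch critic: stacked stride-2 convolutions, spatial score grid."""

    in_channels: int = 6
    base_width: int = 16
    n_stages: int = 3


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (decoupled-weight-decay Adam)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    epochs: int = 500
    batch_size: int = 8
    lambda_adv: float = 0.01
    lambda_gp: float = 10.0
    critic_steps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_gp < 0 or self.lambda_adv < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class EnsembleSpec:
    """Bagging ensemble: elementwise mean over member predictions."""

    n_members: int = 5
    member_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("need at least one ensemble member")
        if len(set(self.member_seeds)) != self.n_members:
            raise ValueError("member seeds must be distinct, one per member")


#: ``reference`` mirrors the full-scale model (~4e7 parameters); ``tiny`` is
#: the desk-scale preset used throughout the test suite (<2e5 parameters).
GENERATOR_PRESETS: dict[str, GeneratorConfig] = {
    "reference": GeneratorConfig(base_width=112, depths=(2, 2, 2, 2), window=8,
                                 levels=3, heads=8, mlp_ratio=4.0),
    "tiny": GeneratorConfig(base_width=16, depths=(1, 1), window=4, levels=1,
                            heads=2, mlp_ratio=2.0),
}

#: ``reference`` carries the full-scale optimizer settings; ``tiny`` is the
#: desk-scale schedule (higher learning rate, few epochs, supervised-only).
TRAIN_PRESETS: dict[str, TrainConfig] = {
    "reference": TrainConfig(),
    "tiny": TrainConfig(learning_rate=2e-3, epochs=20, batch_size=8,
                        lambda_adv=0.0),
}


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """kxk convolution via im2col; ``same`` padding when pad = k//2."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None,
                 zero_init: bool = False):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((c_out, fan_in))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        n, _, h, w0 = x.shape
        xp = ag.pad2d(x, self.pad)
        hp, wp = h + 2 * self.pad, w0 + 2 * self.pad
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        cols = ag.unfold(xp, self.k, self.stride)        # (n, cin*k*k, L)
        y = ag.reshape(self.w, (1, self.c_out, self.c_in * self.k * self.k)) @ cols
        y = y + ag.reshape(self.b, (1, self.c_out, 1))
        return ag.reshape(y, (n, self.c_out, ho, wo))


class LayerNorm(Module):
    """Normalization over the last axis (token channels)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = ag.tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = ag.tmean(xc * xc, axis=-1, keepdims=True)
        return xc / ag.sqrt(var + self.eps) * self.gamma + self.beta


class WindowAttention(Module):
    """Multi-head self-attention restricted to one spatial window's tokens."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("attention width must divide into heads")
        self.dim, self.heads = dim, heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        b, t, c = tokens.shape
        h, dh = self.heads, c // self.heads
        qkv = self.qkv(tokens)                                  # (b, t, 3c)
        qkv = ag.reshape(qkv, (b, t, 3, h, dh))
        qkv = ag.transpose(qkv, (2, 0, 3, 1, 4))                # (3, b, h, t, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ag.softmax((q @ ag.transpose(k, (0, 1, 3, 2))) * (dh ** -0.5))
        out = attn @ v                                          # (b, h, t, dh)
        out = ag.reshape(ag.transpose(out, (0, 2, 1, 3)), (b, t, c))
        return self.proj(out)


class LeWinBlock(Module):
    """Pre-norm windowed attention + MLP, both with residual connections."""

    def __init__(self, dim: int, heads: int, window: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.window = window
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        ws = self.window
        if h % ws or w % ws:
            raise ValueError(
                f"window size {ws} does not divide spatial size {h}x{w}"
            )
        nh, nw = h // ws, w // ws
        t = ag.transpose(x, (0, 2, 3, 1))                       # (n, h, w, c)
        t = ag.reshape(t, (n, nh, ws, nw, ws, c))
        t = ag.transpose(t, (0, 1, 3, 2, 4, 5))
        tokens = ag.reshape(t, (n * nh * nw, ws * ws, c))
        tokens = tokens + self.attn(self.norm1(tokens))
        y = self.norm2(tokens)
        tokens = tokens + self.fc2(ag.leaky_relu(self.fc1(y), 0.2))
        t = ag.reshape(tokens, (n, nh, nw, ws, ws, c))
        t = ag.transpose(t, (0, 1, 3, 2, 4, 5))
        t = ag.reshape(t, (n, h, w, c))
        return ag.transpose(t, (0, 3, 1, 2))


def _upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling from traced shape primitives."""
    n, c, h, w = x.shape
    y = ag.reshape(x, (n, c, h, 1, w, 1))
    y = ag.broadcast_to(y, (n, c, h, 2, w, 2))
    return ag.reshape(y, (n, c, 2 * h, 2 * w))


class Generator(Module):
    """U-shaped windowed-attention de-noiser with residual output."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        cfg = config
        w = cfg.base_width
        self.in_proj = Conv2d(cfg.in_channels, w, 3, rng)
        self.enc_blocks: list[list[LeWinBlock]] = []
        self.downs: list[Conv2d] = []
        widths = [w * 2 ** i for i in range(cfg.levels + 1)]
        for lvl in range(cfg.levels):
            self.enc_blocks.append([
                LeWinBlock(widths[lvl], cfg.heads, cfg.window, cfg.mlp_ratio, rng)
                for _ in range(cfg.depths[lvl])
            ])
            self.downs.append(Conv2d(widths[lvl], widths[lvl + 1], 3, rng, stride=2))
        self.mid_blocks = [
            LeWinBlock(widths[-1], cfg.heads, cfg.window, cfg.mlp_ratio, rng)
            for _ in range(cfg.depths[-1])
        ]
        self.ups: list[Conv2d] = []
        self.merges: list[Conv2d] = []
        self.dec_blocks: list[list[LeWinBlock]] = []
        for lvl in reversed(range(cfg.levels)):
            self.ups.append(Conv2d(widths[lvl + 1], widths[lvl], 3, rng))
            self.merges.append(Conv2d(2 * widths[lvl], widths[lvl], 1, rng))
            self.dec_blocks.append([
                LeWinBlock(widths[lvl], cfg.heads, cfg.window, cfg.mlp_ratio, rng)
                for _ in range(cfg.depths[lvl])
            ])
        # zero-initialized so the untrained generator is exactly the identity
        self.out_proj = Conv2d(w, cfg.out_channels, 3, rng, zero_init=True)

    # flatten nested block lists for Module.parameters()
    def parameters(self) -> list[Parameter]:
        mods: list[Module] = [self.in_proj]
        for blocks, down in zip(self.enc_blocks, self.downs):
            mods.extend(blocks)
            mods.append(down)
        mods.extend(self.mid_blocks)
        for up, mg, blocks in zip(self.ups, self.merges, self.dec_blocks):
            mods.extend([up, mg])
            mods.extend(blocks)
        mods.append(self.out_proj)
        out: list[Parameter] = []
        for m in mods:
            out.extend(m.parameters())
        return out

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        n, c, h, w = x.shape
        factor = cfg.window * 2 ** cfg.levels
        if h % factor or w % factor:
            raise ValueError(
                f"input {h}x{w} not divisible by window*2^levels = {factor}"
            )
        y = self.in_proj(x)
        skips = []
        for blocks, down in zip(self.enc_blocks, self.downs):
            for blk in blocks:
                y = blk(y)
            skips.append(y)
            y = down(y)
        for blk in self.mid_blocks:
            y = blk(y)
        for up, mg, blocks, skip in zip(self.ups, self.merges, self.dec_blocks,
                                        reversed(skips)):
            y = up(_upsample2(y))
            y = mg(ag.concatenate([y, skip], axis=1))
            for blk in blocks:
                y = blk(y)
        out = self.out_proj(y)
        return x + out if cfg.residual else out


class Discriminator(Module):
    """Patch critic: stride-2 conv stack, unbounded spatial scores."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        self.config = config
        c = config.in_channels
        w = config.base_width
        self.convs: list[Conv2d] = []
        for i in range(config.n_stages):
            c_out = w * 2 ** i
            self.convs.append(Conv2d(c, c_out, 4, rng, stride=2, pad=1))
            c = c_out
        self.head = Conv2d(c, 1, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        min_size = 2 ** self.config.n_stages
        if h < min_size or w < min_size:
            raise ValueError(
                f"input {h}x{w} smaller than one receptive field "
                f"({min_size}x{min_size})"
            )
        y = x
        for conv in self.convs:
            y = ag.leaky_relu(conv(y), 0.2)
        return self.head(y)


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Seeded generator; untrained output equals input (residual zero-init)."""
    return Generator(config, np.random.default_rng(seed))


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, np.random.default_rng(seed))


def count_parameters(config: GeneratorConfig) -> int:
    """Analytic parameter count of a generator config (no allocation)."""
    def conv(ci, co, k):
        return co * ci * k * k + co

    def linear(ci, co):
        return ci * co + co

    def block(dim, mlp_ratio):
        hidden = int(dim * mlp_ratio)
        return (2 * (2 * dim)                       # two layer norms
                + linear(dim, 3 * dim) + linear(dim, dim)
                + linear(dim, hidden) + linear(hidden, dim))

    cfg = config
    widths = [cfg.base_width * 2 ** i for i in range(cfg.levels + 1)]
    n = conv(cfg.in_channels, widths[0], 3)
    for lvl in range(cfg.levels):
        n += cfg.depths[lvl] * block(widths[lvl], cfg.mlp_ratio)
        n += conv(widths[lvl], widths[lvl + 1], 3)
    n += cfg.depths[-1] * block(widths[-1], cfg.mlp_ratio)
    for lvl in reversed(range(cfg.levels)):
        n += conv(widths[lvl + 1], widths[lvl], 3)
        n += conv(2 * widths[lvl], widths[lvl], 1)
        n += cfg.depths[lvl] * block(widths[lvl], cfg.mlp_ratio)
    n += conv(widths[0], cfg.out_channels, 3)
    return n


# ---------------------------------------------------------------------------
# Wasserstein losses
# ---------------------------------------------------------------------------

def wgan_gp_losses(critic, real_batch: Tensor, fake_batch: Tensor,
                   lambda_gp: float, seed: int = 0):
    """Wasserstein critic/generator losses with gradient penalty.

    critic_loss = E[critic(fake)] - E[critic(real)] + penalty,
    generator_adv_loss = -E[critic(fake)], and
    penalty = lambda_gp * E[(||grad_x critic(x_tilde)||_2 - 1)^2] on random
    convex interpolates x_tilde between real and fake samples.  All three
    are returned as autodiff tensors; the penalty is differentiable with
    respect to the critic's weights (double backprop).
    """
    if lambda_gp < 0:
        raise ValueError("lambda_gp must be non-negative")
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must share a shape")
    c_real = critic(ag._wrap(real_batch))
    c_fake = critic(ag._wrap(fake_batch))
    gen_adv = -ag.tmean(c_fake)

    n = real_batch.shape[0]
    eps = np.random.default_rng(seed).uniform(size=(n,) + (1,) * (real_batch.ndim - 1))
    x_tilde = Tensor(
        eps * ag._wrap(real_batch).data + (1 - eps) * ag._wrap(fake_batch).data,
        requires_grad=True,
    )
    c_mid = critic(x_tilde)
    (gx,) = ag.grad(ag.tsum(c_mid), [x_tilde])
    sq = ag.tsum(gx * gx, axis=tuple(range(1, gx.ndim)))
    norm = ag.sqrt(sq + 1e-12)
    penalty = lambda_gp * ag.tmean((norm - 1.0) ** 2)
    critic_loss = ag.tmean(c_fake) - ag.tmean(c_real) + penalty
    return critic_loss, gen_adv, penalty


# ---------------------------------------------------------------------------
# Augmentation and splitting
# ---------------------------------------------------------------------------

def rotation_channel_matrix(angle_deg: float) -> np.ndarray:
    """6x6 mixing matrix for tensor channels under in-plane rotation.

    For rotation R about the slice normal, a tensor transforms as
    D' = R D R^T; in the 6-element channel representation this is linear,
    and for 90 degrees it swaps Dxx/Dyy and flips the sign of Dxy.
    """
    t = np.deg2rad(angle_deg)
    r = np.array([
        [np.cos(t), -np.sin(t), 0.0],
        [np.sin(t), np.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    m = np.zeros((6, 6))
    for col, (i, j) in enumerate(pairs):
        basis = np.zeros((3, 3))
        basis[i, j] = basis[j, i] = 1.0
        out = r @ basis @ r.T
        for row, (a, b) in enumerate(pairs):
            m[row, col] = out[a, b]
    return m


def _rotate_spatial(grid: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate a 2-D grid about the image center; exact for 90-degree steps."""
    k = angle_deg / 90.0
    if np.isclose(k, round(k)):
        return np.rot90(grid, k=int(round(k)) % 4).copy()
    return ndimage.rotate(grid, angle_deg, reshape=False, order=order,
                          mode="constant", cval=0.0)


def augment_sample(
    noisy: TensorField,
    target: TensorField,
    mask: np.ndarray,
    angle_deg: float = 0.0,
    crop_shape: tuple[int, int] | None = None,
) -> tuple[TensorField, TensorField, np.ndarray]:
    """Rotate both fields identically (with tensor reorientation) and crop.

    Rotation composes a spatial in-plane rotation of every channel with the
    channel mixing D' = R D R^T — omitting the reorientation would corrupt
    the training targets.  The crop window is centered on the myocardium's
    bounding box and guaranteed to contain it, then padded to ``crop_shape``.
    """
    if noisy.d.shape != target.d.shape:
        raise ValueError("noisy and target fields must share geometry")
    mask = np.asarray(mask, dtype=bool)

    def rotate_field(tf: TensorField) -> np.ndarray:
        # the grid rotation (rot90 / ndimage convention) is a clockwise
        # rotation in the (x=column, y=row) frame, hence the negated angle
        # in the tensor conjugation
        mix = rotation_channel_matrix(-angle_deg)
        d_mixed = tf.d @ mix.T
        return np.stack(
            [_rotate_spatial(d_mixed[..., ch], angle_deg, order=1)
             for ch in range(6)], axis=-1,
        )

    if angle_deg % 360 != 0:
        d_noisy = rotate_field(noisy)
        d_target = rotate_field(target)
        mask_r = _rotate_spatial(mask.astype(float), angle_deg, order=0) > 0.5
    else:
        d_noisy, d_target, mask_r = noisy.d.copy(), target.d.copy(), mask.copy()

    if crop_shape is not None:
        rows = np.flatnonzero(mask_r.any(axis=1))
        cols = np.flatnonzero(mask_r.any(axis=0))
        if rows.size == 0:
            raise ValueError("mask is empty after rotation")
        ch, cw = crop_shape
        h_need = rows[-1] - rows[0] + 1
        w_need = cols[-1] - cols[0] + 1
        if h_need > ch or w_need > cw:
            raise ValueError(
                f"myocardium extent {h_need}x{w_need} exceeds crop {ch}x{cw}"
            )
        r0 = max(0, min((rows[0] + rows[-1] + 1) // 2 - ch // 2,
                        mask_r.shape[0] - ch))
        c0 = max(0, min((cols[0] + cols[-1] + 1) // 2 - cw // 2,
                        mask_r.shape[1] - cw))
        sl = (slice(r0, r0 + ch), slice(c0, c0 + cw))

        def crop(arr):
            out_shape = (ch, cw) + arr.shape[2:]
            out = np.zeros(out_shape, dtype=arr.dtype)
            piece = arr[sl]
            out[:piece.shape[0], :piece.shape[1]] = piece
            return out

        d_noisy, d_target = crop(d_noisy), crop(d_target)
        mask_r = crop(mask_r)

    return (TensorField(d=d_noisy, mask=mask_r),
            TensorField(d=d_target, mask=mask_r), mask_r)


def split_patients(subject_ids: list, seed: int = 0) -> tuple[list, list, list]:
    """Disjoint 80:10:10 subject-level split, largest-remainder rounding."""
    ids = list(subject_ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 subjects, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fracs = np.array([0.8, 0.1, 0.1])
    base = np.floor(fracs * len(ids)).astype(int)
    rem = fracs * len(ids) - base
    for _ in range(len(ids) - base.sum()):
        i = int(np.argmax(rem))
        base[i] += 1
        rem[i] = -1
    shuffled = [ids[i] for i in order]
    train_ids = shuffled[:base[0]]
    val_ids = shuffled[base[0]:base[0] + base[1]]
    test_ids = shuffled[base[0] + base[1]:]
    return train_ids, val_ids, test_ids


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    """One normalized (noisy, reference) tensor pair, channels first."""

    noisy: np.ndarray      # (6, H, W)
    target: np.ndarray     # (6, H, W)


@dataclass
class Checkpoint:
    """A trained generator: weights, config, seed, and training history."""

    generator_config: GeneratorConfig
    params: list[np.ndarray]
    norm_spec: NormalizationSpec
    seed: int
    best_epoch: int
    history: list[dict] = field(default_factory=list)

    def generator(self) -> Generator:
        gen = build_generator(self.generator_config, seed=self.seed)
        gen.load_state(self.params)
        return gen


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float,
                 beta2: float, weight_decay: float = 0.0, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.wd, self.eps = weight_decay, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.wd:
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack_batch(samples: list[TrainingSample]) -> tuple[Tensor, Tensor]:
    x = Tensor(np.stack([s.noisy for s in samples]))
    y = Tensor(np.stack([s.target for s in samples]))
    return x, y


def _mae(pred: Tensor, target: Tensor) -> Tensor:
    return ag.tmean(ag.absolute(pred - target))


def train(
    train_pairs: list[TrainingSample],
    val_pairs: list[TrainingSample],
    generator_config: GeneratorConfig,
    train_config: TrainConfig,
    norm_spec: NormalizationSpec | None = None,
) -> Checkpoint:
    """Train one de-noiser on normalized tensor pairs.

    Loss: mean absolute error, plus ``lambda_adv`` times the Wasserstein
    adversarial term when ``lambda_adv > 0`` (a patch critic is then trained
    alongside with ``critic_steps`` updates per generator update and a
    gradient penalty of weight ``lambda_gp``).  Per-epoch validation MAE is
    logged; the returned checkpoint holds the weights of the epoch with the
    lowest validation loss.  Fully deterministic for a fixed config.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be nonempty")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(generator_config, seed=cfg.seed)
    opt = AdamW(gen.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2,
                cfg.weight_decay)
    adversarial = cfg.lambda_adv > 0
    if adversarial:
        critic = build_discriminator(DiscriminatorConfig(), seed=cfg.seed + 1)
        copt = AdamW(critic.parameters(), cfg.learning_rate, cfg.beta1,
                     cfg.beta2, cfg.weight_decay)

    history: list[dict] = []
    best = (np.inf, -1, None)
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_pairs[i] for i in order[start:start + cfg.batch_size]]
            x, y = _stack_batch(batch)
            if adversarial:
                for _ in range(cfg.critic_steps):
                    fake = Tensor(gen(x).data)          # detached
                    closs, _, _ = wgan_gp_losses(
                        critic, y, fake, cfg.lambda_gp, seed=cfg.seed + step
                    )
                    copt.zero_grad()
                    ag.grad(closs, critic.parameters(), accumulate=True)
                    copt.step()
            pred = gen(x)
            loss = _mae(pred, y)
            if adversarial:
                loss = loss + cfg.lambda_adv * (-ag.tmean(critic(pred)))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss={loss.item()}"
                )
            opt.zero_grad()
            ag.grad(loss, gen.parameters(), accumulate=True)
            opt.step()
            train_losses.append(loss.item())
            step += 1

        val_losses = []
        for start in range(0, len(val_pairs), cfg.batch_size):
            x, y = _stack_batch(val_pairs[start:start + cfg.batch_size])
            val_losses.append((_mae(gen(x), y).item(), x.shape[0]))
        val_mae = float(np.average([v for v, _ in val_losses],
                                   weights=[n for _, n in val_losses]))
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": val_mae})
        if val_mae < best[0]:
            best = (val_mae, epoch, gen.state())

    spec = norm_spec if norm_spec is not None else NormalizationSpec()
    return Checkpoint(
        generator_config=generator_config, params=best[2], norm_spec=spec,
        seed=cfg.seed, best_epoch=best[1], history=history,
    )


def _content_crop_origin(mask: np.ndarray, crop_shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left corner of a crop window centered on the mask bounding box."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    ch, cw = crop_shape
    r0 = max(0, min((rows[0] + rows[-1] + 1) // 2 - ch // 2, mask.shape[0] - ch))
    c0 = max(0, min((cols[0] + cols[-1] + 1) // 2 - cw // 2, mask.shape[1] - cw))
    return r0, c0


def denoise_field(members: list[Checkpoint], noisy: TensorField) -> TensorField:
    """De-noise a full-size tensor field via content-aware crop and paste.

    The myocardium bounding box (with an 8-voxel margin) is cropped to the
    smallest window whose sides divide the generator's window/level factor,
    the ensemble prediction runs on the crop, and the result is pasted back;
    voxels outside the crop keep their input values.
    """
    cfg = members[0].generator_config
    factor = cfg.window * 2 ** cfg.levels
    mask = noisy.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    h = int(np.ceil((rows[-1] - rows[0] + 1 + 8) / factor) * factor)
    w = int(np.ceil((cols[-1] - cols[0] + 1 + 8) / factor) * factor)
    h, w = min(h, int(np.ceil(mask.shape[0] / factor) * factor)), \
        min(w, int(np.ceil(mask.shape[1] / factor) * factor))
    cropped, _, _ = augment_sample(noisy, noisy, mask, 0.0, (h, w))
    den = ensemble_predict(members, cropped)
    out = noisy.d.copy()
    r0, c0 = _content_crop_origin(mask, (h, w))
    piece = out[r0:r0 + h, c0:c0 + w]
    out[r0:r0 + h, c0:c0 + w] = den.d[:piece.shape[0], :piece.shape[1]]
    return TensorField(d=out, mask=mask.copy())


def ensemble_predict(members: list[Checkpoint], noisy: TensorField) -> TensorField:
    """Elementwise mean of member predictions, denormalized to mm^2/s."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    cfg0 = members[0].generator_config
    spec0 = members[0].norm_spec
    for m in members[1:]:
        if m.generator_config != cfg0 or m.norm_spec.mode != spec0.mode:
            raise ValueError("ensemble members have inconsistent configs")
    x = normalize_tensor(noisy, spec0)
    xt = Tensor(np.moveaxis(x, -1, 0)[None])
    preds = [m.generator()(xt).data[0] for m in members]
    mean_pred = np.moveaxis(np.mean(preds, axis=0, dtype=np.float64), 0, -1)
    return denormalize_tensor(mean_pred, spec0, noisy.mask)
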