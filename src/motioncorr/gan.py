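"""Pix2Pix motion correction: U-Net generator, PatchGAN discriminator, training.

The generator is an encoder-decoder U-Net: up to eight stride-2 4x4
convolution levels with skip connections, LeakyReLU on encoder inputs from
the second layer on, ReLU in the decoder, batch normalization on layer
outputs, and a tanh output in [-1, 1].  The discriminator is a PatchGAN that
crops the (reference, candidate) pair into fixed-size patches (32x32 by
default, so a 256x256 image yields 64 patch pairs), classifies each patch
pair as a true or false pair through a two-class softmax, and additionally
combines all patch outputs into one global true/false softmax.

Training alternates discriminator and generator updates per mini-batch with
Adam (learning rate 1e-4, beta1 0.9, beta2 0.999 by default).  The generator
loss is binary cross-entropy against the discriminator plus an L1 term
(weight 100 by default); the baseline trains the same U-Net alone with mean
squared error.  Network depth adapts to the image side (log2), so the same
code runs full 256x256 models and small test configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .evalstats import ssim
from .kspace import PairedSample

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TrainingSpec",
    "UNetGenerator", "PatchDiscriminator", "CorrectionModel",
    "build_generator", "build_discriminator",
    "train_pix2pix", "train_unet_baseline", "correct_image",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyperparameters (depth adapts to image side, max 8)."""

    base_channels: int = 64
    max_depth: int = 8
    bn_from_layer: int = 2      # 1-indexed first encoder layer with BN
    skip_connections: bool = True


@dataclass(frozen=True)
class DiscriminatorSpec:
    patch_size: int = 32
    base_channels: int = 8


@dataclass(frozen=True)
class TrainingSpec:
    """Optimization settings; defaults are the full-scale configuration."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32            # Pix2Pix mini-batch
    unet_batch_size: int = 16       # U-Net baseline mini-batch
    epochs: int = 100
    l1_weight: float = 100.0
    validation_fraction: float = 0.10
    seed: int = 0
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)


def _check_pow2_side(rows: int, cols: int, max_depth: int) -> int:
    side = min(rows, cols)
    depth = min(max_depth, int(np.log2(side)))
    if depth < 2:
        raise ValueError(f"image side {side} too small; need at least 4")
    f = 2 ** depth
    if rows % f or cols % f:
        raise ValueError(
            f"shape {(rows, cols)} not divisible by 2^depth={f}; "
            f"use a power-of-two side of at least {f}")
    return depth


class UNetGenerator:
    """Encoder-decoder with skip connections mapping (N,1,H,W) -> (N,1,H,W)."""

    def __init__(self, input_shape: tuple[int, int],
                 spec: GeneratorSpec = GeneratorSpec(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        rows, cols = input_shape
        self.input_shape = (rows, cols)
        self.spec = spec
        d = _check_pow2_side(rows, cols, spec.max_depth)
        self.depth = d
        b = spec.base_channels
        ch = [b * min(2 ** i, 8) for i in range(d)]
        self.enc_channels = ch

        self.enc_blocks: list[list[nn.Layer]] = []
        for i in range(d):
            blk: list[nn.Layer] = []
            if i > 0:
                blk.append(nn.LeakyReLU(0.2))
            blk.append(nn.Conv2D(1 if i == 0 else ch[i - 1], ch[i], rng=rng))
            # BN on outputs from bn_from_layer onward; innermost level left
            # un-normalized (its spatial extent can be a single pixel).
            if i + 1 >= spec.bn_from_layer and i < d - 1:
                blk.append(nn.BatchNorm2D(ch[i]))
            self.enc_blocks.append(blk)

        self.dec_blocks: list[list[nn.Layer]] = []
        mult = 2 if spec.skip_connections else 1
        for j in range(d):
            blk = [nn.ReLU()]
            cin = ch[d - 1] if j == 0 else mult * ch[d - 1 - j]
            if j < d - 1:
                blk.append(nn.ConvTranspose2D(cin, ch[d - 2 - j], rng=rng))
                blk.append(nn.BatchNorm2D(ch[d - 2 - j]))
            else:
                blk.append(nn.ConvTranspose2D(cin, 1, rng=rng))
                blk.append(nn.Tanh())
            self.dec_blocks.append(blk)

    def params(self) -> list[nn.Param]:
        out = []
        for blk in (*self.enc_blocks, *self.dec_blocks):
            for layer in blk:
                out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[2:] != self.input_shape:
            raise ValueError(f"expected {self.input_shape}, got {x.shape[2:]}")
        self._enc_outs = []
        h = x
        for blk in self.enc_blocks:
            for layer in blk:
                h = layer.forward(h, train)
            self._enc_outs.append(h)
        self._concat_ch = []
        for j, blk in enumerate(self.dec_blocks):
            if j > 0 and self.spec.skip_connections:
                skip = self._enc_outs[self.depth - 1 - j]
                self._concat_ch.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
            for layer in blk:
                h = layer.forward(h, train)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.depth
        skip_grads: list[np.ndarray | None] = [None] * d
        h = dy
        for j in reversed(range(d)):
            for layer in reversed(self.dec_blocks[j]):
                h = layer.backward(h)
            if j > 0 and self.spec.skip_connections:
                c = self._concat_ch[j - 1]
                h, dskip = h[:, :c], h[:, c:]
                skip_grads[d - 1 - j] = dskip
        g = h  # gradient at innermost encoder output
        for i in reversed(range(d)):
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                g = layer.backward(g)
        return g

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class PatchDiscriminator:
    """PatchGAN: per-patch true/false softmax plus a global combined softmax."""

    def __init__(self, input_shape: tuple[int, int],
                 spec: DiscriminatorSpec = DiscriminatorSpec(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        rows, cols = input_shape
        ps = spec.patch_size
        if rows % ps or cols % ps:
            raise ValueError(f"shape {(rows, cols)} not divisible by "
                             f"patch size {ps}")
        self.input_shape = (rows, cols)
        self.patch_size = ps
        self.n_patches = (rows // ps) * (cols // ps)
        c = spec.base_channels
        self.conv_a = nn.Conv2D(1, c, rng=rng)
        self.act_a = nn.LeakyReLU(0.2)
        self.conv_b = nn.Conv2D(1, c, rng=rng)
        self.act_b = nn.LeakyReLU(0.2)
        self.conv_m = nn.Conv2D(2 * c, 2 * c, rng=rng)
        self.bn_m = nn.BatchNorm2D(2 * c)
        self.act_m = nn.LeakyReLU(0.2)
        feat_side = ps // 4
        self.feat_dim = 2 * c * feat_side * feat_side
        self.dense_patch = nn.Dense(self.feat_dim, 2, rng=rng)
        self.dense_global = nn.Dense(self.n_patches * 2, 2, rng=rng)

    def params(self) -> list[nn.Param]:
        out = []
        for layer in (self.conv_a, self.conv_b, self.conv_m, self.bn_m,
                      self.dense_patch, self.dense_global):
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def _patchify(self, x: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        ps = self.patch_size
        x = x.reshape(n, 1, h // ps, ps, w // ps, ps)
        x = x.transpose(0, 2, 4, 1, 3, 5)
        return x.reshape(n * self.n_patches, 1, ps, ps)

    def _unpatchify(self, p: np.ndarray, n: int) -> np.ndarray:
        ps = self.patch_size
        h, w = self.input_shape
        p = p.reshape(n, h // ps, w // ps, 1, ps, ps)
        p = p.transpose(0, 3, 1, 4, 2, 5)
        return p.reshape(n, 1, h, w)

    def forward(self, ref: np.ndarray, cand: np.ndarray, train: bool = True):
        """Return (patch_logits (N*P, 2), global_logits (N, 2))."""
        n = ref.shape[0]
        self._n = n
        pa = self._patchify(ref)
        pb = self._patchify(cand)
        fa = self.act_a.forward(self.conv_a.forward(pa, train), train)
        fb = self.act_b.forward(self.conv_b.forward(pb, train), train)
        self._ca = fa.shape[1]
        f = np.concatenate([fa, fb], axis=1)
        f = self.act_m.forward(
            self.bn_m.forward(self.conv_m.forward(f, train), train), train)
        self._feat_shape = f.shape
        flat = f.reshape(f.shape[0], -1)
        patch_logits = self.dense_patch.forward(flat, train)
        global_in = patch_logits.reshape(n, self.n_patches * 2)
        global_logits = self.dense_global.forward(global_in, train)
        return patch_logits, global_logits

    def backward(self, d_patch_logits: np.ndarray, d_global_logits: np.ndarray):
        """Backpropagate; returns gradient w.r.t. the candidate image."""
        n = self._n
        dg = self.dense_global.backward(d_global_logits)
        d_pl = d_patch_logits + dg.reshape(n * self.n_patches, 2)
        dflat = self.dense_patch.backward(d_pl)
        df = dflat.reshape(self._feat_shape)
        df = self.conv_m.backward(self.bn_m.backward(self.act_m.backward(df)))
        dfa, dfb = df[:, :self._ca], df[:, self._ca:]
        self.conv_a.backward(self.act_a.backward(dfa))  # branch-A weight grads
        dpb = self.conv_b.backward(self.act_b.backward(dfb))
        return self._unpatchify(dpb, n)


def build_generator(spec: GeneratorSpec, input_shape: tuple[int, int],
                    seed: int = 0) -> UNetGenerator:
    return UNetGenerator(input_shape, spec, rng=np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, input_shape: tuple[int, int],
                        seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(input_shape, spec, rng=np.random.default_rng(seed))


class CorrectionModel:
    """A trained generator plus the intensity normalization it was fit with."""

    def __init__(self, generator: UNetGenerator, lo: float, hi: float,
                 kind: str = "pix2pix"):
        self.generator = generator
        self.lo, self.hi = float(lo), float(hi)
        self.kind = kind

    def _norm(self, img: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo or 1.0
        return 2.0 * (img - self.lo) / span - 1.0

    def _denorm(self, x: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo or 1.0
        return np.maximum((x + 1.0) / 2.0 * span + self.lo, 0.0)

    def correct(self, artifact: np.ndarray) -> np.ndarray:
        """Motion-correct one image (deterministic inference mode)."""
        artifact = np.asarray(artifact, dtype=np.float64)
        if artifact.shape != self.generator.input_shape:
            raise ValueError(f"expected {self.generator.input_shape}, "
                             f"got {artifact.shape}")
        x = self._norm(artifact)[None, None]
        y = self.generator.forward(x, train=False)
        return self._denorm(y[0, 0])

    def correct_batch(self, artifacts: np.ndarray) -> np.ndarray:
        x = self._norm(np.asarray(artifacts, dtype=np.float64))[:, None]
        y = self.generator.forward(x, train=False)
        return self._denorm(y[:, 0])


def correct_image(model: CorrectionModel, artifact: np.ndarray) -> np.ndarray:
    return model.correct(artifact)


def _split_by_volume(pairs: list[PairedSample], frac: float,
                     rng: np.random.Generator):
    vol_ids = sorted({p.volume_id for p in pairs})
    n_val = int(round(frac * len(vol_ids))) if len(vol_ids) > 1 else 0
    perm = rng.permutation(len(vol_ids))
    val_ids = {vol_ids[i] for i in perm[:n_val]}
    train = [p for p in pairs if p.volume_id not in val_ids]
    val = [p for p in pairs if p.volume_id in val_ids]
    return train, val


def _to_batches(pairs, lo, hi, idx, batch_size):
    span = hi - lo or 1.0
    for start in range(0, len(idx), batch_size):
        sel = idx[start:start + batch_size]
        x = np.stack([pairs[i].artifact for i in sel])[:, None]
        y = np.stack([pairs[i].original for i in sel])[:, None]
        yield (2 * (x - lo) / span - 1, 2 * (y - lo) / span - 1)


def _val_ssim(model: CorrectionModel, val_pairs) -> float:
    if not val_pairs:
        return float("nan")
    vals = [ssim(model.correct(p.artifact), p.original) for p in val_pairs]
    return float(np.mean(vals))


def _check_finite(loss: float, what: str):
    if not np.isfinite(loss):
        raise RuntimeError(f"{what} loss became non-finite; aborting training")


def train_pix2pix(pairs: list[PairedSample], spec: TrainingSpec,
                  log_dir: str | Path | None = None):
    """Adversarial training with alternating D/G updates per mini-batch.

    Returns ``(CorrectionModel, log)`` where ``log`` is a DataFrame with one
    row per epoch (G loss, D loss, validation SSIM).
    """
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(spec.seed)
    train, val = _split_by_volume(pairs, spec.validation_fraction, rng)
    shape = train[0].original.shape
    all_vals = np.concatenate([np.stack([p.artifact for p in train]).ravel(),
                               np.stack([p.original for p in train]).ravel()])
    lo, hi = float(all_vals.min()), float(all_vals.max())

    G = build_generator(spec.generator, shape, seed=spec.seed)
    D = build_discriminator(spec.discriminator, shape, seed=spec.seed + 1)
    optG = nn.Adam(G.params(), spec.learning_rate, spec.beta1, spec.beta2)
    optD = nn.Adam(D.params(), spec.learning_rate, spec.beta1, spec.beta2)
    model = CorrectionModel(G, lo, hi, kind="pix2pix")

    rows = []
    for epoch in range(spec.epochs):
        idx = rng.permutation(len(train))
        g_losses, d_losses = [], []
        for x, y in _to_batches(train, lo, hi, idx, spec.batch_size):
            fake = G.forward(x, train=True)

            # Discriminator step: true pair (ref, original), false pair
            # (ref, generated); generator weights are untouched.
            pl, gl = D.forward(y, y, train=True)
            loss_r, dpl = nn.softmax_cross_entropy(pl, 1)
            loss_rg, dgl = nn.softmax_cross_entropy(gl, 1)
            D.backward(dpl, dgl)
            pl, gl = D.forward(y, fake, train=True)
            loss_f, dpl = nn.softmax_cross_entropy(pl, 0)
            loss_fg, dgl = nn.softmax_cross_entropy(gl, 0)
            D.backward(dpl, dgl)
            d_loss = 0.5 * (loss_r + loss_rg + loss_f + loss_fg)
            _check_finite(d_loss, "discriminator")
            optD.step()
            optD.zero_grad()

            # Generator step: fool the updated discriminator + L1 fidelity.
            pl, gl = D.forward(y, fake, train=True)
            adv_p, dpl = nn.softmax_cross_entropy(pl, 1)
            adv_g, dgl = nn.softmax_cross_entropy(gl, 1)
            dfake = D.backward(dpl, dgl)
            D.zero_grad()           # discard D grads from the G step
            l1 = np.abs(fake - y).mean()
            dfake = dfake + spec.l1_weight * np.sign(fake - y) / fake.size
            g_loss = adv_p + adv_g + spec.l1_weight * l1
            _check_finite(g_loss, "generator")
            G.backward(dfake)
            optG.step()
            optG.zero_grad()
            g_losses.append(g_loss)
            d_losses.append(d_loss)
        rows.append({"epoch": epoch + 1,
                     "G_loss": float(np.mean(g_losses)),
                     "D_loss": float(np.mean(d_losses)),
                     "val_SSIM": _val_ssim(model, val)})
    log = pd.DataFrame(rows)
    if log_dir is not None:
        _write_log(log_dir, spec, log, model)
    return model, log


def train_unet_baseline(pairs: list[PairedSample], spec: TrainingSpec,
                        log_dir: str | Path | None = None):
    """Train the same U-Net with plain mean-squared-error (no discriminator)."""
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(spec.seed)
    train, val = _split_by_volume(pairs, spec.validation_fraction, rng)
    shape = train[0].original.shape
    all_vals = np.concatenate([np.stack([p.artifact for p in train]).ravel(),
                               np.stack([p.original for p in train]).ravel()])
    lo, hi = float(all_vals.min()), float(all_vals.max())

    G = build_generator(spec.generator, shape, seed=spec.seed)
    opt = nn.Adam(G.params(), spec.learning_rate, spec.beta1, spec.beta2)
    model = CorrectionModel(G, lo, hi, kind="unet")

    rows = []
    for epoch in range(spec.epochs):
        idx = rng.permutation(len(train))
        losses = []
        for x, y in _to_batches(train, lo, hi, idx, spec.unet_batch_size):
            out = G.forward(x, train=True)
            diff = out - y
            loss = float((diff ** 2).mean())
            _check_finite(loss, "baseline")
            G.backward(2.0 * diff / diff.size)
            opt.step()
            opt.zero_grad()
            losses.append(loss)
        rows.append({"epoch": epoch + 1, "MSE": float(np.mean(losses)),
                     "val_SSIM": _val_ssim(model, val)})
    log = pd.DataFrame(rows)
    if log_dir is not None:
        _write_log(log_dir, spec, log, model)
    return model, log


def _write_log(log_dir, spec: TrainingSpec, log: pd.DataFrame,
               model: CorrectionModel):
    out = Path(log_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(_spec_yaml(spec))
    log.to_csv(out / "train_log.csv", index=False)
    save_model(model, out / f"{model.kind}_model.npz")


def _spec_yaml(spec: TrainingSpec) -> str:
    import yaml
    return yaml.safe_dump(asdict(spec), sort_keys=False)


def save_model(model: CorrectionModel, path: str | Path):
    G = model.generator
    arrays = {f"p{i}": p.value for i, p in enumerate(G.params())}
    stats = {}
    for bi, blk in enumerate((*G.enc_blocks, *G.dec_blocks)):
        for li, layer in enumerate(blk):
            if isinstance(layer, nn.BatchNorm2D):
                stats[f"rm_{bi}_{li}"] = layer.running_mean
                stats[f"rv_{bi}_{li}"] = layer.running_var
    meta = {"input_shape": list(G.input_shape), "kind": model.kind,
            "lo": model.lo, "hi": model.hi, "spec": asdict(G.spec)}
    np.savez(path, __meta__=json.dumps(meta), **arrays, **stats)


def load_model(path: str | Path) -> CorrectionModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    G = UNetGenerator(tuple(meta["input_shape"]),
                      GeneratorSpec(**meta["spec"]))
    for i, p in enumerate(G.params()):
        p.value[...] = data[f"p{i}"]
    for bi, blk in enumerate((*G.enc_blocks, *G.dec_blocks)):
        for li, layer in enumerate(blk):
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean = data[f"rm_{bi}_{li}"]
                layer.running_var = data[f"rv_{bi}_{li}"]
    return CorrectionModel(G, meta["lo"], meta["hi"], kind=meta["kind"])
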