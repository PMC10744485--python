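"""Two-view fusion GAN mapping biplanar radiographs to a 3D volume.

Generator: one dense 2D encoder per view; at each scale the 2D feature
maps are channel-matched by plain 2D convolutions, expanded along the
view's projection axis into pseudo-3D feature grids and refined by 3D
convolutions; each view then has its own transposed-convolution 3D
decoder, and a third (fusion) decoding stream combines the two by
rotating the lateral stream's feature grids 90° about the
inferior–superior axis into the anterior frame and averaging
element-wise.  The merge stage additionally sees the raw radiographs
backprojected along their ray axes plus their voxelwise product (the
multiplicative visual hull) — a physics-informed shortcut that gives the
output stage direct access to the two-view consistency constraint.  ReLU
activations throughout; the output passes through a sigmoid (bias
initialised to a dark prior, since CT volumes are mostly air/soft
tissue) so reconstructed volumes always lie in [0, 1].

Discriminator: a conditional 3D patch discriminator with instance
normalization and no dropout; each input radiograph is replicated along
its own projection axis and concatenated to the candidate volume as an
extra channel.

Training: least-squares GAN objectives with Adam, single-sample batches,
and a generator objective combining adversarial, voxel MSE, projection-
consistency, feature-matching and input-consistency ("identity") terms.
The learning rate is constant for the first half of the epochs and then
decays linearly to zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Adam, Conv2d, Conv3d, ConvTranspose3d, DenseBlock2d, Module
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .types import PairedSample

__all__ = [
    "LossWeights",
    "GanConfig",
    "TwoViewFusionGenerator",
    "ConditionalPatchDiscriminator3d",
    "build_generator",
    "build_discriminator",
    "lsgan_loss",
    "reconstruction_loss",
    "projection_loss",
    "feature_matching_loss",
    "identity_loss",
    "learning_rate_at_epoch",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the generator's objective terms."""

    w_gan: float = 0.1
    w_recon: float = 10.0
    w_proj: float = 10.0
    w_fm: float = 1.0
    w_idt: float = 1.0

    def __post_init__(self):
        ws = (self.w_gan, self.w_recon, self.w_proj, self.w_fm, self.w_idt)
        if any(w < 0 for w in ws):
            raise ValueError("loss weights must be nonnegative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class GanConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.99
    batch_size: int = 1
    n_epochs: int = 10
    base_channels: int = 16
    volume_size: int = 128
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    checkpoint_interval: int = 0  # epochs between checkpoints; 0 = final only

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        s = self.volume_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ValueError(
                "volume_size must be a power of two >= 16 (network depth "
                "requires three clean halvings)"
            )
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def _as_view_tensor(x, size: int) -> Tensor:
    if isinstance(x, Tensor):
        t = x
    else:
        t = Tensor(np.asarray(x, dtype=np.float32))
    if t.ndim == 2:
        t = ad.reshape(t, (1,) + t.shape)
    if t.shape != (1, size, size):
        raise ValueError(f"expected a {size}x{size} view, got {t.shape[1:]}")
    return t


class _ViewEncoder(Module):
    """Dense 2D encoder with pseudo-3D bridges at three scales."""

    def __init__(self, c: int, g: int, rng):
        self.block0 = DenseBlock2d(1, c, rng=rng)
        self.down1 = Conv2d(c, 2 * c, stride=2, rng=rng)
        self.block1 = DenseBlock2d(2 * c, 2 * c, rng=rng)
        self.down2 = Conv2d(2 * c, 4 * c, stride=2, rng=rng)
        self.block2 = DenseBlock2d(4 * c, 4 * c, rng=rng)
        self.down3 = Conv2d(4 * c, 4 * c, stride=2, rng=rng)
        self.block3 = DenseBlock2d(4 * c, 4 * c, rng=rng)
        # channel-matching 2D convs + refining 3D convs per scale
        self.match3 = Conv2d(4 * c, 4 * g, rng=rng)
        self.refine3 = Conv3d(4 * g, 4 * g, rng=rng)
        self.match2 = Conv2d(4 * c, 2 * g, rng=rng)
        self.refine2 = Conv3d(2 * g, 2 * g, rng=rng)
        self.match1 = Conv2d(2 * c, g, rng=rng)
        self.refine1 = Conv3d(g, g, rng=rng)

    def forward(self, x: Tensor):
        e0 = self.block0(x)
        e1 = self.block1(ad.relu(self.down1(e0)))
        e2 = self.block2(ad.relu(self.down2(e1)))
        e3 = self.block3(ad.relu(self.down3(e2)))

        def lift(match, refine, feat):
            m = ad.relu(match(feat))
            depth = m.shape[1]
            # expand along the view's projection (ray) axis
            vol = ad.repeat_new_axis(m, depth, axis=2)
            return ad.relu(refine(vol))

        return (
            lift(self.match3, self.refine3, e3),  # (4g, S/8 ...)
            lift(self.match2, self.refine2, e2),  # (2g, S/4 ...)
            lift(self.match1, self.refine1, e1),  # (g,  S/2 ...)
        )


class _DecoderStream(Module):
    """Transposed-convolution 3D decoder with per-scale skip fusion."""

    def __init__(self, g: int, rng):
        self.up1 = ConvTranspose3d(4 * g, 2 * g, rng=rng)
        self.mix1 = Conv3d(4 * g, 2 * g, rng=rng)
        self.up2 = ConvTranspose3d(2 * g, g, rng=rng)
        self.mix2 = Conv3d(2 * g, g, rng=rng)
        self.up3 = ConvTranspose3d(g, g, rng=rng)

    def forward(self, bottom: Tensor, skip_mid: Tensor, skip_fine: Tensor) -> Tensor:
        x = ad.relu(self.up1(bottom))
        x = ad.relu(self.mix1(ad.concat([x, skip_mid], axis=0)))
        x = ad.relu(self.up2(x))
        x = ad.relu(self.mix2(ad.concat([x, skip_fine], axis=0)))
        return ad.relu(self.up3(x))


def _rot_lateral(t: Tensor) -> Tensor:
    """Exact 90° lattice rotation of lateral-stream grids about z."""
    return ad.rot90(t, 1, axes=(3, 2))


class TwoViewFusionGenerator(Module):
    """Biplanar radiographs (anterior, lateral) -> [0, 1] volume."""

    def __init__(self, cfg: GanConfig, rng=None):
        rng = rng or np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        g = max(c // 4, 2)
        self.cfg = cfg
        self.enc1 = _ViewEncoder(c, g, rng)
        self.enc2 = _ViewEncoder(c, g, rng)
        self.dec1 = _DecoderStream(g, rng)
        self.dec2 = _DecoderStream(g, rng)
        self.dec_fused = _DecoderStream(g, rng)
        # merge consumes the three decoder streams plus the two raw-input
        # backprojections and their product (the visual-hull prior)
        self.merge = Conv3d(3 * g + 3, g, rng=rng)
        self.head = Conv3d(g, 1, rng=rng)
        # dark-prior output initialisation: sigmoid(-2.2) ~ 0.1, matching
        # volumes that are mostly non-bone
        self.head.bias.data[:] = -2.2

    def forward(self, xray1, xray2) -> Tensor:
        size = self.cfg.volume_size
        x1 = _as_view_tensor(xray1, size)
        x2 = _as_view_tensor(xray2, size)
        a_bot, a_mid, a_fine = self.enc1(x1)
        l_bot, l_mid, l_fine = self.enc2(x2)
        v1 = self.dec1(a_bot, a_mid, a_fine)
        v2 = self.dec2(l_bot, l_mid, l_fine)
        f_bot = ad.mul(ad.add(a_bot, _rot_lateral(l_bot)), 0.5)
        f_mid = ad.mul(ad.add(a_mid, _rot_lateral(l_mid)), 0.5)
        f_fine = ad.mul(ad.add(a_fine, _rot_lateral(l_fine)), 0.5)
        fused = self.dec_fused(f_bot, f_mid, f_fine)
        bp1 = ad.repeat_new_axis(x1, size, axis=2)  # anterior along y
        bp2 = ad.repeat_new_axis(x2, size, axis=3)  # lateral along x
        hull = ad.mul(bp1, bp2)
        x = ad.relu(
            self.merge(
                ad.concat([fused, v1, _rot_lateral(v2), bp1, bp2, hull], axis=0)
            )
        )
        out = ad.sigmoid(self.head(x))
        return ad.reshape(out, (size, size, size))

    def predict_volume(self, xray1, xray2) -> np.ndarray:
        return np.asarray(self.forward(xray1, xray2).data, dtype=np.float64)


class ConditionalPatchDiscriminator3d(Module):
    """3D patch critic conditioned on the two input radiographs."""

    def __init__(self, cfg: GanConfig, rng=None):
        rng = rng or np.random.default_rng(cfg.seed + 1)
        c = cfg.base_channels
        self.cfg = cfg
        self.conv1 = Conv3d(3, c, kernel=4, stride=2, pad=1, rng=rng)
        self.conv2 = Conv3d(c, 2 * c, kernel=4, stride=2, pad=1, rng=rng)
        self.conv3 = Conv3d(2 * c, 4 * c, kernel=4, stride=2, pad=1, rng=rng)
        self.head = Conv3d(4 * c, 1, kernel=3, stride=1, pad=1, rng=rng)

    def forward(self, volume, xray1, xray2, return_features: bool = False):
        size = self.cfg.volume_size
        vol = volume if isinstance(volume, Tensor) else Tensor(
            np.asarray(volume, dtype=np.float32)
        )
        if vol.ndim == 3:
            vol = ad.reshape(vol, (1,) + vol.shape)
        if vol.shape != (1, size, size, size):
            raise ValueError(
                f"expected a {size}^3 volume, got {tuple(vol.shape[1:])}"
            )
        x1 = _as_view_tensor(xray1, size)
        x2 = _as_view_tensor(xray2, size)
        # condition channels: each view replicated along its projection axis
        cond1 = ad.repeat_new_axis(x1, size, axis=2)  # anterior: along y
        cond2 = ad.repeat_new_axis(x2, size, axis=3)  # lateral: along x
        x = ad.concat([vol, cond1, cond2], axis=0)
        f1 = ad.relu(self.conv1(x))
        f2 = ad.relu(ad.instance_norm(self.conv2(f1)))
        f3 = ad.relu(ad.instance_norm(self.conv3(f2)))
        score = self.head(f3)
        if return_features:
            return score, [f1, f2, f3]
        return score


def build_generator(cfg: GanConfig) -> TwoViewFusionGenerator:
    return TwoViewFusionGenerator(cfg)


def build_discriminator(cfg: GanConfig) -> ConditionalPatchDiscriminator3d:
    return ConditionalPatchDiscriminator3d(cfg)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _finite_tensor(x, name: str) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if not np.all(np.isfinite(t.data)):
        raise ValueError(f"{name} contains non-finite values")
    return t


def lsgan_loss(d_real_scores, d_fake_scores) -> tuple[Tensor, Tensor]:
    """Least-squares GAN objectives.

    loss_D = 1/2 mean((d_real - 1)^2) + 1/2 mean(d_fake^2);
    loss_G_adv = mean((d_fake - 1)^2).
    """
    real = _finite_tensor(d_real_scores, "d_real_scores")
    fake = _finite_tensor(d_fake_scores, "d_fake_scores")
    loss_d = ad.add(
        ad.mul(ad.mean(ad.square(ad.sub(real, 1.0))), 0.5),
        ad.mul(ad.mean(ad.square(fake)), 0.5),
    )
    loss_g = ad.mean(ad.square(ad.sub(fake, 1.0)))
    return loss_d, loss_g


def reconstruction_loss(gen_vol, gt_vol) -> Tensor:
    """Voxelwise mean squared error."""
    gen = gen_vol if isinstance(gen_vol, Tensor) else Tensor(np.asarray(gen_vol))
    gt = gt_vol if isinstance(gt_vol, Tensor) else Tensor(np.asarray(gt_vol))
    if gen.shape != gt.shape:
        raise ValueError(f"shape mismatch: {gen.shape} vs {gt.shape}")
    return ad.mean(ad.square(ad.sub(gen, gt)))


def projection_loss(gen_vol, gt_vol) -> Tensor:
    """Mean over the three orthogonal axes of the MSE between the
    axis-mean projections of the two volumes."""
    gen = gen_vol if isinstance(gen_vol, Tensor) else Tensor(np.asarray(gen_vol))
    gt = gt_vol if isinstance(gt_vol, Tensor) else Tensor(np.asarray(gt_vol))
    if gen.shape != gt.shape:
        raise ValueError(f"shape mismatch: {gen.shape} vs {gt.shape}")
    terms = []
    for axis in range(3):
        pg = ad.mean(gen, axis=axis)
        pt = ad.mean(gt, axis=axis)
        terms.append(ad.mean(ad.square(ad.sub(pg, pt))))
    return ad.mul(ad.add(ad.add(terms[0], terms[1]), terms[2]), 1.0 / 3.0)


def feature_matching_loss(d_features_real, d_features_fake) -> Tensor:
    """Mean absolute difference of discriminator features, averaged over
    layers."""
    if len(d_features_real) != len(d_features_fake):
        raise ValueError("feature lists must have equal length")
    if not d_features_real:
        raise ValueError("feature lists must be nonempty")
    total = None
    for fr, ff in zip(d_features_real, d_features_fake):
        fr = fr if isinstance(fr, Tensor) else Tensor(np.asarray(fr))
        ff = ff if isinstance(ff, Tensor) else Tensor(np.asarray(ff))
        if fr.shape != ff.shape:
            raise ValueError("feature shapes must match layer-wise")
        term = ad.mean(ad.absolute(ad.sub(fr, ff)))
        total = term if total is None else ad.add(total, term)
    return ad.mul(total, 1.0 / len(d_features_real))


def identity_loss(gen_vol, xray1, xray2) -> Tensor:
    """Input-consistency term: the generated volume's mean projections
    along the two acquisition axes should resemble the input views."""
    gen = gen_vol if isinstance(gen_vol, Tensor) else Tensor(np.asarray(gen_vol))
    x1 = xray1 if isinstance(xray1, Tensor) else Tensor(np.asarray(xray1))
    x2 = xray2 if isinstance(xray2, Tensor) else Tensor(np.asarray(xray2))
    x1 = ad.reshape(x1, x1.shape[-2:])
    x2 = ad.reshape(x2, x2.shape[-2:])
    p1 = ad.mean(gen, axis=1)  # along y -> (z, x), anterior view
    p2 = ad.mean(gen, axis=2)  # along x -> (z, y), lateral view
    t1 = ad.mean(ad.square(ad.sub(p1, x1)))
    t2 = ad.mean(ad.square(ad.sub(p2, x2)))
    return ad.mul(ad.add(t1, t2), 0.5)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def learning_rate_at_epoch(base_lr: float, epoch: int, n_epochs: int) -> float:
    """Constant for the first half of training, then linear decay to 0."""
    half = n_epochs // 2
    if epoch < half or n_epochs == 1:
        return base_lr
    return base_lr * (n_epochs - epoch) / (n_epochs - half)


@dataclass
class TrainResult:
    generator: TwoViewFusionGenerator
    discriminator: ConditionalPatchDiscriminator3d
    history: list
    log_path: str | None = None
    checkpoints: list = field(default_factory=list)


def _check_finite(value: float, term: str):
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in term '{term}'; aborting training")


def train(dataset, cfg: GanConfig, log_dir: str | None = None) -> TrainResult:
    """Alternating LSGAN training over a collection of paired samples."""
    samples = list(dataset)
    if not samples:
        raise ValueError("training dataset is empty")
    for s in samples:
        if not isinstance(s, PairedSample):
            raise TypeError("train expects PairedSample records")

    rng = np.random.default_rng(cfg.seed)
    G = TwoViewFusionGenerator(cfg, np.random.default_rng(rng.integers(2**31 - 1)))
    D = ConditionalPatchDiscriminator3d(
        cfg, np.random.default_rng(rng.integers(2**31 - 1))
    )
    opt_g = Adam(G.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_d = Adam(D.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    w = cfg.loss_weights
    adversarial = w.w_gan > 0 or w.w_fm > 0

    history = []
    checkpoints = []
    log_path = None
    if log_dir is not None:
        os.makedirs(log_dir, exist_ok=True)
        log_path = os.path.join(log_dir, "loss_log.csv")
        with open(log_path, "w") as fh:
            fh.write(
                "epoch,lr,loss_d,loss_g,l_adv,l_recon,l_proj,l_fm,l_idt\n"
            )

    for epoch in range(cfg.n_epochs):
        lr = learning_rate_at_epoch(cfg.learning_rate, epoch, cfg.n_epochs)
        opt_g.lr = lr
        opt_d.lr = lr
        order = rng.permutation(len(samples))
        sums = dict.fromkeys(
            ("loss_d", "loss_g", "l_adv", "l_recon", "l_proj", "l_fm", "l_idt"), 0.0
        )
        for idx in order:
            s = samples[idx]
            gt = Tensor(np.asarray(s.ct, dtype=np.float32))
            x1 = np.asarray(s.xray1, dtype=np.float32)
            x2 = np.asarray(s.xray2, dtype=np.float32)

            fake = G(x1, x2)

            if adversarial:
                # --- discriminator step (generator detached) ---
                d_real, feats_real = D(gt, x1, x2, return_features=True)
                d_fake_det = D(Tensor(fake.data.copy()), x1, x2)
                loss_d, _ = lsgan_loss(d_real, d_fake_det)
                _check_finite(float(loss_d.data), "lsgan_D")
                opt_d.zero_grad()
                loss_d.backward()
                opt_d.step()
                feats_real_det = [Tensor(f.data.copy()) for f in feats_real]
            else:
                loss_d = None

            # --- generator step ---
            terms = {}
            total = None

            def add_term(name, weight, tensor):
                nonlocal total
                value = float(tensor.data)
                _check_finite(value, name)
                terms[name] = value
                if weight > 0:
                    weighted = ad.mul(tensor, weight)
                    total = weighted if total is None else ad.add(total, weighted)

            if adversarial:
                d_fake, feats_fake = D(fake, x1, x2, return_features=True)
                l_adv = ad.mean(ad.square(ad.sub(d_fake, 1.0)))
                add_term("l_adv", w.w_gan, l_adv)
                add_term(
                    "l_fm", w.w_fm, feature_matching_loss(feats_real_det, feats_fake)
                )
            else:
                terms["l_adv"] = 0.0
                terms["l_fm"] = 0.0
            add_term("l_recon", w.w_recon, reconstruction_loss(fake, gt))
            add_term("l_proj", w.w_proj, projection_loss(fake, gt))
            add_term("l_idt", w.w_idt, identity_loss(fake, x1, x2))

            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            sums["loss_d"] += float(loss_d.data) if loss_d is not None else 0.0
            sums["loss_g"] += float(total.data)
            for k in ("l_adv", "l_recon", "l_proj", "l_fm", "l_idt"):
                sums[k] += terms[k]

        record = {"epoch": epoch, "lr": lr}
        record.update({k: v / len(samples) for k, v in sums.items()})
        history.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(
                    ",".join(
                        str(record[k])
                        for k in (
                            "epoch",
                            "lr",
                            "loss_d",
                            "loss_g",
                            "l_adv",
                            "l_recon",
                            "l_proj",
                            "l_fm",
                            "l_idt",
                        )
                    )
                    + "\n"
                )
        save_now = (
            cfg.checkpoint_interval > 0
            and (epoch + 1) % cfg.checkpoint_interval == 0
        ) or epoch == cfg.n_epochs - 1
        if log_dir is not None and save_now:
            ckpt = os.path.join(log_dir, f"generator_epoch{epoch:04d}.npz")
            np.savez(ckpt, *G.state_arrays())
            checkpoints.append(ckpt)

    return TrainResult(G, D, history, log_path, checkpoints)
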