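"""Patient-specific conditional GAN for prostate segmentation.

A UNet generator G maps an anatomy projection x (normalised to [0, 1]) to
a segmentation image G(x) in [0, 1]; a PatchGAN discriminator D scores
(x, y) pairs patch-wise.  Training minimises

    G* = arg min_G max_D  L_cGAN(G, D) + lambda * L_L1(G)

with  L_cGAN = E[log D(x, y)] + E[log(1 - D(x, G(x)))]  and
L_L1 = E||y - G(x)||_1, lambda = 100 by default.  The generator's
adversarial term is implemented in the standard non-saturating form
(-log D(x, G(x))) while the lambda * L1 term is unchanged; expectations
are means over patches, pixels and the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .augmentation import TrainingManifest
from .nn import Adam, Conv2d, ConvTranspose2d, InstanceNorm, Module, Tensor
from .nn import autodiff as ad

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ModelArtifact",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_networks",
    "cgan_objective",
    "train_patient_model",
    "CGANSegmenter",
]

SCORE_EPS = 1e-7  # discriminator scores are clamped to [eps, 1 - eps]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``image_size`` must be a power of two and at least 2**generator_depth;
    the defaults target full 512 x 512 projections, while 64 x 64 instances
    (image_size=64, base_channels=8, generator_depth=3) are first-class for
    desk-scale runs.
    """

    image_size: int = 512
    base_channels: int = 64
    generator_depth: int = 6
    discriminator_patch_levels: int = 3
    lambda_l1: float = 100.0
    init_std: float = 0.02

    def __post_init__(self) -> None:
        s = self.image_size
        if s < 2 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two")
        if s < 2**self.generator_depth:
            raise ValueError("image_size must be >= 2**generator_depth")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.base_channels < 1 or self.generator_depth < 1:
            raise ValueError("channels and depth must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam with GAN-standard moments).

    The imbalanced L1 objective has an all-background local minimum that
    some parameter initialisations never escape; after
    ``collapse_check_epochs`` epochs the trainer probes the generator and,
    if its predictions are empty at the segmentation threshold, restarts
    with a reseeded initialisation (up to ``max_restarts`` times, all
    derived deterministically from ``seed``).
    """

    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 2e-4
    seed: int = 0
    max_restarts: int = 6
    collapse_check_epochs: int = 3

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_restarts < 0 or self.collapse_check_epochs < 1:
            raise ValueError("restart parameters must be non-negative / positive")


def _chan(base: int, level: int) -> int:
    return base * min(2**level, 8)


class UNetGenerator(Module):
    """Encoder-decoder with skip connections; sigmoid output in [0, 1].

    ``input_offset``/``input_scale`` define a fixed affine standardisation
    applied to the input before the first convolution.  They are set from
    the training set's mean and standard deviation: the [0, 1] min-max
    interface normalisation leaves anatomy in a narrow high band with
    little contrast, and standardising restores O(1) feature variance.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        d, b, std = cfg.generator_depth, cfg.base_channels, cfg.init_std
        self.depth = d
        self.input_offset = 0.0
        self.input_scale = 1.0
        self.enc = []
        prev = 1
        for level in range(d):
            self.enc.append(Conv2d(prev, _chan(b, level), 4, 2, 1, init_std=std, rng=rng))
            prev = _chan(b, level)
        self.enc_norm = [InstanceNorm(_chan(b, level)) for level in range(1, d)]
        self.dec = []
        self.dec_norm = []
        for i in range(d - 1):
            cin = _chan(b, d - 1 - i) * (1 if i == 0 else 2)
            cout = _chan(b, d - 2 - i)
            self.dec.append(ConvTranspose2d(cin, cout, 4, 2, 1, init_std=std, rng=rng))
            self.dec_norm.append(InstanceNorm(cout))
        cin_last = _chan(b, 0) * (2 if d > 1 else 1)
        self.final = ConvTranspose2d(cin_last, 1, 4, 2, 1, init_std=std, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        if self.input_offset != 0.0 or self.input_scale != 1.0:
            h = Tensor((x.data - self.input_offset) / self.input_scale)
        else:
            h = x
        for level, conv in enumerate(self.enc):
            h = conv(h)
            if level > 0:
                h = self.enc_norm[level - 1](h)
            h = ad.leaky_relu(h, 0.2)
            skips.append(h)
        for i, up in enumerate(self.dec):
            h = self.dec_norm[i](up(h))
            h = ad.relu(h)
            h = ad.concat(h, skips[self.depth - 2 - i])
        return ad.sigmoid(self.final(h))


class PatchDiscriminator(Module):
    """PatchGAN: scores overlapping patches of an (x, y) channel pair."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        n, b, std = cfg.discriminator_patch_levels, cfg.base_channels, cfg.init_std
        self.layers = []
        self.norms: list[InstanceNorm | None] = []
        prev = 2
        for i in range(n):
            stride = 2 if i < n - 1 else 1
            cout = _chan(b, i)
            self.layers.append(Conv2d(prev, cout, 4, stride, 1, init_std=std, rng=rng))
            self.norms.append(InstanceNorm(cout) if i > 0 else None)
            prev = cout
        self.final = Conv2d(prev, 1, 4, 1, 1, init_std=std, rng=rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        h = ad.concat(x, y)
        for conv, norm in zip(self.layers, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = ad.leaky_relu(h, 0.2)
        return ad.sigmoid(self.final(h))


def build_networks(cfg: NetworkConfig, seed: int) -> tuple[UNetGenerator, PatchDiscriminator]:
    """Construct (G, D) with seeded zero-mean normal initialisation."""
    rng = np.random.default_rng(seed)
    g = UNetGenerator(cfg, rng)
    d = PatchDiscriminator(cfg, rng)
    # shape contract checks on a dummy pass
    probe = Tensor(np.zeros((1, 1, cfg.image_size, cfg.image_size)))
    out = g(probe)
    if out.shape != probe.shape:
        raise ValueError("generator output shape does not match input")
    patches = d(probe, out.detach())
    if not (patches.shape[2] < cfg.image_size and patches.shape[3] < cfg.image_size):
        raise ValueError("discriminator patch grid must be smaller than the input")
    return g, d


def cgan_objective(
    d_real: Tensor, d_fake: Tensor, y: Tensor, g_x: Tensor, lam: float
) -> tuple[Tensor, Tensor]:
    """Discriminator and generator losses.

    loss_D = -(mean log D(x,y) + mean log(1 - D(x,G(x))))
    loss_G = -mean log D(x,G(x)) + lambda * mean|y - G(x)|

    Scores are clamped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    dr = ad.clip_eps(d_real, SCORE_EPS)
    df = ad.clip_eps(d_fake, SCORE_EPS)
    one_minus_df = ad.sub(Tensor(np.ones_like(df.data)), df)
    loss_d = ad.scale(ad.add(ad.mean(ad.log(dr)), ad.mean(ad.log(one_minus_df))), -1.0)
    l1 = ad.mean(ad.abs_(ad.sub(y, g_x)))
    loss_g = ad.add(ad.scale(ad.mean(ad.log(df)), -1.0), ad.scale(l1, lam))
    return loss_d, loss_g


@dataclass
class ModelArtifact:
    """A trained patient model: parameters, training history, and configs."""

    generator: UNetGenerator
    discriminator: PatchDiscriminator
    history: list = field(default_factory=list)  # per-epoch {loss_d, loss_g, l1}
    net_config: NetworkConfig = field(default_factory=NetworkConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    restarts: int = 0  # reseeded attempts consumed by collapse detection

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"g_{i}": a for i, a in enumerate(self.generator.state_arrays())}
        arrays.update({f"d_{i}": a for i, a in enumerate(self.discriminator.state_arrays())})
        meta = {
            "net_config": self.net_config.__dict__,
            "train_config": self.train_config.__dict__,
            "seed": self.seed,
            "restarts": self.restarts,
            "input_offset": self.generator.input_offset,
            "input_scale": self.generator.input_scale,
            "history": self.history,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"].tobytes()).decode())
            ncfg = NetworkConfig(**meta["net_config"])
            tcfg = TrainConfig(**meta["train_config"])
            g, d = build_networks(ncfg, meta["seed"])
            g.load_state_arrays([z[f"g_{i}"] for i in range(len(g.parameters()))])
            d.load_state_arrays([z[f"d_{i}"] for i in range(len(d.parameters()))])
            g.input_offset = float(meta.get("input_offset", 0.0))
            g.input_scale = float(meta.get("input_scale", 1.0))
        return cls(g, d, meta["history"], ncfg, tcfg, meta["seed"], meta.get("restarts", 0))


def _predicted_foreground_fraction(g: UNetGenerator, x: np.ndarray, threshold: float = 0.10) -> float:
    probe = x[: min(16, x.shape[0])][:, None]
    return float(np.mean(g(Tensor(probe)).data >= threshold))


def _train_arrays(
    x: np.ndarray, y: np.ndarray, ncfg: NetworkConfig, tcfg: TrainConfig
) -> ModelArtifact:
    """Train with collapse detection and seeded restarts."""
    if x.ndim != 3 or x.shape != y.shape:
        raise ValueError("expected matching (n, H, W) input and target stacks")
    if x.shape[1] != ncfg.image_size or x.shape[2] != ncfg.image_size:
        raise ValueError(
            f"pair size {x.shape[1:]} does not match configured image_size {ncfg.image_size}"
        )
    if x.shape[0] == 0:
        raise ValueError("training set is empty")
    foreground_rate = float(y.mean())
    for attempt in range(tcfg.max_restarts + 1):
        last_attempt = attempt == tcfg.max_restarts
        artifact = _train_once(x, y, ncfg, tcfg, tcfg.seed + 1000 * attempt, last_attempt)
        if artifact is not None:
            artifact.restarts = attempt
            return artifact
    raise RuntimeError("unreachable")  # pragma: no cover


def _train_once(
    x: np.ndarray,
    y: np.ndarray,
    ncfg: NetworkConfig,
    tcfg: TrainConfig,
    seed: int,
    last_attempt: bool,
) -> ModelArtifact | None:
    """One training attempt; returns None on early-detected collapse."""
    g, d = build_networks(ncfg, seed)
    # standardise the generator's view of the input (see UNetGenerator)
    g.input_offset = float(x.mean())
    g.input_scale = max(float(x.std()), 1e-8)
    # prior-probability initialisation of the output bias: start the
    # generator at the foreground base rate so the heavily imbalanced L1
    # term does not immediately drive the sigmoid towards all-background
    # saturation before the network has learned any features
    prior = float(np.clip(y.mean(), 1e-3, 0.5))
    g.final.b.data[:] = np.log(prior / (1.0 - prior))
    opt_g = Adam(g.parameters(), lr=tcfg.learning_rate)
    opt_d = Adam(d.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    history = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        ep_d, ep_g, ep_l1, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            sel = order[start : start + tcfg.batch_size]
            xb = Tensor(x[sel][:, None, :, :])
            yb = Tensor(y[sel][:, None, :, :])
            gx = g(xb)
            gx_det = gx.detach()
            # discriminator update on detached generator output
            d_real = d(xb, yb)
            d_fake = d(xb, gx_det)
            loss_d, _ = cgan_objective(d_real, d_fake, yb, gx_det, ncfg.lambda_l1)
            if not np.isfinite(loss_d.data):
                raise FloatingPointError(
                    f"non-finite discriminator loss at epoch {epoch}, batch {start // tcfg.batch_size}"
                )
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()
            # generator update through the updated discriminator
            d_fake2 = d(xb, gx)
            _, loss_g = cgan_objective(d_real.detach(), d_fake2, yb, gx, ncfg.lambda_l1)
            if not np.isfinite(loss_g.data):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}, batch {start // tcfg.batch_size}"
                )
            opt_g.zero_grad()
            opt_d.zero_grad()
            loss_g.backward()
            opt_g.step()
            ep_d += loss_d.item()
            ep_g += loss_g.item()
            ep_l1 += float(np.mean(np.abs(y[sel][:, None] - gx.data)))
            nb += 1
        history.append({"loss_d": ep_d / nb, "loss_g": ep_g / nb, "l1": ep_l1 / nb})
        if (
            not last_attempt
            and epoch + 1 == tcfg.collapse_check_epochs
            and epoch + 1 < tcfg.epochs
        ):
            # collapsed runs predict (almost) nothing at the segmentation
            # threshold; abandon the attempt and reinitialise
            frac = _predicted_foreground_fraction(g, x)
            if frac < 0.1 * float(y.mean()):
                return None
    return ModelArtifact(g, d, history, ncfg, tcfg, tcfg.seed)


def train_patient_model(
    manifest: TrainingManifest, ncfg: NetworkConfig, tcfg: TrainConfig
) -> ModelArtifact:
    """Train the patient-specific model on a paired training set."""
    if manifest.n_pairs == 0:
        raise ValueError("training manifest is empty")
    x, y, _ = manifest.load_arrays()
    return _train_arrays(x, y, ncfg, tcfg)


class CGANSegmenter(BaseEstimator):
    """Scikit-learn style estimator wrapping the conditional GAN.

    ``fit(X, y)`` takes an (n, s, s) stack of anatomy projections in
    [0, 1] and a matching binary mask stack; ``predict(X)`` returns
    thresholded binary masks and ``predict_proba(X)`` the raw generator
    output in [0, 1].
    """

    def __init__(
        self,
        image_size: int = 64,
        base_channels: int = 8,
        generator_depth: int = 3,
        discriminator_patch_levels: int = 3,
        lambda_l1: float = 100.0,
        epochs: int = 10,
        batch_size: int = 4,
        learning_rate: float = 2e-4,
        threshold: float = 0.10,
        seed: int = 0,
    ):
        self.image_size = image_size
        self.base_channels = base_channels
        self.generator_depth = generator_depth
        self.discriminator_patch_levels = discriminator_patch_levels
        self.lambda_l1 = lambda_l1
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.seed = seed

    def _configs(self) -> tuple[NetworkConfig, TrainConfig]:
        ncfg = NetworkConfig(
            image_size=self.image_size,
            base_channels=self.base_channels,
            generator_depth=self.generator_depth,
            discriminator_patch_levels=self.discriminator_patch_levels,
            lambda_l1=self.lambda_l1,
        )
        tcfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )
        return ncfg, tcfg

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        ncfg, tcfg = self._configs()
        artifact = _train_arrays(X, y, ncfg, tcfg)
        self.artifact_ = artifact
        self.generator_ = artifact.generator
        self.discriminator_ = artifact.discriminator
        self.history_ = artifact.history
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "generator_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float64)
        out = np.empty_like(X)
        for start in range(0, X.shape[0], 8):
            xb = Tensor(X[start : start + 8][:, None])
            out[start : start + 8] = self.generator_(xb).data[:, 0]
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold
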