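"""Cycle-consistent adversarial MV-to-CT intensity translation.

Two generators (MV->CT and CT->MV) and two least-squares discriminators are
trained with the CycleGAN objective (adversarial + lambda * cycle
consistency) on tanh-scaled images.  The networks are small per-pixel
residual intensity maps — the degrees of freedom that matter for the
MV/CT translation problem at toy scale, where the two domains differ by a
monotone intensity transform plus noise — implemented in NumPy so training
is deterministic on one CPU.

A generator computes ``y = tanh(atanh(x) + f(x))`` with ``f`` a small MLP:
it is exactly the identity at ``f = 0``, and the final tanh keeps outputs
strictly inside (-1, 1) so the inverse HU scaling is always finite.

A deterministic *surrogate translator* ships alongside the learned one: a
fixed piecewise-linear HU map that restores the MV soft-tissue contrast
(the inverse of the simulator's MV compression map).  It decouples the
fusion/MAR/metrics pipeline from stochastic optimization.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import constants as C
from .core import ImageVolume, clamp_hu
from .nn import MLP, Adam
from .scaling import METHODS, forward_scale, get_spec, inverse_scale

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "CycleGANModel",
    "SurrogateTranslator",
    "TranslatorBank",
    "build_translator",
    "lr_schedule",
    "train_translator",
    "translate",
    "toy_config",
]

_EPS = 1e-7


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters for the cycle-consistent translator.

    The defaults mirror the clinical training recipe (batch size 6, Adam at
    lr 2e-4 constant for 100 epochs then decayed over 100 more);
    :func:`toy_config` gives the desk-scale variant.
    """

    gen_width: int = 32
    gen_depth: int = 3
    disc_width: int = 32
    cycle_weight: float = 10.0
    batch_size: int = 6
    epochs_constant: int = 100
    epochs_decay: int = 100
    lr0: float = 2e-4
    #: "attenuated by 1% per epoch": 'linear' ramps to zero over the decay
    #: phase (the canonical CycleGAN schedule); 'geometric' multiplies by
    #: 0.99 each decay epoch.
    decay_mode: str = "linear"
    #: Weight of the optional identity loss |G_AB(b) - b| + |G_BA(a) - a|;
    #: 0 disables it (the default objective).  It anchors the intensity
    #: maps against uniform drift.
    identity_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = []
        if self.cycle_weight <= 0:
            bad.append("cycle_weight")
        if self.lr0 <= 0:
            bad.append("lr0")
        if self.batch_size < 1:
            bad.append("batch_size")
        if self.gen_width < 1 or self.gen_depth < 1:
            bad.append("gen_width/gen_depth")
        if self.decay_mode not in ("linear", "geometric"):
            bad.append("decay_mode")
        if bad:
            raise ValueError(f"invalid ModelConfig fields: {', '.join(bad)}")

    @property
    def total_epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay


def toy_config(seed: int = 0, epochs: int = 20) -> ModelConfig:
    """Desk-scale config: small widths, few epochs, batch 4.

    The learning rate is higher than the clinical-mirror default because
    the toy runs see far fewer optimizer steps.
    """
    return ModelConfig(
        gen_width=16,
        gen_depth=2,
        disc_width=16,
        batch_size=4,
        epochs_constant=epochs // 2,
        epochs_decay=epochs - epochs // 2,
        lr0=1e-3,
        identity_weight=1.0,
        seed=seed,
    )


@dataclasses.dataclass
class TrainingHistory:
    gen_adv: list[float] = dataclasses.field(default_factory=list)
    disc: list[float] = dataclasses.field(default_factory=list)
    cycle: list[float] = dataclasses.field(default_factory=list)
    lr: list[float] = dataclasses.field(default_factory=list)
    seed: int = 0


def lr_schedule(epoch: int, config: ModelConfig) -> float:
    """Learning rate at a 0-based epoch index."""
    if epoch < 0 or epoch >= config.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.total_epochs})")
    if epoch < config.epochs_constant:
        return config.lr0
    k = epoch - config.epochs_constant + 1  # 1-based index into the decay phase
    if config.decay_mode == "geometric":
        return config.lr0 * 0.99**k
    return config.lr0 * max(0.0, 1.0 - k / config.epochs_decay)


class _Generator:
    """y = tanh(u + f(u)) with u = atanh(x): per-pixel, residual, bounded.

    Both the residual MLP and the skip operate on the atanh (HU-scale)
    representation, where tissue classes are well separated; the final tanh
    returns to the bounded network domain.
    """

    def __init__(self, width: int, depth: int, rng: np.random.Generator):
        self.mlp = MLP([1] + [width] * depth + [1], rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, -1.0 + _EPS, 1.0 - _EPS)
        self._xc = xc
        u = np.arctanh(xc)
        self._y = np.tanh(u + self.mlp.forward(u))
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gpre = gy * (1.0 - self._y**2)
        gu = gpre + self.mlp.backward(gpre)
        return gu / (1.0 - self._xc**2)

    @property
    def params(self):
        return self.mlp.params

    @property
    def grads(self):
        return self.mlp.grads


class _Discriminator:
    """Least-squares patch critic on the atanh (HU-scale) representation."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.mlp = MLP([1, width, width, 1], rng, out_scale=0.1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, -1.0 + _EPS, 1.0 - _EPS)
        self._xc = xc
        return self.mlp.forward(np.arctanh(xc))

    def backward(self, gs: np.ndarray) -> np.ndarray:
        return self.mlp.backward(gs) / (1.0 - self._xc**2)

    @property
    def params(self):
        return self.mlp.params

    @property
    def grads(self):
        return self.mlp.grads


class CycleGANModel:
    """Two generators + two discriminators with seeded initialization."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.gen_ab = _Generator(config.gen_width, config.gen_depth, rng)  # MV -> CT
        self.gen_ba = _Generator(config.gen_width, config.gen_depth, rng)  # CT -> MV
        self.disc_a = _Discriminator(config.disc_width, rng)
        self.disc_b = _Discriminator(config.disc_width, rng)
        self.trained = False

    def parameter_count(self) -> int:
        nets = [self.gen_ab, self.gen_ba, self.disc_a, self.disc_b]
        return int(sum(p.size for net in nets for p in net.params))

    def generate(self, x: np.ndarray, direction: str = "ab") -> np.ndarray:
        gen = self.gen_ab if direction == "ab" else self.gen_ba
        shape = x.shape
        return gen.forward(x.reshape(-1, 1)).reshape(shape)


def build_translator(config: ModelConfig) -> CycleGANModel:
    """Construct the model; parameters are deterministic given the seed."""
    return CycleGANModel(config)


def _sum_grads(a: list[np.ndarray], b: list[np.ndarray]) -> list[np.ndarray]:
    return [x + y for x, y in zip(a, b)]


def train_translator(
    a_images: np.ndarray,
    b_images: np.ndarray,
    config: ModelConfig,
    model: CycleGANModel | None = None,
) -> tuple[CycleGANModel, TrainingHistory]:
    """Train on scaled images from domain A (MV) and domain B (CT).

    ``a_images``/``b_images`` are arrays of shape (n, H, W) with values in
    (-1, 1).  The objective is least-squares adversarial loss plus
    ``cycle_weight`` times the L1 cycle-consistency loss.  Deterministic
    given the config seed.
    """
    a_images = np.asarray(a_images, dtype=np.float64)
    b_images = np.asarray(b_images, dtype=np.float64)
    if a_images.ndim != 3 or b_images.ndim != 3:
        raise ValueError("expected image stacks of shape (n, H, W)")
    if np.abs(a_images).max() >= 1.0 or np.abs(b_images).max() >= 1.0:
        raise ValueError("training images must be strictly inside (-1, 1); scale them first")

    model = model or build_translator(config)
    rng = np.random.default_rng(config.seed + 1)
    g_params = model.gen_ab.params + model.gen_ba.params
    opt_g = Adam(g_params, lr=config.lr0)
    opt_da = Adam(model.disc_a.params, lr=config.lr0)
    opt_db = Adam(model.disc_b.params, lr=config.lr0)
    hist = TrainingHistory(seed=config.seed)
    lam = config.cycle_weight

    n_a, n_b = len(a_images), len(b_images)
    n_batches = max(1, min(n_a, n_b) // config.batch_size)

    for epoch in range(config.total_epochs):
        lr = lr_schedule(epoch, config)
        opt_g.lr = opt_da.lr = opt_db.lr = lr
        order_a = rng.permutation(n_a)
        order_b = rng.permutation(n_b)
        e_adv, e_disc, e_cyc = 0.0, 0.0, 0.0
        for it in range(n_batches):
            ia = order_a[(it * config.batch_size) % n_a : (it * config.batch_size) % n_a + config.batch_size]
            ib = order_b[(it * config.batch_size) % n_b : (it * config.batch_size) % n_b + config.batch_size]
            a = a_images[ia].reshape(-1, 1)
            b = b_images[ib].reshape(-1, 1)
            na, nb = len(a), len(b)

            # --- generator update (A side: a -> fa -> rec_a) ---------------
            fa = model.gen_ab.forward(a)
            s_fa = model.disc_b.forward(fa)
            adv_b = float(np.mean((s_fa - 1.0) ** 2))
            g_fa_adv = model.disc_b.backward(2.0 * (s_fa - 1.0) / na)
            rec_a = model.gen_ba.forward(fa)
            cyc_a = float(np.mean(np.abs(rec_a - a)))
            g_fa_cyc = model.gen_ba.backward(lam * np.sign(rec_a - a) / na)
            grads_ba_1 = list(model.gen_ba.grads)
            model.gen_ab.backward(g_fa_adv + g_fa_cyc)
            grads_ab_1 = list(model.gen_ab.grads)
            fa_detached = fa.copy()

            # --- generator update (B side: b -> fb -> rec_b) ---------------
            fb = model.gen_ba.forward(b)
            s_fb = model.disc_a.forward(fb)
            adv_a = float(np.mean((s_fb - 1.0) ** 2))
            g_fb_adv = model.disc_a.backward(2.0 * (s_fb - 1.0) / nb)
            rec_b = model.gen_ab.forward(fb)
            cyc_b = float(np.mean(np.abs(rec_b - b)))
            g_fb_cyc = model.gen_ab.backward(lam * np.sign(rec_b - b) / nb)
            grads_ab_2 = list(model.gen_ab.grads)
            model.gen_ba.backward(g_fb_adv + g_fb_cyc)
            grads_ba_2 = list(model.gen_ba.grads)
            fb_detached = fb.copy()

            grads_ab = _sum_grads(grads_ab_1, grads_ab_2)
            grads_ba = _sum_grads(grads_ba_1, grads_ba_2)
            if config.identity_weight > 0:
                # identity terms: each generator should leave its *target*
                # domain unchanged
                id_b = model.gen_ab.forward(b)
                model.gen_ab.backward(config.identity_weight * np.sign(id_b - b) / nb)
                grads_ab = _sum_grads(grads_ab, model.gen_ab.grads)
                id_a = model.gen_ba.forward(a)
                model.gen_ba.backward(config.identity_weight * np.sign(id_a - a) / na)
                grads_ba = _sum_grads(grads_ba, model.gen_ba.grads)
            opt_g.step(grads_ab + grads_ba)

            # --- discriminator updates on detached fakes -------------------
            s_real = model.disc_b.forward(b)
            loss_db = float(np.mean((s_real - 1.0) ** 2))
            model.disc_b.backward(2.0 * (s_real - 1.0) / nb)
            g_real = list(model.disc_b.grads)
            s_fake = model.disc_b.forward(fa_detached)
            loss_db += float(np.mean(s_fake**2))
            model.disc_b.backward(2.0 * s_fake / na)
            opt_db.step(_sum_grads(g_real, model.disc_b.grads))

            s_real = model.disc_a.forward(a)
            loss_da = float(np.mean((s_real - 1.0) ** 2))
            model.disc_a.backward(2.0 * (s_real - 1.0) / na)
            g_real = list(model.disc_a.grads)
            s_fake = model.disc_a.forward(fb_detached)
            loss_da += float(np.mean(s_fake**2))
            model.disc_a.backward(2.0 * s_fake / nb)
            opt_da.step(_sum_grads(g_real, model.disc_a.grads))

            losses = (adv_a, adv_b, cyc_a, cyc_b, loss_da, loss_db)
            if not all(np.isfinite(v) for v in losses):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {it}: {losses}")
            e_adv += adv_a + adv_b
            e_disc += loss_da + loss_db
            e_cyc += cyc_a + cyc_b

        hist.gen_adv.append(e_adv / n_batches)
        hist.disc.append(e_disc / n_batches)
        hist.cycle.append(e_cyc / n_batches)
        hist.lr.append(lr)

    model.trained = True
    return model, hist


# ---------------------------------------------------------------------------
# Translation front ends
# ---------------------------------------------------------------------------

def toy_benchmark_data(n: int, seed: int, size: int = 64, noise_hu: float = 30.0):
    """The synthetic translation benchmark: CT truths and their MV images.

    MV is the fixed monotone contrast-compression of CT plus Gaussian noise
    (sigma ``noise_hu``), clamped to the MV range — the minimal stand-in
    for the modality gap the translator must bridge.  Returns (ct, mv) HU
    stacks of shape (n, size, size).
    """
    from .phantom import PhantomSpec, make_phantom, mv_truth_from_ct

    rng = np.random.default_rng(seed)
    spacing = 128.0 / size
    cts, mvs = [], []
    for i in range(n):
        truth, _ = make_phantom(PhantomSpec(shape=(size, size), spacing=(spacing, spacing), seed=seed * 1000 + i))
        cts.append(np.clip(truth.values, -1000.0, 3000.0))
        mv = mv_truth_from_ct(truth).values + rng.normal(0.0, noise_hu, truth.values.shape)
        mvs.append(np.clip(mv, -1000.0, 1400.0))
    return np.asarray(cts), np.asarray(mvs)


def run_toy_benchmark(seed: int, n_pairs: int = 100, epochs: int = 20, method: str = "P1") -> dict:
    """Train at toy scale and compare against the identity baseline.

    Returns the mean absolute error (HU) of the raw MV images vs the CT
    truths (``mae_identity``) and of the translated images
    (``mae_translated``), both over the training distribution.
    """
    cts, mvs = toy_benchmark_data(n_pairs, seed)
    mv_spec = get_spec(method, "mv")
    ct_spec = get_spec(method, "ct")
    a = np.tanh((mvs - mv_spec.shift) / mv_spec.divisor)
    b = np.tanh((cts - ct_spec.shift) / ct_spec.divisor)
    model, hist = train_translator(a, b, toy_config(seed=seed, epochs=epochs))
    spacing = 128.0 / cts.shape[-1]
    maes = []
    for ct, mv in zip(cts, mvs):
        vol = ImageVolume(mv, (spacing, spacing), modality="mv")
        sct = translate(model, vol, method)
        maes.append(float(np.mean(np.abs(sct.values - ct))))
    return {
        "mae_identity": float(np.mean(np.abs(mvs - cts))),
        "mae_translated": float(np.mean(maes)),
        "history": hist,
        "model": model,
    }


class SurrogateTranslator:
    """Deterministic MV->CT translator needing no training.

    ``mode='contrast'`` (default) applies the fixed piecewise-linear HU map
    that restores soft-tissue contrast (the inverse of the simulator's MV
    compression); ``mode='identity'`` is the identity in the scaled domain,
    so its output is exactly ``inverse_scale(forward_scale(mv))`` under the
    CT-side spec.
    """

    trained = True

    def __init__(self, mode: str = "contrast", mv_contrast: float = 0.6):
        if mode not in ("contrast", "identity"):
            raise ValueError("mode must be 'contrast' or 'identity'")
        self.mode = mode
        kn_ct = C.MV_COMPRESSION_KNOTS_CT.copy()
        kn_mv = C.MV_COMPRESSION_KNOTS_MV.copy()
        kn_mv[1] = kn_ct[1] * mv_contrast
        kn_mv[3] = kn_ct[3] * mv_contrast
        self._kn_mv, self._kn_ct = kn_mv, kn_ct

    def generate(self, x: np.ndarray, method: str) -> np.ndarray:
        if self.mode == "identity":
            return x
        mv_spec = get_spec(method, "mv")
        ct_spec = get_spec(method, "ct")
        xc = np.clip(x, -1.0 + _EPS, 1.0 - _EPS)
        hu_mv = mv_spec.shift + mv_spec.divisor * np.arctanh(xc)
        hu_ct = np.interp(hu_mv, self._kn_mv, self._kn_ct)
        return np.tanh((hu_ct - ct_spec.shift) / ct_spec.divisor)

    def translate(self, mv: ImageVolume, method: str = "P1") -> ImageVolume:
        return translate(self, mv, method)


class TranslatorBank:
    """One trained model per scaling method, behind a common interface."""

    def __init__(self, models: dict[str, CycleGANModel], allow_untrained: bool = False):
        unknown = set(models) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown scaling methods: {sorted(unknown)}")
        self.models = models
        self.allow_untrained = allow_untrained

    def translate(self, mv: ImageVolume, method: str) -> ImageVolume:
        if method not in self.models:
            raise KeyError(f"no model for method {method!r}")
        model = self.models[method]
        if not model.trained and not self.allow_untrained:
            raise RuntimeError(
                f"model for {method!r} is untrained; pass allow_untrained=True to override"
            )
        return translate(model, mv, method)


def translate(model, mv: ImageVolume, method: str = "P1") -> ImageVolume:
    """Full translation pipeline: clamp -> scale -> generate -> unscale -> clamp.

    ``model`` is anything with a ``generate(x, ...)`` mapping scaled MV
    intensities to scaled CT intensities: a :class:`CycleGANModel` (MV->CT
    direction) or a :class:`SurrogateTranslator`.
    """
    mv_c = clamp_hu(mv if mv.modality == "mv" else mv.with_values(mv.values, modality="mv"))
    x = forward_scale(mv_c, get_spec(method, "mv"))
    if isinstance(model, SurrogateTranslator):
        y = model.generate(x, method)
    elif isinstance(model, CycleGANModel):
        y = model.generate(x, direction="ab")
    else:
        y = model.generate(x)
    out = inverse_scale(y, get_spec(method, "ct"), like=mv_c)
    return out.with_values(out.values, modality="sct")
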