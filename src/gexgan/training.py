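"""Adversarial and variational training loops.

The main loop trains a Wasserstein critic with gradient penalty: for each
minibatch the critic takes a step on mean(D(fake)) - mean(D(real)) + GP, and
after every ``n_critic`` critic steps the generator takes a step on
-mean(D(fake)).  The interpolation point for the penalty is drawn once per
sample (not per feature).  All randomness — latent draws, interpolation
coefficients, shuffling — flows from one seeded generator per run, so a run is
fully reproducible from (seed, config, data).

Defaults follow the reference experimental setup: Adam with lr 1e-4, beta1
0.5, beta2 0.9, batch size 32, 500 epochs.  n_critic = 5 and lambda = 10 are
the standard WGAN-GP settings (not stated in the source experiments) and are
exposed in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .core_io import CovariateTable, ExpressionMatrix, ValidationError
from .models import Critic, ModelBundle, save_model


class NumericError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 32
    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    n_critic: int = 5
    gp_lambda: float = 10.0
    seed: int = 0
    device: str = "cpu"
    checkpoint_every: int = 0  # 0 = final checkpoint only

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.n_critic) < 1 or self.lr <= 0:
            raise ValidationError("epochs, batch_size, n_critic must be >= 1 and lr > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValidationError("Adam betas must be in (0, 1)")
        if self.gp_lambda < 0:
            raise ValidationError("gradient penalty weight must be >= 0")

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class TrainHistory:
    critic_loss: list = field(default_factory=list)
    generator_loss: list = field(default_factory=list)
    gradient_penalty: list = field(default_factory=list)
    wasserstein: list = field(default_factory=list)

    def append(self, c, g, gp, w):
        for name, value in (("critic", c), ("generator", g), ("penalty", gp), ("wasserstein", w)):
            if not np.isfinite(value):
                raise NumericError(f"non-finite {name} loss: {value}")
        self.critic_loss.append(float(c))
        self.generator_loss.append(float(g))
        self.gradient_penalty.append(float(gp))
        self.wasserstein.append(float(w))

    def __len__(self):
        return len(self.critic_loss)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("epoch\tcritic_loss\tgenerator_loss\tgradient_penalty\twasserstein\n")
            for i in range(len(self)):
                fh.write(
                    f"{i}\t{self.critic_loss[i]:.8g}\t{self.generator_loss[i]:.8g}"
                    f"\t{self.gradient_penalty[i]:.8g}\t{self.wasserstein[i]:.8g}\n"
                )


# ---------------------------------------------------------------------------
# losses


def gradient_penalty(critic: Critic, x_real, x_fake, c, gp_lambda: float,
                     rng: np.random.Generator) -> Tensor:
    """lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2] on per-sample interpolates.

    xhat = eps * x_real + (1 - eps) * x_fake with eps ~ U(0,1) drawn once per
    sample.  The returned tensor stays in the graph, so differentiating it
    with respect to the critic parameters (double backprop) trains the
    Lipschitz constraint.
    """
    x_real = np.asarray(x_real.data if isinstance(x_real, Tensor) else x_real)
    x_fake = np.asarray(x_fake.data if isinstance(x_fake, Tensor) else x_fake)
    if x_real.shape != x_fake.shape:
        raise ValidationError("real and fake batches must share a shape")
    eps = rng.uniform(size=(x_real.shape[0], 1))
    x_hat = Tensor(eps * x_real + (1.0 - eps) * x_fake, requires_grad=True)
    scores = critic.forward(x_hat, c)
    (g,) = ad.grad(scores.sum(), [x_hat])  # rows are independent, so sum is per-sample
    if not np.all(np.isfinite(g.data)):
        raise NumericError("non-finite critic input gradient in the penalty term")
    sq_norm = (g * g).sum(axis=1)
    norm = ad.sqrt(sq_norm + 1e-12)
    return gp_lambda * ((norm - 1.0) ** 2).mean()


def wgan_gp_losses(scores_real: Tensor, scores_fake: Tensor, penalty) -> tuple[Tensor, Tensor]:
    """(critic loss, generator loss) in minimization form.

    critic loss = mean(D(fake)) - mean(D(real)) + penalty;
    generator loss = -mean(D(fake)).
    """
    if scores_real.data.size == 0 or scores_fake.data.size == 0:
        raise ValidationError("score batches must be nonempty")
    critic_loss = scores_fake.mean() - scores_real.mean() + ad.as_tensor(penalty)
    generator_loss = -scores_fake.mean()
    return critic_loss, generator_loss


def kl_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """Closed-form KL(q || N(0, I)) for a diagonal Gaussian posterior, per batch mean."""
    term = 1.0 + logvar - mu * mu - ad.exp(logvar)
    return (-0.5) * term.sum(axis=1).mean()


# ---------------------------------------------------------------------------
# loop plumbing


def _check_alignment(bundle: ModelBundle, X: ExpressionMatrix, C: CovariateTable | None):
    if X.space_tag == "raw":
        raise ValidationError("training expects normalized expression (apply a normalizer first)")
    if bundle.gene_ids != list(X.gene_ids):
        raise ValidationError("gene order of the model/graph does not match the expression matrix")
    if bundle.embedding is not None:
        if C is None:
            raise ValidationError("model is conditioned but no covariate table was given")
        if C.sample_ids != X.sample_ids:
            raise ValidationError("covariate table is not aligned to the expression matrix")
        if {k: list(v) for k, v in C.vocabularies.items()} != bundle.embedding.vocabularies:
            raise ValidationError("covariate vocabularies do not match the model's embedding spec")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    out = []
    for start in range(0, n, batch_size):
        idx = perm[start:start + batch_size]
        if len(idx) == 1:
            continue  # batch statistics degenerate; dropped (logged by caller)
        out.append(idx)
    return out


def _latent_dim(bundle: ModelBundle) -> int:
    gen = bundle.generator
    return gen.latent_dim if hasattr(gen, "latent_dim") else gen.spec.latent_dim


def _embed(bundle: ModelBundle, codes, track: bool):
    if bundle.embedding is None or codes is None:
        return None
    if track:
        return bundle.embedding(codes)
    with ad.no_grad():
        return Tensor(bundle.embedding(codes).data)


# ---------------------------------------------------------------------------
# training loops


def train_wgan_gp(bundle: ModelBundle, X: ExpressionMatrix, C: CovariateTable | None,
                  config: TrainConfig, checkpoint_dir=None) -> TrainHistory:
    """WGAN-GP loop for both the graph-informed and fully connected generators."""
    _check_alignment(bundle, X, C)
    rng = np.random.default_rng(config.seed)
    codes_all = C.code_matrix() if (C is not None and bundle.embedding is not None) else None
    d = _latent_dim(bundle)

    gen_params = bundle.generator.parameters()
    critic_params = bundle.critic.parameters()
    opt_gen = nn.Adam(gen_params, config.lr, config.beta1, config.beta2)
    opt_critic = nn.Adam(critic_params, config.lr, config.beta1, config.beta2)

    history = TrainHistory()
    step = 0
    for epoch in range(config.epochs):
        c_losses, g_losses, penalties, w_estimates = [], [], [], []
        for idx in _batches(X.n_samples, config.batch_size, rng):
            x_real = X.values[idx]
            codes = codes_all[idx] if codes_all is not None else None

            # critic step (embeddings treated as constants here; they are
            # trained through the generator objective)
            c_vec = _embed(bundle, codes, track=False)
            z = rng.standard_normal((len(idx), d))
            with ad.no_grad():
                x_fake = bundle.generator.forward(z, codes).data
            s_real = bundle.critic.forward(x_real, c_vec)
            s_fake = bundle.critic.forward(x_fake, c_vec)
            gp = gradient_penalty(bundle.critic, x_real, x_fake, c_vec, config.gp_lambda, rng)
            c_loss, _ = wgan_gp_losses(s_real, s_fake, gp)
            grads = ad.grad(c_loss, critic_params)
            opt_critic.step(grads)
            c_losses.append(float(c_loss.data))
            penalties.append(float(gp.data))
            w_estimates.append(float(s_real.data.mean() - s_fake.data.mean()))

            step += 1
            if step % config.n_critic == 0:
                z = rng.standard_normal((len(idx), d))
                c_vec_g = _embed(bundle, codes, track=True)
                fake = bundle.generator.forward(z, codes)
                s_fake = bundle.critic.forward(fake, c_vec_g)
                g_loss = -s_fake.mean()
                grads = ad.grad(g_loss, gen_params)
                opt_gen.step(grads)
                g_losses.append(float(g_loss.data))

        history.append(
            np.mean(c_losses),
            np.mean(g_losses) if g_losses else 0.0,
            np.mean(penalties),
            np.mean(w_estimates),
        )
        if checkpoint_dir and config.checkpoint_every and (epoch + 1) % config.checkpoint_every == 0:
            save_model(bundle, Path(checkpoint_dir) / f"epoch_{epoch + 1:05d}")
    if checkpoint_dir:
        save_model(bundle, Path(checkpoint_dir) / "final")
        history.to_tsv(Path(checkpoint_dir) / "history.tsv")
        (Path(checkpoint_dir) / "train_config.json").write_text(json.dumps(asdict(config), indent=1))
    return history


def train_baseline_gan(bundle: ModelBundle, X: ExpressionMatrix, C: CovariateTable | None,
                       config: TrainConfig, checkpoint_dir=None) -> TrainHistory:
    """Standard (saturating) GAN loop for the fully connected baseline.

    Discriminator scores are logits; the losses use softplus forms of
    -log D(real) - log(1 - D(fake)) and log(1 - D(fake)), which stay finite
    for any score magnitude.
    """
    _check_alignment(bundle, X, C)
    rng = np.random.default_rng(config.seed)
    codes_all = C.code_matrix() if (C is not None and bundle.embedding is not None) else None
    d = _latent_dim(bundle)
    gen_params = bundle.generator.parameters()
    disc_params = bundle.critic.parameters()
    opt_gen = nn.Adam(gen_params, config.lr, config.beta1, config.beta2)
    opt_disc = nn.Adam(disc_params, config.lr, config.beta1, config.beta2)

    history = TrainHistory()
    for _epoch in range(config.epochs):
        d_losses, g_losses = [], []
        for idx in _batches(X.n_samples, config.batch_size, rng):
            x_real = X.values[idx]
            codes = codes_all[idx] if codes_all is not None else None
            c_vec = _embed(bundle, codes, track=False)

            z = rng.standard_normal((len(idx), d))
            with ad.no_grad():
                x_fake = bundle.generator.forward(z, codes).data
            s_real = bundle.critic.forward(x_real, c_vec)
            s_fake = bundle.critic.forward(x_fake, c_vec)
            d_loss = ad.softplus(-s_real).mean() + ad.softplus(s_fake).mean()
            opt_disc.step(ad.grad(d_loss, disc_params))
            d_losses.append(float(d_loss.data))

            z = rng.standard_normal((len(idx), d))
            c_vec_g = _embed(bundle, codes, track=True)
            fake = bundle.generator.forward(z, codes)
            s_fake = bundle.critic.forward(fake, c_vec_g)
            g_loss = (-ad.softplus(s_fake)).mean()  # minimize log(1 - D(G(z)))
            opt_gen.step(ad.grad(g_loss, gen_params))
            g_losses.append(float(g_loss.data))
        history.append(np.mean(d_losses), np.mean(g_losses), 0.0, 0.0)
    if checkpoint_dir:
        save_model(bundle, Path(checkpoint_dir) / "final")
        history.to_tsv(Path(checkpoint_dir) / "history.tsv")
    return history


def train_cvae(bundle: ModelBundle, X: ExpressionMatrix, C: CovariateTable | None,
               config: TrainConfig, checkpoint_dir=None) -> TrainHistory:
    """CVAE loop maximizing the ELBO (MSE reconstruction + closed-form KL)."""
    _check_alignment(bundle, X, C)
    rng = np.random.default_rng(config.seed)
    codes_all = C.code_matrix() if (C is not None and bundle.embedding is not None) else None
    params = bundle.generator.parameters()
    opt = nn.Adam(params, config.lr, config.beta1, config.beta2)
    model = bundle.generator
    history = TrainHistory()
    for _epoch in range(config.epochs):
        losses, recons, kls = [], [], []
        for idx in _batches(X.n_samples, config.batch_size, rng):
            x = X.values[idx]
            codes = codes_all[idx] if codes_all is not None else None
            eps = rng.standard_normal((len(idx), model.latent_dim))
            x_hat, mu, logvar = model.forward(x, codes, eps)
            recon = ((x_hat - x) ** 2).sum(axis=1).mean()
            kl = kl_standard_normal(mu, logvar)
            loss = recon + kl
            opt.step(ad.grad(loss, params))
            losses.append(float(loss.data))
            recons.append(float(recon.data))
            kls.append(float(kl.data))
        history.append(np.mean(losses), np.mean(recons), np.mean(kls), 0.0)
    if checkpoint_dir:
        save_model(bundle, Path(checkpoint_dir) / "final")
        history.to_tsv(Path(checkpoint_dir) / "history.tsv")
    return history


def train(bundle: ModelBundle, X: ExpressionMatrix, C: CovariateTable | None,
          config: TrainConfig, checkpoint_dir=None) -> TrainHistory:
    """Dispatch on the bundle kind (graph_wgan_gp / wgan_gp / gan / cvae)."""
    if bundle.kind in ("graph_wgan_gp", "wgan_gp"):
        return train_wgan_gp(bundle, X, C, config, checkpoint_dir)
    if bundle.kind == "gan":
        return train_baseline_gan(bundle, X, C, config, checkpoint_dir)
    if bundle.kind == "cvae":
        return train_cvae(bundle, X, C, config, checkpoint_dir)
    raise ValidationError(f"unknown model kind {bundle.kind!r}")
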