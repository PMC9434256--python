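"""2-D embeddings of a genotype dosage matrix by eight methods.

Linear/graph methods (PCA, MDS, t-SNE, UMAP) wrap scikit-learn and
umap-learn at their library defaults, fed the raw {0,1,2} dosage matrix
with no centering and no PCA pre-reduction.  Neural methods (autoencoder,
VAE, contrastive) are small fully connected networks — 2 hidden layers of
256 and 128 units, 2-D latent — trained for 100 epochs with Adam.  A
randomly initialized, untrained network of the same shape serves as the
baseline projection: any structure it appears to show is an artifact, so
trained methods must beat it.

Encodings per method:

* AE — each site is a 3-class categorical (dosage 0/1/2); reconstruction
  loss is categorical cross-entropy; learning rate 1e-4.
* VAE — inputs scaled to [0, 1] (dosage / 2); binary cross-entropy
  reconstruction plus KL to a standard-Normal prior; batch-normalized
  encoder/decoder; learning rate 1e-3; the returned embedding is the
  posterior mean.  No early stopping.
* Contrastive — instance discrimination: the positive for a sample is the
  same sample with homozygous sites flipped to heterozygous with
  probability 0.1; the negative is a different sample from the batch;
  similarity is cosine on the 2-D embedding; learning rate 1e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _nn
from ._nn import F32

__all__ = [
    "GenotypeMatrix",
    "EmbeddingResult",
    "NeuralConfig",
    "METHODS",
    "embed",
    "embed_pca",
    "embed_mds",
    "embed_tsne",
    "embed_umap",
    "embed_autoencoder",
    "embed_vae",
    "embed_contrastive",
    "embed_random",
    "augment_het",
    "contrastive_loss",
]


@dataclass
class GenotypeMatrix:
    """Individuals × sites dosage matrix with values in {0, 1, 2}."""

    values: np.ndarray
    ids: list
    snp_chrom: np.ndarray | None = None
    snp_pos: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("id count does not match row count")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise ValueError("dosage values must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class EmbeddingResult:
    """n × 2 coordinates with provenance (method, hyperparameters, seed)."""

    coords: np.ndarray
    ids: list
    method: str
    hyperparams: dict
    seed: int
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be (n_individuals, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.method}: non-finite coordinates")


@dataclass(frozen=True)
class NeuralConfig:
    """Shared architecture/training settings for the neural methods."""

    hidden: tuple[int, int] = (256, 128)
    latent_dim: int = 2
    epochs: int = 100
    lr_ae: float = 1e-4
    lr_vae: float = 1e-3
    lr_contrastive: float = 1e-4
    batch_size: int | None = None     # None -> min(256, n)
    augment_p: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.latent_dim != 2:
            raise ValueError("latent_dim must be 2 for visualization")

    def resolve_batch(self, n: int) -> int:
        return min(256, n) if self.batch_size is None else min(self.batch_size, n)


def _as_float(X: GenotypeMatrix) -> np.ndarray:
    return np.ascontiguousarray(X.values, dtype=F32)


# ---------------------------------------------------------------------------
# linear and graph-based methods (library wrappers, library defaults)
# ---------------------------------------------------------------------------

def embed_pca(X: GenotypeMatrix, seed: int = 0) -> EmbeddingResult:
    """Scores on the first two principal components (centered internally)."""
    from sklearn.decomposition import PCA

    if X.n_individuals < 3:
        raise ValueError("PCA embedding needs at least 3 individuals")
    vals = np.asarray(X.values, dtype=np.float64)
    if np.all(vals.var(axis=0) == 0):
        raise ValueError("genotype matrix is constant; PCA undefined")
    # arpack: exact leading components, much faster than full SVD at p >> n
    pca = PCA(n_components=2, svd_solver="arpack", random_state=seed)
    coords = pca.fit_transform(vals)
    return EmbeddingResult(coords, list(X.ids), "pca",
                           {"explained_variance_ratio":
                            pca.explained_variance_ratio_.tolist()}, seed)


def embed_mds(X: GenotypeMatrix, seed: int = 0) -> EmbeddingResult:
    """Metric MDS (SMACOF) on Euclidean distances in marker space."""
    from sklearn.manifold import MDS

    if X.n_individuals < 3:
        raise ValueError("MDS embedding needs at least 3 individuals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_components=2, random_state=seed, normalized_stress=False)
        coords = mds.fit_transform(_as_float(X).astype(np.float64))
    return EmbeddingResult(coords, list(X.ids), "mds",
                           {"n_init": mds.n_init, "max_iter": mds.max_iter},
                           seed)


def embed_tsne(X: GenotypeMatrix, seed: int = 0) -> EmbeddingResult:
    """t-SNE at scikit-learn defaults on the raw dosage matrix."""
    from sklearn.manifold import TSNE

    if X.n_individuals < 5:
        raise ValueError("t-SNE embedding needs at least 5 individuals")
    tsne = TSNE(n_components=2, random_state=seed)
    coords = tsne.fit_transform(_as_float(X))
    return EmbeddingResult(coords, list(X.ids), "tsne",
                           {"perplexity": tsne.perplexity,
                            "learning_rate": str(tsne.learning_rate),
                            "init": str(tsne.init)}, seed)


def embed_umap(X: GenotypeMatrix, seed: int = 0) -> EmbeddingResult:
    """UMAP at umap-learn defaults on the raw dosage matrix."""
    import umap

    if X.n_individuals < 5:
        raise ValueError("UMAP embedding needs at least 5 individuals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, random_state=seed)
        coords = reducer.fit_transform(_as_float(X))
    return EmbeddingResult(np.asarray(coords), list(X.ids), "umap",
                           {"n_neighbors": reducer.n_neighbors,
                            "min_dist": reducer.min_dist,
                            "metric": reducer.metric}, seed)


# ---------------------------------------------------------------------------
# neural methods
# ---------------------------------------------------------------------------

def _encoder(n_in: int, cfg: NeuralConfig, rng, batchnorm: bool = False,
             n_out: int | None = None) -> _nn.Sequential:
    h1, h2 = cfg.hidden
    n_out = cfg.latent_dim if n_out is None else n_out
    # no gradient w.r.t. the genotype input is ever needed
    layers: list[_nn.Layer] = [_nn.Dense(n_in, h1, rng, input_grad=False)]
    if batchnorm:
        layers.append(_nn.BatchNorm(h1))
    layers += [_nn.ReLU(), _nn.Dense(h1, h2, rng)]
    if batchnorm:
        layers.append(_nn.BatchNorm(h2))
    layers += [_nn.ReLU(), _nn.Dense(h2, n_out, rng)]
    return _nn.Sequential(*layers)


def _decoder(n_out: int, cfg: NeuralConfig, rng,
             batchnorm: bool = False) -> _nn.Sequential:
    h1, h2 = cfg.hidden
    layers: list[_nn.Layer] = [_nn.Dense(cfg.latent_dim, h2, rng)]
    if batchnorm:
        layers.append(_nn.BatchNorm(h2))
    layers += [_nn.ReLU(), _nn.Dense(h2, h1, rng)]
    if batchnorm:
        layers.append(_nn.BatchNorm(h1))
    layers += [_nn.ReLU(), _nn.Dense(h1, n_out, rng)]
    return _nn.Sequential(*layers)


def embed_autoencoder(X: GenotypeMatrix, cfg: NeuralConfig | None = None,
                      seed: int | None = None) -> EmbeddingResult:
    """Autoencoder with per-site 3-class categorical reconstruction."""
    cfg = cfg or NeuralConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x = _as_float(X)
    n, S = x.shape
    target = X.values.astype(np.int64)
    enc = _encoder(S, cfg, rng)
    dec = _decoder(3 * S, cfg, rng)
    opt = _nn.Adam([enc, dec], lr=cfg.lr_ae)
    bs = cfg.resolve_batch(n)
    history = []
    for epoch in range(cfg.epochs):
        total, seen = 0.0, 0
        for idx in _nn.minibatches(n, bs, rng):
            xb, tb = x[idx], target[idx]
            z = enc.forward(xb, train=True)
            logits = dec.forward(z, train=True).reshape(len(idx), S, 3)
            loss, dlogits = _nn.softmax_xent(logits, tb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"AE loss non-finite at epoch {epoch}")
            opt.zero_grad()
            dz = dec.backward(dlogits.reshape(len(idx), 3 * S))
            enc.backward(dz)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
    coords = enc.forward(x, train=False)
    return EmbeddingResult(coords, list(X.ids), "ae",
                           {"hidden": cfg.hidden, "lr": cfg.lr_ae,
                            "epochs": cfg.epochs, "batch_size": bs,
                            "loss": "categorical_crossentropy"},
                           seed, history=history)


def embed_vae(X: GenotypeMatrix, cfg: NeuralConfig | None = None,
              seed: int | None = None) -> EmbeddingResult:
    """VAE on [0,1]-scaled dosages; returns per-individual posterior means.

    Loss = binary cross-entropy reconstruction (summed over sites) +
    KL(q(z|x) || N(0, I)); encoder and decoder are batch-normalized; no
    early stopping.
    """
    cfg = cfg or NeuralConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x01 = (_as_float(X) / F32(2))
    n, S = x01.shape
    enc_trunk = _encoder(S, cfg, rng, batchnorm=True, n_out=cfg.hidden[1])
    # trunk ends in Dense(h1->h2); drop its last layer and attach two heads
    trunk = _nn.Sequential(*enc_trunk.layers[:-1])
    head_in = cfg.hidden[1]
    mu_head = _nn.Dense(head_in, cfg.latent_dim, rng)
    lv_head = _nn.Dense(head_in, cfg.latent_dim, rng)
    dec = _decoder(S, cfg, rng, batchnorm=True)
    opt = _nn.Adam([trunk, mu_head, lv_head, dec], lr=cfg.lr_vae)
    bs = cfg.resolve_batch(n)
    history = []
    for epoch in range(cfg.epochs):
        total, seen = 0.0, 0
        for idx in _nn.minibatches(n, bs, rng):
            xb = x01[idx]
            h = trunk.forward(xb, train=True)
            mu = mu_head.forward(h, train=True)
            logvar = np.clip(lv_head.forward(h, train=True), -10, 10)
            sigma = np.exp(0.5 * logvar).astype(F32)
            eps = rng.standard_normal(mu.shape).astype(F32)
            z = mu + sigma * eps
            logits = dec.forward(z, train=True)
            rec, dlogits = _nn.bce_with_logits(logits, xb)
            kl, dmu_kl, dlv_kl = _nn.gaussian_kl(mu, logvar)
            loss = rec + kl
            if not np.isfinite(loss):
                raise FloatingPointError(f"VAE loss non-finite at epoch {epoch}")
            opt.zero_grad()
            dz = dec.backward(dlogits)
            dmu = dz + dmu_kl
            dlv = (dz * eps * 0.5 * sigma) + dlv_kl
            dh = mu_head.backward(dmu.astype(F32)) + lv_head.backward(dlv.astype(F32))
            trunk.backward(dh.astype(F32))
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
    h = trunk.forward(x01, train=False)
    mu = mu_head.forward(h, train=False)
    logvar = lv_head.forward(h, train=False)
    if np.allclose(np.var(mu, axis=0), 0, atol=1e-6) or np.all(np.exp(logvar) > 0.95):
        warnings.warn("VAE posterior is close to the prior everywhere "
                      "(possible posterior collapse)")
    return EmbeddingResult(mu, list(X.ids), "vae",
                           {"hidden": cfg.hidden, "lr": cfg.lr_vae,
                            "epochs": cfg.epochs, "batch_size": bs,
                            "loss": "bce+kl", "batchnorm": True,
                            "embedding": "posterior_mean"},
                           seed, history=history)


def augment_het(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each homozygous site (dosage 0 or 2) to heterozygous (1) with
    probability ``p``; heterozygous sites are untouched."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"augmentation probability must be in [0,1], got {p}")
    x = np.asarray(x)
    hom = (x == 0) | (x == 2)
    flip = hom & (rng.random(x.shape) < p)
    out = x.copy()
    out[flip] = 1
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return (a * b).sum(axis=-1) / (na * nb)


def contrastive_loss(z: np.ndarray, z_pos: np.ndarray,
                     z_neg: np.ndarray) -> float:
    """−log[ e^φ(z,z⁺) / (e^φ(z,z⁺) + e^φ(z,z⁻)) ] with φ = cosine similarity.

    Accepts single vectors or batches (mean over the batch).  Equal
    similarities give ln 2; the loss decreases monotonically in φ(z,z⁺).
    """
    z, zp, zn = (np.atleast_2d(np.asarray(v, dtype=np.float64))
                 for v in (z, z_pos, z_neg))
    a = _cosine(z, zp)
    b = _cosine(z, zn)
    # −log softmax = softplus(b − a), numerically stable
    d = b - a
    return float(np.mean(np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))))


def _normalize_rows(z: np.ndarray):
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    norm = np.maximum(norm, 1e-12)
    return z / norm, norm


def embed_contrastive(X: GenotypeMatrix, cfg: NeuralConfig | None = None,
                      seed: int | None = None) -> EmbeddingResult:
    """Instance-wise contrastive embedding in 2-D.

    Positives are heterozygosity-augmented copies of each anchor
    (``augment_het`` with p = 0.1); the negative is a uniformly drawn
    different sample from the same batch; similarity is cosine, so the
    learned arrangement is angular (ring-like).
    """
    cfg = cfg or NeuralConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x = _as_float(X)
    n, S = x.shape
    if n < 2:
        raise ValueError("contrastive embedding needs at least 2 individuals")
    enc = _encoder(S, cfg, rng)
    opt = _nn.Adam([enc], lr=cfg.lr_contrastive)
    bs = cfg.resolve_batch(n)
    history = []
    for epoch in range(cfg.epochs):
        total, seen = 0.0, 0
        for idx in _nn.minibatches(n, bs, rng):
            B = len(idx)
            if B < 2:
                continue
            xb = x[idx]
            xpos = augment_het(X.values[idx], cfg.augment_p, rng).astype(F32)
            # negative for anchor i: a different sample j from the batch
            neg = (np.arange(B) + rng.integers(1, B, size=B)) % B
            both = enc.forward(np.concatenate([xb, xpos]), train=True)
            z_raw, zp_raw = both[:B], both[B:]
            zh, zn_ = _normalize_rows(z_raw)
            ph, pn_ = _normalize_rows(zp_raw)
            nh = zh[neg]
            a = (zh * ph).sum(axis=1)
            b = (zh * nh).sum(axis=1)
            d = b - a
            loss = float(np.mean(np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"contrastive loss non-finite at epoch {epoch}")
            s = (1.0 / (1.0 + np.exp(-d)))[:, None] / B  # dL/dd per anchor
            dzh = s * (nh - ph)
            dph = -s * zh
            np.add.at(dzh, neg, s * zh)
            # back through the row normalization u -> u/|u|
            dz_raw = (dzh - (zh * dzh).sum(axis=1, keepdims=True) * zh) / zn_
            dp_raw = (dph - (ph * dph).sum(axis=1, keepdims=True) * ph) / pn_
            opt.zero_grad()
            enc.backward(np.concatenate([dz_raw, dp_raw]).astype(F32))
            opt.step()
            total += loss * B
            seen += B
        history.append(total / max(seen, 1))
    coords = enc.forward(x, train=False)
    return EmbeddingResult(coords, list(X.ids), "contrastive",
                           {"hidden": cfg.hidden, "lr": cfg.lr_contrastive,
                            "epochs": cfg.epochs, "batch_size": bs,
                            "augment_p": cfg.augment_p,
                            "similarity": "cosine"},
                           seed, history=history)


def embed_random(X: GenotypeMatrix, seed: int = 0,
                 cfg: NeuralConfig | None = None) -> EmbeddingResult:
    """Untrained random nonlinear projection (the comparison baseline).

    The encoder architecture with freshly initialized weights, applied
    without any optimization; a pure function of (X, seed).
    """
    cfg = cfg or NeuralConfig()
    rng = np.random.default_rng(seed)
    x = _as_float(X)
    enc = _encoder(x.shape[1], cfg, rng)
    coords = enc.forward(x, train=False)
    return EmbeddingResult(coords, list(X.ids), "random",
                           {"hidden": cfg.hidden, "trained": False}, seed)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

METHODS: dict[str, Callable] = {
    "pca": embed_pca,
    "mds": embed_mds,
    "tsne": embed_tsne,
    "umap": embed_umap,
    "ae": embed_autoencoder,
    "vae": embed_vae,
    "contrastive": embed_contrastive,
    "random": embed_random,
}

_NEURAL = {"ae", "vae", "contrastive"}


def embed(X: GenotypeMatrix, method: str, seed: int = 0,
          cfg: NeuralConfig | None = None) -> EmbeddingResult:
    """Run one named embedding method on a genotype matrix."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {sorted(METHODS)}")
    if method in _NEURAL:
        return METHODS[method](X, cfg, seed=seed)
    if method == "random":
        return embed_random(X, seed=seed, cfg=cfg)
    return METHODS[method](X, seed=seed)
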