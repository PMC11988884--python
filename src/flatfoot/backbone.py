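"""Deterministic Vision-Transformer feature extractor.

Maps a square RGB image to a fixed-length feature vector via the standard
ViT pipeline: 16x16 patch extraction, linear patch embedding with a
prepended class token and learned position embeddings, a stack of pre-norm
encoder blocks (multi-head self-attention + GELU MLP, both residual), a
final LayerNorm, and a linear feature head applied to the class token.

At full scale (224px image, 16px patches, 768-dim embedding, 12 blocks)
the token sequence is 197 x 768 and the head emits 1000 features; every
dimension is configurable down to toy scale so the full pass runs in
milliseconds during tests.

The forward pass is a pure function of ``(weights, image)``: no dropout is
applied unless a rate > 0 *and* an RNG are supplied (training mode).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.special import erf

from .exceptions import (
    InvalidConfigError,
    InvalidInputError,
    InvalidWeightsError,
    NumericError,
)
from .samples import UNLABELED, ImageSample

__all__ = [
    "BackboneConfig",
    "BlockWeights",
    "BackboneWeights",
    "preprocess",
    "patchify",
    "unpatchify",
    "embed_tokens",
    "scaled_attention",
    "encoder_block",
    "forward_features",
    "init_backbone",
    "weights_to_named_arrays",
    "weights_from_named_arrays",
    "weights_from_vit_b16_names",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the transformer backbone.

    Defaults are the ViT-B/16 geometry: 224px input, 16px patches
    (14*14 + 1 class token = 197 tokens), 768-dim embedding, 12 blocks of
    12 heads, MLP ratio 4, and a 1000-dim feature head.
    """

    image_size: int = 224
    patch_size: int = 16
    channels: int = 3
    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 12
    mlp_ratio: int = 4
    feature_dim: int = 1000
    dropout_rate: float = 0.0
    #: per-channel affine normalization applied on entry to the forward
    #: pass: ``(x - mean) / std``; pixel values themselves stay in [0, 1]
    #: inside :class:`~flatfoot.samples.ImageSample`.
    normalize_mean: float = 0.5
    normalize_std: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("image_size", "patch_size", "channels", "embed_dim",
                     "depth", "n_heads", "mlp_ratio", "feature_dim"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be positive")
        if self.image_size % self.patch_size:
            raise InvalidConfigError(
                f"image_size {self.image_size} not divisible by "
                f"patch_size {self.patch_size}")
        if self.embed_dim % self.n_heads:
            raise InvalidConfigError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"n_heads {self.n_heads}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidConfigError("dropout_rate must be in [0, 1)")
        if self.normalize_std <= 0:
            raise InvalidConfigError("normalize_std must be positive")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def n_tokens(self) -> int:
        """Patch tokens plus the prepended class token."""
        return self.n_patches + 1

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2 * self.channels


@dataclass
class BlockWeights:
    """Parameters of one pre-norm encoder block.

    Attention projections are stored per head: ``wq/wk/wv`` have shape
    ``(n_heads, embed_dim, head_dim)`` with matching ``(n_heads, head_dim)``
    biases; ``wo`` recombines the concatenated heads.
    """

    ln1_gamma: np.ndarray
    ln1_beta: np.ndarray
    wq: np.ndarray
    bq: np.ndarray
    wk: np.ndarray
    bk: np.ndarray
    wv: np.ndarray
    bv: np.ndarray
    wo: np.ndarray
    bo: np.ndarray
    ln2_gamma: np.ndarray
    ln2_beta: np.ndarray
    mlp_w1: np.ndarray
    mlp_b1: np.ndarray
    mlp_w2: np.ndarray
    mlp_b2: np.ndarray


@dataclass
class BackboneWeights:
    """All arrays of the backbone; shapes are fixed by a config."""

    patch_proj: np.ndarray      # (patch_dim, embed_dim)
    patch_bias: np.ndarray      # (embed_dim,)
    cls_token: np.ndarray       # (embed_dim,)
    pos_embed: np.ndarray       # (n_tokens, embed_dim)
    blocks: list[BlockWeights] = field(default_factory=list)
    ln_f_gamma: np.ndarray = None
    ln_f_beta: np.ndarray = None
    head_w: np.ndarray = None   # (embed_dim, feature_dim)
    head_b: np.ndarray = None   # (feature_dim,)


def _validate_weights(weights: BackboneWeights, config: BackboneConfig) -> None:
    d, t, p, f = (config.embed_dim, config.n_tokens, config.patch_dim,
                  config.feature_dim)
    checks = [
        (weights.patch_proj.shape, (p, d), "patch_proj"),
        (weights.pos_embed.shape, (t, d), "pos_embed"),
        (weights.cls_token.shape, (d,), "cls_token"),
        (weights.head_w.shape, (d, f), "head_w"),
    ]
    for got, want, name in checks:
        if got != want:
            raise InvalidWeightsError(f"{name}: expected {want}, got {got}")
    if len(weights.blocks) != config.depth:
        raise InvalidWeightsError(
            f"expected {config.depth} blocks, got {len(weights.blocks)}")
    hd = config.head_dim
    for i, blk in enumerate(weights.blocks):
        if blk.wq.shape != (config.n_heads, d, hd):
            raise InvalidWeightsError(f"block {i} attention shape mismatch")


# ---------------------------------------------------------------------------
# elementary ops


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
               eps: float = 1e-6) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def preprocess(image: np.ndarray, config: BackboneConfig) -> ImageSample:
    """Resize to ``image_size`` square, scale to [0, 1], force 3 channels.

    Accepts ``(H, W)``, ``(H, W, 1)`` or ``(H, W, 3)`` arrays, integer
    (assumed 0..255) or float valued. Single-channel input is replicated
    across channels; resizing is bilinear and skipped when the geometry
    already matches.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise InvalidInputError(f"expected 1 or 3 channels, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise InvalidInputError("zero-area image")
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer) or arr.max() > 1.0:
        arr = arr / 255.0
    arr = np.clip(arr, 0.0, 1.0)
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    side = config.image_size
    if arr.shape[:2] != (side, side):
        chans = [
            np.asarray(
                Image.fromarray(arr[:, :, c].astype(np.float32), mode="F")
                .resize((side, side), Image.BILINEAR),
                dtype=np.float64)
            for c in range(arr.shape[2])
        ]
        arr = np.clip(np.stack(chans, axis=2), 0.0, 1.0)
    return ImageSample(pixels=arr, label=UNLABELED)


def patchify(sample: ImageSample | np.ndarray, patch_size: int) -> np.ndarray:
    """Split a square image into row-major, top-left-first flat patches.

    Returns ``(side/patch_size)**2`` rows, each the row-major flattening of
    one ``patch_size x patch_size x channels`` tile; :func:`unpatchify`
    inverts the operation exactly.
    """
    pix = sample.pixels if isinstance(sample, ImageSample) else np.asarray(sample)
    if pix.ndim == 2:
        pix = pix[:, :, None]
    side, side2, c = pix.shape
    if side != side2:
        raise InvalidInputError("image must be square")
    if side % patch_size:
        raise InvalidConfigError(
            f"side {side} not divisible by patch_size {patch_size}")
    n = side // patch_size
    tiles = pix.reshape(n, patch_size, n, patch_size, c)
    return tiles.transpose(0, 2, 1, 3, 4).reshape(n * n, patch_size ** 2 * c)


def unpatchify(patches: np.ndarray, side: int, channels: int) -> np.ndarray:
    """Inverse of :func:`patchify` (used by reconstruction checks)."""
    n_patches, flat = patches.shape
    n = int(round(np.sqrt(n_patches)))
    p = side // n
    tiles = patches.reshape(n, n, p, p, channels)
    return tiles.transpose(0, 2, 1, 3, 4).reshape(side, side, channels)


def embed_tokens(patches: np.ndarray, weights: BackboneWeights) -> np.ndarray:
    """Linear patch embedding + class token + position embeddings.

    Token 0 is the class token plus position row 0; token ``i > 0`` is the
    projection of patch ``i - 1`` plus position row ``i``.
    """
    n_tok, d = weights.pos_embed.shape
    if patches.shape[0] + 1 != n_tok:
        raise InvalidWeightsError(
            f"{patches.shape[0]} patches need {patches.shape[0] + 1} position "
            f"rows, weights have {n_tok}")
    if patches.shape[1] != weights.patch_proj.shape[0]:
        raise InvalidWeightsError("patch length does not match projection")
    embedded = patches @ weights.patch_proj + weights.patch_bias
    tokens = np.vstack([weights.cls_token[None, :], embedded])
    return tokens + weights.pos_embed


def scaled_attention(queries: np.ndarray, keys: np.ndarray,
                     values: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d)) V``.

    ``d`` is the key/query width (the per-head dimension); every softmax
    row sums to 1.
    """
    q, k, v = (np.atleast_2d(np.asarray(m, dtype=np.float64))
               for m in (queries, keys, values))
    if q.size == 0 or k.size == 0 or v.size == 0:
        raise InvalidInputError("empty attention input")
    if q.shape[1] != k.shape[1]:
        raise InvalidInputError("query/key width mismatch")
    if k.shape[0] != v.shape[0]:
        raise InvalidInputError("key/value row-count mismatch")
    scores = q @ k.T / np.sqrt(q.shape[1])
    return softmax(scores, axis=-1) @ v


def _multi_head_attention(tokens: np.ndarray, blk: BlockWeights) -> np.ndarray:
    heads = [
        scaled_attention(tokens @ blk.wq[h] + blk.bq[h],
                         tokens @ blk.wk[h] + blk.bk[h],
                         tokens @ blk.wv[h] + blk.bv[h])
        for h in range(blk.wq.shape[0])
    ]
    return np.concatenate(heads, axis=1) @ blk.wo + blk.bo


def _dropout(x: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0.0 or rng is None:
        return x
    keep = rng.random(x.shape) >= rate
    return x * keep / (1.0 - rate)


def encoder_block(tokens: np.ndarray, blk: BlockWeights,
                  dropout_rate: float = 0.0, rng=None) -> np.ndarray:
    """One pre-norm residual block: ``x + MHA(LN(x))`` then ``+ MLP(LN(.))``.

    Output shape equals input shape; with all attention and MLP weights
    zero the block is the identity map.
    """
    if not np.isfinite(tokens).all():
        raise NumericError("non-finite token values entering encoder block")
    attn = _multi_head_attention(layer_norm(tokens, blk.ln1_gamma, blk.ln1_beta), blk)
    x = tokens + _dropout(attn, dropout_rate, rng)
    h = layer_norm(x, blk.ln2_gamma, blk.ln2_beta)
    mlp = gelu(h @ blk.mlp_w1 + blk.mlp_b1) @ blk.mlp_w2 + blk.mlp_b2
    return x + _dropout(mlp, dropout_rate, rng)


def forward_features(sample: ImageSample, weights: BackboneWeights,
                     config: BackboneConfig, rng=None) -> np.ndarray:
    """Full deterministic forward pass to a ``feature_dim`` vector.

    patchify -> embed -> ``depth`` encoder blocks -> final LayerNorm ->
    class-token row -> linear feature head. ``rng`` enables training-mode
    dropout; at the default it is ignored and the pass is pure.
    """
    _validate_weights(weights, config)
    pix = sample.pixels
    if pix.shape != (config.image_size, config.image_size, config.channels):
        raise InvalidWeightsError(
            f"sample shape {pix.shape} does not match config "
            f"({config.image_size}, {config.image_size}, {config.channels}); "
            "run preprocess first")
    x = (pix - config.normalize_mean) / config.normalize_std
    tokens = embed_tokens(patchify(x, config.patch_size), weights)
    for blk in weights.blocks:
        tokens = encoder_block(tokens, blk, config.dropout_rate, rng)
    tokens = layer_norm(tokens, weights.ln_f_gamma, weights.ln_f_beta)
    cls = tokens[0]
    return cls @ weights.head_w + weights.head_b


def extract_features(samples, weights: BackboneWeights,
                     config: BackboneConfig) -> np.ndarray:
    """Stack :func:`forward_features` over an iterable of samples."""
    return np.array([forward_features(s, weights, config) for s in samples])


# ---------------------------------------------------------------------------
# initialization and checkpoint interop


def init_backbone(config: BackboneConfig, seed: int | None = None) -> BackboneWeights:
    """Random small-variance Gaussian init (sigma=0.02), reproducible.

    Intended for desk-scale experiments and tests; LayerNorm scales start
    at 1, every bias at 0.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d, hd, nh = config.embed_dim, config.head_dim, config.n_heads
    sig = 0.02

    def g(*shape):
        return rng.normal(0.0, sig, size=shape)

    blocks = [
        BlockWeights(
            ln1_gamma=np.ones(d), ln1_beta=np.zeros(d),
            wq=g(nh, d, hd), bq=np.zeros((nh, hd)),
            wk=g(nh, d, hd), bk=np.zeros((nh, hd)),
            wv=g(nh, d, hd), bv=np.zeros((nh, hd)),
            wo=g(d, d), bo=np.zeros(d),
            ln2_gamma=np.ones(d), ln2_beta=np.zeros(d),
            mlp_w1=g(d, config.mlp_ratio * d), mlp_b1=np.zeros(config.mlp_ratio * d),
            mlp_w2=g(config.mlp_ratio * d, d), mlp_b2=np.zeros(d),
        )
        for _ in range(config.depth)
    ]
    return BackboneWeights(
        patch_proj=g(config.patch_dim, d),
        patch_bias=np.zeros(d),
        cls_token=g(d),
        pos_embed=g(config.n_tokens, d),
        blocks=blocks,
        ln_f_gamma=np.ones(d), ln_f_beta=np.zeros(d),
        head_w=g(d, config.feature_dim), head_b=np.zeros(config.feature_dim),
    )


#: Manifest of the flat named-array checkpoint format. Block-level entries
#: are templated on the block index.
NAME_MANIFEST = {
    "patch_proj": "patch_embed/proj", "patch_bias": "patch_embed/bias",
    "cls_token": "cls_token", "pos_embed": "pos_embed",
    "ln_f_gamma": "norm/gamma", "ln_f_beta": "norm/beta",
    "head_w": "head/weight", "head_b": "head/bias",
}
_BLOCK_FIELDS = ("ln1_gamma", "ln1_beta", "wq", "bq", "wk", "bk", "wv", "bv",
                 "wo", "bo", "ln2_gamma", "ln2_beta",
                 "mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2")


def weights_to_named_arrays(weights: BackboneWeights) -> dict[str, np.ndarray]:
    """Flatten weights to the documented name manifest (for .npz saving)."""
    out = {v: getattr(weights, k) for k, v in NAME_MANIFEST.items()}
    for i, blk in enumerate(weights.blocks):
        for f in _BLOCK_FIELDS:
            out[f"blocks/{i}/{f}"] = getattr(blk, f)
    return out


def weights_from_named_arrays(arrays: dict[str, np.ndarray],
                              config: BackboneConfig) -> BackboneWeights:
    """Rebuild :class:`BackboneWeights` from the flat manifest names."""
    try:
        blocks = [
            BlockWeights(**{f: np.asarray(arrays[f"blocks/{i}/{f}"])
                            for f in _BLOCK_FIELDS})
            for i in range(config.depth)
        ]
        weights = BackboneWeights(
            blocks=blocks,
            **{k: np.asarray(arrays[v]) for k, v in NAME_MANIFEST.items()})
    except KeyError as exc:
        raise InvalidWeightsError(f"checkpoint missing array {exc.args[0]!r}")
    _validate_weights(weights, config)
    return weights


def weights_from_vit_b16_names(arrays: dict[str, np.ndarray],
                               config: BackboneConfig) -> BackboneWeights:
    """Adapter for checkpoints using the common ViT-B/16 naming scheme.

    Expects names like ``patch_embed.proj.weight`` (conv kernel, shape
    ``(embed, channels, p, p)``), fused ``blocks.N.attn.qkv.weight`` /
    ``.bias``, ``blocks.N.mlp.fc1/fc2``, ``norm.weight`` and
    ``head.weight``. Linear weights are stored as ``(out, in)`` and are
    transposed; the conv kernel is reordered to match this package's
    row-major ``(p, p, channels)`` patch flattening.
    """
    d, hd, nh, p = (config.embed_dim, config.head_dim, config.n_heads,
                    config.patch_size)

    def get(name):
        try:
            return np.asarray(arrays[name], dtype=np.float64)
        except KeyError:
            raise InvalidWeightsError(f"checkpoint missing array {name!r}")

    conv = get("patch_embed.proj.weight")        # (d, c, p, p)
    patch_proj = conv.transpose(2, 3, 1, 0).reshape(p * p * config.channels, d)
    blocks = []
    for i in range(config.depth):
        pre = f"blocks.{i}."
        qkv_w = get(pre + "attn.qkv.weight")     # (3d, d)
        qkv_b = get(pre + "attn.qkv.bias")
        wq, wk, wv = (m.T.reshape(d, nh, hd).transpose(1, 0, 2)
                      for m in np.split(qkv_w, 3, axis=0))
        bq, bk, bv = (b.reshape(nh, hd) for b in np.split(qkv_b, 3))
        blocks.append(BlockWeights(
            ln1_gamma=get(pre + "norm1.weight"), ln1_beta=get(pre + "norm1.bias"),
            wq=wq, bq=bq, wk=wk, bk=bk, wv=wv, bv=bv,
            wo=get(pre + "attn.proj.weight").T, bo=get(pre + "attn.proj.bias"),
            ln2_gamma=get(pre + "norm2.weight"), ln2_beta=get(pre + "norm2.bias"),
            mlp_w1=get(pre + "mlp.fc1.weight").T, mlp_b1=get(pre + "mlp.fc1.bias"),
            mlp_w2=get(pre + "mlp.fc2.weight").T, mlp_b2=get(pre + "mlp.fc2.bias"),
        ))
    weights = BackboneWeights(
        patch_proj=patch_proj, patch_bias=get("patch_embed.proj.bias"),
        cls_token=get("cls_token").reshape(-1),
        pos_embed=get("pos_embed").reshape(config.n_tokens, d),
        blocks=blocks,
        ln_f_gamma=get("norm.weight"), ln_f_beta=get("norm.bias"),
        head_w=get("head.weight").T, head_b=get("head.bias"),
    )
    _validate_weights(weights, config)
    return weights
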