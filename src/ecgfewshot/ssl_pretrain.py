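"""SimCLR-style contrastive pretraining on the unlabeled pool.

Each source record is expanded into two stochastically augmented views; the
encoder and projection head embed all 2N views of a batch, and the NT-Xent
(normalized temperature-scaled cross-entropy) objective

    L(i,j) = -log  exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau)

pulls the two views of a record together and pushes the other in-batch views
apart; sim is cosine similarity and tau the temperature (0.1 by default).
Pretraining never reads labels — any labeled record in the pool is a hard
failure.  After training the projection head is discarded and only encoder
weights are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentationConfig, make_view_pair
from .nn import Adam, Encoder, EncoderSpec, ProjectionHead, ProjectionSpec, Tensor, logsumexp
from .synthetic_ecg import EcgRecord

__all__ = [
    "PretrainConfig",
    "PretrainResult",
    "LeakageError",
    "cosine_similarity_matrix",
    "nt_xent_loss",
    "encode",
    "pretrain",
]


class LeakageError(RuntimeError):
    """Label information reached a stage that must not see labels."""


@dataclass(frozen=True)
class PretrainConfig:
    """Contrastive pretraining hyperparameters.

    ``batch_pairs`` is the number N of source records per batch (2N views).
    """

    batch_pairs: int = 64
    temperature: float = 0.1
    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_pairs < 1 or self.epochs < 1:
            raise ValueError("batch_pairs and epochs must be >= 1")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


@dataclass
class PretrainResult:
    encoder_state: dict[str, np.ndarray]
    encoder_spec: EncoderSpec
    loss_history: list[float]
    config: PretrainConfig

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loss_history)):
            raise ValueError("loss history contains non-finite values")


def cosine_similarity_matrix(Z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of the rows of ``Z`` (no zero rows)."""
    Z = np.asarray(Z, dtype=np.float64)
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine similarity undefined for zero-norm rows")
    Zn = Z / norms[:, None]
    S = Zn @ Zn.T
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def _default_pairs(n_rows: int) -> np.ndarray:
    return np.arange(n_rows).reshape(-1, 2)


def _check_pairing(pairs: np.ndarray, n_rows: int) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairing must be an (N, 2) index array")
    flat = pairs.ravel()
    if sorted(flat.tolist()) != list(range(n_rows)):
        raise ValueError("pairing must be a perfect matching of all rows")
    return pairs


def _nt_xent_tensor(Z: Tensor, pairs: np.ndarray, temperature: float) -> Tensor:
    """Differentiable NT-Xent over a (2N, d) embedding tensor."""
    n = Z.shape[0]
    norms = (Z * Z).sum(axis=1, keepdims=True) ** 0.5
    Zn = Z / norms
    S = (Zn @ Zn.swapaxes(0, 1)) * (1.0 / temperature)
    # exclude self-similarity from every denominator
    mask = np.zeros((n, n), dtype=Z.data.dtype)
    np.fill_diagonal(mask, -1e9)
    S = S + Tensor(mask)
    logp = S - logsumexp(S, axis=1, keepdims=True)
    anchors = np.concatenate([pairs[:, 0], pairs[:, 1]])
    positives = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return -(logp[anchors, positives].mean())


def nt_xent_loss(
    Z: np.ndarray, pairing: np.ndarray | None = None, temperature: float = 0.1
) -> float:
    """Mean NT-Xent loss over all 2N anchors of a view batch.

    ``Z`` holds 2N embeddings (row count must be even); ``pairing`` is an
    (N, 2) array matching each view with its positive partner (default:
    consecutive rows (0,1), (2,3), ...).  Computed in float64; numerically
    stable for |sim/tau| up to ~1e3 via max-shifted log-sum-exp.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] % 2 != 0 or Z.shape[0] < 2:
        raise ValueError("Z must be (2N, d) with N >= 1")
    if np.any(np.linalg.norm(Z, axis=1) == 0):
        raise ValueError("zero-norm embedding row")
    pairs = _default_pairs(Z.shape[0]) if pairing is None else _check_pairing(pairing, Z.shape[0])
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    loss = _nt_xent_tensor(Tensor(Z), pairs, temperature)
    return float(loss.data)


def encode(x: np.ndarray, encoder: Encoder) -> np.ndarray:
    """Deterministic representation h for one (12, T) signal or a (B, 12, T) batch."""
    x = np.asarray(x)
    single = x.ndim == 2
    if single:
        x = x[None]
    h = encoder(Tensor(x.astype(np.float32))).data
    return h[0] if single else h


def pretrain(
    pool: list[EcgRecord],
    enc_spec: EncoderSpec | None = None,
    proj_spec: ProjectionSpec | None = None,
    aug: AugmentationConfig | None = None,
    cfg: PretrainConfig | None = None,
) -> PretrainResult:
    """Contrastive pretraining on an unlabeled pool; returns encoder weights only."""
    if not pool:
        raise ValueError("pretraining pool is empty")
    labeled = [r.record_id for r in pool if r.label is not None]
    if labeled:
        raise LeakageError(
            f"pretraining pool contains labeled records (e.g. {labeled[0]!r})"
        )
    enc_spec = enc_spec or EncoderSpec()
    proj_spec = proj_spec or ProjectionSpec()
    aug = aug or AugmentationConfig()
    cfg = cfg or PretrainConfig()

    ss = np.random.SeedSequence(cfg.seed)
    enc_ss, proj_ss, data_ss = ss.spawn(3)
    encoder = Encoder(enc_spec, np.random.Generator(np.random.PCG64(enc_ss)))
    proj = ProjectionHead(proj_spec, np.random.Generator(np.random.PCG64(proj_ss)))
    data_rng = np.random.Generator(np.random.PCG64(data_ss))
    opt = Adam(encoder.parameters() + proj.parameters(), lr=cfg.learning_rate)

    loss_history: list[float] = []
    for _ in range(cfg.epochs):
        order = data_rng.permutation(len(pool))
        epoch_losses: list[float] = []
        for start in range(0, len(pool), cfg.batch_pairs):
            idx = order[start : start + cfg.batch_pairs]
            if len(idx) < 2:
                continue  # a single pair gives a degenerate (zero) loss
            views = np.empty((2 * len(idx), 12, pool[0].n_samples), dtype=np.float32)
            for row, i in enumerate(idx):
                vp = make_view_pair(pool[i], aug, data_rng)
                views[2 * row] = vp.view_i
                views[2 * row + 1] = vp.view_j
            opt.zero_grad()
            Z = proj(encoder(Tensor(views)))
            loss = _nt_xent_tensor(Z, _default_pairs(Z.shape[0]), cfg.temperature)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        loss_history.append(float(np.mean(epoch_losses)))

    return PretrainResult(
        encoder_state=encoder.state_dict(),
        encoder_spec=enc_spec,
        loss_history=loss_history,
        config=cfg,
    )
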