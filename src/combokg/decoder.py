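"""Convolutional link-prediction scorer (InteractE-style).

The score of a triple (i, r, j) is

    S_{i,r,j} = [ Flatten( sigma( BN( Conv( Omega(h_i, h_r); Theta ) ) ) ) W_proj ] . h_j

where Omega interleaves (optionally permuted copies of) h_i and h_r into a
2-D checkered map, Conv is a bank of circularly padded kernels Theta, BN is
batch normalisation, and the flattened feature map is projected back to the
embedding dimension before the inner product with the tail embedding.

The whole map Omega + patch extraction is a single constant sparse gather,
so scoring reduces to two dense matmuls per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .kg import KGError


@dataclass
class DecoderConfig:
    kappa: int = 32
    channels: int = 32
    kernel_size: int = 3
    map_h: int = 4          # checkered map is map_h x (2*kappa / map_h)
    n_perm: int = 1
    dropout: float = 0.3
    activation: str = "relu"
    use_bn: bool = True
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self):
        if (2 * self.kappa) % self.map_h != 0:
            raise KGError(
                f"2*kappa={2 * self.kappa} not divisible by map_h={self.map_h}"
            )
        w = 2 * self.kappa // self.map_h
        n_even = sum(1 for y in range(self.map_h) for x in range(w) if (x + y) % 2 == 0)
        if n_even != self.kappa:
            raise KGError("checkered map does not split evenly between head and relation")


def _checker_sources(cfg: DecoderConfig, rng: np.random.Generator) -> np.ndarray:
    """For each permutation: flat map cell -> column of [h_i | h_r] (length 2*kappa)."""
    H, W = cfg.map_h, 2 * cfg.kappa // cfg.map_h
    out = np.zeros((cfg.n_perm, H * W), dtype=np.int64)
    for p in range(cfg.n_perm):
        perm_i = np.arange(cfg.kappa) if p == 0 else rng.permutation(cfg.kappa)
        perm_r = np.arange(cfg.kappa) if p == 0 else rng.permutation(cfg.kappa)
        ci = cr = 0
        for y in range(H):
            for x in range(W):
                if (x + y) % 2 == 0:
                    out[p, y * W + x] = perm_i[ci]
                    ci += 1
                else:
                    out[p, y * W + x] = cfg.kappa + perm_r[cr]
                    cr += 1
    return out


class Decoder:
    """Holds decoder parameters, BN running statistics and cached gathers."""

    def __init__(self, cfg: DecoderConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k, C, K = cfg.kappa, cfg.channels, cfg.kernel_size
        H, W = cfg.map_h, 2 * k // cfg.map_h
        self.map_hw = (H, W)
        sources = _checker_sources(cfg, rng)

        # one sparse matrix: [h_i | h_r] (B, 2k) -> conv patches (B, P * T)
        # P = n_perm * H * W output positions, T = K*K taps (in-channels merged
        # into taps across permutations is avoided: each perm is its own sample
        # plane, kernels see n_perm input channels)
        taps = [(dy - K // 2, dx - K // 2) for dy in range(K) for dx in range(K)]
        rows, cols = [], []
        P = H * W
        self.n_pos = P
        self.n_taps = K * K * cfg.n_perm
        for p in range(cfg.n_perm):
            for y in range(H):
                for x in range(W):
                    pos = y * W + x
                    for t, (dy, dx) in enumerate(taps):
                        yy, xx = (y + dy) % H, (x + dx) % W
                        col = pos * self.n_taps + p * (K * K) + t
                        rows.append(sources[p, yy * W + xx])
                        cols.append(col)
        self.patch_S = sp.csr_matrix(
            (np.ones(len(rows), dtype=ad.default_dtype()), (rows, cols)),
            shape=(2 * k, P * self.n_taps),
        ).T.tocsr()  # (P*T, 2k): spmm-compatible after transpose of input

        self.params: dict[str, Tensor] = {
            "conv_w": ad.param(ad.xavier_normal(rng, (self.n_taps, C))),
            "conv_b": ad.param(np.zeros(C)),
            "proj_w": ad.param(ad.xavier_normal(rng, (P * C, k))),
            "proj_b": ad.param(np.zeros(k)),
        }
        if cfg.use_bn:
            self.params["bn_gamma"] = ad.param(np.ones(C))
            self.params["bn_beta"] = ad.param(np.zeros(C))
        self.running_mean = np.zeros(C)
        self.running_var = np.ones(C)

    def features(
        self,
        HI: Tensor,
        HR: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Map (B, kappa) head and relation embeddings to (B, kappa) features."""
        cfg = self.cfg
        cat = ad.concat([HI, HR], axis=1)                       # (B, 2k)
        patches = ad.transpose(ad.spmm(self.patch_S, ad.transpose(cat)))
        B = cat.data.shape[0]
        patches = ad.reshape(patches, (B, self.n_pos, self.n_taps))
        conv = ad.add(ad.matmul(patches, self.params["conv_w"]), self.params["conv_b"])
        if cfg.use_bn:
            conv = self._batchnorm(conv, training)
        act = ad.ACTIVATIONS[cfg.activation]
        conv = act(conv)
        flat = ad.reshape(conv, (B, self.n_pos * cfg.channels))
        if training and cfg.dropout > 0:
            if rng is None:
                raise KGError("training dropout requires an rng")
            mask = (rng.random(flat.data.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            flat = ad.mul(flat, ad.constant(mask))
        return ad.add(ad.matmul(flat, self.params["proj_w"]), self.params["proj_b"])

    def _batchnorm(self, x: Tensor, training: bool) -> Tensor:
        cfg = self.cfg
        gamma = ad.reshape(self.params["bn_gamma"], (1, 1, -1))
        beta = ad.reshape(self.params["bn_beta"], (1, 1, -1))
        if training:
            mu = ad.tmean(x, axis=(0, 1), keepdims=True)
            xc = ad.sub(x, mu)
            var = ad.tmean(ad.mul(xc, xc), axis=(0, 1), keepdims=True)
            m = cfg.bn_momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = ad.constant(self.running_mean.reshape(1, 1, -1))
            var = ad.constant(self.running_var.reshape(1, 1, -1))
            xc = ad.sub(x, mu)
        inv = ad.powc(ad.add(var, ad.constant(cfg.bn_eps)), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), gamma), beta)

    def score_against(
        self,
        HI: Tensor,
        HR: Tensor,
        H_tails: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Scores (B, n_tails) of every (head, relation) row against every tail."""
        feat = self.features(HI, HR, training=training, rng=rng)
        return ad.matmul(feat, ad.transpose(H_tails))

    def score(self, h_i: np.ndarray, h_r: np.ndarray, h_j: np.ndarray) -> float:
        """Eval-mode scalar score of one triple."""
        for v in (h_i, h_r, h_j):
            if np.asarray(v).shape != (self.cfg.kappa,):
                raise KGError(f"expected vectors of length {self.cfg.kappa}")
        s = self.score_against(
            ad.constant(np.asarray(h_i)[None, :]),
            ad.constant(np.asarray(h_r)[None, :]),
            ad.constant(np.asarray(h_j)[None, :]),
        )
        return float(s.data[0, 0])

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out["running_mean"] = self.running_mean.copy()
        out["running_var"] = self.running_var.copy()
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k].data = np.array(d[k])
        self.running_mean = np.array(d["running_mean"])
        self.running_var = np.array(d["running_var"])


def bce_loss(pairs: list[tuple[float, float]]) -> float:
    """Mean binary cross-entropy over (label, predicted-probability) pairs.

    Probabilities are clamped to [1e-12, 1 - 1e-12] so exact 0/1 predictions
    yield a large finite loss instead of infinity.
    """
    if not pairs:
        raise KGError("empty pair list")
    y = np.array([p[0] for p in pairs], dtype=float)
    yhat = np.clip(np.array([p[1] for p in pairs], dtype=float), 1e-12, 1 - 1e-12)
    return float(np.mean(-(y * np.log(yhat) + (1 - y) * np.log(1 - yhat))))
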