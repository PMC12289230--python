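"""Sequence feature extraction: gated multiscale convolutions followed by
frequency-domain (DCT) channel attention.

Three parallel gated convolutional branches (kernel sizes 3, 5 and 7) each
map the L x 1280 embedding matrix to L x 512; their concatenation (L x 1536)
passes through a per-residue fully connected layer back to L x 512, giving
the intermediate representation D. Each of the 512 channels of D is then
viewed as a length-L signal, transformed with an orthonormal DCT-II, and
summarized to a scalar; the 512 summaries pass through a small bottleneck
MLP and a sigmoid to yield per-channel weights w in (0,1)^512, and the
output is X = D ⊙ w (squeeze-excitation style channel reweighting).

Because the per-channel DCT spectrum has length L but the excitation MLP
needs a fixed-width input, a length-invariant scalar summary per channel is
required; the default is the mean absolute DCT coefficient (total spectral
magnitude). The DC coefficient alone and a low-frequency band mean are
available as alternatives, as is a literal mode in which the sigmoid output
itself is returned broadcast over residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft

from .autodiff import Tensor, concat
from .layers import DTYPE, Conv1dSame, Linear, Module

SUMMARY_MODES = ("absmean", "dc", "lowk")
_LOWK = 8


@dataclass
class SequenceFeatures:
    """Encoder output X (L x 512) with optional intermediates."""

    X: Tensor
    D: np.ndarray | None = None
    channel_weights: np.ndarray | None = None


def dct_1d(v: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II of a 1-D signal (invertible by :func:`idct_1d`)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("dct_1d expects a non-empty 1-D vector")
    return scipy.fft.dct(v, type=2, norm="ortho")


def idct_1d(c: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct_1d` (orthonormal DCT-III)."""
    return scipy.fft.idct(np.asarray(c, dtype=np.float64), type=2, norm="ortho")


@lru_cache(maxsize=64)
def dct_matrix(L: int) -> np.ndarray:
    """Orthonormal DCT-II as an L x L matrix (C @ v == dct_1d(v))."""
    return scipy.fft.dct(np.eye(L), type=2, norm="ortho", axis=0).astype(DTYPE)


class GatedConvBranch(Module):
    """GLU-style gated 1-D convolution: conv_a(M) ⊙ sigmoid(conv_b(M))."""

    def __init__(self, d_in: int, d_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (3, 5, 7):
            raise ValueError(f"kernel must be one of 3, 5, 7; got {kernel}")
        self.kernel = kernel
        self.conv = Conv1dSame(d_in, d_out, kernel, rng)
        self.gate = Conv1dSame(d_in, d_out, kernel, rng)

    def __call__(self, m: Tensor) -> Tensor:
        return self.conv(m) * self.gate(m).sigmoid()


class FrequencyAttention(Module):
    """Channel attention from per-channel DCT spectra.

    ``enabled=False`` makes the module the identity (w ≡ 1), the ablation
    switch for the no-frequency-attention variant.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 bottleneck: int = 128, summary: str = "absmean",
                 variant: str = "reweight", enabled: bool = True):
        if summary not in SUMMARY_MODES:
            raise ValueError(f"summary must be one of {SUMMARY_MODES}")
        if variant not in ("reweight", "literal"):
            raise ValueError("variant must be 'reweight' or 'literal'")
        self.summary = summary
        self.variant = variant
        self.enabled = enabled
        self.fc1 = Linear(channels, bottleneck, rng)
        self.fc2 = Linear(bottleneck, channels, rng)

    def spectrum_summary(self, d: Tensor) -> Tensor:
        """(L, C) -> (1, C) length-invariant per-channel spectral summary."""
        L = d.shape[0]
        C = Tensor(dct_matrix(L))
        freq = C @ d  # (L, C): column c is the DCT spectrum of channel c
        if self.summary == "absmean":
            return freq.abs().mean(axis=0, keepdims=True)
        if self.summary == "dc":
            return freq[0:1].abs()
        k = min(_LOWK, L)
        return freq[0:k].abs().mean(axis=0, keepdims=True)

    def __call__(self, d: Tensor) -> tuple[Tensor, np.ndarray | None]:
        if not self.enabled:
            return d, None
        summary = self.spectrum_summary(d)
        w = self.fc2(self.fc1(summary).relu()).sigmoid()  # (1, C), entries in (0,1)
        if self.variant == "literal":
            x = d * 0.0 + w  # broadcast the weights themselves over residues
        else:
            x = d * w
        return x, w.data.ravel().copy()


class SequenceEncoder(Module):
    """L x 1280 embeddings -> L x 512 sequence features X."""

    def __init__(self, rng: np.random.Generator, d_in: int = 1280,
                 width: int = 512, kernels: tuple[int, ...] = (3, 5, 7),
                 freq_summary: str = "absmean", freq_variant: str = "reweight",
                 freq_enabled: bool = True):
        self.d_in = d_in
        self.width = width
        self.branches = [GatedConvBranch(d_in, width, k, rng) for k in kernels]
        self.fc = Linear(width * len(kernels), width, rng)
        self.freq = FrequencyAttention(width, rng, summary=freq_summary,
                                       variant=freq_variant, enabled=freq_enabled)

    def multiscale(self, m: Tensor) -> Tensor:
        """Gated branches -> concat (L x 1536) -> FC -> D (L x 512)."""
        parts = [branch(m) for branch in self.branches]
        return self.fc(concat(parts, axis=1))

    def __call__(self, m: Tensor | np.ndarray, keep_intermediates: bool = False
                 ) -> SequenceFeatures:
        if not isinstance(m, Tensor):
            m = Tensor(np.asarray(m, dtype=DTYPE))
        if m.ndim != 2 or m.shape[1] != self.d_in:
            raise ValueError(f"expected L x {self.d_in} input, got {m.shape}")
        d = self.multiscale(m)
        x, w = self.freq(d)
        return SequenceFeatures(
            X=x,
            D=d.data.copy() if keep_intermediates else None,
            channel_weights=w if keep_intermediates else None,
        )
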