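"""Reversible conversion between feature maps and patch-ordered sequences.

The location-preserving tokenizer: a (B, C, H, W) feature map is rearranged
into a (B, C, P, N) sequence where ``P = ph*pw`` indexes the position inside a
patch (row-major) and ``N = (H/ph)*(W/pw)`` indexes patches over the image
grid (row-major).  The rearrangement is a pure permutation per (b, c) slice,
so folding back is exact — no embedding, no positional encoding, no
information loss.

All three operations work on plain NumPy arrays or autograd tensors; for
tensors the permutation is expressed through differentiable reshape/transpose
moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor

__all__ = ["PatchSequence", "unfold", "fold", "patch_transpose"]


@dataclass
class PatchSequence:
    """A patch-ordered pixel sequence with the metadata needed to fold back.

    ``data`` has shape (B, C, P, N) — or (B, C, N, P) after
    :func:`patch_transpose`, tracked by ``transposed``.
    """

    data: Tensor | np.ndarray
    patch_shape: tuple[int, int]
    origin_shape: tuple[int, int]
    transposed: bool = False

    @property
    def shape(self):
        return self.data.shape

    def validate(self) -> None:
        ph, pw = self.patch_shape
        H, W = self.origin_shape
        P, N = ph * pw, (H * W) // (ph * pw)
        expect = (N, P) if self.transposed else (P, N)
        if self.data.ndim != 4 or self.data.shape[2:] != expect:
            raise ValueError(
                f"inconsistent PatchSequence: data shape {self.data.shape} "
                f"does not match patch_shape {self.patch_shape} / "
                f"origin_shape {self.origin_shape}")


def _check_divisible(H: int, W: int, ph: int, pw: int) -> None:
    if H % ph or W % pw:
        raise ValueError(
            f"spatial dims ({H}x{W}) are not divisible by the patch shape "
            f"({ph}x{pw}); resize the input explicitly instead")


def unfold(x, patch_shape: tuple[int, int] = (2, 2)) -> PatchSequence:
    """Rearrange (B, C, H, W) -> (B, C, P, N).

    Element mapping: ``X[b,c,p,n] = x[b,c, (n // (W/pw))*ph + p // pw,
    (n % (W/pw))*pw + p % pw]``.
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 feature map, got shape {x.shape}")
    B, C, H, W = x.shape
    ph, pw = patch_shape
    _check_divisible(H, W, ph, pw)
    gh, gw = H // ph, W // pw
    seq = (x.reshape(B, C, gh, ph, gw, pw)
            .transpose(0, 1, 3, 5, 2, 4)          # (B, C, ph, pw, gh, gw)
            .reshape(B, C, ph * pw, gh * gw))
    return PatchSequence(seq, (ph, pw), (H, W))


def fold(X: PatchSequence) -> Tensor:
    """Exact inverse of :func:`unfold`: (B, C, P, N) -> (B, C, H, W)."""
    X.validate()
    if X.transposed:
        X = patch_transpose(X)
    ph, pw = X.patch_shape
    H, W = X.origin_shape
    gh, gw = H // ph, W // pw
    data = X.data if isinstance(X.data, Tensor) else Tensor(np.asarray(X.data))
    B, C = data.shape[:2]
    return (data.reshape(B, C, ph, pw, gh, gw)
                .transpose(0, 1, 4, 2, 5, 3)      # (B, C, gh, ph, gw, pw)
                .reshape(B, C, H, W))


def patch_transpose(X: PatchSequence) -> PatchSequence:
    """Swap the patch-position and patch-index axes (an involution)."""
    X.validate()
    data = X.data if isinstance(X.data, Tensor) else Tensor(np.asarray(X.data))
    return PatchSequence(data.transpose(0, 1, 3, 2), X.patch_shape,
                         X.origin_shape, transposed=not X.transposed)
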