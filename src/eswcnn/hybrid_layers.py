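"""The two bespoke learnable layers of the hybrid network.

``hybrid_conv_forward`` depth-concatenates raw feature channels with their
fixed scattering maps and applies a shared 3x3 / stride-2 / pad-1
convolution, bias and activation:

    y_j = f( sum_i W_{i,j} ((x (+) S[x]) (*) K) + b_j )

``fft_filter_forward`` is a residual frequency-domain filter with a
learnable complex weight map W:

    F_out = F + Re( IFFT( W o FFT(F) ) )          (o = Hadamard product)

with the unnormalized forward DFT and the 1/(H*W) inverse, so a weight w on
the DC bin maps a constant input c to c*(1 + Re w).  W is initialized to
zero, making the layer exactly the identity at the start of training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, Layer

__all__ = [
    "HybridConvParams",
    "SpectralFilterParams",
    "hybrid_conv_forward",
    "fft_filter_forward",
    "SpectralFilter2d",
]

_ACTIVATIONS = {
    "relu": lambda z: np.where(z > 0, z, 0.0),
    "identity": lambda z: z,
}


@dataclass
class HybridConvParams:
    """Learnable kernels of the scattering-concatenation convolution.

    ``K`` has shape (out_channels, in_depth, 3, 3) where in_depth counts the
    raw channels plus the scattering maps; kernel size, stride 2 and 1-pixel
    padding are fixed by the architecture.
    """

    K: np.ndarray
    b: np.ndarray
    activation: str = "relu"
    stride: int = 2
    pad: int = 1

    def __post_init__(self) -> None:
        if self.K.ndim != 4 or self.K.shape[2:] != (3, 3):
            raise ValueError(f"kernels must have shape (out, in, 3, 3), got {self.K.shape}")
        if self.stride != 2 or self.pad != 1:
            raise ValueError("the hybrid convolution is fixed at stride 2, padding 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def hybrid_conv_forward(
    x: np.ndarray, s: np.ndarray, params: HybridConvParams
) -> np.ndarray:
    """Concatenate ``x`` with scattering maps ``s`` along depth and convolve.

    Both inputs are (N, C, H, W) batches sharing spatial dimensions; the
    output spatial size is ceil(H/2) x ceil(W/2).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape[0] != s.shape[0] or x.shape[2:] != s.shape[2:]:
        raise ValueError(
            f"spatial/batch mismatch between x {x.shape} and scattering stack "
            f"{s.shape}; produce s with scatter_features(x, bank) so the maps "
            "are upsampled to the input grid"
        )
    cat = np.concatenate([x, s], axis=1)
    if cat.shape[1] != params.K.shape[1]:
        raise ValueError(
            f"concatenated depth {cat.shape[1]} does not match kernel depth {params.K.shape[1]}"
        )
    conv = _conv_with_params(cat, params)
    return _ACTIVATIONS[params.activation](conv)


def _conv_with_params(x: np.ndarray, params: HybridConvParams) -> np.ndarray:
    from .nn import _im2col

    n = x.shape[0]
    out_ch = params.K.shape[0]
    cols, h_out, w_out = _im2col(x, 3, params.stride, params.pad)
    w_mat = params.K.reshape(out_ch, -1)
    y = np.einsum("oc,ncp->nop", w_mat, cols) + params.b[None, :, None]
    return y.reshape(n, out_ch, h_out, w_out)


@dataclass
class SpectralFilterParams:
    """Complex weight map of the discriminant FFT filter, stored as two
    real arrays so it can be trained with real-valued SGD."""

    w_real: np.ndarray
    w_imag: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "SpectralFilterParams":
        """Zero initialization: the filter starts as the exact identity."""
        return cls(np.zeros(shape), np.zeros(shape))

    @property
    def weight_map(self) -> np.ndarray:
        return self.w_real + 1j * self.w_imag


def fft_filter_forward(f: np.ndarray, params: SpectralFilterParams) -> np.ndarray:
    """Residual learnable frequency filter, 2-D transform over the last two
    (spatial) axes; accepts (..., H, W) stacks with a matching weight map or
    a weight map broadcastable over the leading axes."""
    f = np.asarray(f, dtype=float)
    w = params.weight_map
    if w.shape != f.shape[-w.ndim :]:
        raise ValueError(
            f"weight map shape {w.shape} does not match trailing input dims of {f.shape}"
        )
    f_hat = np.fft.fft2(f, axes=(-2, -1))
    return f + np.real(np.fft.ifft2(w * f_hat, axes=(-2, -1)))


class SpectralFilter2d(Layer):
    """Trainable wrapper around :func:`fft_filter_forward`.

    The weight map has shape (C, H, W) and is shared across the batch.
    Gradients follow from the DFT adjoint: with G the output gradient and
    N = H*W,  dL/dW = FFT(F) o conj(FFT(G)) / N  (real part to w_real, minus
    imaginary part to w_imag), and the input gradient adds
    Re(IFFT(conj(W) o FFT(G))).
    """

    def __init__(self, channels: int, height: int, width: int) -> None:
        super().__init__()
        self.params["w_real"] = np.zeros((channels, height, width))
        self.params["w_imag"] = np.zeros((channels, height, width))
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        p = SpectralFilterParams(self.params["w_real"], self.params["w_imag"])
        return fft_filter_forward(x, p)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = gout.shape[-2:]
        n = h * w
        f_hat = np.fft.fft2(self._x, axes=(-2, -1))
        g_hat = np.fft.fft2(gout, axes=(-2, -1))
        z = (f_hat * np.conj(g_hat)).sum(axis=0) / n  # sum over batch
        self.grads["w_real"] += np.real(z)
        self.grads["w_imag"] += -np.imag(z)
        wmap = self.params["w_real"] + 1j * self.params["w_imag"]
        gin = np.real(np.fft.ifft2(np.conj(wmap) * g_hat, axes=(-2, -1)))
        return gout + gin
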