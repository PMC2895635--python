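"""Kernel registry.

Kernels are keyed by their usual abbreviations: sl, st, sst, spt, kbsps,
cosine, edit.
"""

from __future__ import annotations

from .base import PairwiseKernel
from .dependency import (
    CosineKernel,
    EditKernel,
    KBSPSKernel,
    TolerantMatchConfig,
    path_tokens,
    tolerant_match,
    word_edit_distance,
)
from .surface import SLKernel
from .tree import SpTKernel, SSTKernel, STKernel

KERNELS: dict[str, type[PairwiseKernel]] = {
    cls.name: cls
    for cls in (
        KBSPSKernel,
        CosineKernel,
        EditKernel,
        SLKernel,
        SpTKernel,
        STKernel,
        SSTKernel,
    )
}


def make_kernel(kernel: PairwiseKernel | str, **params) -> PairwiseKernel:
    """Resolve a kernel name (or pass through an instance), applying params."""
    if isinstance(kernel, PairwiseKernel):
        if params:
            kernel = kernel.set_params(**params)
        return kernel
    try:
        cls = KERNELS[kernel]
    except KeyError:
        available = ", ".join(sorted(KERNELS))
        raise ValueError(f"unknown kernel {kernel!r}; available: {available}") from None
    return cls(**params)


__all__ = [
    "PairwiseKernel",
    "KBSPSKernel",
    "CosineKernel",
    "EditKernel",
    "SLKernel",
    "SpTKernel",
    "STKernel",
    "SSTKernel",
    "TolerantMatchConfig",
    "tolerant_match",
    "path_tokens",
    "word_edit_distance",
    "KERNELS",
    "make_kernel",
]
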