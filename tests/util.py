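"""Shared test helpers: finite-difference gradient checking."""

from __future__ import annotations

import numpy as np

from circrbp.kernels import KernelModel, loss_and_grads


def fd_gradients(
    model: KernelModel,
    bi: np.ndarray,
    bj: np.ndarray,
    y: np.ndarray,
    Yin: np.ndarray | None,
    h: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Central finite differences of the mean clamped-BCE objective."""

    def loss_only() -> float:
        val, _ = loss_and_grads(model, bi, bj, y, Yin)
        return val

    grads = {}
    for name, arr in model.params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + h
            lp = loss_only()
            flat[k] = orig - h
            lm = loss_only()
            flat[k] = orig
            gflat[k] = (lp - lm) / (2.0 * h)
        grads[name] = g
    return grads


def relative_grad_error(analytic: dict, numeric: dict) -> float:
    """||g_a - g_fd|| / max(||g_a||, ||g_fd||) over all parameters jointly."""
    ga = np.concatenate([analytic[k].ravel() for k in sorted(analytic)])
    gf = np.concatenate([numeric[k].ravel() for k in sorted(numeric)])
    denom = max(np.linalg.norm(ga), np.linalg.norm(gf), 1e-12)
    return float(np.linalg.norm(ga - gf) / denom)
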