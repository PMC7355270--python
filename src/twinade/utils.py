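"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["psd_project", "safe_cholesky", "symmetrize"]


def symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def psd_project(a: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest (in eigenvalue clipping sense) PSD matrix with eigenvalues >= floor.

    Sample cross-twin moment matrices and rounded published correlation
    matrices need not be positive semidefinite; clipping makes them usable
    as Cholesky-factorizable covariance inputs.
    """
    a = symmetrize(np.asarray(a, dtype=float))
    w, v = np.linalg.eigh(a)
    return symmetrize(v @ np.diag(np.maximum(w, floor)) @ v.T)


def safe_cholesky(a: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Lower Cholesky factor, PSD-projecting first if necessary."""
    try:
        return np.linalg.cholesky(symmetrize(a))
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(psd_project(a, floor))
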