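"""Natural-abundance correction of measured mass-isotopomer distributions.

Only carbon is corrected (the tracked element): each of the ``n - j``
carbons of an M+j isotopolog that do not carry tracer label has probability
``a`` (natural 13C abundance, default 0.0107) of being heavy anyway, so the
measured distribution is the true one pushed through a lower-triangular
binomial mixing matrix.  Correction inverts that matrix, clips small
negative fractions produced by measurement noise and renormalizes.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

NATURAL_13C = 0.0107


def natural_abundance_matrix(n_carbons: int, abundance: float) -> np.ndarray:
    """Forward mixing matrix C with C[i, j] = P(observe M+i | true M+j)."""
    if not 0.0 <= abundance < 0.5:
        raise ValueError("abundance must lie in [0, 0.5)")
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    js = np.arange(n + 1)
    from math import comb
    for j in js:
        for i in range(j, n + 1):
            C[i, j] = comb(n - j, i - j) * abundance ** (i - j) \
                * (1.0 - abundance) ** (n - i)
    return C


def apply_natural_abundance(mid, abundance: float = NATURAL_13C) -> np.ndarray:
    """Contaminate a true MID with natural-abundance 13C (forward model)."""
    mid = np.asarray(mid, dtype=float)
    return natural_abundance_matrix(len(mid) - 1, abundance) @ mid


def correct_natural_abundance(measured, n_carbons: int,
                              abundance: float = NATURAL_13C,
                              clip: bool = True) -> np.ndarray:
    """Invert the binomial contamination of a measured MID.

    With ``clip`` (default) negative fractions arising from noise are set to
    zero and the vector renormalized, matching common correction-tool
    behavior; ``clip=False`` returns the raw inverse for exactness checks.
    """
    measured = np.asarray(measured, dtype=float)
    if len(measured) != n_carbons + 1:
        raise ValueError("measured MID length must be n_carbons + 1")
    if measured.sum() > 1.0 + 1e-6:
        raise ValueError("measured fractions sum to more than 1")
    C = natural_abundance_matrix(n_carbons, abundance)
    x = solve_triangular(C, measured, lower=True)
    if not clip:
        return x
    x = np.clip(x, 0.0, None)
    s = x.sum()
    return x / s if s > 0 else x
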