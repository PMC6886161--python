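"""Independent numeric oracles shared by tests."""

import numpy as np


def char_poly_eigenvalues(s: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric matrix via the Faddeev-LeVerrier
    characteristic polynomial and polynomial root finding (independent of
    the LAPACK symmetric eigensolver used by the implementation)."""
    n = s.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    m = np.zeros_like(s, dtype=float)
    for k in range(1, n + 1):
        m = s @ m + coeffs[k - 1] * np.eye(n)
        coeffs[k] = -(s @ m).trace() / k
    return np.sort(np.roots(coeffs).real)
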