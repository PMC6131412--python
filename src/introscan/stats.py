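"""Shared statistical primitives: BH adjustment and NB log-likelihoods."""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    Raises ``ValueError`` for p-values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def nb_loglik(y, mu, dispersion) -> np.ndarray:
    """Elementwise NB log-likelihood with mean ``mu`` and dispersion ``alpha``.

    Uses the gamma-function form, so ``y`` need not be integral (library-size
    equalized pseudo-counts are supported).  ``mu == 0`` contributes 0 when
    ``y == 0`` and ``-inf`` otherwise.  Near-zero dispersion falls back to the
    Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.full(np.broadcast(y, mu).shape, -np.inf)
    zero = np.broadcast_to(mu, out.shape) <= 0
    ok = ~zero
    y_b = np.broadcast_to(y, out.shape)
    mu_b = np.broadcast_to(mu, out.shape)
    if dispersion < 1e-8:
        out[ok] = (
            y_b[ok] * np.log(mu_b[ok]) - mu_b[ok] - gammaln(y_b[ok] + 1.0)
        )
    else:
        r = 1.0 / dispersion
        yv, mv = y_b[ok], mu_b[ok]
        out[ok] = (
            gammaln(yv + r)
            - gammaln(r)
            - gammaln(yv + 1.0)
            + r * np.log(r / (r + mv))
            + yv * np.log(mv / (r + mv))
        )
    out[zero & (y_b == 0)] = 0.0
    return out
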