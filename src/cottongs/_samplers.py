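"""Numba kernels for the Gibbs samplers.

All kernels update the regression state in place and keep the running
residual vector ``r = y - mu - X b - ...`` consistent, so a full-conditional
update of one coefficient costs O(n).  Genotype matrices are expected in
Fortran order so column slices are contiguous.

Randomness: the kernels draw from numba's internal np.random state, which is
separate from any numpy ``Generator`` used at the Python level.  ``seed_rng``
must be called (inside numba) once per chain to make runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_rng", "sweep_gaussian", "sweep_spike_slab"]


@njit(cache=True)
def seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def sweep_gaussian(X, r, b, tau, var_b):
    """One Gibbs sweep over coefficients with Gaussian priors.

    b_k | rest ~ N(c/C, 1/C) with C = sum_i tau_i x_ik^2 + 1/var_b[k] and
    c = sum_i tau_i x_ik (r_i + x_ik b_k).  ``tau`` is the per-record
    residual precision (heteroscedastic residuals supported).
    """
    n, p = X.shape
    for k in range(p):
        bk = b[k]
        c = 0.0
        C = 1.0 / var_b[k]
        for i in range(n):
            x = X[i, k]
            c += tau[i] * x * (r[i] + x * bk)
            C += tau[i] * x * x
        new = c / C + np.random.normal() / np.sqrt(C)
        d = new - bk
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, k] * d
        b[k] = new


@njit(cache=True)
def sweep_spike_slab(X, r, b, delta, tau, var_b, logit_pi):
    """One Gibbs sweep of a spike-and-slab prior (joint (delta_k, b_k) update).

    For each marker the slab coefficient is integrated out analytically to
    obtain the inclusion odds, then b_k is drawn from its conditional when
    included and set to 0 otherwise.  Returns the number of included markers.
    """
    n, p = X.shape
    n_in = 0
    for k in range(p):
        bk = b[k]
        c = 0.0
        C0 = 0.0
        for i in range(n):
            x = X[i, k]
            c += tau[i] * x * (r[i] + x * bk)
            C0 += tau[i] * x * x
        C = C0 + 1.0 / var_b[k]
        # log Bayes factor of inclusion vs exclusion, slab integrated out
        log_bf = 0.5 * (np.log(1.0 / (var_b[k] * C)) + c * c / C)
        z = logit_pi + log_bf
        if z > 35.0:
            p_in = 1.0
        elif z < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + np.exp(-z))
        if np.random.random() < p_in:
            new = c / C + np.random.normal() / np.sqrt(C)
            delta[k] = 1
            n_in += 1
        else:
            new = 0.0
            delta[k] = 0
        d = new - bk
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, k] * d
        b[k] = new
    return n_in
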