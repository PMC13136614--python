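"""Logistic basis functions shared by the rate-fitting and growth layers."""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def logistic(t, amplitude, midpoint, slope):
    """``A / (1 + exp(-(t - m)/s))``, numerically stable for any argument."""
    w = (np.asarray(t, dtype=float) - midpoint) / slope
    return amplitude * expit(w)


def logistic_derivative(t, amplitude, midpoint, slope):
    """Analytic time derivative of :func:`logistic` (stable sech^2 form)."""
    w = (np.asarray(t, dtype=float) - midpoint) / slope
    p = expit(w)
    return amplitude * p * (1.0 - p) / slope


def sigmoid_sum(t, amplitudes, midpoints, slopes, offset=0.0):
    """Sum of logistic terms plus a constant offset."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, float(offset), dtype=float)
    for a, m, s in zip(amplitudes, midpoints, slopes):
        out = out + logistic(t, a, m, s)
    return out


def sigmoid_sum_derivative(t, amplitudes, midpoints, slopes):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for a, m, s in zip(amplitudes, midpoints, slopes):
        out = out + logistic_derivative(t, a, m, s)
    return out


def pack_params(amplitudes, midpoints, slopes, offset):
    return np.concatenate([np.ravel(amplitudes), np.ravel(midpoints),
                           np.ravel(slopes), [offset]])


def unpack_params(theta, n_basis):
    theta = np.asarray(theta, dtype=float)
    a = theta[:n_basis]
    m = theta[n_basis:2 * n_basis]
    s = theta[2 * n_basis:3 * n_basis]
    return a, m, s, float(theta[3 * n_basis])


def evaluate(theta, t, n_basis):
    a, m, s, c = unpack_params(theta, n_basis)
    return sigmoid_sum(t, a, m, s, c)


def evaluate_derivative(theta, t, n_basis):
    a, m, s, _ = unpack_params(theta, n_basis)
    return sigmoid_sum_derivative(t, a, m, s)
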