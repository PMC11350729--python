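"""Shared numerics: information criteria, rounding, warnings and errors."""

from __future__ import annotations

import math

import numpy as np


class HisfkinError(Exception):
    """Base class for package errors."""


class ValidationError(HisfkinError):
    """A scheme, trace or config violated its invariants."""


class DegenerateDataError(HisfkinError):
    """Input data carry no usable signal (e.g. constant trace)."""


class IntegrationError(HisfkinError):
    """ODE integration failed; carries the last successful time point."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class EquilibriumError(HisfkinError):
    """No finite mass-action equilibrium (irreversible step or inconsistent cycle)."""


class FitError(HisfkinError):
    """Nonlinear fit failed to converge; may carry the best-so-far result."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class IdentifiabilityWarning(UserWarning):
    """A fitted parameter is effectively unconstrained by the data."""


def aicc(ssr: float, n: int, p: int) -> float:
    """Small-sample corrected Akaike information criterion for a least-squares fit.

    Uses the Gaussian log-likelihood form ``n*log(ssr/n) + 2k`` with
    ``k = p + 1`` (the noise variance counts as a parameter) and the
    finite-sample correction ``2k(k+1)/(n-k-1)``.
    """
    if n <= 0 or p < 0:
        raise ValueError("need n > 0 and p >= 0")
    k = p + 1
    if n - k - 1 <= 0:
        return math.inf
    ssr = max(float(ssr), 1e-300)
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def round_sig(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` significant digits (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - ndigits + 1)
    return math.floor(abs(x) / scale + 0.5) * scale * (1 if x > 0 else -1)


def weighted_linear_lstsq(design: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Minimum-norm weighted least squares; returns (coefs, fitted, ssr)."""
    if w is not None:
        design = design * w[:, None]
        y = y * w
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coefs
    resid = y - fitted
    return coefs, fitted, float(resid @ resid)
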