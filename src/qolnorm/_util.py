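"""Small shared numerics and error types."""

from __future__ import annotations

import numpy as np


class QolnormError(Exception):
    """Base class for package errors."""


class ValidationError(QolnormError, ValueError):
    """Input outside its documented domain."""


class ConfigurationError(QolnormError, ValueError):
    """Inconsistent or incomplete configuration (tariff keys, rates, coefficients)."""


class DegenerateRangeError(QolnormError, ValueError):
    """A normalisation range has zero width."""


class ConvergenceError(QolnormError, RuntimeError):
    """Optimiser failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class PerfectFitWarning(UserWarning):
    """Precision diverging: the beta component is collapsing on a point."""


class SeparationWarning(UserWarning):
    """(Quasi-)complete separation detected in a logistic component."""


def sigmoid(eta):
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
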