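"""Elementwise variable transforms used to approach marginal normality.

Intensity panels are often right-skewed; a square-root (or log) transform of
selected variables brings them closer to the Gaussian marginals the
multivariate-normal imputation model assumes.  Transforms are applied before
model fitting and inverted before any value is reported, so all predictions
live on the measurement scale.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, ValidationError

TRANSFORM_KINDS = ("none", "sqrt", "log")


def apply_transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Transform `values` elementwise; NaN (missing) entries pass through.

    sqrt requires values >= 0, log requires values > 0; violations raise
    ValidationError listing the offending positions.
    """
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x.copy()
    if kind == "sqrt":
        bad = np.flatnonzero(~np.isnan(x) & (x < 0))
        if bad.size:
            raise ValidationError(
                f"sqrt transform requires nonnegative values; offending indices: {bad[:10].tolist()}"
            )
        return np.sqrt(x)
    if kind == "log":
        bad = np.flatnonzero(~np.isnan(x) & (x <= 0))
        if bad.size:
            raise ValidationError(
                f"log transform requires strictly positive values; offending indices: {bad[:10].tolist()}"
            )
        return np.log(x)
    raise ConfigError(f"unknown transform {kind!r}; expected one of {TRANSFORM_KINDS}")


def inverse_transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Invert `apply_transform`; the sqrt inverse squares, hence is >= 0."""
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x.copy()
    if kind == "sqrt":
        return np.square(x)
    if kind == "log":
        return np.exp(x)
    raise ConfigError(f"unknown transform {kind!r}; expected one of {TRANSFORM_KINDS}")
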