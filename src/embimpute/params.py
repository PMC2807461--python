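"""Configuration objects for the EM engine and the multiple-imputation run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

from .errors import ConfigError
from ._transforms import TRANSFORM_KINDS

INIT_METHODS = ("listwise_deletion", "identity")


@dataclass(frozen=True)
class EMConfig:
    """Settings for the incomplete-data multivariate-normal EM fit.

    init : starting point — "listwise_deletion" (complete-rows MLE, falling
        back to identity when too few complete rows exist) or "identity"
        (observed column means, identity covariance on the standardized scale).
    ridge : prior weight expressed as a fraction of n, shrinking covariances
        toward their diagonal; 0 disables, and a singular fit is retried once
        at 0.01 automatically.
    tol : convergence threshold on the maximum relative parameter change.
    max_iter : iteration cap; hitting it flags non-convergence, no exception.
    """

    init: str = "listwise_deletion"
    ridge: float = 0.0
    tol: float = 1e-4
    max_iter: int = 1000

    def __post_init__(self):
        if self.init not in INIT_METHODS:
            raise ConfigError(f"init must be one of {INIT_METHODS}, got {self.init!r}")
        if self.ridge < 0:
            raise ConfigError("ridge must be >= 0")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")


@dataclass(frozen=True)
class ImputationParams:
    """One full multiple-imputation configuration.

    m : number of imputations (completed datasets drawn).
    polytime_order : polynomial order q of the scaled-time covariates (0–3).
    cross_section : add a 0/1 dummy per non-reference cell type.
    intercs : let the time polynomial differ per cell type (requires
        cross_section); adds time-by-dummy interaction columns.
    transform : per-protein transform ("none"/"sqrt"/"log"); the wildcard
        key "*" sets the default for proteins not named explicitly.
    em : EM fit configuration.
    seed : master seed; per-draw bootstrap and imputation streams are spawned
        from it so results do not depend on execution order.
    """

    m: int = 1
    polytime_order: int = 2
    cross_section: bool = True
    intercs: bool = True
    transform: Mapping[str, str] = field(default_factory=dict)
    em: EMConfig = field(default_factory=EMConfig)
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.polytime_order not in (0, 1, 2, 3):
            raise ConfigError("polytime_order must be in {0,1,2,3}")
        if self.intercs and not self.cross_section:
            raise ConfigError("intercs requires cross_section")
        for prot, kind in dict(self.transform).items():
            if kind not in TRANSFORM_KINDS:
                raise ConfigError(
                    f"transform for {prot!r} must be one of {TRANSFORM_KINDS}, got {kind!r}"
                )
        object.__setattr__(self, "transform", dict(self.transform))

    def transform_for(self, protein: str) -> str:
        """Resolve the transform for one protein, honoring the "*" wildcard."""
        t = self.transform
        return t.get(protein, t.get("*", "none"))

    def with_seed(self, seed: int) -> "ImputationParams":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transform"] = dict(self.transform)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImputationParams":
        d = dict(d)
        em = d.pop("em", {})
        if isinstance(em, EMConfig):
            pass
        else:
            em = EMConfig(**em)
        return cls(em=em, **d)
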