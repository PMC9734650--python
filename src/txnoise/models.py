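"""Kinetic parameter containers and the qualitative-regime coordinate map.

The models describe a gene whose transcription rate K(t) is itself a
stochastic process with mean-reversion rate ``kappa``, gain ``theta`` and
driver frequency ``a``; transcripts are spliced at rate ``beta`` and degrade
at rate ``gamma_``.  The stationary law of K(t) is Gamma(a/kappa, theta) for
both drivers considered here, so the mean transcription rate is
``<K> = a * theta / kappa``.

Qualitative distribution shape is controlled by two dimensionless numbers:
the reversion coordinate kappa/(kappa+beta+gamma) and the gain coordinate
theta/(theta+a).  The corners of the (0,1)^2 square correspond to the four
limiting models (constitutive, mixture, bursty, heavy-tailed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ModelKind",
    "ModelParams",
    "RegimeCoordinates",
    "ParamValidationError",
    "mean_transcription_rate",
    "regime_coordinates",
    "params_from_regime",
    "regime_lattice",
    "params_from_json",
    "params_to_json",
]


class ParamValidationError(ValueError):
    """Raised when a kinetic parameter is out of its admissible domain."""


class ModelKind(Enum):
    """Model labels: the two SDE-driven models and their limiting regimes.

    CIR_LIMIT is the heavy-tailed large-kappa limit of the CIR model (the
    third reduced model used for coarse regime assignment); it is not one of
    the four classical corners but is needed to name that fit.
    """

    GOU = "gou"
    CIR = "cir"
    CONSTITUTIVE = "constitutive"
    MIXTURE = "mixture"
    BURSTY = "bursty"
    CIR_LIMIT = "cir_limit"

    @classmethod
    def from_string(cls, s: str) -> "ModelKind":
        try:
            return cls(s.strip().lower())
        except ValueError:
            raise ParamValidationError(
                f"unknown model kind {s!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def _check_positive_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v) or v <= 0.0:
        raise ParamValidationError(
            f"parameter {name!r} must be strictly positive and finite, got {value!r}"
        )
    return v


@dataclass(frozen=True)
class ModelParams:
    """The five kinetic parameters shared by every model variant.

    kappa : mean-reversion rate of the transcription-rate driver (1/time)
    theta : gain (jump mean for the gamma-OU driver / CLE gain for CIR;
            transcription-rate units)
    a     : driver arrival/production frequency (1/time)
    beta  : splicing rate (1/time)
    gamma_: mature-RNA degradation rate (1/time)
    """

    kappa: float
    theta: float
    a: float
    beta: float
    gamma_: float

    def __post_init__(self):
        for name in ("kappa", "theta", "a", "beta", "gamma_"):
            object.__setattr__(
                self, name, _check_positive_finite(name, getattr(self, name))
            )

    @property
    def mean_rate(self) -> float:
        """Stationary mean transcription rate <K> = a*theta/kappa."""
        return self.a * self.theta / self.kappa

    # --- derived quantities used by the limiting models -------------------
    @property
    def burst_size(self) -> float:
        """Mean geometric burst size b = theta/kappa of the bursty limit."""
        return self.theta / self.kappa

    @property
    def mixture_shape(self) -> float:
        """Gamma shape alpha = a/kappa of the stationary rate law."""
        return self.a / self.kappa

    def replace(self, **kw) -> "ModelParams":
        d = dict(
            kappa=self.kappa, theta=self.theta, a=self.a,
            beta=self.beta, gamma_=self.gamma_,
        )
        d.update(kw)
        return ModelParams(**d)


@dataclass(frozen=True)
class RegimeCoordinates:
    """Point in the two-dimensional qualitative-regime square (0,1)^2."""

    reversion_coord: float  # kappa / (kappa + beta + gamma)
    gain_coord: float       # theta / (theta + a)

    def __post_init__(self):
        for name in ("reversion_coord", "gain_coord"):
            v = float(getattr(self, name))
            if not (0.0 < v < 1.0):
                raise ParamValidationError(
                    f"{name} must lie in the open interval (0, 1), got {v!r}"
                )
            object.__setattr__(self, name, v)


def mean_transcription_rate(p: ModelParams) -> float:
    """Stationary mean transcription rate <K> = a*theta/kappa."""
    return p.mean_rate


def regime_coordinates(p: ModelParams) -> RegimeCoordinates:
    """Map parameters to the qualitative-regime square.

    The reversion coordinate kappa/(kappa+beta+gamma) compares driver
    mean-reversion with RNA turnover; the gain coordinate theta/(theta+a)
    compares fluctuation size with fluctuation frequency.
    """
    return RegimeCoordinates(
        reversion_coord=p.kappa / (p.kappa + p.beta + p.gamma_),
        gain_coord=p.theta / (p.theta + p.a),
    )


def params_from_regime(
    reversion_coord: float,
    gain_coord: float,
    mean_rate: float,
    beta: float,
    gamma_: float,
) -> ModelParams:
    """Invert the regime-coordinate map at fixed (<K>, beta, gamma).

    Solves kappa/(kappa+beta+gamma) = r, theta/(theta+a) = g and
    a*theta/kappa = <K> jointly:

        kappa = (beta+gamma) r / (1-r)
        theta = sqrt(<K> * kappa * g / (1-g))
        a     = theta (1-g) / g
    """
    r = float(reversion_coord)
    g = float(gain_coord)
    if not (0.0 < r < 1.0) or not (0.0 < g < 1.0):
        raise ParamValidationError(
            f"regime coordinates must lie strictly inside (0,1), got ({r}, {g})"
        )
    mean_rate = _check_positive_finite("mean_rate", mean_rate)
    beta = _check_positive_finite("beta", beta)
    gamma_ = _check_positive_finite("gamma_", gamma_)
    kappa = (beta + gamma_) * r / (1.0 - r)
    theta = math.sqrt(mean_rate * kappa * g / (1.0 - g))
    a = theta * (1.0 - g) / g
    return ModelParams(kappa=kappa, theta=theta, a=a, beta=beta, gamma_=gamma_)


def regime_lattice(
    n_per_axis: int = 10,
    lo: float = 0.05,
    hi: float = 0.95,
) -> list[RegimeCoordinates]:
    """Even lattice over the qualitative-regime square.

    Stands in for the "uniform coverage" parameter-set design of the
    distinguishability experiments; bounds avoid the singular edges.
    """
    if n_per_axis < 1:
        raise ParamValidationError("n_per_axis must be >= 1")
    axis = np.linspace(lo, hi, n_per_axis)
    return [
        RegimeCoordinates(float(r), float(g)) for r in axis for g in axis
    ]


# --- JSON parameter files --------------------------------------------------

def params_to_json(p: ModelParams, model: ModelKind | None = None) -> str:
    d = {
        "kappa": p.kappa, "theta": p.theta, "a": p.a,
        "beta": p.beta, "gamma": p.gamma_,
    }
    if model is not None:
        d = {"model": model.value, **d}
    return json.dumps(d, indent=2)


def params_from_json(text: str) -> tuple[ModelParams, ModelKind | None]:
    """Parse a parameter JSON; accepts explicit rates or regime coordinates.

    Explicit form:  {"model": "gou", "kappa": ..., "theta": ..., "a": ...,
                     "beta": ..., "gamma": ...}
    Regime form:    {"model": "cir", "reversion_coord": ..., "gain_coord": ...,
                     "mean_rate": ..., "beta": ..., "gamma": ...}
    """
    d = json.loads(text)
    model = ModelKind.from_string(d["model"]) if "model" in d else None
    if "kappa" in d:
        p = ModelParams(
            kappa=d["kappa"], theta=d["theta"], a=d["a"],
            beta=d["beta"], gamma_=d["gamma"],
        )
    else:
        p = params_from_regime(
            d["reversion_coord"], d["gain_coord"], d["mean_rate"],
            d["beta"], d["gamma"],
        )
    return p, model
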