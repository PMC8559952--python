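"""Cognitive choice models for the resource-allocation game.

Subjective value of an allocation (pi_self, pi_other) is linear in the
other's payoff with slope tan(alpha), where alpha is the social-value-
orientation (SVO) angle:

    V(pi_self, pi_other) = pi_self + tan(alpha) * pi_other

The default allocation additionally carries a bias term kappa, an amount of
penalty (kappa > 0) or bonus (kappa < 0) points capturing a demand-driven
propensity to pick alternatives regardless of their social content:

    V(D) = 100 + tan(alpha) * 50 - kappa

Two families map values onto choice:

* Stable Attitude — alpha is a fixed trait; choice noise is a softmax on the
  value difference with temperature tau (in points):
  logit Pr(D) = (V_D - V_A) / tau.
* Variable Attitude (random preference) — alpha is redrawn each trial from
  Normal(mu, sigma); the trial's indifference threshold is
  T_alpha = atan((pi_self - 100 + kappa) / (50 - pi_other)), and Pr(D) is the
  probit mass of the attitude distribution on the default's side of T_alpha.

Both are finally mixed with a lapse: with probability epsilon the response is
a coin flip.  All angles at the API are degrees; radians are internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, ndtr

from .task_design import Allocation, Phase

__all__ = [
    "Family",
    "Scheme",
    "ModelSpec",
    "ALL_MODEL_SPECS",
    "ParameterSet",
    "Choice",
    "ChoiceRecord",
    "utility",
    "default_value",
    "threshold_alpha",
    "p_default_stable",
    "p_default_variable",
    "apply_lapse",
    "p_default",
    "log_likelihood",
    "trial_arrays",
]

PROB_FLOOR = 1e-300
EPSILON_MAX = 0.5


class Family(str, Enum):
    stable = "stable"
    variable = "variable"


class Scheme(str, Enum):
    """Which subject-level parameters are tied across the two phases."""

    full = "full"                          # attitude and variability both vary
    shared_attitude = "shared_attitude"    # one attitude for the whole task
    shared_variability = "shared_variability"  # one tau/sigma for the whole task


@dataclass(frozen=True)
class ModelSpec:
    family: Family
    scheme: Scheme

    @property
    def name(self) -> str:
        return f"{self.family.value}/{self.scheme.value}"


ALL_MODEL_SPECS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(f, s) for f in Family for s in Scheme
)


@dataclass(frozen=True)
class ParameterSet:
    """Subject-level parameters of one phase.

    attitude: degrees; the trait alpha for the stable family, the centre mu
        of the trial-wise sampling distribution for the variable family.
    variability: tau in points (stable) or sigma in degrees (variable); > 0.
    bias_kappa: points added against the default allocation.
    lapse_epsilon: probability of a random response, in [0, 1].
    """

    attitude: float
    variability: float
    bias_kappa: float = 0.0
    lapse_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 < self.attitude < 90.0:
            raise ValueError("attitude must lie in (-90, 90) degrees")
        if self.variability <= 0:
            raise ValueError("variability must be positive")
        if not 0.0 <= self.lapse_epsilon <= 1.0:
            raise ValueError("lapse_epsilon is a probability")


class Choice(str, Enum):
    default = "default"
    alternative = "alternative"
    missing = "missing"


@dataclass(frozen=True)
class ChoiceRecord:
    allocation: Allocation
    phase: Phase
    choice: Choice


class DegenerateTrialError(ValueError):
    """Trial with pi_other = 50: the attitude threshold is undefined."""


def _tan_deg(alpha):
    alpha = np.asarray(alpha, dtype=float)
    if np.any(np.abs(alpha) >= 90.0):
        raise ValueError("attitude must lie strictly inside (-90, 90) degrees")
    return np.tan(np.radians(alpha))


def utility(pi_self, pi_other, attitude_alpha):
    """Subjective value pi_self + tan(alpha) * pi_other (alpha in degrees)."""
    return np.asarray(pi_self, float) + _tan_deg(attitude_alpha) * np.asarray(pi_other, float)


def default_value(attitude_alpha, bias_kappa=0.0):
    """Value of the default allocation: 100 + tan(alpha)*50 - kappa."""
    return 100.0 + _tan_deg(attitude_alpha) * 50.0 - np.asarray(bias_kappa, float)


def threshold_alpha(a: Allocation | tuple, bias_kappa=0.0):
    """Indifference attitude T_alpha for one allocation, in degrees.

    The alpha at which default and alternative have equal value:
    T_alpha = atan((pi_self - 100 + kappa) / (50 - pi_other)).
    Undefined for pi_other = 50 (the value difference no longer depends on
    attitude).
    """
    x, y = (a.pi_self, a.pi_other) if isinstance(a, Allocation) else (a[0], a[1])
    if y == 50:
        raise DegenerateTrialError("pi_other = 50: attitude-independent trial")
    return _threshold_alpha_arr(
        np.asarray(x, float), np.asarray(y, float), np.asarray(bias_kappa, float)
    )


def _threshold_alpha_arr(pi_self, pi_other, kappa):
    return np.degrees(np.arctan((pi_self - 100.0 + kappa) / (50.0 - pi_other)))


def p_default_stable(a: Allocation | tuple, params: ParameterSet):
    """Softmax probability of choosing the default, before lapse mixing."""
    x, y = (a.pi_self, a.pi_other) if isinstance(a, Allocation) else (a[0], a[1])
    return _p_default_stable_arr(
        np.asarray(x, float), np.asarray(y, float),
        params.attitude, params.variability, params.bias_kappa,
    )


def _p_default_stable_arr(pi_self, pi_other, alpha, tau, kappa):
    vd = default_value(alpha, kappa)
    va = utility(pi_self, pi_other, alpha)
    return expit((vd - va) / np.asarray(tau, float))


def p_default_variable(a: Allocation | tuple, params: ParameterSet):
    """Random-preference probability of choosing the default, before lapse.

    Mass of Normal(mu, sigma) on the default's side of the trial threshold:
    Phi((T_alpha - mu)/sigma) on prosocial trials (pi_other > 50), and
    Phi((mu - T_alpha)/sigma) on antisocial ones.
    """
    x, y = (a.pi_self, a.pi_other) if isinstance(a, Allocation) else (a[0], a[1])
    if y == 50:
        raise DegenerateTrialError("pi_other = 50: attitude-independent trial")
    return _p_default_variable_arr(
        np.asarray(x, float), np.asarray(y, float),
        params.attitude, params.variability, params.bias_kappa,
    )


def _p_default_variable_arr(pi_self, pi_other, mu, sigma, kappa):
    t = _threshold_alpha_arr(pi_self, pi_other, np.asarray(kappa, float))
    z = (t - np.asarray(mu, float)) / np.asarray(sigma, float)
    pro = pi_other > 50.0
    return np.where(pro, ndtr(z), ndtr(-z))


def apply_lapse(p_model, lapse_epsilon):
    """Mixture (1 - eps) * p_model + eps / 2."""
    p = np.asarray(p_model, float)
    e = np.asarray(lapse_epsilon, float)
    if np.any(p < 0) or np.any(p > 1) or np.any(e < 0) or np.any(e > 1):
        raise ValueError("inputs must be probabilities")
    return (1.0 - e) * p + e * 0.5


def _p_default_degenerate_arr(pi_self, alpha, variability, kappa, family: Family):
    # pi_other = 50: V_A - V_D = pi_self - 100 + kappa exactly, attitude-free.
    dv = np.asarray(pi_self, float) - 100.0 + np.asarray(kappa, float)
    if family is Family.stable:
        return expit(-dv / np.asarray(variability, float))
    return np.where(dv > 0, 0.0, np.where(dv < 0, 1.0, 0.5)) + 0.0 * np.asarray(alpha, float)


def p_default(a: Allocation | tuple, params: ParameterSet, family: Family):
    """Lapse-mixed probability of the default choice under either family.

    Degenerate trials (pi_other = 50) use the attitude-free value difference
    pi_self - 100 + kappa: a softmax for the stable family and a hard step
    (0.5 at exact indifference) for the variable family.
    """
    x, y = (a.pi_self, a.pi_other) if isinstance(a, Allocation) else (a[0], a[1])
    if y == 50:
        p = _p_default_degenerate_arr(
            x, params.attitude, params.variability, params.bias_kappa, family
        )
    elif family is Family.stable:
        p = p_default_stable(a, params)
    else:
        p = p_default_variable(a, params)
    return apply_lapse(p, params.lapse_epsilon)


def choice_probabilities(pi_self, pi_other, params: ParameterSet, family: Family):
    """Lapse-mixed default-choice probabilities over arrays of trials."""
    x = np.asarray(pi_self, float)
    y = np.asarray(pi_other, float)
    p = _p_default_mixed_arr(x, y, params.attitude, params.variability,
                             params.bias_kappa, family)
    return apply_lapse(p, params.lapse_epsilon)


def _p_default_mixed_arr(pi_self, pi_other, alpha, variability, kappa,
                         family: Family):
    """Pre-lapse default probability, handling degenerate pi_other = 50."""
    deg = pi_other == 50.0
    if family is Family.stable:
        p = _p_default_stable_arr(pi_self, pi_other, alpha, variability, kappa)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = _p_default_variable_arr(pi_self, pi_other, alpha, variability, kappa)
    if np.any(deg):
        pdeg = _p_default_degenerate_arr(pi_self, alpha, variability, kappa, family)
        p = np.where(deg, pdeg, p)
    return p


# ---------------------------------------------------------------------------
# Vectorised likelihood

def trial_arrays(records: Sequence[ChoiceRecord], phase: Phase | None = None):
    """Pack records into (pi_self, pi_other, chose_default, answered) arrays.

    ``chose_default`` is 1.0 for default, 0.0 for alternative, and arbitrary
    where ``answered`` is False (missing trials never enter likelihoods).
    """
    recs = [r for r in records if phase is None or r.phase == phase]
    x = np.array([r.allocation.pi_self for r in recs], float)
    y = np.array([r.allocation.pi_other for r in recs], float)
    d = np.array([1.0 if r.choice is Choice.default else 0.0 for r in recs])
    m = np.array([r.choice is not Choice.missing for r in recs], bool)
    return x, y, d, m


def loglik_arrays(pi_self, pi_other, chose_default, answered,
                  alpha, variability, kappa, epsilon, family: Family) -> float:
    """Log-likelihood of one phase's choices for one parameter point.

    Parameters are scalars (or broadcastable); trial inputs are 1-D arrays.
    """
    p = _p_default_mixed_arr(pi_self, pi_other, alpha, variability, kappa, family)
    p = apply_lapse(p, epsilon)
    like = np.where(chose_default == 1.0, p, 1.0 - p)
    like = np.maximum(like, PROB_FLOOR)
    return float(np.sum(np.log(like), where=answered))


def log_likelihood(
    records: Sequence[ChoiceRecord],
    params_by_phase: Mapping[Phase, ParameterSet],
    spec: ModelSpec,
) -> float:
    """Summed log-probability of the observed choices under a model spec.

    ``params_by_phase`` supplies a ParameterSet for each phase present in the
    records.  Under ``shared_attitude`` (``shared_variability``) the
    attitude (variability) entries must agree across phases — the tied
    parameter is a single quantity.
    """
    phases = sorted({r.phase for r in records}, key=lambda p: p.value)
    if not records:
        warnings.warn("empty record list: log-likelihood is 0", stacklevel=2)
        return 0.0
    if len(phases) > 1:
        vals = [params_by_phase[p] for p in phases]
        if spec.scheme is Scheme.shared_attitude and len({v.attitude for v in vals}) > 1:
            raise ValueError("shared_attitude scheme requires one attitude across phases")
        if spec.scheme is Scheme.shared_variability and len({v.variability for v in vals}) > 1:
            raise ValueError("shared_variability scheme requires one variability across phases")
    total = 0.0
    for ph in phases:
        pr = params_by_phase[ph]
        x, y, d, m = trial_arrays(records, ph)
        total += loglik_arrays(x, y, d, m, pr.attitude, pr.variability,
                               pr.bias_kappa, pr.lapse_epsilon, spec.family)
    return total
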