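"""Derived behavioural measures.

Attitude classification uses only raw choices: each chosen alternative
contributes half its polar angle, atan((pi_other - 50) / (r + pi_self - 50)),
and the sign of the sum labels the participant prosocial (>= 0) or antisocial.
Conformity is measured against the observed agent's attitude alpha_obs as

    delta_diff = |alpha_before - alpha_obs| - |alpha_after - alpha_obs|

(positive: moved toward the agent; overshooting past the agent is penalised)
with the signed robustness variant delta_alpha = sgn(alpha_obs) * (after -
before).  The compliance index is the smaller of the percentages of prosocial
and antisocial alternatives a participant chose; at or above 25% the
participant is flagged as susceptible to experimenter demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import Choice, ChoiceRecord
from .task_design import Role

__all__ = [
    "classify_attitude",
    "attitude_convergence",
    "attitude_polarisation",
    "compliance_index",
    "is_compliant",
    "consistency_change",
    "MeasuresRow",
    "measures_frame",
    "COMPLIANCE_THRESHOLD",
]

COMPLIANCE_THRESHOLD = 25.0


class NoScorableTrialsError(ValueError):
    """No answered, non-degenerate trials to classify an attitude from."""


class UndefinedComplianceError(ValueError):
    """A phase with no answered prosocial or no answered antisocial trial."""


def _half_angle_deg(pi_self: float, pi_other: float) -> float:
    # atan(y / (r + x)) is the half-angle of (x, y); summing halves keeps the
    # score bounded while preserving the sign of the mean chosen angle
    x, y = pi_self - 50.0, pi_other - 50.0
    r = math.hypot(x, y)
    return math.degrees(math.atan2(y, r + x))


def classify_attitude(before_records: Sequence[ChoiceRecord]) -> tuple[str, float]:
    """Label a participant prosocial/antisocial from raw before-phase choices.

    Returns ``(label, score)`` where score is the summed half-angle (degrees)
    of all chosen alternatives.  Ties (score exactly 0, e.g. no alternatives
    chosen) classify prosocial.  Degenerate trials (pi_other = 50) carry no
    attitude information and are excluded.
    """
    scorable = [
        r for r in before_records
        if r.choice is not Choice.missing and r.allocation.pi_other != 50
    ]
    if not scorable:
        raise NoScorableTrialsError("no answered non-degenerate trials")
    score = sum(
        _half_angle_deg(r.allocation.pi_self, r.allocation.pi_other)
        for r in scorable
        if r.choice is Choice.alternative
    )
    return ("prosocial" if score >= 0 else "antisocial"), score


def attitude_convergence(alpha_before: float, alpha_after: float,
                         alpha_obs: float) -> float:
    """delta_diff: reduction in absolute distance to the agent, degrees."""
    return abs(alpha_before - alpha_obs) - abs(alpha_after - alpha_obs)


def attitude_polarisation(alpha_before: float, alpha_after: float,
                          alpha_obs: float) -> float:
    """delta_alpha: signed attitude change in the agent's direction."""
    if alpha_obs == 0:
        raise ValueError("alpha_obs must be nonzero")
    return math.copysign(1.0, alpha_obs) * (alpha_after - alpha_before)


def compliance_index(before_records: Sequence[ChoiceRecord]) -> float:
    """min(% prosocial alternatives chosen, % antisocial chosen), in [0, 100].

    Denominators count answered trials only.  Undefined (raises) when either
    trial type has no answered trials — such participants are excluded from
    compliance analyses.
    """
    props = []
    for role in (Role.prosocial_alt, Role.antisocial_alt):
        answered = [r for r in before_records
                    if r.allocation.role is role and r.choice is not Choice.missing]
        if not answered:
            raise UndefinedComplianceError(f"no answered {role.value} trials")
        chosen = sum(r.choice is Choice.alternative for r in answered)
        props.append(100.0 * chosen / len(answered))
    return min(props)


def is_compliant(index: float, threshold: float = COMPLIANCE_THRESHOLD) -> bool:
    """Index at or above threshold (default 25%): both alternative types
    chosen at least once in every four opportunities."""
    return index >= threshold


def consistency_change(sigma_before: float, sigma_after: float) -> float:
    """sigma_before - sigma_after, degrees; positive = more consistent after."""
    if sigma_before <= 0 or sigma_after <= 0:
        raise ValueError("variability parameters are positive")
    return sigma_before - sigma_after


@dataclass(frozen=True)
class MeasuresRow:
    participant_id: str
    condition: str
    alpha_before: float
    alpha_after: float
    sigma_before: float
    sigma_after: float
    kappa_before: float
    alpha_obs: float
    delta_diff: float
    delta_alpha: float
    compliance_index: float | None
    compliant: bool | None
    consistency_change: float


def measures_frame(rows: Sequence[MeasuresRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    # recomputation invariant: delta_diff must match its definition
    chk = (df.alpha_before - df.alpha_obs).abs() - (df.alpha_after - df.alpha_obs).abs()
    if not np.allclose(chk, df.delta_diff, atol=1e-9):
        raise ValueError("delta_diff rows inconsistent with their definition")
    return df


def build_measures_row(
    participant_id: str,
    condition: str,
    alpha_before: float,
    alpha_after: float,
    sigma_before: float,
    sigma_after: float,
    kappa_before: float,
    alpha_obs: float,
    before_records: Sequence[ChoiceRecord],
    threshold: float = COMPLIANCE_THRESHOLD,
) -> MeasuresRow:
    """Assemble one participant's row, handling the undefined-compliance case."""
    try:
        idx = compliance_index(before_records)
        comp = is_compliant(idx, threshold)
    except UndefinedComplianceError:
        idx, comp = None, None
    return MeasuresRow(
        participant_id=participant_id,
        condition=condition,
        alpha_before=alpha_before,
        alpha_after=alpha_after,
        sigma_before=sigma_before,
        sigma_after=sigma_after,
        kappa_before=kappa_before,
        alpha_obs=alpha_obs,
        delta_diff=attitude_convergence(alpha_before, alpha_after, alpha_obs),
        delta_alpha=attitude_polarisation(alpha_before, alpha_after, alpha_obs),
        compliance_index=idx,
        compliant=comp,
        consistency_change=consistency_change(sigma_before, sigma_after),
    )
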