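"""Synthetic participants for the four-condition conformity study.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline is testable without participant data:

* a between-subjects design with Baseline / Computer / Individual / Group
  conditions;
* a 75/25 prosocial/antisocial mixture of social attitudes, with prosocial
  attitudes centred at +20 deg (SD 14) and antisocial at -22 deg (SD 20);
* a compliant subpopulation (17%) with a strongly elevated default-penalty
  bias kappa (mean 11.48 points vs 1.14 for the rest), modelling
  susceptibility to experimenter demand;
* extreme observed agents at +/-45 deg whose sign matches the participant's
  pre-manipulation classification;
* condition-dependent attitude shifts toward the agent (0/4/6/5 deg for
  Baseline/Computer/Individual/Group), applied to the compliant subgroup in
  the Computer condition and to the non-compliant subgroup in the human
  conditions — the pattern the measures and statistics stages are built to
  detect;
* 4-point Likert social-appropriateness ratings whose monotone trend over the
  probed allocations follows the sign of the participant's attitude.

The after-phase attitude is produced by a deterministic shift plus Gaussian
jitter, not by a learning process: the analysis measures conformity, it does
not model the learning dynamics that produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .measures import classify_attitude
from .models import (
    Choice,
    ChoiceRecord,
    Family,
    ParameterSet,
    choice_probabilities,
)
from .task_design import (
    Allocation,
    Phase,
    Role,
    TrialSet,
    allocation_angle,
    generate_allocation_set,
    make_manipulation_set,
    make_selfish_trials,
    partition_subsets,
)

__all__ = [
    "CONDITIONS",
    "PopulationConfig",
    "StudyDesign",
    "SyntheticParticipant",
    "PredictionRecord",
    "build_design",
    "subsample_trialset",
    "sample_population",
    "simulate_choices",
    "assign_agent",
    "simulate_group_agent",
    "simulate_norm_ratings",
    "write_choices_csv",
    "write_truth_csv",
    "read_choices_csv",
]

CONDITIONS = ("baseline", "computer", "individual", "group")
AGENT_ATTITUDE = 45.0
ATTITUDE_CLIP = 85.0  # keep ground truth well inside tan's domain


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth distributions of the simulated sample.

    Defaults are the study conditions; see the module docstring.  The
    ``shift_recipients`` mapping states which subgroup of each condition
    receives the convergence shift ("all", "compliant" or "noncompliant").
    """

    n_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {c: 100 for c in CONDITIONS})
    prosocial_fraction: float = 0.75
    attitude_mean_pro: float = 20.0
    attitude_sd_pro: float = 14.0
    attitude_mean_anti: float = -22.0
    attitude_sd_anti: float = 20.0
    compliant_fraction: float = 0.17
    kappa_mean_compliant: float = 11.48
    kappa_sd_compliant: float = 4.0
    kappa_mean_noncompliant: float = 1.14
    kappa_sd_noncompliant: float = 2.0
    convergence_shift: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 0.0, "computer": 4.0,
                                 "individual": 6.0, "group": 5.0})
    shift_recipients: Mapping[str, str] = field(
        default_factory=lambda: {"baseline": "all", "computer": "compliant",
                                 "individual": "noncompliant",
                                 "group": "noncompliant"})
    shift_jitter_sd: float = 3.0
    sigma_log_mean: float = float(np.log(10.0))
    sigma_log_sd: float = 0.4
    sigma_after_log_ratio_mean: float = float(np.log(0.85))
    sigma_after_log_ratio_sd: float = 0.15
    epsilon_low: float = 0.01
    epsilon_high: float = 0.05
    missing_rate: float = 0.0
    family: Family = Family.variable
    agent_sigma: float = 2.0
    agent_epsilon: float = 0.01
    group_size: int = 5
    prediction_accuracy: float = 0.93
    norm_noise_sd: float = 0.6
    n_norm_probes: int = 24
    trials_per_phase: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f_ in (self.prosocial_fraction, self.compliant_fraction,
                   self.missing_rate, self.prediction_accuracy):
            if not 0.0 <= f_ <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for s in (self.attitude_sd_pro, self.attitude_sd_anti,
                  self.sigma_log_sd, self.agent_sigma):
            if s <= 0:
                raise ValueError("standard deviations must be positive")
        if any(n < 0 for n in self.n_per_condition.values()):
            raise ValueError("condition counts must be non-negative")
        if self.group_size % 2 == 0:
            raise ValueError("group size must be odd (modal response must exist)")


@dataclass(frozen=True)
class StudyDesign:
    """Trial material shared by every simulated participant."""

    subsets: tuple[TrialSet, ...]
    selfish: tuple[Allocation, ...]
    before_sets: Mapping[str, TrialSet]
    after_sets: Mapping[str, TrialSet]
    manipulation_set: TrialSet
    norm_probes: tuple[Allocation, ...]


@dataclass(frozen=True)
class PredictionRecord:
    allocation: Allocation
    agent_choice: Choice
    correct: bool


@dataclass(frozen=True)
class SyntheticParticipant:
    participant_id: str
    condition: str
    prosocial: bool
    compliant: bool
    true_params_before: ParameterSet
    true_params_after: ParameterSet
    agent_attitude: float
    before_records: tuple[ChoiceRecord, ...]
    after_records: tuple[ChoiceRecord, ...]
    prediction_records: tuple[PredictionRecord, ...]
    norm_ratings: tuple[int, ...] | None

    @property
    def records(self) -> tuple[ChoiceRecord, ...]:
        return self.before_records + self.after_records


def _stratified_pick(allocations: Sequence[Allocation], n: int,
                     rng: np.random.Generator) -> list[Allocation]:
    ordered = sorted(allocations, key=allocation_angle)
    edges = np.linspace(0, len(ordered), n + 1)
    out = []
    for i in range(n):
        lo, hi = int(edges[i]), max(int(edges[i]), int(edges[i + 1]) - 1)
        out.append(ordered[int(rng.integers(lo, hi + 1))])
    return out


def build_design(seed: int = 0) -> StudyDesign:
    """Assemble the full trial material from the generation rules.

    Baseline uses the two 102-trial subsets for its choice phases; the other
    conditions use the two 101-trial subsets, with subset 1 held out to feed
    the 63-trial manipulation phase.  The 9 selfish alternatives are appended
    to every choice phase.  24 angle-stratified allocations from subset 2
    serve as norm-elicitation probes.
    """
    rng = np.random.default_rng(seed)
    subsets = partition_subsets(generate_allocation_set())
    selfish = tuple(make_selfish_trials(9, rng))
    s102a, s102b, s101a, s101b = subsets  # sizes 102, 102, 101, 101

    def phase_set(src: TrialSet, phase: Phase) -> TrialSet:
        return TrialSet(src.allocations + selfish, phase, src.subset_id)

    before_sets = {"baseline": phase_set(s102a, Phase.before)}
    after_sets = {"baseline": phase_set(s102b, Phase.after)}
    for cond in ("computer", "individual", "group"):
        before_sets[cond] = phase_set(s101a, Phase.before)
        after_sets[cond] = phase_set(s101b, Phase.after)
    manipulation = make_manipulation_set(s102a, 63, rng)
    probes = tuple(_stratified_pick(s102b.allocations, 24, rng))
    return StudyDesign(subsets, selfish, before_sets, after_sets,
                       manipulation, probes)


def subsample_trialset(ts: TrialSet, n: int, seed: int | np.random.Generator = 0,
                       keep_selfish: bool = True) -> TrialSet:
    """Angle-stratified subsample of a phase set, keeping selfish trials."""
    rng = np.random.default_rng(seed)
    band = [a for a in ts.allocations if a.role is not Role.selfish_alt]
    selfish = tuple(a for a in ts.allocations if a.role is Role.selfish_alt)
    if not keep_selfish:
        selfish = ()
    n_band = n - len(selfish)
    if n_band <= 0 or n_band > len(band):
        raise ValueError("requested size incompatible with the source set")
    picks = _stratified_pick(band, n_band, rng)
    return TrialSet(tuple(picks) + selfish, ts.phase, ts.subset_id)


def simulate_choices(
    params: ParameterSet,
    trials: TrialSet,
    family: Family,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
) -> list[ChoiceRecord]:
    """One sampled choice per trial under the family's lapse-mixed model."""
    rng = np.random.default_rng(seed)
    x = np.array([a.pi_self for a in trials.allocations], float)
    y = np.array([a.pi_other for a in trials.allocations], float)
    p = choice_probabilities(x, y, params, family)
    is_default = rng.random(len(x)) < p
    is_missing = rng.random(len(x)) < missing_rate
    out = []
    for a, d, m in zip(trials.allocations, is_default, is_missing):
        choice = Choice.missing if m else (Choice.default if d else Choice.alternative)
        out.append(ChoiceRecord(a, trials.phase, choice))
    return out


def assign_agent(before_records: Sequence[ChoiceRecord]) -> float:
    """Agent attitude: +45 deg for prosocial participants, -45 for antisocial."""
    label, _ = classify_attitude(before_records)
    return AGENT_ATTITUDE if label == "prosocial" else -AGENT_ATTITUDE


def simulate_group_agent(
    members: Sequence[ParameterSet],
    trials: TrialSet,
    family: Family = Family.variable,
    seed: int | np.random.Generator = 0,
) -> list[Choice]:
    """Per-trial modal choice of independently simulated group members."""
    if len(members) % 2 == 0:
        raise ValueError("member count must be odd")
    rng = np.random.default_rng(seed)
    votes = np.zeros(len(trials), dtype=int)
    for m in members:
        recs = simulate_choices(m, trials, family, rng)
        votes += np.array([r.choice is Choice.default for r in recs], int)
    return [Choice.default if v > len(members) / 2 else Choice.alternative
            for v in votes]


def simulate_norm_ratings(
    attitude_sign: float,
    probe_allocations: Sequence[Allocation],
    noise_sd: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Likert 1-4 appropriateness ratings for the probed allocations.

    A latent appropriateness sgn(attitude) * (pi_other - 50)/50 plus Gaussian
    noise is cut at (-0.5, 0, +0.5): prosocial raters consider generous
    allocations appropriate, antisocial raters the opposite.  With zero noise
    the ratings are monotone in pi_other; as noise grows they decouple from
    attitude.
    """
    rng = np.random.default_rng(seed)
    sign = 1.0 if attitude_sign >= 0 else -1.0
    y = np.array([a.pi_other for a in probe_allocations], float)
    latent = sign * (y - 50.0) / 50.0
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=len(y))
    return (np.digitize(latent, [-0.5, 0.0, 0.5]) + 1).astype(int)


def _draw_params(cfg: PopulationConfig, rng: np.random.Generator
                 ) -> tuple[bool, bool, ParameterSet, float]:
    """Draw one participant's mixture flags and before-phase parameters."""
    prosocial = rng.random() < cfg.prosocial_fraction
    compliant = rng.random() < cfg.compliant_fraction
    if prosocial:
        att = rng.normal(cfg.attitude_mean_pro, cfg.attitude_sd_pro)
    else:
        att = rng.normal(cfg.attitude_mean_anti, cfg.attitude_sd_anti)
    att = float(np.clip(att, -ATTITUDE_CLIP, ATTITUDE_CLIP))
    if compliant:
        kappa = rng.normal(cfg.kappa_mean_compliant, cfg.kappa_sd_compliant)
    else:
        kappa = rng.normal(cfg.kappa_mean_noncompliant, cfg.kappa_sd_noncompliant)
    sigma = float(np.exp(rng.normal(cfg.sigma_log_mean, cfg.sigma_log_sd)))
    eps = float(rng.uniform(cfg.epsilon_low, cfg.epsilon_high))
    before = ParameterSet(att, sigma, float(kappa), eps)
    sigma_after = sigma * float(np.exp(rng.normal(
        cfg.sigma_after_log_ratio_mean, cfg.sigma_after_log_ratio_sd)))
    return prosocial, compliant, before, sigma_after


def _shift_applies(cfg: PopulationConfig, condition: str, compliant: bool) -> bool:
    rule = cfg.shift_recipients.get(condition, "all")
    return (rule == "all"
            or (rule == "compliant" and compliant)
            or (rule == "noncompliant" and not compliant))


def _agent_choices(cfg: PopulationConfig, design: StudyDesign, condition: str,
                   agent_attitude: float, rng: np.random.Generator) -> list[Choice]:
    agent_params = ParameterSet(agent_attitude, cfg.agent_sigma, 0.0,
                                cfg.agent_epsilon)
    if condition == "individual":
        recs = simulate_choices(agent_params, design.manipulation_set,
                                Family.variable, rng)
        return [r.choice for r in recs]
    # group, and the computer that mimics the group's modal choices
    members = [replace(agent_params,
                       attitude=float(np.clip(
                           rng.normal(agent_attitude, cfg.agent_sigma),
                           -ATTITUDE_CLIP, ATTITUDE_CLIP)))
               for _ in range(cfg.group_size)]
    return simulate_group_agent(members, design.manipulation_set,
                                Family.variable, rng)


def sample_population(
    config: PopulationConfig, design: StudyDesign | None = None
) -> list[SyntheticParticipant]:
    """Simulate the full between-subjects sample; reproducible under seed.

    All randomness flows from ``config.seed`` through per-participant
    substreams, so the population is invariant to the order conditions are
    listed in and stable when counts change in other conditions.
    """
    if design is None:
        design = build_design(config.seed)
    participants: list[SyntheticParticipant] = []
    for cond in config.n_per_condition:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        before_set, after_set = design.before_sets[cond], design.after_sets[cond]
        for i in range(config.n_per_condition[cond]):
            # per-participant substream keyed by (seed, condition, index):
            # stable under reordering or resizing of other conditions
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=(config.seed, CONDITIONS.index(cond), i)))
            if config.trials_per_phase is not None:
                b_set = subsample_trialset(before_set, config.trials_per_phase, rng)
                a_set = subsample_trialset(after_set, config.trials_per_phase, rng)
            else:
                b_set, a_set = before_set, after_set
            prosocial, compliant, before, sigma_after = _draw_params(config, rng)
            before_recs = tuple(simulate_choices(
                before, b_set, config.family, rng, config.missing_rate))
            agent = assign_agent(before_recs)
            att_after = before.attitude
            if _shift_applies(config, cond, compliant):
                gap = agent - before.attitude
                att_after += float(np.sign(gap)) * min(
                    config.convergence_shift.get(cond, 0.0), abs(gap))
            att_after += float(rng.normal(0.0, config.shift_jitter_sd))
            att_after = float(np.clip(att_after, -ATTITUDE_CLIP, ATTITUDE_CLIP))
            after = ParameterSet(att_after, sigma_after, before.bias_kappa,
                                 float(rng.uniform(config.epsilon_low,
                                                   config.epsilon_high)))
            after_recs = tuple(simulate_choices(
                after, a_set, config.family, rng, config.missing_rate))
            preds: tuple[PredictionRecord, ...] = ()
            ratings = None
            if cond != "baseline":
                agent_choices = _agent_choices(config, design, cond, agent, rng)
                hits = rng.random(len(agent_choices)) < config.prediction_accuracy
                preds = tuple(
                    PredictionRecord(a, c, bool(h))
                    for a, c, h in zip(design.manipulation_set.allocations,
                                       agent_choices, hits))
                ratings = tuple(int(r) for r in simulate_norm_ratings(
                    agent, design.norm_probes, config.norm_noise_sd, rng))
            participants.append(SyntheticParticipant(
                participant_id=f"{cond}_{i:03d}",
                condition=cond,
                prosocial=prosocial,
                compliant=compliant,
                true_params_before=before,
                true_params_after=after,
                agent_attitude=agent,
                before_records=before_recs,
                after_records=after_recs,
                prediction_records=preds,
                norm_ratings=ratings,
            ))
    return participants


# ---------------------------------------------------------------------------
# CSV dialect: participant_id,condition,phase,trial_index,pi_self,pi_other,choice

_CHOICE_CODE = {Choice.default: 0, Choice.alternative: 1}


def write_choices_csv(path, participants: Sequence[SyntheticParticipant]) -> None:
    rows = []
    for p in participants:
        for phase_recs in (p.before_records, p.after_records):
            for t, r in enumerate(phase_recs):
                rows.append({
                    "participant_id": p.participant_id,
                    "condition": p.condition,
                    "phase": r.phase.value,
                    "trial_index": t,
                    "pi_self": r.allocation.pi_self,
                    "pi_other": r.allocation.pi_other,
                    "choice": _CHOICE_CODE.get(r.choice, pd.NA),
                })
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def read_choices_csv(path) -> dict[str, list[ChoiceRecord]]:
    """Read the shared choice dialect into records keyed by participant."""
    df = pd.read_csv(path, na_values=["NA"])
    out: dict[str, list[ChoiceRecord]] = {}
    for row in df.itertuples():
        x, y = int(row.pi_self), int(row.pi_other)
        if y == 50 and x > 100:
            role = Role.selfish_alt
        elif y > 50:
            role = Role.prosocial_alt
        else:
            role = Role.antisocial_alt
        if pd.isna(row.choice):
            choice = Choice.missing
        else:
            choice = Choice.default if int(row.choice) == 0 else Choice.alternative
        out.setdefault(str(row.participant_id), []).append(
            ChoiceRecord(Allocation(x, y, role), Phase(row.phase), choice))
    return out


def write_truth_csv(path, participants: Sequence[SyntheticParticipant]) -> None:
    rows = []
    for p in participants:
        b, a = p.true_params_before, p.true_params_after
        rows.append({
            "participant_id": p.participant_id, "condition": p.condition,
            "prosocial": p.prosocial, "compliant": p.compliant,
            "agent_attitude": p.agent_attitude,
            "alpha_before": b.attitude, "alpha_after": a.attitude,
            "sigma_before": b.variability, "sigma_after": a.variability,
            "kappa_before": b.bias_kappa, "kappa_after": a.bias_kappa,
            "epsilon_before": b.lapse_epsilon, "epsilon_after": a.lapse_epsilon,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
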