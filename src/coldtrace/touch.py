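"""Gentle-touch behavioral scoring.

Each of three touch trials is scored 0-4: one point per behavior observed
(pause, head withdrawal, turn, reverse locomotion), 0 for no response.  The
three trial scores sum to a total of at most 12 per animal.  Cohorts are
summarized as per-trial score proportions (score 0 doubling as the
no-response category) and the mean total score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyCohortError, ParameterError
from .synthgen import TouchCohort

N_TRIALS = 3
MAX_TRIAL_SCORE = 4


@dataclass
class TouchScorecard:
    """Per-animal trial scores (0-4 each, 3 trials) and total (0-12)."""

    animal_id: str
    trial_scores: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.trial_scores) != N_TRIALS:
            raise ParameterError("exactly 3 trial scores required")
        if any(not (0 <= s <= MAX_TRIAL_SCORE) for s in self.trial_scores):
            raise ParameterError("trial scores must lie in [0, 4]")

    @property
    def total(self) -> int:
        return int(sum(self.trial_scores))


def score_trial(outcomes) -> int:
    """Score one trial: the number of the four behaviors observed (0-4)."""
    o = np.asarray(outcomes)
    if o.shape != (4,):
        raise ParameterError("exactly four binary outcomes required")
    if not np.isin(o, (0, 1)).all():
        raise ParameterError("outcomes must be 0 or 1")
    return int(o.sum())


def total_score(trial_scores) -> int:
    """Total over exactly three trials (0-12)."""
    s = list(trial_scores)
    if len(s) != N_TRIALS:
        raise ParameterError("exactly 3 trials required")
    if any(not (0 <= v <= MAX_TRIAL_SCORE) for v in s):
        raise ParameterError("trial scores must lie in [0, 4]")
    return int(sum(s))


def score_cohort(cohort: TouchCohort) -> list[TouchScorecard]:
    """Score every animal of a simulated or observed cohort."""
    cards = []
    for i in range(cohort.n_animals):
        trials = tuple(score_trial(cohort.outcomes[i, t]) for t in range(N_TRIALS))
        cards.append(TouchScorecard(animal_id=f"animal{i}", trial_scores=trials))
    return cards


def score_distribution(cards: list[TouchScorecard]) -> dict:
    """Cohort summary: per-trial score proportions and the mean total.

    Returns a dict with ``proportions`` — a (3 trials, 5 scores) array whose
    rows sum to 1, score 0 being the no-response category — plus
    ``mean_total``, ``mean_trial_score``, and ``n_animals``.
    """
    if not cards:
        raise EmptyCohortError("no scorecards to summarize")
    scores = np.array([c.trial_scores for c in cards])      # (n, 3)
    props = np.zeros((N_TRIALS, MAX_TRIAL_SCORE + 1))
    for t in range(N_TRIALS):
        for s in range(MAX_TRIAL_SCORE + 1):
            props[t, s] = np.mean(scores[:, t] == s)
    totals = scores.sum(axis=1)
    return dict(proportions=props,
                mean_total=float(totals.mean()),
                mean_trial_score=float(scores.mean()),
                totals=totals,
                n_animals=len(cards))
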