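"""Cohort-level behavioral scoring and learner-group contrasts.

Behavioral scoring follows the PST conventions: training accuracy is the
percentage of trials on which the optimal pair member was chosen (per
half); test-phase "approach" accuracy is choosing the most-rewarded
stimulus when paired against the intermediate stimuli, and "avoidance"
accuracy is not choosing the least-rewarded stimulus in such pairings.
Subjects are split into rapid and slow learners at the median of first-half
training accuracy (strictly above the median -> rapid; ties -> slow).

Contrast machinery: classical paired t tests with Cohen's d computed as
mean(diff)/sd(diff), and the 2x2 within-subject interaction computed via
the difference-of-differences identity, F = t² on
(a11 - a12) - (a21 - a22), which is algebraically identical to the
repeated-measures ANOVA interaction for this design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agents import BehavioralSession

__all__ = [
    "score_behavior",
    "median_split",
    "paired_contrast",
    "interaction_contrast",
    "summarize_cohort",
    "PairedContrast",
    "InteractionContrast",
]


def score_behavior(session: BehavioralSession) -> dict[str, float]:
    """Per-subject behavioral summary (accuracies in %, RTs in ms)."""
    trials = session.trials
    train = trials[trials["phase"] == "training"]
    test = trials[trials["phase"] == "test"]
    if len(train) == 0 or len(test) == 0:
        raise ValueError("session must contain both training and test phases")

    cfg = session.config
    optimal = train["pair"].map(
        lambda p: cfg.optimal_of((p[0], p[1]))
    )
    correct_choice = (train["choice"] == optimal).to_numpy()
    rt = session.rt_ms[session.training_mask()]
    h1 = (train["half"] == "H1").to_numpy()

    probs = cfg.reward_prob
    best = max(probs, key=probs.get)
    worst = min(probs, key=probs.get)
    pairs = test["pair"]
    approach = pairs.str.contains(best) & ~pairs.str.contains(worst)
    avoid = pairs.str.contains(worst) & ~pairs.str.contains(best)
    test_rt = session.rt_ms[~session.training_mask()]

    def pct(x):
        return 100.0 * float(np.mean(x)) if len(x) else np.nan

    return {
        "train_acc_h1": pct(correct_choice[h1]),
        "train_acc_h2": pct(correct_choice[~h1]),
        "train_rt_h1": float(rt[h1].mean()),
        "train_rt_h2": float(rt[~h1].mean()),
        "approach_acc": pct((test["choice"][approach] == best)),
        "avoidance_acc": pct((test["choice"][avoid] != worst)),
        "approach_rt": float(test_rt[approach.to_numpy()].mean()),
        "avoidance_rt": float(test_rt[avoid.to_numpy()].mean()),
    }


def median_split(half1_accuracies) -> np.ndarray:
    """Label subjects 'rapid' (strictly above the median) or 'slow'.

    Ties at the median go to the slow group, so every subject is labeled.
    """
    acc = np.asarray(half1_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("median split needs at least two subjects")
    med = np.median(acc)
    return np.where(acc > med, "rapid", "slow")


@dataclass(frozen=True)
class PairedContrast:
    """Paired t test result with Cohen's d = mean(diff)/sd(diff)."""

    t: float
    df: int
    p: float
    d: float
    mean_diff: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < 0.05


def paired_contrast(values_a, values_b) -> PairedContrast:
    """Classical paired t between two equal-length condition vectors.

    Zero-variance differences are flagged degenerate (t and p are not
    meaningful there; the sign of the mean difference is preserved).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return PairedContrast(
            t=0.0 if mean == 0.0 else float(np.sign(mean)) * np.inf,
            df=df, p=np.nan, d=np.nan, mean_diff=mean, degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedContrast(
        t=float(t), df=df, p=float(p), d=mean / sd, mean_diff=mean
    )


@dataclass(frozen=True)
class InteractionContrast:
    """2x2 within-subject interaction, F(1, n-1) = t² on the DoD."""

    F: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < 0.05


def interaction_contrast(cells) -> InteractionContrast:
    """Interaction from per-subject 2x2 cell values.

    ``cells`` is (n_subjects, 2, 2); the interaction is the paired t on
    the per-subject difference-of-differences against zero, squared.
    """
    c = np.asarray(cells, dtype=float)
    if c.ndim != 3 or c.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n_subjects, 2, 2)")
    if np.isnan(c).any():
        raise ValueError("missing cells")
    dod = (c[:, 0, 0] - c[:, 0, 1]) - (c[:, 1, 0] - c[:, 1, 1])
    res = paired_contrast(dod, np.zeros_like(dod))
    if res.degenerate:
        return InteractionContrast(
            F=np.nan if np.isinf(res.t) else 0.0,
            df=(1, res.df), p=np.nan, degenerate=True,
        )
    return InteractionContrast(F=res.t**2, df=(1, res.df), p=res.p)


def summarize_cohort(
    sessions: list[BehavioralSession],
    fits: list | None = None,
) -> pd.DataFrame:
    """Per-subject behavior (+ optional fitted parameters) with group labels."""
    rows = [score_behavior(s) for s in sessions]
    df = pd.DataFrame(rows)
    df.insert(0, "subject", np.arange(len(sessions)))
    if fits is not None:
        df["alpha_gain_hat"] = [f.params_hat.alpha_gain for f in fits]
        df["alpha_loss_hat"] = [f.params_hat.alpha_loss for f in fits]
        df["beta_hat"] = [f.params_hat.beta for f in fits]
        df["pseudo_r2"] = [f.pseudo_r2 for f in fits]
    df["learner_group"] = median_split(df["train_acc_h1"])
    return df
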