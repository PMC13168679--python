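"""Maximum-likelihood Q-learning model: Model/Results objects and recovery.

:class:`QLearningModel` replays the asymmetric-learning-rate Q-learning
recursion deterministically over an observed (choice, feedback) sequence and
scores the observed training-phase choices under the softmax rule.  Fitting
maximizes the log likelihood with multi-start Nelder-Mead (Simplex) over
(alpha_gain, alpha_loss, beta); bounds are enforced by a logistic parameter
transform so the simplex itself is unconstrained.  Goodness of fit is the
likelihood pseudo-R², oriented so that 0 is chance and 1 perfect prediction.

The likelihood replay is JIT-compiled with numba when available; a
pure-Python implementation of the same function is used otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .agents import AgentParams, BehavioralSession, simulate_session
from .task import CORRECT, TaskConfig

__all__ = [
    "QLearningModel",
    "QLearningResults",
    "FitResult",
    "RecoveryReport",
    "negative_log_likelihood",
    "fit_session",
    "pseudo_r2",
    "grid_min_nll",
    "run_recovery",
]

#: Probability floor inside the log, keeping the objective finite at
#: degenerate parameters (e.g. extreme beta).
PROB_FLOOR = 1e-12

#: Default fitting bounds: learning rates on the unit interval, beta on
#: [0.01, 20].
DEFAULT_BOUNDS = {
    "alpha_gain": (0.0, 1.0),
    "alpha_loss": (0.0, 1.0),
    "beta": (0.01, 20.0),
}


def _replay_nll_py(chosen, other, reward, n_stim, alpha_g, alpha_l, beta,
                   q_init, gain_convention):
    """Sequential likelihood replay (reference implementation)."""
    q = np.full(n_stim, q_init)
    nll = 0.0
    for t in range(chosen.shape[0]):
        qc = q[chosen[t]]
        qo = q[other[t]]
        x = beta * (qc - qo) if gain_convention else (qc - qo) / beta
        if x > 30.0:
            p = 1.0
        elif x < -30.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + math.exp(-x))
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        nll -= math.log(p)
        rpe = reward[t] - qc
        if rpe > 0.0:
            q[chosen[t]] = qc + alpha_g * rpe
        elif rpe < 0.0:
            q[chosen[t]] = qc + alpha_l * rpe
    return nll


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _replay_nll = njit(cache=False)(_replay_nll_py)
    # trigger compilation once at import with a trivial call
    _replay_nll(
        np.zeros(1, np.int64), np.ones(1, np.int64), np.ones(1, np.float64),
        2, 0.1, 0.1, 1.0, 0.5, True,
    )
except Exception:  # pragma: no cover
    _replay_nll = _replay_nll_py


class QLearningModel:
    """Q-learning choice model for one subject's training-phase data.

    Parameters
    ----------
    chosen, other
        Integer stimulus indices of the chosen and unchosen pair member on
        each training trial, in trial order.
    reward
        1.0 for "Correct", 0.0 for "Incorrect" feedback.
    stimuli
        Stimulus labels indexed by the integer codes above.
    q_init
        Common initial value for all stimuli (default 0.5).
    softmax_convention
        "gain" (exponent beta*Q) or "temperature" (exponent Q/beta).
    """

    def __init__(self, chosen, other, reward, stimuli, q_init=0.5,
                 softmax_convention="gain"):
        self.chosen = np.ascontiguousarray(chosen, dtype=np.int64)
        self.other = np.ascontiguousarray(other, dtype=np.int64)
        self.reward = np.ascontiguousarray(reward, dtype=np.float64)
        if not (len(self.chosen) == len(self.other) == len(self.reward)):
            raise ValueError("chosen, other and reward must be equal length")
        if len(self.chosen) == 0:
            raise ValueError("need at least one training trial")
        self.stimuli = tuple(stimuli)
        self.q_init = float(q_init)
        self.softmax_convention = softmax_convention
        self.nobs = len(self.chosen)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_session(cls, session: BehavioralSession,
                     q_init: float | None = None,
                     softmax_convention: str | None = None) -> "QLearningModel":
        if q_init is None:
            q_init = session.q_init
        if softmax_convention is None:
            softmax_convention = (
                session.params_true.softmax_convention
                if session.params_true is not None else "gain"
            )
        return cls.from_dataframe(
            session.training, stimuli=session.config.stimuli,
            q_init=q_init, softmax_convention=softmax_convention,
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, stimuli=None, q_init=0.5,
                       softmax_convention="gain") -> "QLearningModel":
        """Build from a trial table with ``pair``, ``choice``, ``feedback``.

        Only rows with actual feedback enter the likelihood; feedback-free
        (test) rows are dropped.
        """
        df = data[data["feedback"] != "none"]
        if len(df) == 0:
            raise ValueError("no feedback trials in data")
        if stimuli is None:
            stimuli = sorted({s for p in df["pair"] for s in p})
        index = {s: i for i, s in enumerate(stimuli)}
        chosen = np.array([index[c] for c in df["choice"]], dtype=np.int64)
        other = np.array(
            [index[p[0] if c == p[1] else p[1]]
             for p, c in zip(df["pair"], df["choice"])],
            dtype=np.int64,
        )
        reward = (df["feedback"] == CORRECT).to_numpy(np.float64)
        return cls(chosen, other, reward, stimuli, q_init, softmax_convention)

    # -- likelihood -------------------------------------------------------
    def nloglike(self, params: AgentParams | np.ndarray) -> float:
        """Negative log likelihood (nats) of the observed choices."""
        if isinstance(params, AgentParams):
            ag, al, b = params.alpha_gain, params.alpha_loss, params.beta
        else:
            ag, al, b = (float(v) for v in params)
        return float(
            _replay_nll(
                self.chosen, self.other, self.reward, len(self.stimuli),
                ag, al, b, self.q_init, self.softmax_convention == "gain",
            )
        )

    def loglike(self, params) -> float:
        return -self.nloglike(params)

    # -- fitting ----------------------------------------------------------
    @staticmethod
    def _to_unconstrained(theta: np.ndarray, bounds) -> np.ndarray:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        frac = np.clip((theta - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        return logit(frac)

    @staticmethod
    def _to_bounded(x: np.ndarray, bounds) -> np.ndarray:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        return lo + (hi - lo) * expit(x)

    def fit(self, n_starts: int = 10, seed: int = 0, bounds=None,
            maxiter: int = 2000) -> "QLearningResults":
        """Multi-start Nelder-Mead maximum-likelihood fit.

        Starting points are drawn uniformly within the bounds from a
        generator seeded by ``seed``; the best converged start wins.
        Deterministic given ``seed``.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if bounds is None:
            bounds = DEFAULT_BOUNDS
        blist = [bounds["alpha_gain"], bounds["alpha_loss"], bounds["beta"]]
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in blist])
        hi = np.array([b[1] for b in blist])

        best = None
        any_ok = False
        failures = []
        for _ in range(n_starts):
            theta0 = lo + (hi - lo) * rng.random(3)
            x0 = self._to_unconstrained(theta0, blist)
            try:
                res = optimize.minimize(
                    lambda x: self.nloglike(self._to_bounded(x, blist)),
                    x0, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": maxiter},
                )
            except Exception as exc:  # pragma: no cover
                failures.append(str(exc))
                continue
            any_ok = True
            if best is None or res.fun < best.fun:
                best = res
        if not any_ok or best is None:
            raise RuntimeError(
                f"all {n_starts} optimizer starts failed: {failures}"
            )
        theta = self._to_bounded(best.x, blist)
        params_hat = AgentParams(
            alpha_gain=float(np.clip(theta[0], 0.0, 1.0)),
            alpha_loss=float(np.clip(theta[1], 0.0, 1.0)),
            beta=float(theta[2]),
            q_init=self.q_init,
            softmax_convention=self.softmax_convention,
        )
        llf = -float(best.fun)
        return QLearningResults(
            model=self, params=params_hat, llf=llf,
            pseudo_r2=pseudo_r2(llf, self.nobs),
            n_starts=n_starts, converged=bool(best.success),
            optimizer_result=best,
        )

    def predict(self, params: AgentParams) -> np.ndarray:
        """Per-trial probability assigned to each observed choice."""
        probs = np.empty(self.nobs)
        q = np.full(len(self.stimuli), self.q_init)
        gain = self.softmax_convention == "gain"
        for t in range(self.nobs):
            qc, qo = q[self.chosen[t]], q[self.other[t]]
            x = params.beta * (qc - qo) if gain else (qc - qo) / params.beta
            probs[t] = expit(x)
            rpe = self.reward[t] - qc
            rate = params.alpha_gain if rpe > 0 else params.alpha_loss
            if rpe != 0:
                q[self.chosen[t]] = qc + rate * rpe
        return probs


@dataclass
class QLearningResults:
    """Fit results: estimates, likelihood, pseudo-R² and a summary table."""

    model: QLearningModel
    params: AgentParams
    llf: float
    pseudo_r2: float
    n_starts: int
    converged: bool
    optimizer_result: object = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def as_fit_result(self) -> "FitResult":
        return FitResult(
            params_hat=self.params, log_likelihood=self.llf,
            pseudo_r2=self.pseudo_r2, n_trials=self.nobs,
            n_starts=self.n_starts, converged=self.converged,
        )

    def summary(self) -> str:
        lines = [
            "Q-learning model (softmax convention: "
            f"{self.model.softmax_convention})",
            "=" * 56,
            f"{'alpha_gain':<14}{self.params.alpha_gain:>10.4f}",
            f"{'alpha_loss':<14}{self.params.alpha_loss:>10.4f}",
            f"{'beta':<14}{self.params.beta:>10.4f}",
            "-" * 56,
            f"{'n trials':<14}{self.nobs:>10d}",
            f"{'log-likelihood':<14}{self.llf:>10.3f}",
            f"{'pseudo R2':<14}{self.pseudo_r2:>10.4f}",
            f"{'starts':<14}{self.n_starts:>10d}",
            f"{'converged':<14}{str(self.converged):>10}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class FitResult:
    """Lightweight record of one maximum-likelihood fit."""

    params_hat: AgentParams
    log_likelihood: float
    pseudo_r2: float
    n_trials: int
    n_starts: int
    converged: bool

    def __post_init__(self) -> None:
        if self.log_likelihood > 1e-9:
            raise ValueError("log likelihood of discrete choices cannot exceed 0")

    def to_dict(self) -> dict:
        return {
            "alpha_gain": self.params_hat.alpha_gain,
            "alpha_loss": self.params_hat.alpha_loss,
            "beta": self.params_hat.beta,
            "log_likelihood": self.log_likelihood,
            "pseudo_r2": self.pseudo_r2,
            "n_trials": self.n_trials,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }


def negative_log_likelihood(params: AgentParams,
                            session: BehavioralSession) -> float:
    """NLL (nats) of the session's training choices under ``params``."""
    model = QLearningModel.from_session(
        session, q_init=params.q_init,
        softmax_convention=params.softmax_convention,
    )
    return model.nloglike(params)


def fit_session(session: BehavioralSession, bounds=None, n_starts: int = 10,
                seed: int = 0) -> FitResult:
    """Fit a session and return a :class:`FitResult` record."""
    model = QLearningModel.from_session(session)
    return model.fit(n_starts=n_starts, seed=seed, bounds=bounds).as_fit_result()


def pseudo_r2(log_likelihood: float, n_trials: int) -> float:
    """Likelihood pseudo-R² against a two-alternative chance model.

    With r = n*ln(0.5) the statistic is (LLE - r)/(-r): 0 when the model
    does no better than chance, 1 when it predicts every choice with
    certainty.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if log_likelihood > 1e-12:
        raise ValueError("log likelihood must be <= 0")
    r = n_trials * math.log(0.5)
    return (log_likelihood - r) / (-r)


def grid_min_nll(session: BehavioralSession, n_grid: int = 11,
                 bounds=None) -> tuple[float, AgentParams]:
    """Brute-force oracle: minimum NLL over an n³ bounded parameter grid."""
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    model = QLearningModel.from_session(session)
    ag_grid = np.linspace(*bounds["alpha_gain"], n_grid)
    al_grid = np.linspace(*bounds["alpha_loss"], n_grid)
    b_grid = np.linspace(*bounds["beta"], n_grid)
    best = np.inf
    best_theta = None
    for ag in ag_grid:
        for al in al_grid:
            for b in b_grid:
                nll = model.nloglike(np.array([ag, al, b]))
                if nll < best:
                    best = nll
                    best_theta = (ag, al, b)
    params = AgentParams(
        alpha_gain=best_theta[0], alpha_loss=best_theta[1],
        beta=best_theta[2], q_init=model.q_init,
        softmax_convention=model.softmax_convention,
    )
    return float(best), params


@dataclass
class RecoveryReport:
    """Parameter-recovery diagnostics over a grid of generating agents."""

    table: pd.DataFrame  # one row per simulated+fitted agent
    n_agents: int
    n_trials: int
    seed: int
    grid: list = field(default_factory=list)

    _PARAMS = ("alpha_gain", "alpha_loss", "beta")

    def summary(self) -> pd.DataFrame:
        """Per-parameter bias, RMSE and Spearman rank correlation."""
        rows = {}
        for p in self._PARAMS:
            err = self.table[f"{p}_hat"] - self.table[f"{p}_true"]
            if self.table[f"{p}_true"].nunique() > 1:
                rho = stats.spearmanr(
                    self.table[f"{p}_true"], self.table[f"{p}_hat"]
                ).statistic
            else:
                rho = np.nan
            rows[p] = {
                "bias": err.mean(),
                "rmse": np.sqrt((err**2).mean()),
                "rank_corr": rho,
            }
        return pd.DataFrame(rows).T

    def group_means(self, param: str = "alpha_gain") -> pd.Series:
        """Mean recovered value per generating value of ``param``."""
        return self.table.groupby(f"{param}_true")[f"{param}_hat"].mean()


def run_recovery(grid, config: TaskConfig | None = None, n_agents: int = 20,
                 seed: int = 0, n_starts: int = 10) -> RecoveryReport:
    """Simulate-and-refit recovery harness.

    For each generating :class:`AgentParams` in ``grid``, simulates
    ``n_agents`` sessions at the task's trial count and refits each one;
    the report aggregates bias, RMSE and rank correlation per parameter.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if config is None:
        config = TaskConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for gi, gen in enumerate(grid):
        for child in ss.spawn(n_agents):
            s = int(child.generate_state(1)[0] % (2**31))
            session = simulate_session(gen, config, seed=s)
            try:
                fit = fit_session(session, n_starts=n_starts, seed=s)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"fit failed for grid point {gi} (seed {s}): {exc}"
                ) from exc
            rows.append(
                {
                    "grid_index": gi,
                    "alpha_gain_true": gen.alpha_gain,
                    "alpha_loss_true": gen.alpha_loss,
                    "beta_true": gen.beta,
                    "alpha_gain_hat": fit.params_hat.alpha_gain,
                    "alpha_loss_hat": fit.params_hat.alpha_loss,
                    "beta_hat": fit.params_hat.beta,
                    "log_likelihood": fit.log_likelihood,
                    "pseudo_r2": fit.pseudo_r2,
                }
            )
    return RecoveryReport(
        table=pd.DataFrame(rows), n_agents=n_agents,
        n_trials=config.n_training_trials, seed=seed, grid=grid,
    )
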