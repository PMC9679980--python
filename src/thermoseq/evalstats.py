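"""Regression metrics, Welch's t comparison of repeated runs, and the
hyperparameter-search procedures (random sampling, greedy refinement),
plus a thin harness over scikit-learn's classical regressors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricReport",
    "SearchSpace",
    "WelchResult",
    "regression_metrics",
    "welch_t",
    "random_search",
    "greedy_search",
    "make_regressor",
    "CLASSICAL_REGRESSORS",
]


@dataclass
class MetricReport:
    r2: float
    rmse: float
    pearson: float
    spearman: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2, "rmse": self.rmse, "pearson": self.pearson,
            "spearman": self.spearman, "n": self.n,
        }


@dataclass
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    p_one_sided: float


@dataclass
class SearchSpace:
    """Per-parameter candidate lists with a draw budget."""

    candidates: dict[str, list]
    budget: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.candidates:
            raise ValueError("empty search space")
        for name, values in self.candidates.items():
            if not values:
                raise ValueError(f"parameter {name!r} has no candidates")

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.candidates.values()]))


def regression_metrics(y_true, y_pred) -> MetricReport:
    """R², RMSE (°C), Pearson and Spearman (average-rank ties) correlations.

    With a constant ``y_true`` the variance-normalized quantities are
    undefined and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least 2 samples")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return MetricReport(r2=math.nan, rmse=rmse, pearson=math.nan,
                            spearman=math.nan, n=n)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if np.std(y_pred) == 0:
        pearson = spearman = math.nan
    else:
        pearson = float(sps.pearsonr(y_true, y_pred).statistic)
        spearman = float(sps.spearmanr(y_true, y_pred).statistic)
    return MetricReport(r2=r2, rmse=rmse, pearson=pearson, spearman=spearman, n=n)


def welch_t(a, b) -> WelchResult:
    """Unequal-variance t test with Welch–Satterthwaite degrees of freedom.

    The one-sided p is for the alternative mean(a) > mean(b). When both
    samples are constant and equal the statistic is undefined; p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return WelchResult(t=0.0, df=float(na + nb - 2), p_two_sided=1.0,
                           p_one_sided=1.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_two = 2.0 * float(sps.t.sf(abs(t), df))
    p_one = float(sps.t.sf(t, df))
    return WelchResult(t=float(t), df=float(df), p_two_sided=p_two,
                       p_one_sided=p_one)


def random_search(space: SearchSpace, objective) -> list[tuple[dict, float]]:
    """Draw ``budget`` distinct configurations, score, rank ascending.

    Sampling is without replacement over the finite product space, so the
    budget must not exceed the number of distinct configurations. The
    objective is a validation loss: smaller is better.
    """
    space.validate()
    if space.budget > space.size:
        raise ValueError(
            f"budget {space.budget} exceeds space size {space.size}"
        )
    rng = np.random.default_rng(space.seed)
    names = list(space.candidates)
    sizes = [len(space.candidates[k]) for k in names]
    if space.size <= 10**6:
        flat = rng.choice(space.size, size=space.budget, replace=False)
    else:
        # avoid materializing an enormous index range
        seen: set[int] = set()
        while len(seen) < space.budget:
            seen.add(int(rng.integers(space.size)))
        flat = np.fromiter(seen, dtype=np.int64)
    scored = []
    for code in flat:
        cfg = {}
        rem = int(code)
        for name, sz in zip(reversed(names), reversed(sizes)):
            cfg[name] = space.candidates[name][rem % sz]
            rem //= sz
        cfg = {k: cfg[k] for k in names}
        scored.append((cfg, float(objective(cfg))))
    scored.sort(key=lambda cs: cs[1])
    return scored


def greedy_search(space: SearchSpace, start: dict, objective) -> dict:
    """Coordinate-wise greedy refinement.

    Sweeps the parameters in their declared order, accepting the best
    candidate per coordinate, and repeats until a full sweep yields no
    improvement. The result is never worse than the start.
    """
    space.validate()
    for name, value in start.items():
        if name not in space.candidates or value not in space.candidates[name]:
            raise ValueError(f"start value {name}={value!r} not in the space")
    current = dict(start)
    best = float(objective(current))
    improved = True
    while improved:
        improved = False
        for name in space.candidates:
            for value in space.candidates[name]:
                if value == current[name]:
                    continue
                trial = {**current, name: value}
                score = float(objective(trial))
                if score < best:
                    best, current = score, trial
                    improved = True
    return current


# ----------------------------------------------- classical regressor harness

def make_regressor(name: str, **params):
    """Instantiate one of the standard scikit-learn regressors by name."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import BayesianRidge, ElasticNet
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    registry = {
        "bayesian_ridge": BayesianRidge,
        "elastic_net": ElasticNet,
        "decision_tree": DecisionTreeRegressor,
        "random_forest": RandomForestRegressor,
        "svm": SVR,
    }
    if name not in registry:
        raise ValueError(f"unknown regressor {name!r}; choose from {sorted(registry)}")
    return registry[name](**params)


CLASSICAL_REGRESSORS = ("bayesian_ridge", "elastic_net", "decision_tree",
                        "random_forest", "svm")
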