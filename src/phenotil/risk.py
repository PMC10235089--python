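"""Elastic-net Cox survival risk scoring over niche counts.

A patient's overall-survival risk score is the linear combination

    OSRS_i = sum_j N_ij * beta_j

of their niche counts N_ij with coefficients beta_j from a Cox
proportional-hazards model fit under an elastic-net penalty.  Patients
are dichotomized at the training-set median OSRS ("high risk" strictly
above the median); each niche is labeled constructive (beta_j > 0),
obstructive (beta_j < 0) or neutral (beta_j = 0).  Evaluation reports
the two-sided Mantel-Haenszel log-rank p-value, the hazard ratio of
high vs low risk with 95% CI, Harrell's concordance index with a
Noether-type standard error, and Kaplan-Meier curves per group.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold


class NoEventsError(ValueError):
    """All records censored: the partial likelihood is undefined."""


class DegenerateStratificationError(ValueError):
    """A risk group has no members."""


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    sv = survival.copy()
    req = {"patient_id", "time", "event"}
    if not req.issubset(sv.columns):
        raise ValueError(f"survival table needs columns {sorted(req)}")
    if (sv["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not sv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return sv


@dataclasses.dataclass
class PenaltyConfig:
    """Elastic-net penalty search space."""

    l1_ratio: float = 0.5
    alphas: tuple[float, ...] = (0.01, 0.1, 1.0)
    cv_folds: int = 5


@dataclasses.dataclass
class RiskModel:
    beta: np.ndarray               # length-K coefficients on raw counts
    cluster_names: list[str]
    l1_ratio: float
    alpha: float                   # selected penalty strength
    alpha_scores: dict[float, float]  # out-of-fold mean log partial likelihood
    cutoff: float                  # training-median OSRS
    seed: int
    use_proportions: bool = False

    def scores(self, N: pd.DataFrame | np.ndarray) -> np.ndarray:
        N = _as_matrix(N, self.cluster_names)
        if self.use_proportions:
            N = _to_proportions(N)
        return compute_osrs(N, self.beta)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "beta": self.beta.tolist(), "cluster_names": self.cluster_names,
            "l1_ratio": self.l1_ratio, "alpha": self.alpha,
            "alpha_scores": {str(k): v for k, v in self.alpha_scores.items()},
            "cutoff": self.cutoff, "seed": self.seed,
            "use_proportions": self.use_proportions,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(beta=np.asarray(d["beta"]), cluster_names=d["cluster_names"],
                   l1_ratio=d["l1_ratio"], alpha=d["alpha"],
                   alpha_scores={float(k): v for k, v in d["alpha_scores"].items()},
                   cutoff=d["cutoff"], seed=d["seed"],
                   use_proportions=d["use_proportions"])


def _as_matrix(N, names=None) -> pd.DataFrame:
    if isinstance(N, pd.DataFrame):
        return N
    N = np.asarray(N, float)
    cols = names if names is not None else [f"C{j}" for j in range(1, N.shape[1] + 1)]
    return pd.DataFrame(N, columns=cols)


def _to_proportions(N: pd.DataFrame) -> pd.DataFrame:
    tot = N.sum(axis=1).replace(0, np.nan)
    return N.div(tot, axis=0).fillna(0.0)


def fit_risk_model(
    N: pd.DataFrame | np.ndarray,
    survival: pd.DataFrame,
    penalty: PenaltyConfig | None = None,
    seed: int = 0,
    use_proportions: bool = False,
) -> RiskModel:
    """Fit the elastic-net Cox model on niche counts.

    Coefficients come from the penalized partial likelihood (Efron tie
    handling); the penalty strength is chosen among
    ``penalty.alphas`` by mean out-of-fold log partial likelihood over
    seeded K-fold splits.  Counts are used raw by default
    (``use_proportions`` normalizes each row by the patient's total
    TIL count).  The dichotomization cutoff is the median training
    OSRS.

    Requires n >= 30 patients with >= 10 events; zero-variance count
    columns are retained with their coefficient forced to 0.
    """
    penalty = penalty or PenaltyConfig()
    Nm = _as_matrix(N)
    sv = _check_survival(survival)
    if len(Nm) != len(sv):
        raise ValueError("N and survival must have the same number of patients")
    n_events = int(sv["event"].sum())
    if n_events == 0:
        raise NoEventsError("all records are censored")
    if len(Nm) < 30 or n_events < 10:
        raise ValueError(f"need n >= 30 and >= 10 events; got n={len(Nm)}, events={n_events}")
    X = _to_proportions(Nm) if use_proportions else Nm.copy()
    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance columns {list(X.columns[zero_var])}: coefficients forced to 0"
        )
    active = list(X.columns[~zero_var])
    df = X[active].reset_index(drop=True)
    df["time"] = sv["time"].to_numpy()
    df["event"] = sv["event"].to_numpy()

    def _fit(frame: pd.DataFrame, alpha: float) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=alpha, l1_ratio=penalty.l1_ratio)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
        return cph

    scores: dict[float, float] = {}
    kf = KFold(n_splits=penalty.cv_folds, shuffle=True, random_state=seed)
    for alpha in penalty.alphas:
        fold_ll = []
        for tr, te in kf.split(df):
            train, test = df.iloc[tr], df.iloc[te]
            if train["event"].sum() == 0 or test["event"].sum() == 0:
                continue
            try:
                cph = _fit(train, alpha)
                fold_ll.append(cph.score(test, scoring_method="log_likelihood"))
            except Exception:
                fold_ll.append(-np.inf)
        scores[alpha] = float(np.mean(fold_ll)) if fold_ll else -np.inf
    best_alpha = max(scores, key=lambda a: (scores[a], -a))
    cph = _fit(df, best_alpha)
    beta = np.zeros(Nm.shape[1])
    for j, name in enumerate(Nm.columns):
        if name in active:
            beta[j] = float(cph.params_[name])
    osrs = compute_osrs(X, beta)
    return RiskModel(
        beta=beta, cluster_names=list(Nm.columns), l1_ratio=penalty.l1_ratio,
        alpha=best_alpha, alpha_scores=scores, cutoff=float(np.median(osrs)),
        seed=seed, use_proportions=use_proportions,
    )


def compute_osrs(N: pd.DataFrame | np.ndarray, beta: np.ndarray) -> np.ndarray:
    """OSRS_i = sum_j N_ij beta_j — exact linear combination, no intercept."""
    Nm = _as_matrix(N)
    beta = np.asarray(beta, float)
    if Nm.shape[1] != len(beta):
        raise ValueError("beta length must match number of clusters")
    return Nm.to_numpy(float) @ beta


def stratify(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """Dichotomize: strictly above the cutoff -> ``high``, else ``low``."""
    scores = np.asarray(scores, float)
    return np.where(scores > cutoff, "high", "low")


def cluster_roles(beta: np.ndarray) -> list[str]:
    """Sign rule: beta > 0 constructive, < 0 obstructive, = 0 neutral."""
    return [
        "constructive" if b > 0 else ("obstructive" if b < 0 else "neutral")
        for b in np.asarray(beta, float)
    ]


def concordance_with_se(time: np.ndarray, event: np.ndarray,
                        scores: np.ndarray) -> tuple[float, float]:
    """Harrell's C over continuous scores (higher score = higher risk).

    A pair is comparable when the earlier time is an event; concordant
    when the earlier-failing patient carries the higher score; ties in
    score count 1/2.  The standard error is the Noether-type estimator
    sqrt(C(1-C)/n_pairs).
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    s = np.asarray(scores, float)
    # comparable pairs: t_i < t_j with event_i, or t_i == t_j with exactly one event
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    si, sj = s[:, None], s[None, :]
    comp = (ti < tj) & (ei == 1)
    conc = (comp & (si > sj)).sum()
    tied = (comp & (si == sj)).sum()
    n_pairs = comp.sum()
    if n_pairs == 0:
        return 0.5, 0.0
    c = (conc + 0.5 * tied) / n_pairs
    se = float(np.sqrt(c * (1 - c) / n_pairs))
    return float(c), se


@dataclasses.dataclass
class EvalReport:
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    c_index: float
    c_se: float
    km: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    n_low: int
    n_high: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "logrank_p": self.logrank_p, "hr": self.hr, "hr_ci": list(self.hr_ci),
            "c_index": self.c_index, "c_se": self.c_se,
            "n_low": self.n_low, "n_high": self.n_high,
            "km": {g: df.to_dict(orient="list") for g, df in self.km.items()},
        }))


def evaluate_survival(
    survival: pd.DataFrame,
    scores: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    cutoff: float | None = None,
) -> EvalReport:
    """Survival separation of the high- vs low-risk groups.

    Provide continuous ``scores`` (dichotomized at ``cutoff``, default
    their median) and/or precomputed ``groups``.  The log-rank test is
    two-sided; the hazard ratio comes from a univariable Cox fit on the
    binary group indicator; the concordance index uses the continuous
    scores when available, else the group indicator.
    """
    sv = _check_survival(survival)
    if groups is None:
        if scores is None:
            raise ValueError("provide scores or groups")
        cut = float(np.median(scores)) if cutoff is None else cutoff
        groups = stratify(scores, cut)
    groups = np.asarray(groups)
    lo, hi = groups == "low", groups == "high"
    if lo.sum() == 0 or hi.sum() == 0:
        raise DegenerateStratificationError("both risk groups must be non-empty")
    t, e = sv["time"].to_numpy(float), sv["event"].to_numpy(int)

    lr = logrank_test(t[lo], t[hi], event_observed_A=e[lo], event_observed_B=e[hi])
    cox_df = pd.DataFrame({"high": hi.astype(int), "time": t, "event": e})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(cox_df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_.loc["high"].to_numpy()
    with np.errstate(over="ignore"):  # perfectly separated groups -> inf bound
        hr_ci = (float(np.exp(ci[0])), float(np.exp(ci[1])))

    c_scores = scores if scores is not None else hi.astype(float)
    c, c_se = concordance_with_se(t, e, np.asarray(c_scores, float))

    km = {}
    for name, m in (("low", lo), ("high", hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=name)
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        km[name] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf[name].to_numpy(float),
            "at_risk": at_risk.to_numpy(float),
        })
    return EvalReport(
        logrank_p=float(lr.p_value), hr=hr, hr_ci=hr_ci, c_index=c, c_se=c_se,
        km=km, n_low=int(lo.sum()), n_high=int(hi.sum()),
    )
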