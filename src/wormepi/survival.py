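"""Replicate-structured lifespan analysis.

Worm lifespan assays score cohorts of animals (typically ~90 per
replicate plate) for day of death, censoring escapers and bagged
animals. Each biological replicate pairs a treated and a control
cohort; the treated-vs-control comparison is made per replicate with
the log-rank test and the per-replicate p-values are combined across
replicates with Fisher's method. The headline summary is the percent
mean-lifespan extension, computed on observed-event lifespans.

Kaplan-Meier estimation and the log-rank test are implemented from
their definitions (product-limit estimator; observed-minus-expected
deaths with hypergeometric variance over distinct event days, same-day
events pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import FisherCombined, TestResult, fishers_method

__all__ = [
    "SurvivalCohort",
    "LifespanExperiment",
    "KmCurve",
    "LifespanSummary",
    "kaplan_meier",
    "logrank_test",
    "combined_lifespan_test",
    "lifespan_report",
    "read_lifespan_tsv",
    "write_lifespan_tsv",
]


@dataclass
class SurvivalCohort:
    """One cohort of individually scored animals.

    ``days`` is the day of death (event=True) or of censoring
    (event=False); all days must be positive.
    """

    days: np.ndarray
    events: np.ndarray
    condition: str
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.days.size == 0:
            raise ValueError("cohort is empty")
        if self.days.size != self.events.size:
            raise ValueError("days and events lengths differ")
        if np.any(self.days <= 0):
            raise ValueError("all lifespans must be positive")

    @property
    def n(self) -> int:
        return int(self.days.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def observed_lifespans(self) -> np.ndarray:
        """Lifespans of animals whose death was observed (censored excluded)."""
        return self.days[self.events]


@dataclass
class LifespanExperiment:
    """Paired treated/control cohorts, one pair per biological replicate."""

    replicates: list[tuple[SurvivalCohort, SurvivalCohort]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("experiment has no replicate pairs")
        for t, c in self.replicates:
            if t.condition == c.condition:
                raise ValueError("treated and control conditions must differ")


@dataclass
class KmCurve:
    """Right-continuous Kaplan-Meier step function."""

    times: np.ndarray  # distinct observed-event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def kaplan_meier(cohort: SurvivalCohort) -> KmCurve:
    """Product-limit survival estimate honouring right censoring.

    At each distinct observed-event time t: S -> S * (1 - d_t / n_t),
    with n_t the number still at risk just before t (animals censored
    at t count as at risk at t).
    """
    if cohort.n_events == 0:
        raise ValueError("cohort has no observed events")
    event_times = np.unique(cohort.days[cohort.events])
    surv = []
    risk = []
    s = 1.0
    for t in event_times:
        n_t = int(np.sum(cohort.days >= t))
        d_t = int(np.sum((cohort.days == t) & cohort.events))
        s *= 1.0 - d_t / n_t
        surv.append(s)
        risk.append(n_t)
    return KmCurve(event_times, np.asarray(surv), np.asarray(risk, dtype=int))


def logrank_test(a: SurvivalCohort, b: SurvivalCohort) -> TestResult:
    """Two-sample log-rank test, chi-square with 1 df.

    Events sharing a day are pooled into one risk-set update; at each
    distinct event day the expected deaths in cohort a and the
    hypergeometric variance are accumulated, and the statistic is
    (sum O - sum E)^2 / sum V.
    """
    if a.n_events == 0 or b.n_events == 0:
        raise ValueError("both cohorts need >= 1 observed event")
    days = np.concatenate([a.days, b.days])
    events = np.concatenate([a.events, b.events])
    in_a = np.concatenate([np.ones(a.n, bool), np.zeros(b.n, bool)])
    event_times = np.unique(days[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = days >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dead = (days == t) & events
        d = int(dead.sum())
        d1 = int((dead & in_a).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return TestResult(0.0, 1.0, 1.0, "logrank")
    chi2 = o_minus_e**2 / var
    return TestResult(float(chi2), 1.0, float(sps.chi2.sf(chi2, 1)), "logrank")


@dataclass
class LifespanSummary:
    """Combined result for one replicated lifespan experiment."""

    label: str
    replicate_ps: list[float]
    combined: FisherCombined
    mean_treated: float  # pooled mean over observed-event lifespans (days)
    mean_control: float
    mean_extension_pct: float  # 100 * (treated - control) / control, pooled
    per_replicate_extension_pct: list[float] = field(default_factory=list)
    n_per_replicate: list[int] = field(default_factory=list)


def combined_lifespan_test(
    exp: LifespanExperiment, p_floor: float | None = 1e-300
) -> LifespanSummary:
    """Per-replicate log-rank tests combined with Fisher's method.

    Mean lifespans use observed-event animals only (censored animals are
    excluded, the usual handling of escapers in worm assays). The
    pooled extension uses all replicates' observed lifespans together;
    a per-replicate extension list is also reported.
    """
    ps = []
    per_rep_ext = []
    n_per_rep = []
    treated_all, control_all = [], []
    for t_coh, c_coh in exp.replicates:
        ps.append(logrank_test(t_coh, c_coh).p)
        lt = t_coh.observed_lifespans()
        lc = c_coh.observed_lifespans()
        treated_all.append(lt)
        control_all.append(lc)
        per_rep_ext.append(100.0 * (lt.mean() - lc.mean()) / lc.mean())
        n_per_rep.append(t_coh.n + c_coh.n)
    combined = fishers_method(ps, floor=p_floor)
    mt = float(np.concatenate(treated_all).mean())
    mc = float(np.concatenate(control_all).mean())
    return LifespanSummary(
        label=exp.label,
        replicate_ps=[float(p) for p in ps],
        combined=combined,
        mean_treated=mt,
        mean_control=mc,
        mean_extension_pct=100.0 * (mt - mc) / mc,
        per_replicate_extension_pct=[float(e) for e in per_rep_ext],
        n_per_replicate=n_per_rep,
    )


def lifespan_report(summaries: list[LifespanSummary]) -> pd.DataFrame:
    """One row per experiment, mirroring a lifespan-replicate summary table."""
    if not summaries:
        raise ValueError("no summaries given")
    rows = []
    for s in summaries:
        rows.append(
            {
                "experiment": s.label,
                "n_replicates": len(s.replicate_ps),
                "n_total": int(sum(s.n_per_replicate)),
                "mean_treated_days": s.mean_treated,
                "mean_control_days": s.mean_control,
                "extension_pct": s.mean_extension_pct,
                "combined_chi2": s.combined.chi2,
                "combined_df": s.combined.df,
                "combined_p": s.combined.p,
            }
        )
    return pd.DataFrame(rows)


def read_lifespan_tsv(path) -> LifespanExperiment:
    """Read a lifespan table with columns (id, condition, replicate, day, event).

    The condition appearing first in the file is taken as treated unless
    exactly one condition is named 'control' or 'WT' (case-insensitive),
    which is then the control.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "day", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lifespan TSV missing columns: {sorted(missing)}")
    conds = list(dict.fromkeys(df["condition"]))
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {conds}")
    control = next(
        (c for c in conds if str(c).lower() in {"control", "wt"}), conds[1]
    )
    treated = conds[0] if conds[1] == control else conds[1]
    pairs = []
    for rep, sub in df.groupby("replicate", sort=True):
        cohorts = {}
        for cond, csub in sub.groupby("condition"):
            cohorts[cond] = SurvivalCohort(
                csub["day"].to_numpy(float),
                csub["event"].to_numpy(bool),
                condition=str(cond),
                replicate=str(rep),
            )
        if treated not in cohorts or control not in cohorts:
            raise ValueError(f"replicate {rep} lacks one condition")
        pairs.append((cohorts[treated], cohorts[control]))
    return LifespanExperiment(pairs)


def write_lifespan_tsv(exp: LifespanExperiment, path) -> None:
    rows = []
    i = 0
    for t_coh, c_coh in exp.replicates:
        for coh in (t_coh, c_coh):
            for day, ev in zip(coh.days, coh.events):
                rows.append(
                    {
                        "id": f"w{i:05d}",
                        "condition": coh.condition,
                        "replicate": coh.replicate,
                        "day": int(day) if float(day).is_integer() else day,
                        "event": int(ev),
                    }
                )
                i += 1
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
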