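"""Model-comparison statistics over a per-model detection metrics table.

Given one row per detector (precision, recall, mAP50, DSC on a common test
set), the module computes per-metric summaries (mean, n-1 standard
deviation, Student-t 95% confidence interval), one-sample t-tests against a
per-metric baseline, Cohen's d effect sizes (d = (mean - mu0)/sd, so
t = d * sqrt(n) identically), Shapiro-Wilk normality checks, and a top-3
model ranking per metric.

Note on the published analysis this reproduces: the source report's prose
swaps the "precision" and "recall" labels relative to its own results table.
This module keys every statistic by the column it was computed from, and the
default baselines (precision 0.80, recall 0.78, mAP50 0.82) are attached to
the columns that reproduce the printed t statistics and effect sizes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

METRICS = ("precision", "recall", "map50")

#: The seven-detector comparison table (input data, not a computed result).
MODEL_METRICS_CSV = """\
model,precision,recall,map50,dsc
YOLOv7,0.69,0.60,0.69,0.58
YOLOv8,0.65,0.66,0.74,0.74
YOLOv9,0.68,0.79,0.77,0.73
YOLOv10,0.82,0.63,0.79,0.71
YOLOv11,0.78,0.80,0.82,0.78
YOLOv12,0.56,0.69,0.61,0.62
Modified YOLOv8,0.75,0.83,0.85,0.77
"""

#: Baselines keyed by column identity (see module docstring).
DEFAULT_BASELINES = {"precision": 0.80, "recall": 0.78, "map50": 0.82}


class StatsError(ValueError):
    pass


@dataclass
class ModelMetricsTable:
    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("model",) + METRICS if c not in self.frame.columns]
        if missing:
            raise StatsError(f"metrics table missing columns {missing}")
        vals = self.frame[list(METRICS)]
        if vals.isna().any().any():
            raise StatsError("metrics table has missing cells")
        if ((vals < 0) | (vals > 1)).any().any():
            raise StatsError("metric values must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path_or_text) -> "ModelMetricsTable":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            return cls(pd.read_csv(io.StringIO(path_or_text)))
        return cls(pd.read_csv(path_or_text))

    @classmethod
    def reference(cls) -> "ModelMetricsTable":
        return cls.from_csv(MODEL_METRICS_CSV)

    def column(self, metric: str) -> np.ndarray:
        return self.frame[metric].to_numpy(float)


@dataclass
class StatsResult:
    metric: str
    n: int
    mean: float
    sd: float
    ci95: tuple
    t_stat: float
    df: int
    p_two_sided: float
    cohens_d: float
    shapiro_w: float
    shapiro_p: float
    baseline: float
    top3: list = field(default_factory=list)


def summarize(values, level: float = 0.95):
    """(mean, sd, (lo, hi)) with an n-1 sd and a Student-t interval."""
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise StatsError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    tcrit = float(sps.t.ppf((1 + level) / 2, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return mean, sd, (mean - half, mean + half)


def one_sample_t(values, mu0: float):
    """Two-sided one-sample t-test: t = (mean - mu0) * sqrt(n) / sd."""
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise StatsError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise StatsError("zero standard deviation: t undefined")
    t = float((v.mean() - mu0) * np.sqrt(n) / sd)
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return t, n - 1, p


def cohens_d(values, mu0: float) -> float:
    """Standardized mean difference against a fixed baseline."""
    v = np.asarray(values, float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise StatsError("zero standard deviation: d undefined")
    return float((v.mean() - mu0) / sd)


def shapiro_wilk(values):
    """Shapiro-Wilk W with Royston's p approximation (3 <= n <= 5000)."""
    v = np.asarray(values, float)
    if not 3 <= v.size <= 5000:
        raise StatsError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise StatsError("constant vector: Shapiro-Wilk undefined")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def compare_table(table: ModelMetricsTable,
                  baselines: dict | None = None) -> list[StatsResult]:
    """One StatsResult per metric column, with a top-3 model ranking."""
    baselines = dict(DEFAULT_BASELINES, **(baselines or {}))
    results = []
    for metric in METRICS:
        if metric not in baselines:
            raise StatsError(f"no baseline given for {metric}")
        v = table.column(metric)
        mu0 = float(baselines[metric])
        mean, sd, ci = summarize(v)
        if sd > 0:
            t, df, p = one_sample_t(v, mu0)
            d = cohens_d(v, mu0)
            w, sp = shapiro_wilk(v) if np.ptp(v) > 0 and len(v) >= 3 \
                else (float("nan"), float("nan"))
        else:
            # constant column: the test statistic is undefined, but the
            # summary and ranking remain meaningful
            t = p = d = w = sp = float("nan")
            df = v.size - 1
        order = np.argsort(-v, kind="stable")
        names = table.frame["model"].tolist()
        top3 = [names[i] for i in order[:3]]
        # flag rank ties among the leaders
        lead = v[order[0]]
        ties = [names[i] for i in order if v[i] == lead]
        if len(ties) > 1:
            top3 = ties[:3]
        results.append(StatsResult(metric=metric, n=v.size, mean=mean, sd=sd,
                                   ci95=ci, t_stat=t, df=df, p_two_sided=p,
                                   cohens_d=d, shapiro_w=w, shapiro_p=sp,
                                   baseline=mu0, top3=top3))
    return results


def round4(x: float) -> float:
    """Display rounding: 4 decimals, round-half-even."""
    return float(np.round(x, 4))


def results_to_frame(results: list[StatsResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"metric": r.metric, "n": r.n, "mean": round4(r.mean),
                     "sd": round4(r.sd), "ci_lo": round4(r.ci95[0]),
                     "ci_hi": round4(r.ci95[1]), "t": round4(r.t_stat),
                     "df": r.df, "p": round4(r.p_two_sided),
                     "cohens_d": round4(r.cohens_d),
                     "shapiro_w": round4(r.shapiro_w),
                     "shapiro_p": round4(r.shapiro_p),
                     "baseline": r.baseline, "top3": "; ".join(r.top3)})
    return pd.DataFrame(rows)
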