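"""Classifier metrics and the group-level statistical machinery.

Mind-wandering is the positive class: sensitivity is the fraction of
mind-wandering trials detected, specificity the fraction of on-task trials
detected. Group statistics cover the comparisons the analysis reports:
paired and one-sample t tests with Cohen's d, Spearman rank correlations
(classifier bias vs mind-wandering rate), TOST equivalence tests
(single-marker vs full model), and 2x2 within-subject ANOVA (state x period)
with generalized eta squared for the band power / ISPC markers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .synth import MIND_WANDERING, ON_TASK

__all__ = ["confusion_metrics", "TTestResult", "one_sample_t", "paired_t_d",
           "spearman", "TostResult", "tost_equivalence", "rm_anova_ges",
           "build_report"]


def confusion_metrics(y_true, y_pred) -> tuple[float, float | None, float | None]:
    """Accuracy, sensitivity and specificity with MW as the positive class.

    A metric whose reference class is absent from the true labels is returned
    as None (missing), never as 0, so group averages are not dragged down by
    undefined cells.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    bad = set(np.unique(y_true)) - {MIND_WANDERING, ON_TASK}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    accuracy = float(np.mean(y_true == y_pred))
    mw = y_true == MIND_WANDERING
    ot = y_true == ON_TASK
    sensitivity = float(np.mean(y_pred[mw] == MIND_WANDERING)) if mw.any() else None
    specificity = float(np.mean(y_pred[ot] == ON_TASK)) if ot.any() else None
    return accuracy, sensitivity, specificity


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float                    # Cohen's d


def one_sample_t(values, mu: float, two_sided: bool = True) -> TTestResult:
    """One-sample t test against ``mu``; d = (mean - mu) / sd.

    The degenerate all-equal-to-mu input (e.g. paired test of identical
    samples) returns t = 0, d = 0, p = 1; any other zero-variance input
    raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        if np.allclose(x, mu):
            return TTestResult(t=0.0, df=x.size - 1, p=1.0, d=0.0)
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu, alternative="two-sided" if two_sided else "greater")
    return TTestResult(t=float(res.statistic), df=x.size - 1,
                       p=float(res.pvalue), d=float((x.mean() - mu) / sd))


def paired_t_d(a, b, two_sided: bool = True) -> TTestResult:
    """Paired t test on a - b; d = mean(diff) / sd(diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return one_sample_t(a - b, 0.0, two_sided=two_sided)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class TostResult:
    mean_diff: float
    ci: tuple[float, float]     # (1 - 2*alpha) CI used for the TOST decision
    bounds: tuple[float, float]
    equivalent: bool
    p: float                    # larger of the two one-sided p values


def tost_equivalence(diffs, bounds, alpha: float = 0.05) -> TostResult:
    """Two one-sided tests for equivalence of paired differences.

    ``bounds`` is either a symmetric margin (scalar m -> (-m, m)) or an
    explicit (lo, hi). Equivalence is declared iff the (1 - 2*alpha)
    confidence interval of the mean difference lies inside the bounds, which
    is the standard CI formulation of TOST.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2")
    if np.isscalar(bounds):
        bounds = (-abs(bounds), abs(bounds))
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must be ordered")
    m = d.mean()
    se = d.std(ddof=1) / np.sqrt(d.size)
    if se == 0:
        # exactly constant differences: the CI degenerates to the point
        equivalent = bool(lo < m < hi)
        return TostResult(mean_diff=float(m), ci=(float(m), float(m)),
                          bounds=(float(lo), float(hi)), equivalent=equivalent,
                          p=0.0 if equivalent else 1.0)
    df = d.size - 1
    tcrit = stats.t.ppf(1 - alpha, df)
    ci = (m - tcrit * se, m + tcrit * se)
    p_lower = stats.t.sf((m - lo) / se, df)   # H0: diff <= lo
    p_upper = stats.t.cdf((m - hi) / se, df)  # H0: diff >= hi
    p = float(max(p_lower, p_upper))
    equivalent = bool(lo < ci[0] and ci[1] < hi)
    return TostResult(mean_diff=float(m), ci=(float(ci[0]), float(ci[1])),
                      bounds=(float(lo), float(hi)), equivalent=equivalent, p=p)


def rm_anova_ges(long: pd.DataFrame, dv: str = "value", subject: str = "subject",
                 within: tuple[str, str] = ("state", "time")) -> pd.DataFrame:
    """2x2 within-subject ANOVA with generalized eta squared.

    ``long`` must hold a complete balanced design: every subject contributes
    one value per (state x time) cell (cell replicates are averaged first).
    Returns a table with F, df, p and generalized eta squared for the two
    main effects and the interaction.
    """
    w1, w2 = within
    cells = long.groupby([subject, w1, w2], observed=True)[dv].mean().reset_index()
    counts = cells.groupby(subject, observed=True).size()
    n_l1 = cells[w1].nunique()
    n_l2 = cells[w2].nunique()
    if (counts != n_l1 * n_l2).any():
        raise ValueError("incomplete within-subject design (missing cells)")
    aov = pg.rm_anova(data=cells, dv=dv, within=[w1, w2], subject=subject,
                      detailed=True, effsize="ng2")
    out = aov.rename(columns={"Source": "effect", "p_unc": "p"})
    keep = [c for c in ("effect", "SS", "ddof1", "ddof2", "F", "p", "ng2")
            if c in out.columns]
    return out[keep]


def build_report(sections: dict, out_dir: str | Path | None = None,
                 required: tuple[str, ...] = ("classification",)) -> dict:
    """Consolidate stage outputs into one report (JSON + markdown summary).

    ``sections`` maps section name to JSON-serializable content (DataFrames
    are converted to records). Raises if a required section is missing or
    empty. With ``out_dir`` set, writes ``report.json`` and ``report.md`` and
    one CSV per tabular section.
    """
    for name in required:
        if name not in sections or sections[name] is None or (
                hasattr(sections[name], "__len__") and len(sections[name]) == 0):
            raise ValueError(f"required report section {name!r} missing or empty")

    def _clean(obj):
        if isinstance(obj, pd.DataFrame):
            return json.loads(obj.to_json(orient="records"))
        if isinstance(obj, (TTestResult, TostResult)):
            return asdict(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    report = {name: _clean(content) for name, content in sections.items()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        lines = ["# Run report", ""]
        for name, content in sections.items():
            lines.append(f"## {name}")
            if isinstance(content, pd.DataFrame):
                content.to_csv(out_dir / f"{name}.csv", index=False)
                lines.append(content.to_string(index=False))
            else:
                lines.append(json.dumps(report[name], indent=1, sort_keys=True))
            lines.append("")
        (out_dir / "report.md").write_text("\n".join(lines))
    return report
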