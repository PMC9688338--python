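"""Inferential protocol for comparing GSW and RS network metrics.

Per frequency: Shapiro–Wilk on the per-subject GSW−RS differences gates the
choice between a paired t-test (normal) and the Wilcoxon signed-rank test
(non-normal; normal approximation with continuity correction, zero
differences dropped), with Bonferroni adjustment over the 12 analysis
frequencies.  Across frequencies: a 2 (state) × 12 (frequency) repeated-
measures ANOVA with Mauchly's sphericity check and Greenhouse–Geisser
correction on the frequency-involving effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .connectivity import DEFAULT_FREQS

__all__ = [
    "StatReport",
    "metric_table",
    "paired_state_comparison",
    "rm_anova_state_frequency",
]

_COLUMNS = ("subject", "frequency", "state", "value")


@dataclass
class StatReport:
    test: str
    statistic: float
    df: float | None
    p: float
    adjusted_p: float
    direction: str
    normality_p: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p cannot be smaller than p")


def metric_table(
    values_gsw: np.ndarray,
    values_rs: np.ndarray,
    freqs: tuple[int, ...] = DEFAULT_FREQS,
) -> pd.DataFrame:
    """Long-format table from (subjects x freqs) metric arrays per state."""
    rows = []
    for state, vals in (("GSW", np.asarray(values_gsw)),
                        ("RS", np.asarray(values_rs))):
        for s in range(vals.shape[0]):
            for fi, f in enumerate(freqs):
                rows.append((s, f, state, float(vals[s, fi])))
    return pd.DataFrame(rows, columns=_COLUMNS)


def _paired_values(table: pd.DataFrame, frequency: float):
    sub = table[table["frequency"] == frequency]
    wide = sub.pivot(index="subject", columns="state", values="value")
    if wide.isna().any().any() or not {"GSW", "RS"} <= set(wide.columns):
        raise ValueError(f"incomplete pairing at frequency {frequency}")
    return wide["GSW"].to_numpy(), wide["RS"].to_numpy()


def paired_state_comparison(
    table: pd.DataFrame,
    frequency: float,
    n_comparisons: int = 12,
    normality_alpha: float = 0.05,
) -> StatReport:
    """Normality-gated paired comparison of GSW vs RS at one frequency.

    Returns a two-sided test with Bonferroni-adjusted p over
    ``n_comparisons`` frequencies.  All-zero differences degenerate to
    statistic 0, p = 1.
    """
    gsw, rs = _paired_values(table, frequency)
    if gsw.size < 3:
        raise ValueError("need >= 3 paired subjects")
    diffs = gsw - rs
    direction = ("GSW>RS" if np.mean(diffs) > 0
                 else "GSW<RS" if np.mean(diffs) < 0 else "none")
    if np.all(diffs == 0):
        return StatReport("degenerate", 0.0, None, 1.0, 1.0, "none")
    if np.std(diffs) == 0:
        # nonzero constant difference: normality test undefined, t blows up
        return StatReport("degenerate", 0.0, None, 1.0, 1.0, direction)

    sw_stat, sw_p = stats.shapiro(diffs)
    if sw_p >= normality_alpha:
        t, p = stats.ttest_rel(gsw, rs)
        report = StatReport("paired-t", float(t), float(gsw.size - 1),
                            float(p), min(1.0, n_comparisons * float(p)),
                            direction, normality_p=float(sw_p))
    else:
        res = stats.wilcoxon(gsw, rs, zero_method="wilcox",
                             correction=True, method="approx")
        report = StatReport("wilcoxon", float(res.statistic), None,
                            float(res.pvalue),
                            min(1.0, n_comparisons * float(res.pvalue)),
                            direction, normality_p=float(sw_p))
    return report


def rm_anova_state_frequency(table: pd.DataFrame) -> dict[str, StatReport]:
    """2 (state) × 12 (frequency) within-subject ANOVA.

    Requires a complete crossing.  Mauchly's test runs on the frequency
    factor (state-averaged values); when it rejects at 0.05 the
    Greenhouse–Geisser corrected p is reported for the frequency and
    interaction effects.  Partial eta-squared accompanies each effect.
    """
    df = table.copy()
    counts = df.groupby(["subject"]).size()
    n_freq = df["frequency"].nunique()
    expected = 2 * n_freq
    missing = counts[counts != expected]
    if len(missing) or df[list(_COLUMNS)].isna().any().any():
        raise ValueError(
            f"incomplete design: subjects with missing cells: "
            f"{missing.index.tolist()}")

    aov = pg.rm_anova(data=df, dv="value", within=["state", "frequency"],
                      subject="subject", detailed=True, effsize="np2")
    collapsed = (df.groupby(["subject", "frequency"], as_index=False)["value"]
                 .mean())
    spher = pg.sphericity(data=collapsed, dv="value", within="frequency",
                          subject="subject")
    mauchly_p = float(spher.pval)
    use_gg = mauchly_p < 0.05

    reports: dict[str, StatReport] = {}
    for _, row in aov.iterrows():
        source = row["Source"]
        name = {"state": "state", "frequency": "frequency",
                "state * frequency": "interaction"}.get(source, source)
        gg_applies = use_gg and name != "state"
        p_unc = float(row["p_unc"])
        p = float(row["p_GG_corr"]) if gg_applies else p_unc
        reports[name] = StatReport(
            "rm-anova" + ("-GG" if gg_applies else ""),
            float(row["F"]), float(row["ddof1"]), p, p, "",
            detail={"np2": float(row["np2"]),
                    "eps": float(row.get("eps", np.nan)),
                    "mauchly_p": mauchly_p,
                    "p_uncorrected": p_unc})
    return reports
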