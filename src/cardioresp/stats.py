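"""Nonparametric paired/group tests and unbalanced two-way ANOVA.

Matched-pairs comparisons use the Wilcoxon signed-rank test: exact
enumeration of the rank-sum distribution for n ≤ 20 non-zero pairs, the
continuity-corrected normal approximation above.  Between-group comparisons
use the Mann–Whitney rank-sum test (exact when sample sizes permit and no
ties, asymptotic with tie correction otherwise).

The two-way ANOVA uses *sequential* (Type I) sums of squares — factor A,
then B, then the A×B interaction — so the source components sum exactly to
the total sum of squares even for heavily unbalanced group sizes.  In the
maneuver design, factor A is the paced-breathing condition of the increment
(CR6 vs CR15, 2 levels), factor B the HRR type (4 levels), and the response
a per-subject δ; with 183 subjects × 2 conditions this yields the
(1, 3, 3, 358) degrees-of-freedom pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Largest n for which the signed-rank null distribution is enumerated exactly.
WILCOXON_EXACT_N = 20

ANOVA_SOURCES = ("A", "B", "AB", "error", "total")


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon matched-pairs result: |z| (as conventionally tabulated) and two-sided p."""

    z: float
    p: float
    n: int  # non-zero pairs


@dataclass(frozen=True)
class AnovaTable:
    """Source decomposition: sums of squares, degrees of freedom, mean squares,
    F statistics and p-values for sources A, B and AB."""

    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for src in ANOVA_SOURCES:
            rows.append(
                {
                    "source": src,
                    "df": self.df[src],
                    "ss": self.ss[src],
                    "ms": self.ms.get(src, np.nan),
                    "f": self.f.get(src, np.nan),
                    "p": self.p.get(src, np.nan),
                }
            )
        return pd.DataFrame(rows)


def wilcoxon_signed(x, y, exact_n: int = WILCOXON_EXACT_N) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; requires ≥ 5 informative pairs.  The
    reported z is the magnitude of the continuity-corrected normal
    standardization of the rank sum; p comes from exact enumeration for
    n ≤ ``exact_n`` and the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError(f"need at least 5 non-zero pairs, got {n}")
    ties = len(np.unique(np.abs(d))) < n
    approx = sps.wilcoxon(d, correction=True, method="approx")
    z = abs(float(approx.zstatistic))
    if n <= exact_n and not ties:
        p = float(sps.wilcoxon(d, method="exact").pvalue)
    else:
        p = float(approx.pvalue)
    return PairedTestResult(z=z, p=min(p, 1.0), n=n)


def mannwhitney(a, b) -> float:
    """Two-sided Mann–Whitney rank-sum p-value between independent groups.

    Exact when both groups are small with no ties, else the tie-corrected
    normal approximation (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def anova2(values, factor_a, factor_b) -> AnovaTable:
    """Sequential (Type I) two-way ANOVA with interaction.

    Sums of squares are the sequential decomposition A → B → A×B fitted by
    ordinary least squares; the source components and the residual add up to
    the total sum of squares exactly.  Every A×B cell must be non-empty and
    the residual must retain at least one degree of freedom.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    if df["y"].isna().any():
        raise ValueError("response contains NaN")
    cells = df.groupby(["a", "b"], observed=False).size()
    if (cells == 0).any():
        empty = cells[cells == 0].index.tolist()
        raise ValueError(f"empty design cell(s): {empty}")
    n = len(df)
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    df_err = n - n_a * n_b
    if df_err < 1:
        raise ValueError("no residual degrees of freedom for the interaction model")

    model = smf.ols("y ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=1)

    ss = {
        "A": float(tab.loc["C(a)", "sum_sq"]),
        "B": float(tab.loc["C(b)", "sum_sq"]),
        "AB": float(tab.loc["C(a):C(b)", "sum_sq"]),
        "error": float(tab.loc["Residual", "sum_sq"]),
    }
    dfs = {
        "A": int(tab.loc["C(a)", "df"]),
        "B": int(tab.loc["C(b)", "df"]),
        "AB": int(tab.loc["C(a):C(b)", "df"]),
        "error": int(tab.loc["Residual", "df"]),
    }
    return assemble_anova_table(ss, dfs)


def assemble_anova_table(ss: dict[str, float], dfs: dict[str, int]) -> AnovaTable:
    """Finish an ANOVA table from per-source sums of squares and degrees of freedom.

    MS = SS/df per source; F = MS_source / MS_error for A, B and AB; p from
    the F distribution; the total row is the sum of all components.
    """
    if "error" not in ss or "error" not in dfs:
        raise ValueError("missing error source")
    sources = [s for s in ("A", "B", "AB") if s in ss]
    for s in sources + ["error"]:
        if dfs[s] <= 0:
            raise ValueError(f"source {s}: df must be positive")
    ss = {s: float(ss[s]) for s in sources + ["error"]}
    dfs = {s: int(dfs[s]) for s in sources + ["error"]}
    ss["total"] = sum(ss.values())
    dfs["total"] = sum(dfs.values())
    ms = {s: ss[s] / dfs[s] for s in sources + ["error", "total"]}
    f = {s: ms[s] / ms["error"] for s in sources}
    p = {s: float(sps.f.sf(f[s], dfs[s], dfs["error"])) for s in sources}
    return AnovaTable(ss=ss, df=dfs, ms=ms, f=f, p=p)
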