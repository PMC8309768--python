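"""Statistical comparison layer for the two-site study design.

Behavioral endpoints are compared between sites with Welch two-sample
t-tests on tank means (the tank is the independent unit; 12 per site in
the reference design).  Morphometric endpoints use individual fish:
MANOVA (Pillai's trace, two-factor crossed Population x Sex model with
Type II scatter matrices) on shape PC scores, a two-way ANOVA with
Tukey HSD on the posterior/anterior area ratio, a paired Wilcoxon
signed-rank test of posterior versus anterior region areas, and a
Kruskal-Wallis test on standard length.

Welch, Kruskal-Wallis, ANOVA, and Tukey delegate to scipy/statsmodels.
The two hand-rolled pieces are (a) the per-term Type II Pillai MANOVA,
built directly from between/within scatter matrices, and (b) the exact
Wilcoxon signed-rank distribution, computed by dynamic programming over
the (tie-averaged) ranks so exact p-values remain available when ties
are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.linalg import eigh as scipy_eigh
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import ConfigError, DataError

__all__ = [
    "TestResult",
    "SummaryStats",
    "summarize",
    "welch_t",
    "welch_t_from_summary",
    "shape_manova",
    "ratio_anova_tukey",
    "paired_wilcoxon",
    "kruskal_wallis",
]


class DegenerateDataError(DataError):
    """Data carry no information for the requested test."""


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p, direction."""

    name: str
    statistic: float
    df: float | tuple[float, ...]
    p_value: float
    effect_direction: str = ""
    n_per_group: tuple[int, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        df = self.df if not isinstance(self.df, tuple) else list(self.df)
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": df,
            "p_value": float(self.p_value),
            "effect_direction": self.effect_direction,
            "n_per_group": list(self.n_per_group),
            **{k: v for k, v in self.extras.items()},
        }


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- SEM with sample size, the reporting convention of the
    source tables."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ConfigError("SEM must be strictly positive")
        if self.n < 2:
            raise ConfigError("n must be at least 2")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


def summarize(x: np.ndarray | list[float]) -> SummaryStats:
    x = np.asarray(x, dtype=float)
    return SummaryStats(mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(len(x))), n=len(x))


# ---------------------------------------------------------------------------
# Welch t


def _direction(mean_a: float, mean_b: float, labels: tuple[str, str]) -> str:
    if mean_a == mean_b:
        return "none"
    return f"{labels[0]} > {labels[1]}" if mean_a > mean_b else f"{labels[1]} > {labels[0]}"


def welch_t(
    sample_a: np.ndarray | list[float],
    sample_b: np.ndarray | list[float],
    labels: tuple[str, str] = ("a", "b"),
    name: str = "welch_t",
) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance in both samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        effect_direction=_direction(a.mean(), b.mean(), labels),
        n_per_group=(len(a), len(b)),
    )


def welch_t_from_summary(
    a: SummaryStats, b: SummaryStats, labels: tuple[str, str] = ("a", "b"), name: str = "welch_t"
) -> TestResult:
    """Welch t recomputed from printed means +/- SEMs.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2).  The pooled df
    n_a + n_b - 2 (the convention of the source tables) is reported as
    ``df``; the Welch-Satterthwaite df and two-sided p computed from it
    are in ``extras``.
    """
    se = np.sqrt(a.sem**2 + b.sem**2)
    t = (a.mean - b.mean) / se
    df_pooled = a.n + b.n - 2
    v_a, v_b = a.sem**2, b.sem**2
    df_welch = (v_a + v_b) ** 2 / (v_a**2 / (a.n - 1) + v_b**2 / (b.n - 1))
    p = float(2 * sps.t.sf(abs(t), df_welch))
    return TestResult(
        name=name,
        statistic=float(t),
        df=float(df_pooled),
        p_value=p,
        effect_direction=_direction(a.mean, b.mean, labels),
        n_per_group=(a.n, b.n),
        extras={"df_welch": float(df_welch)},
    )


# ---------------------------------------------------------------------------
# two-factor MANOVA, Pillai's trace, Type II scatter matrices


def _design_matrices(population: np.ndarray, sex: np.ndarray) -> dict[str, np.ndarray]:
    """Treatment-coded design blocks for intercept, the two main
    effects, and their interaction."""
    pop_levels = sorted(set(population))
    sex_levels = sorted(set(sex))
    if len(pop_levels) < 2 or len(sex_levels) < 2:
        raise DataError("each factor needs at least 2 levels")
    n = len(population)
    A = np.column_stack([(population == l).astype(float) for l in pop_levels[1:]])
    B = np.column_stack([(sex == l).astype(float) for l in sex_levels[1:]])
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])
    return {"1": np.ones((n, 1)), "Population": A, "Sex": B, "Population:Sex": AB}


def _residual_sscp(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def _pillai_f(V: float, p: int, q: int, df_error: int) -> tuple[float, float, float, float]:
    """F approximation for Pillai's trace V with p responses, hypothesis
    df q, and error df df_error."""
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_error - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * (V / (s - V))
    pval = float(sps.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), pval


def shape_manova(
    pc_scores: np.ndarray,
    population: list[str] | np.ndarray,
    sex: list[str] | np.ndarray,
) -> dict[str, TestResult]:
    """Two-factor crossed MANOVA (Population, Sex, Population:Sex) on
    multivariate responses, Pillai's trace per term.

    Type II: each main effect is tested against the model containing
    the other main effect; the interaction is tested against the
    additive model.  The error scatter matrix comes from the full model.
    """
    Y = np.asarray(pc_scores, dtype=float)
    if Y.ndim != 2:
        raise DataError("pc_scores must be a 2-D array (specimens x responses)")
    population = np.asarray(population)
    sex = np.asarray(sex)
    n, p = Y.shape
    blocks = _design_matrices(population, sex)
    X_full = np.hstack([blocks["1"], blocks["Population"], blocks["Sex"], blocks["Population:Sex"]])
    rank_full = np.linalg.matrix_rank(X_full)
    df_error = n - rank_full
    if df_error <= p:
        raise DataError(
            f"within-group scatter is singular or near-singular "
            f"({n} specimens, {p} responses, error df {df_error}); reduce the "
            "response dimension (fewer PC axes) before testing"
        )
    E = _residual_sscp(X_full, Y)

    comparisons = {
        "Population": (["1", "Sex"], ["1", "Population", "Sex"]),
        "Sex": (["1", "Population"], ["1", "Population", "Sex"]),
        "Population:Sex": (
            ["1", "Population", "Sex"],
            ["1", "Population", "Sex", "Population:Sex"],
        ),
    }
    out: dict[str, TestResult] = {}
    counts = tuple(int(np.sum(population == l)) for l in sorted(set(population)))
    for term, (reduced, full) in comparisons.items():
        Xr = np.hstack([blocks[b] for b in reduced])
        Xf = np.hstack([blocks[b] for b in full])
        H = _residual_sscp(Xr, Y) - _residual_sscp(Xf, Y)
        H = 0.5 * (H + H.T)
        q = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr)
        # eigenvalues of (H+E)^-1 H via the generalized symmetric problem
        eigvals = scipy_eigh(H, 0.5 * ((H + E) + (H + E).T), eigvals_only=True)
        V = float(np.sum(np.clip(eigvals, 0.0, 1.0)))
        F, df1, df2, pval = _pillai_f(V, p, q, df_error)
        out[term] = TestResult(
            name=f"manova_{term}",
            statistic=V,
            df=(df1, df2),
            p_value=pval,
            n_per_group=counts,
            extras={"F": F, "term": term, "df_error": float(df_error), "n_responses": p},
        )
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey on the area ratio


def ratio_anova_tukey(
    ratio: np.ndarray | list[float],
    population: list[str] | np.ndarray,
    sex: list[str] | np.ndarray,
) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """Two-way ANOVA with interaction (Type II sums of squares, the
    appropriate choice for the unbalanced sex ratios of a field sample)
    on the posterior/anterior area ratio, plus Tukey HSD over the four
    Population x Sex cells (Tukey-Kramer for unequal cell sizes)."""
    df = pd.DataFrame(
        {"ratio": np.asarray(ratio, dtype=float), "population": population, "sex": sex}
    )
    cells = df.groupby(["population", "sex"], observed=True).size()
    all_cells = [(p, s) for p in sorted(df.population.unique()) for s in sorted(df.sex.unique())]
    for cell in all_cells:
        if cell not in cells.index:
            raise DataError(f"empty Population x Sex cell {cell}")
    model = smf.ols("ratio ~ C(population) * C(sex)", data=df).fit()
    table = anova_lm(model, typ=2)
    name_map = {
        "C(population)": "Population",
        "C(sex)": "Sex",
        "C(population):C(sex)": "Population:Sex",
    }
    df_resid = float(table.loc["Residual", "df"])
    results: dict[str, TestResult] = {}
    for raw, term in name_map.items():
        results[term] = TestResult(
            name=f"anova_{term}",
            statistic=float(table.loc[raw, "F"]),
            df=(float(table.loc[raw, "df"]), df_resid),
            p_value=float(table.loc[raw, "PR(>F)"]),
            n_per_group=tuple(int(c) for c in cells),
            extras={"sum_sq": float(table.loc[raw, "sum_sq"]), "ss_type": "II"},
        )
    cell_label = df.population.astype(str) + ":" + df.sex.astype(str)
    tukey = pairwise_tukeyhsd(df.ratio.values, cell_label.values, alpha=0.05)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return results, tukey_df


# ---------------------------------------------------------------------------
# Wilcoxon signed rank (exact by DP, ties allowed)


def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of twice the positive-rank sum over all 2^n equally
    likely sign assignments, by polynomial DP.  ``ranks2`` are the
    tie-averaged ranks doubled so they are integers."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def paired_wilcoxon(
    posterior: np.ndarray | list[float],
    anterior: np.ndarray | list[float],
    alternative: str = "two-sided",
    exact_n_max: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences
    (posterior - anterior).

    Zero differences are dropped; ties get average ranks.  The p-value
    is exact (full sign-assignment distribution via DP) for n <=
    ``exact_n_max`` non-zero pairs, otherwise a normal approximation
    with continuity and tie correction is used.  The statistic is W+,
    the positive-rank sum.
    """
    post = np.asarray(posterior, dtype=float)
    ant = np.asarray(anterior, dtype=float)
    if post.shape != ant.shape:
        raise DataError("paired samples must have equal length")
    if len(post) < 5:
        raise DataError("need at least 5 pairs")
    d = post - ant
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # == n(n+1)/2

    if n <= exact_n_max:
        ranks2 = np.rint(ranks * 2).astype(int)
        pmf = _signed_rank_pmf(ranks2)
        w2 = int(round(w_plus * 2))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[w2])
        p_ge = float(pmf[w2:].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = total / 2.0
        # tie correction for the variance of W+
        _, tie_sizes = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            z = (w_plus - mu - 0.5) / sd
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mu + 0.5) / sd
            p = float(sps.norm.cdf(z))
        else:
            z = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / sd
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal-approx"
    direction = "posterior > anterior" if w_plus > total / 2 else (
        "anterior > posterior" if w_plus < total / 2 else "none"
    )
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=w_plus,
        df=float(n),
        p_value=p,
        effect_direction=direction,
        n_per_group=(n,),
        extras={"method": method, "alternative": alternative},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(
    values: np.ndarray | list[float], groups: list[str] | np.ndarray, name: str = "kruskal_wallis"
) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-squared p on
    k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise DataError("need at least 2 groups")
    samples = [values[groups == l] for l in levels]
    if np.ptp(values) == 0:
        raise DegenerateDataError("all values identical")
    H, p = sps.kruskal(*samples)
    medians = {l: float(np.median(s)) for l, s in zip(levels, samples)}
    top = max(medians, key=medians.get)
    return TestResult(
        name=name,
        statistic=float(H),
        df=float(len(levels) - 1),
        p_value=float(p),
        effect_direction=f"largest median: {top}",
        n_per_group=tuple(len(s) for s in samples),
        extras={"medians": medians},
    )
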