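"""Statistics on mouth-morph count data.

Phenotypes are proportions of eurystomatous (Eu) versus stenostomatous (St)
animals; rare intermediates are tallied but excluded from every analysis
denominator.  Available tools: exact (Clopper–Pearson) confidence intervals,
pairwise Pearson chi-square and pooled two-proportion Z tests with
Benjamini–Hochberg adjustment, and a binomial GLM with logit link (fitted by
iteratively reweighted least squares) for genotype/dosage effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

#: fitted probabilities are clamped into this range when a group is entirely
#: one morph (complete separation, which all-Eu / all-St genotypes force)
PROB_CLAMP = 1e-8


@dataclass(frozen=True, slots=True)
class MorphCount:
    """Eu/St/intermediate tallies for one line (or one replicate of a line)."""

    line: str
    replicate: str = ""
    n_eu: int = 0
    n_st: int = 0
    n_intermediate: int = 0

    def __post_init__(self) -> None:
        if min(self.n_eu, self.n_st, self.n_intermediate) < 0:
            raise ValueError("morph counts must be non-negative")

    @property
    def n(self) -> int:
        """Analysis denominator: Eu + St, intermediates excluded."""
        return self.n_eu + self.n_st


def pool_counts(counts: Iterable[MorphCount]) -> MorphCount:
    """Pool replicates within a line (for display/CI, not for the GLM)."""
    counts = list(counts)
    lines = {c.line for c in counts}
    line = counts[0].line if len(lines) == 1 else "+".join(sorted(lines))
    return MorphCount(
        line=line,
        replicate="pooled",
        n_eu=sum(c.n_eu for c in counts),
        n_st=sum(c.n_st for c in counts),
        n_intermediate=sum(c.n_intermediate for c in counts),
    )


class ProportionCI(NamedTuple):
    proportion: float
    low: float
    high: float


def eu_fraction(count: MorphCount, confidence: float = 0.95) -> ProportionCI:
    """Eu proportion with an exact binomial (Clopper–Pearson) CI."""
    n = count.n
    if n < 1:
        raise ValueError("need at least one non-intermediate individual")
    ci = stats.binomtest(count.n_eu, n).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return ProportionCI(count.n_eu / n, ci.low, ci.high)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


def chisq_2x2(counts_a: MorphCount, counts_b: MorphCount) -> TestResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    table = np.array([[counts_a.n_eu, counts_a.n_st], [counts_b.n_eu, counts_b.n_st]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # a zero margin means the proportions are trivially indistinguishable
        return TestResult(0.0, 1.0)
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(float(res.statistic), float(res.pvalue))


def z_two_proportions(counts_a: MorphCount, counts_b: MorphCount) -> TestResult:
    """Two-sided pooled-variance Z test for two proportions (z**2 = Pearson X2)."""
    n1, n2 = counts_a.n, counts_b.n
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one non-intermediate individual")
    p1, p2 = counts_a.n_eu / n1, counts_b.n_eu / n2
    pooled = (counts_a.n_eu + counts_b.n_eu) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return TestResult(0.0, 1.0)
    z = (p1 - p2) / np.sqrt(var)
    return TestResult(float(z), float(2.0 * stats.norm.sf(abs(z))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass(frozen=True)
class GlmFit:
    """A fitted binomial/logit GLM on (n_eu, n_st) responses."""

    coefficients: pd.Series  # log-odds scale
    fitted: np.ndarray  # fitted Eu proportions, clamped away from 0/1
    deviance: float
    null_deviance: float
    n_iter: int
    converged: bool
    separation: bool
    n_params: int

    def predict_proportion(self, row: pd.Series) -> float:
        eta = float(np.dot(row.values, self.coefficients.values))
        return float(1.0 / (1.0 + np.exp(-eta)))


def _design_matrix(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals (first level as reference) + numerics."""
    pieces = [pd.Series(1.0, index=data.index, name="Intercept")]
    for col in covariates:
        series = data[col]
        if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            pieces.append(dummies.astype(float))
        else:
            pieces.append(series.astype(float))
    return pd.concat(pieces, axis=1)


def fit_binomial_glm(
    data: pd.DataFrame | Iterable[MorphCount],
    covariates: Sequence[str] = ("line",),
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GlmFit:
    """Fit Eu/(Eu+St) ~ covariates with binomial errors and a logit link.

    ``data`` is a DataFrame with ``n_eu``/``n_st`` columns plus the covariate
    columns (categoricals are dummy-coded against their first level), or an
    iterable of :class:`MorphCount` (then covariates default to the line
    factor).  Fitting is by IRLS to a relative deviance change below ``tol``.
    Groups that are entirely one morph separate the likelihood; the fit is
    then reported on a clamped scale with ``separation=True``.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(
            [
                {"line": c.line, "replicate": c.replicate, "n_eu": c.n_eu, "n_st": c.n_st}
                for c in data
            ]
        )
    if data.empty:
        raise ValueError("no observations")
    if (data["n_eu"] + data["n_st"]).min() < 1:
        raise ValueError("every observation needs denominator n_eu + n_st >= 1")
    endog = data[["n_eu", "n_st"]].to_numpy(dtype=float)
    exog = _design_matrix(data, covariates)

    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.GLM(endog, exog.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
        null_model = sm.GLM(endog, np.ones((len(data), 1)), family=sm.families.Binomial())
        null_dev = float(null_model.fit(maxiter=max_iter, tol=tol, scale=1.0).deviance)
    separated_warn = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)

    fitted = np.asarray(res.mu, dtype=float)
    separation = separated_warn or bool(
        (fitted < PROB_CLAMP).any() or (fitted > 1.0 - PROB_CLAMP).any()
    )
    fitted = np.clip(fitted, PROB_CLAMP, 1.0 - PROB_CLAMP)
    n_iter = len(res.fit_history.get("deviance", [])) if hasattr(res, "fit_history") else 0
    return GlmFit(
        coefficients=pd.Series(res.params, index=list(exog.columns)),
        fitted=fitted,
        deviance=float(res.deviance),
        null_deviance=null_dev,
        n_iter=n_iter,
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
        n_params=exog.shape[1],
    )


def likelihood_ratio(null_fit: GlmFit, alt_fit: GlmFit) -> TestResult:
    """LR test between nested GLM fits: deviance difference ~ chi-square."""
    stat = null_fit.deviance - alt_fit.deviance
    df = alt_fit.n_params - null_fit.n_params
    if df < 1:
        raise ValueError("alternative model must have more parameters than the null")
    return TestResult(float(stat), float(stats.chi2.sf(stat, df)))


def pairwise_tests(
    counts: Sequence[MorphCount],
    method: str = "chisq",
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise line comparisons (replicates pooled), BH-adjusted."""
    pooled: dict[str, MorphCount] = {}
    for c in counts:
        pooled[c.line] = pool_counts([pooled[c.line], c]) if c.line in pooled else c
    lines = sorted(pooled)
    rows = []
    test = chisq_2x2 if method == "chisq" else z_two_proportions
    for i, a in enumerate(lines):
        for b in lines[i + 1 :]:
            stat, p = test(pooled[a], pooled[b])
            rows.append({"line_a": a, "line_b": b, "statistic": stat, "pvalue": p})
    df = pd.DataFrame(rows, columns=["line_a", "line_b", "statistic", "pvalue"])
    if adjust and not df.empty:
        df["pvalue_bh"] = bh_adjust(df["pvalue"].to_numpy())
    return df


def read_morph_counts(path) -> list[MorphCount]:
    """Read a tab-separated morph-count table (line, replicate, n_eu, n_st[, n_intermediate])."""
    df = pd.read_csv(path, sep="\t")
    return [
        MorphCount(
            line=str(r.line),
            replicate=str(getattr(r, "replicate", "")),
            n_eu=int(r.n_eu),
            n_st=int(r.n_st),
            n_intermediate=int(getattr(r, "n_intermediate", 0)),
        )
        for r in df.itertuples(index=False)
    ]


def write_morph_counts(counts: Iterable[MorphCount], path) -> None:
    pd.DataFrame(
        [
            {
                "line": c.line,
                "replicate": c.replicate,
                "n_eu": c.n_eu,
                "n_st": c.n_st,
                "n_intermediate": c.n_intermediate,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)
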