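"""Group-comparison decision tree with Holm-Bonferroni correction.

The comparison procedure mirrors the study's rules: normality of every group
(Shapiro-Wilk, α = 0.05) routes the family to the parametric branch — Welch
one-way ANOVA for the omnibus and unpaired t tests whose variance assumption
is picked by an F test — or to the nonparametric branch — Kruskal-Wallis plus
Mann-Whitney U (with Levene's test recorded for the variance question).
Paired designs use repeated-measures ANOVA / paired t when normal, otherwise
Friedman / Wilcoxon signed-rank. Pairwise p values are Holm-Bonferroni
corrected within each explicitly declared family; adjusted p < 0.05 is
significant. One-tailed contrasts test the alternative "first group greater
than second".

The step-down Holm correction is implemented here; the individual tests
delegate to scipy and pingouin.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ComparisonResult, validate_cohort

logger = logging.getLogger(__name__)

ALPHA = 0.05

Contrast = tuple[str, str]


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p values.

    Sort ascending; the k-th smallest (1-based) is multiplied by (m − k + 1),
    a running maximum enforces monotonicity, and values are clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _f_test_variances(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = sps.f.sf(f, len(a) - 1, len(b) - 1)
    return float(min(1.0, 2 * min(p, 1 - p)))


def _groups_normal(samples: Mapping[str, np.ndarray], alpha: float = ALPHA) -> bool:
    """All groups pass Shapiro-Wilk at the given α (zero-variance counts as non-normal)."""
    for name, x in samples.items():
        if np.ptp(x) == 0:
            return False
        if sps.shapiro(x).pvalue < alpha:
            return False
    return True


def _alternative(tails: str) -> str:
    return "greater" if tails == "one" else "two-sided"


def _pairwise_unpaired(a, b, normal: bool, tails: str) -> tuple[str, float]:
    if normal:
        equal_var = _f_test_variances(a, b) >= ALPHA
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=_alternative(tails))
        name = "t (equal var)" if equal_var else "Welch t"
        return name, float(res.pvalue)
    res = sps.mannwhitneyu(a, b, alternative=_alternative(tails))
    return "Mann-Whitney U", float(res.pvalue)


def _pairwise_paired(a, b, normal: bool, tails: str) -> tuple[str, float]:
    if normal:
        res = sps.ttest_rel(a, b, alternative=_alternative(tails))
        return "paired t", float(res.pvalue)
    res = sps.wilcoxon(a, b, alternative=_alternative(tails))
    return "Wilcoxon signed-rank", float(res.pvalue)


def _omnibus(samples: Mapping[str, np.ndarray], normal: bool, paired: bool,
             data: pd.DataFrame) -> tuple[str, float]:
    arrays = list(samples.values())
    if paired:
        if normal:
            import pingouin as pg

            long = data.rename(columns={"group": "within"})
            res = pg.rm_anova(data=long, dv="value", within="within", subject="mouse")
            return "repeated-measures ANOVA", float(res["p_unc"].iloc[0])
        stat = sps.friedmanchisquare(*arrays)
        return "Friedman", float(stat.pvalue)
    if normal:
        import pingouin as pg

        res = pg.welch_anova(data=data, dv="value", between="group")
        return "Welch ANOVA", float(res["p_unc"].iloc[0])
    stat = sps.kruskal(*arrays)
    return "Kruskal-Wallis", float(stat.pvalue)


def compare_groups(
    cohort: pd.DataFrame,
    design: Literal["unpaired", "paired"] = "unpaired",
    tails: Literal["one", "two"] = "two",
    families: Mapping[str, Sequence[Contrast]] | None = None,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Run the comparison decision tree on a tidy cohort table.

    ``families`` maps a family label to the pairwise contrasts corrected
    together (Holm); it must be given explicitly, since the grouping of
    comparisons into correction families is a design input. Omnibus tests
    (when a family involves 3+ groups) are reported uncorrected with the
    contrast label "omnibus". Paired designs require every mouse in every
    compared group.
    """
    paired = design == "paired"
    validate_cohort(cohort, allow_repeated_groups=paired)
    if families is None or not families:
        raise ValueError("declare the Holm correction families explicitly")
    results: list[ComparisonResult] = []

    for fam_name, contrasts in families.items():
        groups = sorted({g for pair in contrasts for g in pair})
        sub = cohort[cohort["group"].isin(groups)]
        samples: dict[str, np.ndarray] = {}
        if paired:
            wide = sub.pivot_table(index="mouse", columns="group", values="value")
            if wide[groups].isna().any().any():
                raise ValueError("paired design: every mouse needs a value in every group")
            for g in groups:
                samples[g] = wide[g].to_numpy()
        else:
            for g in groups:
                samples[g] = sub.loc[sub["group"] == g, "value"].to_numpy()
        for g, x in samples.items():
            if len(x) < 3:
                raise ValueError(f"group {g}: need at least 3 observations")

        normal = _groups_normal(samples, alpha)
        logger.info("family %s: %s branch", fam_name,
                    "parametric" if normal else "nonparametric")

        if not normal and not paired and len(groups) >= 2:
            lev = sps.levene(*samples.values())
            logger.info("family %s: Levene p=%.3g", fam_name, lev.pvalue)

        if len(groups) >= 3:
            name, p_omni = _omnibus(samples, normal, paired, sub)
            results.append(ComparisonResult(
                contrast="omnibus", test=name, tails="two", p_raw=p_omni,
                p_adjusted=p_omni, significant=p_omni < alpha, family=fam_name))

        raw: list[float] = []
        names: list[str] = []
        for a, b in contrasts:
            if paired:
                test, p = _pairwise_paired(samples[a], samples[b], normal, tails)
            else:
                test, p = _pairwise_unpaired(samples[a], samples[b], normal, tails)
            raw.append(p)
            names.append(test)
        adjusted = holm_bonferroni(raw)
        for (a, b), test, p, padj in zip(contrasts, names, raw, adjusted):
            results.append(ComparisonResult(
                contrast=f"{a} vs {b}", test=test, tails=tails, p_raw=p,
                p_adjusted=float(padj), significant=padj < alpha, family=fam_name))
    return results


def results_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a tidy DataFrame."""
    return pd.DataFrame([vars(r) for r in results])
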