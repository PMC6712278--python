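"""Per-sample composition tables and multi-factor ANOVA with BH-FDR.

Once each protein is classified (loop architecture or phylum) and traced
to its sample of origin, per-sample category proportions form the
response for a five-way main-effects analysis of variance across the
metagenome design variables (strain, provider, housing location, sex,
diet).  Sums of squares are Type II (appropriate for the unbalanced
designs real mouse cohorts produce); no interactions are fitted.  The raw
per-sample proportion is the response — no transform.

Significance across the whole (category x factor) family within one
analysis is decided only by the Benjamini–Hochberg step-up procedure at a
configurable false-discovery rate (default 0.05); loop-category and
phylum analyses form separate BH families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

FACTORS = ("strain", "provider", "location", "sex", "diet")


@dataclass
class AnovaResult:
    response_category: str
    factor: str
    F: float
    p: float
    p_adj_significant: Optional[bool] = None  # set only by the BH step


class DesignError(ValueError):
    """Raised for singular / aliased ANOVA designs, naming the factors."""


def composition_by_sample(
    assignments: pd.DataFrame,
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample category proportions from per-protein assignments.

    ``assignments`` needs columns ``protein_id``, ``sample_id``,
    ``category``.  Rows with a null category are "unclassified" and are
    excluded from the denominator; samples with zero classified proteins
    are omitted with a warning.  Returns a tidy frame (sample_id,
    category, proportion) whose proportions sum to 1 per sample.
    """
    required = {"protein_id", "sample_id", "category"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments must have columns {sorted(required)}")
    classified = assignments.dropna(subset=["category"])
    dropped = sorted(
        set(assignments["sample_id"]) - set(classified["sample_id"])
    )
    if dropped:
        warnings.warn(f"samples with no classified proteins omitted: {dropped}")
    counts = (
        classified.groupby(["sample_id", "category"]).size().rename("count").reset_index()
    )
    if categories is None:
        categories = sorted(classified["category"].unique())
    grid = pd.MultiIndex.from_product(
        [sorted(classified["sample_id"].unique()), list(categories)],
        names=["sample_id", "category"],
    )
    counts = (
        counts.set_index(["sample_id", "category"])["count"]
        .reindex(grid, fill_value=0)
        .reset_index()
    )
    totals = counts.groupby("sample_id")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts[["sample_id", "category", "proportion"]]


def five_way_anova(
    composition: pd.DataFrame,
    metadata: pd.DataFrame,
    category: str,
    factors: Sequence[str] = FACTORS,
) -> list[AnovaResult]:
    """Main-effects ANOVA of one category's per-sample proportion.

    ``metadata`` is keyed by ``sample_id`` with one column per factor.
    Factors with a single observed level are dropped with a warning;
    aliased (rank-deficient) designs raise :class:`DesignError` naming
    the offending factors.  F and p per factor come from Type II sums of
    squares.  A constant response yields F = 0, p = 1 for every factor.
    """
    sub = composition[composition["category"] == category]
    if sub.empty:
        raise ValueError(f"no composition rows for category {category!r}")
    unknown = set(sub["sample_id"]) - set(metadata["sample_id"])
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    df = sub.merge(metadata, on="sample_id", how="left")

    kept: list[str] = []
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"metadata lacks factor column {f!r}")
        if df[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single observed level; dropped")
        else:
            kept.append(f)
    if not kept:
        raise DesignError("no factor has two or more observed levels")

    y = df["proportion"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return [AnovaResult(category, f, F=0.0, p=1.0) for f in kept]

    n_params = 1 + sum(df[f].nunique() - 1 for f in kept)
    if len(df) <= n_params:
        raise DesignError(
            f"{len(df)} samples cannot support {n_params} model parameters"
        )

    formula = "proportion ~ " + " + ".join(f"C({f})" for f in kept)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        aliased = _find_aliased(df, kept)
        raise DesignError(f"singular design; aliased factors: {aliased}")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=2)
    results = []
    for f in kept:
        row = table.loc[f"C({f})"]
        results.append(
            AnovaResult(category, f, F=float(row["F"]), p=float(row["PR(>F)"]))
        )
    return results


def _find_aliased(df: pd.DataFrame, factors: Sequence[str]) -> list[str]:
    """Factors whose dummy columns are linearly dependent on the others."""
    import patsy

    full = patsy.dmatrix(" + ".join(f"C({f})" for f in factors), df)
    full_rank = np.linalg.matrix_rank(np.asarray(full))
    aliased = []
    for f in factors:
        rest = [g for g in factors if g != f]
        if not rest:
            continue
        sub = patsy.dmatrix(" + ".join(f"C({g})" for g in rest), df)
        if np.linalg.matrix_rank(np.asarray(sub)) == full_rank:
            aliased.append(f)
    return aliased or list(factors)


def bh_correct(pvals: Sequence[float], fdr: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags, original order.

    Sort ascending, find the largest k with p_(k) <= k * q / m, flag the
    k smallest p values.  Flags are monotone: anything no larger than a
    flagged p value is flagged too.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def anova_with_bh(
    composition: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr: float = 0.05,
    factors: Sequence[str] = FACTORS,
) -> pd.DataFrame:
    """Run the per-category ANOVA over all categories and BH-correct.

    The BH family is every (category x factor) test in this one call.
    Returns a tidy frame (response, factor, F, p, significant).
    """
    results: list[AnovaResult] = []
    for category in sorted(composition["category"].unique()):
        results.extend(five_way_anova(composition, metadata, category, factors))
    flags = bh_correct([r.p for r in results], fdr=fdr)
    for r, flag in zip(results, flags):
        r.p_adj_significant = bool(flag)
    return pd.DataFrame(
        {
            "response": [r.response_category for r in results],
            "factor": [r.factor for r in results],
            "F": [r.F for r in results],
            "p": [r.p for r in results],
            "significant": [r.p_adj_significant for r in results],
        }
    )
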