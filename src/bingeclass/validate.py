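"""Internal and external validation of the group classifier.

Internal validation cross-tabulates the K-means-derived grouping (the gold
standard) against the ordinal model's predictions and reports per-group and
overall misclassification.  External validation applies the frozen
classifier to a new cohort and profiles the per-group means of the retained
items.  Composition statistics break the grouping down by an attribute
(typically gender) in both directions of normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .survey import N_GROUPS, RETAINED_ITEMS


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceTable:
    """Gold (rows) vs predicted (columns) group cross-tabulation."""

    counts: pd.DataFrame  # K x K, rows gold, columns predicted
    row_errors: np.ndarray  # off-diagonal share per gold group, fraction
    overall_error: float  # fraction

    @property
    def row_errors_pct(self) -> list[float]:
        """Per-group misclassification in percent, half-up to one decimal."""
        return [round_half_up(100 * e, 1) for e in self.row_errors]

    @property
    def overall_error_pct(self) -> float:
        return round_half_up(100 * self.overall_error, 1)

    @classmethod
    def from_counts(cls, counts) -> "ConcordanceTable":
        """Build the table (and its error rates) from a K x K count matrix."""
        arr = np.asarray(counts, float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        k = arr.shape[0]
        groups = list(range(1, k + 1))
        df = pd.DataFrame(arr, index=groups, columns=groups)
        row_tot = arr.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row_err = np.where(row_tot > 0, (row_tot - np.diag(arr)) / row_tot, np.nan)
        total = arr.sum()
        overall = float((total - np.trace(arr)) / total) if total > 0 else float("nan")
        return cls(counts=df, row_errors=row_err, overall_error=overall)


def concordance(gold, predicted, n_groups: int = N_GROUPS) -> ConcordanceTable:
    """Cross-tabulate gold vs predicted group labels with error rates."""
    gold = np.asarray(gold, int)
    predicted = np.asarray(predicted, int)
    if gold.shape != predicted.shape:
        raise ValueError(
            f"label vectors differ in length ({len(gold)} vs {len(predicted)})"
        )
    counts = np.zeros((n_groups, n_groups))
    for g, p in zip(gold, predicted):
        counts[g - 1, p - 1] += 1
    return ConcordanceTable.from_counts(counts)


def external_group_means(
    cohort: pd.DataFrame, classifier, items=RETAINED_ITEMS
) -> pd.DataFrame:
    """Classify a cohort with a frozen model and profile per-group item means.

    Groups empty in the cohort appear with n=0 and NaN means (marked, not an
    error) so small external samples keep the full four-row layout.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    predicted = classifier.predict(cohort[list(classifier.spec_.predictors)])
    out = pd.DataFrame(index=pd.Index(range(1, classifier.n_levels + 1), name="group"))
    df = cohort[list(items)].copy()
    df["group"] = predicted
    sizes = df.groupby("group").size()
    out["n"] = sizes.reindex(out.index, fill_value=0).astype(int)
    means = df.groupby("group").mean()
    for item in items:
        out[item] = means[item].reindex(out.index)
    return out


def composition_by(
    labels, attribute_values, n_groups: int = N_GROUPS
) -> dict[str, pd.DataFrame]:
    """Group-by-attribute composition in the three reported normalisations.

    Returns a dict of DataFrames (groups 1..K as rows):

    ``share_of_attribute``
        Of all holders of each attribute value, the percentage falling in
        each group (columns sum to 100 per attribute value) — e.g. "the
        percentage of women was highest in group 1".
    ``share_within_group``
        Within each group, the percentage holding each attribute value
        (rows sum to 100).
    ``group_share``
        Each group's share of the whole sample, percent.
    ``counts``
        The raw group x attribute-value counts.
    """
    labels = np.asarray(labels, int)
    attr = np.asarray(attribute_values, dtype=object)
    if labels.shape != attr.shape:
        raise ValueError("labels and attribute values differ in length")
    if len(labels) == 0:
        raise ValueError("empty cohort")
    values = sorted(set(attr.tolist()), key=str)
    groups = list(range(1, n_groups + 1))
    counts = pd.DataFrame(0, index=pd.Index(groups, name="group"), columns=values)
    for g, a in zip(labels, attr):
        counts.loc[g, a] += 1

    col_tot = counts.sum(axis=0)
    row_tot = counts.sum(axis=1)
    share_of_attribute = 100 * counts / col_tot.replace(0, np.nan)
    share_within_group = 100 * counts.div(row_tot.replace(0, np.nan), axis=0)
    group_share = pd.DataFrame(
        {"pct_of_sample": 100 * row_tot / row_tot.sum()}, index=counts.index
    )
    return {
        "counts": counts,
        "share_of_attribute": share_of_attribute,
        "share_within_group": share_within_group,
        "group_share": group_share,
    }


def composition_from_counts(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Same normalisations as :func:`composition_by`, from a count table."""
    counts = counts.copy()
    col_tot = counts.sum(axis=0)
    row_tot = counts.sum(axis=1)
    return {
        "counts": counts,
        "share_of_attribute": 100 * counts / col_tot.replace(0, np.nan),
        "share_within_group": 100 * counts.div(row_tot.replace(0, np.nan), axis=0),
        "group_share": pd.DataFrame(
            {"pct_of_sample": 100 * row_tot / row_tot.sum()}, index=counts.index
        ),
    }


def covariate_effect_on_error(
    X: pd.DataFrame,
    gold,
    covariate: str,
    predictors=None,
    proportional=None,
    **fit_options,
) -> dict:
    """Refit the ordinal model with an extra covariate; compare error profiles.

    Fits the model without and with ``covariate`` appended (as a shared-
    coefficient predictor), recomputes internal concordance against the
    gold grouping, and returns both per-group error profiles for
    side-by-side comparison.  Purely descriptive — no test statistic.
    """
    from .ppom import fit_ppom

    if covariate not in X.columns:
        raise ValueError(f"covariate {covariate!r} not present in data")
    if predictors is None:
        predictors = [c for c in X.columns if c != covariate]
    predictors = list(predictors)

    base = fit_ppom(X[predictors], gold, predictors=predictors,
                    proportional=proportional, **fit_options)
    aug_predictors = predictors + [covariate]
    if isinstance(proportional, dict):
        aug_prop = dict(proportional)
        aug_prop.setdefault(covariate, True)
    else:
        aug_prop = proportional
    augmented = fit_ppom(X[aug_predictors], gold, predictors=aug_predictors,
                         proportional=aug_prop, **fit_options)

    gold = np.asarray(gold, int)
    without = concordance(gold, base.predict(X[predictors]))
    with_cov = concordance(gold, augmented.predict(X[aug_predictors]))
    return {
        "without": without,
        "with": with_cov,
        "fit_without": base,
        "fit_with": augmented,
        "flagged": not (base.converged_ and augmented.converged_)
        or base.se_flagged_ or augmented.se_flagged_,
    }
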