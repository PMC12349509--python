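"""Association battery: regressions, group ANOVA and paired comparisons.

Every association in the analysis is a simple ordinary-least-squares
regression of one estimate on one covariate, reported as slope, intercept,
R-squared and the two-sided t-test p-value on the slope, with significance
bands p < 0.05 (significant) and 0.05 <= p < 0.10 (marginal). Group
differences (e.g. burden by country of origin) use one-way fixed-effects
ANOVA over groups meeting a minimum size. A Benjamini-Hochberg adjusted
p-value column is emitted alongside tidy results as a labelled extension;
the primary per-test alpha reporting applies no multiplicity correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("gburden")

#: the six per-sample estimates screened pairwise
ESTIMATES = ("B_tot", "B_het", "B_hom",
             "expressed_gene_count", "mean_tpm", "rin")
BURDENS = ("B_tot", "B_het", "B_hom")
EXTRA_ESTIMATES = ("expressed_gene_count", "mean_tpm", "rin")
#: the three conservation-related accession features
FEATURES = ("y_last", "y_acq", "r")


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significance: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnovaResult:
    grouping: str
    f_statistic: float
    p_value: float
    groups_used: list[str]
    group_n: dict[str, int]
    group_means: dict[str, float]

    @property
    def n(self) -> int:
        return sum(self.group_n.values())


def significance_class(p: float, alpha: float = 0.05,
                       marginal: float = 0.10) -> str:
    if p < alpha:
        return "significant"
    if p < marginal:
        return "marginal"
    return "ns"


def regress(y, x, response: str = "y", predictor: str = "x",
            alpha: float = 0.05, marginal: float = 0.10) -> AssociationResult:
    """OLS regression of ``y`` on ``x`` with a two-sided slope t-test."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise AssociationError("y and x must be 1-D vectors of equal length")
    if np.isnan(y).any() or np.isnan(x).any():
        raise AssociationError("missing values in regression input")
    if len(y) < 3:
        raise AssociationError(f"need n >= 3 observations, got {len(y)}")
    if np.ptp(x) == 0:
        raise AssociationError(f"degenerate predictor {predictor!r} (constant)")
    fit = stats.linregress(x, y)
    return AssociationResult(
        response=response, predictor=predictor,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_value=float(fit.pvalue),
        n=len(y), significance=significance_class(fit.pvalue, alpha, marginal))


def anova_by_group(values, groups, min_group_n: int = 3,
                   grouping: str = "group") -> AnovaResult:
    """One-way fixed-effects ANOVA over groups meeting ``min_group_n``.

    Groups below the size threshold are excluded (and not reported in
    ``groups_used``); at least two eligible groups are required. With two
    groups the F statistic equals the squared pooled two-sample t statistic.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise AssociationError("values and groups must align")
    labels, counts = np.unique(groups, return_counts=True)
    eligible = [str(g) for g, c in zip(labels, counts) if c >= min_group_n]
    if len(eligible) < 2:
        raise AssociationError(
            f"need >= 2 groups with n >= {min_group_n}; have {len(eligible)}")
    arrays = [values[groups == g] for g in eligible]
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        grouping=grouping, f_statistic=float(f), p_value=float(p),
        groups_used=eligible,
        group_n={g: int(len(a)) for g, a in zip(eligible, arrays)},
        group_means={g: float(a.mean()) for g, a in zip(eligible, arrays)})


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------

def build_bundle(burden: pd.DataFrame, expression: pd.DataFrame,
                 meta: pd.DataFrame) -> pd.DataFrame:
    """Join burdens, expression summaries and RIN into the six-estimate bundle.

    Inputs are indexed by sample_id; the join is inner, and a warning is
    logged when samples are lost.
    """
    bundle = burden[list(BURDENS)].join(
        expression[["expressed_gene_count", "mean_tpm"]], how="inner")
    bundle = bundle.join(meta[["rin"]], how="inner")
    lost = max(len(burden), len(expression), len(meta)) - len(bundle)
    if lost > 0:
        logger.warning("build_bundle: join lost %d sample(s)", lost)
    if bundle.isna().any().any():
        raise AssociationError("missing values in estimate bundle after join")
    return bundle


def run_battery(bundle: pd.DataFrame, meta: pd.DataFrame,
                alpha: float = 0.05, marginal: float = 0.10) -> pd.DataFrame:
    """Run the full association battery and return one tidy row per test.

    Tests, labelled by ``family``: the 9 burden x conservation-feature
    regressions; the 15 unordered pairwise regressions among the six
    estimates; and the 9 extra-estimate x feature regressions. A
    ``p_bh`` Benjamini-Hochberg column is appended as a labelled extension.
    """
    joined = bundle.join(meta[[c for c in FEATURES if c not in bundle.columns]],
                         how="inner")
    if len(joined) < len(bundle):
        logger.warning("run_battery: feature join lost %d sample(s)",
                       len(bundle) - len(joined))
    rows = []
    for b, f in itertools.product(BURDENS, FEATURES):
        res = regress(joined[b], joined[f], response=b, predictor=f,
                      alpha=alpha, marginal=marginal)
        rows.append({"family": "burden_x_feature", **res.to_dict()})
    for a, b in itertools.combinations(ESTIMATES, 2):
        res = regress(joined[a], joined[b], response=a, predictor=b,
                      alpha=alpha, marginal=marginal)
        rows.append({"family": "pairwise_estimates", **res.to_dict()})
    for e, f in itertools.product(EXTRA_ESTIMATES, FEATURES):
        res = regress(joined[e], joined[f], response=e, predictor=f,
                      alpha=alpha, marginal=marginal)
        rows.append({"family": "extra_x_feature", **res.to_dict()})
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def paired_compare(a: pd.DataFrame, b: pd.DataFrame,
                   labels: tuple[str, str] = ("a", "b"),
                   alpha: float = 0.05, marginal: float = 0.10) -> pd.DataFrame:
    """Regress one assay's estimates on another's over shared samples.

    ``a`` and ``b`` are estimate bundles (columns = estimates, index =
    sample_id) from two assays of the same material, e.g. seed-based vs
    leaf-based. For every shared estimate column, a's values are regressed on
    b's over the sample-ID intersection; each tidy row carries the shared
    sample count.
    """
    shared_samples = a.index.intersection(b.index)
    if len(shared_samples) == 0:
        raise AssociationError("no shared samples between the two bundles")
    shared_cols = [c for c in a.columns if c in b.columns]
    rows = []
    for col in shared_cols:
        res = regress(a.loc[shared_samples, col], b.loc[shared_samples, col],
                      response=f"{labels[0]}:{col}", predictor=f"{labels[1]}:{col}",
                      alpha=alpha, marginal=marginal)
        rows.append({"family": "paired_assays", "estimate": col, **res.to_dict()})
    return pd.DataFrame(rows)
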