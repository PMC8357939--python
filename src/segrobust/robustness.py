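"""Per-feature robustness to segmentation variability via ICC(2,1).

Each radiomic feature yields a subjects x raters rating matrix (patients x
observers). Robustness is quantified with the intraclass correlation for a
two-way random-effects model with single measurements and absolute
agreement:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E + (k / n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the between-subject, between-rater and
residual mean squares of the two-way ANOVA, n the number of subjects and k
the number of raters. Mean squares are computed from explicit sums of
squares (no model-fitting package), which keeps the estimator transparent
and lets tests check it against an independent ANOVA decomposition.

A feature is robust when its ICC strictly exceeds the threshold (default
0.75). Negative ICCs are reported as computed and are never robust;
matrices with a vanishing denominator yield NaN (flagged, never robust).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingMatrix",
    "icc21",
    "feature_icc_table",
    "robust_summary",
    "top_features",
    "discipline_icc_wilcoxon",
    "rank_agreement",
    "DEFAULT_ICC_THRESHOLD",
]

DEFAULT_ICC_THRESHOLD = 0.75

_DENOM_TOL = 1e-12


@dataclass
class RatingMatrix:
    """Subjects x raters table of one feature's values."""

    values: np.ndarray
    subject_ids: tuple = ()
    rater_ids: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("RatingMatrix requires a 2D table")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rating matrix contains non-finite cells")


def _icc21_stack(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ICC(2,1) over a stack of rating matrices.

    values has shape (..., n, k); returns (icc, ms_r, ms_c, ms_e) with the
    leading shape. Vanishing denominators yield NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    n, k = values.shape[-2:]
    grand = values.mean(axis=(-2, -1), keepdims=True)
    row_means = values.mean(axis=-1, keepdims=True)
    col_means = values.mean(axis=-2, keepdims=True)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=(-2, -1))
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=(-2, -1))
    ss_total = ((values - grand) ** 2).sum(axis=(-2, -1))
    ss_err = np.clip(ss_total - ss_rows - ss_cols, 0.0, None)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(np.abs(denom) > _DENOM_TOL, (ms_r - ms_e) / denom, np.nan)
    return icc, ms_r, ms_c, ms_e


def icc21(m: RatingMatrix | np.ndarray) -> tuple[float, dict]:
    """ICC(2,1) of one rating matrix, with its three mean squares.

    Returns ``(icc, mean_squares)`` where ``mean_squares`` has keys
    ``ms_r``, ``ms_c``, ``ms_e``. The value may be negative; a vanishing
    denominator (e.g. an all-identical matrix) yields NaN.
    """
    values = m.values if isinstance(m, RatingMatrix) else RatingMatrix(np.asarray(m)).values
    icc, ms_r, ms_c, ms_e = _icc21_stack(values)
    return float(icc), {"ms_r": float(ms_r), "ms_c": float(ms_c), "ms_e": float(ms_e)}


# ---------------------------------------------------------------------------
# Cohort-level ICC tables
# ---------------------------------------------------------------------------

def feature_icc_table(
    features: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> pd.DataFrame:
    """ICC(2,1) per feature for all observers and per discipline group.

    Parameters
    ----------
    features : DataFrame
        Long table with columns patient_id, observer_id, feature_id,
        filter, feature_class, name, value — one complete panel per
        (patient, observer).
    groups : dict
        observer_id -> discipline label. Groups with fewer than 2 observers
        are rejected.
    threshold : float
        Robustness cutoff; robust means ICC strictly greater.

    Returns
    -------
    DataFrame with one row per (feature, group in {'all'} + disciplines):
    feature_id, filter, feature_class, name, group, icc, ms_r, ms_c, ms_e,
    robust.
    """
    observers = sorted(groups)
    disciplines = sorted(set(groups.values()))
    meta = (
        features[["feature_id", "filter", "feature_class", "name"]]
        .drop_duplicates("feature_id")
        .set_index("feature_id")
    )
    wide = features.pivot_table(
        index="feature_id", columns=["patient_id", "observer_id"], values="value",
        sort=True,
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any(axis=0)]
        raise ValueError(f"missing feature vectors for {list(missing)[:5]} ...")
    patients = wide.columns.get_level_values(0).unique()
    feature_ids = wide.index
    cube = wide.to_numpy().reshape(len(feature_ids), len(patients), -1)
    obs_order = list(wide.columns.get_level_values(1).unique())

    records = []
    group_members = {"all": observers}
    for d in disciplines:
        group_members[d] = [o for o in observers if groups[o] == d]
    for g, members in group_members.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observers")
        cols = [obs_order.index(o) for o in members]
        icc, ms_r, ms_c, ms_e = _icc21_stack(cube[:, :, cols])
        robust = np.where(np.isnan(icc), False, icc > threshold)
        for i, fid in enumerate(feature_ids):
            records.append(
                (
                    fid, meta.at[fid, "filter"], meta.at[fid, "feature_class"],
                    meta.at[fid, "name"], g, icc[i], ms_r[i], ms_c[i], ms_e[i],
                    bool(robust[i]),
                )
            )
    return pd.DataFrame(
        records,
        columns=[
            "feature_id", "filter", "feature_class", "name", "group",
            "icc", "ms_r", "ms_c", "ms_e", "robust",
        ],
    )


def robust_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Robust-feature counts per (filter, feature_class, group).

    Returns the summary table (total, robust, pct_robust per cell) and a
    dict with per-group robust totals plus the cross-group intersection
    sizes of the robust feature-name sets.
    """
    summary = (
        records.groupby(["group", "filter", "feature_class"])
        .agg(total=("feature_id", "size"), robust=("robust", "sum"))
        .reset_index()
    )
    summary["pct_robust"] = 100.0 * summary["robust"] / summary["total"]
    groups = sorted(records["group"].unique())
    robust_sets = {
        g: set(records.loc[(records["group"] == g) & records["robust"], "feature_id"])
        for g in groups
    }
    info: dict = {f"n_robust_{g}": len(robust_sets[g]) for g in groups}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            info[f"n_robust_{g1}_and_{g2}"] = len(robust_sets[g1] & robust_sets[g2])
    return summary, info


def top_features(
    records: pd.DataFrame, group: str, per_filter_k: int = 3
) -> pd.DataFrame:
    """Top-k features by ICC within each filter for one group.

    Ties break by feature name ascending; NaN ICCs are excluded.
    """
    sub = records[(records["group"] == group) & records["icc"].notna()].copy()
    sub = sub.sort_values(["filter", "icc", "name"], ascending=[True, False, True])
    out = sub.groupby("filter", sort=True).head(per_filter_k).copy()
    out["rank"] = out.groupby("filter").cumcount() + 1
    return out[["filter", "rank", "icc", "feature_id", "feature_class", "name"]].reset_index(
        drop=True
    )


def _wilcoxon_exact_ok(diff: np.ndarray) -> bool:
    return len(diff) <= 25 and len(np.unique(np.abs(diff))) == len(diff)


def discipline_icc_wilcoxon(
    records: pd.DataFrame, group_a: str = "A", group_b: str = "B"
) -> pd.DataFrame:
    """Wilcoxon signed-rank test on paired per-feature ICCs, per filter.

    Pairs are the (ICC_A, ICC_B) values of each feature within a filter;
    features with a NaN ICC in either group are excluded, zero differences
    are dropped (standard convention). The exact null distribution is used
    for n <= 25 untied differences, the normal approximation otherwise.
    An empty pair set yields NaN statistics (degenerate, flagged by n_pairs).
    """
    piv = records.pivot_table(index=["filter", "feature_id"], columns="group", values="icc")
    if group_a not in piv.columns or group_b not in piv.columns:
        raise ValueError(f"records lack groups {group_a!r}/{group_b!r}")
    rows = []
    for filt, sub in piv.groupby(level="filter", sort=True):
        pair = sub[[group_a, group_b]].dropna()
        diff = pair[group_a].to_numpy() - pair[group_b].to_numpy()
        diff = diff[diff != 0.0]
        if len(diff) == 0:
            rows.append((filt, 0, np.nan, np.nan))
            continue
        method = "exact" if _wilcoxon_exact_ok(diff) else "approx"
        res = stats.wilcoxon(diff, alternative="two-sided", method=method)
        rows.append((filt, len(diff), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["filter", "n_pairs", "statistic", "p_value"])


def rank_agreement(
    records: pd.DataFrame,
    group_a: str = "A",
    group_b: str = "B",
    filters: tuple[str, ...] = ("original",),
) -> pd.DataFrame:
    """Between-group agreement of within-class robustness rankings.

    Within each feature class (restricted to the original-image features by
    default), features are ranked by ICC separately per group (ties get
    average ranks) and the ranks are compared by ordinary least squares of
    rank_B on rank_A. Perfect agreement gives slope 1 and R^2 = 1; exactly
    reversed rankings give slope -1 and R^2 = 1.
    """
    sub = records[records["filter"].isin(filters)]
    piv = sub.pivot_table(
        index=["feature_class", "feature_id"], columns="group", values="icc"
    )
    rows = []
    for fclass, block in piv.groupby(level="feature_class", sort=True):
        pair = block[[group_a, group_b]].dropna()
        if len(pair) < 3:
            raise ValueError(f"feature class {fclass!r} has fewer than 3 usable features")
        ra = stats.rankdata(pair[group_a])
        rb = stats.rankdata(pair[group_b])
        fit = stats.linregress(ra, rb)
        rows.append((fclass, len(pair), float(fit.slope), float(fit.rvalue**2)))
    return pd.DataFrame(rows, columns=["feature_class", "n_features", "slope", "r_squared"])
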