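"""Consensus segmentation (STAPLE), Dice agreement and discipline comparisons.

The consensus volume is estimated with STAPLE (Simultaneous Truth And
Performance Level Estimation): an EM algorithm over a per-voxel latent true
segmentation, with per-observer sensitivity ``p_j`` and specificity ``q_j``.
Each observer's delineation is then scored against the consensus with the
Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|) and graded on the
fixed scale High (DSC ≥ 0.85), Medium (0.85 > DSC ≥ 0.70), Low
(0.7 > DSC ≥ 0.5), Very Low (DSC < 0.5).

All agreement computations run on the native (pre-resampling) mask grid;
isotropic resampling is a feature-extraction concern only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image_model import BinaryMask
from .synthetic_cohort import StudyCohort

__all__ = [
    "StapleResult",
    "dice",
    "staple",
    "grade_agreement",
    "per_patient_agreement",
    "compare_disciplines_dsc",
    "compare_volumes",
    "GRADE_LABELS",
]

GRADE_LABELS = ("High", "Medium", "Low", "VeryLow")

# STAPLE voxels outside the bounding box of the union of all observer masks
# (plus this margin) are uninformative for the consensus; they are excluded
# from the EM sums so distant empty background does not inflate specificity.
_STAPLE_MARGIN = 5

_PQ_CLAMP = 1e-8  # keep sensitivities/specificities off exact 0/1 inside EM


@dataclass
class StapleResult:
    """Output of the STAPLE EM.

    probability_map holds the per-voxel posterior probability of foreground
    on the full input grid; ``consensus`` is its binarization at 0.5 (ties
    to foreground). ``sensitivity``/``specificity`` map observer index to
    the estimated (p_j, q_j).
    """

    probability_map: np.ndarray
    consensus: BinaryMask
    sensitivity: np.ndarray
    specificity: np.ndarray
    iterations: int
    converged: bool


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Defined as 1.0 when both masks are empty. Symmetric; 1 iff the
    (non-empty) masks are identical, 0 iff disjoint.
    """
    if not a.same_geometry(b):
        raise ValueError("dice: masks do not share geometry")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.indicator, b.indicator).sum())
    return 2.0 * inter / (na + nb)


def staple(
    masks: list[BinaryMask], tol: float = 1e-6, max_iter: int = 100
) -> StapleResult:
    """Estimate the consensus segmentation of ≥ 2 binary delineations.

    EM with a global scalar prior equal to the mean foreground fraction
    across observers; initial p_j = q_j = 0.99999. Iterates until the
    maximum absolute change in any p_j or q_j falls below ``tol`` or
    ``max_iter`` is reached.
    """
    if len(masks) < 2:
        raise ValueError("staple requires at least 2 masks")
    first = masks[0]
    for m in masks[1:]:
        if not m.same_geometry(first):
            raise ValueError("staple: masks do not share geometry")
    if all(m.voxel_count == 0 for m in masks):
        raise ValueError("staple: all masks are empty")

    stack = np.stack([m.indicator for m in masks])  # (J, nx, ny, nz)
    union = np.any(stack, axis=0)
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - _STAPLE_MARGIN, 0)
    hi = np.minimum(idx.max(axis=0) + _STAPLE_MARGIN + 1, union.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    d = stack[(slice(None),) + box].reshape(len(masks), -1).astype(np.float64)  # (J, V)

    j_obs = len(masks)
    prior = float(d.mean())
    p = np.full(j_obs, 0.99999)
    q = np.full(j_obs, 0.99999)

    iterations = 0
    converged = False
    w = np.full(d.shape[1], prior)
    for iterations in range(1, max_iter + 1):
        # E-step: posterior foreground probability per voxel
        log_a = np.log(p) @ d + np.log1p(-p) @ (1.0 - d)
        log_b = np.log1p(-q) @ d + np.log(q) @ (1.0 - d)
        a = prior * np.exp(log_a)
        b = (1.0 - prior) * np.exp(log_b)
        denom = a + b
        w = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), prior)
        # M-step: re-estimate observer performance
        sw = w.sum()
        swc = (1.0 - w).sum()
        p_new = (d @ w) / sw if sw > 0 else p
        q_new = ((1.0 - d) @ (1.0 - w)) / swc if swc > 0 else q
        p_new = np.clip(p_new, _PQ_CLAMP, 1.0 - _PQ_CLAMP)
        q_new = np.clip(q_new, _PQ_CLAMP, 1.0 - _PQ_CLAMP)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    # full-grid probability map: outside the box every observer reported
    # background, so the posterior is the all-zero-pattern value
    log_a0 = float(np.log1p(-p).sum())
    log_b0 = float(np.log(q).sum())
    a0 = prior * np.exp(log_a0)
    b0 = (1.0 - prior) * np.exp(log_b0)
    w0 = a0 / (a0 + b0) if (a0 + b0) > 0 else prior
    prob = np.full(union.shape, w0, dtype=np.float64)
    prob[box] = w.reshape(tuple(h - l for l, h in zip(lo, hi)))
    consensus = BinaryMask(prob >= 0.5, first.spacing, first.origin)
    return StapleResult(prob, consensus, p, q, iterations, converged)


def grade_agreement(dsc: float) -> str:
    """Map a DSC value onto the four-level agreement scale."""
    if not (0.0 <= dsc <= 1.0):
        raise ValueError(f"DSC must lie in [0, 1], got {dsc}")
    if dsc >= 0.85:
        return "High"
    if dsc >= 0.70:
        return "Medium"
    if dsc >= 0.5:
        return "Low"
    return "VeryLow"


def per_patient_agreement(
    cohort: StudyCohort, tol: float = 1e-6, max_iter: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, StapleResult]]:
    """Per-observer agreement with the all-observer STAPLE consensus.

    Returns
    -------
    records : DataFrame
        One row per (patient, observer): patient_id, observer_id,
        discipline, volume_cm3, dsc, grade.
    summary : DataFrame
        Per patient and discipline: mean and SD of DSC.
    consensus : dict
        patient_id -> :class:`StapleResult`.
    """
    profiles = cohort.observer_profiles()
    rows = []
    results: dict[str, StapleResult] = {}
    for case in cohort.patients:
        obs_ids = sorted(case.observer_masks)
        res = staple([case.observer_masks[o] for o in obs_ids], tol=tol, max_iter=max_iter)
        results[case.patient_id] = res
        for o in obs_ids:
            mask = case.observer_masks[o]
            d = dice(mask, res.consensus)
            rows.append(
                dict(
                    patient_id=case.patient_id,
                    observer_id=o,
                    discipline=profiles[o].discipline,
                    volume_cm3=mask.volume_cm3,
                    dsc=d,
                    grade=grade_agreement(d),
                )
            )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["patient_id", "discipline"])["dsc"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    return records, summary, results


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test with explicit degenerate handling.

    If every paired difference is identical the t statistic is 0 (p = 1)
    when the common difference is 0, and ±inf (p = 0) otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError("paired test requires at least 2 pairs")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, pval = stats.ttest_rel(x, y)
    return float(t), float(pval)


def compare_disciplines_dsc(records: pd.DataFrame) -> dict:
    """Paired two-tailed t-test on per-patient discipline-mean DSCs."""
    means = records.pivot_table(index="patient_id", columns="discipline", values="dsc")
    disciplines = sorted(means.columns)
    if len(disciplines) != 2 or means.isna().any().any():
        raise ValueError("both disciplines must be present for every patient")
    a, b = disciplines
    t, pval = _paired_t(means[a].to_numpy(), means[b].to_numpy())
    return {
        "discipline_a": a,
        "discipline_b": b,
        "mean_dsc_a": float(means[a].mean()),
        "sd_dsc_a": float(means[a].std(ddof=1)),
        "mean_dsc_b": float(means[b].mean()),
        "sd_dsc_b": float(means[b].std(ddof=1)),
        "t_statistic": t,
        "p_value": pval,
    }


def compare_volumes(cohort: StudyCohort) -> dict:
    """Per-discipline delineated volume (cm^3) and its paired comparison.

    Volume is voxel count × voxel volume. Per patient, observer volumes are
    averaged within discipline; the two disciplines are then compared with
    the same paired two-tailed design as the DSC comparison.
    """
    profiles = cohort.observer_profiles()
    rows = [
        dict(
            patient_id=case.patient_id,
            discipline=profiles[o].discipline,
            volume_cm3=m.volume_cm3,
        )
        for case in cohort.patients
        for o, m in case.observer_masks.items()
    ]
    df = pd.DataFrame(rows)
    means = df.pivot_table(index="patient_id", columns="discipline", values="volume_cm3")
    disciplines = sorted(means.columns)
    if len(disciplines) != 2 or means.isna().any().any():
        raise ValueError("both disciplines must be present for every patient")
    a, b = disciplines
    if len(means) >= 2:
        t, pval = _paired_t(means[a].to_numpy(), means[b].to_numpy())
    else:
        t, pval = float("nan"), float("nan")
    return {
        "discipline_a": a,
        "discipline_b": b,
        "mean_volume_a_cm3": float(means[a].mean()),
        "sd_volume_a_cm3": float(means[a].std(ddof=1)),
        "mean_volume_b_cm3": float(means[b].mean()),
        "sd_volume_b_cm3": float(means[b].std(ddof=1)),
        "t_statistic": t,
        "p_value": pval,
    }
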