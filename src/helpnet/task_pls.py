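"""Mean-centered task PLS with permutation and bootstrap inference.

The decomposition takes the k x p matrix of per-condition mean activities
M, removes the unweighted mean of the condition rows, and applies a
singular value decomposition

    R = M - mean_rows(M) = U diag(s) V^T.

Each latent variable (LV) pairs a condition contrast (column of U) with a
brain-region salience pattern (column of V) and a singular value measuring
the cross-block covariance it captures. At most k - 1 LVs are non-null
because centering removes one degree of freedom.

Inference follows the standard task-PLS recipe: LV significance by
permuting condition labels over subjects (without replacement) and
re-running the decomposition; salience reliability by resampling subjects
with replacement within their condition, realigning each resampled V to
the original by an orthogonal Procrustes rotation, and forming the
bootstrap ratio BR = salience / bootstrap SD. Regions with |BR| above a
critical value (default 2.57, the two-sided 99% normal point) are taken as
reliably contributing to the LV. Because saliences for all regions come
from a single decomposition, no multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from helpnet.data_model import ActivityMatrix, DegenerateInputError, ValidationError

__all__ = [
    "PLSResult",
    "group_mean_center",
    "fit",
    "permutation_test",
    "bootstrap_saliences",
    "run",
    "reliable_regions",
    "br_critical_value",
    "brainwide_mean_ttest",
]

#: singular values below this multiple of the largest are treated as null
_NULL_SV_RTOL = 1e-10

#: default bootstrap-ratio cutoff, ~ two-sided 99% normal critical value
DEFAULT_BR_THRESHOLD = 2.57


@dataclass
class PLSResult:
    """Decomposition plus (optional) resampling inference for one fit."""

    saliences: np.ndarray  # (p, L) region weights V
    contrasts: np.ndarray  # (k, L) condition weights U
    singular_values: np.ndarray  # (L,)
    brain_scores: np.ndarray  # (n, L)
    region_ids: list[str]
    conditions: list[str]
    perm_p: Optional[np.ndarray] = None
    bootstrap_ratio: Optional[np.ndarray] = None  # (p, L)
    reliable_mask: Optional[np.ndarray] = None  # (p, L) bool
    n_perm: int = 0
    n_boot: int = 0
    seed: Optional[int] = None
    br_threshold: float = DEFAULT_BR_THRESHOLD

    @property
    def n_lv(self) -> int:
        return int(self.singular_values.size)


def br_critical_value(confidence: float = 0.99) -> float:
    """Two-sided standard-normal critical value for a confidence level.

    At 99% this is ~2.576, the conventional bootstrap-ratio cutoff.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return float(scipy.stats.norm.ppf(1 - (1 - confidence) / 2))


def _check_ready(m: ActivityMatrix) -> None:
    if m.has_missing():
        raise ValidationError(
            "matrix has missing values; run cfos_prep.interpolate_missing first"
        )
    if len(m.conditions) < 2:
        raise ValidationError("task PLS needs at least 2 conditions")


def _condition_means(
    values: np.ndarray, condition: np.ndarray, levels: list[str]
) -> np.ndarray:
    return np.stack([values[condition == lev].mean(axis=0) for lev in levels])


def group_mean_center(m: ActivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Condition means M (k x p) and their row-centered version R.

    Centering subtracts the unweighted mean of M's rows, so each column of
    R sums to zero regardless of group sizes.
    """
    _check_ready(m)
    M = _condition_means(m.values, m.condition, m.conditions)
    R = M - M.mean(axis=0)
    return R, M


def fit(m: ActivityMatrix) -> PLSResult:
    """SVD of the centered condition means; keeps the <= k-1 non-null LVs.

    Brain scores project each subject's row (centered by the unweighted
    grand-mean row of M, matching the centering of R) onto the saliences.
    """
    R, M = group_mean_center(m)
    k = R.shape[0]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    L = min(k - 1, s.size)
    if L and s[0] > 0:
        L = int(np.sum(s[:L] > _NULL_SV_RTOL * s[0]))
    else:
        L = 0
    U, s, V = U[:, :L], s[:L], Vt[:L].T
    scores = (m.values - M.mean(axis=0)) @ V
    return PLSResult(
        saliences=V,
        contrasts=U,
        singular_values=s,
        brain_scores=scores,
        region_ids=list(m.region_ids),
        conditions=m.conditions,
    )


def _stream(seed: Optional[int], label: str) -> np.random.Generator:
    # named streams: permutation and bootstrap draws stay independent of
    # one another and of each other's counts
    tag = {"permutation": 1, "bootstrap": 2}[label]
    return np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed, tag)))


def permutation_test(
    m: ActivityMatrix,
    n_perm: int = 500,
    seed: Optional[int] = None,
    result: Optional[PLSResult] = None,
) -> np.ndarray:
    """Permutation p-value per LV by shuffling condition labels.

    Labels are permuted over subjects without replacement; the centering
    and SVD are recomputed each time and the singular value of each LV is
    compared with the observed one. The add-one convention
    p = (1 + #{s_perm >= s_obs}) / (1 + n_perm) keeps p > 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if result is None:
        result = fit(m)
    s_obs = result.singular_values
    if s_obs.size == 0:
        return np.array([])
    rng = _stream(seed, "permutation")
    levels = m.conditions
    values = m.values
    counts = np.zeros(s_obs.size)
    labels = m.condition
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        Mp = _condition_means(values, perm, levels)
        sp = np.linalg.svd(Mp - Mp.mean(axis=0), compute_uv=False)
        counts += sp[: s_obs.size] >= s_obs
    return (1.0 + counts) / (1.0 + n_perm)


def bootstrap_saliences(
    m: ActivityMatrix,
    n_boot: int = 500,
    seed: Optional[int] = None,
    threshold: float = DEFAULT_BR_THRESHOLD,
    result: Optional[PLSResult] = None,
    align: str = "procrustes",
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap ratios for region saliences, resampling within condition.

    Each draw resamples subjects with replacement while keeping them
    assigned to their condition, re-runs the decomposition, and aligns the
    resampled saliences to the original ones — by a full orthogonal
    Procrustes rotation (default), which absorbs the sign and axis-order
    indeterminacy of the SVD, or by a per-LV sign flip (``align='sign'``,
    adequate when L = 1).

    The quantity bootstrapped is the singular-value-weighted salience
    V diag(s) (for two groups this is the centered mean-difference
    pattern itself), the usual task-PLS convention: unit-normalizing each
    draw would shrink its fluctuations and understate the standard error.
    BR is the observed weighted salience divided by the SD of the aligned
    bootstrap values; scale cancels, so thresholds carry over unchanged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if align not in ("procrustes", "sign"):
        raise ValueError(f"unknown align mode {align!r}")
    if result is None:
        result = fit(m)
    V = result.saliences
    if V.shape[1] == 0:
        empty = np.zeros_like(V)
        return empty, empty.astype(bool)
    levels = m.conditions
    idx_by_level = [np.nonzero(m.condition == lev)[0] for lev in levels]
    for lev, idx in zip(levels, idx_by_level):
        if idx.size < 2:
            raise ValidationError(
                f"condition {lev} has a single subject; bootstrap undefined"
            )
    rng = _stream(seed, "bootstrap")
    L = V.shape[1]
    W = V * result.singular_values  # weighted saliences, the bootstrapped scale
    draws = np.empty((n_boot, V.shape[0], L))
    values = m.values
    for b in range(n_boot):
        Mb = np.empty((len(levels), values.shape[1]))
        for gi, idx in enumerate(idx_by_level):
            take = rng.choice(idx, size=idx.size, replace=True)
            Mb[gi] = values[take].mean(axis=0)
        Rb = Mb - Mb.mean(axis=0)
        Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        Wb = Vbt[:L].T * sb[:L]
        if align == "procrustes":
            A = Vbt[:L].T.T @ V  # rotation from the unit saliences
            Ua, _, Vat = np.linalg.svd(A)
            Wb = Wb @ (Ua @ Vat)
        else:
            signs = np.sign(np.einsum("pl,pl->l", Vbt[:L].T, V))
            signs[signs == 0] = 1.0
            Wb = Wb * signs
        draws[b] = Wb
    sd = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        br = np.where(sd > 0, W / sd, np.inf * np.sign(W))
    mask = np.abs(br) > threshold
    return br, mask


def run(
    m: ActivityMatrix,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: Optional[int] = None,
    threshold: float = DEFAULT_BR_THRESHOLD,
    align: str = "procrustes",
) -> PLSResult:
    """Full task PLS: decomposition, permutation test, bootstrap ratios."""
    result = fit(m)
    result.perm_p = permutation_test(m, n_perm=n_perm, seed=seed, result=result)
    result.bootstrap_ratio, result.reliable_mask = bootstrap_saliences(
        m, n_boot=n_boot, seed=seed, threshold=threshold, result=result, align=align
    )
    result.n_perm = n_perm
    result.n_boot = n_boot
    result.seed = seed
    result.br_threshold = threshold
    return result


def reliable_regions(
    result: PLSResult, lv_index: int = 0, threshold: Optional[float] = None
) -> pd.DataFrame:
    """Regions whose |BR| exceeds the cutoff for one LV, strongest first."""
    if result.bootstrap_ratio is None:
        raise ValidationError("run bootstrap_saliences before reliable_regions")
    if not 0 <= lv_index < result.n_lv:
        raise IndexError(f"lv_index {lv_index} out of range for {result.n_lv} LV(s)")
    thr = result.br_threshold if threshold is None else threshold
    br = result.bootstrap_ratio[:, lv_index]
    sal = result.saliences[:, lv_index]
    keep = np.abs(br) > thr
    df = pd.DataFrame(
        {
            "region_id": np.asarray(result.region_ids, dtype=object)[keep],
            "salience": sal[keep],
            "bootstrap_ratio": br[keep],
        }
    )
    return df.reindex(
        df["bootstrap_ratio"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def brainwide_mean_ttest(
    m: ActivityMatrix, condition_a: str, condition_b: str
) -> tuple[float, int, float]:
    """Two-sample Student t on per-subject mean density across regions.

    A coarse univariate companion to the PLS contrast: collapses each
    subject to one number (mean density over all regions) and compares the
    two conditions with a pooled-variance t test.
    """
    _check_ready(m)
    a = m.values[m.condition_mask(condition_a)].mean(axis=1)
    b = m.values[m.condition_mask(condition_b)].mean(axis=1)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 subjects per condition")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise DegenerateInputError("zero pooled variance in brain-wide means")
    return float(t), int(a.size + b.size - 2), float(p)
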