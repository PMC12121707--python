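"""Transcriptomic arm: sex-adjusted per-gene linear model, fold-change DEG
screen, TFBM promoter-prevalence bootstrap, and ddCt qPCR quantification.

Per gene, log2(TPM + offset) is regressed on an intercept, a group
indicator (opener vs nonopener) and a sex indicator; the group coefficient
is a log2 fold change (FC = 2^beta). Genes at |FC| >= 1.5 (inclusive) are
screened as up/down DEGs. Transcription-factor binding-motif prevalence is
compared between up- and down-regulated promoter sets as a log2 ratio of
mean motif counts, with standard errors from a residual-vector bootstrap
across genes: whole per-gene residual vectors are reassigned to fitted
values (keeping within-gene, across-sample dependence intact), the model
and DEG screen are re-run, and the motif statistic recomputed each cycle.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from helpnet.data_model import (
    CtRecord,
    DegenerateInputError,
    ExpressionMatrix,
    TFBMMatrix,
    ValidationError,
)

__all__ = [
    "DEGResult",
    "TFBMResult",
    "DDCtResult",
    "CollinearDesignError",
    "fit_deg_model",
    "select_degs",
    "tfbm_statistic",
    "tfbm_bootstrap",
    "ddct_fold_change",
    "group_ttest",
]

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_TFBM_EPSILON = 0.5
DEFAULT_TFBM_CYCLES = 200


class CollinearDesignError(ValidationError):
    """The model design is rank-deficient (e.g. sex confounded with group)."""


@dataclass
class DEGResult:
    """Per-gene estimates from the group + sex linear model."""

    gene_ids: list[str]
    beta_group: np.ndarray  # log2 units
    t_stat: np.ndarray
    p: np.ndarray
    residuals: np.ndarray  # (g, m), kept for the TFBM bootstrap
    fitted: np.ndarray  # (g, m) on the log2 scale
    design: np.ndarray  # (m, 3): intercept, group, sex
    df_resid: int
    threshold: float = DEFAULT_FC_THRESHOLD
    p_bh: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p_bh is None:
            self.p_bh = multipletests(self.p, method="fdr_bh")[1]

    @property
    def fold_change(self) -> np.ndarray:
        return np.exp2(self.beta_group)

    @property
    def direction(self) -> np.ndarray:
        fc = self.fold_change
        out = np.full(fc.shape, "none", dtype=object)
        out[fc >= self.threshold] = "up"
        out[fc <= 1.0 / self.threshold] = "down"
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "beta_group": self.beta_group,
                "fold_change": self.fold_change,
                "t_stat": self.t_stat,
                "p": self.p,
                "p_bh": self.p_bh,
                "direction": self.direction,
            }
        ).sort_values("fold_change", ascending=False, kind="mergesort").reset_index(
            drop=True
        )


@dataclass
class TFBMResult:
    """Per-motif prevalence statistics with bootstrap standard errors."""

    motif_ids: list[str]
    statistic: np.ndarray  # log2 up-vs-down mean-count ratio
    boot_se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_cycles: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_id": self.motif_ids,
                "statistic": self.statistic,
                "boot_se": self.boot_se,
                "z": self.z,
                "p": self.p,
            }
        )


@dataclass
class DDCtResult:
    """Per-sample ddCt fold changes plus group summaries."""

    samples: pd.DataFrame  # sample_id, group, delta_ct, delta_delta_ct, fold_change
    reference_group: str
    group_summary: pd.DataFrame  # group, mean_fc, sem_fc, n


def _design(e: ExpressionMatrix) -> tuple[np.ndarray, str, str]:
    groups = sorted(set(e.group))
    sexes = sorted(set(e.sex))
    # group indicator: 1 for "opener" if present, else the second level
    g1 = "opener" if "opener" in groups else groups[-1]
    s1 = "male" if "male" in sexes else sexes[-1]
    X = np.column_stack(
        [
            np.ones(e.n_samples),
            (e.group == g1).astype(float),
            (e.sex == s1).astype(float),
        ]
    )
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearDesignError(
            "design is rank-deficient: sex is confounded with group "
            f"(groups={groups}, sexes={sexes})"
        )
    return X, g1, s1


def fit_deg_model(
    e: ExpressionMatrix, threshold: float = DEFAULT_FC_THRESHOLD
) -> DEGResult:
    """OLS of log2(TPM + offset) on intercept + group + sex, per gene.

    The group coefficient is the log2 fold change of the focal group
    ("opener" when that label is present) over the other, adjusted for
    sex; t statistics use m - 3 residual degrees of freedom. Residual
    vectors are retained for the TFBM bootstrap.
    """
    if e.n_samples < 4:
        raise ValidationError("need at least 4 samples to fit the model")
    X, _, _ = _design(e)
    Y = e.log2_abundance()  # (g, m)
    beta, fitted, resid = _ols(X, Y)
    m = e.n_samples
    df = m - 3
    xtx_inv = np.linalg.inv(X.T @ X)
    rss = np.einsum("gm,gm->g", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, 0.0)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return DEGResult(
        gene_ids=list(e.gene_ids),
        beta_group=beta[:, 1],
        t_stat=t,
        p=p,
        residuals=resid,
        fitted=fitted,
        design=X,
        df_resid=df,
        threshold=threshold,
    )


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares of each row of Y (g x m) on X (m x q)."""
    pinv = np.linalg.pinv(X)  # (q, m)
    beta = Y @ pinv.T  # (g, q)
    fitted = beta @ X.T
    return beta, fitted, Y - fitted


def select_degs(
    d: DEGResult, threshold: Optional[float] = None
) -> tuple[list[str], list[str], dict[str, int]]:
    """Partition genes into up/down lists by the fold-change screen.

    The boundary is inclusive: a gene at exactly the threshold fold change
    counts as differentially expressed.
    """
    thr = d.threshold if threshold is None else threshold
    if thr <= 1:
        raise ValueError(f"fold-change threshold must exceed 1, got {thr}")
    fc = np.exp2(d.beta_group)
    genes = np.asarray(d.gene_ids, dtype=object)
    up = list(genes[fc >= thr])
    down = list(genes[fc <= 1.0 / thr])
    return up, down, {"up": len(up), "down": len(down), "total": len(up) + len(down)}


def top_degs(d: DEGResult, n: int = 10) -> pd.DataFrame:
    """Top-n up- and down-regulated genes by |log2 fold change|."""
    df = d.to_frame()
    return pd.concat([df.head(n), df.tail(n)]).reset_index(drop=True)


def tfbm_statistic(
    t: TFBMMatrix,
    up: Sequence[str],
    down: Sequence[str],
    epsilon: float = DEFAULT_TFBM_EPSILON,
) -> np.ndarray:
    """Per-motif log2 ratio of mean promoter counts, up vs down genes.

    statistic_m = log2((mean count over up promoters + eps) /
                       (mean count over down promoters + eps)).
    Positive values mean the motif is more prevalent in promoters of
    up-regulated genes.
    """
    if len(up) == 0 or len(down) == 0:
        raise ValidationError("up and down gene sets must both be non-empty")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    mean_up = t.subset(list(up)).mean(axis=0)
    mean_down = t.subset(list(down)).mean(axis=0)
    with np.errstate(divide="ignore"):
        return np.log2(mean_up + epsilon) - np.log2(mean_down + epsilon)


def tfbm_bootstrap(
    e: ExpressionMatrix,
    d: DEGResult,
    t: TFBMMatrix,
    n_cycles: int = DEFAULT_TFBM_CYCLES,
    seed: Optional[int] = None,
    epsilon: float = DEFAULT_TFBM_EPSILON,
    max_skip_fraction: float = 0.2,
) -> TFBMResult:
    """Bootstrap SEs for the TFBM statistic by resampling genes.

    Each cycle draws genes with replacement; every drawn gene carries its
    whole fitted + residual vector (so within-gene dependence across
    samples stays intact) and its promoter motif counts. The linear model
    is re-evaluated on the resampled pseudo-data, the fold-change screen
    re-derives the up/down sets, and the statistic is recomputed. The SD
    of the statistic over cycles estimates its gene-sampling standard
    error without assuming genes are independent or counts follow any
    parametric model.

    Two superficially similar schemes fail and are deliberately not used:
    reassigning per-gene residual vectors to other genes' fitted values
    changes no coefficient at all (OLS residuals are orthogonal to the
    design), and resampling per-sample residual vectors conditions on the
    observed motif counts of the stably-selected genes, understating the
    null SE several-fold.

    Cycles whose pseudo-data yield an empty up or down set are skipped
    with a warning; more than ``max_skip_fraction`` skipped is an error.
    z = statistic / SE and p = 2 Phi(-|z|).
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    up, down, _ = select_degs(d)
    observed = tfbm_statistic(t, up, down, epsilon=epsilon)
    gene_index = {gid: i for i, gid in enumerate(t.gene_ids)}
    missing = [g for g in d.gene_ids if g not in gene_index]
    if missing:
        raise ValidationError(f"genes absent from TFBM matrix: {missing[:5]}")
    counts = t.subset(list(d.gene_ids))  # aligned to the expression genes
    g = len(d.gene_ids)
    rng = np.random.default_rng(
        np.random.SeedSequence((0 if seed is None else seed, 3))
    )
    thr_log2 = np.log2(d.threshold)
    pinv_row1 = np.linalg.pinv(d.design)[1]  # only beta_group is needed
    data = d.fitted + d.residuals  # the observed log2 responses
    stats = []
    n_skipped = 0
    for _ in range(n_cycles):
        take = rng.integers(0, g, size=g)
        beta_g = data[take] @ pinv_row1
        ctake = counts[take]
        up_mask = beta_g >= thr_log2
        down_mask = beta_g <= -thr_log2
        if not up_mask.any() or not down_mask.any():
            n_skipped += 1
            continue
        mean_up = ctake[up_mask].mean(axis=0)
        mean_down = ctake[down_mask].mean(axis=0)
        stats.append(np.log2(mean_up + epsilon) - np.log2(mean_down + epsilon))
    if n_skipped:
        warnings.warn(
            f"{n_skipped}/{n_cycles} bootstrap cycles produced an empty DEG set "
            "and were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_skipped > max_skip_fraction * n_cycles:
        raise ValidationError(
            f"{n_skipped}/{n_cycles} bootstrap cycles skipped (> "
            f"{max_skip_fraction:.0%}); DEG signal too weak for the bootstrap"
        )
    arr = np.asarray(stats)
    boot_se = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(boot_se > 0, observed / boot_se, np.inf * np.sign(observed))
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return TFBMResult(
        motif_ids=list(t.motif_ids),
        statistic=observed,
        boot_se=boot_se,
        z=z,
        p=np.clip(p, np.finfo(float).tiny, 1.0),
        n_cycles=n_cycles,
        n_skipped=n_skipped,
    )


def ddct_fold_change(
    records: Sequence[CtRecord], reference_group: str = "nonopener"
) -> DDCtResult:
    """Comparative ddCt quantification relative to a reference group.

    Per sample, dCt = Ct_target - Ct_reference normalizes to the
    housekeeping gene; ddCt subtracts the reference group's mean dCt; fold
    change = 2^(-ddCt). By construction the reference group's geometric
    mean fold change is exactly 1.
    """
    if not records:
        raise ValidationError("empty Ct table")
    groups = {r.group for r in records}
    if reference_group not in groups:
        raise ValidationError(
            f"reference group {reference_group!r} absent (groups: {sorted(groups)})"
        )
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "delta_ct": [r.ct_target - r.ct_reference for r in records],
        }
    )
    ref_mean = df.loc[df["group"] == reference_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - ref_mean
    df["fold_change"] = np.exp2(-df["delta_delta_ct"])
    summary = (
        df.groupby("group", sort=False)["fold_change"]
        .agg(mean_fc="mean", sem_fc=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="size")
        .reset_index()
    )
    return DDCtResult(samples=df, reference_group=reference_group, group_summary=summary)


def group_ttest(values, groups) -> tuple[float, int, float]:
    """Student two-sample t (pooled variance) with two-sided p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 samples per group")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise DegenerateInputError("zero pooled variance")
    return float(t), int(a.size + b.size - 2), float(p)
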