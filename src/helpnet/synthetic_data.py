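"""Seeded synthetic generators for every pipeline input, with ground truth.

Each generator is a pure function of its parameters and seed and returns,
alongside the data, a :class:`GroundTruth` record holding the planted
effects exactly as used, so parameter-recovery tests read effects from the
generated object and never from hard-coded constants.

Default dimensions mirror the scale of the study the pipeline was built
for: 137 brain regions, a 13-subject c-Fos cohort (9 openers / 4
nonopeners), 32 behavioral pairs tested over 12 days, and a 20-sample
expression design balanced over group and sex. Densities and
log2-expression use Gaussian noise (truncated at zero for densities — a
mild deviation from normality that is negligible at the effect sizes
used); promoter motif counts are Poisson.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from helpnet.data_model import (
    BoldnessRecord,
    CtRecord,
    ExpressionMatrix,
    RegionActivityRecord,
    SessionRecord,
    SocialInteractionSummary,
    TFBMMatrix,
)

__all__ = [
    "GroundTruth",
    "gen_cfos",
    "gen_behavior",
    "gen_expression",
    "gen_ct",
]


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset."""

    seed: int
    salient_regions: dict[str, float] = field(default_factory=dict)
    opener_fraction: Optional[float] = None
    openers: list[str] = field(default_factory=list)
    learning_day: dict[str, int] = field(default_factory=dict)
    planted_degs: dict[str, float] = field(default_factory=dict)
    enriched_motifs: dict[str, float] = field(default_factory=dict)
    si_latency_slope: Optional[float] = None
    group_shift_cycles: Optional[float] = None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


# ---------------------------------------------------------------------------
# c-Fos region activity


def gen_cfos(
    n_per_condition: Mapping[str, int] | None = None,
    p_regions: int = 137,
    n_salient: int = 10,
    effect: float = 1.5,
    sigma: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    salient_regions: Optional[Sequence[str]] = None,
) -> tuple[list[RegionActivityRecord], dict[str, str], GroundTruth]:
    """Group-structured region activity with a planted salient subset.

    Densities are Normal(mu_region + effect * sigma for salient regions in
    openers, sigma), truncated at zero; counts and sampled areas are
    back-computed so that the count * 250 / area density convention
    reproduces the drawn densities. ``missing_rate`` removes cells
    uniformly at random (at most 30%).
    """
    if n_per_condition is None:
        n_per_condition = {"opener": 9, "nonopener": 4}
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 <= missing_rate <= 0.3:
        raise ValueError("missing_rate must be in [0, 0.3]")
    rng = _rng(seed)
    region_ids = [f"R{j:03d}" for j in range(p_regions)]
    if salient_regions is None:
        salient = list(rng.choice(region_ids, size=n_salient, replace=False))
    else:
        salient = [str(r) for r in salient_regions]
    salient_set = set(salient)
    mu = rng.uniform(5.0, 15.0, size=p_regions)

    subjects: list[tuple[str, str]] = []
    for cond, n in n_per_condition.items():
        subjects += [(f"{cond[:4]}{i:02d}", cond) for i in range(n)]
    conditions = dict(subjects)

    is_salient = np.array([r in salient_set for r in region_ids])
    records: list[RegionActivityRecord] = []
    for subj, cond in subjects:
        bump = effect * sigma if cond == "opener" else 0.0
        dens = rng.normal(mu + bump * is_salient, sigma)
        dens = np.clip(dens, 0.0, None)
        keep = rng.random(p_regions) >= missing_rate
        for j, rid in enumerate(region_ids):
            if not keep[j]:
                continue
            d = dens[j]
            if d <= 0:
                count, area = 0, 1000.0
            else:
                count = max(1, int(round(d * 4)))  # ~1000 um^2 nominal sample
                area = count * 250.0 / d
            records.append(
                RegionActivityRecord(
                    subject_id=subj, region_id=rid, cfos_count=count, sampled_area=area
                )
            )
    truth = GroundTruth(
        seed=seed,
        salient_regions={r: effect for r in salient},
        params={
            "n_per_condition": dict(n_per_condition),
            "p_regions": p_regions,
            "effect": effect,
            "sigma": sigma,
            "missing_rate": missing_rate,
        },
    )
    return records, conditions, truth


# ---------------------------------------------------------------------------
# Behavior


def gen_behavior(
    n_pairs: int = 32,
    opener_fraction: float = 0.4375,
    n_days: int = 12,
    si_latency_slope: float = -0.4,
    seed: int = 0,
) -> tuple[
    dict[str, list[SessionRecord]],
    dict[str, list[BoldnessRecord]],
    list[SocialInteractionSummary],
    GroundTruth,
]:
    """Door-opening learning curves with a configurable opener fraction.

    Designated openers draw a learning day (centered near day 5) and open
    on every later day with decreasing latency — guaranteeing >= 2
    openings in the final 3 days — while non-openers open at most once and
    never in the final 3 days. Social-interaction counts are negatively
    coupled to the pair's mean opening latency with slope
    ``si_latency_slope`` (counts per minute of latency) plus noise.
    """
    if not 0 <= opener_fraction <= 1:
        raise ValueError("opener_fraction must be in [0, 1]")
    if n_days < 4:
        raise ValueError("need at least 4 testing days")
    rng = _rng(seed)
    n_openers = int(round(opener_fraction * n_pairs))
    pair_ids = [f"pair{i:02d}" for i in range(n_pairs)]
    opener_flags = np.zeros(n_pairs, dtype=bool)
    opener_flags[rng.choice(n_pairs, size=n_openers, replace=False)] = True

    sessions: dict[str, list[SessionRecord]] = {}
    boldness: dict[str, list[BoldnessRecord]] = {}
    si: list[SocialInteractionSummary] = []
    learning_day: dict[str, int] = {}
    mean_latencies: dict[str, float] = {}

    for pid, is_opener in zip(pair_ids, opener_flags):
        log: list[SessionRecord] = []
        if is_opener:
            lday = int(np.clip(round(rng.normal(5.0, 1.5)), 2, n_days - 2))
            learning_day[pid] = lday
            for day in range(1, n_days + 1):
                if day < lday:
                    log.append(SessionRecord(pid, day, opened_by_free=False))
                else:
                    lat = 20.0 * np.exp(-0.35 * (day - lday)) + rng.uniform(0.5, 3.0)
                    lat = float(np.clip(lat, 0.2, 39.5))
                    log.append(
                        SessionRecord(pid, day, opened_by_free=True, latency=lat)
                    )
        else:
            # at most one stray opening, never in the final 3 days
            stray = rng.integers(1, n_days - 3) if rng.random() < 0.3 else None
            for day in range(1, n_days + 1):
                if stray is not None and day == stray:
                    log.append(
                        SessionRecord(
                            pid,
                            day,
                            opened_by_free=True,
                            latency=float(rng.uniform(20.0, 39.5)),
                        )
                    )
                else:
                    log.append(SessionRecord(pid, day, opened_by_free=False))
        sessions[pid] = log
        lats = [r.latency if r.opened_by_free else 40.0 for r in log]
        mean_latencies[pid] = float(np.mean(lats))

        # boldness: the designated free rat peeks first on >= 3 of 5 days
        free_id, trapped_id = f"{pid}_F", f"{pid}_T"
        n_first = int(rng.integers(3, 6))
        first_days = set(rng.choice(np.arange(1, 6), size=n_first, replace=False))
        blog: list[BoldnessRecord] = []
        for day in range(1, 6):
            base = float(rng.uniform(30.0, 150.0))
            if day in first_days:
                f_lat, t_lat = base, base * float(rng.uniform(1.3, 2.0))
            else:
                f_lat, t_lat = base * float(rng.uniform(1.3, 2.0)), base
            for rid, lat in ((free_id, f_lat), (trapped_id, t_lat)):
                lat = float(min(lat, 300.0))
                blog.append(
                    BoldnessRecord(
                        pid, rid, day, peek_latency=lat, peeked=lat < 300.0
                    )
                )
        boldness[pid] = blog

        # social interaction coupled to helping latency
        for session in ("pre_HBT", "first_HBT"):
            coupling = si_latency_slope if session == "first_HBT" else 0.0
            count = max(
                0,
                int(round(20.0 + coupling * mean_latencies[pid] + rng.normal(0, 2.0))),
            )
            duration = 0.0 if count == 0 else float(
                count * rng.uniform(2.0, 5.0)
            )
            si.append(
                SocialInteractionSummary(
                    pair_id=pid,
                    session=session,
                    si_count=count,
                    si_duration=duration,
                )
            )

    truth = GroundTruth(
        seed=seed,
        opener_fraction=opener_fraction,
        openers=[p for p, f in zip(pair_ids, opener_flags) if f],
        learning_day=learning_day,
        si_latency_slope=si_latency_slope,
        params={"n_pairs": n_pairs, "n_days": n_days},
    )
    return sessions, boldness, si, truth


# ---------------------------------------------------------------------------
# Expression + TFBM


def gen_expression(
    g_genes: int = 2000,
    n_per_group_per_sex: int = 5,
    planted_degs: Optional[Mapping[str, float]] = None,
    n_up: int = 50,
    n_down: int = 30,
    deg_log2_effect: float = 1.0,
    sex_effect: float = 0.5,
    sigma: float = 0.25,
    n_motifs: int = 50,
    enriched_motifs: Optional[Mapping[str, float]] = None,
    n_enriched_motifs: int = 5,
    motif_enrichment: float = 4.0,
    log_offset: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TFBMMatrix, GroundTruth]:
    """Expression with planted fold changes, a sex covariate, and motif
    counts enriched in planted up-DEG promoters.

    log2 expression = baseline + effect * 1[opener] + sex_effect * 1[male]
    + Normal(0, sigma); TPM = max(2^log2 - offset, 0) so that the model's
    log2(TPM + offset) transform recovers the linear structure. Motif
    counts are Poisson with the rate multiplied by the enrichment factor
    for enriched motifs in planted up-regulated promoters.
    """
    if g_genes < 10:
        raise ValueError("need at least 10 genes for a stable bootstrap")
    rng = _rng(seed)
    gene_ids = [f"G{j:04d}" for j in range(g_genes)]
    if planted_degs is None:
        if n_up + n_down > g_genes:
            raise ValueError("n_up + n_down cannot exceed g_genes")
        chosen = rng.choice(g_genes, size=n_up + n_down, replace=False)
        planted_degs = {gene_ids[j]: deg_log2_effect for j in chosen[:n_up]}
        planted_degs.update(
            {gene_ids[j]: -deg_log2_effect for j in chosen[n_up : n_up + n_down]}
        )
    effects = np.array([planted_degs.get(g, 0.0) for g in gene_ids])

    m = 4 * n_per_group_per_sex
    group = np.array(
        ["opener"] * (2 * n_per_group_per_sex) + ["nonopener"] * (2 * n_per_group_per_sex),
        dtype=object,
    )
    sex = np.array(
        (["male"] * n_per_group_per_sex + ["female"] * n_per_group_per_sex) * 2,
        dtype=object,
    )
    sample_ids = [f"s{i:02d}_{g[:4]}_{x[0]}" for i, (g, x) in enumerate(zip(group, sex))]

    baseline = rng.uniform(3.0, 9.0, size=g_genes)
    log2_expr = (
        baseline[:, None]
        + effects[:, None] * (group == "opener")[None, :]
        + sex_effect * (sex == "male")[None, :]
        + rng.normal(0.0, sigma, size=(g_genes, m))
    )
    tpm = np.clip(np.exp2(log2_expr) - log_offset, 0.0, None)
    e = ExpressionMatrix(
        abundance=tpm,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        group=group,
        sex=sex,
        log_offset=log_offset,
    )

    motif_ids = [f"M{j:02d}" for j in range(n_motifs)]
    if enriched_motifs is None:
        chosen_m = rng.choice(n_motifs, size=n_enriched_motifs, replace=False)
        enriched_motifs = {motif_ids[j]: motif_enrichment for j in chosen_m}
    rates = rng.uniform(0.5, 3.0, size=n_motifs)
    up_genes = {g for g, eff in planted_degs.items() if eff > 0}
    lam = np.tile(rates, (g_genes, 1))
    up_rows = np.array([g in up_genes for g in gene_ids])
    for mid, factor in enriched_motifs.items():
        j = motif_ids.index(mid)
        lam[up_rows, j] *= factor
    counts = rng.poisson(lam).astype(float)
    t = TFBMMatrix(counts=counts, gene_ids=gene_ids, motif_ids=motif_ids)

    truth = GroundTruth(
        seed=seed,
        planted_degs=dict(planted_degs),
        enriched_motifs=dict(enriched_motifs),
        params={
            "g_genes": g_genes,
            "n_per_group_per_sex": n_per_group_per_sex,
            "sex_effect": sex_effect,
            "sigma": sigma,
            "n_motifs": n_motifs,
            "log_offset": log_offset,
        },
    )
    return e, t, truth


# ---------------------------------------------------------------------------
# qPCR


def gen_ct(
    n_per_group: int = 5,
    group_shift_cycles: float = 1.0,
    sigma: float = 0.25,
    seed: int = 0,
    baseline_delta_ct: float = 6.0,
) -> tuple[list[CtRecord], GroundTruth]:
    """Ct tables with a planted group shift in dCt.

    dCt ~ Normal(baseline - shift * 1[opener], sigma); a shift of one
    cycle corresponds to a twofold expression increase in openers.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _rng(seed)
    records: list[CtRecord] = []
    for group in ("nonopener", "opener"):
        shift = group_shift_cycles if group == "opener" else 0.0
        for i in range(n_per_group):
            ct_ref = float(rng.normal(18.0, 0.3))
            dct = float(rng.normal(baseline_delta_ct - shift, sigma))
            records.append(
                CtRecord(
                    sample_id=f"{group[:4]}{i:02d}",
                    group=group,
                    ct_target=ct_ref + dct,
                    ct_reference=ct_ref,
                )
            )
    truth = GroundTruth(
        seed=seed,
        group_shift_cycles=group_shift_cycles,
        params={"n_per_group": n_per_group, "sigma": sigma},
    )
    return records, truth
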