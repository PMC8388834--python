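"""Relative competitive fitness from AUC ratios, with group comparisons.

Relative fitness of a focal strain under a condition is the ratio of its
fluorescence AUC in that condition to the mean fluorescence AUC of the same
strain grown as a monoculture.  Fluorescence — not optical density — carries
the strain identity: in a mixed culture only a strain-specific reporter can
attribute growth to one strain.  Conditions are compared with a one-way
ANOVA and Bonferroni-corrected post-hoc t tests of each condition against
the monoculture reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NormalizationError

__all__ = [
    "AnovaResult",
    "FitnessResult",
    "fitness_from_metrics",
    "one_way_anova",
    "relative_fitness",
]


@dataclass
class FitnessResult:
    focal_strain: str
    channel: str
    condition: str
    replicate_ratios: np.ndarray
    mean_ratio: float
    sd_ratio: float
    monoculture_auc_mean: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    #: (group_pair, raw_p, bonferroni_p) per post-hoc comparison
    posthoc: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)


def relative_fitness(
    condition_aucs,
    monoculture_aucs,
    focal_strain: str = "",
    channel: str = "",
    condition: str = "",
) -> FitnessResult:
    """Per-replicate AUC ratios against the monoculture mean AUC.

    Each replicate ratio is ``condition AUC / mean(monoculture AUCs)``;
    monoculture wells evaluated against their own group mean therefore have
    a mean ratio of exactly 1.  The ratios are scale-invariant: rescaling
    every AUC by the same factor leaves them unchanged.
    """
    cond = np.asarray(condition_aucs, dtype=float)
    mono = np.asarray(monoculture_aucs, dtype=float)
    if cond.size == 0 or mono.size == 0:
        raise InsufficientDataError("empty AUC sequence")
    mono_mean = float(np.mean(mono))
    if not mono_mean > 0:
        raise NormalizationError(
            f"monoculture mean AUC must be positive, got {mono_mean}"
        )
    ratios = cond / mono_mean
    return FitnessResult(
        focal_strain=focal_strain,
        channel=channel,
        condition=condition,
        replicate_ratios=ratios,
        mean_ratio=float(np.mean(ratios)),
        sd_ratio=float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0,
        monoculture_auc_mean=mono_mean,
    )


def one_way_anova(
    groups: dict[str, np.ndarray],
    reference: str | None = None,
    all_pairs: bool = False,
) -> AnovaResult:
    """Classical one-way ANOVA plus Bonferroni post-hoc t tests.

    ``groups`` maps condition label to replicate values.  Post-hoc tests are
    pooled-variance two-sided t tests of each group against ``reference``
    (the monoculture), Bonferroni-multiplied by the number of reference
    comparisons; with ``all_pairs`` every pair is tested and the multiplier
    widens accordingly.  Identical constant groups yield F=0, p=1 rather
    than NaN.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InsufficientDataError("need >=2 groups with >=2 values each")
    n_total = sum(a.size for a in arrays)
    if n_total <= len(arrays):
        raise InsufficientDataError("total n must exceed the number of groups")

    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:  # all values identical: define F=0, p=1
        f_stat, p_val = 0.0, 1.0
    else:
        res = stats.f_oneway(*arrays)
        f_stat, p_val = float(res.statistic), float(res.pvalue)
        if not np.isfinite(f_stat):  # zero within-group variance, means differ
            f_stat, p_val = float("inf"), np.finfo(float).tiny

    if all_pairs:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        ref = reference if reference is not None else labels[0]
        if ref not in groups:
            raise InsufficientDataError(f"reference group {ref!r} not present")
        pairs = [(ref, g) for g in labels if g != ref]

    posthoc = []
    for a, b in pairs:
        res = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        raw = float(res.pvalue)
        if not np.isfinite(raw):  # two identical constant groups
            raw = 1.0
        posthoc.append(((a, b), raw, min(1.0, raw * len(pairs))))

    return AnovaResult(
        f_statistic=f_stat,
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p_value=min(max(p_val, np.finfo(float).tiny), 1.0),
        posthoc=posthoc,
    )


def fitness_from_metrics(
    metrics: pd.DataFrame,
    focal_strain: str,
    channel: str,
    monoculture_condition: str,
    all_pairs: bool = False,
) -> tuple[list[FitnessResult], AnovaResult | None, pd.DataFrame]:
    """Fitness of one strain across all conditions in a metrics table.

    Selects the focal strain's rows for its reporter channel, normalizes
    every condition's per-well AUCs by the monoculture mean AUC, and runs
    the ANOVA across the resulting ratio groups with the monoculture as
    post-hoc reference.  Returns the per-condition results, the ANOVA
    (``None`` for a monoculture-only design, where there is nothing to
    compare), and a tidy per-condition summary frame.
    """
    sel = metrics[
        (metrics["strain"] == focal_strain) & (metrics["channel"] == channel)
    ]
    if sel.empty:
        raise InsufficientDataError(
            f"no rows for strain {focal_strain!r} on channel {channel!r}"
        )
    by_cond = {c: g["auc"].to_numpy() for c, g in sel.groupby("condition", sort=True)}
    if monoculture_condition not in by_cond:
        raise InsufficientDataError(
            f"monoculture condition {monoculture_condition!r} not present"
        )
    mono = by_cond[monoculture_condition]
    results = [
        relative_fitness(
            by_cond[c], mono, focal_strain=focal_strain, channel=channel, condition=c
        )
        for c in by_cond
    ]
    ratio_groups = {r.condition: r.replicate_ratios for r in results}
    if len(ratio_groups) >= 2:
        anova = one_way_anova(
            ratio_groups, reference=monoculture_condition, all_pairs=all_pairs
        )
    else:  # monoculture-only design: nothing to compare
        anova = None
    table = pd.DataFrame(
        {
            "focal_strain": focal_strain,
            "channel": channel,
            "condition": [r.condition for r in results],
            "n_replicates": [r.replicate_ratios.size for r in results],
            "mean_ratio": [r.mean_ratio for r in results],
            "sd_ratio": [r.sd_ratio for r in results],
            "monoculture_auc_mean": [r.monoculture_auc_mean for r in results],
        }
    )
    return results, anova, table
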