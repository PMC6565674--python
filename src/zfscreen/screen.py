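"""Dose-response evaluation of mono- and polytherapy conditions.

Candidate combinations from the fingerprint selection are evaluated over a
semi-log dose grid (10, 30, 100% of the screening concentration by
default). Each condition gets an efficacy score (mean per-larva seizure
reduction from paired baseline/post LFP recordings) and a side-effect
score (RMS behavioral divergence from the untreated baseline group), and
polytherapy conditions are compared against their same-dose monotherapies
with unpaired two-tailed t-tests on the per-larva efficacy values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import SideEffectScore, side_effect_score
from .lfp import SeizureCallSet, SeizureDetector, detect_seizures, efficacy_score
from .synth.lfp import LFPTrace

logger = logging.getLogger(__name__)

DEFAULT_DOSES = (0.1, 0.3, 1.0)


@dataclass(frozen=True)
class TreatmentCondition:
    """One or two compounds at per-compound dose fractions."""

    compounds: tuple[str, ...]
    doses: tuple[float, ...]
    n_larvae: int = 5

    def __post_init__(self) -> None:
        if not 1 <= len(self.compounds) <= 2:
            raise ValueError("1 or 2 compounds per condition")
        if len(self.doses) != len(self.compounds):
            raise ValueError("one dose per compound")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")

    @property
    def label(self) -> str:
        return "+".join(
            f"{c}@{int(round(d * 100))}%" for c, d in zip(self.compounds, self.doses)
        )


@dataclass
class ConditionScores:
    condition: TreatmentCondition
    efficacy_mean: float
    efficacy_sd: float
    per_larva_efficacy: np.ndarray
    side_effect: SideEffectScore | None = None


def condition_grid(
    compounds: list[str], doses: tuple[float, ...] = DEFAULT_DOSES, n_larvae: int = 5
) -> list[TreatmentCondition]:
    """All monotherapies plus pairwise dose combinations.

    For ``m`` compounds and ``k`` doses: m*k monotherapy rows plus
    C(m, 2) * k^2 pairwise rows (e.g. 2 compounds x 3 doses -> 6 + 9 = 15).
    """
    conds = [
        TreatmentCondition((c,), (d,), n_larvae) for c in compounds for d in doses
    ]
    for a, b in combinations(compounds, 2):
        for da, db in product(doses, doses):
            conds.append(TreatmentCondition((a, b), (da, db), n_larvae))
    return conds


def evaluate_condition(
    cond: TreatmentCondition,
    lfp_pairs: list[tuple[LFPTrace, LFPTrace]],
    detector: SeizureDetector,
    behavior_treated: pd.DataFrame | None = None,
    behavior_baseline: pd.DataFrame | None = None,
) -> ConditionScores:
    """Score one condition from per-larva (baseline, post) LFP recordings
    and optional behavioral feature tables.

    Larvae with zero detected baseline seizures are excluded (logged).
    """
    if len(lfp_pairs) < 5:
        logger.warning(
            "condition %s: only %d larvae for efficacy (5+ expected)",
            cond.label, len(lfp_pairs),
        )
    scores = []
    for baseline, post in lfp_pairs:
        calls_base = detect_seizures(baseline, detector)
        calls_post = detect_seizures(post, detector)
        if calls_base.frequency == 0:
            logger.warning("condition %s: larva with 0 baseline seizures excluded", cond.label)
            continue
        scores.append(efficacy_score(calls_base, calls_post).score)
    if not scores:
        raise ValueError(f"condition {cond.label}: no larva with nonzero baseline seizures")
    arr = np.asarray(scores)
    se = None
    if behavior_treated is not None and behavior_baseline is not None:
        if len(behavior_treated) < 10:
            logger.warning(
                "condition %s: only %d larvae for side effect (10 expected)",
                cond.label, len(behavior_treated),
            )
        se = side_effect_score(behavior_treated, behavior_baseline)
    return ConditionScores(
        condition=cond,
        efficacy_mean=float(arr.mean()),
        efficacy_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        per_larva_efficacy=arr,
        side_effect=se,
    )


def scores_from_callsets(
    cond: TreatmentCondition,
    call_pairs: list[tuple[SeizureCallSet, SeizureCallSet]],
) -> ConditionScores:
    """Score a condition from precomputed seizure call sets."""
    scores = [
        efficacy_score(b, p).score for b, p in call_pairs if b.frequency > 0
    ]
    if not scores:
        raise ValueError("no larva with nonzero baseline seizures")
    arr = np.asarray(scores)
    return ConditionScores(
        condition=cond,
        efficacy_mean=float(arr.mean()),
        efficacy_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        per_larva_efficacy=arr,
    )


def dose_response_table(results: list[ConditionScores]) -> pd.DataFrame:
    """Tidy per-condition summary of the dose grid."""
    rows = []
    for r in results:
        rows.append({
            "condition": r.condition.label,
            "compounds": "+".join(r.condition.compounds),
            "doses": "+".join(str(d) for d in r.condition.doses),
            "n_larvae": len(r.per_larva_efficacy),
            "efficacy_mean": r.efficacy_mean,
            "efficacy_sd": r.efficacy_sd,
            "side_effect": r.side_effect.x_combined if r.side_effect else np.nan,
            "side_effect_sd": r.side_effect.sd if r.side_effect else np.nan,
        })
    return pd.DataFrame(rows)


def compare_poly_vs_mono(
    combo: ConditionScores, components: list[ConditionScores]
) -> dict[str, float]:
    """Unpaired two-tailed t-tests of a combination against each same-dose
    monotherapy's per-larva efficacy values."""
    out: dict[str, float] = {}
    for mono in components:
        if len(combo.per_larva_efficacy) < 2 or len(mono.per_larva_efficacy) < 2:
            raise ValueError("need >= 2 larvae per group for the t-test")
        t = stats.ttest_ind(combo.per_larva_efficacy, mono.per_larva_efficacy)
        out[mono.condition.label] = float(t.pvalue)
    return out
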