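"""Cross-dataset, cross-species miRNA candidate cascade.

A miRNA becomes a candidate when it

1. is expressed (mean RPM above threshold) in both human datasets and the
   mouse dataset;
2. changes by more than ``both_change`` in both human datasets, OR changes
   at least ``single_fold``-fold in exactly one human dataset while staying
   inside a no-change band in the other;
3. changes by more than ``mouse_change`` in the mouse dataset;
4. changes in the same direction in all three datasets;
5. has no other miRNA in the supplied human catalog with the same seed
   (no paralog).

"Changes by more than f" is symmetric on the ratio scale: fc >= 1+f or
fc <= 1/(1+f), boundaries inclusive.  Fold changes are computed on group
mean RPM after adding a pseudocount to both means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quant import mean_rpm_filter
from .seeds import MatureMiRNA

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeRecord",
    "SelectionThresholds",
    "CandidateReport",
    "fold_change",
    "fold_change_table",
    "is_changed",
    "human_candidate_filter",
    "mouse_filter",
    "direction_filter",
    "paralog_filter",
    "select_candidates",
]

CASE, CONTROL = "case", "control"


@dataclass(frozen=True)
class FoldChangeRecord:
    """Case/control mean expression and their (pseudocounted) ratio."""

    mirna_id: str
    mean_case: float
    mean_control: float
    fc: float
    log2fc: float


@dataclass(frozen=True)
class SelectionThresholds:
    """Tunable thresholds of the candidate cascade (defaults as published)."""

    min_rpm: float = 5.0
    both_change: float = 0.50
    single_fold: float = 2.0
    no_change_band: float = 0.20
    mouse_change: float = 0.25
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_rpm", "both_change", "single_fold", "no_change_band", "mouse_change", "pseudocount"):
            if getattr(self, name) <= 0 and name != "min_rpm":
                raise ValueError(f"{name} must be positive")
        if self.min_rpm < 0:
            raise ValueError("min_rpm must be >= 0")
        if not self.both_change < self.single_fold - 1:
            raise ValueError("both_change must be < single_fold - 1")
        if not self.no_change_band < self.both_change:
            raise ValueError("no_change_band must be < both_change")


@dataclass(frozen=True)
class CandidateReport:
    """Per-miRNA stage flags plus the final candidate set and funnel sizes."""

    flags: pd.DataFrame
    candidates: tuple[str, ...]
    funnel: dict[str, int] = field(default_factory=dict)
    fold_changes: dict[str, pd.DataFrame] = field(default_factory=dict)


def fold_change(
    mean_case: float,
    mean_control: float,
    pseudocount: float = 0.5,
    mirna_id: str = "",
) -> FoldChangeRecord:
    """fc = (mean_case + pseudocount) / (mean_control + pseudocount)."""
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = mean_control + pseudocount
    if denom == 0:
        raise ValueError("zero control mean with zero pseudocount")
    fc = (mean_case + pseudocount) / denom
    return FoldChangeRecord(mirna_id, mean_case, mean_control, fc, math.log2(fc))


def fold_change_table(
    rpm: pd.DataFrame, groups: Mapping[str, str], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-miRNA case/control means and fold change for one dataset.

    ``groups`` maps every sample column to ``"case"`` or ``"control"``.
    """
    labels = {groups.get(s) for s in rpm.columns}
    missing = [s for s in rpm.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    if not {CASE, CONTROL} <= labels:
        raise ValueError("groups must include both 'case' and 'control' samples")
    case_cols = [s for s in rpm.columns if groups[s] == CASE]
    control_cols = [s for s in rpm.columns if groups[s] == CONTROL]
    mean_case = rpm[case_cols].mean(axis=1)
    mean_control = rpm[control_cols].mean(axis=1)
    fc = (mean_case + pseudocount) / (mean_control + pseudocount)
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fc": fc,
            "log2fc": fc.map(math.log2),
        }
    )


def is_changed(fc: float, frac: float) -> bool:
    """True when the fold change is at least ``frac`` away from 1 on either
    side of the (symmetric, inclusive) ratio scale."""
    if fc <= 0:
        raise ValueError("fold change must be > 0")
    if frac <= 0:
        raise ValueError("fractional change must be > 0")
    return fc >= 1 + frac or fc <= 1 / (1 + frac)


def _is_extreme(fc: float, fold: float) -> bool:
    return fc >= fold or fc <= 1 / fold


def human_candidate_filter(
    fc1: Mapping[str, float] | pd.Series,
    fc2: Mapping[str, float] | pd.Series,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> set[str]:
    """Candidates from the two human datasets.

    Kept when changed in both datasets (both-rule), or at least
    ``single_fold``-fold in one dataset while the other stays inside the
    no-change band (single-rule).  Evaluated on the intersection of the two
    miRNA universes.
    """
    s1, s2 = pd.Series(fc1, dtype=float), pd.Series(fc2, dtype=float)
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise ValueError("fold-change tables share no miRNAs")
    if len(shared) < max(len(s1), len(s2)):
        logger.info(
            "human_candidate_filter: universes differ (%d vs %d, %d shared)",
            len(s1),
            len(s2),
            len(shared),
        )
    kept = set()
    for mid in shared:
        f1, f2 = float(s1[mid]), float(s2[mid])
        both = is_changed(f1, thresholds.both_change) and is_changed(f2, thresholds.both_change)
        single = (
            _is_extreme(f1, thresholds.single_fold)
            and not is_changed(f2, thresholds.no_change_band)
        ) or (
            _is_extreme(f2, thresholds.single_fold)
            and not is_changed(f1, thresholds.no_change_band)
        )
        if both or single:
            kept.add(mid)
    return kept


def mouse_filter(
    ids: Iterable[str],
    fc_mouse: Mapping[str, float] | pd.Series,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> set[str]:
    """Keep ids whose mouse fold change exceeds the mouse-change threshold."""
    series = pd.Series(fc_mouse, dtype=float)
    kept = set()
    for mid in ids:
        if mid not in series.index:
            logger.warning("mouse_filter: %r missing from mouse table, dropped", mid)
            continue
        if is_changed(float(series[mid]), thresholds.mouse_change):
            kept.add(mid)
    return kept


def direction_filter(
    ids: Iterable[str],
    fc1: Mapping[str, float] | pd.Series,
    fc2: Mapping[str, float] | pd.Series,
    fc_mouse: Mapping[str, float] | pd.Series,
) -> set[str]:
    """Keep ids whose fold change has the same nonzero sign in all tables."""
    tables = [pd.Series(t, dtype=float) for t in (fc1, fc2, fc_mouse)]
    kept = set()
    for mid in ids:
        try:
            fcs = [float(t[mid]) for t in tables]
        except KeyError as exc:
            raise ValueError(f"id {mid!r} missing from a fold-change table") from exc
        signs = {1 if f > 1 else (-1 if f < 1 else 0) for f in fcs}
        if len(signs) == 1 and 0 not in signs:
            kept.add(mid)
    return kept


def paralog_filter(ids: Iterable[str], mirnas: Sequence[MatureMiRNA]) -> set[str]:
    """Drop ids sharing a seed with any OTHER miRNA in the human catalog."""
    by_id = {m.mirna_id: m for m in mirnas}
    family_sizes: dict[str, int] = {}
    for m in mirnas:
        family_sizes[m.family_id] = family_sizes.get(m.family_id, 0) + 1
    kept = set()
    for mid in ids:
        if mid not in by_id:
            raise ValueError(f"candidate {mid!r} has no mature sequence in the catalog")
        if family_sizes[by_id[mid].family_id] == 1:
            kept.add(mid)
    return kept


def select_candidates(
    rpm1: pd.DataFrame,
    rpm2: pd.DataFrame,
    rpm_mouse: pd.DataFrame,
    groups1: Mapping[str, str],
    groups2: Mapping[str, str],
    groups_mouse: Mapping[str, str],
    mirnas: Sequence[MatureMiRNA],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> CandidateReport:
    """Run the full cascade and record every intermediate flag.

    Stages: expression filter per dataset -> fold change per dataset ->
    human both/single rule -> mouse change -> direction consistency ->
    paralog exclusion.
    """
    expr1 = mean_rpm_filter(rpm1, thresholds.min_rpm)
    expr2 = mean_rpm_filter(rpm2, thresholds.min_rpm)
    expr_m = mean_rpm_filter(rpm_mouse, thresholds.min_rpm)

    fc1 = fold_change_table(rpm1, groups1, thresholds.pseudocount)
    fc2 = fold_change_table(rpm2, groups2, thresholds.pseudocount)
    fcm = fold_change_table(rpm_mouse, groups_mouse, thresholds.pseudocount)

    universe = sorted(set(rpm1.index) | set(rpm2.index) | set(rpm_mouse.index))
    expressed_all = expr1 & expr2 & expr_m

    human_kept = (
        human_candidate_filter(fc1["fc"], fc2["fc"], thresholds) & expressed_all
        if expressed_all
        else set()
    )
    mouse_kept = mouse_filter(human_kept, fcm["fc"], thresholds)
    dir_kept = direction_filter(mouse_kept, fc1["fc"], fc2["fc"], fcm["fc"])
    final = paralog_filter(dir_kept, mirnas)

    catalog_ids = {m.mirna_id for m in mirnas}
    family_sizes: dict[str, int] = {}
    for m in mirnas:
        family_sizes[m.family_id] = family_sizes.get(m.family_id, 0) + 1
    by_id = {m.mirna_id: m for m in mirnas}

    rows = []
    for mid in universe:
        f1 = float(fc1["fc"].get(mid, float("nan")))
        f2 = float(fc2["fc"].get(mid, float("nan")))
        fm = float(fcm["fc"].get(mid, float("nan")))
        have_h = mid in fc1.index and mid in fc2.index
        both_rule = (
            have_h
            and is_changed(f1, thresholds.both_change)
            and is_changed(f2, thresholds.both_change)
        )
        single_rule = have_h and (
            (
                _is_extreme(f1, thresholds.single_fold)
                and not is_changed(f2, thresholds.no_change_band)
            )
            or (
                _is_extreme(f2, thresholds.single_fold)
                and not is_changed(f1, thresholds.no_change_band)
            )
        )
        rows.append(
            {
                "mirna_id": mid,
                "expressed_ds1": mid in expr1,
                "expressed_ds2": mid in expr2,
                "expressed_mouse": mid in expr_m,
                "both_rule": bool(both_rule),
                "single_rule": bool(single_rule),
                "mouse_rule": mid in fcm.index
                and fm == fm
                and is_changed(fm, thresholds.mouse_change),
                "direction_consistent": mid in dir_kept
                or (
                    mid in fc1.index
                    and mid in fc2.index
                    and mid in fcm.index
                    and mid in direction_filter([mid], fc1["fc"], fc2["fc"], fcm["fc"])
                ),
                "paralog_free": mid in catalog_ids
                and family_sizes[by_id[mid].family_id] == 1,
                "candidate": mid in final,
            }
        )
    flags = pd.DataFrame(rows).set_index("mirna_id")

    funnel = {
        "n_universe": len(universe),
        "n_expressed_all": len(expressed_all),
        "n_human": len(human_kept),
        "n_mouse": len(mouse_kept),
        "n_direction": len(dir_kept),
        "n_final": len(final),
    }
    logger.info("candidate funnel: %s", funnel)
    return CandidateReport(
        flags=flags,
        candidates=tuple(sorted(final)),
        funnel=funnel,
        fold_changes={"human1": fc1, "human2": fc2, "mouse": fcm},
    )
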