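"""Binding x frequency-class enrichment: contingency tables, the 19-non-native
background, cumulative effect-score curves, and group comparisons.

The central questions: are common (vs rare) SAVs depleted at binding-interface
residues, and do effect-score distributions differ between binding and
non-binding SAVs of each frequency class? Enrichment is a 2x2 Fisher test on
(common/rare) x (binding/other); distribution contrasts are two-sample KS
tests plus cumulative fraction-at-or-above-threshold curves over the integer
score grid -100..100.

The *background* ("random") group pools, for every residue position carrying
at least one observed SAV, the effect scores of all 19 non-native amino-acid
substitutions at that position; each position contributes exactly 19 entries
regardless of how many SAVs were observed there, and the background inherits
the residue's binding annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .data_model import (
    BINDING,
    BINDING_CLASSES,
    COMMON,
    OTHER,
    RARE,
    RESIDUE_KEY,
    UNKNOWN,
)
from .stats_core import BootstrapEstimate, ContingencyTable2x2, KSResult

__all__ = [
    "GroupKey",
    "CumulativeCurve",
    "build_background_19",
    "build_contingency",
    "cumulative_curve",
    "binding_fraction",
    "compare_groups",
    "multi_binding_partition",
]

BACKGROUND = "background"
ANY_BINDING = "any"
NON_BINDING = "non_binding"

SCORE_GRID = np.arange(-100, 101)


@dataclass(frozen=True)
class GroupKey:
    """Selects one score group from the analysis table.

    ``freq_class``: 'common', 'rare' or 'background' (the 19-non-native pool).
    ``binding_class``: 'protein' | 'dna' | 'rna' | 'any' (union over the
    three classes) | 'non_binding' | None (no binding restriction).
    Optional filters: ``effect_min`` keeps scores >= threshold;
    ``binding_reliability_min`` keeps rows whose |binding score| for the
    relevant class(es) is >= threshold (confident binding AND confident
    non-binding calls both pass).
    """

    freq_class: str
    binding_class: str | None = None
    effect_min: float | None = None
    binding_reliability_min: float | None = None

    def label(self) -> str:
        parts = [self.freq_class, self.binding_class or "all"]
        if self.effect_min is not None:
            parts.append(f"effect>={self.effect_min:g}")
        if self.binding_reliability_min is not None:
            parts.append(f"|bind|>={self.binding_reliability_min:g}")
        return "_".join(parts)


@dataclass(frozen=True)
class CumulativeCurve:
    """Fraction of scores at or above each threshold of the integer grid."""

    thresholds: np.ndarray
    fraction_at_or_above: np.ndarray
    group: GroupKey | None = None
    n: int = 0


def build_background_19(
    positions: pd.DataFrame,
    all_sub_scores: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pool the 19-non-native substitution scores of the given positions.

    ``positions``: unique (protein_id, position) rows (the residues carrying
    observed SAVs). ``all_sub_scores``: per-substitution scores with columns
    protein_id, position, alt_aa, snap2_score — exactly 19 distinct non-native
    substitutions per position, or an error naming the position. The pooled
    frame carries the residue's binding statuses when ``annotations`` (or
    status columns on ``positions``) are supplied.
    """
    pos = positions[RESIDUE_KEY].drop_duplicates()
    pooled = pos.merge(all_sub_scores, on=RESIDUE_KEY, how="left")
    if pooled["snap2_score"].isna().any():
        bad = pooled[pooled["snap2_score"].isna()].iloc[0]
        raise ValueError(
            f"position {bad['protein_id']}:{bad['position']} lacks background scores"
        )
    counts = pooled.groupby(RESIDUE_KEY, sort=False).agg(
        n=("alt_aa", "size"), n_distinct=("alt_aa", "nunique")
    )
    bad = counts[(counts["n"] != 19) | (counts["n_distinct"] != 19)]
    if len(bad):
        key = bad.index[0]
        raise ValueError(
            f"position {key[0]}:{key[1]} has {int(bad['n'].iloc[0])} background "
            f"substitutions ({int(bad['n_distinct'].iloc[0])} distinct); expected 19"
        )
    src = annotations if annotations is not None else positions
    status_cols = [c for c in src.columns if c.endswith("_status")]
    if status_cols:
        pooled = pooled.merge(
            src[RESIDUE_KEY + status_cols].drop_duplicates(RESIDUE_KEY),
            on=RESIDUE_KEY,
            how="left",
        )
        pooled["any_binding"] = (pooled[status_cols] == BINDING).any(axis=1)
    return pooled


def _status_series(table: pd.DataFrame, binding_class: str) -> pd.Series:
    """Ternary binding status for a class spec: 'binding'/'other'/'unknown'."""
    if binding_class in BINDING_CLASSES:
        return table[f"{binding_class}_status"]
    status_cols = [f"{c}_status" for c in BINDING_CLASSES]
    any_b = (table[status_cols] == BINDING).any(axis=1)
    all_unknown = (table[status_cols] == UNKNOWN).all(axis=1)
    out = pd.Series(np.where(any_b, BINDING, OTHER), index=table.index)
    out[all_unknown] = UNKNOWN
    if binding_class == ANY_BINDING:
        return out
    if binding_class == NON_BINDING:
        flipped = out.map({BINDING: OTHER, OTHER: BINDING, UNKNOWN: UNKNOWN})
        return flipped
    raise ValueError(f"unknown binding class {binding_class!r}")


def _apply_reliability(table: pd.DataFrame, binding_class: str, min_abs: float) -> pd.DataFrame:
    """Keep rows whose relevant binding score is confidently called:
    |score| >= min_abs (confident binding and confident non-binding alike)."""
    if binding_class in BINDING_CLASSES:
        cols = [f"{binding_class}_score"]
    else:
        cols = [f"{c}_score" for c in BINDING_CLASSES]
    present = [c for c in cols if c in table.columns]
    if not present:
        raise ValueError("binding reliability filter requires binding score columns")
    keep = np.zeros(len(table), dtype=bool)
    for c in present:
        s = pd.to_numeric(table[c], errors="coerce")
        keep |= (s.abs() >= min_abs).fillna(False).to_numpy()
    return table[keep]


def build_contingency(
    table: pd.DataFrame,
    binding_class: str = ANY_BINDING,
    effect_min: float | None = None,
    binding_reliability_min: float | None = None,
) -> ContingencyTable2x2:
    """Count (common/rare) x (binding/other) SAVs for one binding class.

    Rows with unknown status are excluded; filters are applied before
    counting. An empty frequency class after filtering is a degenerate table
    and raises.
    """
    t = table[table["freq_class"].isin([COMMON, RARE])]
    if effect_min is not None:
        t = t[t["snap2_score"] >= effect_min]
    if binding_reliability_min is not None:
        t = _apply_reliability(t, binding_class, binding_reliability_min)
    status = _status_series(t, binding_class)
    t = t[status != UNKNOWN]
    status = status.loc[t.index]
    is_common = t["freq_class"] == COMMON
    is_binding = status == BINDING
    tab = ContingencyTable2x2(
        n_cb=int((is_common & is_binding).sum()),
        n_cn=int((is_common & ~is_binding).sum()),
        n_rb=int((~is_common & is_binding).sum()),
        n_rn=int((~is_common & ~is_binding).sum()),
    )
    if tab.n_cb + tab.n_cn == 0 or tab.n_rb + tab.n_rn == 0:
        raise ValueError(
            f"degenerate contingency table for class {binding_class!r}: "
            f"a frequency class is empty after filtering"
        )
    return tab


def cumulative_curve(
    scores,
    grid: np.ndarray = SCORE_GRID,
    inclusive: bool = True,
    group: GroupKey | None = None,
) -> CumulativeCurve:
    """Fraction of scores at (or above) each grid threshold.

    Inclusive (>= t, the default) makes the curve exactly 1.0 at t = -100
    since scores are bounded below by -100.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ValueError("cumulative_curve requires a non-empty score set")
    side = "left" if inclusive else "right"
    frac = 1.0 - np.searchsorted(s, grid, side=side) / s.size
    return CumulativeCurve(
        thresholds=np.asarray(grid), fraction_at_or_above=frac, group=group, n=s.size
    )


def binding_fraction(
    table: pd.DataFrame,
    binding_class: str = ANY_BINDING,
    effect_min: float | None = None,
    binding_reliability_min: float | None = None,
    n_replicates: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
) -> BootstrapEstimate:
    """Fraction of SAVs at binding residues, with a subsampling-bootstrap SE
    (1000 draws of 50% without replacement by default)."""
    t = table
    if effect_min is not None:
        t = t[t["snap2_score"] >= effect_min]
    if binding_reliability_min is not None:
        t = _apply_reliability(t, binding_class, binding_reliability_min)
    status = _status_series(t, binding_class)
    flags = (status[status != UNKNOWN] == BINDING).to_numpy(dtype=float)
    if flags.size == 0:
        raise ValueError("no SAVs with known binding status")
    return stats_core.bootstrap(
        np.mean, flags, n_replicates=n_replicates, fraction=fraction, seed=seed
    )


def extract_group_scores(
    table: pd.DataFrame,
    key: GroupKey,
    background: pd.DataFrame | None = None,
) -> np.ndarray:
    """Score multiset for one group. Background groups are drawn from the
    19-non-native pool (see :func:`build_background_19`)."""
    if key.freq_class == BACKGROUND:
        if background is None:
            raise ValueError(f"group {key.label()} requires the 19-non-native pool")
        t = background
    else:
        t = table[table["freq_class"] == key.freq_class]
    if key.binding_reliability_min is not None:
        t = _apply_reliability(t, key.binding_class or ANY_BINDING, key.binding_reliability_min)
    if key.binding_class is not None:
        status = _status_series(t, key.binding_class)
        t = t[status == BINDING]
    scores = t["snap2_score"].to_numpy(dtype=float)
    if key.effect_min is not None:
        scores = scores[scores >= key.effect_min]
    if scores.size == 0:
        raise ValueError(f"group {key.label()} is empty after filtering")
    return scores


def compare_groups(
    table: pd.DataFrame,
    group_a: GroupKey,
    group_b: GroupKey,
    background: pd.DataFrame | None = None,
) -> tuple[KSResult, CumulativeCurve, CumulativeCurve]:
    """KS test between two groups' score distributions, plus both cumulative
    curves. Supports every pair in the (common, rare, background) x
    (binding, non-binding, any) grid."""
    a = extract_group_scores(table, group_a, background)
    b = extract_group_scores(table, group_b, background)
    ks = stats_core.ks_two_sample(a, b)
    return ks, cumulative_curve(a, group=group_a), cumulative_curve(b, group=group_b)


MULTI_COMBOS = (
    ("protein",),
    ("dna",),
    ("rna",),
    ("protein", "dna"),
    ("protein", "rna"),
    ("dna", "rna"),
    ("protein", "dna", "rna"),
)


def multi_binding_partition(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Partition binding SAVs by their exact combination of binding classes.

    Returns score arrays keyed 'protein', 'protein+dna', ..., plus
    'non_binding'; the partition is exclusive (a triple-binding SAV appears
    only under 'protein+dna+rna') and its cells sum to the binding count.
    """
    flags = {c: (table[f"{c}_status"] == BINDING).to_numpy() for c in BINDING_CLASSES}
    out: dict[str, np.ndarray] = {}
    any_b = np.zeros(len(table), dtype=bool)
    for combo in MULTI_COMBOS:
        mask = np.ones(len(table), dtype=bool)
        for c in BINDING_CLASSES:
            mask &= flags[c] if c in combo else ~flags[c]
        out["+".join(combo)] = table.loc[mask, "snap2_score"].to_numpy(dtype=float)
        any_b |= mask
    out[NON_BINDING] = table.loc[~any_b, "snap2_score"].to_numpy(dtype=float)
    return out
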