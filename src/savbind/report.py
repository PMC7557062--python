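"""Pipeline orchestration, accounting tables and report formatting.

``run_pipeline`` drives the full analysis: join variant / effect-score /
binding-annotation tables, drop the uncommon frequency band, build the
per-class and any-class contingency tables with Fisher statistics, the
bootstrap binding fractions, the cumulative-curve / KS comparison grid
(including the 19-non-native background when substitution scores are
supplied), and the tissue stage when an expression matrix is supplied.
Results are written as tidy TSV plus a machine-readable JSON summary; every
number in the human-readable report is traceable to a JSON field.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import data_model, enrichment_analysis as ea, stats_core, tissue_enrichment as te
from .data_model import BINDING, BINDING_CLASSES, COMMON, OTHER, RARE
from .enrichment_analysis import ANY_BINDING, BACKGROUND, NON_BINDING, GroupKey
from .stats_core import MACHINE_EPS_P

__all__ = [
    "RunConfig",
    "run_pipeline",
    "table1_accounting",
    "union_percentage",
    "format_percentage",
    "format_p_value",
]


# ---------------------------------------------------------------- formatting

def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(pct: float) -> str:
    """Half-up rounding: 2 decimals below 1%, 1 decimal at or above."""
    if not np.isfinite(pct):
        return "n/a"
    if abs(pct) < 1.0:
        return f"{_round_half_up(pct, 2):.2f}%"
    return f"{_round_half_up(pct, 1):.1f}%"


def format_p_value(p: float) -> str:
    """Floor the rendering at the double-precision limit, R-style."""
    if p < MACHINE_EPS_P:
        return "< 2.2e-16"
    return f"{p:.3g}"


def union_percentage(
    n_common: int, n_rare: int, total_common: int, total_rare: int
) -> tuple[int, float]:
    """Combine per-frequency-class counts into a union count and its
    percentage of all common+rare SAVs (raw, unrounded)."""
    count = n_common + n_rare
    total = total_common + total_rare
    return count, 100.0 * count / total if total else float("nan")


# ------------------------------------------------------------- table 1 style

def table1_accounting(table: pd.DataFrame) -> pd.DataFrame:
    """Per annotation type x frequency class accounting of experimentally
    annotated SAVs, mirroring the interface/other/effect layout.

    ``table`` is a joined analysis table whose status columns carry
    experimental semantics ('other' = not observed binding in the examined
    structure) and, optionally, a boolean ``has_experimental_effect`` column.
    The union rows are true unions over SAVs: 'SUM binding' is the union over
    the three classes (double-binding counted once); 'SUM experimental' the
    union of binding-annotated, other-annotated and effect-annotated SAVs.
    Percentages are over the common+rare totals.
    """
    t = table[table["freq_class"].isin([COMMON, RARE])]
    totals = {fc: int((t["freq_class"] == fc).sum()) for fc in (COMMON, RARE)}
    has_effect = (
        t["has_experimental_effect"].fillna(False).astype(bool)
        if "has_experimental_effect" in t.columns
        else pd.Series(False, index=t.index)
    )

    def counts(mask) -> dict:
        n_c = int((mask & (t["freq_class"] == COMMON)).sum())
        n_r = int((mask & (t["freq_class"] == RARE)).sum())
        _, pct = union_percentage(n_c, n_r, totals[COMMON], totals[RARE])
        return {"common": n_c, "rare": n_r, "union": n_c + n_r, "pct_of_total": pct}

    rows = []
    any_binding = pd.Series(False, index=t.index)
    any_other = pd.Series(False, index=t.index)
    for cls in BINDING_CLASSES:
        status = t[f"{cls}_status"]
        b, o = status == BINDING, status == OTHER
        any_binding |= b
        any_other |= o
        rows.append({"annotation": cls, "category": "interface", **counts(b)})
        rows.append({"annotation": cls, "category": "other", **counts(o)})
    rows.append({"annotation": "sum_binding", "category": "interface", **counts(any_binding)})
    rows.append(
        {"annotation": "sum_binding", "category": "other", **counts(any_other & ~any_binding)}
    )
    rows.append({"annotation": "effect", "category": "effect", **counts(has_effect)})
    rows.append(
        {
            "annotation": "sum_experimental",
            "category": "any",
            **counts(any_binding | any_other | has_effect),
        }
    )
    rows.append(
        {
            "annotation": "variants",
            "category": "total",
            "common": totals[COMMON],
            "rare": totals[RARE],
            "union": totals[COMMON] + totals[RARE],
            "pct_of_total": 100.0,
        }
    )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ pipeline

@dataclass
class RunConfig:
    variants: str
    effect_scores: str
    residue_annotations: str
    background_scores: str | None = None
    expression: str | None = None
    out_dir: str = "savbind-results"
    common_min_ldaf: float = 0.05
    rare_max_ldaf: float = 0.01
    effect_min: float | None = None
    binding_reliability_min: float | None = None
    tissue_effect_min: float = 50.0
    tissue_min_level: float = 1.0
    tissue_fold: float = 4.0
    bootstrap_replicates: int = 1000
    bootstrap_fraction: float = 0.5
    plots: bool = False
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def _p_fields(p: float) -> dict:
    return {"p_value": p, "lt_machine_eps": bool(p < MACHINE_EPS_P)}


_COMPARISONS = [
    (GroupKey(COMMON, ANY_BINDING), GroupKey(RARE, ANY_BINDING)),
    (GroupKey(COMMON, ANY_BINDING), GroupKey(BACKGROUND, ANY_BINDING)),
    (GroupKey(RARE, ANY_BINDING), GroupKey(BACKGROUND, ANY_BINDING)),
    (GroupKey(COMMON, NON_BINDING), GroupKey(RARE, NON_BINDING)),
    (GroupKey(COMMON, ANY_BINDING), GroupKey(COMMON, NON_BINDING)),
    (GroupKey(RARE, ANY_BINDING), GroupKey(RARE, NON_BINDING)),
]


def run_pipeline(config: RunConfig) -> dict:
    """Execute join -> enrichment -> curves/KS -> tissue; write result tables,
    a JSON summary and a run manifest into ``config.out_dir``.

    Returns the summary dict. Counts are logged at every filtering step
    (read, joined, excluded, per-class binding) so the accounting of the full
    run is reproducible from the summary alone.
    """
    stage = "load"
    try:
        variants = data_model.read_variants_tsv(
            config.variants, config.common_min_ldaf, config.rare_max_ldaf
        )
        effects = data_model.read_effect_scores_tsv(config.effect_scores)
        annotations = data_model.read_residue_annotations_tsv(config.residue_annotations)
        background_scores = (
            pd.read_csv(config.background_scores, sep="\t", dtype={"protein_id": str})
            if config.background_scores
            else None
        )
        expression = (
            te.read_expression_tsv(config.expression) if config.expression else None
        )

        stage = "join"
        joined, excluded = data_model.join_annotations(variants, effects, annotations)
        table = data_model.filter_extremes(joined)

        counts = {
            "savs_read": int(len(variants)),
            "savs_joined": int(len(joined)),
            "savs_excluded": int(len(excluded)),
            "exclusion_reasons": excluded.get(
                "exclusion_reason", pd.Series(dtype=object)
            ).value_counts().to_dict(),
            "savs_after_extremes_filter": int(len(table)),
            "common": int((table["freq_class"] == COMMON).sum()),
            "rare": int((table["freq_class"] == RARE).sum()),
        }
        for cls in BINDING_CLASSES + (ANY_BINDING,):
            status = ea._status_series(table, cls if cls != ANY_BINDING else ANY_BINDING)
            counts[f"binding_{cls}"] = int((status == BINDING).sum())

        stage = "enrichment"
        enrichment_rows = []
        for cls in (ANY_BINDING,) + BINDING_CLASSES:
            t2 = ea.build_contingency(
                table, cls,
                effect_min=config.effect_min,
                binding_reliability_min=config.binding_reliability_min,
            )
            zero_cell = 0 in t2.as_tuple()
            res = stats_core.enrichment_result(t2, haldane=zero_cell)
            enrichment_rows.append(
                {
                    "binding_class": cls,
                    "n_cb": t2.n_cb, "n_cn": t2.n_cn, "n_rb": t2.n_rb, "n_rn": t2.n_rn,
                    "odds_ratio": res.odds_ratio if not zero_cell else None,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "haldane_corrected": zero_cell,
                    **_p_fields(res.p_value),
                }
            )

        stage = "binding_fraction"
        fractions = {}
        for cls in (ANY_BINDING,) + BINDING_CLASSES:
            est = ea.binding_fraction(
                table, cls,
                effect_min=config.effect_min,
                binding_reliability_min=config.binding_reliability_min,
                n_replicates=config.bootstrap_replicates,
                fraction=config.bootstrap_fraction,
                seed=config.seed,
            )
            fractions[cls] = {
                "fraction": est.point,
                "std_error": est.std_error,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_replicates": est.n_replicates,
            }

        stage = "curves_ks"
        background = None
        if background_scores is not None:
            background = ea.build_background_19(table, background_scores, annotations)
        ks_rows, curve_rows = [], []
        seen_curves = set()
        for ga, gb in _COMPARISONS:
            if background is None and BACKGROUND in (ga.freq_class, gb.freq_class):
                continue
            try:
                ks, ca, cb = ea.compare_groups(table, ga, gb, background)
            except ValueError:
                continue
            ks_rows.append(
                {
                    "group_a": ga.label(), "group_b": gb.label(),
                    "n_a": ca.n, "n_b": cb.n,
                    "d_statistic": ks.d_statistic, "d_signed": ks.d_signed,
                    **_p_fields(ks.p_value),
                }
            )
            for curve in (ca, cb):
                lbl = curve.group.label()
                if lbl in seen_curves:
                    continue
                seen_curves.add(lbl)
                for thr, frac in zip(curve.thresholds, curve.fraction_at_or_above):
                    curve_rows.append(
                        {"group": lbl, "threshold": int(thr), "fraction_at_or_above": float(frac)}
                    )

        stage = "tissue"
        tissue_df = None
        if expression is not None:
            pairs = te.enriched_pairs(expression, config.tissue_min_level, config.tissue_fold)
            tissue_df = te.all_tissue_scores(
                table, pairs, effect_min=config.tissue_effect_min
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    os.makedirs(config.out_dir, exist_ok=True)
    pd.DataFrame(enrichment_rows).to_csv(
        os.path.join(config.out_dir, "enrichment.tsv"), sep="\t", index=False
    )
    pd.DataFrame(ks_rows).to_csv(
        os.path.join(config.out_dir, "ks_tests.tsv"), sep="\t", index=False
    )
    pd.DataFrame(curve_rows).to_csv(
        os.path.join(config.out_dir, "curves.tsv"), sep="\t", index=False
    )
    if tissue_df is not None:
        tissue_df.to_csv(os.path.join(config.out_dir, "tissue.tsv"), sep="\t", index=False)
    if config.plots and curve_rows:
        plot_curves(pd.DataFrame(curve_rows), os.path.join(config.out_dir, "curves.png"))

    summary = {
        "counts": counts,
        "enrichment": enrichment_rows,
        "binding_fractions": fractions,
        "ks_tests": ks_rows,
        "tissue": tissue_df.to_dict(orient="records") if tissue_df is not None else None,
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(_json_ready(summary), fh, indent=2, sort_keys=True)

    inputs = {
        k: v
        for k, v in (
            ("variants", config.variants),
            ("effect_scores", config.effect_scores),
            ("residue_annotations", config.residue_annotations),
            ("background_scores", config.background_scores),
            ("expression", config.expression),
        )
        if v
    }
    manifest = {
        "config": asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
        "package": "savbind 0.1.0",
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(_json_ready(manifest), fh, indent=2, sort_keys=True)
    return summary


def plot_curves(curves: pd.DataFrame, out_path: str) -> None:
    """Cumulative effect-score curves, one line per group: the fraction of
    each group's SAVs at or above every score threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for group, sub in curves.groupby("group"):
        sub = sub.sort_values("threshold")
        ax.plot(sub["threshold"], 100 * sub["fraction_at_or_above"], label=group)
    ax.set_xlabel("effect-score threshold")
    ax.set_ylabel("% of SAVs at or above threshold")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def render_report(summary: dict) -> str:
    """Human-readable digest; every number maps to a summary.json field."""
    lines = ["savbind run summary", "==================="]
    c = summary["counts"]
    lines.append(
        f"SAVs read {c['savs_read']}, joined {c['savs_joined']}, "
        f"excluded {c['savs_excluded']}; after dropping the uncommon band: "
        f"{c['savs_after_extremes_filter']} ({c['common']} common, {c['rare']} rare)"
    )
    for key, f in summary["binding_fractions"].items():
        pct = 100 * f["fraction"]
        lines.append(
            f"binding fraction [{key}]: {format_percentage(pct)} "
            f"+/- {100 * f['std_error']:.2f} (bootstrap SE)"
        )
    for row in summary["enrichment"]:
        orv = row["odds_ratio"]
        or_s = f"{orv:.2f}" if orv is not None else "n/a (zero cell)"
        lines.append(
            f"odds ratio [{row['binding_class']}]: {or_s} "
            f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
            f"Fisher p {format_p_value(row['p_value'])}"
        )
    for row in summary["ks_tests"]:
        lines.append(
            f"KS {row['group_a']} vs {row['group_b']}: D = {row['d_statistic']:.3f}, "
            f"p {format_p_value(row['p_value'])}"
        )
    return "\n".join(lines)
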