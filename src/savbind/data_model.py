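"""Domain types and table plumbing for single amino-acid variants (SAVs).

A SAV is one amino-acid substitution at a protein sequence position, carrying
a linkage-disequilibrium allele frequency (LDAF). Variants are classified as
common (LDAF >= 0.05), uncommon (0.01 <= LDAF < 0.05) or rare (LDAF < 0.01);
the uncommon middle band is dropped before any enrichment statistic so the
common/rare contrast does not hinge on a single threshold.

Tabular inputs are plain TSV; the canonical in-memory container is a pandas
DataFrame. ``join_annotations`` assembles the analysis table: one row per SAV
with its functional-effect score (SNAP2-like, in [-100, 100]) and the
per-class binding annotation of its residue (protein / DNA / RNA, each
scored in [-100, 100] for predictions, or a categorical status for
experimental annotations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "BINDING_CLASSES",
    "COMMON",
    "UNCOMMON",
    "RARE",
    "BINDING",
    "OTHER",
    "UNKNOWN",
    "SAV",
    "classify_frequency",
    "read_variants_tsv",
    "read_effect_scores_tsv",
    "read_residue_annotations_tsv",
    "join_annotations",
    "filter_extremes",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BINDING_CLASSES = ("protein", "dna", "rna")

COMMON, UNCOMMON, RARE = "common", "uncommon", "rare"
BINDING, OTHER, UNKNOWN = "binding", "other", "unknown"

#: default LDAF thresholds (config-overridable)
COMMON_MIN_LDAF = 0.05
RARE_MAX_LDAF = 0.01

SAV_KEY = ["protein_id", "position", "ref_aa", "alt_aa"]
RESIDUE_KEY = ["protein_id", "position"]


def classify_frequency(
    ldaf: float, common_min: float = COMMON_MIN_LDAF, rare_max: float = RARE_MAX_LDAF
) -> str:
    """Classify an allele frequency: common iff ``ldaf >= common_min``,
    rare iff ``ldaf < rare_max``, uncommon in between. Boundary-exact."""
    if not (0.0 <= ldaf <= 1.0):
        raise ValueError(f"allele frequency must be in [0, 1], got {ldaf!r}")
    if ldaf >= common_min:
        return COMMON
    if ldaf >= rare_max:
        return UNCOMMON
    return RARE


def classify_frequency_array(
    ldaf: np.ndarray, common_min: float = COMMON_MIN_LDAF, rare_max: float = RARE_MAX_LDAF
) -> np.ndarray:
    ldaf = np.asarray(ldaf, dtype=float)
    if np.any((ldaf < 0) | (ldaf > 1)) or np.any(~np.isfinite(ldaf)):
        bad = ldaf[(ldaf < 0) | (ldaf > 1) | ~np.isfinite(ldaf)][:1]
        raise ValueError(f"allele frequency must be in [0, 1], got {bad}")
    out = np.full(ldaf.shape, UNCOMMON, dtype=object)
    out[ldaf >= common_min] = COMMON
    out[ldaf < rare_max] = RARE
    return out


@dataclass(frozen=True)
class SAV:
    """One amino-acid substitution with its allele frequency.

    Identity is (protein_id, position, ref_aa, alt_aa); several SAVs may hit
    the same residue and each counts separately in SAV-level statistics.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    ldaf: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AMINO_ACIDS:
            raise ValueError(f"unknown reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS:
            raise ValueError(f"unknown alternate amino acid {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ")
        if not (0.0 <= self.ldaf <= 1.0):
            raise ValueError(f"ldaf must be in [0, 1], got {self.ldaf}")

    @property
    def freq_class(self) -> str:
        return classify_frequency(self.ldaf)


def _validate_scores(values: pd.Series, what: str) -> None:
    v = pd.to_numeric(values.dropna(), errors="raise")
    if ((v < -100) | (v > 100)).any():
        bad = v[(v < -100) | (v > 100)].iloc[0]
        raise ValueError(f"{what} outside [-100, 100]: {bad} (inputs are rejected, not clamped)")


def _reject_duplicates(df: pd.DataFrame, key: list[str], what: str) -> None:
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate {what} key: {tuple(first)}")


def read_variants_tsv(
    path, common_min: float = COMMON_MIN_LDAF, rare_max: float = RARE_MAX_LDAF
) -> pd.DataFrame:
    """Read a variant table (protein_id, position, ref_aa, alt_aa, ldaf) and
    attach the frequency class."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    required = set(SAV_KEY + ["ldaf"])
    if not required.issubset(df.columns):
        raise ValueError(f"variant table missing columns {sorted(required - set(df.columns))}")
    df = df.copy()
    df["position"] = df["position"].astype(int)
    _reject_duplicates(df, SAV_KEY, "SAV")
    if (df["ref_aa"] == df["alt_aa"]).any():
        raise ValueError("ref_aa == alt_aa in variant table")
    df["freq_class"] = classify_frequency_array(df["ldaf"].to_numpy(), common_min, rare_max)
    return df


def read_effect_scores_tsv(path) -> pd.DataFrame:
    """Read per-SAV effect scores (columns: SAV key + snap2_score)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if "snap2_score" not in df.columns:
        raise ValueError("effect-score table missing column 'snap2_score'")
    df = df.copy()
    df["position"] = df["position"].astype(int)
    _reject_duplicates(df, SAV_KEY, "effect score")
    _validate_scores(df["snap2_score"], "effect score")
    return df


def _derive_statuses(df: pd.DataFrame) -> pd.DataFrame:
    """Fill per-class status columns. For predicted rows a present class score
    determines status (binding iff score > 0, unknown when absent); for
    experimental rows the provided status columns are kept ('other' there
    means not observed binding in the examined structure, not proven
    non-binding)."""
    df = df.copy()
    for cls in BINDING_CLASSES:
        score_col, status_col = f"{cls}_score", f"{cls}_status"
        if status_col not in df.columns:
            df[status_col] = pd.NA
        predicted = df["source"] == "predicted"
        score = pd.to_numeric(df.get(score_col, pd.Series(pd.NA, index=df.index)), errors="coerce")
        derived = np.where(score > 0, BINDING, OTHER)
        derived = np.where(score.isna(), UNKNOWN, derived)
        df.loc[predicted, status_col] = derived[predicted.to_numpy()]
        df[status_col] = df[status_col].fillna(UNKNOWN)
        bad = ~df[status_col].isin([BINDING, OTHER, UNKNOWN])
        if bad.any():
            raise ValueError(f"invalid {status_col} value {df.loc[bad, status_col].iloc[0]!r}")
    return df


def read_residue_annotations_tsv(path) -> pd.DataFrame:
    """Read per-residue binding annotations.

    Columns: protein_id, position, source (predicted|experimental), then
    either per-class scores (protein_score, dna_score, rna_score; predicted
    rows) or per-class statuses (protein_status, ...; experimental rows).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if "source" not in df.columns:
        raise ValueError("residue-annotation table missing column 'source'")
    df = df.copy()
    df["position"] = df["position"].astype(int)
    if not df["source"].isin(["predicted", "experimental"]).all():
        raise ValueError("source must be 'predicted' or 'experimental'")
    _reject_duplicates(df, RESIDUE_KEY + ["source"], "residue annotation")
    for cls in BINDING_CLASSES:
        col = f"{cls}_score"
        if col in df.columns:
            _validate_scores(df[col], f"{cls} binding score")
    return _derive_statuses(df)


def join_annotations(
    variants: pd.DataFrame,
    effect_scores: pd.DataFrame,
    residue_annotations: pd.DataFrame,
    source: str = "predicted",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the analysis table: one row per SAV carrying its effect score
    and its residue's binding annotation.

    SAVs lacking either record are excluded from downstream statistics and
    returned separately with an ``exclusion_reason``. Conflicting duplicate
    annotations raise, naming the offending key.
    """
    _reject_duplicates(variants, SAV_KEY, "SAV")
    _reject_duplicates(effect_scores, SAV_KEY, "effect score")
    ann = residue_annotations[residue_annotations["source"] == source]
    _reject_duplicates(ann, RESIDUE_KEY, f"{source} residue annotation")
    if not all(f"{c}_status" in ann.columns for c in BINDING_CLASSES):
        ann = _derive_statuses(ann)

    joined = variants.merge(
        effect_scores[SAV_KEY + ["snap2_score"]], on=SAV_KEY, how="left"
    )
    ann_cols = RESIDUE_KEY + ["source"] + [
        c for c in ann.columns
        if c.endswith("_score") or c.endswith("_status")
    ]
    joined = joined.merge(ann[ann_cols], on=RESIDUE_KEY, how="left")

    missing_score = joined["snap2_score"].isna()
    missing_ann = joined["source"].isna()
    reason = np.select(
        [missing_score & missing_ann, missing_score, missing_ann],
        ["missing_effect_score+annotation", "missing_effect_score", "missing_annotation"],
        default="",
    )
    excluded = joined[reason != ""].copy()
    excluded["exclusion_reason"] = reason[reason != ""]
    joined = joined[reason == ""].copy()

    status_cols = [f"{c}_status" for c in BINDING_CLASSES]
    joined["any_binding"] = (joined[status_cols] == BINDING).any(axis=1)
    return joined.reset_index(drop=True), excluded.reset_index(drop=True)


def filter_extremes(table: pd.DataFrame) -> pd.DataFrame:
    """Drop uncommon SAVs, keeping the common/rare extremes only."""
    if "freq_class" not in table.columns:
        raise ValueError("table lacks a freq_class column")
    return table[table["freq_class"] != UNCOMMON].reset_index(drop=True)


def savs_to_frame(savs: Iterable[SAV]) -> pd.DataFrame:
    rows = [
        dict(protein_id=s.protein_id, position=s.position, ref_aa=s.ref_aa,
             alt_aa=s.alt_aa, ldaf=s.ldaf, freq_class=s.freq_class)
        for s in savs
    ]
    return pd.DataFrame(rows, columns=SAV_KEY + ["ldaf", "freq_class"])
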