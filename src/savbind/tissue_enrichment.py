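"""Tissue-enriched variant calling and normalized over/under-representation.

A protein is *enriched* in a tissue when its expression there is at least
``min_level`` (1 TPM/FPKM) and at least ``fold`` (4x) the arithmetic mean of
its expression over all *other* tissues. SAVs inherit enrichment from their
protein; a protein enriched in several tissues contributes its SAVs to each,
and the overall pool counts (SAV, tissue) pairs — this keeps the
enriched-count-weighted mean of the per-tissue percentages exactly equal to
the overall percentage.

For one tissue, binding class and frequency class, with SAVs restricted to
strong predicted effect (score > 50 by default):

    normalized = (PERC_tissue - PERC_overall) / PERC_overall

where PERC_tissue is the percentage of binding-class SAVs among the tissue's
enriched SAVs of that frequency class, and PERC_overall the same percentage
over the pooled enriched SAVs of all tissues. 0 means as expected by chance,
< 0 under-representation (bounded below by -1), > 0 over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BINDING, RESIDUE_KEY, UNKNOWN
from .enrichment_analysis import _status_series, ANY_BINDING

__all__ = [
    "TissueEnrichmentResult",
    "read_expression_tsv",
    "call_tissue_enriched",
    "enriched_pairs",
    "tissue_enrichment_score",
    "all_tissue_scores",
]


@dataclass(frozen=True)
class TissueEnrichmentResult:
    tissue: str
    binding_class: str
    freq_class: str
    perc_tissue: float
    perc_overall: float
    normalized: float
    n_tissue: int
    n_overall: int
    undefined: bool = False  # perc_overall == 0
    empty: bool = False      # no enriched SAVs in the tissue


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix TSV: protein_id column plus one column per tissue."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise ValueError("expression table missing column 'protein_id'")
    df = df.set_index("protein_id")
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissues")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression levels must be non-negative")
    return df


def _enriched_matrix(matrix: pd.DataFrame, min_level: float, fold: float) -> pd.DataFrame:
    if matrix.shape[1] < 2:
        raise ValueError("enrichment needs at least 2 tissues")
    x = matrix.to_numpy(dtype=float)
    n_t = x.shape[1]
    # mean over the *other* tissues, per focal tissue
    other_mean = (x.sum(axis=1, keepdims=True) - x) / (n_t - 1)
    # zero mean over others: enriched iff the level gate passes
    enriched = (x >= min_level) & ((x >= fold * other_mean) | (other_mean == 0))
    return pd.DataFrame(enriched, index=matrix.index, columns=matrix.columns)


def call_tissue_enriched(
    matrix: pd.DataFrame,
    protein: str,
    tissue: str,
    min_level: float = 1.0,
    fold: float = 4.0,
) -> bool:
    """Is ``protein`` enriched in ``tissue``? (level >= min_level and
    >= fold x mean over the other tissues; a zero other-tissue mean reduces
    to the level gate alone)."""
    if protein not in matrix.index:
        raise KeyError(f"protein {protein!r} not in expression matrix")
    if tissue not in matrix.columns:
        raise KeyError(f"tissue {tissue!r} not in expression matrix")
    return bool(_enriched_matrix(matrix, min_level, fold).loc[protein, tissue])


def enriched_pairs(
    matrix: pd.DataFrame, min_level: float = 1.0, fold: float = 4.0
) -> pd.DataFrame:
    """All (protein_id, tissue) pairs passing the enrichment rule."""
    em = _enriched_matrix(matrix, min_level, fold)
    stacked = em.stack()
    pairs = stacked[stacked].index.to_frame(index=False)
    pairs.columns = ["protein_id", "tissue"]
    return pairs


def _effect_filtered(table: pd.DataFrame, effect_min: float, strict: bool) -> pd.DataFrame:
    if strict:
        return table[table["snap2_score"] > effect_min]
    return table[table["snap2_score"] >= effect_min]


def _binding_share(table: pd.DataFrame, binding_class: str) -> tuple[float, int]:
    status = _status_series(table, binding_class)
    known = status != UNKNOWN
    n = int(known.sum())
    if n == 0:
        return float("nan"), 0
    return 100.0 * float((status[known] == BINDING).mean()), n


def tissue_enrichment_score(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    tissue: str,
    binding_class: str = ANY_BINDING,
    freq_class: str = "common",
    effect_min: float = 50.0,
    strict_effect: bool = True,
) -> TissueEnrichmentResult:
    """Normalized over/under-representation of binding-class SAVs in a tissue.

    ``table`` is the joined analysis table; ``pairs`` the enriched
    (protein_id, tissue) pairs from :func:`enriched_pairs`. SAVs are
    restricted to the given frequency class and to strong predicted effect
    (strictly > ``effect_min`` by default; set ``strict_effect=False`` for an
    inclusive threshold).
    """
    t = _effect_filtered(table[table["freq_class"] == freq_class], effect_min, strict_effect)
    # pooled (SAV, tissue) pairs over all enriched tissues
    pooled = t.merge(pairs, on="protein_id", how="inner")
    perc_overall, n_overall = _binding_share(pooled, binding_class)
    in_tissue = pooled[pooled["tissue"] == tissue]
    perc_tissue, n_tissue = _binding_share(in_tissue, binding_class)

    empty = n_tissue == 0
    undefined = (n_overall == 0) or (not np.isfinite(perc_overall)) or perc_overall == 0
    if empty or undefined:
        normalized = float("nan")
    else:
        normalized = (perc_tissue - perc_overall) / perc_overall
    return TissueEnrichmentResult(
        tissue=tissue,
        binding_class=binding_class,
        freq_class=freq_class,
        perc_tissue=perc_tissue,
        perc_overall=perc_overall,
        normalized=normalized,
        n_tissue=n_tissue,
        n_overall=n_overall,
        undefined=bool(undefined),
        empty=bool(empty),
    )


def all_tissue_scores(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    binding_classes=("protein", "dna", "rna"),
    freq_classes=("common", "rare"),
    effect_min: float = 50.0,
    strict_effect: bool = True,
) -> pd.DataFrame:
    """The full tissue x binding-class x frequency-class grid as a tidy frame
    (heat-map ready)."""
    rows = []
    for tissue in sorted(pairs["tissue"].unique()):
        for bc in binding_classes:
            for fc in freq_classes:
                r = tissue_enrichment_score(
                    table, pairs, tissue, bc, fc, effect_min, strict_effect
                )
                rows.append(r.__dict__)
    return pd.DataFrame(rows)
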