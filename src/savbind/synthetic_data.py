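"""Synthetic inputs with known planted structure.

Every input kind of the pipeline can be generated here so that each stage is
testable against the generator's own bookkeeping, with no external download:

* a variant table shaped like an exome-aggregation extract (SAVs placed
  uniformly on synthetic proteins, allele frequencies from a configurable
  common/uncommon/rare mixture — defaulting to the observed 34,309 / 25,217 /
  6,639,624 class proportions of the 6.7 M-SAV human reference set);
* predictor-shaped score tables: per-SAV effect scores, the 19-non-native
  substitution scores per SAV position, and per-residue binding scores for
  the three classes, with a *planted* common-vs-rare binding odds ratio and
  per-class marginal binding rates (defaults 9.6% / 12.4% / 8.0% per class,
  22.5% any-class);
* a toy multi-chain structure (PDB) with substrate atoms placed at controlled
  distances so the <= 6 A interface truth set is known exactly;
* a tissue x protein expression matrix with planted tissue enrichment.

Effect scores are integers in [-100, 100], drawn from discretized normals
truncated by resampling (never clamping); shapes are configuration, not
doctrine. Allele frequencies within each class are log-uniform over the class
interval — only class membership matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import AMINO_ACIDS, COMMON, RARE, UNCOMMON

__all__ = [
    "GeneratorConfig",
    "ScoreModel",
    "ComplexConfig",
    "ExpressionConfig",
    "generate_variants",
    "generate_scores",
    "generate_complex",
    "generate_expression",
    "generate_dataset",
    "write_dataset",
]

# reference class proportions of the 6,699,150-SAV human variant set
_N_COMMON, _N_UNCOMMON, _N_RARE = 34_309, 25_217, 6_639_624
_N_TOTAL = _N_COMMON + _N_UNCOMMON + _N_RARE


@dataclass(frozen=True)
class ScoreModel:
    """Per-group effect-score means (common/rare x binding/other) and the
    additive shift of the 19-non-native background above the rare-group
    means. Chosen to reproduce the qualitative ordering of the cumulative
    score curves (background highest; binding above non-binding; common
    above rare)."""

    mean_common_binding: float = 20.0
    mean_common_other: float = 0.0
    mean_rare_binding: float = 10.0
    mean_rare_other: float = -15.0
    background_shift: float = 15.0
    #: extra mean per additional binding class at the residue (multi-binding
    #: SAVs shift most strongly toward effect)
    multi_binding_bonus: float = 5.0
    sd: float = 40.0

    def mean(self, freq_class: str, binding: bool) -> float:
        if freq_class == COMMON:
            return self.mean_common_binding if binding else self.mean_common_other
        if freq_class == RARE:
            return self.mean_rare_binding if binding else self.mean_rare_other
        # uncommon SAVs are dropped downstream; give them the midpoint
        return 0.5 * (self.mean(COMMON, binding) + self.mean(RARE, binding))

    def background_mean(self, binding: bool) -> float:
        return self.mean(RARE, binding) + self.background_shift


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 20
    protein_length: tuple[int, int] = (200, 500)
    n_savs: int = 10_000
    #: common / uncommon / rare mixture proportions
    class_probs: tuple[float, float, float] = (
        _N_COMMON / _N_TOTAL, _N_UNCOMMON / _N_TOTAL, _N_RARE / _N_TOTAL
    )
    #: marginal P(binding) per class and for the union over classes
    binding_rate: dict = field(
        default_factory=lambda: {"protein": 0.096, "dna": 0.124, "rna": 0.080, "any": 0.225}
    )
    #: target common-vs-rare odds ratio of binding membership
    planted_or: float = 0.88
    score_model: ScoreModel = field(default_factory=ScoreModel)
    #: fraction of binding scores with |score| >= 50 (confident calls)
    reliable_fraction: float = 0.5
    seed: int = 0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _log_uniform(rng, low, high, size):
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def generate_variants(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Place ``n_savs`` distinct SAVs uniformly over the synthetic proteome.

    Each residue has one native amino acid; the SAV space is (residue,
    non-native alternate), sampled without replacement, so SAV keys are
    unique and at most 19 SAVs share a residue. Returns the variant frame and
    bookkeeping (protein lengths, native sequences, true class counts,
    per-residue SAV placements).
    """
    rng = _rng(config.seed, 0)
    lengths = rng.integers(config.protein_length[0], config.protein_length[1] + 1,
                           size=config.n_proteins)
    protein_ids = [f"SYN{i + 1:04d}" for i in range(config.n_proteins)]
    natives = {
        pid: rng.integers(0, 20, size=int(n)) for pid, n in zip(protein_ids, lengths)
    }
    total_residues = int(lengths.sum())
    space = total_residues * 19
    if config.n_savs > space:
        raise ValueError(
            f"n_savs={config.n_savs} exceeds the {space} possible substitutions "
            f"({total_residues} residues x 19)"
        )
    codes = rng.choice(space, size=config.n_savs, replace=False)
    res_idx = codes // 19
    alt_rank = codes % 19

    offsets = np.concatenate([[0], np.cumsum(lengths)])
    prot_idx = np.searchsorted(offsets, res_idx, side="right") - 1
    pos = res_idx - offsets[prot_idx] + 1  # 1-based

    native_flat = np.concatenate([natives[p] for p in protein_ids])
    ref_idx = native_flat[res_idx]
    alt_idx = np.where(alt_rank < ref_idx, alt_rank, alt_rank + 1)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    classes = rng.choice(
        [COMMON, UNCOMMON, RARE], size=config.n_savs, p=config.class_probs
    )
    ldaf = np.empty(config.n_savs)
    for cls, lo, hi in ((COMMON, 0.05, 1.0), (UNCOMMON, 0.01, 0.05), (RARE, 1e-6, 0.01)):
        m = classes == cls
        ldaf[m] = _log_uniform(rng, lo, hi, int(m.sum()))

    df = pd.DataFrame(
        {
            "protein_id": np.array(protein_ids, dtype=object)[prot_idx],
            "position": pos.astype(int),
            "ref_aa": aa[ref_idx],
            "alt_aa": aa[alt_idx],
            "ldaf": ldaf,
            "freq_class": classes,
        }
    ).sort_values(["protein_id", "position", "alt_aa"], ignore_index=True)

    bookkeeping = {
        "protein_lengths": dict(zip(protein_ids, (int(x) for x in lengths))),
        "native_aa": natives,
        "class_counts": {c: int((classes == c).sum()) for c in (COMMON, UNCOMMON, RARE)},
        "n_residues_hit": int(df[["protein_id", "position"]].drop_duplicates().shape[0]),
    }
    return df, bookkeeping


def _solve_class_rates(p_any: float, planted_or: float, w_common: float) -> tuple[float, float]:
    """Common/rare binding probabilities hitting the marginal ``p_any`` with
    odds(common)/odds(rare) = planted_or."""
    if planted_or <= 0:
        raise ValueError("planted_or must be positive")
    if p_any <= 0:
        return 0.0, 0.0
    if p_any >= 1:
        return 1.0, 1.0

    def p_common(p_rare):
        odds = planted_or * p_rare / (1 - p_rare)
        return odds / (1 + odds)

    f = lambda p_rare: w_common * p_common(p_rare) + (1 - w_common) * p_rare - p_any  # noqa: E731
    p_rare = brentq(f, 1e-12, 1 - 1e-12)
    return p_common(p_rare), p_rare


def _conditional_class_rates(rates: dict) -> np.ndarray:
    """Per-class Bernoulli rates r_c such that, conditioned on at least one
    class firing, the class marginals equal rate_c / rate_any."""
    q = np.array([rates["protein"], rates["dna"], rates["rna"]]) / rates["any"]
    if np.any(q > 1 + 1e-12):
        raise ValueError(
            f"infeasible rates: a per-class rate exceeds the any-class rate "
            f"(feasible: each class rate <= {rates['any']})"
        )
    q = np.minimum(q, 1.0)
    if q.sum() <= 1 + 1e-12 and np.count_nonzero(q) > 1:
        raise ValueError(
            "infeasible rates: per-class rates must sum to at least the "
            "any-class rate (classes can overlap, not undershoot)"
        )
    if np.count_nonzero(q) <= 1:
        return q
    u = 1.0
    for _ in range(200):
        u_new = 1.0 - np.prod(1.0 - q * u)
        if abs(u_new - u) < 1e-14:
            break
        u = u_new
    return q * u


def _truncated_scores(rng, mean, sd, size) -> np.ndarray:
    """Discretized normal on [-100, 100]; out-of-range draws are resampled,
    never clamped."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    out = np.empty(size)
    todo = np.ones(size, dtype=bool)
    while todo.any():
        draws = rng.normal(mean[todo], sd)
        out[todo] = draws
        todo &= (out < -100) | (out > 100)
    return np.rint(out).astype(int)


def generate_scores(
    config: GeneratorConfig, variants: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw binding membership and all score tables for generated variants.

    Binding membership is drawn per residue position so that the realized
    common/rare odds ratio of SAV-level binding targets ``planted_or`` and
    the per-class marginals target ``binding_rate``. Returns
    ``(effect_scores, background_scores, residue_annotations, bookkeeping)``:
    per-SAV effect scores, the 19 substitution scores per SAV position, and
    per-residue predicted binding scores (score > 0 iff binding), plus
    bookkeeping of the true memberships and expected means.
    """
    rng = _rng(config.seed, 1)
    sm = config.score_model
    rates = config.binding_rate

    positions = variants[["protein_id", "position", "ref_aa"]].drop_duplicates(
        ["protein_id", "position"]
    ).reset_index(drop=True)
    # the frequency class driving each residue's binding rate: common wins
    # when a residue carries both common and rare SAVs (uncommon -> rare
    # rate; those SAVs are dropped downstream anyway)
    is_common = (
        variants.assign(_c=variants["freq_class"] == COMMON)
        .groupby(["protein_id", "position"], sort=False)["_c"]
        .any()
        .to_numpy()
    )
    w_common = float(is_common.mean())

    if rates["any"] <= 0:
        any_binding = np.zeros(len(positions), dtype=bool)
        p_c = p_r = 0.0
    else:
        p_c, p_r = _solve_class_rates(rates["any"], config.planted_or, w_common)
        p = np.where(is_common, p_c, p_r)
        any_binding = rng.random(len(positions)) < p

    member = np.zeros((len(positions), 3), dtype=bool)
    if any_binding.any() and rates["any"] > 0:
        r = _conditional_class_rates(rates)
        idx = np.flatnonzero(any_binding)
        draws = rng.random((len(idx), 3)) < r
        redo = ~draws.any(axis=1)
        while redo.any():
            draws[redo] = rng.random((int(redo.sum()), 3)) < r
            redo = ~draws.any(axis=1)
        member[idx] = draws

    # per-class binding scores: sign consistent with membership, magnitude
    # exceeding 50 for a `reliable_fraction` of residues
    n_pos = len(positions)
    reliable = rng.random((n_pos, 3)) < config.reliable_fraction
    lo = np.where(reliable, 50, 1)
    hi = np.where(reliable, 101, 50)
    magnitude = rng.integers(lo, hi)
    sign = np.where(member, 1, -1)
    binding_scores = sign * magnitude

    annotations = positions[["protein_id", "position"]].copy()
    annotations["source"] = "predicted"
    for j, cls in enumerate(("protein", "dna", "rna")):
        annotations[f"{cls}_score"] = binding_scores[:, j]

    # per-SAV effect scores from the (freq_class, binding) group means
    n_classes = member.sum(axis=1)
    pos_info = positions[["protein_id", "position"]].assign(
        _any=any_binding,
        _bonus=sm.multi_binding_bonus * np.maximum(n_classes - 1, 0),
    )
    sav_info = variants[["protein_id", "position", "freq_class"]].merge(
        pos_info, on=["protein_id", "position"], how="left"
    )
    sav_binding = sav_info["_any"].to_numpy(dtype=bool)
    fc = sav_info["freq_class"].to_numpy()
    means = np.select(
        [
            (fc == COMMON) & sav_binding,
            (fc == COMMON) & ~sav_binding,
            (fc == RARE) & sav_binding,
            (fc == RARE) & ~sav_binding,
            sav_binding,
        ],
        [
            sm.mean(COMMON, True),
            sm.mean(COMMON, False),
            sm.mean(RARE, True),
            sm.mean(RARE, False),
            sm.mean(UNCOMMON, True),
        ],
        default=sm.mean(UNCOMMON, False),
    ) + sav_info["_bonus"].to_numpy(dtype=float)
    effect_scores = variants[["protein_id", "position", "ref_aa", "alt_aa"]].copy()
    effect_scores["snap2_score"] = _truncated_scores(rng, means, sm.sd, len(variants))

    # 19-non-native background per SAV position
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    ref_idx = np.array([AMINO_ACIDS.index(a) for a in positions["ref_aa"]])
    alt_rank = np.tile(np.arange(19), n_pos)
    ref_rep = np.repeat(ref_idx, 19)
    alt_idx = np.where(alt_rank < ref_rep, alt_rank, alt_rank + 1)
    bg_binding = np.repeat(any_binding, 19)
    bg_means = np.where(
        bg_binding, sm.background_mean(True), sm.background_mean(False)
    )
    background = pd.DataFrame(
        {
            "protein_id": np.repeat(positions["protein_id"].to_numpy(), 19),
            "position": np.repeat(positions["position"].to_numpy(), 19),
            "ref_aa": np.repeat(positions["ref_aa"].to_numpy(), 19),
            "alt_aa": aa[alt_idx],
            "snap2_score": _truncated_scores(rng, bg_means, sm.sd, n_pos * 19),
        }
    )

    sav_common = (variants["freq_class"] == COMMON).to_numpy()
    sav_rare = (variants["freq_class"] == RARE).to_numpy()
    bookkeeping = {
        "p_binding_common": p_c,
        "p_binding_rare": p_r,
        "true_any_binding": {
            (pid, int(pos)): bool(b)
            for pid, pos, b in zip(
                positions["protein_id"], positions["position"], any_binding
            )
        },
        "n_scored_savs": len(variants),
        "realized_counts": {
            "n_cb": int((sav_common & sav_binding).sum()),
            "n_cn": int((sav_common & ~sav_binding).sum()),
            "n_rb": int((sav_rare & sav_binding).sum()),
            "n_rn": int((sav_rare & ~sav_binding).sum()),
        },
        "expected_background_mean": float(np.mean(bg_means)),
        "binding_fraction_positions": float(any_binding.mean()),
    }
    return effect_scores, background, annotations, bookkeeping


@dataclass(frozen=True)
class ComplexConfig:
    """Toy complex: a C-alpha-trace protein query chain along the x-axis plus
    substrate chains whose atoms sit at a controlled distance from planted
    residues. The default 5.5 A contact distance keeps neighbours of a
    planted residue outside 6 A (sqrt(3.8^2 + 5.5^2) > 6)."""

    n_residues: int = 30
    protein_contacts: tuple[int, ...] = (3, 8, 15)   # 1-based query positions
    dna_contacts: tuple[int, ...] = (5, 20)
    rna_contacts: tuple[int, ...] = (25,)
    contact_distance: float = 5.5
    protein_id: str = "SYNC0001"
    seq_offset: int = 100  # chain residue i maps to sequence position i + offset
    ca_spacing: float = 3.8


def _add_residue(chain: gemmi.Chain, name: str, seqid: int, atom_name: str,
                 element: str, xyz: tuple[float, float, float]) -> None:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(seqid, " ")
    atom = gemmi.Atom()
    atom.name = atom_name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*xyz)
    atom.occ = 1.0
    res.add_atom(atom)
    chain.add_residue(res)


def generate_complex(config: ComplexConfig = ComplexConfig()) -> tuple[
    gemmi.Structure, pd.DataFrame, pd.DataFrame
]:
    """Build the toy structure, its residue mapping, and the planted truth.

    Returns ``(structure, mapping, planted)``: mapping columns are chain_id,
    struct_resnum, protein_id, seq_pos; planted columns protein_id, seq_pos,
    binding_class — exactly the residues whose closest substrate atom of each
    class lies at ``contact_distance``.
    """
    for contacts in (config.protein_contacts, config.dna_contacts, config.rna_contacts):
        if any(p < 1 or p > config.n_residues for p in contacts):
            raise ValueError("planted contact outside the query chain")

    st = gemmi.Structure()
    st.name = "synthetic-complex"
    model = gemmi.Model("1")

    qchain = gemmi.Chain("A")
    for i in range(config.n_residues):
        _add_residue(qchain, "GLY", i + 1, "CA", "C", (config.ca_spacing * i, 0.0, 0.0))
    model.add_chain(qchain)

    d = config.contact_distance
    substrate_spec = [
        ("B", "protein", "GLY", "CA", "C", config.protein_contacts, (0.0, d, 0.0)),
        ("C", "dna", "DA", "P", "P", config.dna_contacts, (0.0, -d, 0.0)),
        ("D", "rna", "A", "P", "P", config.rna_contacts, (0.0, 0.0, d)),
    ]
    planted_rows = []
    for chain_id, cls, resname, atom_name, element, contacts, offset in substrate_spec:
        ch = gemmi.Chain(chain_id)
        seq = 1
        for p in contacts:
            base = (config.ca_spacing * (p - 1), 0.0, 0.0)
            xyz = tuple(b + o for b, o in zip(base, offset))
            _add_residue(ch, resname, seq, atom_name, element, xyz)
            seq += 1
            planted_rows.append(
                {"protein_id": config.protein_id,
                 "seq_pos": p + config.seq_offset,
                 "binding_class": cls}
            )
        # distant anchor so the chain types correctly even with no contacts
        _add_residue(ch, resname, seq, atom_name, element, (0.0, 300.0 + 10 * seq, 300.0))
        model.add_chain(ch)

    st.add_model(model)
    st.setup_entities()

    mapping = pd.DataFrame(
        {
            "chain_id": "A",
            "struct_resnum": [str(i + 1) for i in range(config.n_residues)],
            "protein_id": config.protein_id,
            "seq_pos": [i + 1 + config.seq_offset for i in range(config.n_residues)],
        }
    )
    planted = pd.DataFrame(planted_rows, columns=["protein_id", "seq_pos", "binding_class"])
    return st, mapping, planted


@dataclass(frozen=True)
class ExpressionConfig:
    n_tissues: int = 12
    #: planted (protein index or id -> tissue index) over-expression pairs
    n_planted_per_tissue: int = 2
    baseline_log_mean: float = np.log(5.0)
    baseline_log_sd: float = 1.0
    min_level: float = 1.0
    fold: float = 4.0
    planting_margin: float = 1.5
    seed: int = 0


def generate_expression(
    protein_ids, config: ExpressionConfig = ExpressionConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal baseline expression with planted tissue enrichment.

    Planted (protein, tissue) pairs get their focal-tissue level raised to
    ``planting_margin * max(min_level, fold * mean-over-other-tissues)``, so
    the four-fold rule is guaranteed to fire for them. Returns the matrix
    (proteins x tissues) and the planted pairs.
    """
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _rng(config.seed, 2)
    protein_ids = list(protein_ids)
    tissues = [f"tissue_{j + 1:02d}" for j in range(config.n_tissues)]
    x = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                      size=(len(protein_ids), config.n_tissues))

    planted_rows = []
    if config.n_planted_per_tissue > 0:
        # distinct proteins across all plantings: raising a protein in one
        # tissue would otherwise lift the other-tissue mean of a second
        # planting for the same protein and break its four-fold margin
        total = min(config.n_planted_per_tissue * config.n_tissues, len(protein_ids))
        picks = rng.choice(len(protein_ids), size=total, replace=False)
        for k, i in enumerate(picks):
            j = k % config.n_tissues
            other_mean = (x[i].sum() - x[i, j]) / (config.n_tissues - 1)
            x[i, j] = config.planting_margin * max(
                config.min_level, config.fold * other_mean
            )
            planted_rows.append({"protein_id": protein_ids[i], "tissue": tissues[j]})

    matrix = pd.DataFrame(x, index=pd.Index(protein_ids, name="protein_id"),
                          columns=tissues)
    planted = pd.DataFrame(planted_rows, columns=["protein_id", "tissue"])
    return matrix, planted.drop_duplicates(ignore_index=True)


def generate_dataset(config: GeneratorConfig,
                     expression: ExpressionConfig | None = None) -> dict:
    """All four input kinds from one config; bookkeeping included."""
    variants, vbook = generate_variants(config)
    effect, background, annotations, sbook = generate_scores(config, variants)
    expr_cfg = expression or ExpressionConfig(seed=config.seed)
    matrix, planted_expr = generate_expression(
        sorted(variants["protein_id"].unique()), expr_cfg
    )
    st, mapping, planted_iface = generate_complex(ComplexConfig())
    return {
        "variants": variants,
        "effect_scores": effect,
        "background_scores": background,
        "residue_annotations": annotations,
        "expression": matrix,
        "structure": st,
        "structure_mapping": mapping,
        "planted_interfaces": planted_iface,
        "planted_expression": planted_expr,
        "bookkeeping": {**vbook, **sbook},
    }


def write_dataset(bundle: dict, outdir) -> dict:
    """Serialize a generated bundle to TSV/PDB files; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def tsv(name, df, index=False):
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    tsv("variants.tsv", bundle["variants"])
    tsv("effect_scores.tsv", bundle["effect_scores"])
    tsv("background_scores.tsv", bundle["background_scores"])
    tsv("residue_annotations.tsv", bundle["residue_annotations"])
    tsv("expression.tsv", bundle["expression"].reset_index())
    tsv("structure_mapping.tsv", bundle["structure_mapping"])
    tsv("planted_interfaces.tsv", bundle["planted_interfaces"])
    pdb_path = os.path.join(outdir, "complex.pdb")
    bundle["structure"].write_pdb(pdb_path)
    paths["complex.pdb"] = pdb_path
    return paths
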