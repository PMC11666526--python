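"""Score harmonization across binding predictors, consensus ranking, and
the multifocal sharing screen.

Predictors disagree on scale and direction: binding-affinity tools report
IC50-like concentrations (nM, lower = stronger), eluted-ligand and motif
tools report scores where higher = stronger.  Harmonization proceeds in
three steps:

1. ``b = 1 / log10(a)`` for affinity-type pre-scores ``a``, turning them
   into a score that increases with binding strength; eluted-ligand and
   SYFPEITHI scores pass through unchanged.
2. Fold change ``FC = a_wt / a_mut`` captures how much the mutation
   improves predicted binding (FC > 1: mutant binds better).
3. Each score column is min-max rescaled onto [1, 20]:
   ``c = (b - min b) / (max b - min b) * 19 + 1``, so all columns share one
   plotting/comparison scale.  A degenerate column (all values equal) maps
   to the midpoint 10.5.

The logarithm base is configurable; it cancels in the rank-preserving
rescaled score.  Affinity pre-scores at or below 1 nM are clamped to
1 + eps before the transform (the log would vanish or change sign).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import Algorithm, BinderCall, BindingRecord, BA_TYPE
from .peptide_enum import PeptidePair

__all__ = [
    "HarmonizedScore",
    "CandidateRanking",
    "transform_b",
    "fold_change",
    "rescale_c",
    "harmonize",
    "select_top",
    "foci_distribution",
    "write_ranking_tsv",
]

logger = logging.getLogger(__name__)

#: guard for affinity pre-scores near 1 nM, where 1/log a is singular
EPSILON_A = 0.01

RESCALE_FLOOR = 1.0
RESCALE_SPAN = 19.0
DEGENERATE_C = 10.5  # midpoint of [1, 20]

FOLD_CHANGE = "FOLD_CHANGE"


@dataclass(frozen=True)
class HarmonizedScore:
    pair_id: str
    algorithm: str  # Algorithm value or "FOLD_CHANGE"
    b: float
    c: float | None = None
    raw_a: float | None = None
    fc: float | None = None


@dataclass
class CandidateRanking:
    """Ranked candidates with the per-algorithm rescaled-score matrix."""

    pair_ids: list[str]
    c_matrix: pd.DataFrame  # pairs x algorithm columns, values in [1, 20]
    consensus: pd.Series  # per pair, mean of available c values
    ic50_mut: pd.Series
    pairs: dict[str, PeptidePair]

    @property
    def foci_matrix(self) -> pd.DataFrame:
        """Pairs x foci boolean presence matrix, in rank order."""
        all_foci = sorted(set().union(*(self.pairs[i].foci for i in self.pair_ids)) or set())
        return pd.DataFrame(
            [[f in self.pairs[i].foci for f in all_foci] for i in self.pair_ids],
            index=pd.Index(self.pair_ids, name="pair_id"),
            columns=all_foci,
        )


def transform_b(raw_a: float, algorithm: Algorithm, log_base: float = 10.0) -> float:
    """Direction-harmonizing transform of one pre-score.

    Affinity-type algorithms: ``b = 1 / log(a)`` (strictly decreasing in a
    on (1, inf)); eluted-ligand / SYFPEITHI scores are returned unchanged.
    Affinity pre-scores <= 1 + eps are clamped with a warning.
    """
    if raw_a <= 0:
        raise ValueError("pre-score must be positive")
    if algorithm not in BA_TYPE:
        return raw_a
    if raw_a <= 1 + EPSILON_A:
        logger.warning("pre-score %.4g clamped to %.4g before 1/log transform", raw_a, 1 + EPSILON_A)
        raw_a = 1 + EPSILON_A
    return 1.0 / (math.log(raw_a) / math.log(log_base))


def fold_change(a_wt: float, a_mut: float) -> float:
    """Wild-type pre-score over mutant pre-score; > 1 means the mutant
    binds at a lower (better) concentration than the wild type."""
    if a_mut <= 0 or a_wt <= 0:
        raise ValueError("pre-scores must be positive")
    return a_wt / a_mut


def rescale_c(values) -> list[float]:
    """Min-max rescale a score batch onto [1, 20], order-preserving.

    The batch minimum maps to 1 and the maximum to 20; a degenerate batch
    (max == min) maps every value to the midpoint 10.5.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rescale an empty batch")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return [DEGENERATE_C] * arr.size
    return list((arr - lo) / (hi - lo) * RESCALE_SPAN + RESCALE_FLOOR)


def harmonize(
    pairs: list[PeptidePair],
    records: list[BindingRecord],
    allele: str,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Per-pair harmonized score matrix for one allele.

    Columns: one per algorithm present in ``records`` (rescaled c of the
    transformed mutant score) plus ``FOLD_CHANGE`` (rescaled c of
    a_wt / a_mut) where an affinity-type column provides both members.
    Rescaling is done within each column across the supplied batch of pairs.
    """
    lookup: dict[tuple[str, Algorithm], float] = {}
    for r in records:
        if r.allele == allele:
            lookup[(r.peptide, r.algorithm)] = r.pre_score_a
    algos = sorted({a for (_, a) in lookup}, key=lambda a: a.value)
    columns: dict[str, dict[str, float]] = {}
    for algo in algos:
        b_col = {}
        for p in pairs:
            a = lookup.get((p.mt_seq, algo))
            if a is not None:
                b_col[p.pair_id] = transform_b(a, algo, log_base)
        if b_col:
            columns[algo.value] = b_col
    # fold change from the first affinity-type algorithm with both members
    for algo in algos:
        if algo not in BA_TYPE:
            continue
        fc_col = {}
        for p in pairs:
            a_mut = lookup.get((p.mt_seq, algo))
            a_wt = lookup.get((p.wt_seq, algo))
            if a_mut is not None and a_wt is not None:
                fc_col[p.pair_id] = fold_change(a_wt, a_mut)
        if fc_col:
            columns[FOLD_CHANGE] = fc_col
            break
    out = {}
    for name, col in columns.items():
        ids = list(col)
        out[name] = pd.Series(rescale_c([col[i] for i in ids]), index=ids)
    return pd.DataFrame(out)


def select_top(
    pairs: list[PeptidePair],
    calls: list[BinderCall],
    c_matrix: pd.DataFrame | None = None,
    n: int = 30,
) -> CandidateRanking:
    """Select the n candidates with strongest first-round mutant binding.

    Selection is by lowest mutant IC50 (each pair's best call); the
    returned ranking is then ordered by consensus — the unweighted mean of
    the pair's available rescaled scores — descending, ties broken by
    mutant IC50 then pair id.  Expects deduplicated, high-binder pairs.
    """
    best_ic50: dict[str, float] = {}
    for c in calls:
        if c.pair_id not in best_ic50 or c.ic50_mut < best_ic50[c.pair_id]:
            best_ic50[c.pair_id] = c.ic50_mut
    scored = [p for p in pairs if p.pair_id in best_ic50]
    if n > len(scored):
        logger.info("requested top %d but only %d scored candidates", n, len(scored))
    selected = sorted(scored, key=lambda p: (best_ic50[p.pair_id], p.pair_id))[:n]
    ids = [p.pair_id for p in selected]
    if c_matrix is None:
        c_matrix = pd.DataFrame(index=ids)
    c_matrix = c_matrix.reindex(ids)
    consensus = (
        c_matrix.mean(axis=1) if not c_matrix.empty and c_matrix.shape[1] else
        pd.Series(0.0, index=ids)
    )
    consensus = consensus.fillna(0.0)
    order = sorted(ids, key=lambda i: (-consensus[i], best_ic50[i], i))
    return CandidateRanking(
        pair_ids=order,
        c_matrix=c_matrix.reindex(order),
        consensus=consensus.reindex(order),
        ic50_mut=pd.Series({i: best_ic50[i] for i in order}).reindex(order),
        pairs={p.pair_id: p for p in selected},
    )


def foci_distribution(
    ranking: CandidateRanking | list[PeptidePair], min_foci: int = 2
) -> tuple[list[PeptidePair], pd.DataFrame]:
    """Candidates present in at least ``min_foci`` tumor foci.

    Accepts a ranking (preserves its order) or a bare pair list.  Returns
    the qualifying pairs and the full presence matrix (pairs x foci) for
    context.
    """
    if isinstance(ranking, CandidateRanking):
        pairs = [ranking.pairs[i] for i in ranking.pair_ids]
    else:
        pairs = list(ranking)
    all_foci = sorted(set().union(*(p.foci for p in pairs)) if pairs else set())
    matrix = pd.DataFrame(
        [[f in p.foci for f in all_foci] for p in pairs],
        index=pd.Index([p.pair_id for p in pairs], name="pair_id"),
        columns=all_foci,
    )
    shared = [p for p in pairs if len(p.foci) >= min_foci]
    return shared, matrix


def write_ranking_tsv(path, ranking: CandidateRanking, calls: list[BinderCall] | None = None) -> None:
    wt_ic50: dict[str, float] = {}
    if calls:
        best: dict[str, BinderCall] = {}
        for c in calls:
            if c.pair_id not in best or c.ic50_mut < best[c.pair_id].ic50_mut:
                best[c.pair_id] = c
        wt_ic50 = {i: b.ic50_wt for i, b in best.items()}
    rows = []
    for i in ranking.pair_ids:
        p = ranking.pairs[i]
        row = {
            "pair_id": i,
            "gene": p.gene,
            "wt_seq": p.wt_seq,
            "mt_seq": p.mt_seq,
            "ic50_wt": round(wt_ic50[i], 1) if i in wt_ic50 else "",
            "ic50_mut": round(float(ranking.ic50_mut[i]), 1),
        }
        for col in ranking.c_matrix.columns:
            v = ranking.c_matrix.loc[i, col]
            row[f"c_{col}"] = "" if pd.isna(v) else round(float(v), 4)
        row["consensus"] = round(float(ranking.consensus[i]), 4)
        row["foci"] = ";".join(sorted(p.foci))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
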