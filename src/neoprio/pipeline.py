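"""End-to-end orchestration: variants -> peptides -> filter -> ranking.

Chains the stage modules so the command-line interface, the report writer
and scripted analyses all execute the identical sequence of operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import binding as _binding
from . import harmonize_rank as _hr
from . import peptide_enum as _pe
from .binding import BinderCall, BindingRecord
from .cohort_model import Focus, SomaticVariant, VariantClass
from .peptide_enum import PeptidePair, Transcript

__all__ = ["PipelineResult", "enumerate_cohort_pairs", "run_pipeline"]


def enumerate_cohort_pairs(
    variants: list[SomaticVariant],
    transcripts: list[Transcript],
    lengths: frozenset[int] = _pe.DEFAULT_LENGTHS,
) -> list[PeptidePair]:
    """Deduplicated candidate pairs for every coding, non-silent variant."""
    by_gene = {t.gene: t for t in transcripts}
    all_pairs: list[PeptidePair] = []
    for v in variants:
        if v.is_silent or v.variant_class is VariantClass.SPLICE_SITE:
            continue
        tr = by_gene.get(v.gene)
        if tr is None:
            continue
        event = _pe.apply_variant(tr, v)
        if event is None:
            continue
        all_pairs.extend(
            _pe.pairs_from_event(event, pair_prefix=f"{v.gene}.{v.key}", lengths=lengths)
        )
    return _pe.deduplicate(all_pairs)


@dataclass
class PipelineResult:
    pairs: list[PeptidePair]  # deduplicated candidate pairs
    records: list[BindingRecord]
    calls: list[BinderCall]
    high_binders: list[PeptidePair]
    ranking: _hr.CandidateRanking
    shared: list[PeptidePair]  # candidates in >= min_foci foci
    tnb: pd.DataFrame
    pair_index: dict[str, PeptidePair] = field(default_factory=dict)


def run_pipeline(
    variants: list[SomaticVariant],
    transcripts: list[Transcript],
    alleles: list[str],
    records: list[BindingRecord] | None = None,
    lengths: frozenset[int] = _pe.DEFAULT_LENGTHS,
    ic50_threshold: float = _binding.DEFAULT_IC50_THRESHOLD,
    top_n: int = 30,
    min_foci: int = 2,
    log_base: float = 10.0,
    seed: int = 0,
) -> PipelineResult:
    """Run enumeration, filtering, harmonization and ranking in one pass.

    When ``records`` is None the built-in toy predictor scores every
    peptide; supply parsed external-predictor records to use real scores.
    Splice-site and silent variants yield no peptides.
    """
    pairs = enumerate_cohort_pairs(variants, transcripts, lengths)
    if records is None:
        records = _binding.predict_pairs(pairs, alleles, seed=seed)
    calls = _binding.call_high_binders(pairs, records, ic50_threshold, alleles=alleles)

    high_ids = {c.pair_id for c in calls if c.is_high_binder}
    high_binders = [p for p in pairs if p.pair_id in high_ids]
    high_calls = [c for c in calls if c.pair_id in high_ids]

    # round 1: select by best mutant IC50; round 2: harmonize and re-rank the
    # selected batch (the [1, 20] rescale is defined within the displayed set)
    round1 = _hr.select_top(high_binders, high_calls, None, n=top_n)
    sel = set(round1.pair_ids)
    sel_pairs = [round1.pairs[i] for i in round1.pair_ids]
    sel_calls = [c for c in high_calls if c.pair_id in sel]
    c_matrix = _hr.harmonize(sel_pairs, records, alleles[0], log_base) if alleles else None
    ranking = _hr.select_top(sel_pairs, sel_calls, c_matrix, n=top_n)
    shared, _ = _hr.foci_distribution(ranking, min_foci=min_foci)

    pair_index = {p.pair_id: p for p in pairs}
    tnb = _binding.compute_tnb(variants, calls, pair_index)
    return PipelineResult(
        pairs=pairs,
        records=records,
        calls=calls,
        high_binders=high_binders,
        ranking=ranking,
        shared=shared,
        tnb=tnb,
        pair_index=pair_index,
    )
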