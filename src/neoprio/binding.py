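"""Binding-prediction backends, predictor-output parsers, the high-binder
filter, and tumor neoantigen burden (TNB).

A *high binder* is a mutant peptide with predicted IC50 below 500 nM that
also binds more strongly than its wild-type counterpart (IC50 mutant <
IC50 wild-type), both inequalities strict.  TNB for a sample is the number
of distinct non-silent mutations yielding at least one high-binder peptide.

The built-in toy predictor is a deterministic pseudo-IC50 model that
rewards canonical HLA-A*02:01 anchor residues (L/M at position 2, V/L/I at
the C-terminus); it exists so the whole pipeline runs offline and is fully
reproducible, not to approximate any published predictor's accuracy.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .cohort_model import SomaticVariant, VariantType
from .peptide_enum import STANDARD_AA, PeptidePair

__all__ = [
    "Algorithm",
    "Direction",
    "BindingRecord",
    "BinderCall",
    "toy_predict",
    "predict_pairs",
    "parse_predictor_table",
    "call_high_binders",
    "compute_tnb",
    "write_calls_tsv",
    "DEFAULT_IC50_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_IC50_THRESHOLD = 500.0
MAX_IC50 = 50000.0


class Algorithm(str, Enum):
    NETMHCPAN = "NETMHCPAN"
    IEDB_BA = "IEDB_BA"
    IEDB_EL = "IEDB_EL"
    SYFPEITHI = "SYFPEITHI"
    TOY = "TOY"


class Direction(str, Enum):
    LOWER_IS_BETTER = "LOWER_IS_BETTER"  # binding-affinity (nM) scores
    HIGHER_IS_BETTER = "HIGHER_IS_BETTER"  # eluted-ligand / SYFPEITHI scores


BA_TYPE = {Algorithm.NETMHCPAN, Algorithm.IEDB_BA, Algorithm.TOY}


def direction_for(algorithm: Algorithm) -> Direction:
    return (
        Direction.LOWER_IS_BETTER if algorithm in BA_TYPE else Direction.HIGHER_IS_BETTER
    )


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    algorithm: Algorithm
    pre_score_a: float

    def __post_init__(self) -> None:
        if self.pre_score_a <= 0:
            raise ValueError("pre-score must be positive")

    @property
    def direction(self) -> Direction:
        return direction_for(self.algorithm)


@dataclass(frozen=True)
class BinderCall:
    pair_id: str
    allele: str
    ic50_mut: float
    ic50_wt: float
    is_high_binder: bool


# ---------------------------------------------------------------------------
# Toy predictor

#: anchor bonuses: each matched anchor divides the pseudo-IC50 by this factor
_ANCHOR_FACTOR = 25.0
_P2_ANCHORS = frozenset("LM")
_CTERM_ANCHORS = frozenset("VLI")


def toy_predict(peptide: str, allele: str, seed: int = 0) -> BindingRecord:
    """Deterministic pseudo-IC50 for one peptide/allele combination.

    The base affinity is a log-uniform value in (0, 50000] nM derived from a
    SHA-256 hash of (peptide, allele, seed); peptides with the canonical
    A*02:01 anchor residues (L/M at P2, V/L/I at the C-terminus) are
    rewarded with a fixed multiplicative bonus per matched anchor.  Same
    inputs always give the same value.
    """
    if not (8 <= len(peptide) <= 11):
        raise ValueError("peptide must be 8-11 residues")
    if not set(peptide) <= STANDARD_AA:
        bad = sorted(set(peptide) - STANDARD_AA)
        raise ValueError(f"nonstandard residue(s) {bad} in {peptide!r}")
    digest = hashlib.sha256(f"{peptide}|{allele}|{seed}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64  # uniform [0, 1)
    # log-uniform over [100, 2000] nM before anchor bonuses; the base span
    # (20x) is kept below the anchor factor (25x) so an extra matched anchor
    # always outranks any hash draw
    ic50 = 100.0 * (20.0 ** u)
    if peptide[1] in _P2_ANCHORS:
        ic50 /= _ANCHOR_FACTOR
    if peptide[-1] in _CTERM_ANCHORS:
        ic50 /= _ANCHOR_FACTOR
    ic50 = min(max(ic50, 1e-3), MAX_IC50)
    return BindingRecord(peptide=peptide, allele=allele, algorithm=Algorithm.TOY, pre_score_a=ic50)


def predict_pairs(
    pairs: list[PeptidePair], alleles: list[str], seed: int = 0
) -> list[BindingRecord]:
    """Toy-predict both members of every pair against every allele."""
    records = []
    seen = set()
    for p in pairs:
        for pep in (p.mt_seq, p.wt_seq):
            for allele in alleles:
                if (pep, allele) in seen:
                    continue
                seen.add((pep, allele))
                records.append(toy_predict(pep, allele, seed))
    return records


# ---------------------------------------------------------------------------
# External predictor table parsers

def parse_predictor_table(path: str | Path, format: str) -> list[BindingRecord]:
    """Parse one external predictor's tabular output.

    Dialects (one golden fixture of each ships in ``fixtures/``):

    - ``NETMHCPAN_XLS``: the tab-separated "xls" export; line 1 carries the
      allele name, line 2 the column header including ``Peptide`` and ``nM``.
    - ``IEDB_CSV``: comma-separated with ``allele,peptide,ic50`` columns
      (binding-affinity mode) or ``allele,peptide,score`` (eluted-ligand
      mode).
    - ``SYFPEITHI_TSV``: tab-separated ``allele, peptide, score`` with
      integer motif scores (higher is better).
    """
    path = Path(path)
    if format == "NETMHCPAN_XLS":
        return _parse_netmhcpan_xls(path)
    if format == "IEDB_CSV":
        return _parse_iedb_csv(path)
    if format == "SYFPEITHI_TSV":
        return _parse_syfpeithi_tsv(path)
    raise ValueError(f"unknown predictor format {format!r}")


class PredictorFormatError(ValueError):
    pass


def _parse_netmhcpan_xls(path: Path) -> list[BindingRecord]:
    with open(path) as fh:
        allele_line = fh.readline().strip()
        header = fh.readline().rstrip("\n").split("\t")
        if "Peptide" not in header or "nM" not in header:
            raise PredictorFormatError(
                f"not a NetMHCpan-style table; detected header: {header}"
            )
        allele = allele_line.split("\t")[0].strip() or "HLA-A*02:01"
        pep_i, nm_i = header.index("Peptide"), header.index("nM")
        records = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            records.append(
                BindingRecord(
                    peptide=fields[pep_i],
                    allele=allele,
                    algorithm=Algorithm.NETMHCPAN,
                    pre_score_a=float(fields[nm_i]),
                )
            )
    return records


def _parse_iedb_csv(path: Path) -> list[BindingRecord]:
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"allele", "peptide"} <= cols:
        raise PredictorFormatError(f"not an IEDB-style table; detected header: {sorted(cols)}")
    if "ic50" in cols:
        algo, value_col = Algorithm.IEDB_BA, "ic50"
    elif "score" in cols:
        algo, value_col = Algorithm.IEDB_EL, "score"
    else:
        raise PredictorFormatError("IEDB table needs an 'ic50' or 'score' column")
    return [
        BindingRecord(
            peptide=row.peptide,
            allele=row.allele,
            algorithm=algo,
            pre_score_a=float(getattr(row, value_col)),
        )
        for row in df.itertuples(index=False)
    ]


def _parse_syfpeithi_tsv(path: Path) -> list[BindingRecord]:
    df = pd.read_csv(path, sep="\t")
    if not {"allele", "peptide", "score"} <= set(df.columns):
        raise PredictorFormatError(
            f"not a SYFPEITHI-style table; detected header: {list(df.columns)}"
        )
    return [
        BindingRecord(
            peptide=row.peptide,
            allele=row.allele,
            algorithm=Algorithm.SYFPEITHI,
            pre_score_a=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# High-binder filter

def call_high_binders(
    pairs: list[PeptidePair],
    records: list[BindingRecord],
    ic50_threshold: float = DEFAULT_IC50_THRESHOLD,
    alleles: list[str] | None = None,
) -> list[BinderCall]:
    """Apply the first-round filter: IC50(mut) < threshold and < IC50(wt).

    ``records`` must contain binding-affinity-type predictions for both the
    mutant and wild-type sequence of each pair.  The filter is evaluated on
    a single IC50 source: the first affinity-type algorithm present, in the
    order NetMHCpan, toy, IEDB-BA (mixing sources inside one inequality
    would compare concentrations from different models).  With several
    alleles a pair is called against each; it is a high binder if the
    condition holds for at least one.  One BinderCall per (pair, allele)
    with scores; the call carrying the pair's best (lowest) mutant IC50 is
    listed first per pair.  Pairs missing a score are skipped with a
    warning, never silently dropped into the non-binder pool.
    """
    present = {r.algorithm for r in records}
    source = next(
        (a for a in (Algorithm.NETMHCPAN, Algorithm.TOY, Algorithm.IEDB_BA) if a in present),
        None,
    )
    lookup: dict[tuple[str, str], float] = {}
    for r in records:
        if r.algorithm is source:
            lookup[(r.peptide, r.allele)] = r.pre_score_a
    if alleles is None:
        alleles = sorted({r.allele for r in records if r.algorithm is source})
    calls = []
    for p in pairs:
        pair_calls = []
        for allele in alleles:
            mut = lookup.get((p.mt_seq, allele))
            wt = lookup.get((p.wt_seq, allele))
            if mut is None or wt is None:
                logger.warning(
                    "pair %s skipped for allele %s: missing %s score",
                    p.pair_id,
                    allele,
                    "mutant" if mut is None else "wild-type",
                )
                continue
            is_high = (mut < ic50_threshold) and (mut < wt)
            pair_calls.append(BinderCall(p.pair_id, allele, mut, wt, is_high))
        pair_calls.sort(key=lambda c: c.ic50_mut)
        calls.extend(pair_calls)
    return calls


# ---------------------------------------------------------------------------
# Tumor neoantigen burden

def compute_tnb(
    variants: list[SomaticVariant],
    calls: list[BinderCall],
    pair_index: dict[str, PeptidePair],
    mhc_class: str = "I",
) -> pd.DataFrame:
    """TNB per sample: distinct mutations with >= 1 high-binder peptide.

    Provenance runs call -> pair (via ``pair_index``) -> originating variant
    (via the pair's ``variant_key``).  Split into SNV- and InDel-derived
    burden; the two components sum to the total.  ``mhc_class`` is a label
    only — class-II calls come from external parsers and flow through the
    same accounting.
    """
    if mhc_class not in ("I", "II"):
        raise ValueError("mhc_class must be 'I' or 'II'")
    binder_keys: set[tuple[str, str]] = set()  # (sample_id, variant_key)
    for c in calls:
        if not c.is_high_binder:
            continue
        pair = pair_index.get(c.pair_id)
        if pair is None or not pair.variant_key:
            continue
        for sample in pair.foci:
            binder_keys.add((sample, pair.variant_key))
    samples = sorted({v.sample_id for v in variants})
    vtype_of = {v.key: v.variant_type for v in variants if not v.is_silent}
    rows = []
    for s in samples:
        snv = indel = 0
        for sample, key in binder_keys:
            if sample != s or key not in vtype_of:
                continue
            if vtype_of[key] is VariantType.SNV:
                snv += 1
            else:
                indel += 1
        rows.append({"snv_tnb": snv, "indel_tnb": indel, "total_tnb": snv + indel})
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"))


def write_calls_tsv(path: str | Path, calls: list[BinderCall]) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": c.pair_id,
                "allele": c.allele,
                "ic50_wt": round(c.ic50_wt, 1),
                "ic50_mut": round(c.ic50_mut, 1),
                "is_high_binder": c.is_high_binder,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
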