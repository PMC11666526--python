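"""Mutant protein construction and 8-11-mer peptide enumeration.

Variants are applied to a coding sequence (CDS), the edited CDS is
re-translated, and every mutant window of the requested lengths that
overlaps the altered protein span is paired with the wild-type window at
the same protein coordinate.  For substitutions the pair differs at exactly
one residue; for frameshifts the wild-type window can be entirely unrelated
to the mutant one, which is what is observed for real frameshift
neoantigens.

Coordinates: protein positions are 1-based; a window of length k starting
at s covers residues [s, s+k-1] inclusive.  The toy-genome convention used
by the simulator places each gene on its own contig with the CDS starting
at position 1, so a variant's ``pos`` is its 1-based offset into the CDS.
Only plus-strand transcripts are supported.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from Bio.Seq import Seq

from .cohort_model import SomaticVariant, VariantType

__all__ = [
    "Transcript",
    "Consequence",
    "MutantProteinEvent",
    "PeptidePair",
    "read_transcript_fasta",
    "write_transcript_fasta",
    "apply_variant",
    "enumerate_peptides",
    "pairs_from_event",
    "deduplicate",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_peptide_fasta",
]

DEFAULT_LENGTHS = frozenset({8, 9, 10, 11})

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class Consequence(str, Enum):
    SUBSTITUTION = "SUBSTITUTION"
    IN_FRAME_INDEL = "IN_FRAME_INDEL"
    FRAMESHIFT = "FRAMESHIFT"
    STOP_GAIN = "STOP_GAIN"
    STOP_LOSS = "STOP_LOSS"


@dataclass(frozen=True)
class Transcript:
    """A coding sequence: starts ATG, ends with a stop, no internal stops."""

    gene: str
    cds: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length not a multiple of 3")
        if not self.cds.startswith("ATG"):
            raise ValueError(f"{self.gene}: CDS must start with ATG")
        prot = str(Seq(self.cds).translate())
        if not prot.endswith("*"):
            raise ValueError(f"{self.gene}: CDS must end with a stop codon")
        if "*" in prot[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon")

    @property
    def protein(self) -> str:
        """Translated protein, stop stripped."""
        return str(Seq(self.cds).translate())[:-1]


@dataclass(frozen=True)
class MutantProteinEvent:
    gene: str
    wt_protein: str
    mt_protein: str
    altered_span: tuple[int, int]  # 1-based inclusive, mutant coordinates
    consequence: Consequence
    variant_key: str = ""
    sample_id: str = ""


@dataclass(frozen=True)
class PeptidePair:
    """A mutant 8-11-mer with its wild-type counterpart and provenance."""

    pair_id: str
    gene: str
    wt_seq: str
    mt_seq: str
    mutation_type: str  # "SNV" or "INDEL"
    foci: frozenset[str] = frozenset()
    variant_key: str = ""

    def __post_init__(self) -> None:
        if not (8 <= len(self.mt_seq) <= 11):
            raise ValueError(f"{self.pair_id}: mutant peptide must be 8-11 residues")
        if self.mt_seq == self.wt_seq:
            raise ValueError(f"{self.pair_id}: mutant equals wild-type")
        if self.mutation_type == "SNV":
            if len(self.wt_seq) != len(self.mt_seq):
                raise ValueError(f"{self.pair_id}: SNV pair must be equal-length")


# ---------------------------------------------------------------------------
# FASTA I/O (header convention: >gene|transcript_id)

def read_transcript_fasta(path: str | Path) -> list[Transcript]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, tid = rec.id.partition("|")
        out.append(Transcript(gene=gene, cds=str(rec.seq).upper(), transcript_id=tid))
    return out


def write_transcript_fasta(path: str | Path, transcripts: list[Transcript]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            header = f"{t.gene}|{t.transcript_id}" if t.transcript_id else t.gene
            fh.write(f">{header}\n")
            for i in range(0, len(t.cds), 60):
                fh.write(t.cds[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Variant application

def _edit_cds(cds: str, variant: SomaticVariant, cds_pos: int) -> str:
    """Apply the variant to the CDS at 1-based position ``cds_pos``."""
    i = cds_pos - 1
    if variant.variant_type is VariantType.SNV:
        if cds[i] != variant.ref_allele:
            raise ValueError(
                f"reference mismatch at {variant.gene}:{cds_pos} "
                f"(CDS has {cds[i]}, variant says {variant.ref_allele})"
            )
        return cds[:i] + variant.alt_allele + cds[i + 1 :]
    if variant.variant_type is VariantType.DEL:
        ref = variant.ref_allele
        if cds[i : i + len(ref)] != ref:
            raise ValueError(f"reference mismatch for deletion at {variant.gene}:{cds_pos}")
        return cds[:i] + cds[i + len(ref) :]
    # insertion: alt inserted starting AT cds_pos (MAF '-' ref convention)
    return cds[:i] + variant.alt_allele + cds[i:]


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate codon-by-codon to the first stop; returns (protein, saw_stop)."""
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = str(Seq(seq[i : i + 3]).translate())
        if aa == "*":
            return "".join(prot), True
        prot.append(aa)
    return "".join(prot), False


def apply_variant(
    transcript: Transcript, variant: SomaticVariant, cds_offset: int | None = None
) -> MutantProteinEvent | None:
    """Apply a coding variant and return the resulting protein event.

    ``cds_offset`` is the variant's 1-based position within the CDS; when
    omitted, ``variant.pos`` is used directly (the toy-genome convention).
    Returns None for synonymous outcomes, splice-site variants and variants
    outside the CDS.
    """
    cds_pos = cds_offset if cds_offset is not None else variant.pos
    if not (1 <= cds_pos <= len(transcript.cds)):
        return None  # non-coding
    if variant.variant_class.value == "SPLICE_SITE":
        return None

    wt = transcript.protein
    mt_cds = _edit_cds(transcript.cds, variant, cds_pos)
    mt, saw_stop = _translate_to_stop(mt_cds)

    if mt == wt:
        return None  # synonymous

    # classify by comparing translated proteins
    ref_len = 0 if variant.ref_allele == "-" else len(variant.ref_allele)
    alt_len = 0 if variant.alt_allele == "-" else len(variant.alt_allele)
    frameshift = (ref_len - alt_len) % 3 != 0

    # longest common prefix
    p = 0
    while p < min(len(wt), len(mt)) and wt[p] == mt[p]:
        p += 1

    if variant.variant_type is VariantType.SNV and len(mt) == len(wt) and not frameshift:
        # single-residue substitution (or stop-related below)
        consequence = Consequence.SUBSTITUTION
        span = (p + 1, p + 1)
    elif variant.variant_type is VariantType.SNV and len(mt) < len(wt):
        consequence = Consequence.STOP_GAIN
        span = (p + 1, len(mt)) if p < len(mt) else (max(len(mt), 1), max(len(mt), 1))
    elif variant.variant_type is VariantType.SNV and len(mt) > len(wt):
        consequence = Consequence.STOP_LOSS
        span = (p + 1, len(mt))
    elif frameshift:
        consequence = Consequence.FRAMESHIFT if saw_stop else Consequence.STOP_LOSS
        span = (min(p + 1, len(mt)), len(mt))
    else:
        consequence = Consequence.IN_FRAME_INDEL
        # longest common suffix not overlapping the prefix
        s = 0
        while (
            s < min(len(wt), len(mt)) - p
            and wt[len(wt) - 1 - s] == mt[len(mt) - 1 - s]
        ):
            s += 1
        lo, hi = p + 1, len(mt) - s
        if hi < lo:  # pure deletion: mark the junction
            lo = max(1, p)
            hi = min(len(mt), p + 1)
        span = (lo, hi)

    if not mt:
        return None  # mutation destroyed the start codon / truncated to nothing

    return MutantProteinEvent(
        gene=transcript.gene,
        wt_protein=wt,
        mt_protein=mt,
        altered_span=span,
        consequence=consequence,
        variant_key=variant.key,
        sample_id=variant.sample_id,
    )


# ---------------------------------------------------------------------------
# Window enumeration

def enumerate_peptides(
    event: MutantProteinEvent, lengths: frozenset[int] | set[int] = DEFAULT_LENGTHS
) -> list[tuple[str, str, int, int]]:
    """All mutant windows of the given lengths overlapping the altered span.

    Returns ``(wt_window, mt_window, length, start)`` tuples with 1-based
    starts.  The wild-type counterpart is the wild-type protein window at
    the same start coordinate; if that window would run past the wild-type
    terminus it is right-aligned to the terminus, and omitted (empty string)
    when the wild-type protein is shorter than the window length.
    """
    mt, wt = event.mt_protein, event.wt_protein
    lo, hi = event.altered_span
    out = []
    for k in sorted(lengths):
        if len(mt) < k:
            continue
        start_min = max(1, lo - k + 1)
        start_max = min(hi, len(mt) - k + 1)
        for s in range(start_min, start_max + 1):
            mt_win = mt[s - 1 : s - 1 + k]
            if len(wt) >= k:
                ws = min(s, len(wt) - k + 1)
                wt_win = wt[ws - 1 : ws - 1 + k]
            else:
                wt_win = ""
            out.append((wt_win, mt_win, k, s))
    return out


def pairs_from_event(
    event: MutantProteinEvent,
    pair_prefix: str,
    lengths: frozenset[int] | set[int] = DEFAULT_LENGTHS,
) -> list[PeptidePair]:
    """Peptide pairs for one event; drops windows with stops, ambiguity,
    missing wild-type counterparts, or mutant identical to wild-type."""
    mutation_type = "SNV" if event.consequence is Consequence.SUBSTITUTION else "INDEL"
    pairs = []
    n = 0
    for wt_win, mt_win, k, s in enumerate_peptides(event, lengths):
        if not wt_win or mt_win == wt_win:
            continue
        if not (set(mt_win) <= STANDARD_AA and set(wt_win) <= STANDARD_AA):
            continue
        n += 1
        pairs.append(
            PeptidePair(
                pair_id=f"{pair_prefix}.{k}.{s}",
                gene=event.gene,
                wt_seq=wt_win,
                mt_seq=mt_win,
                mutation_type=mutation_type,
                foci=frozenset({event.sample_id} if event.sample_id else set()),
                variant_key=event.variant_key,
            )
        )
    return pairs


def deduplicate(
    pairs: list[PeptidePair],
    policy: str = "BY_GENE_AND_PEPTIDE",
    scores: dict[str, float] | None = None,
) -> list[PeptidePair]:
    """Collapse duplicate candidates, unioning their foci sets.

    ``BY_GENE_AND_PEPTIDE`` (default) keeps at most one pair per
    (gene, mutant sequence); ``BY_PEPTIDE`` keys on the mutant sequence
    alone.  Among duplicates, the pair with the best (lowest) mutant
    pre-score survives when ``scores`` (pair_id -> score) is given,
    otherwise the first occurrence.  Idempotent.
    """
    if policy not in ("BY_PEPTIDE", "BY_GENE_AND_PEPTIDE"):
        raise ValueError(f"unknown policy {policy!r}")
    groups: dict[tuple, list[PeptidePair]] = defaultdict(list)
    order: list[tuple] = []
    for p in pairs:
        key = (p.gene, p.mt_seq) if policy == "BY_GENE_AND_PEPTIDE" else (p.mt_seq,)
        if key not in groups:
            order.append(key)
        groups[key].append(p)
    out = []
    for key in order:
        group = groups[key]
        if scores:
            best = min(
                group, key=lambda p: scores.get(p.pair_id, float("inf"))
            )
        else:
            best = group[0]
        foci = frozenset().union(*(p.foci for p in group))
        out.append(replace(best, foci=foci))
    return out


# ---------------------------------------------------------------------------
# Tabular output

def write_pairs_tsv(path: str | Path, pairs: list[PeptidePair]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "gene": p.gene,
                "wt_seq": p.wt_seq,
                "mt_seq": p.mt_seq,
                "mutation_type": p.mutation_type,
                "foci": ";".join(sorted(p.foci)),
                "variant_key": p.variant_key,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[PeptidePair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pair_id", "gene", "wt_seq", "mt_seq", "mutation_type", "foci"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pairs TSV missing column(s): {', '.join(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        foci = frozenset(
            s.strip() for s in str(row.foci).replace(",", ";").split(";") if s.strip()
        )
        vkey = getattr(row, "variant_key", "") or ""
        if isinstance(vkey, float):
            vkey = ""
        pairs.append(
            PeptidePair(
                pair_id=row.pair_id,
                gene=row.gene,
                wt_seq=row.wt_seq,
                mt_seq=row.mt_seq,
                mutation_type=str(row.mutation_type).upper().replace("INDEL", "INDEL"),
                foci=foci,
                variant_key=vkey,
            )
        )
    return pairs


def write_peptide_fasta(path: str | Path, pairs: list[PeptidePair]) -> None:
    """Peptide FASTA for external binding predictors (MT and WT entries)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}|MT|{p.gene}\n{p.mt_seq}\n")
            fh.write(f">{p.pair_id}|WT|{p.gene}\n{p.wt_seq}\n")
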