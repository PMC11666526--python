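"""Synthetic multi-patient, multi-focus cohorts with known ground truth.

The generator emulates a small whole-exome study of multifocal lung
adenocarcinoma: a handful of patients, each contributing one or more tumor
foci (pre-invasive or invasive), with somatic variants drawn from a
missense-dominant class distribution.  A *trunk* variant is shared by every
focus of its patient at identical coordinates; *private* variants belong to
a single focus.  Binding scores are simulated separately: a configurable
fraction of mutant peptides is planted as unambiguous high binders
(IC50 mutant below threshold and well below wild type), the rest are
guaranteed to fail at least one filter condition.

Everything is reproducible from a single integer seed; ground truth
(implanted variants, trunk labels, planted binder pair ids, true per-sample
class counts) is returned alongside the written files so tests can score
recovery exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_model import (
    MAF_CLASS_INV,
    Focus,
    Patient,
    SomaticVariant,
    Stage,
    VariantClass,
    VariantType,
    write_cohort_tsv,
)
from .peptide_enum import Transcript, write_transcript_fasta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_binding",
    "write_maf",
]

#: default variant-class mix: missense-dominant, as seen in lung
#: adenocarcinoma exomes (missense 75.4%, frameshift deletions 8.8%,
#: in-frame deletions 5.6%, frameshift insertions 3.3%; the remaining 6.9%
#: split over nonsense, splice-site, in-frame insertions and nonstop)
DEFAULT_CLASS_WEIGHTS: dict[VariantClass, float] = {
    VariantClass.MISSENSE: 0.754,
    VariantClass.FRAMESHIFT_DEL: 0.088,
    VariantClass.IN_FRAME_DEL: 0.056,
    VariantClass.FRAMESHIFT_INS: 0.033,
    VariantClass.NONSENSE: 0.035,
    VariantClass.SPLICE_SITE: 0.020,
    VariantClass.IN_FRAME_INS: 0.010,
    VariantClass.NONSTOP: 0.004,
}

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the cohort generator.

    Defaults mirror a four-patient exome cohort with one multifocal
    patient-like focus layout (two pre-invasive + two invasive foci per
    patient), ~216 somatic mutations per focus (Poisson), and a
    missense-dominant class mix.
    """

    n_patients: int = 4
    foci_per_patient: tuple[tuple[Stage, int], ...] = (
        (Stage.PRE_INVASIVE, 2),
        (Stage.INVASIVE, 2),
    )
    n_genes: int = 120
    transcript_length_range: tuple[int, int] = (60, 180)  # codons incl. start/stop
    class_weights: dict[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    trunk_fraction: float = 0.3
    mutations_per_focus: float = 216.0
    binder_fraction: float = 0.1
    hla_allele: str = "HLA-A*02:01"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1 (got {total})")
        for name in ("trunk_fraction", "binder_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("need at least one patient and one gene")


@dataclass
class GroundTruth:
    """Exactly what was implanted, reconstructible from the seed."""

    variants: list[SomaticVariant]
    trunk_keys: set[str]  # variant coordinate keys shared across a patient's foci
    class_counts: dict[str, dict[str, int]]  # sample -> class value -> count
    planted_binder_pair_ids: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "trunk_keys": sorted(self.trunk_keys),
                "class_counts": self.class_counts,
                "planted_binder_pair_ids": sorted(self.planted_binder_pair_ids),
                "n_variants": len(self.variants),
            },
            indent=2,
        )


@dataclass
class SimulatedCohort:
    patients: list[Patient]
    foci: list[Focus]
    transcripts: list[Transcript]
    variants: list[SomaticVariant]
    truth: GroundTruth
    maf_path: Path | None = None
    fasta_path: Path | None = None
    cohort_path: Path | None = None


# ---------------------------------------------------------------------------
# Toy genome

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(rng.choice(list(_BASES), 3))
            if c not in _STOPS:
                codons.append(c)
                break
    codons.append(str(rng.choice(sorted(_STOPS))))
    return "".join(codons)


def _make_transcripts(rng: np.random.Generator, config: SimulationConfig) -> list[Transcript]:
    lo, hi = config.transcript_length_range
    return [
        Transcript(
            gene=f"GENE{i:04d}",
            cds=_random_cds(rng, int(rng.integers(lo, hi + 1))),
            transcript_id=f"T{i:04d}",
        )
        for i in range(config.n_genes)
    ]


# ---------------------------------------------------------------------------
# Variant construction (transcript-relative, plus strand, one gene per contig)

_AA_OF: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    if codon not in _AA_OF:
        _AA_OF[codon] = str(Seq(codon).translate())
    return _AA_OF[codon]


def _draw_variant(
    rng: np.random.Generator,
    transcript: Transcript,
    vclass: VariantClass,
    sample_id: str,
) -> SomaticVariant | None:
    """One random variant of the requested class inside the CDS; None when
    the transcript cannot host the class (caller retries on another gene)."""
    cds = transcript.cds
    n_codons = len(cds) // 3
    interior = range(1, n_codons - 1)  # codon indices, 0-based, skip start/stop

    def snv_at(codon_idx: int, want) -> tuple[int, str, str] | None:
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        aa = _translate_codon(codon)
        offsets = list(rng.permutation(3))
        for off in offsets:
            for alt in rng.permutation(list(_BASES)):
                if alt == codon[off]:
                    continue
                new = codon[:off] + alt + codon[off + 1 :]
                new_aa = _translate_codon(new)
                if want(aa, new_aa):
                    return codon_idx * 3 + off + 1, codon[off], alt
        return None

    if vclass in (VariantClass.MISSENSE, VariantClass.SILENT, VariantClass.NONSENSE, VariantClass.NONSTOP):
        if vclass is VariantClass.MISSENSE:
            want = lambda a, b: b != a and b != "*"
            pool = list(interior)
        elif vclass is VariantClass.SILENT:
            want = lambda a, b: b == a
            pool = list(interior)
        elif vclass is VariantClass.NONSENSE:
            want = lambda a, b: b == "*"
            pool = list(interior)
        else:  # NONSTOP: mutate the stop codon away from stop
            want = lambda a, b: a == "*" and b != "*"
            pool = [n_codons - 1]
        for codon_idx in rng.permutation(pool)[: 30]:
            hit = snv_at(int(codon_idx), want)
            if hit:
                pos, ref, alt = hit
                return SomaticVariant(
                    sample_id=sample_id,
                    gene=transcript.gene,
                    chrom=transcript.gene,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_class=vclass,
                    variant_type=VariantType.SNV,
                    protein_change=None,
                )
        return None

    if vclass is VariantClass.SPLICE_SITE:
        # toy transcripts are single-exon; model as an SNV flagged splice,
        # placed at the first base (yields no peptide downstream)
        ref = cds[0]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        return SomaticVariant(
            sample_id=sample_id,
            gene=transcript.gene,
            chrom=transcript.gene,
            pos=1,
            ref_allele=ref,
            alt_allele=alt,
            variant_class=vclass,
            variant_type=VariantType.SNV,
        )

    # indels: positioned in the interior, away from start and stop codons
    lo_base, hi_base = 4, len(cds) - 6
    if hi_base <= lo_base + 4:
        return None
    if vclass is VariantClass.FRAMESHIFT_DEL:
        length, vtype = int(rng.choice([1, 2])), VariantType.DEL
    elif vclass is VariantClass.FRAMESHIFT_INS:
        length, vtype = int(rng.choice([1, 2])), VariantType.INS
    elif vclass is VariantClass.IN_FRAME_DEL:
        length, vtype = 3, VariantType.DEL
    else:  # IN_FRAME_INS
        length, vtype = 3, VariantType.INS
    pos = int(rng.integers(lo_base, hi_base - length))
    if vtype is VariantType.DEL:
        ref, alt = cds[pos - 1 : pos - 1 + length], "-"
    else:
        ref, alt = "-", "".join(rng.choice(list(_BASES), length))
    return SomaticVariant(
        sample_id=sample_id,
        gene=transcript.gene,
        chrom=transcript.gene,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=vclass,
        variant_type=vtype,
    )


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Generate a cohort; optionally write MAF / FASTA / cohort TSV / truth JSON.

    Trunk variants (probability ``trunk_fraction``) are replicated into every
    focus of their patient with identical coordinates and classes; the rest
    are private to one focus.  Written files round-trip losslessly through
    the package readers.
    """
    rng = np.random.default_rng(config.seed)
    transcripts = _make_transcripts(rng, config)

    patients = [
        Patient(f"P{i + 1}", (config.hla_allele,)) for i in range(config.n_patients)
    ]
    foci: list[Focus] = []
    for p in patients:
        k = 0
        for stage, count in config.foci_per_patient:
            for _ in range(count):
                k += 1
                foci.append(Focus(f"{p.patient_id}.{k}", p.patient_id, stage))

    classes = list(config.class_weights)
    weights = np.array([config.class_weights[c] for c in classes])
    weights = weights / weights.sum()

    variants: list[SomaticVariant] = []
    trunk_keys: set[str] = set()
    used_positions: set[tuple[str, int]] = set()

    def draw_one(sample_id: str) -> SomaticVariant:
        for _ in range(1000):
            vclass = classes[int(rng.choice(len(classes), p=weights))]
            tr = transcripts[int(rng.integers(len(transcripts)))]
            v = _draw_variant(rng, tr, vclass, sample_id)
            if v is not None and (v.chrom, v.pos) not in used_positions:
                used_positions.add((v.chrom, v.pos))
                return v
        raise RuntimeError(
            "could not place a variant; genome too small for the requested load"
        )

    foci_by_patient: dict[str, list[Focus]] = {}
    for f in foci:
        foci_by_patient.setdefault(f.patient_id, []).append(f)

    # Each patient carries a Poisson number of distinct mutation events; every
    # event is trunk with probability trunk_fraction (present in all foci) or
    # private to one uniformly chosen focus.  The event rate is scaled so the
    # expected per-focus burden equals mutations_per_focus.
    t = config.trunk_fraction
    for p in patients:
        pfoci = foci_by_patient[p.patient_id]
        n_foci = len(pfoci)
        mu_events = config.mutations_per_focus / (t + (1 - t) / n_foci)
        n_events = int(rng.poisson(mu_events))
        for _ in range(n_events):
            if rng.random() < t:
                v = draw_one(pfoci[0].sample_id)
                for f in pfoci:
                    variants.append(dataclasses.replace(v, sample_id=f.sample_id))
                trunk_keys.add(v.key)
            else:
                f = pfoci[int(rng.integers(n_foci))]
                variants.append(draw_one(f.sample_id))

    class_counts: dict[str, dict[str, int]] = {}
    for f in foci:
        counts: dict[str, int] = {}
        for v in variants:
            if v.sample_id == f.sample_id:
                counts[v.variant_class.value] = counts.get(v.variant_class.value, 0) + 1
        class_counts[f.sample_id] = counts

    truth = GroundTruth(variants=variants, trunk_keys=trunk_keys, class_counts=class_counts)
    cohort = SimulatedCohort(
        patients=patients, foci=foci, transcripts=transcripts, variants=variants, truth=truth
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.maf_path = out_dir / "cohort.maf"
        cohort.fasta_path = out_dir / "transcripts.fasta"
        cohort.cohort_path = out_dir / "cohort.tsv"
        write_maf(cohort.maf_path, variants)
        write_transcript_fasta(cohort.fasta_path, transcripts)
        write_cohort_tsv(cohort.cohort_path, patients, foci)
        (out_dir / "ground_truth.json").write_text(truth.to_json())
    return cohort


def write_maf(path: str | Path, variants: list[SomaticVariant]) -> None:
    """Write variants as a minimal tab-separated MAF."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "Hugo_Symbol": v.gene,
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref_allele,
                "Tumor_Seq_Allele2": v.alt_allele,
                "Variant_Classification": MAF_CLASS_INV[v.variant_class],
                "Variant_Type": v.variant_type.value,
                "Tumor_Sample_Barcode": v.sample_id,
                "HGVSp_Short": v.protein_change or "",
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binding simulation

def simulate_binding(pairs, config: SimulationConfig, rng: np.random.Generator | None = None):
    """Plant high binders and emit predictor records with known ground truth.

    Pairs are grouped by their originating mutation; with probability
    ``binder_fraction`` a mutation's peptide set contains exactly one planted
    high binder — IC50(mut) ~ U(10, 450) nM and IC50(wt) = IC50(mut) x
    U(1.5, 10), satisfying both filter conditions by construction.  All
    other peptides draw IC50(mut) ~ U(600, 20000) nM, failing the 500 nM
    threshold.  Eluted-ligand and SYFPEITHI columns are generated
    rank-concordant with affinity plus multiplicative noise.  Peptide
    sequences shared between pairs keep their first-assigned score (planted
    scores are assigned first so a plant is never overwritten).

    Returns ``(records, planted_pair_ids)``.
    """
    from .binding import Algorithm, BindingRecord

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    allele = config.hla_allele

    by_mutation: dict[str, list] = {}
    for p in pairs:
        by_mutation.setdefault(p.variant_key or p.pair_id, []).append(p)

    planted: set[str] = set()
    score: dict[str, float] = {}  # peptide -> IC50
    # planted scores first, so shared sequences can't demote a plant
    for key in sorted(by_mutation):
        group = by_mutation[key]
        if rng.random() < config.binder_fraction:
            chosen = group[int(rng.integers(len(group)))]
            ic50_mut = float(rng.uniform(10, 450))
            score.setdefault(chosen.mt_seq, ic50_mut)
            score.setdefault(chosen.wt_seq, ic50_mut * float(rng.uniform(1.5, 10)))
            planted.add(chosen.pair_id)
    for p in pairs:
        score.setdefault(p.mt_seq, float(rng.uniform(600, 20000)))
        score.setdefault(p.wt_seq, float(rng.uniform(600, 20000)))

    records: list[BindingRecord] = []
    for pep, ic50 in score.items():
        records.append(BindingRecord(pep, allele, Algorithm.NETMHCPAN, ic50))
        records.append(
            BindingRecord(pep, allele, Algorithm.IEDB_BA, ic50 * float(rng.uniform(0.8, 1.25)))
        )
        # rank-concordant higher-is-better scores with multiplicative noise
        el = 1.0 / np.log10(max(ic50, 1.02))
        records.append(
            BindingRecord(pep, allele, Algorithm.IEDB_EL, max(el * float(rng.uniform(0.9, 1.1)), 1e-6))
        )
        records.append(
            BindingRecord(
                pep, allele, Algorithm.SYFPEITHI,
                max(1.0, float(round(30 * el * float(rng.uniform(0.85, 1.15))))),
            )
        )
    return records, planted
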