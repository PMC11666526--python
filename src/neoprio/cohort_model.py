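"""Cohort data model: patients, foci, somatic variants, and burden summaries.

The unit of observation is a tumor *focus* (one sequenced tissue sample);
several foci may belong to one patient in multifocal disease.  Somatic
variants carry a MAF-style classification (missense, nonsense, frameshift
insertion/deletion, ...) and a coarse type (SNV / INS / DEL).  Silent
variants are parsed and retained but excluded from every burden tally and
from downstream peptide generation.

Tumor mutational burden (TMB) is the count of non-silent somatic mutations
per megabase of interrogated sequence; the interrogated size is a
configuration value (default 38 Mb, a typical whole-exome capture).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "Stage",
    "VariantClass",
    "VariantType",
    "Patient",
    "Focus",
    "SomaticVariant",
    "CohortSummary",
    "DEFAULT_INTERROGATED_MB",
    "MAF_COLUMNS",
    "read_maf",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "tally_variant_classes",
    "snv_six_class_spectrum",
    "compute_tmb",
    "rank_genes",
    "consistent_genes_across_patients",
    "summarize_cohort",
    "write_summary_tsv",
]

DEFAULT_INTERROGATED_MB = 38.0

HLA_ALLELE_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2}$")


class Stage(str, Enum):
    PRE_INVASIVE = "PRE_INVASIVE"
    INVASIVE = "INVASIVE"


class VariantClass(str, Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    NONSTOP = "NONSTOP"
    SPLICE_SITE = "SPLICE_SITE"
    FRAMESHIFT_DEL = "FRAMESHIFT_DEL"
    FRAMESHIFT_INS = "FRAMESHIFT_INS"
    IN_FRAME_DEL = "IN_FRAME_DEL"
    IN_FRAME_INS = "IN_FRAME_INS"
    SILENT = "SILENT"


class VariantType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


#: MAF Variant_Classification vocabulary -> internal class
MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.NONSTOP,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_DEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INS,
    "In_Frame_Del": VariantClass.IN_FRAME_DEL,
    "In_Frame_Ins": VariantClass.IN_FRAME_INS,
    "Silent": VariantClass.SILENT,
}
MAF_CLASS_INV = {v: k for k, v in MAF_CLASS_MAP.items()}

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]

#: the six pyrimidine-reference substitution classes, canonical order
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FormatError(ValueError):
    """Input file does not match the documented dialect."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    hla_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for allele in self.hla_alleles:
            if not HLA_ALLELE_RE.match(allele):
                raise ValueError(
                    f"malformed HLA allele {allele!r}; expected e.g. 'HLA-A*02:01'"
                )


@dataclass(frozen=True)
class Focus:
    """One sequenced tumor sample (focus) belonging to a patient."""

    sample_id: str
    patient_id: str
    stage: Stage = Stage.INVASIVE


@dataclass(frozen=True)
class SomaticVariant:
    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    variant_type: VariantType
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.variant_type is VariantType.SNV:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNV ref and alt must differ")
        ref_len = 0 if self.ref_allele == "-" else len(self.ref_allele)
        alt_len = 0 if self.alt_allele == "-" else len(self.alt_allele)
        delta = abs(ref_len - alt_len)
        if self.variant_class in (VariantClass.FRAMESHIFT_DEL, VariantClass.FRAMESHIFT_INS):
            if delta % 3 == 0:
                raise ValueError("frameshift indel length must not be a multiple of 3")
        if self.variant_class in (VariantClass.IN_FRAME_DEL, VariantClass.IN_FRAME_INS):
            if delta == 0 or delta % 3 != 0:
                raise ValueError("in-frame indel length must be a non-zero multiple of 3")

    @property
    def is_silent(self) -> bool:
        return self.variant_class is VariantClass.SILENT

    @property
    def key(self) -> str:
        """Coordinate key identifying the mutation event (sample-independent)."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class CohortSummary:
    """Per-sample tallies feeding plots, ranking and the sharing screens."""

    class_counts: pd.DataFrame  # samples x VariantClass
    type_counts: pd.DataFrame  # samples x VariantType
    snv_spectrum: pd.DataFrame  # samples x six classes, proportions
    gene_matrix: pd.DataFrame  # genes x samples, non-silent variant counts
    tmb: pd.DataFrame  # samples x (snv_tmb, indel_tmb, total_tmb)

    @property
    def samples(self) -> list[str]:
        return list(self.class_counts.index)


# ---------------------------------------------------------------------------
# Readers / writers

def _infer_patient(sample_id: str) -> str:
    return sample_id.split(".")[0]


def read_maf(path: str | Path, dialect: str = "MAF") -> tuple[list[SomaticVariant], list[Focus]]:
    """Read somatic variants from a MAF table or a minimal annotated VCF.

    The MAF dialect is tab-separated with the standard columns
    ``Hugo_Symbol, Chromosome, Start_Position, Reference_Allele,
    Tumor_Seq_Allele2, Variant_Classification, Variant_Type,
    Tumor_Sample_Barcode`` (``HGVSp_Short`` optional).  The annotated-VCF
    dialect is a single-sample VCF whose INFO field carries ``GENE``,
    ``CLASS`` and optionally ``PCHANGE``; coordinates are normalized to the
    1-based MAF convention (indel anchor base stripped).

    Silent rows are parsed and returned; downstream tallies exclude them.
    Foci are inferred from the sample barcodes (patient = prefix before the
    first dot; stage defaults to invasive — use a cohort TSV for real stages).
    """
    path = Path(path)
    if dialect == "MAF":
        variants = _read_maf_table(path)
    elif dialect == "ANNOTATED_VCF":
        variants = _read_annotated_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    seen: dict[str, Focus] = {}
    for v in variants:
        if v.sample_id not in seen:
            seen[v.sample_id] = Focus(v.sample_id, _infer_patient(v.sample_id))
    return variants, list(seen.values())


def _read_maf_table(path: Path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file {path} missing required column(s): {', '.join(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        cls = getattr(row, "Variant_Classification")
        if cls not in MAF_CLASS_MAP:
            raise FormatError(
                f"unknown Variant_Classification {cls!r}; accepted: "
                + ", ".join(sorted(MAF_CLASS_MAP))
            )
        vtype = getattr(row, "Variant_Type")
        if vtype not in VariantType.__members__:
            raise FormatError(f"unknown Variant_Type {vtype!r}; accepted: SNV, INS, DEL")
        pchange = getattr(row, "HGVSp_Short", None)
        if isinstance(pchange, float):  # NaN from pandas
            pchange = None
        variants.append(
            SomaticVariant(
                sample_id=row.Tumor_Sample_Barcode,
                gene=row.Hugo_Symbol,
                chrom=str(row.Chromosome),
                pos=int(row.Start_Position),
                ref_allele=row.Reference_Allele,
                alt_allele=row.Tumor_Seq_Allele2,
                variant_class=MAF_CLASS_MAP[cls],
                variant_type=VariantType[vtype],
                protein_change=pchange,
            )
        )
    return variants


def _read_annotated_vcf(path: Path) -> list[SomaticVariant]:
    """Minimal single-sample VCF reader for the documented annotated dialect.

    Plain-text VCF with INFO keys GENE=<symbol>;CLASS=<MAF classification>
    (;PCHANGE=<p.xxx>); the sample name is taken from the header #CHROM line
    (10th column).  Indels are left-anchored in VCF; the shared anchor base
    is stripped and the position shifted to the first changed base, matching
    the MAF convention used everywhere else in this package.
    """
    variants: list[SomaticVariant] = []
    sample_id = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise FormatError("annotated VCF must have exactly one sample column")
                sample_id = cols[9]
                continue
            if sample_id is None:
                raise FormatError("VCF data row before #CHROM header")
            fields = line.split("\t")
            chrom, pos, _id, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            if "GENE" not in info or "CLASS" not in info:
                raise FormatError("annotated VCF INFO must carry GENE and CLASS keys")
            cls = info["CLASS"]
            if cls not in MAF_CLASS_MAP:
                raise FormatError(
                    f"unknown CLASS {cls!r}; accepted: " + ", ".join(sorted(MAF_CLASS_MAP))
                )
            if len(ref) == 1 and len(alt) == 1:
                vtype = VariantType.SNV
            elif len(alt) > len(ref):
                vtype = VariantType.INS
                # strip shared anchor base
                pos, ref, alt = pos + 1, "-", alt[len(ref):]
            else:
                vtype = VariantType.DEL
                pos, ref, alt = pos + 1, ref[len(alt):], "-"
            variants.append(
                SomaticVariant(
                    sample_id=sample_id,
                    gene=info["GENE"],
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_class=MAF_CLASS_MAP[cls],
                    variant_type=vtype,
                    protein_change=info.get("PCHANGE"),
                )
            )
    return variants


def read_cohort_tsv(path: str | Path) -> tuple[list[Patient], list[Focus]]:
    """Read cohort metadata: sample_id, patient_id, stage, hla_alleles (;-sep)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "patient_id", "stage", "hla_alleles"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"cohort TSV missing column(s): {', '.join(missing)}")
    patients: dict[str, Patient] = {}
    foci: list[Focus] = []
    for row in df.itertuples(index=False):
        alleles = tuple(a for a in str(row.hla_alleles).split(";") if a and a != "nan")
        if row.patient_id not in patients:
            patients[row.patient_id] = Patient(row.patient_id, alleles)
        foci.append(Focus(row.sample_id, row.patient_id, Stage[row.stage]))
    ids = [f.sample_id for f in foci]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in cohort TSV")
    return list(patients.values()), foci


def write_cohort_tsv(path: str | Path, patients: list[Patient], foci: list[Focus]) -> None:
    by_id = {p.patient_id: p for p in patients}
    rows = [
        {
            "sample_id": f.sample_id,
            "patient_id": f.patient_id,
            "stage": f.stage.value,
            "hla_alleles": ";".join(by_id[f.patient_id].hla_alleles),
        }
        for f in foci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tallies and burdens

def tally_variant_classes(
    variants: list[SomaticVariant], exclude_silent: bool = True
) -> tuple[dict[VariantClass, int], dict[VariantClass, float] | None]:
    """Count variants per class; proportions over the non-silent total.

    Returns ``(counts, proportions)``; proportions are ``None`` for an empty
    (or all-silent, when excluded) input rather than a division by zero.
    """
    pool = [v for v in variants if not (exclude_silent and v.is_silent)]
    counts = Counter(v.variant_class for v in pool)
    counts_full = {c: counts.get(c, 0) for c in VariantClass}
    total = sum(counts.values())
    if total == 0:
        return counts_full, None
    proportions = {c: counts_full[c] / total for c in VariantClass}
    return counts_full, proportions


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a base substitution onto the pyrimidine-reference class.

    G>A is reported as C>T, A>G as T>C, etc.  Idempotent on already-collapsed
    pairs.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}"
    if label not in SIX_CLASSES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return label


def snv_six_class_spectrum(variants: list[SomaticVariant]) -> dict[str, float] | None:
    """Proportions of the six substitution classes among SNVs (None if no SNV)."""
    snvs = [v for v in variants if v.variant_type is VariantType.SNV]
    if not snvs:
        return None
    counts = Counter(collapse_substitution(v.ref_allele, v.alt_allele) for v in snvs)
    total = len(snvs)
    return {c: counts.get(c, 0) / total for c in SIX_CLASSES}


def compute_tmb(
    variants: list[SomaticVariant],
    interrogated_mb: float = DEFAULT_INTERROGATED_MB,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Tumor mutational burden per sample, split by SNV / InDel origin.

    TMB = non-silent mutation count / interrogated megabases.  The SNV and
    InDel components sum to the total exactly.
    """
    if interrogated_mb <= 0:
        raise ValueError("interrogated_mb must be positive")
    by_sample: dict[str, Counter] = defaultdict(Counter)
    for v in variants:
        if v.is_silent:
            continue
        kind = "snv" if v.variant_type is VariantType.SNV else "indel"
        by_sample[v.sample_id][kind] += 1
    index = samples if samples is not None else sorted(by_sample)
    rows = []
    for s in index:
        c = by_sample.get(s, Counter())
        rows.append(
            {
                "snv_tmb": c["snv"] / interrogated_mb,
                "indel_tmb": c["indel"] / interrogated_mb,
                "total_tmb": (c["snv"] + c["indel"]) / interrogated_mb,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(index, name="sample_id"))


def gene_sample_matrix(variants: list[SomaticVariant]) -> pd.DataFrame:
    """Genes x samples matrix of non-silent variant counts."""
    counts: dict[tuple[str, str], int] = Counter()
    for v in variants:
        if not v.is_silent:
            counts[(v.gene, v.sample_id)] += 1
    if not counts:
        return pd.DataFrame(dtype=int)
    ser = pd.Series(counts, dtype=int)
    return ser.unstack(fill_value=0)


def rank_genes(variants: list[SomaticVariant], n: int) -> pd.DataFrame:
    """Top-n genes by mutation frequency, with the gene-by-sample matrix.

    Frequency = number of samples carrying a non-silent variant in the gene;
    ties broken by total variant count (descending) then gene symbol.
    Returns the matrix restricted to the top n, in rank order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mat = gene_sample_matrix(variants)
    if mat.empty:
        return mat
    n_samples = (mat > 0).sum(axis=1)
    totals = mat.sum(axis=1)
    order = sorted(mat.index, key=lambda g: (-n_samples[g], -totals[g], g))
    return mat.loc[order[:n]]


def consistent_genes_across_patients(
    variants: list[SomaticVariant],
    foci: list[Focus],
    gene_pool: list[str] | None = None,
) -> list[str]:
    """Genes mutated in every patient with a single shared variant class.

    A gene qualifies iff every patient has at least one focus carrying a
    non-silent variant in it AND the set of variant classes observed for the
    gene, pooled over all patients, is a single class.
    """
    patient_of = {f.sample_id: f.patient_id for f in foci}
    patients = sorted(set(patient_of.values()))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients")
    per_gene_patients: dict[str, set] = defaultdict(set)
    per_gene_classes: dict[str, set] = defaultdict(set)
    for v in variants:
        if v.is_silent or v.sample_id not in patient_of:
            continue
        if gene_pool is not None and v.gene not in gene_pool:
            continue
        per_gene_patients[v.gene].add(patient_of[v.sample_id])
        per_gene_classes[v.gene].add(v.variant_class)
    return sorted(
        g
        for g in per_gene_patients
        if per_gene_patients[g] == set(patients) and len(per_gene_classes[g]) == 1
    )


def summarize_cohort(
    variants: list[SomaticVariant],
    foci: list[Focus] | None = None,
    interrogated_mb: float = DEFAULT_INTERROGATED_MB,
) -> CohortSummary:
    samples = (
        [f.sample_id for f in foci]
        if foci is not None
        else sorted({v.sample_id for v in variants})
    )
    by_sample: dict[str, list[SomaticVariant]] = defaultdict(list)
    for v in variants:
        by_sample[v.sample_id].append(v)

    class_rows, type_rows, spec_rows = [], [], []
    for s in samples:
        vs = [v for v in by_sample.get(s, []) if not v.is_silent]
        cc = Counter(v.variant_class for v in vs)
        class_rows.append({c.value: cc.get(c, 0) for c in VariantClass if c is not VariantClass.SILENT})
        tc = Counter(v.variant_type for v in vs)
        type_rows.append({t.value: tc.get(t, 0) for t in VariantType})
        spec = snv_six_class_spectrum(vs)
        spec_rows.append({c: (spec[c] if spec else float("nan")) for c in SIX_CLASSES})

    idx = pd.Index(samples, name="sample_id")
    return CohortSummary(
        class_counts=pd.DataFrame(class_rows, index=idx),
        type_counts=pd.DataFrame(type_rows, index=idx),
        snv_spectrum=pd.DataFrame(spec_rows, index=idx),
        gene_matrix=gene_sample_matrix(variants).reindex(columns=samples, fill_value=0),
        tmb=compute_tmb(variants, interrogated_mb, samples=samples),
    )


def write_summary_tsv(summary: CohortSummary, path: str | Path) -> None:
    """Flat per-sample summary: class counts, type counts, spectrum, TMB."""
    out = pd.concat(
        [
            summary.class_counts,
            summary.type_counts,
            summary.snv_spectrum.add_prefix("spectrum_"),
            summary.tmb.round(4),
        ],
        axis=1,
    )
    out.to_csv(path, sep="\t")
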