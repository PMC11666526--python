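# neoprio

Neoantigen candidate screening for multifocal somatic-variant cohorts:
from per-focus somatic variant calls to ranked, filter-passing,
multi-algorithm-harmonized mutant/wild-type peptide pairs, with tumor
mutational burden (TMB) and tumor neoantigen burden (TNB) summaries and a
multifocal sharing screen.

## The problem

Tumor-specific somatic mutations create *neoantigens* — mutant peptides
absent from normal tissue that MHC class I molecules can present to CD8+
T cells. Picking vaccine or adoptive-therapy candidates from an exome's
worth of mutations is a funnel: enumerate every 8–11-mer mutant peptide
overlapping a coding change, predict peptide–MHC binding, keep mutant
peptides that bind well *and* better than their wild-type counterparts,
reconcile scores from predictors that disagree on scale and direction, and
— in multifocal disease — prefer candidates shared across tumor foci, since
a peptide private to one focus cannot target the others.

`neoprio` implements that funnel for cohorts of patients with one or more
sequenced tumor foci each (e.g. pre-invasive and invasive foci of a
multifocal lung adenocarcinoma), plus a synthetic-cohort generator with
known ground truth so every stage is testable offline.

## The method

**Burdens.** TMB = non-silent somatic mutations per megabase of
interrogated sequence (default 38 Mb, a typical exome capture), split into
SNV- and InDel-derived components. TNB = number of distinct mutations
yielding at least one high-binder peptide.

**First-round filter.** A mutant peptide is a *high binder* iff

```
IC50(mut) < 500 nM   and   IC50(mut) < IC50(wt)
```

with strict inequalities.

**Score harmonization.** Affinity-type pre-scores *a* (nM; higher = weaker)
are transformed to *b* = 1/log₁₀ *a* so that larger means stronger;
eluted-ligand and SYFPEITHI scores pass through unchanged. Fold change
FC = *a*(wt)/*a*(mut) captures the binding gain of the mutation. Each score
column is min-max rescaled onto [1, 20]:

```
c = (b − min b) / (max b − min b) × 19 + 1
```

Candidates are selected by best mutant IC50 (top 30 by default), displayed
with per-algorithm *c* columns, and ordered by consensus (mean of available
*c* values).

**Multifocal screen.** Candidates present in ≥ 2 foci (configurable) are
flagged as shareable targets; trunk candidates appear in every focus.

## Worked example

The repo ships a seven-candidate table (`fixtures/table2_pairs.tsv`) of
mutant/wild-type peptide pairs from a four-focus patient. Screening it for
multifocal sharing:

```
$ neoprio multifocal --pairs fixtures/table2_pairs.tsv --min-foci 2 --out-dir out/
3 candidates in >= 2 foci written to out/
```

`out/shared_pairs.tsv` then contains exactly the three shareable
candidates — the TAS2R46 pair present in all four foci, the UBQLN2 pair in
two, and the NANOGNB pair (WLTPVIPAL → WLMPVIPAL) in three:

```
pair_id  gene     wt_seq      mt_seq      mutation_type  foci
LUAD-1   TAS2R46  FLVCHLFVI   FLACHLFVI   SNV            P4.1;P4.2;P4.3;P4.4
LUAD-6   UBQLN2   GPTVSSAAPS  GLLCPALHLV  INDEL          P4.1;P4.4
LUAD-7   NANOGNB  WLTPVIPAL   WLMPVIPAL   SNV            P4.1;P4.3;P4.4
```

An end-to-end synthetic run (generate a 4-patient, 16-focus cohort, then
tally, enumerate, score with the built-in deterministic toy predictor,
filter, harmonize, rank and screen):

```
$ neoprio simulate --seed 7 --out-dir sim/
$ neoprio report --maf sim/cohort.maf --fasta sim/transcripts.fasta \
      --cohort sim/cohort.tsv --seed 7 --out-dir report/
samples: 16; non-silent variants: 3565
missense proportion: 0.767
high-binder candidates: 28543; ranked: 30; shared (>= 2 foci): 12
```

The missense proportion reflects the generator's missense-dominant default
class mix (75.4%); `report/` holds per-sample summaries (class counts,
six-class SNV spectrum, TMB), the TNB table, binder calls, the ranked
candidate table and a manifest recording the exact configuration and input
checksums.

Real predictor outputs (NetMHCpan tab-separated export, IEDB CSV, SYFPEITHI
TSV) can be parsed with `neoprio.binding.parse_predictor_table` and used in
place of the toy predictor.

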