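# ssaso-triage

Rule-based amenability triage of loss-of-function (LoF) variants for
**splice-switching antisense oligonucleotide (ssASO)** strategies.

Individualized ASO treatments have been developed for single patients with
severe monogenic disease, but only a narrow class of variants is actually
approachable this way. Given a transcript model, a variant with its
**functionally observed** splicing outcome, and optional domain/pathogenicity
annotations, `ssaso-triage` answers one question:

> Is this variant plausibly treatable by (a) blocking a variant-created
> cryptic splice site, or (b) skipping the variant-containing exon — and if
> not, exactly which criterion fails?

Every verdict carries an ordered, auditable trace of the decision nodes
fired. The tool **never predicts** splice effects: observed effects are
required inputs, and claims without a functional assay yield
`INSUFFICIENT_EVIDENCE`.

## The two decision trees

**Cryptic-splice blocking** — for variants shown to create/activate a
cryptic splice site (e.g. cryptic-exon inclusion from a deep-intronic
variant). An ASO covering the variant masks the cryptic site and restores
canonical splicing, provided:

1. the effect is confirmed by a functional assay (RT-qPCR, minigene, RNA-seq, …);
2. canonical splicing is otherwise intact (partially intact → capped at
   `CONDITIONALLY_AMENABLE`);
3. the variant is **not** on a canonical ±1/±2 dinucleotide and **not** in
   the branch-point window (18–40 nt upstream of the intron 3' end) — an ASO
   there would block elements the spliceosome needs → `NOT_AMENABLE`;
4. the variant is ≥ 5 nt from the nearest splice site (hard cut-off;
   closer → `NOT_AMENABLE`) and ideally ≥ 15 nt (recommended cut-off;
   in between → `CONDITIONALLY_AMENABLE` with a proximity caution).
   Deep-intronic positions (> 100 nt from any junction) are the ideal case.

Overlap with the extended donor (−3..+6) or acceptor (−20..+1) regions caps
the verdict at `CONDITIONALLY_AMENABLE`; exonic cryptic variants additionally
carry a whole-exon-skip risk caution.

**Exon skipping** — for exonic LoF variants (nonsense, frameshift, missense)
without a splicing effect of their own. Skipping the variant exon is viable
only when **all** gates pass:

1. the exon is an internal coding exon (not the first or last coding exon);
2. its coding length is divisible by 3 (frame-preserving skip);
3. the new exon–exon junction does not create a stop codon (junction codons
   are reconstructed from the transcript sequence);
4. the exon overlaps no known functional domain;
5. skipping/deleting this exon is not itself a known pathogenic event
   (overridable only with an explicit documented justification).

Removal of more than 10 % of the coding sequence, junction missense events,
and heterozygosity (allele specificity) attach cautions, never silent
rejections. Missense variants are additionally screened against a
pathogenic-missense hotspot analysis and are never rated better than
`CONDITIONALLY_AMENABLE` — expert review is mandatory.

Verdict categories: `AMENABLE_CRYPTIC_SPLICE_BLOCK`, `AMENABLE_EXON_SKIP`,
`CONDITIONALLY_AMENABLE`, `NOT_AMENABLE`, `INSUFFICIENT_EVIDENCE`,
`OUT_OF_SCOPE` (gain-of-function / dominant-negative mechanisms, UTR
variants, synonymous variants without a splicing effect).

A five-criterion patient-selection checklist (disease severity, monogenic
cause, locally dosable tissue, treatability horizon, definable outcome
measures) is available as `ssaso-triage patient check`.

## Quick start

The package ships a self-contained demonstration transcript with 8 archetype
variants covering every branch of both trees:

```console
$ ssaso-triage fixtures export --out-dir fixture_bundle
$ ssaso-triage triage \
    --gene-model fixture_bundle/gene_model.json \
    --variants fixture_bundle/variants.json \
    --domains fixture_bundle/domains.json \
    --pathogenic-table fixture_bundle/pathogenic_table.tsv \
    --out-json report.json --out-tsv summary.tsv
archetype_1	NOT_AMENABLE
archetype_2	NOT_AMENABLE
archetype_3	AMENABLE_CRYPTIC_SPLICE_BLOCK
archetype_4	AMENABLE_CRYPTIC_SPLICE_BLOCK
archetype_5	NOT_AMENABLE
archetype_6	AMENABLE_EXON_SKIP
archetype_7	NOT_AMENABLE
archetype_8	NOT_AMENABLE
```

`summary.tsv` adds warnings and mandatory follow-ups per variant:

```text
label        variant        category                        warnings                   followups
archetype_3  c.457-1340A>G  AMENABLE_CRYPTIC_SPLICE_BLOCK
archetype_6  c.490C>T       AMENABLE_EXON_SKIP              allele_specificity_needed  functional_validation_of_skipped_protein;expert_consultation_on_protein_function
archetype_8  c.670C>G       NOT_AMENABLE                    large_removal_caution
```

`report.json` contains, for every variant, the region report (landmark
distances) and the full decision trace. Gene models are accepted as a JSON
document or as GFF3 + FASTA (`--gff3/--fasta/--transcript-id`); both routes
produce identical results for identical content. Variants use a strict
HGVS-c subset (substitution, del, dup, ins, delins, with `-`/`*` UTR anchors
and `+`/`-` intronic offsets); anything else is rejected with exit code 2.

Python API:

```python
from ssaso_triage import build_hypothetical_transcript, triage

bundle = build_hypothetical_transcript()
a = bundle.variant(3)  # c.457-1340A>G, confirmed cryptic-exon inclusion
verdict = triage(bundle.model, a.variant, a.evidence)
print(verdict.category.value)            # AMENABLE_CRYPTIC_SPLICE_BLOCK
for node in verdict.trace.nodes:
    print(node.node_id, "->", node.consequence)
```

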