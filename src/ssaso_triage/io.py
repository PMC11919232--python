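"""Readers and writers for the on-disk formats.

Formats
-------
* gene-model JSON: ``transcript_id``, ``gene``, ``strand``, ``exons``
  (``genomic_start``/``genomic_end`` in transcript orientation),
  ``cds_start``/``cds_end`` (spliced-transcript coordinates), optional
  ``sequence``.
* GFF3 + FASTA: exon and CDS features of one mRNA, read with gffutils and
  pyfaidx; produces a model identical to the JSON route for equal content.
* domains: BED (0-based half-open on disk, coding coordinates, converted to
  1-based inclusive on read — the classic off-by-one lives HERE and only
  here) or JSON (already 1-based inclusive).
* variants: JSON list of ``{"hgvs": ..., "zygosity": ...,
  "evidence": {...}, "population_evidence": ..., "mechanism": ...}``.
* pathogenic table: TSV with header
  ``position_c  consequence  classification  functional_lof``.
* VCF: accepted only together with a JSON sidecar naming the contig the
  transcript lives on (``{"chrom": ...}``); records are projected onto the
  transcript with the model's own genomic-to-cDNA mapping. No genome-build
  inference.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .exceptions import TriageInputError
from .transcript_model import (
    DomainAnnotation,
    TranscriptModel,
    build_transcript,
    model_to_document,
)
from .variant_model import (
    SpliceEvidence,
    VariantDescriptor,
    VariantKind,
    Zygosity,
    parse_hgvs_c,
)

PATHOGENIC_TABLE_COLUMNS = [
    "position_c",
    "consequence",
    "classification",
    "functional_lof",
]


# --------------------------------------------------------------------------
# gene models
# --------------------------------------------------------------------------


def read_gene_model_json(path: str | Path) -> TranscriptModel:
    with open(path) as fh:
        return build_transcript(json.load(fh))


def write_gene_model_json(model: TranscriptModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_document(model), fh, indent=1)
        fh.write("\n")


def read_gene_model(
    gff3_path: str | Path, fasta_path: Optional[str | Path], transcript_id: str
) -> TranscriptModel:
    """Build a transcript model from GFF3 exon/CDS features plus a genomic
    FASTA (FASTA optional: without it the model carries no sequence)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    try:
        mrna = db[transcript_id]
    except gffutils.FeatureNotFoundError:
        raise TriageInputError(
            f"transcript {transcript_id!r} not found in {gff3_path}"
        ) from None
    strand = mrna.strand
    if strand not in ("+", "-"):
        raise TriageInputError(f"transcript {transcript_id!r} has no strand")
    exon_feats = sorted(
        db.children(mrna, featuretype="exon"), key=lambda f: f.start
    )
    cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
    if not exon_feats:
        raise TriageInputError(f"transcript {transcript_id!r} has no exon features")
    if not cds_feats:
        raise TriageInputError(f"transcript {transcript_id!r} has no CDS features")
    if strand == "-":
        exon_feats = exon_feats[::-1]
    # genomic CDS extent -> spliced-transcript coordinates
    cds_gmin = min(f.start for f in cds_feats)
    cds_gmax = max(f.end for f in cds_feats)
    exons = [
        {"genomic_start": f.start, "genomic_end": f.end} for f in exon_feats
    ]
    doc = {
        "transcript_id": transcript_id,
        "gene": mrna.attributes.get("gene", [""])[0]
        or mrna.attributes.get("gene_name", [""])[0],
        "strand": strand,
        "exons": exons,
        # placeholder CDS; fixed below once the model can map coordinates
        "cds_start": 1,
        "cds_end": 3,
    }
    probe = build_transcript({**doc, "cds_end": sum(
        e["genomic_end"] - e["genomic_start"] + 1 for e in exons
    ) - (sum(e["genomic_end"] - e["genomic_start"] + 1 for e in exons) % 3)})
    t_a = probe.genomic_to_t(cds_gmin)
    t_b = probe.genomic_to_t(cds_gmax)
    if t_a is None or t_b is None:
        raise TriageInputError(
            f"CDS bounds of {transcript_id!r} fall outside its exons"
        )
    doc["cds_start"], doc["cds_end"] = min(t_a, t_b), max(t_a, t_b)
    if fasta_path is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path))
        seq_parts = []
        for f in exon_feats:
            part = str(fa[f.seqid][f.start - 1 : f.end])
            if strand == "-":
                from Bio.Seq import Seq

                part = str(Seq(part).reverse_complement())
            seq_parts.append(part.upper())
        doc["sequence"] = "".join(seq_parts)
    return build_transcript(doc)


def write_gene_model_gff3_fasta(
    model: TranscriptModel,
    gff3_path: str | Path,
    fasta_path: str | Path,
    seqid: str = "chrF",
) -> None:
    """Export a model (with sequence) as GFF3 + genomic FASTA.

    Intronic genomic sequence is synthesized as 'A' runs — the triage logic
    never reads intron nucleotides, only intron lengths.
    """
    exons_g = sorted(
        [(ex.genomic_start, ex.genomic_end, ex.index) for ex in model.exons]
    )
    gmin, gmax = exons_g[0][0], exons_g[-1][1]
    tid = model.transcript_id
    lines = [
        "##gff-version 3",
        f"{seqid}\tssaso\tgene\t{gmin}\t{gmax}\t.\t{model.strand}\t.\t"
        f"ID=gene-{model.gene_symbol};gene={model.gene_symbol}",
        f"{seqid}\tssaso\tmRNA\t{gmin}\t{gmax}\t.\t{model.strand}\t.\t"
        f"ID={tid};Parent=gene-{model.gene_symbol};gene={model.gene_symbol}",
    ]
    cds_g = []
    for ex in model.exons:
        lines.append(
            f"{seqid}\tssaso\texon\t{ex.genomic_start}\t{ex.genomic_end}\t.\t"
            f"{model.strand}\t.\tID={tid}-exon{ex.index};Parent={tid}"
        )
        interval = model.exon_cds_interval(ex.index)
        if interval is not None:
            t_start, t_end = model.exon_t_interval(ex.index)
            lo_t = max(t_start, model.cds_start)
            hi_t = min(t_end, model.cds_end)
            g1, g2 = model.t_to_genomic(lo_t), model.t_to_genomic(hi_t)
            cds_g.append((min(g1, g2), max(g1, g2), ex.index))
    for g1, g2, idx in sorted(cds_g):
        lines.append(
            f"{seqid}\tssaso\tCDS\t{g1}\t{g2}\t.\t{model.strand}\t0\t"
            f"ID={tid}-cds{idx};Parent={tid}"
        )
    Path(gff3_path).write_text("\n".join(lines) + "\n")

    if model.sequence is None:
        raise TriageInputError("FASTA export requires a model with sequence")
    from Bio.Seq import Seq

    genome = ["A"] * gmax
    for ex in model.exons:
        t_start, t_end = model.exon_t_interval(ex.index)
        part = model.sequence[t_start - 1 : t_end]
        if model.strand == "-":
            part = str(Seq(part).reverse_complement())
        genome[ex.genomic_start - 1 : ex.genomic_end] = list(part)
    with open(fasta_path, "w") as fh:
        fh.write(f">{seqid}\n")
        seq = "".join(genome)
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# --------------------------------------------------------------------------
# domains
# --------------------------------------------------------------------------


def read_domains_bed(path: str | Path) -> list[DomainAnnotation]:
    """BED domains in coding coordinates: 0-based half-open on disk,
    converted to 1-based inclusive in memory."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TriageInputError(f"{path}:{ln}: BED line needs >= 3 columns")
            start0, end0 = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"domain_{ln}"
            out.append(
                DomainAnnotation(name, start0 + 1, end0, source=str(path))
            )
    return out


def read_domains_json(path: str | Path) -> list[DomainAnnotation]:
    with open(path) as fh:
        docs = json.load(fh)
    return [
        DomainAnnotation(
            d["name"], int(d["start_c"]), int(d["end_c"]), d.get("source", str(path))
        )
        for d in docs
    ]


def write_domains_json(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"name": d.name, "start_c": d.start_c, "end_c": d.end_c,
                 "source": d.source}
                for d in domains
            ],
            fh,
            indent=1,
        )
        fh.write("\n")


# --------------------------------------------------------------------------
# variants, evidence, tables
# --------------------------------------------------------------------------


def read_variants_json(path: str | Path) -> list[dict]:
    """Variant worklist: each entry has ``hgvs`` plus optional ``zygosity``,
    ``evidence``, ``population_evidence`` and ``mechanism``."""
    with open(path) as fh:
        docs = json.load(fh)
    if not isinstance(docs, list):
        raise TriageInputError(f"{path}: variant file must hold a JSON list")
    out = []
    for i, d in enumerate(docs):
        if "hgvs" not in d:
            raise TriageInputError(f"{path}: variant entry {i} missing 'hgvs'")
        variant = parse_hgvs_c(d["hgvs"], d.get("zygosity", "unknown"))
        evidence = SpliceEvidence.from_dict(d.get("evidence", {}))
        out.append(
            {
                "variant": variant,
                "evidence": evidence,
                "population_evidence": d.get("population_evidence", "unknown"),
                "mechanism": d.get("mechanism", "lof"),
                "label": d.get("label", d["hgvs"]),
            }
        )
    return out


def read_pathogenic_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in PATHOGENIC_TABLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise TriageInputError(
            f"{path}: pathogenic table missing column(s) {missing}"
        )
    if "functional_lof" not in df.columns:
        df["functional_lof"] = ""
    return df


def write_pathogenic_table(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows), columns=PATHOGENIC_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def variants_from_vcf(
    vcf_path: str | Path, sidecar_path: str | Path, model: TranscriptModel
) -> list[VariantDescriptor]:
    """Project SNVs/small indels from a VCF onto the transcript.

    The sidecar JSON must name the contig (``chrom``) the transcript's
    genomic coordinates refer to; records on other contigs are rejected.
    """
    import pysam

    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    chrom = sidecar.get("chrom")
    if not chrom:
        raise TriageInputError(f"{sidecar_path}: sidecar must provide 'chrom'")
    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.chrom != chrom:
                raise TriageInputError(
                    f"VCF record on contig {rec.chrom!r}; sidecar maps {chrom!r}"
                )
            if rec.alts is None or len(rec.alts) != 1:
                raise TriageInputError(
                    f"VCF record at {rec.pos} must have exactly one ALT"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) == 1 and len(alt) == 1:
                cpos = model.map_genomic_to_c(rec.pos)
                raw = _format_cpos(cpos) + f"{ref}>{alt}"
            elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
                # deletion of ref[1:] starting after pos
                a = model.map_genomic_to_c(rec.pos + 1)
                b = model.map_genomic_to_c(rec.pos + len(ref) - 1)
                a, b = sorted([a, b], key=lambda p: (p.pos, p.offset))
                raw = (
                    "c." + _bare(a) + ("_" + _bare(b) if (len(ref) > 2) else "") + "del"
                )
            elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
                a = model.map_genomic_to_c(rec.pos)
                b = model.map_genomic_to_c(rec.pos + 1)
                a, b = sorted([a, b], key=lambda p: (p.pos, p.offset))
                raw = f"c.{_bare(a)}_{_bare(b)}ins{alt[1:]}"
            else:
                raise TriageInputError(
                    f"unsupported VCF allele pair {ref}>{alt} at {rec.pos}"
                )
            out.append(parse_hgvs_c(raw))
    return out


def _bare(cpos) -> str:
    prefix = {"cds": "", "utr5": "-", "utr3": "*"}[cpos.region]
    s = f"{prefix}{cpos.pos}"
    if cpos.offset:
        s += f"{cpos.offset:+d}"
    return s


def _format_cpos(cpos) -> str:
    return "c." + _bare(cpos)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")


SUMMARY_COLUMNS = ["label", "variant", "category", "warnings", "followups"]


def write_summary_tsv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# fixture bundle export
# --------------------------------------------------------------------------


def export_fixture_bundle(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle as the on-disk formats the CLI consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_model": outdir / "gene_model.json",
        "variants": outdir / "variants.json",
        "domains": outdir / "domains.json",
        "pathogenic_table": outdir / "pathogenic_table.tsv",
    }
    write_gene_model_json(bundle.model, paths["gene_model"])
    variant_docs = [
        {
            "label": f"archetype_{a.number}",
            "hgvs": a.variant.raw,
            "zygosity": a.variant.zygosity.value,
            "evidence": a.evidence.to_dict(),
            "expected_category": a.expected_category.value,
        }
        for a in bundle.variants
    ]
    with open(paths["variants"], "w") as fh:
        json.dump(variant_docs, fh, indent=1)
        fh.write("\n")
    write_domains_json(bundle.domains, paths["domains"])
    write_pathogenic_table(bundle.pathogenic_table, paths["pathogenic_table"])
    return paths
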