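"""File-format boundary: FASTA, GTF, BED, VCF and the package's TSVs.

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and VCF (1-based) are converted here and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnm import DNMRecord
from .models import GeneModel


# ---------------------------------------------------------------- FASTA

def write_fasta(path, records: dict, width: int = 60) -> None:
    """Write ``{name: sequence}`` as FASTA wrapped at ``width`` columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(recs)


def read_fasta(path) -> dict:
    """Read FASTA into ``{name: upper-case sequence}`` (order preserved)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


# ------------------------------------------------------------------ GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _attrs(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def write_gtf(path, genes, source: str = "gcdrift") -> None:
    """Write gene/transcript/exon/CDS features (1-based, inclusive).

    Isoform weights are carried in a ``weight`` attribute on transcript
    features so that a written annotation re-reads to the identical
    gene-model set.
    """
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}";'
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for tid, weight in g.isoforms:
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; weight "{weight:g}";'
            lines.append(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}"
            )
            for s, e in g.exons:
                lines.append(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}"
                )
            if g.cds_start is not None and g.cds_end is not None:
                lines.append(
                    f"{g.chrom}\t{source}\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t{g.strand}\t.\t{tattrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path) -> list:
    """Read a GTF written by :func:`write_gtf` back into GeneModels."""
    by_gene: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, feature, start, end, _score, strand, _frame, attr_field = (
            line.split("\t")
        )
        attrs = _attrs(attr_field)
        gid = attrs["gene_id"]
        entry = by_gene.setdefault(
            gid,
            {"chrom": chrom, "strand": strand, "exons": set(), "cds": None, "isoforms": {}},
        )
        if feature == "transcript":
            entry["isoforms"][attrs["transcript_id"]] = float(attrs.get("weight", 1.0))
        elif feature == "exon":
            entry["exons"].add((int(start) - 1, int(end)))
        elif feature == "CDS":
            entry["cds"] = (int(start) - 1, int(end))
    genes = []
    for gid, entry in by_gene.items():
        exons = tuple(sorted(entry["exons"]))
        tss = exons[0][0] if entry["strand"] == "+" else exons[-1][1] - 1
        cds = entry["cds"] or (None, None)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                tss=tss,
                exons=exons,
                cds_start=cds[0],
                cds_end=cds[1],
                isoforms=tuple(sorted(entry["isoforms"].items())),
            )
        )
    return genes


# ------------------------------------------------------------------ BED

def write_bed6(path, regions) -> None:
    """Write anchored regions as BED6 (name = source_id)."""
    lines = []
    for r in regions:
        start = r.genomic_start if r.genomic_start is not None else 0
        lines.append(
            f"{r.chrom or '.'}\t{start}\t{start + len(r.sequence)}\t"
            f"{r.source_id}\t0\t{r.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------- TSS scores

def write_tss_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tss_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------ DNM

def write_dnms_tsv(path, dnms) -> None:
    pd.DataFrame(
        {
            "chrom": [d.chrom for d in dnms],
            "pos": [d.pos for d in dnms],
            "ref": [d.ref for d in dnms],
            "alt": [d.alt for d in dnms],
        }
    ).to_csv(path, sep="\t", index=False)


def read_dnms_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        DNMRecord(chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt))
        for r in df.itertuples()
    ]


def write_dnms_vcf(path, dnms, contigs: dict | None = None) -> None:
    """Write a minimal SNV-only VCF (CHROM, POS, ID, REF, ALT)."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for d in dnms:
        lines.append(f"{d.chrom}\t{d.pos}\t.\t{d.ref}\t{d.alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dnms_vcf(path) -> list:
    """Read SNVs from a VCF via pysam; multi-allelic records expand to
    one DNMRecord per alt."""
    from pysam import VariantFile

    records = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                records.append(
                    DNMRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                )
    return records


# ------------------------------------------------------------ truth TSV

def write_truth_table(path, loci: dict) -> None:
    """Write ``{locus_id: TrioLocus}`` truth events as TSV."""
    rows = []
    for locus_id, locus in loci.items():
        for ev in locus.truth:
            rows.append(
                (locus_id, ev.site, ev.lineage, ev.from_base, ev.to_base, ev.order_index)
            )
    pd.DataFrame(
        rows, columns=["locus", "site", "lineage", "from", "to", "order"]
    ).to_csv(path, sep="\t", index=False)


def write_events(path, events) -> None:
    """Write inferred substitution events as TSV."""
    pd.DataFrame(
        {
            "source_id": [e.source_id for e in events],
            "rel_pos": [e.rel_pos for e in events],
            "lineage": [e.lineage for e in events],
            "from": [e.from_base for e in events],
            "to": [e.to_base for e in events],
            "klass": [e.klass for e in events],
            "cpg": [e.cpg_context for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def write_series(path, series) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)
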