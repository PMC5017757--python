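"""File formats: FASTA genomes, FASTQ reads with truth tags, minimal VCF
truth sets and call sets, TSV alignments/coverage.

Species is encoded in FASTA headers as a ``|human`` / ``|mouse`` suffix.
Read ground truth travels in the FASTQ read name as
``id|species|contig|pos|strand`` (0-based start).  Mutation truth sets and
variant calls are minimal VCF v4.2 (1-based POS); alignments use a small
TSV, deliberately simpler than SAM.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hybridalign import AlignmentRecord, CoverageProfile
from .somaticeval import VariantCall
from .synthdata import Contig, Read, SomaticMutation, SpeciesGenome


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genomes: SpeciesGenome | Iterable[SpeciesGenome], path) -> None:
    if isinstance(genomes, SpeciesGenome):
        genomes = [genomes]
    records = [SeqRecord(Seq(c.sequence), id=f"{c.name}|{c.species}",
                         description="")
               for g in genomes for c in g.contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> SpeciesGenome:
    """Read a genome; species is parsed from the ``|human``/``|mouse``
    header suffix (headers without a suffix default to human)."""
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, species = rec.id.rpartition("|")
        if species not in ("human", "mouse"):
            name, species = rec.id, "human"
        contigs.append(Contig(name=name, species=species,
                              sequence=str(rec.seq).upper()))
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return SpeciesGenome(contigs)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(
            Seq(r.sequence),
            id=f"{r.id}|{r.truth_species}|{r.truth_contig}"
               f"|{r.truth_pos}|{r.truth_strand}",
            description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = rec.id.split("|")
        if len(fields) != 5:
            raise ValueError(f"read name lacks truth tags: {rec.id!r}")
        rid, species, contig, pos, strand = fields
        reads.append(Read(id=rid, sequence=str(rec.seq).upper(),
                          truth_species=species, truth_contig=contig,
                          truth_pos=int(pos), truth_strand=strand))
    return reads


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_truth_vcf(mutations: Sequence[SomaticMutation], path,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Write a mutation truth set as minimal VCF v4.2 (INFO carries VAF)."""
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=VAF,Number=1,Type=Float,'
             'Description="True variant allele frequency">']
    contigs = contig_lengths or {}
    for name in sorted({m.contig for m in mutations} | set(contigs)):
        length = f",length={contigs[name]}" if name in contigs else ""
        lines.append(f"##contig=<ID={name}{length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for m in sorted(mutations, key=lambda m: (m.contig, m.pos)):
        lines.append(f"{m.contig}\t{m.pos + 1}\t.\t{m.ref}\t{m.alt}"
                     f"\t.\tPASS\tVAF={m.vaf:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_vcf(path) -> list[SomaticMutation]:
    muts = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            # htslib stores INFO floats as float32; shed the excess digits
            vaf = float(f"{float(rec.info['VAF']):.6g}")
            muts.append(SomaticMutation(
                contig=rec.contig, pos=rec.pos - 1, ref=rec.ref,
                alt=rec.alts[0], vaf=vaf))
    return muts


def write_calls_vcf(calls: Sequence[VariantCall], path,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Write somatic calls as minimal VCF v4.2 (INFO: DP, AD, P)."""
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=DP,Number=1,Type=Integer,Description="Tumor depth">',
             '##INFO=<ID=AD,Number=1,Type=Integer,'
             'Description="Alternate allele read count">',
             '##INFO=<ID=P,Number=1,Type=Float,'
             'Description="Binomial upper-tail probability">']
    contigs = contig_lengths or {}
    for name in sorted({c.contig for c in calls} | set(contigs)):
        length = f",length={contigs[name]}" if name in contigs else ""
        lines.append(f"##contig=<ID={name}{length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
        lines.append(f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS"
                     f"\tDP={c.depth};AD={c.alt_count};P={c.p_value:.3g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignments / coverage
# ---------------------------------------------------------------------------

def write_alignments_tsv(alignments: Sequence[AlignmentRecord], path) -> None:
    """Write alignments as TSV (pos is 1-based here; internal coordinates
    are 0-based half-open)."""
    pd.DataFrame(
        [{"read_id": a.read_id, "contig": a.contig or ".",
          "pos1based": a.pos + 1 if a.pos >= 0 else 0, "strand": a.strand,
          "score": a.score, "n_best": a.n_best, "status": a.status}
         for a in alignments]).to_csv(path, sep="\t", index=False)


def write_coverage(profile: CoverageProfile, tsv_path, json_path) -> None:
    pd.DataFrame({"pos": range(len(profile.depth)),
                  "depth": profile.depth}).to_csv(tsv_path, sep="\t",
                                                  index=False)
    with open(json_path, "w") as fh:
        json.dump({"contig": profile.contig, "mean_doc": profile.mean_doc,
                   "frac_ge": {str(t): v
                               for t, v in profile.frac_ge.items()}},
                  fh, indent=2)
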