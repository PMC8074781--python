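"""File formats: FASTA/FASTQ via Biopython, tab-separated feature/amplicon/
k-mer/truth tables with commented headers, BED-like tracks, CSV difference
lists and JSON reports.

All tabular outputs use 0-based half-open coordinates, stated in the
commented header line of each file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kmers import KmerTable, decode_kmer, encode_kmer, canonical_code
from .seqs import CircularSequence, FeatureAnnotation, FeatureKind
from .synth import Amplicon, EvidenceSet, PairedRead, ReadSet


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(path, records) -> None:
    """``records``: CircularSequence, (id, seq) tuples, or a mix."""
    recs = []
    for r in records if isinstance(records, (list, tuple)) else [records]:
        if isinstance(r, CircularSequence):
            rid, seq = r.id, r.seq
        else:
            rid, seq = r
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _fastq_records(named_seqs):
    for rid, seq in named_seqs:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        yield rec


def write_read_set(readset: ReadSet, prefix) -> dict[str, str]:
    """Write paired reads as <prefix>_1.fastq / <prefix>_2.fastq and long
    reads as <prefix>_long.fastq; returns the paths written."""
    prefix = str(prefix)
    out = {}
    if readset.paired:
        for mate in (1, 2):
            path = f"{prefix}_{mate}.fastq"
            seqs = [(f"pair{i:06d}/{mate}", pr.read1 if mate == 1 else pr.read2)
                    for i, pr in enumerate(readset.paired)]
            SeqIO.write(_fastq_records(seqs), path, "fastq")
            out[f"reads_{mate}"] = path
    if readset.long_reads:
        path = f"{prefix}_long.fastq"
        seqs = [(f"long{i:04d}", lr.seq) for i, lr in enumerate(readset.long_reads)]
        SeqIO.write(_fastq_records(seqs), path, "fastq")
        out["long_reads"] = path
    return out


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_paired_fastq(path1, path2) -> ReadSet:
    rs = ReadSet()
    for (i1, s1), (i2, s2) in zip(read_fastq(path1), read_fastq(path2)):
        rs.paired.append(PairedRead(s1, s2, -1, -1))
    return rs


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_feature_table(path, features: list[FeatureAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tkind\tstart\tend\tstrand\t(0-based, half-open; "
                 "end may exceed length for origin-wrapping features)\n")
        for f in features:
            fh.write(f"{f.name}\t{f.kind.value}\t{f.start}\t{f.end}\t{f.strand}\n")


def read_feature_table(path) -> list[FeatureAnnotation]:
    out = []
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        name, kind, start, end, strand = line.rstrip("\n").split("\t")[:5]
        out.append(FeatureAnnotation(name, FeatureKind(kind), int(start),
                                     int(end), strand))
    return out


def write_gff3(path, seqid: str, features: list[FeatureAnnotation],
               length: int | None = None) -> None:
    """GFF3-style feature table (1-based inclusive per the format; features
    wrapping the origin keep end > length, flagged in the attributes)."""
    kind_to_so = {FeatureKind.PCG: "gene", FeatureKind.TRNA: "tRNA",
                  FeatureKind.RRNA: "rRNA", FeatureKind.CR: "D_loop",
                  FeatureKind.TR: "tandem_repeat"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if length:
            fh.write(f"##sequence-region {seqid} 1 {length}\n")
        for f in features:
            so = kind_to_so.get(f.kind, "region")
            attrs = f"Name={f.name}"
            if length and f.end > length:
                attrs += ";wraps_origin=true"
            fh.write(f"{seqid}\tmitoforge\t{so}\t{f.start + 1}\t{f.end}\t.\t"
                     f"{f.strand}\t.\t{attrs}\n")


def extract_feature_sequences(genome: CircularSequence,
                              features: list[FeatureAnnotation]
                              ) -> list[tuple[str, str]]:
    """(name, sequence) for each feature, reverse-complemented for minus
    strand features."""
    from .seqs import revcomp
    out = []
    for f in features:
        seq = genome.slice_circular(f.start % genome.length,
                                    f.start % genome.length + f.length)
        out.append((f.name, revcomp(seq) if f.strand == "-" else seq))
    return out


def write_amplicon_table(path, evidence: EvidenceSet) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tfwd_pos\trev_pos\texpected_length\tfwd_seq\trev_seq\t"
                 "(0-based, half-open)\n")
        for a in evidence.amplicons:
            fh.write(f"{a.id}\t{a.fwd_pos}\t{a.rev_pos}\t{a.expected_length}\t"
                     f"{a.fwd_seq}\t{a.rev_seq}\n")


def read_amplicon_table(path, insert_model=(500.0, 50.0),
                        length_tolerance: float = 0.10) -> EvidenceSet:
    amps = []
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        aid, fwd, rev, exp, fseq, rseq = line.rstrip("\n").split("\t")[:6]
        amps.append(Amplicon(aid, int(fwd), int(rev), int(exp), fseq, rseq))
    return EvidenceSet(amps, insert_model, [], length_tolerance)


def write_numt_truth(path, background) -> None:
    with open(path, "w") as fh:
        fh.write("# insertion_pos\tlength\tmito_start\tmito_end\tstrand\t"
                 "target_identity\trealized_identity\t(0-based, half-open)\n")
        for p in background.planted:
            fh.write(f"{p.insertion_pos}\t{p.length}\t{p.mito_start}\t{p.mito_end}\t"
                     f"{p.strand}\t{p.target_identity:.4f}\t{p.realized_identity:.4f}\n")


def write_kmer_table(path, table: KmerTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# canonical {table.k}-mer\tcount\n")
        for code in sorted(table.counts):
            fh.write(f"{decode_kmer(code, table.k)}\t{table.counts[code]}\n")


def read_kmer_table(path) -> KmerTable:
    counts = {}
    k = None
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        kmer, cnt = line.split("\t")[:2]
        k = len(kmer)
        counts[canonical_code(encode_kmer(kmer), k)] = int(cnt)
    if k is None:
        raise ValueError(f"empty k-mer table {path}")
    return KmerTable(k=k, counts=counts)


def write_numt_hits(path, hits) -> None:
    """BED-compatible first three columns plus mito coordinates, identity
    and e-value."""
    with open(path, "w") as fh:
        fh.write("# nuclear_id\tnuclear_start\tnuclear_end\tmito_start\tmito_end\t"
                 "strand\taligned_length\tidentity_pct\tevalue\tscore\n")
        for h in hits:
            fh.write(f"{h.nuclear_id}\t{h.nuclear_start}\t{h.nuclear_end}\t"
                     f"{h.mito_start}\t{h.mito_end}\t{h.strand}\t{h.aligned_length}\t"
                     f"{h.identity:.2f}\t{h.evalue:.3g}\t{h.score:.1f}\n")


def write_bed_track(path, name: str, intervals) -> None:
    """``intervals``: iterable of (chrom, start, end, value)."""
    with open(path, "w") as fh:
        fh.write(f"# {name}: chrom\tstart\tend\tvalue\t(0-based, half-open)\n")
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def write_density_track(path, chrom: str, track) -> None:
    write_bed_track(path, "variant density", [
        (chrom, i * track.window, (i + 1) * track.window, int(c))
        for i, c in enumerate(track.counts)])


def write_difference_csv(path, diffs) -> None:
    with open(path, "w") as fh:
        fh.write("reference_taxon,other_taxon,position\n")
        for p in diffs.positions:
            fh.write(f"{diffs.reference_taxon},{diffs.other_taxon},{p}\n")


def write_depth_track(path, chrom: str, depth) -> None:
    with open(path, "w") as fh:
        fh.write("# position\tdepth\t(0-based)\n")
        for i, d in enumerate(depth):
            fh.write(f"{i}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, CircularSequence):
        return {"id": obj.id, "length": obj.length, "is_circular": obj.is_circular}
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
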