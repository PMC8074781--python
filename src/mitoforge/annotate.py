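"""Lightweight annotation: ORF discovery under the vertebrate
mitochondrial genetic code and coordinate transfer of a reference
annotation onto a freshly assembled mitogenome.

tRNA structure scanning is out of scope — tRNA features reach a new
assembly only through :func:`transfer_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .seqs import CircularSequence, FeatureAnnotation, locate_infix, revcomp


@dataclass
class OrfRecord:
    start: int          # 0-based on the forward strand
    end: int            # half-open; may exceed length (wraparound)
    strand: str
    frame: int          # 0..2 on the ORF's own strand
    length_aa: int      # codons excluding the stop
    truncated: bool = False


def find_orfs(genome: CircularSequence,
              min_aa: int = 30,
              code_table: int = 2,
              alt_starts: bool = False) -> list[OrfRecord]:
    """All maximal ORFs on both strands under the given genetic code
    (default: vertebrate mitochondrial), wrapping the origin on circular
    input.

    An ORF is the first start codon after the previous in-frame stop,
    running to the next stop.  With ``alt_starts`` the code table's full
    start-codon set (ATA/ATT/GTG etc. for the mitochondrial code) is
    allowed; otherwise only ATG.
    """
    table = CodonTable.unambiguous_dna_by_id[code_table]
    stops = set(table.stop_codons)
    starts = set(table.start_codons) if alt_starts else {"ATG"}
    L = genome.length
    out: list[OrfRecord] = []
    for strand in "+-":
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        work = seq + seq if genome.is_circular else seq
        for frame in range(3):
            orf_start = None
            for pos in range(frame, len(work) - 2, 3):
                codon = work[pos:pos + 3]
                if orf_start is None:
                    if codon in starts and pos < L:
                        orf_start = pos
                elif codon in stops:
                    _emit(out, orf_start, pos + 3, strand, frame, L, min_aa,
                          truncated=False)
                    orf_start = None
            if orf_start is not None and not genome.is_circular:
                end = len(work) - (len(work) - frame) % 3
                _emit(out, orf_start, end, strand, frame, L, min_aa,
                      truncated=True)
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _emit(out: list[OrfRecord], s: int, e: int, strand: str, frame: int,
          L: int, min_aa: int, truncated: bool) -> None:
    if e - s > L:       # wrapped past a full circle: not a real ORF interval
        return
    aa = (e - s) // 3 - (0 if truncated else 1)
    if aa < min_aa:
        return
    if strand == "-":
        # map from reverse-strand coordinates back to the forward strand
        fs = (L - (e % L)) % L
        s, e = fs, fs + (e - s)
    out.append(OrfRecord(s, e, strand, frame, aa, truncated))


# ---------------------------------------------------------------------------
# annotation transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    placed: list[FeatureAnnotation]
    unplaced: list[str]
    identities: dict[str, float] = field(default_factory=dict)   # percent


def transfer_annotation(reference: CircularSequence,
                        ref_features: list[FeatureAnnotation],
                        target: CircularSequence,
                        min_identity: float = 70.0) -> TransferResult:
    """Locate each reference feature on a target assembly by gapped infix
    alignment of the feature's sequence (both strands of the doubled
    target, so origin-spanning placements work); features whose best
    placement falls below ``min_identity`` percent are reported unplaced."""
    L = target.length
    fwd = target.doubled()
    rev = revcomp(fwd)
    placed: list[FeatureAnnotation] = []
    unplaced: list[str] = []
    idents: dict[str, float] = {}
    for feat in ref_features:
        query = reference.slice_circular(feat.start, feat.end)
        if feat.strand == "-":
            query = revcomp(query)
        best = None     # (identity, start, end, strand)
        for strand, hay in (("+", fwd), ("-", rev)):
            loc = locate_infix(query, hay)
            if loc is None:
                continue
            s, e, ident = loc
            if strand == "-":
                s, e = len(hay) - e, len(hay) - s
            if s >= L:
                s, e = s - L, e - L
            if best is None or ident > best[0]:
                best = (ident, s, e, strand)
        if best is None or best[0] * 100.0 < min_identity:
            unplaced.append(feat.name)
            if best is not None:
                idents[feat.name] = best[0] * 100.0
            continue
        ident, s, e, strand = best
        out_strand = strand if feat.strand == "+" else ("-" if strand == "+" else "+")
        placed.append(FeatureAnnotation(feat.name, feat.kind, s, e, out_strand))
        idents[feat.name] = ident * 100.0
    return TransferResult(placed, unplaced, idents)
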