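"""Reading, writing and summarising genome assemblies and coding sequences.

The pipeline's internal conventions, used by every downstream module:

* nucleotide alphabet is restricted to ``{A, C, G, T, N}``; any other IUPAC
  code is normalised to ``N`` on read (with a logged warning);
* coordinates are 1-based inclusive on the forward strand (GFF3 convention);
* peptides never carry a terminal stop -- ``*`` is stripped wherever a
  translation ends on a stop codon.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return nt.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for empty input or duplicated record identifiers."""


@dataclass
class GenomeAssembly:
    """A named, ordered collection of contigs.

    Contig identifiers must be unique, sequences non-empty and restricted to
    the ``{A,C,G,T,N}`` alphabet (enforce by normalising before construction,
    as :func:`parse_fasta` does).
    """

    name: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FastaFormatError("assembly must contain at least one contig")
        seen: set[str] = set()
        for contig_id, seq in self.contigs:
            if contig_id in seen:
                raise FastaFormatError(f"duplicate contig id {contig_id!r}")
            seen.add(contig_id)
            if not seq:
                raise FastaFormatError(f"contig {contig_id!r} has an empty sequence")
            if not set(seq) <= NUCLEOTIDES:
                bad = sorted(set(seq) - NUCLEOTIDES)
                raise FastaFormatError(
                    f"contig {contig_id!r} contains non-ACGTN symbols {bad}; "
                    "normalise before constructing the assembly"
                )

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


@dataclass(frozen=True)
class GenomeStats:
    """Assembly-level summary: contig count, total size and GC percentage.

    ``gc_percent`` is computed over informative (A/C/G/T) bases only and is
    NaN for an assembly made entirely of ``N``.
    """

    n_contigs: int
    total_length_bp: int
    gc_percent: float


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence anchored on a contig.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates; the
    nucleotide span includes the stop codon, while ``peptide`` does not
    include the corresponding ``*``.
    """

    cds_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    peptide: str
    annotation_label: str = ""
    pathway_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if (self.end - self.start + 1) % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


def _normalise(seq: str, contig_id: str) -> str:
    seq = seq.upper()
    if set(seq) <= NUCLEOTIDES:
        return seq
    replaced = sum(1 for c in seq if c not in NUCLEOTIDES)
    logger.warning(
        "contig %s: %d non-ACGTN symbol(s) replaced by N", contig_id, replaced
    )
    return "".join(c if c in NUCLEOTIDES else "N" for c in seq)


def parse_fasta(stream: TextIO | str, name: str = "assembly") -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    Record order is preserved; lowercase is folded to uppercase and any
    symbol outside ``{A,C,G,T,N}`` becomes ``N`` with a logged warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    contigs: list[tuple[str, str]] = []
    for record in SeqIO.parse(stream, "fasta"):
        contigs.append((record.id, _normalise(str(record.seq), record.id)))
    if not contigs:
        raise FastaFormatError("empty FASTA input")
    return GenomeAssembly(name=name, contigs=contigs)


def write_fasta(assembly: GenomeAssembly, handle: TextIO, width: int = 80) -> None:
    """Write an assembly as FASTA, wrapped at ``width`` columns."""
    for contig_id, seq in assembly.contigs:
        handle.write(f">{contig_id}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def genome_stats(assembly: GenomeAssembly) -> GenomeStats:
    """Contig count, total length, and GC% over informative bases.

    ``N`` is excluded from both the numerator and the denominator of the GC
    fraction; an all-N assembly yields ``gc_percent = nan``.
    """
    gc = at = 0
    for _, seq in assembly.contigs:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    informative = gc + at
    if informative == 0:
        logger.warning("assembly %s contains only N bases; GC undefined", assembly.name)
        gc_percent = math.nan
    else:
        gc_percent = 100.0 * gc / informative
    return GenomeStats(
        n_contigs=len(assembly.contigs),
        total_length_bp=assembly.total_length,
        gc_percent=gc_percent,
    )


def translate(nt: str, frame: int = 0) -> str:
    """Translate a nucleotide string with the standard genetic code.

    The trailing partial codon is dropped, stop codons render as ``*`` (no
    read-through) and any codon containing ``N`` renders as ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    nt = nt.upper()
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)


def _attr_values(attributes, key: str) -> list[str]:
    values: list[str] = []
    for raw in attributes.get(key, []):
        values.extend(v.strip() for v in raw.split(",") if v.strip())
    return values


def read_cds_gff3(stream: TextIO | str, assembly: GenomeAssembly) -> list[CdsRecord]:
    """Extract CDS features from GFF3 text and derive their peptides.

    Features on the minus strand are reverse-complemented before
    translation.  A CDS running past its contig end, or whose length is not
    a multiple of 3, is rejected with a logged warning.  ``product`` and
    ``pathway`` attributes populate ``annotation_label`` / ``pathway_labels``.
    """
    import gffutils

    text = stream if isinstance(stream, str) else stream.read()
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    lengths = {cid: len(seq) for cid, seq in assembly.contigs}
    records: list[CdsRecord] = []
    counter = 0
    for feature in db.features_of_type("CDS", order_by=("seqid", "start")):
        counter += 1
        contig_id = feature.seqid
        if contig_id not in lengths:
            logger.warning("CDS on unknown contig %s rejected", contig_id)
            continue
        start, end = feature.start, feature.end
        if end > lengths[contig_id] or start < 1:
            logger.warning(
                "CDS %s..%d extends past contig %s end; rejected", start, end, contig_id
            )
            continue
        if (end - start + 1) % 3:
            logger.warning(
                "CDS %s:%d..%d length not divisible by 3; rejected",
                contig_id, start, end,
            )
            continue
        nt = assembly.sequence(contig_id)[start - 1 : end]
        if feature.strand == "-":
            nt = reverse_complement(nt)
        peptide = translate(nt).rstrip("*")
        ids = _attr_values(feature.attributes, "ID")
        cds_id = ids[0] if ids else f"{contig_id}:{start}-{end}"
        products = _attr_values(feature.attributes, "product")
        pathways = frozenset(_attr_values(feature.attributes, "pathway"))
        records.append(
            CdsRecord(
                cds_id=cds_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand="-" if feature.strand == "-" else "+",
                peptide=peptide,
                annotation_label=products[0] if products else "",
                pathway_labels=pathways,
            )
        )
    return records


def cds_to_gff3(records: Iterable[CdsRecord], source: str = "coldadapt") -> str:
    """Serialise CDS records as GFF3 text."""
    lines = ["##gff-version 3"]
    for rec in records:
        attrs = [f"ID={rec.cds_id}"]
        if rec.annotation_label:
            attrs.append(f"product={rec.annotation_label}")
        if rec.pathway_labels:
            attrs.append("pathway=" + ",".join(sorted(rec.pathway_labels)))
        lines.append(
            "\t".join(
                [
                    rec.contig_id, source, "CDS", str(rec.start), str(rec.end),
                    ".", rec.strand, "0", ";".join(attrs),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def stats_table(assemblies: Iterable[GenomeAssembly]):
    """Genome statistics for several assemblies as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for asm in assemblies:
        st = genome_stats(asm)
        rows.append(
            {
                "assembly": asm.name,
                "n_contigs": st.n_contigs,
                "total_length_bp": st.total_length_bp,
                "gc_percent": st.gc_percent,
            }
        )
    return pd.DataFrame(rows)
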