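"""Discovery, positional classification and comparison of small ORFs.

A small ORF (smORF) is an ``ATG`` followed by the first in-frame stop, with
a total span -- stop codon included -- of 30 to 300 nt.  All six reading
frames are scanned and every qualifying ATG yields its own ORF, including
ATGs nested inside a longer ORF of the same frame.  Coordinates are always
reported on the forward strand.

Positional classes relative to annotated coding sequences:

* ``CDSSmORF``   -- fully contained in a CDS interval (strand-agnostic);
* ``5'SmORF``    -- fully inside the 1,000-nt window upstream of a CDS
  (upstream defined by that CDS's strand);
* ``3'SmORF``    -- fully inside the 1,000-nt window downstream;
* ``intergenic`` -- none of the above.

Precedence is CDS > 5' > 3', so an ORF is counted once.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .sequence_io import (
    CdsRecord,
    GenomeAssembly,
    START_CODON,
    STOP_CODONS,
    reverse_complement,
    translate,
)

logger = logging.getLogger(__name__)

POSITION_CLASSES = ("CDSSmORF", "5'SmORF", "3'SmORF", "intergenic")


@dataclass(frozen=True)
class SmOrf:
    """A small open reading frame.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates;
    ``frame`` is the reading frame (0-2) on the ORF's own strand; ``nt_seq``
    runs in reading direction from ATG through the stop codon; ``peptide``
    has the stop stripped.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    peptide: str
    position_class: str = "intergenic"

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span % 3 or not span == len(self.nt_seq):
            raise ValueError("ORF span must be divisible by 3 and match nt_seq")
        if not self.nt_seq.startswith(START_CODON):
            raise ValueError("ORF must begin with ATG")
        if self.nt_seq[-3:] not in STOP_CODONS:
            raise ValueError("ORF must end with a stop codon")
        if self.position_class not in POSITION_CLASSES:
            raise ValueError(f"unknown position class {self.position_class!r}")


@dataclass(frozen=True)
class SmOrfMatch:
    """A filtered local-alignment hit of a query smORF against a reference."""

    query_id: str
    reference_id: str
    identity_percent: float
    coverage_percent: float
    score: float
    best: bool = False


def _scan_strand(seq: str, min_len: int, max_len: int):
    """Yield (offset0, span, frame) for ORFs in the scanned orientation."""
    n = len(seq)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops: list[int] = []
        atgs: list[int] = []
        for pos in codon_starts:
            codon = seq[pos : pos + 3]
            if codon == START_CODON:
                atgs.append(pos)
            elif codon in STOP_CODONS:
                stops.append(pos)
        for a in atgs:
            k = bisect_left(stops, a)
            if k == len(stops):
                continue
            span = stops[k] + 3 - a
            if min_len <= span <= max_len:
                yield a, span, frame


def find_orfs(
    assembly: GenomeAssembly, min_len: int = 30, max_len: int = 300
) -> list[SmOrf]:
    """Exhaustive six-frame ORF scan with first-stop rule and ATG starts.

    Length bounds include the stop codon and must be multiples of 3.  ORFs
    are not wrapped across contig ends.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if min_len % 3 or max_len % 3:
        raise ValueError("length bounds must be divisible by 3")
    orfs: list[SmOrf] = []
    for contig_id, seq in assembly.contigs:
        n = len(seq)
        for a, span, frame in _scan_strand(seq, min_len, max_len):
            nt = seq[a : a + span]
            orfs.append(
                SmOrf(
                    contig_id=contig_id,
                    start=a + 1,
                    end=a + span,
                    strand="+",
                    frame=frame,
                    nt_seq=nt,
                    peptide=translate(nt).rstrip("*"),
                )
            )
        rc = reverse_complement(seq)
        for a, span, frame in _scan_strand(rc, min_len, max_len):
            nt = rc[a : a + span]
            orfs.append(
                SmOrf(
                    contig_id=contig_id,
                    start=n - (a + span) + 1,
                    end=n - a,
                    strand="-",
                    frame=frame,
                    nt_seq=nt,
                    peptide=translate(nt).rstrip("*"),
                )
            )
    orfs.sort(key=lambda o: (o.contig_id, o.start, o.end, o.strand, o.frame))
    return orfs


def _window(cds: CdsRecord, side: str, window: int) -> tuple[int, int]:
    """Forward-strand interval of the 5' or 3' window of a CDS."""
    upstream_left = cds.strand == "+"
    if (side == "5'") == upstream_left:
        return cds.start - window, cds.start - 1
    return cds.end + 1, cds.end + window


def classify_smorfs(
    orfs: Sequence[SmOrf], cds_list: Sequence[CdsRecord], window: int = 1000
) -> list[SmOrf]:
    """Assign each ORF exactly one positional class relative to the CDSs.

    Containment (not mere overlap) defines every class; precedence is
    CDS > 5' > 3' > intergenic.  With an empty CDS list everything is
    intergenic.
    """
    by_contig: dict[str, list[CdsRecord]] = {}
    for cds in cds_list:
        by_contig.setdefault(cds.contig_id, []).append(cds)

    out: list[SmOrf] = []
    for orf in orfs:
        cdss = by_contig.get(orf.contig_id, [])
        cls = "intergenic"
        if any(c.start <= orf.start and orf.end <= c.end for c in cdss):
            cls = "CDSSmORF"
        else:
            for side, name in (("5'", "5'SmORF"), ("3'", "3'SmORF")):
                hit = False
                for c in cdss:
                    lo, hi = _window(c, side, window)
                    if lo <= orf.start and orf.end <= hi:
                        hit = True
                        break
                if hit:
                    cls = name
                    break
        out.append(replace(orf, position_class=cls))
    return out


def count_shared_smorfs(
    set_a: Iterable[SmOrf], set_b: Iterable[SmOrf], level: str = "peptide"
) -> int:
    """Number of distinct sequences present in both smORF sets.

    ``level`` selects nucleotide or peptide identity; multiplicity within a
    set is ignored, so the count is symmetric.
    """
    if level not in ("nucleotide", "peptide"):
        raise ValueError("level must be 'nucleotide' or 'peptide'")
    attr = "nt_seq" if level == "nucleotide" else "peptide"
    return len(
        {getattr(o, attr) for o in set_a} & {getattr(o, attr) for o in set_b}
    )


def match_smorfs(
    queries: Sequence[SmOrf],
    reference_peptides: Sequence[tuple[str, str]],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> list[SmOrfMatch]:
    """Local-align query peptides against a reference set and filter hits.

    A hit is kept when identity and query coverage both meet their
    thresholds; the best-scoring hit per query is flagged.
    """
    from .phylo import local_align

    if not reference_peptides:
        raise ValueError("reference set must be non-empty")
    matches: list[SmOrfMatch] = []
    for qi, query in enumerate(queries):
        if not query.peptide:
            logger.warning("query %d has an empty peptide; skipped", qi)
            continue
        qid = f"{query.contig_id}:{query.start}-{query.end}({query.strand})"
        hits: list[SmOrfMatch] = []
        for rid, ref in reference_peptides:
            aln = local_align(query.peptide, ref)
            if (
                aln.identity_percent >= min_identity
                and aln.coverage_percent >= min_coverage
            ):
                hits.append(
                    SmOrfMatch(
                        query_id=qid,
                        reference_id=rid,
                        identity_percent=aln.identity_percent,
                        coverage_percent=aln.coverage_percent,
                        score=aln.score,
                    )
                )
        if hits:
            best = max(range(len(hits)), key=lambda i: hits[i].score)
            hits[best] = replace(hits[best], best=True)
        matches.extend(hits)
    return matches


def smorf_table(orfs: Iterable[SmOrf]):
    """SmORFs as a tidy DataFrame (one row per ORF)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig_id": o.contig_id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "frame": o.frame,
                "position_class": o.position_class,
                "nt_seq": o.nt_seq,
                "peptide": o.peptide,
            }
            for o in orfs
        ]
    )
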