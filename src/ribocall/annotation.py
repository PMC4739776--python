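"""Transcript models, annotation parsing, coordinate maps, and biotype rules.

Internal convention: all genomic coordinates are 0-based half-open;
transcript-space positions run 5'->3' of the RNA regardless of genomic
strand, so downstream ORF logic never sees a strand. Sequences are stored
in the DNA alphabet (T); U is accepted on input.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = [
    "GenomeInterval",
    "Transcript",
    "BiotypeRules",
    "AnnotationError",
    "parse_genepred",
    "parse_gtf",
    "parse_annotation",
    "extract_sequence",
    "assign_biotype",
    "biotype_table",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BIOTYPES = ("mRNA", "lncRNA", "pseudogene", "short_ncRNA", "unclassified")


class AnnotationError(ValueError):
    """Raised for malformed annotation records or out-of-range lookups."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeInterval:
    """A half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """Strand-aware exon-block model of one RNA.

    ``exons`` are sorted 5'->3' in transcript orientation: ascending genome
    coordinates on '+', descending on '-'. ``cds_start``/``cds_end`` are
    transcript-space offsets of the canonical ORF (stop codon included).
    """

    id: str
    gene_id: str
    exons: list[GenomeInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "unclassified"
    cds_incomplete: bool = False
    _cum: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(f"transcript {self.id}: exons span chrom/strand")
        ivs = sorted((e.start, e.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise AnnotationError(f"transcript {self.id}: overlapping exons")
        # cumulative transcript offsets of exon starts, 5'->3'
        cum, acc = [], 0
        for e in self.exons:
            cum.append(acc)
            acc += len(e)
        self._cum = cum
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise AnnotationError(f"transcript {self.id}: CDS out of bounds")
            if (self.cds_end - self.cds_start) % 3 != 0:
                self.cds_incomplete = True

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return self._cum[-1] + len(self.exons[-1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and not self.cds_incomplete

    def to_genome(self, pos: int) -> tuple[str, int]:
        """Map a transcript position to (chrom, genome position)."""
        if not 0 <= pos < self.length:
            raise AnnotationError(
                f"position {pos} outside transcript {self.id} [0,{self.length})"
            )
        i = bisect.bisect_right(self._cum, pos) - 1
        e, off = self.exons[i], pos - self._cum[i]
        g = e.start + off if self.strand == "+" else e.end - 1 - off
        return self.chrom, g

    def to_transcript(self, chrom: str, gpos: int) -> int | None:
        """Inverse of :meth:`to_genome`; None if gpos is not exonic here."""
        if chrom != self.chrom:
            return None
        for i, e in enumerate(self.exons):
            if e.start <= gpos < e.end:
                off = gpos - e.start if self.strand == "+" else e.end - 1 - gpos
                return self._cum[i] + off
        return None

    def blocks_to_genome(self, tstart: int, tend: int) -> list[tuple[int, int]]:
        """Genomic blocks covering transcript span [tstart, tend).

        Blocks are returned in ascending genome order (SAM orientation),
        merged across exon boundaries where contiguous.
        """
        if not (0 <= tstart < tend <= self.length):
            raise AnnotationError(f"span [{tstart},{tend}) outside {self.id}")
        blocks = []
        pos = tstart
        while pos < tend:
            i = bisect.bisect_right(self._cum, pos) - 1
            e = self.exons[i]
            take = min(tend, self._cum[i] + len(e)) - pos
            off = pos - self._cum[i]
            if self.strand == "+":
                blocks.append((e.start + off, e.start + off + take))
            else:
                blocks.append((e.end - off - take, e.end - off))
            pos += take
        blocks.sort()
        merged = [list(blocks[0])]
        for s, e2 in blocks[1:]:
            if s == merged[-1][1]:
                merged[-1][1] = e2
            else:
                merged.append([s, e2])
        return [tuple(b) for b in merged]


@dataclass
class BiotypeRules:
    """Thresholds for biotype assignment of non-coding transcripts."""

    lncrna_min_monoexonic_length: int = 500
    short_ncrna_max_length: int = 200

    def __post_init__(self) -> None:
        if self.lncrna_min_monoexonic_length <= 0 or self.short_ncrna_max_length <= 0:
            raise ValueError("biotype length thresholds must be positive")


# ---------------------------------------------------------------------------
# parsing


def _genome_cds_to_transcript(t: Transcript, g_cds_start: int, g_cds_end: int):
    if g_cds_start >= g_cds_end:  # genePred encodes "no CDS" as start == end
        return None, None
    if t.strand == "+":
        cs = t.to_transcript(t.chrom, g_cds_start)
        ce = t.to_transcript(t.chrom, g_cds_end - 1)
        return cs, None if ce is None else ce + 1
    cs = t.to_transcript(t.chrom, g_cds_end - 1)
    ce = t.to_transcript(t.chrom, g_cds_start)
    return cs, None if ce is None else ce + 1


def parse_genepred(stream) -> list[Transcript]:
    """Parse UCSC genePred (10- or 15-column extended) text into transcripts."""
    out = []
    for ln, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 10:
            raise AnnotationError(f"genePred line {ln}: expected >=10 columns")
        try:
            name, chrom, strand = f[0], f[1], f[2]
            cds_s, cds_e = int(f[5]), int(f[6])
            n_exons = int(f[7])
            starts = [int(x) for x in f[8].rstrip(",").split(",")]
            ends = [int(x) for x in f[9].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(f"genePred line {ln}: {exc}") from exc
        if len(starts) != n_exons or len(ends) != n_exons:
            raise AnnotationError(f"genePred line {ln}: exon count mismatch")
        gene = f[11] if len(f) > 11 and f[11] else name
        exons = [GenomeInterval(chrom, s, e, strand) for s, e in zip(starts, ends)]
        if strand == "-":
            exons = exons[::-1]
        t = Transcript(name, gene, exons)
        cs, ce = _genome_cds_to_transcript(t, cds_s, cds_e)
        if cs is not None and ce is not None:
            t = Transcript(name, gene, exons, cds_start=cs, cds_end=ce)
        out.append(t)
    return out


def parse_gtf(stream) -> list[Transcript]:
    """Parse GTF2.2 exon/CDS features into transcripts (1-based starts -> 0-based)."""
    exons: dict[str, list[GenomeInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, str] = {}
    for ln, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise AnnotationError(f"GTF line {ln}: expected 9 columns")
        chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
        if feat not in ("exon", "CDS"):
            continue
        try:
            iv = (int(start) - 1, int(end))
        except ValueError as exc:
            raise AnnotationError(f"GTF line {ln}: {exc}") from exc
        tags = {}
        for item in attrs.rstrip(";").split(";"):
            item = item.strip()
            if not item:
                continue
            key, _, val = item.partition(" ")
            tags[key] = val.strip().strip('"')
        tid = tags.get("transcript_id")
        if tid is None:
            raise AnnotationError(f"GTF line {ln}: missing transcript_id")
        genes.setdefault(tid, tags.get("gene_id", tid))
        if feat == "exon":
            exons.setdefault(tid, []).append(GenomeInterval(chrom, *iv, strand))
        else:
            cds.setdefault(tid, []).append(iv)
    out = []
    for tid, exs in exons.items():
        exs = sorted(exs, key=lambda e: e.start, reverse=(exs[0].strand == "-"))
        t = Transcript(tid, genes[tid], exs)
        if tid in cds:
            g_s = min(s for s, _ in cds[tid])
            g_e = max(e for _, e in cds[tid])
            # GTF CDS excludes the stop codon; extend by 3 to include it
            if t.strand == "+":
                g_e = min(g_e + 3, t.exons[-1].end)
            else:
                g_s = max(g_s - 3, t.exons[-1].start)
            cs, ce = _genome_cds_to_transcript(t, g_s, g_e)
            if cs is not None and ce is not None:
                t = Transcript(tid, genes[tid], exs, cds_start=cs, cds_end=ce)
        out.append(t)
    return out


def parse_annotation(stream, dialect: str = "genepred") -> list[Transcript]:
    """Dispatch to the genePred or GTF reader."""
    if dialect == "genepred":
        return parse_genepred(stream)
    if dialect == "gtf":
        return parse_gtf(stream)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sequence extraction


def extract_sequence(t: Transcript, genome) -> str:
    """Spliced, strand-corrected transcript sequence.

    ``genome`` is any chrom -> sliceable mapping (a dict of strings or a
    ``pyfaidx.Fasta``).
    """
    try:
        chrom_seq = genome[t.chrom]
    except KeyError as exc:
        raise AnnotationError(f"chromosome {t.chrom!r} not in genome") from exc
    parts = []
    for e in t.exons:
        s = str(chrom_seq[e.start : e.end]).upper().replace("U", "T")
        parts.append(reverse_complement(s) if t.strand == "-" else s)
    seq = "".join(parts)
    if len(seq) != t.length:
        raise AnnotationError(
            f"transcript {t.id}: exon outside genome bounds "
            f"(got {len(seq)} nt, expected {t.length})"
        )
    return seq


# ---------------------------------------------------------------------------
# biotype assignment


class _ExonOverlapIndex:
    """Same-strand exonic overlap queries over a set of transcripts."""

    def __init__(self, transcripts):
        self._ivs: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for t in transcripts:
            key = (t.chrom, t.strand)
            for e in t.exons:
                self._ivs.setdefault(key, []).append((e.start, e.end, t.id))
        for v in self._ivs.values():
            v.sort()

    def overlaps(self, t: Transcript, exclude_id: str | None = None) -> bool:
        ivs = self._ivs.get((t.chrom, t.strand), ())
        for e in t.exons:
            for s, x, tid in ivs:
                if s >= e.end:
                    break
                if x > e.start and tid != exclude_id:
                    return True
        return False


def assign_biotype(
    t: Transcript,
    coding: list[Transcript] | None = None,
    pseudogenes: list[Transcript] | None = None,
    rules: BiotypeRules | None = None,
    _coding_index: _ExonOverlapIndex | None = None,
    _pseudo_index: _ExonOverlapIndex | None = None,
) -> str:
    """Assign one biotype per the source-set and overlap rules.

    mRNA: annotated in-frame CDS. short_ncRNA: length under the short-RNA
    cap. pseudogene: in the pseudogene source set and no protein-coding
    overlap. lncRNA: spliced or long enough, with no same-strand exonic
    overlap with a coding gene or pseudogene. Everything else is
    unclassified. Overlap means >=1 shared exonic base on the same strand.
    """
    rules = rules or BiotypeRules()
    coding = coding or []
    pseudogenes = pseudogenes or []
    coding_ids = {c.id for c in coding}
    if t.has_cds and (not coding_ids or t.id in coding_ids):
        return "mRNA"
    if t.length < rules.short_ncrna_max_length:
        return "short_ncRNA"
    cidx = _coding_index or _ExonOverlapIndex(coding)
    pidx = _pseudo_index or _ExonOverlapIndex(pseudogenes)
    if t.id in {p.id for p in pseudogenes}:
        return "pseudogene" if not cidx.overlaps(t, exclude_id=t.id) else "unclassified"
    if t.n_exons > 1 or t.length > rules.lncrna_min_monoexonic_length:
        if not cidx.overlaps(t, exclude_id=t.id) and not pidx.overlaps(
            t, exclude_id=t.id
        ):
            return "lncRNA"
    return "unclassified"


def assign_biotypes(
    transcripts,
    coding=None,
    pseudogenes=None,
    rules: BiotypeRules | None = None,
) -> dict[str, str]:
    """Vector form of :func:`assign_biotype`; order-independent."""
    coding = coding or []
    pseudogenes = pseudogenes or []
    cidx = _ExonOverlapIndex(coding)
    pidx = _ExonOverlapIndex(pseudogenes)
    return {
        t.id: assign_biotype(
            t, coding, pseudogenes, rules, _coding_index=cidx, _pseudo_index=pidx
        )
        for t in transcripts
    }


def biotype_table(transcripts, biotypes: dict[str, str] | None = None):
    """TSV-ready table (id, biotype, length, n_exons) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "id": t.id,
            "biotype": biotypes[t.id] if biotypes else t.biotype,
            "length": t.length,
            "n_exons": t.n_exons,
        }
        for t in transcripts
    ]
    return pd.DataFrame(rows, columns=["id", "biotype", "length", "n_exons"])
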