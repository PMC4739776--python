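"""Candidate-ORF enumeration, typing relative to the canonical CDS, and
representative-start selection among same-stop ORF groups.

All coordinates are transcript-space (5'->3' of the RNA). ORF spans include
the stop codon; encoded peptide length excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CandidateORF",
    "enumerate_orfs",
    "classify_orf",
    "group_by_stop",
    "select_representative",
    "orf_table",
    "START_CODONS",
    "STOP_CODONS",
]

# DNA alphabet internally; reported as RNA
START_CODONS = ("ATG", "CTG", "GTG", "TTG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

ORF_TYPES = (
    "canonical",
    "truncated",
    "extended",
    "uORF",
    "overlapping_uORF",
    "internal",
    "dORF",
    "noncoding_ORF",
)


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass(frozen=True)
class CandidateORF:
    """One ORF in transcript space: [start, stop) including the stop codon."""

    transcript_id: str
    start: int
    stop: int
    start_codon: str  # RNA alphabet: AUG/CUG/GUG/UUG
    orf_type: str = "noncoding_ORF"

    def __post_init__(self) -> None:
        if (self.stop - self.start) % 3 != 0 or self.stop - self.start < 6:
            raise ValueError(
                f"ORF [{self.start},{self.stop}) is not a whole codon span"
            )

    @property
    def length_nt(self) -> int:
        return self.stop - self.start

    @property
    def n_codons(self) -> int:
        """Codons encoding peptide (stop excluded)."""
        return (self.stop - self.start) // 3 - 1

    @property
    def peptide_length(self) -> int:
        return self.n_codons

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.start, self.stop)


def enumerate_orfs(
    seq: str,
    transcript_id: str = "",
    starts=START_CODONS,
    min_len_aa: int = 6,
) -> list[CandidateORF]:
    """All ORFs from an allowed start codon to the first in-frame stop.

    ORFs lacking an in-frame stop within the sequence are not reported;
    peptides shorter than ``min_len_aa`` amino acids are dropped.
    """
    seq = seq.upper().replace("U", "T")
    starts = {s.upper().replace("U", "T") for s in starts}
    n = len(seq)
    # next in-frame stop at-or-after each position, per frame
    next_stop = [dict() for _ in range(3)]
    last = [None, None, None]
    for i in range(n - 3, -1, -1):
        f = i % 3
        if seq[i : i + 3] in STOP_CODONS:
            last[f] = i
        next_stop[f][i] = last[f]
    out = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon not in starts:
            continue
        stop = next_stop[i % 3].get(i)
        if stop is None or stop == i:
            continue
        if (stop - i) // 3 < min_len_aa:  # peptide codons, stop excluded
            continue
        out.append(CandidateORF(transcript_id, i, stop + 3, _rna(codon)))
    return out


def classify_orf(orf: CandidateORF, cds: tuple[int, int] | None) -> str:
    """Type an ORF relative to the canonical CDS span (transcript space).

    With no CDS everything is a noncoding_ORF. Sharing the canonical stop
    makes the ORF canonical/extended/truncated by start position. ORFs
    entirely 5' of the CDS are uORFs; off-frame ORFs starting in the 5'UTR
    and ending past the CDS start are overlapping uORFs; off-frame ORFs
    starting inside the CDS are internal; ORFs entirely 3' of the CDS are
    dORFs.
    """
    if cds is None:
        return "noncoding_ORF"
    cs, ce = cds
    if orf.stop == ce:
        if orf.start == cs:
            return "canonical"
        return "extended" if orf.start < cs else "truncated"
    if orf.stop <= cs:
        return "uORF"
    if orf.start >= ce:
        return "dORF"
    if orf.start < cs:
        return "overlapping_uORF"
    return "internal"


def classify_all(
    orfs: list[CandidateORF], cds: tuple[int, int] | None
) -> list[CandidateORF]:
    return [replace(o, orf_type=classify_orf(o, cds)) for o in orfs]


def group_by_stop(orfs) -> list[list[CandidateORF]]:
    """Group ORFs sharing (transcript, stop); members sorted by start."""
    groups: dict[tuple[str, int], list[CandidateORF]] = {}
    for o in orfs:
        groups.setdefault((o.transcript_id, o.stop), []).append(o)
    return [sorted(g, key=lambda o: o.start) for _, g in sorted(groups.items())]


def select_representative(group, counts) -> CandidateORF:
    """Pick the representative start of a same-stop ORF group.

    AUG starts are preferred when present; among those the 5'-most start
    wins, unless there is no A-site read between it and the next downstream
    candidate start, in which case selection advances to that candidate and
    the rule repeats. ``counts`` is the transcript A-site count vector.
    """
    if not group:
        raise ValueError("empty ORF group")
    members = sorted(group, key=lambda o: o.start)
    augs = [o for o in members if o.start_codon == "AUG"]
    pool = augs if augs else members
    counts = np.asarray(counts)
    i = 0
    while i + 1 < len(pool):
        nxt = pool[i + 1]
        if counts[pool[i].start : nxt.start].sum() == 0:
            i += 1
        else:
            break
    return pool[i]


def orf_table(orfs):
    """Candidate-ORF table as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        {
            "transcript_id": o.transcript_id,
            "start": o.start,
            "stop": o.stop,
            "start_codon": o.start_codon,
            "orf_type": o.orf_type,
            "peptide_length": o.peptide_length,
        }
        for o in orfs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "start",
            "stop",
            "start_codon",
            "orf_type",
            "peptide_length",
        ],
    )
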