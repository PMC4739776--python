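"""End-to-end wiring of the pipeline stages.

These helpers connect annotation, alignment, discovery, features and the
classifier so the command-line interface, the test-suite and downstream
scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import (
    AsiteProfile,
    OffsetTable,
    TranscriptPositionIndex,
    assign_asites,
    calibrate_offsets,
)
from .annotation import Transcript, extract_sequence
from .classifier import TrainingSpec, TranslatedOrfSVM, build_sets, call_orfs
from .features import feature_table
from .orfs import CandidateORF, classify_all, enumerate_orfs

__all__ = [
    "discover_catalog",
    "RiboRun",
    "run_ribo_stages",
    "label_catalog",
    "count_reads_per_transcript",
    "count_reads_in_span",
]


def discover_catalog(
    transcripts: list[Transcript],
    genome,
    starts=("ATG", "CTG", "GTG", "TTG"),
    min_len_aa: int = 6,
) -> list[CandidateORF]:
    """Enumerate and type candidate ORFs on every transcript."""
    catalog = []
    for t in transcripts:
        seq = extract_sequence(t, genome)
        orfs = enumerate_orfs(seq, transcript_id=t.id, starts=starts, min_len_aa=min_len_aa)
        cds = (t.cds_start, t.cds_end) if t.has_cds else None
        catalog.extend(classify_all(orfs, cds))
    return catalog


@dataclass
class RiboRun:
    """Artifacts of the ribo-seq side of the pipeline."""

    offsets: OffsetTable
    profiles: dict[str, AsiteProfile]
    catalog: list[CandidateORF]
    features: pd.DataFrame
    library_size: int
    index: TranscriptPositionIndex = field(repr=False, default=None)


def run_ribo_stages(
    reads,
    transcripts,
    genome,
    support_min: int = 100,
    min_len_aa: int = 6,
    starts=("ATG", "CTG", "GTG", "TTG"),
    offsets: OffsetTable | None = None,
) -> RiboRun:
    """Calibrate offsets, build A-site profiles, discover ORFs, compute
    features; one call from aligned reads to the feature table."""
    index = TranscriptPositionIndex(transcripts)
    if offsets is None:
        offsets = calibrate_offsets(reads, transcripts, support_min=support_min, index=index)
    profiles = assign_asites(reads, offsets, transcripts, index=index)
    catalog = discover_catalog(transcripts, genome, starts=starts, min_len_aa=min_len_aa)
    library_size = len(reads)
    feats = feature_table(profiles, catalog, library_size)
    return RiboRun(offsets, profiles, catalog, feats, library_size, index)


def label_catalog(features: pd.DataFrame, truth_keys: set) -> pd.Series:
    """1/0 labels for a feature table against a set of true translated
    (transcript, start, stop) keys."""
    return pd.Series(
        [
            1 if (r.transcript_id, r.start, r.stop) in truth_keys else 0
            for r in features.itertuples()
        ],
        index=features.index,
        name="label",
    )


def count_reads_per_transcript(reads, index: TranscriptPositionIndex) -> dict[str, int]:
    """Reads per transcript by 5'-end containment (RNA-seq quantification)."""
    counts = {tid: 0 for tid in index.transcripts}
    for r in reads:
        for t, _ in index.lookup(r.chrom, r.strand, r.five_prime):
            counts[t.id] += 1
    return counts


def count_reads_in_span(reads, index: TranscriptPositionIndex, orf) -> int:
    """Reads whose 5' end falls inside an ORF span on its transcript."""
    n = 0
    for r in reads:
        for t, p in index.lookup(r.chrom, r.strand, r.five_prime):
            if t.id == orf.transcript_id and orf.start <= p < orf.stop:
                n += 1
    return n
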