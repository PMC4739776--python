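"""Per-ORF classifier features: codon-position read fractions, the
percentage-of-maximum-entropy (PME) uniformity score, read counts and RPKM.

All features are computed on A-site counts over the coding span of the ORF,
excluding the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ORFFeatureVector",
    "codon_fractions",
    "pme",
    "pme_from_codon_counts",
    "rpkm",
    "orf_features",
    "feature_table",
]


@dataclass(frozen=True)
class ORFFeatureVector:
    """Feature bundle for one candidate ORF."""

    f1: float
    f2: float
    f3: float
    pme: float
    n_reads: int
    n_codons: int
    rpkm: float

    @property
    def expressed(self) -> bool:
        return self.n_reads > 0


def _coding_counts(counts, orf) -> np.ndarray:
    """A-site counts over the ORF coding span (stop codon excluded)."""
    counts = np.asarray(counts)
    if orf.stop > len(counts):
        raise ValueError(f"ORF {orf.key} exceeds profile length {len(counts)}")
    return counts[orf.start : orf.stop - 3]


def codon_fractions(counts, orf) -> tuple[float, float, float]:
    """Fractions of A-site reads at codon nucleotides 1/2/3.

    Positions are bucketed by (pos - start) mod 3 over the coding span.
    Returns (0, 0, 0) for an ORF with no reads.
    """
    window = _coding_counts(counts, orf)
    n = window.sum()
    if n == 0:
        return (0.0, 0.0, 0.0)
    by_phase = window.reshape(-1, 3).sum(axis=0)
    f = by_phase / n
    return (float(f[0]), float(f[1]), float(f[2]))


def pme_from_codon_counts(codon_counts) -> float:
    """PME from per-codon A-site read counts.

    With N reads over L codons, the ORF is cut into regions of 1 codon when
    N > L and floor(L/N) codons otherwise; remainder codons join the last
    region. PME is the Shannon entropy of the per-region read fractions
    divided by log2 of the region count — 1 for perfectly even coverage, 0
    for reads piled at a single region. Zero reads or a single region give
    a defined PME of 0.
    """
    codon_counts = np.asarray(codon_counts)
    L = len(codon_counts)
    N = int(codon_counts.sum())
    if N == 0 or L == 0:
        return 0.0
    region_len = 1 if N > L else L // N
    n_regions = L // region_len
    if n_regions < 2:
        return 0.0
    # last region absorbs the remainder codons
    edges = [i * region_len for i in range(n_regions)] + [L]
    region_counts = np.add.reduceat(codon_counts, edges[:-1])
    p = region_counts[region_counts > 0] / N
    h = float(-(p * np.log2(p)).sum())
    return h / np.log2(n_regions) + 0.0  # normalize -0.0


def pme(counts, orf) -> float:
    """PME of an ORF given its transcript A-site profile."""
    window = _coding_counts(counts, orf)
    return pme_from_codon_counts(window.reshape(-1, 3).sum(axis=1))


def rpkm(n_reads: int, length_nt: int, library_size: int) -> float:
    """Reads per kilobase per million mappable reads."""
    if length_nt <= 0:
        raise ValueError("zero-length region")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return n_reads / (length_nt / 1000.0) / (library_size / 1e6)


def orf_features(counts, orf, library_size: int) -> ORFFeatureVector:
    """Assemble the full feature vector for one ORF."""
    window = _coding_counts(counts, orf)
    n = int(window.sum())
    f1, f2, f3 = codon_fractions(counts, orf)
    return ORFFeatureVector(
        f1=f1,
        f2=f2,
        f3=f3,
        pme=pme_from_codon_counts(window.reshape(-1, 3).sum(axis=1)),
        n_reads=n,
        n_codons=orf.n_codons,
        rpkm=rpkm(n, orf.length_nt, library_size),
    )


def feature_table(profiles: dict, orfs, library_size: int):
    """One row per candidate ORF with all feature fields (DataFrame)."""
    import pandas as pd

    rows = []
    for o in orfs:
        fv = orf_features(profiles[o.transcript_id], o, library_size)
        rows.append(
            {
                "transcript_id": o.transcript_id,
                "start": o.start,
                "stop": o.stop,
                "start_codon": o.start_codon,
                "orf_type": o.orf_type,
                "f1": fv.f1,
                "f2": fv.f2,
                "f3": fv.f3,
                "pme": fv.pme,
                "n_reads": fv.n_reads,
                "n_codons": fv.n_codons,
                "rpkm": fv.rpkm,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "start",
            "stop",
            "start_codon",
            "orf_type",
            "f1",
            "f2",
            "f3",
            "pme",
            "n_reads",
            "n_codons",
            "rpkm",
        ],
    )
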