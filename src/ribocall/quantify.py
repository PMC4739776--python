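"""Expression calling and translation-efficiency statistics.

Expression of a transcript is tested against a Poisson null whose rate is
proportional to transcript length within the tested set, with
Benjamini–Hochberg correction across transcripts. Translation efficiency
is the log2 ratio of ribosome-profiling RPKM to RNA-seq RPKM over the same
ORF span.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log2

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import rpkm

__all__ = [
    "ExpressionCall",
    "TEResult",
    "expression_test",
    "translation_efficiency",
    "relative_te_class",
    "cn_ratio",
    "overlap_retained_fraction",
]


@dataclass(frozen=True)
class ExpressionCall:
    transcript_id: str
    n_reads: int
    expected: float
    p: float
    q: float
    expressed: bool


@dataclass(frozen=True)
class TEResult:
    orf_id: tuple
    ribo_rpkm: float
    rna_rpkm: float
    log2_te: float  # inf when eligible but rna_rpkm == 0; nan when ineligible
    eligible: bool


def expression_test(
    counts: dict[str, int],
    lengths: dict[str, int],
    library_size: int,
    q_max: float = 1e-3,
    reads_min: int = 10,
    peptide_encoding: set[str] | None = None,
) -> pd.DataFrame:
    """Poisson expression test with BH correction across tested transcripts.

    The null rate for transcript t is library_size * length_t / total
    tested length; p = P(Poisson(lambda_t) >= observed). A transcript is
    called expressed when q < ``q_max`` and it has strictly more than
    ``reads_min`` reads, or when it encodes a called peptide
    (``peptide_encoding`` ids).
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    ids = list(counts)
    total_len = sum(lengths[i] for i in ids)
    if total_len <= 0:
        raise ValueError("no tested transcript length")
    lam = np.array([library_size * lengths[i] / total_len for i in ids])
    obs = np.array([counts[i] for i in ids])
    p = stats.poisson.sf(obs - 1, lam)  # P(X >= obs)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    peptide_encoding = peptide_encoding or set()
    expressed = [
        (qi < q_max and o > reads_min) or (i in peptide_encoding)
        for i, o, qi in zip(ids, obs, q)
    ]
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "n_reads": obs,
            "expected": lam,
            "p": p,
            "q": q,
            "expressed": expressed,
        }
    )


def overlap_retained_fraction(orfs) -> dict[tuple, float]:
    """Fraction of each ORF span not overlapped by ORFs of other types.

    Backs the translation-efficiency exclusion of ORF regions shared with
    other ORF classes; computed per nucleotide in transcript space.
    """
    by_tx: dict[str, list] = {}
    for o in orfs:
        by_tx.setdefault(o.transcript_id, []).append(o)
    out = {}
    for tx, group in by_tx.items():
        length = max(o.stop for o in group)
        cover: dict[str, np.ndarray] = {}
        for o in group:
            m = cover.setdefault(o.orf_type, np.zeros(length, dtype=bool))
            m[o.start : o.stop] = True
        for o in group:
            other = np.zeros(length, dtype=bool)
            for t, m in cover.items():
                if t != o.orf_type:
                    other |= m
            masked = other[o.start : o.stop].sum()
            out[o.key] = 1.0 - masked / o.length_nt
    return out


def translation_efficiency(
    ribo_reads: int,
    rna_reads: int,
    orf_length_nt: int,
    ribo_library: int,
    rna_library: int,
    orf_id: tuple = ("", 0, 0),
    reads_min: int = 10,
    retained_fraction: float = 1.0,
    min_retained: float = 0.5,
) -> TEResult:
    """log2(ribo RPKM / RNA RPKM) for one ORF.

    Eligibility requires strictly more than ``reads_min`` reads in both
    libraries and at least ``min_retained`` of the span free of other-type
    ORF overlap. Ineligible ORFs carry NaN; an eligible ORF with zero RNA
    RPKM is flagged infinite and excluded from summaries.
    """
    ribo = rpkm(ribo_reads, orf_length_nt, ribo_library)
    rna = rpkm(rna_reads, orf_length_nt, rna_library)
    eligible = (
        ribo_reads > reads_min
        and rna_reads > reads_min
        and retained_fraction >= min_retained
    )
    if not eligible:
        te = float("nan")
    elif rna == 0:
        te = inf
    else:
        te = log2(ribo / rna)
    return TEResult(orf_id, ribo, rna, te, eligible)


def relative_te_class(
    te_noncanonical: float, te_canonical: float, fold: float = 3.0
) -> str:
    """Class of a uORF/dORF TE relative to the canonical ORF of its gene.

    'high' above ``fold``-fold the canonical TE, 'low' below 1/``fold``,
    otherwise 'neither'.
    """
    ratio = 2.0 ** (te_noncanonical - te_canonical)
    if ratio > fold:
        return "high"
    if ratio < 1.0 / fold:
        return "low"
    return "neither"


def cn_ratio(
    cytosol_rpkm: float,
    nucleus_rpkm: float,
    total_reads: int,
    min_total_reads: int = 50,
    eps: float = 0.0,
) -> float:
    """log2 cytosol:nucleus RPKM ratio for one transcript.

    Transcripts with ``min_total_reads`` or fewer RNA-seq reads across the
    two fractions are excluded (NaN). With the default eps = 0 a zero
    denominator is excluded rather than smoothed.
    """
    if total_reads <= min_total_reads:
        return float("nan")
    num, den = cytosol_rpkm + eps, nucleus_rpkm + eps
    if den == 0:
        return float("nan")
    return log2(num / den)
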