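"""Nei–Gojobori (1986) approximate-method Ka/Ks for codon-aligned ORF pairs.

Synonymous/nonsynonymous site counts per codon come from enumerating the
nine possible point mutations; observed differences are averaged over all
minimal mutational pathways; proportions are Jukes–Cantor corrected. Pairs
are assumed pre-aligned (gapless, codon-aligned); homolog pairing by
Liftover/BLASTP is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isnan, log, nan

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonPairAlignment",
    "KaKsResult",
    "count_sites",
    "count_differences",
    "kaks",
    "SaturationError",
]

_BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when a difference proportion is beyond the Jukes–Cantor limit."""


def _codon_map(table_id: int = 1) -> dict[str, str]:
    table = unambiguous_dna_by_id[table_id]
    amap = dict(table.forward_table)
    for stop in table.stop_codons:
        amap[stop] = "*"
    return amap


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class CodonPairAlignment:
    """A gapless codon alignment of two coding sequences."""

    a: str
    b: str
    table_id: int = 1

    def __post_init__(self) -> None:
        a, b = _clean(self.a), _clean(self.b)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        amap = _codon_map(self.table_id)
        for seq, name in ((a, "A"), (b, "B")):
            for i in range(0, len(seq), 3):
                if amap.get(seq[i : i + 3]) == "*":
                    raise ValueError(f"internal stop codon in sequence {name} at {i}")

    def codon_pairs(self):
        for i in range(0, len(self.a), 3):
            yield self.a[i : i + 3], self.b[i : i + 3]


@dataclass(frozen=True)
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when Ks = 0 (undefined)."""
        if self.ks == 0:
            return nan
        return self.ka / self.ks

    @property
    def defined(self) -> bool:
        return not isnan(self.ratio)


def count_sites(seq: str, table_id: int = 1) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one coding sequence.

    Each codon position contributes the fraction of its three possible
    point mutations that preserve the amino acid; mutations creating a stop
    codon count as nonsynonymous. Codons containing ambiguous bases are
    skipped.
    """
    seq = _clean(seq)
    amap = _codon_map(table_id)
    s = 0.0
    n_codons_counted = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = amap.get(codon)
        if aa is None or aa == "*":
            continue
        n_codons_counted += 1
        for pos in range(3):
            syn = 0
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if amap[mut] == aa:  # stop mutants map to '*', never equal
                    syn += 1
            s += syn / 3.0
    return s, 3.0 * n_codons_counted - s


def _pathway_counts(ca: str, cb: str, amap: dict[str, str]):
    """(Sd, Nd) for one codon pair, averaged over minimal pathways.

    Pathways passing through a stop-codon intermediate are excluded; if
    every pathway is blocked, all pathways are used with stop steps counted
    nonsynonymous.
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if amap[nxt] == "*" and nxt != cb:
                blocked = True
            cur = nxt
        paths.append((blocked, steps))
    usable = [p for blocked, p in paths if not blocked] or [p for _, p in paths]
    sd = nd = 0.0
    for steps in usable:
        for c1, c2 in steps:
            if amap[c1] != "*" and amap[c1] == amap[c2]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def count_differences(pair: CodonPairAlignment) -> tuple[float, float]:
    """Pathway-averaged synonymous and nonsynonymous difference counts."""
    amap = _codon_map(pair.table_id)
    sd = nd = 0.0
    for ca, cb in pair.codon_pairs():
        if any(b not in _BASES for b in ca + cb):
            continue
        dsd, dnd = _pathway_counts(ca, cb, amap)
        sd += dsd
        nd += dnd
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.3f} beyond Jukes-Cantor limit 3/4"
        )
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def kaks(
    a: str | CodonPairAlignment, b: str | None = None, table_id: int = 1
) -> KaKsResult:
    """Full NG86 computation for one pre-aligned pair.

    Site counts are averaged over the two sequences; pS = Sd/S and
    pN = Nd/N are Jukes–Cantor corrected to Ks and Ka. The Ka/Ks ratio is
    flagged undefined (NaN) when Ks = 0.
    """
    pair = a if isinstance(a, CodonPairAlignment) else CodonPairAlignment(a, b, table_id)
    sa, na = count_sites(pair.a, pair.table_id)
    sb, nb = count_sites(pair.b, pair.table_id)
    s_sites, n_sites = (sa + sb) / 2.0, (na + nb) / 2.0
    sd, nd = count_differences(pair)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=_jukes_cantor(ps),
        ka=_jukes_cantor(pn),
    )


def kaks_table(pairs: dict[str, tuple[str, str]], table_id: int = 1):
    """Ka/Ks results for named pairs as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for pair_id, (a, b) in pairs.items():
        r = kaks(a, b, table_id=table_id)
        rows.append(
            {
                "pair_id": pair_id,
                "S": r.s_sites,
                "N": r.n_sites,
                "Sd": r.sd,
                "Nd": r.nd,
                "Ka": r.ka,
                "Ks": r.ks,
                "ratio": r.ratio,
            }
        )
    return pd.DataFrame(rows)
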