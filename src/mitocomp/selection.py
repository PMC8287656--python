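"""Codon-aware alignment and NG86 Ka/Ks with positive-selection flagging.

The estimator is Nei-Gojobori (1986) counting with Jukes-Cantor
correction: per-codon synonymous/nonsynonymous site fractions, pathway-
averaged difference counts, site counts averaged across the two
sequences.  Changes to stop codons are excluded from site denominators
and stop-crossing pathways are excluded from pathway averages (with a
logged fallback when every pathway crosses a stop).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

from ._align import codon_gapped_pair
from .mito_io import CodingSequence

log = logging.getLogger(__name__)

_BASES = "ACGT"


@lru_cache(maxsize=None)
def _code(table: int) -> tuple[dict[str, str], frozenset[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    fwd = dict(tbl.forward_table)
    stops = frozenset(tbl.stop_codons)
    return fwd, stops


def translate_codon(codon: str, table: int = 4) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    fwd, stops = _code(table)
    if codon in stops:
        return None
    return fwd[codon]


def sense_codons(table: int = 4) -> list[str]:
    fwd, _ = _code(table)
    return sorted(fwd)


@dataclass
class CodonAlignment:
    gene: str
    taxon_a: str
    taxon_b: str
    codon_columns: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.codon_columns)


@dataclass
class SubstitutionCounts:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ka: float | None
    ks: float | None
    ka_raw: float
    ks_raw: float
    ratio: float | None

    @property
    def positive_selection(self) -> bool:
        return self.ratio is not None and self.ratio > 1.0


def codon_align(
    a: CodingSequence, b: CodingSequence, table: int = 4
) -> CodonAlignment:
    """Protein-guided codon alignment, filtered to clean paired columns.

    Columns containing gaps, ambiguity characters, or stop codons are
    removed; terminal stops are dropped before alignment.
    """
    aa_a, aa_b = a.aa, b.aa
    if not aa_a or not aa_b:
        raise ValueError("empty protein after trimming; cannot codon-align")
    ga, gb = codon_gapped_pair(a.nt, b.nt, aa_a, aa_b)
    _, stops = _code(table)
    columns: list[tuple[str, str]] = []
    for k in range(0, len(ga), 3):
        ca, cb = ga[k : k + 3], gb[k : k + 3]
        if "-" in ca or "-" in cb:
            continue
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in stops or cb in stops:
            continue
        columns.append((ca, cb))
    return CodonAlignment(a.gene, a.genome_id, b.genome_id, columns)


@lru_cache(maxsize=None)
def ng86_sites(codon: str, table: int = 4) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (summing to 3) of a codon.

    At each position the synonymous fraction is taken over the single-
    nucleotide changes that do not create a stop codon.
    """
    fwd, stops = _code(table)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    aa = fwd[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in stops:
                continue
            valid += 1
            if fwd[mut] == aa:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


def ng86_differences(
    codon_a: str, codon_b: str, table: int = 4
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    Multi-hit codon pairs are averaged over all orderings of the differing
    positions; pathways passing through a stop codon are excluded (when
    every pathway does, all are used and the event is logged).
    """
    fwd, stops = _code(table)
    for c in (codon_a, codon_b):
        if c in stops or any(ch not in _BASES for ch in c):
            raise ValueError(f"non-sense codon {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in stops:
                return None
            sd += fwd[cur] == fwd[nxt]
            nd += fwd[cur] != fwd[nxt]
            cur = nxt
        return float(sd), float(nd)

    results = []
    blocked = []
    for order in permutations(diff_pos):
        r = walk(order)
        if r is not None:
            results.append(r)
        else:
            blocked.append(order)
    if not results:
        log.warning(
            "all mutational pathways %s -> %s cross a stop codon; "
            "including them in the average",
            codon_a,
            codon_b,
        )
        for order in blocked:
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                a1 = fwd.get(cur)
                a2 = fwd.get(nxt)
                sd += a1 is not None and a1 == a2
                nd += not (a1 is not None and a1 == a2)
                cur = nxt
            results.append((float(sd), float(nd)))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def kaks(aln: CodonAlignment, table: int = 4) -> SubstitutionCounts:
    """NG86 Ka/Ks on a filtered codon alignment.

    Site counts are averaged over the two sequences; proportions are
    Jukes-Cantor corrected.  The ratio is missing when Ks is zero or
    either correction is undefined.
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codon_columns:
        sa, na = ng86_sites(ca, table)
        sb, nb = ng86_sites(cb, table)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = ng86_differences(ca, cb, table)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0.0:
        ratio = ka / ks
    return SubstitutionCounts(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ka=ka,
        ks=ks,
        ka_raw=pn,
        ks_raw=ps,
        ratio=ratio,
    )


def kaks_table(genomes, genes, table: int = 4):
    """Pairwise Ka/Ks across a cohort as a long-format DataFrame."""
    import pandas as pd

    from .mito_io import extract_cds

    rows = []
    for gene in genes:
        holders = [g for g in genomes if g.has(gene)]
        cds = {g.id: extract_cds(g, gene, table=table) for g in holders}
        ids = sorted(cds)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                aln = codon_align(cds[ids[i]], cds[ids[j]], table=table)
                counts = kaks(aln, table=table)
                rows.append(
                    {
                        "gene": gene,
                        "taxon_a": ids[i],
                        "taxon_b": ids[j],
                        "S_sites": counts.s_sites,
                        "N_sites": counts.n_sites,
                        "Sd": counts.sd,
                        "Nd": counts.nd,
                        "Ka": counts.ka,
                        "Ks": counts.ks,
                        "ka_raw": counts.ka_raw,
                        "ks_raw": counts.ks_raw,
                        "ratio": counts.ratio,
                        "positive_selection": counts.positive_selection,
                    }
                )
    return pd.DataFrame(rows)
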