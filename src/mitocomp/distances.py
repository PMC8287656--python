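"""Pairwise K2P distances per gene and a neighbor-joining tree utility."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._align import codon_gapped_pair
from .mito_io import MitoGenome, extract_cds

log = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_CANONICAL = {"A", "C", "G", "T"}


def pairwise_k2p(a: str, b: str) -> float | None:
    """Kimura 2-parameter distance between two aligned DNA strings.

    Columns where either symbol is a gap or not a canonical base are
    removed first (pairwise deletion).  With P the transition and Q the
    transversion fraction over retained columns,

        d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

    Returns ``None`` when the correction is undefined (saturation) or no
    columns remain.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a = a.upper()
    b = b.upper()
    n = 0
    transitions = 0
    transversions = 0
    for x, y in zip(a, b):
        if x not in _CANONICAL or y not in _CANONICAL:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        log.warning("K2P: no retained columns after pairwise deletion")
        return None
    p = transitions / n
    q = transversions / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return None
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def p_distance(a: str, b: str) -> float | None:
    """Uncorrected proportion of differing retained columns (same filtering)."""
    if len(a) != len(b):
        raise ValueError("aligned lengths differ")
    n = d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _CANONICAL or y not in _CANONICAL:
            continue
        n += 1
        d += x != y
    return d / n if n else None


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # NaN marks missing entries
    gene: str = "concatenated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        np.fill_diagonal(self.values, 0.0)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.taxa), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def mean(self) -> float:
        """Arithmetic mean over defined off-diagonal pairs."""
        n = len(self.taxa)
        iu = np.triu_indices(n, k=1)
        vals = self.values[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def gene_k2p_matrix(
    genomes: Sequence[MitoGenome], gene: str, table: int = 4
) -> DistanceMatrix:
    """K2P distance matrix for one gene across a genome cohort.

    Each pair is aligned with a global protein-guided codon alignment
    before the nucleotide-level K2P computation.  Entries are NaN when the
    gene is absent in either taxon or the pair is saturated.
    """
    taxa = [g.id for g in genomes]
    holders = [g for g in genomes if g.has(gene)]
    if len(holders) < 2:
        raise KeyError(f"gene {gene!r} present in fewer than two genomes")
    cds = {g.id: extract_cds(g, gene, table=table) for g in holders}
    n = len(taxa)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            ca = cds.get(taxa[i])
            cb = cds.get(taxa[j])
            if ca is None or cb is None or not ca.aa or not cb.aa:
                continue
            ga, gb = codon_gapped_pair(ca.nt, cb.nt, ca.aa, cb.aa)
            d = pairwise_k2p(ga, gb)
            if d is not None:
                mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(taxa), mat, gene=gene)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(matrix: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch; ties in the Q criterion break on the lowest taxon
    index pair, so output is deterministic.
    """
    if len(matrix.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.has_missing:
        raise ValueError(
            "distance matrix has missing entries; impute them or drop taxa first"
        )
    d = matrix.values.copy()
    nodes = [_Node(label=t) for t in matrix.taxa]
    active = list(range(len(nodes)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-15:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new internal node to the remainder
        newrow = np.full(d.shape[0] + 1, 0.0)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            newrow[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = newrow[:-1]
        d[:-1, -1] = newrow[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    parts = ",".join(
        f"{nodes[t].newick()}:{bl:.6g}" for t, bl in zip((i, j, k), lengths)
    )
    return f"({parts});"


def long_format(matrices: Sequence[DistanceMatrix]):
    """Long-format TSV-ready table (gene, taxon_a, taxon_b, k2p)."""
    import pandas as pd

    rows = []
    for m in matrices:
        for i in range(len(m.taxa)):
            for j in range(i + 1, len(m.taxa)):
                v = m.values[i, j]
                rows.append(
                    {
                        "gene": m.gene,
                        "taxon_a": m.taxa[i],
                        "taxon_b": m.taxa[j],
                        "k2p": None if np.isnan(v) else v,
                    }
                )
    return pd.DataFrame(rows)
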