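"""Circular gene-order extraction, canonicalization and rearrangement stats.

Orders are sequences of (symbol, strand) over a gene panel (default: the
15 core protein-coding genes plus the two rRNAs).  Comparisons are
orientation-aware: adjacencies carry strand information, so inversions
are visible as breakpoints.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from . import DEFAULT_PANEL
from .mito_io import MitoGenome

log = logging.getLogger(__name__)

ANCHOR = "cox1"


class AnnotationError(ValueError):
    pass


class NoMajorityError(ValueError):
    pass


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass
class GeneOrder:
    genome_id: str
    order: list[tuple[str, str]]  # circular, in genomic occurrence order
    panel: tuple[str, ...] = DEFAULT_PANEL
    missing: frozenset[str] = field(default_factory=frozenset)

    def symbols(self) -> list[str]:
        return [g for g, _ in self.order]

    def restricted(self, genes: set[str]) -> "GeneOrder":
        return GeneOrder(
            genome_id=self.genome_id,
            order=[(g, s) for g, s in self.order if g in genes],
            panel=self.panel,
            missing=frozenset(set(self.panel) - genes),
        )


def extract_order(
    genome: MitoGenome, panel: Sequence[str] = DEFAULT_PANEL
) -> GeneOrder:
    """Panel genes in order of genomic occurrence; duplicates are an error."""
    hits = [(f.start, f.name, f.strand) for f in genome.features if f.name in panel]
    names = [n for _, n, _ in hits]
    dupes = [n for n, c in Counter(names).items() if c > 1]
    if dupes:
        raise AnnotationError(
            f"{genome.id}: duplicated panel gene(s) {sorted(dupes)}"
        )
    hits.sort()
    return GeneOrder(
        genome_id=genome.id,
        order=[(n, s) for _, n, s in hits],
        panel=tuple(panel),
        missing=frozenset(set(panel) - set(names)),
    )


def canonicalize_circular(order: GeneOrder) -> GeneOrder:
    """Rotate/reflect into canonical form.

    The anchor gene (cox1, else the lexicographically smallest symbol)
    comes first on the '+' strand; when it is on '-', the whole circle is
    reflected and strands flipped.  Idempotent by construction.
    """
    seq = list(order.order)
    if not seq:
        raise ValueError("empty gene order")
    symbols = [g for g, _ in seq]
    anchor = ANCHOR if ANCHOR in symbols else min(symbols)
    i = symbols.index(anchor)
    if seq[i][1] == "-":
        seq = [(g, _flip(s)) for g, s in reversed(seq)]
        symbols = [g for g, _ in seq]
        i = symbols.index(anchor)
    seq = seq[i:] + seq[:i]
    return GeneOrder(order.genome_id, seq, order.panel, order.missing)


def _adjacencies(order: GeneOrder) -> set[tuple]:
    """Orientation-aware circular adjacency set (reflection-invariant keys)."""
    seq = order.order
    n = len(seq)
    adj = set()
    for k in range(n):
        (a, sa), (b, sb) = seq[k], seq[(k + 1) % n]
        fwd = (a, sa, b, sb)
        rev = (b, _flip(sb), a, _flip(sa))
        adj.add(min(fwd, rev))
    return adj


def _common_restriction(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    shared = set(a.symbols()) & set(b.symbols())
    if not shared:
        raise ValueError(
            f"gene orders of {a.genome_id} and {b.genome_id} share no genes"
        )
    if shared != set(a.symbols()) or shared != set(b.symbols()):
        log.info(
            "comparing %s and %s on their %d shared genes",
            a.genome_id,
            b.genome_id,
            len(shared),
        )
    return a.restricted(shared), b.restricted(shared)


def orders_identical(a: GeneOrder, b: GeneOrder) -> bool:
    """True iff canonical forms match on the shared gene set."""
    ra, rb = _common_restriction(a, b)
    return canonicalize_circular(ra).order == canonicalize_circular(rb).order


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of oriented circular adjacencies of ``a`` absent from ``b``."""
    ra, rb = _common_restriction(a, b)
    return len(_adjacencies(canonicalize_circular(ra)) - _adjacencies(canonicalize_circular(rb)))


def _incident(adj: set[tuple], gene: str) -> frozenset:
    return frozenset(t for t in adj if t[0] == gene or t[2] == gene)


def rearranged_genes(order: GeneOrder, ancestor: GeneOrder) -> list[str]:
    """Genes whose oriented neighbor pairs differ from the ancestor's."""
    ro, ra = _common_restriction(order, ancestor)
    adj_o = _adjacencies(canonicalize_circular(ro))
    adj_a = _adjacencies(canonicalize_circular(ra))
    return sorted(
        g for g in ro.symbols() if _incident(adj_o, g) != _incident(adj_a, g)
    )


def classify_rearranged(
    orders: Sequence[GeneOrder], ancestor: GeneOrder
) -> dict[str, list[str]]:
    """Per-genome list of rearranged genes relative to an ancestral order."""
    return {o.genome_id: rearranged_genes(o, ancestor) for o in orders}


def majority_ancestor(orders: Sequence[GeneOrder]) -> GeneOrder:
    """The plurality canonical arrangement of a cohort.

    Raises :class:`NoMajorityError` when every arrangement is unique or
    the plurality is tied.
    """
    if len(orders) < 3:
        raise ValueError("need at least 3 gene orders")
    canon = [canonicalize_circular(o) for o in orders]
    keys = [tuple(c.order) for c in canon]
    counts = Counter(keys)
    ranked = counts.most_common()
    top_key, top_n = ranked[0]
    if top_n < 2:
        raise NoMajorityError("all gene arrangements are unique; no plurality")
    tied = [k for k, c in ranked if c == top_n]
    if len(tied) > 1:
        raise NoMajorityError(
            f"{len(tied)} arrangements tied at count {top_n}: "
            + "; ".join(" ".join(f"{g}{s}" for g, s in k) for k in tied)
        )
    rep = next(c for c, k in zip(canon, keys) if k == top_key)
    return GeneOrder("ancestor", list(rep.order), rep.panel, rep.missing)


def order_table(orders: Sequence[GeneOrder]):
    import pandas as pd

    rows = []
    for o in sorted(orders, key=lambda o: o.genome_id):
        for pos, (g, s) in enumerate(o.order, start=1):
            rows.append(
                {"genome_id": o.genome_id, "position": pos, "gene": g, "strand": s}
            )
    return pd.DataFrame(rows)
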