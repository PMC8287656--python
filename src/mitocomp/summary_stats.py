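"""Cohort comparative table and size-vs-intron-number correlation."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import base_composition
from .mito_io import (
    KIND_INTRONIC_ORF,
    KIND_PCG,
    KIND_PLASMID,
    KIND_RRNA,
    KIND_TRNA,
    KIND_UNKNOWN_ORF,
    MitoGenome,
    summarize_annotation,
)

log = logging.getLogger(__name__)

# per-base precedence when intervals overlap: intron > coding > RNA > intergenic
_INTERGENIC, _RNA, _CODING, _INTRON = 0, 1, 2, 3


def _region_labels(genome: MitoGenome) -> np.ndarray:
    lab = np.full(genome.length, _INTERGENIC, dtype=np.int8)
    for f in genome.features:
        if f.kind in (KIND_TRNA, KIND_RRNA):
            for s, e in f.exons:
                lab[s - 1 : e] = np.maximum(lab[s - 1 : e], _RNA)
    for f in genome.features:
        if f.kind in (KIND_PCG, KIND_PLASMID, KIND_UNKNOWN_ORF):
            for s, e in f.exons:
                lab[s - 1 : e] = np.maximum(lab[s - 1 : e], _CODING)
    for intr in genome.introns:
        s, e = intr.genome_interval
        lab[s - 1 : e] = _INTRON
    return lab


def comparative_table(genomes: Sequence[MitoGenome]) -> pd.DataFrame:
    """Per-genome composition/annotation/region-fraction table.

    Region classes partition the genome: coding (PCG exons), RNA
    (tRNA+rRNA), intron (intron intervals, which also claim intron-encoded
    ORF bases), intergenic (remainder).  ``pct_coding_incl_intronic_orf``
    reports the alternative accounting where intronic ORF bases count as
    coding.
    """
    if not genomes:
        raise ValueError("no genomes")
    rows = []
    for g in sorted(genomes, key=lambda g: g.id):
        comp = base_composition(g.sequence)
        summ = summarize_annotation(g)
        lab = _region_labels(g)
        n = g.length
        counts = np.bincount(lab, minlength=4)
        orf_in_intron = 0
        for f in g.features:
            if f.kind == KIND_INTRONIC_ORF:
                orf_in_intron += f.spliced_length
        rows.append(
            {
                "genome_id": g.id,
                "length": n,
                "GC_pct": round(100 * comp.gc_content, 2),
                "AT_skew": comp.at_skew,
                "GC_skew": comp.gc_skew,
                "n_pcg": summ.n_pcg,
                "n_trna": summ.n_trna,
                "n_rrna": summ.n_rrna,
                "n_intron": summ.n_intron,
                "pct_intron": 100 * counts[_INTRON] / n,
                "pct_coding": 100 * counts[_CODING] / n,
                "pct_rna": 100 * counts[_RNA] / n,
                "pct_intergenic": 100 * counts[_INTERGENIC] / n,
                "pct_coding_incl_intronic_orf": 100
                * (counts[_CODING] + orf_in_intron)
                / n,
            }
        )
    return pd.DataFrame(rows)


def correlate_size_intron(
    sizes: Sequence[float], intron_counts: Sequence[float]
) -> tuple[float, float, float, float]:
    """(Pearson r, p) and (Spearman rho, p) for size vs intron count.

    Pearson p is the two-sided t-test; Spearman uses average ranks for
    ties with the t approximation.  Returns NaNs (with a warning) when
    either vector has zero variance.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(intron_counts, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance in one vector; correlation undefined")
        return (float("nan"),) * 4
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue)


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 199,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    Computed as (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = abs(float(xc @ yc) / denom)
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    r_perm = np.abs(perms @ xc) / denom
    return (1.0 + int((r_perm >= r_obs - 1e-15).sum())) / (n_perm + 1.0)
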