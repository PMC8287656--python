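"""Intron position-class (Pcl) mapping and common/rare classification.

Each intron insertion site is projected through a protein-guided
alignment onto a reference coding sequence; the class name is "P" plus
the 1-based reference nucleotide immediately 5' of the insertion point.
A class present in more than 1/5 of the species panel is *common*,
otherwise *rare*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import codon_gapped_pair
from .mito_io import CodingSequence, MitoGenome, extract_cds

log = logging.getLogger(__name__)

DEFAULT_IDENTITY_FLOOR = 0.30
COMMON_FRACTION = 0.2


@dataclass
class PclAssignment:
    genome_id: str
    host_gene: str
    intron_index: int
    ref_position: int
    pcl_name: str
    alignment_support: float
    low_confidence: bool = False


@dataclass
class PclMatrix:
    species: list[str]
    pcls: list[str]
    presence: pd.DataFrame  # species x pcls, 0/1
    labels: dict[str, str] = field(default_factory=dict)  # pcl -> common/rare

    @property
    def prevalence(self) -> pd.Series:
        return self.presence.sum(axis=0)

    @property
    def n_species(self) -> int:
        return len(self.species)


def _map_offset(gapped_q: str, gapped_r: str, offset: int) -> int:
    """Reference coordinate of the last reference nt 5' of a query offset.

    ``offset`` counts query nucleotides 5' of the junction.  When the
    junction column sits in a reference gap, the nearest 5' non-gap
    reference position is returned.
    """
    q_seen = 0
    r_seen = 0
    for qc, rc in zip(gapped_q, gapped_r):
        if rc != "-":
            r_seen += 1
        if qc != "-":
            q_seen += 1
            if q_seen == offset:
                break
    return max(r_seen, 1)


def _window_support(gapped_q: str, gapped_r: str, offset: int, half: int = 15) -> float:
    """Identity fraction in a +/-`half` nt window around a query offset."""
    q_seen = 0
    col = len(gapped_q)
    for k, qc in enumerate(gapped_q):
        if qc != "-":
            q_seen += 1
            if q_seen == offset:
                col = k
                break
    lo = max(0, col - half)
    hi = min(len(gapped_q), col + half + 1)
    window = range(lo, hi)
    if not len(window):
        return 0.0
    matches = sum(gapped_q[k] == gapped_r[k] != "-" for k in window)
    return matches / len(window)


def map_intron_positions(
    genome: MitoGenome,
    host_gene: str,
    reference_cds: CodingSequence,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    table: int = 4,
) -> list[PclAssignment]:
    """Project the host gene's intron junctions onto the reference CDS.

    The spliced host CDS is globally aligned to the reference (protein-
    guided); each exon-junction CDS offset maps through the alignment to a
    reference coordinate, yielding one assignment per intron.
    """
    cds = extract_cds(genome, host_gene, table=table)
    if not cds.exon_boundaries:
        return []
    gq, gr = codon_gapped_pair(cds.nt, reference_cds.nt, cds.aa, reference_cds.aa)
    cols = [(a, b) for a, b in zip(gq, gr) if a != "-" and b != "-"]
    identity = (
        sum(a == b for a, b in cols) / len(cols) if cols else 0.0
    )
    low = identity < identity_floor
    if low:
        log.warning(
            "%s/%s: alignment identity %.1f%% below %.0f%% floor; "
            "Pcl assignments are low-confidence",
            genome.id,
            host_gene,
            100 * identity,
            100 * identity_floor,
        )
    ref_len = len(reference_cds.nt)
    out = []
    for idx, offset in enumerate(cds.exon_boundaries, start=1):
        pos = _map_offset(gq, gr, offset)
        pos = min(pos, ref_len - 1)
        out.append(
            PclAssignment(
                genome_id=genome.id,
                host_gene=host_gene,
                intron_index=idx,
                ref_position=pos,
                pcl_name=f"P{pos}",
                alignment_support=_window_support(gq, gr, offset),
                low_confidence=low,
            )
        )
    return out


def assign_pcls(
    assignments: Iterable[PclAssignment], merge_window: int = 0
) -> PclMatrix:
    """Pool assignments into a species x Pcl presence/absence matrix.

    Pcls are keyed by exact reference position by default; a positive
    ``merge_window`` merges positions within that distance into the
    lowest-position class.
    """
    assignments = list(assignments)
    species = sorted({a.genome_id for a in assignments})
    positions = sorted({a.ref_position for a in assignments})
    canon: dict[int, int] = {}
    if merge_window > 0:
        for p in positions:
            for q in sorted(canon.values()):
                if abs(p - q) <= merge_window:
                    canon[p] = q
                    break
            else:
                canon[p] = p
    else:
        canon = {p: p for p in positions}
    pcl_positions = sorted(set(canon.values()))
    pcls = [f"P{p}" for p in pcl_positions]
    presence = pd.DataFrame(
        np.zeros((len(species), len(pcls)), dtype=int), index=species, columns=pcls
    )
    for a in assignments:
        presence.loc[a.genome_id, f"P{canon[a.ref_position]}"] = 1
    return PclMatrix(species=species, pcls=pcls, presence=presence)


def classify_common_rare(
    matrix: PclMatrix, common_fraction: float = COMMON_FRACTION
) -> PclMatrix:
    """Label each Pcl common iff prevalence/n_species > common_fraction (strict)."""
    if matrix.n_species < 1:
        raise ValueError("empty matrix")
    threshold = common_fraction * matrix.n_species
    labels = {
        pcl: ("common" if count > threshold else "rare")
        for pcl, count in matrix.prevalence.items()
    }
    return PclMatrix(
        species=list(matrix.species),
        pcls=list(matrix.pcls),
        presence=matrix.presence.copy(),
        labels=labels,
    )


def flag_disjunct_pcls(
    matrix: PclMatrix, groups: Mapping[str, str], focal_clade: str
) -> list[dict]:
    """Pcls present in exactly one focal-clade member and >=1 other clade.

    Such disjunct distributions are candidate horizontal-transfer events.
    Returns one record per flagged Pcl with the witness species and the
    non-focal clades carrying it.
    """
    unknown = set(matrix.species) - set(groups)
    if unknown:
        raise ValueError(f"species without a clade label: {sorted(unknown)}")
    flagged = []
    for pcl in matrix.pcls:
        col = matrix.presence[pcl]
        carriers = [sp for sp in matrix.species if col[sp]]
        focal = [sp for sp in carriers if groups[sp] == focal_clade]
        outside = sorted({groups[sp] for sp in carriers if groups[sp] != focal_clade})
        if len(focal) == 1 and outside:
            flagged.append(
                {
                    "pcl": pcl,
                    "witness": focal[0],
                    "other_clades": outside,
                }
            )
    return flagged


def assignments_table(assignments: Sequence[PclAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": a.genome_id,
                "gene": a.host_gene,
                "intron_idx": a.intron_index,
                "ref_pos": a.ref_position,
                "pcl": a.pcl_name,
                "support": a.alignment_support,
                "low_confidence": a.low_confidence,
            }
            for a in assignments
        ]
    )
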