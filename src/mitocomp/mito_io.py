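"""Read/write GenBank and FASTA, build the in-memory genome model, splice CDS.

Coordinates are 1-based inclusive externally (GenBank convention) and
0-based half-open only inside private helpers.  The genetic code used for
translation defaults to the mold/protozoan mitochondrial code (table 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import CORE_PCGS

log = logging.getLogger(__name__)

DEFAULT_TABLE = 4

KIND_PCG = "PCG"
KIND_RRNA = "rRNA"
KIND_TRNA = "tRNA"
KIND_INTRONIC_ORF = "intronic_ORF"
KIND_PLASMID = "plasmid_derived"
KIND_UNKNOWN_ORF = "unknown_ORF"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed input files."""


class CoordinateError(ValueError):
    """Raised when a feature interval falls outside the sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene with its exon structure.

    ``exons`` are 1-based inclusive genomic intervals, sorted by start;
    for '-' strand genes the coding order is the reverse of this list.
    """

    name: str
    kind: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    product: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class IntronFeature:
    host_gene: str
    index: int  # 1-based ordinal within host, 5'->3' on the coding strand
    genome_interval: tuple[int, int]
    group: str = "unknown"  # 'I', 'II' or 'unknown'
    encoded_orfs: list[str] = field(default_factory=list)


@dataclass
class CodingSequence:
    genome_id: str
    gene: str
    nt: str
    aa: str
    exon_boundaries: list[int] = field(default_factory=list)


@dataclass
class MitoGenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    introns: list[IntronFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{self.id}: unsupported sequence characters {sorted(bad)!r} "
                "(only A/C/G/T/N allowed)"
            )
        for f in self.features:
            for s, e in f.exons:
                if not (1 <= s <= e <= len(self.sequence)):
                    raise CoordinateError(
                        f"{self.id}: feature {f.name} interval ({s},{e}) outside "
                        f"[1,{len(self.sequence)}]"
                    )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get(self, gene: str) -> GeneFeature:
        for f in self.features:
            if f.name == gene:
                return f
        raise KeyError(f"gene {gene!r} not found in {self.id}")

    def has(self, gene: str) -> bool:
        return any(f.name == gene for f in self.features)

    def introns_of(self, gene: str) -> list[IntronFeature]:
        return sorted(
            (i for i in self.introns if i.host_gene == gene), key=lambda i: i.index
        )


@dataclass
class AnnotationSummary:
    genome_id: str
    n_pcg: int  # protein-coding genes excluding intron-encoded ORFs
    n_pcg_incl_intronic: int
    n_core_pcg: int
    n_trna: int
    n_rrna: int
    n_intron: int
    n_intronic_orf: int
    len_rns: int | None
    len_rnl: int | None
    gene_lengths: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# classification helpers

_PLASMID_NAMES = {"dpo", "rpo", "dpoB", "rpoB"}


def _classify_cds(name: str, product: str) -> str:
    lname = name.lower()
    if name in CORE_PCGS or lname in {g.lower() for g in CORE_PCGS}:
        return KIND_PCG
    if lname in {n.lower() for n in _PLASMID_NAMES} or "polymerase" in product.lower():
        return KIND_PLASMID
    if lname.startswith("orf"):
        return KIND_UNKNOWN_ORF  # may be reassigned to intronic_ORF later
    return KIND_PCG


def _within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


# ---------------------------------------------------------------------------
# GenBank reading


def _location_to_exons(loc) -> tuple[str, list[tuple[int, int]]]:
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    exons = sorted((int(p.start) + 1, int(p.end)) for p in parts)
    return strand, exons


def read_genbank(path: str) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Gene/CDS/tRNA/rRNA/intron features are ingested; ``join()`` and
    ``complement()`` locations become oriented exon lists.  Introns absent
    from the record are inferred from the gaps between consecutive CDS
    exons of the same gene.  Circular topology is read from the LOCUS line.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper().replace("U", "T")
    circular = record.annotations.get("topology", "linear") == "circular"

    features: list[GeneFeature] = []
    introns: list[IntronFeature] = []
    seen_cds: set[str] = set()
    for feat in record.features:
        if feat.type not in {"CDS", "tRNA", "rRNA", "intron"}:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("label", [None])[0]
            or feat.type
        )
        product = feat.qualifiers.get("product", [""])[0]
        strand, exons = _location_to_exons(feat.location)
        for s, e in exons:
            if not (1 <= s <= e <= len(seq)):
                raise CoordinateError(
                    f"{path}: feature {name} interval ({s},{e}) outside sequence "
                    f"bounds [1,{len(seq)}]"
                )
        if feat.type == "intron":
            host = feat.qualifiers.get("gene", [name])[0]
            introns.append(
                IntronFeature(
                    host_gene=host,
                    index=int(feat.qualifiers.get("number", [0])[0]) or 0,
                    genome_interval=(exons[0][0], exons[-1][1]),
                    group=feat.qualifiers.get("note", ["unknown"])[0]
                    if feat.qualifiers.get("note", [""])[0] in ("I", "II")
                    else "unknown",
                )
            )
            continue
        if feat.type == "CDS":
            if name in seen_cds:
                continue
            seen_cds.add(name)
            kind = _classify_cds(name, product)
        elif feat.type == "tRNA":
            kind = KIND_TRNA
        else:
            kind = KIND_RRNA
        features.append(GeneFeature(name, kind, strand, exons, product))

    genome = MitoGenome(
        id=record.id or record.name,
        sequence=seq,
        circular=circular,
        features=features,
        introns=introns,
        source=str(path),
    )
    _infer_missing_introns(genome)
    _assign_intronic_orfs(genome)
    return genome


def _infer_missing_introns(genome: MitoGenome) -> None:
    """Fill in intron records from multi-exon CDS gaps when absent."""
    recorded = {(i.host_gene, i.genome_interval) for i in genome.introns}
    by_host: dict[str, list[IntronFeature]] = {}
    for i in genome.introns:
        by_host.setdefault(i.host_gene, []).append(i)
    for f in genome.features:
        if f.kind not in (KIND_PCG, KIND_PLASMID, KIND_UNKNOWN_ORF):
            continue
        if len(f.exons) < 2:
            continue
        gaps = [
            (f.exons[k][1] + 1, f.exons[k + 1][0] - 1)
            for k in range(len(f.exons) - 1)
        ]
        # ordinal runs 5'->3' on the coding strand
        ordered = gaps if f.strand == "+" else list(reversed(gaps))
        for idx, iv in enumerate(ordered, start=1):
            if (f.name, iv) in recorded:
                continue
            existing = [i for i in by_host.get(f.name, []) if i.genome_interval == iv]
            if existing:
                continue
            genome.introns.append(IntronFeature(f.name, idx, iv))
    # renumber per host by coding order
    for host in {i.host_gene for i in genome.introns}:
        host_introns = [i for i in genome.introns if i.host_gene == host]
        try:
            strand = genome.get(host).strand
        except KeyError:
            strand = "+"
        host_introns.sort(key=lambda i: i.genome_interval[0], reverse=strand == "-")
        for idx, i in enumerate(host_introns, start=1):
            i.index = idx


def _assign_intronic_orfs(genome: MitoGenome) -> None:
    """Reclassify ORFs lying inside an intron interval as intron-encoded."""
    for f in genome.features:
        if f.kind not in (KIND_UNKNOWN_ORF, KIND_PCG):
            continue
        span = (f.start, f.end)
        for intr in genome.introns:
            if f.name == intr.host_gene:
                continue
            if _within(span, intr.genome_interval):
                f.kind = KIND_INTRONIC_ORF
                if f.name not in intr.encoded_orfs:
                    intr.encoded_orfs.append(f.name)
                break


# ---------------------------------------------------------------------------
# GenBank writing


def write_genbank(genome: MitoGenome, path: str) -> None:
    """Serialize a MitoGenome to a GenBank flat file (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="synthetic mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s - 1, e, strand) for s, e in f.exons]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = {
            KIND_TRNA: "tRNA",
            KIND_RRNA: "rRNA",
        }.get(f.kind, "CDS")
        quals = {"gene": [f.name]}
        if f.product:
            quals["product"] = [f.product]
        if ftype == "CDS":
            quals["transl_table"] = [str(DEFAULT_TABLE)]
        record.features.append(SeqFeature(location, type=ftype, qualifiers=quals))
    for intr in genome.introns:
        s, e = intr.genome_interval
        record.features.append(
            SeqFeature(
                SimpleLocation(s - 1, e, 1),
                type="intron",
                qualifiers={"gene": [intr.host_gene], "number": [str(intr.index)]},
            )
        )
    SeqIO.write([record], path, "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs; U mapped to T."""
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                if header is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.upper().replace("U", "T"))
        if header is not None:
            records.append((header, "".join(chunks)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rid, seq in records:
        if not seq:
            raise FormatError(f"{path}: record {rid!r} has an empty sequence")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(
    genome: MitoGenome, gene: str, table: int = DEFAULT_TABLE
) -> CodingSequence:
    """Splice a protein-coding gene and translate it.

    '-' strand features are reverse-complemented into coding orientation.
    An internal stop codon before the final codon is logged as a warning
    (annotation slippage is common in these records), not raised.
    """
    feat = genome.get(gene)
    if feat.kind not in (KIND_PCG, KIND_PLASMID, KIND_UNKNOWN_ORF, KIND_INTRONIC_ORF):
        raise ValueError(f"{gene} is not protein-coding (kind={feat.kind})")
    pieces = [genome.sequence[s - 1 : e] for s, e in feat.exons]
    if feat.strand == "-":
        pieces = [reverse_complement(p) for p in reversed(pieces)]
    nt = "".join(pieces)
    boundaries: list[int] = []
    acc = 0
    for p in pieces[:-1]:
        acc += len(p)
        boundaries.append(acc)
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        log.warning(
            "%s/%s: internal stop codon at aa position %d",
            genome.id,
            gene,
            aa.index("*") + 1,
        )
    return CodingSequence(genome.id, gene, nt, aa, boundaries)


# ---------------------------------------------------------------------------
# annotation summary


def summarize_annotation(genome: MitoGenome) -> AnnotationSummary:
    """Count features by kind; PCG count excludes intron-encoded ORFs."""
    kinds: dict[str, int] = {}
    for f in genome.features:
        kinds[f.kind] = kinds.get(f.kind, 0) + 1
    n_coding_non_intronic = (
        kinds.get(KIND_PCG, 0) + kinds.get(KIND_PLASMID, 0) + kinds.get(KIND_UNKNOWN_ORF, 0)
    )
    n_intronic = kinds.get(KIND_INTRONIC_ORF, 0)
    lengths = {f.name: f.spliced_length for f in genome.features}
    n_core = sum(1 for f in genome.features if f.name in CORE_PCGS)
    return AnnotationSummary(
        genome_id=genome.id,
        n_pcg=n_coding_non_intronic,
        n_pcg_incl_intronic=n_coding_non_intronic + n_intronic,
        n_core_pcg=n_core,
        n_trna=kinds.get(KIND_TRNA, 0),
        n_rrna=kinds.get(KIND_RRNA, 0),
        n_intron=len(genome.introns),
        n_intronic_orf=n_intronic,
        len_rns=lengths.get("rns"),
        len_rnl=lengths.get("rnl"),
        gene_lengths=lengths,
    )


def summary_table(genomes: Sequence[MitoGenome]):
    """Annotation summary for several genomes as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for g in sorted(genomes, key=lambda g: g.id):
        s = summarize_annotation(g)
        rows.append(
            {
                "genome_id": s.genome_id,
                "n_pcg": s.n_pcg,
                "n_trna": s.n_trna,
                "n_rrna": s.n_rrna,
                "n_intron": s.n_intron,
                "n_intronic_orf": s.n_intronic_orf,
                "len_rns": s.len_rns,
                "len_rnl": s.len_rnl,
            }
        )
    return pd.DataFrame(rows)
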