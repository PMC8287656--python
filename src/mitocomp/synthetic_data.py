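"""Synthetic annotated mitogenomes with a ground-truth manifest.

Every pipeline stage is exercised against genomes generated here:
composition targets, gene orders, planted introns, duplications, tandem
arrays and per-gene mutation rates are all recorded in the manifest, so
tests are parameter-recovery checks rather than golden files.

Randomness comes from numpy's PCG64 seeded through ``SeedSequence`` with
per-purpose substreams (sequence, repeats, mutation), so adding one
planted feature never shifts another feature's draws.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import DEFAULT_PANEL
from .mito_io import (
    KIND_INTRONIC_ORF,
    KIND_PCG,
    KIND_RRNA,
    KIND_TRNA,
    GeneFeature,
    IntronFeature,
    MitoGenome,
    reverse_complement,
)
from .selection import translate_codon

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG"}  # translation table 4


class SpecError(ValueError):
    """Raised when a genome spec cannot accommodate its planted features."""


@dataclass
class GeneSpec:
    name: str
    kind: str  # PCG / tRNA / rRNA
    strand: str = "+"
    length: int = 300  # coding length incl. stop for PCGs


@dataclass
class IntronSpec:
    host: str
    cds_pos: int  # intron inserted after this many CDS nucleotides
    length: int = 150
    orf_length: int = 0  # nt length of an embedded intronic ORF (0 = none)


@dataclass
class DuplicationSpec:
    length: int
    inverted: bool = False


@dataclass
class TandemSpec:
    period: int
    copies: int


@dataclass
class GenomeSpec:
    id: str
    length: int = 44000
    gc: float = 0.25
    at_skew: float = 0.0
    gc_skew: float = 0.0
    genes: list[GeneSpec] = field(default_factory=list)
    introns: list[IntronSpec] = field(default_factory=list)
    duplications: list[DuplicationSpec] = field(default_factory=list)
    tandems: list[TandemSpec] = field(default_factory=list)


_DEFAULT_PCG_LEN = {
    "atp6": 768, "atp8": 147, "atp9": 225, "cob": 1164, "cox1": 1608,
    "cox2": 750, "cox3": 810, "nad1": 1086, "nad2": 1500, "nad3": 417,
    "nad4": 1467, "nad4L": 270, "nad5": 1998, "nad6": 642, "rps3": 1278,
}


def default_gene_specs(n_trna: int = 6) -> list[GeneSpec]:
    """A plausible 17-gene panel layout plus placeholder tRNAs."""
    genes = [GeneSpec("cox1", KIND_PCG, "+", _DEFAULT_PCG_LEN["cox1"])]
    rest = [g for g in DEFAULT_PANEL if g not in ("cox1", "rns", "rnl")]
    for i, name in enumerate(rest):
        strand = "+" if i % 3 else "-"
        genes.append(GeneSpec(name, KIND_PCG, strand, _DEFAULT_PCG_LEN[name]))
    genes.insert(4, GeneSpec("rnl", KIND_RRNA, "+", 3768))
    genes.insert(9, GeneSpec("rns", KIND_RRNA, "+", 1973))
    for i in range(n_trna):
        genes.append(GeneSpec(f"trn{chr(ord('A') + i)}", KIND_TRNA, "+", 72))
    return genes


def _base_probs(gc: float, at_skew: float, gc_skew: float) -> np.ndarray:
    pa = (1 - gc) / 2 * (1 + at_skew)
    pt = (1 - gc) / 2 * (1 - at_skew)
    pg = gc / 2 * (1 + gc_skew)
    pc = gc / 2 * (1 - gc_skew)
    probs = np.array([pa, pc, pg, pt])  # ACGT order
    if (probs < 0).any():
        raise SpecError("composition targets imply negative base probabilities")
    return probs / probs.sum()


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)]) if n else ""


def _random_cds(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    """Random CDS under table 4: ATG start, TAA stop, no internal stops."""
    if length % 3:
        raise SpecError(f"PCG length {length} not a multiple of 3")
    n_codons = length // 3
    if n_codons < 3:
        raise SpecError("PCG shorter than 3 codons")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[rng.choice(4, size=3, p=probs)])
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _map_interval(sense_iv: tuple[int, int], start0: int, blen: int, strand: str):
    """Map a 0-based half-open sense-block interval to 1-based genomic."""
    u, v = sense_iv
    if strand == "+":
        return (start0 + u + 1, start0 + v)
    return (start0 + blen - v + 1, start0 + blen - u)


def generate_genome(
    spec: GenomeSpec,
    seed: int,
    gene_seqs: Mapping[str, str] | None = None,
) -> tuple[MitoGenome, dict]:
    """Build one annotated circular genome and its ground-truth manifest.

    ``gene_seqs`` overrides the random coding/RNA sequences per gene
    (sense strand, intron-free), which lets cohorts share an ancestor's
    genes while differing in order or planted features.
    """
    ss = np.random.SeedSequence(seed)
    rng_seq, rng_rep = [np.random.default_rng(s) for s in ss.spawn(2)]
    probs = _base_probs(spec.gc, spec.at_skew, spec.gc_skew)
    genes = spec.genes or default_gene_specs()

    # 1. gene sequences (sense strand, no introns yet)
    seqs: dict[str, str] = {}
    for g in genes:
        if gene_seqs and g.name in gene_seqs:
            seqs[g.name] = gene_seqs[g.name]
        elif g.kind == KIND_PCG:
            seqs[g.name] = _random_cds(rng_seq, g.length, probs)
        else:
            seqs[g.name] = _random_seq(rng_seq, g.length, probs)

    # 2. plant introns: per host, build block with exon/intron layout
    introns_by_host: dict[str, list[IntronSpec]] = {}
    for ispec in spec.introns:
        if ispec.host not in seqs:
            raise SpecError(f"intron host {ispec.host} not in gene list")
        introns_by_host.setdefault(ispec.host, []).append(ispec)

    blocks: dict[str, dict] = {}
    orf_counter = 0
    for g in genes:
        cds = seqs[g.name]
        planted = sorted(introns_by_host.get(g.name, []), key=lambda i: i.cds_pos)
        block_seq = ""
        exon_ivs: list[tuple[int, int]] = []  # sense-block 0-based half-open
        intron_spans: list[dict] = []
        cursor = 0
        for ispec in planted:
            if not (0 < ispec.cds_pos < len(cds)):
                raise SpecError(
                    f"intron position {ispec.cds_pos} outside CDS of {g.name}"
                )
            intron_seq = _random_seq(rng_seq, ispec.length, probs)
            orf_rec = None
            if ispec.orf_length:
                if ispec.orf_length + 24 > ispec.length:
                    raise SpecError("intronic ORF longer than its intron")
                orf_counter += 1
                orf_nt = _random_cds(rng_seq, ispec.orf_length, probs)
                pad = 12
                intron_seq = (
                    intron_seq[:pad]
                    + orf_nt
                    + intron_seq[pad + ispec.orf_length :]
                )
                orf_rec = {"name": f"orf{ispec.orf_length // 3}_{orf_counter}",
                           "offset_in_intron": pad, "length": ispec.orf_length}
            exon_ivs.append((len(block_seq), len(block_seq) + ispec.cds_pos - cursor))
            block_seq += cds[cursor : ispec.cds_pos]
            cursor = ispec.cds_pos
            intron_spans.append(
                {
                    "iv": (len(block_seq), len(block_seq) + len(intron_seq)),
                    "spec": ispec,
                    "orf": orf_rec,
                }
            )
            block_seq += intron_seq
        exon_ivs.append((len(block_seq), len(block_seq) + len(cds) - cursor))
        block_seq += cds[cursor:]
        blocks[g.name] = {
            "seq": block_seq if g.strand == "+" else reverse_complement(block_seq),
            "sense_len": len(block_seq),
            "exons": exon_ivs,
            "introns": intron_spans,
            "cds": cds,
        }

    # 3. spacer budget
    gene_total = sum(len(b["seq"]) for b in blocks.values())
    spacer_total = spec.length - gene_total
    n_sp = len(genes)
    if spacer_total < n_sp * 20:
        raise SpecError(
            f"spec length {spec.length} too small for {gene_total} nt of genes "
            f"plus {n_sp} spacers"
        )
    base = spacer_total // n_sp
    spacer_lens = [base + (1 if i < spacer_total % n_sp else 0) for i in range(n_sp)]
    spacers = [_random_seq(rng_seq, L, probs) for L in spacer_lens]

    # 4. plant repeats into spacers (largest spacers first, fixed offsets)
    spacer_ids = sorted(range(n_sp), key=lambda i: -spacer_lens[i])
    slot = 0
    planted_dups: list[dict] = []
    planted_tandems: list[dict] = []

    def _claim(need: int) -> int:
        nonlocal slot
        while slot < n_sp and spacer_lens[spacer_ids[slot]] < need + 10:
            slot += 1
        if slot >= n_sp:
            raise SpecError("not enough spacer room for planted repeats")
        i = spacer_ids[slot]
        slot += 1
        return i

    for dspec in spec.duplications:
        unit = _random_seq(rng_rep, dspec.length, probs)
        i1, i2 = _claim(dspec.length), _claim(dspec.length)
        copy2 = reverse_complement(unit) if dspec.inverted else unit
        off1 = (spacer_lens[i1] - dspec.length) // 2
        off2 = (spacer_lens[i2] - dspec.length) // 2
        spacers[i1] = spacers[i1][:off1] + unit + spacers[i1][off1 + dspec.length :]
        spacers[i2] = spacers[i2][:off2] + copy2 + spacers[i2][off2 + dspec.length :]
        planted_dups.append(
            {"spacers": [(i1, off1), (i2, off2)], "length": dspec.length,
             "inverted": dspec.inverted}
        )
    for tspec in spec.tandems:
        total = tspec.period * tspec.copies
        unit = _random_seq(rng_rep, tspec.period, probs)
        i1 = _claim(total)
        off = (spacer_lens[i1] - total) // 2
        spacers[i1] = spacers[i1][:off] + unit * tspec.copies + spacers[i1][off + total :]
        planted_tandems.append(
            {"spacer": (i1, off), "period": tspec.period, "copies": tspec.copies}
        )

    # 5. assemble: gene_i then spacer_i, circular
    chunks: list[str] = []
    pos = 0
    features: list[GeneFeature] = []
    intron_feats: list[IntronFeature] = []
    manifest_genes: dict[str, dict] = {}
    manifest_introns: list[dict] = []
    spacer_starts: dict[int, int] = {}
    for gi, g in enumerate(genes):
        b = blocks[g.name]
        blen = b["sense_len"]
        exons = [
            _map_interval(iv, pos, blen, g.strand) for iv in b["exons"]
        ]
        exons.sort()
        features.append(GeneFeature(g.name, g.kind, g.strand, exons))
        n_planted = len(b["introns"])
        for k, ins in enumerate(b["introns"]):
            giv = _map_interval(ins["iv"], pos, blen, g.strand)
            index = k + 1 if g.strand == "+" else n_planted - k
            intron_feats.append(
                IntronFeature(g.name, index, giv, group="I")
            )
            manifest_introns.append(
                {
                    "host": g.name,
                    "cds_pos": ins["spec"].cds_pos,
                    "interval": list(giv),
                    "length": ins["spec"].length,
                }
            )
            if ins["orf"]:
                o = ins["orf"]
                o_sense = (
                    ins["iv"][0] + o["offset_in_intron"],
                    ins["iv"][0] + o["offset_in_intron"] + o["length"],
                )
                oiv = _map_interval(o_sense, pos, blen, g.strand)
                features.append(
                    GeneFeature(o["name"], KIND_INTRONIC_ORF, g.strand, [oiv])
                )
        manifest_genes[g.name] = {
            "kind": g.kind,
            "strand": g.strand,
            "start": pos + 1,
            "end": pos + blen,
            "cds": b["cds"] if g.kind == KIND_PCG else None,
            "length": len(b["cds"]),
        }
        chunks.append(b["seq"])
        pos += blen
        spacer_starts[gi] = pos
        chunks.append(spacers[gi])
        pos += spacer_lens[gi]

    sequence = "".join(chunks)
    assert len(sequence) == spec.length

    def _spacer_iv(spacer_idx: int, off: int, length: int) -> list[int]:
        s0 = spacer_starts[spacer_idx] + off
        return [s0 + 1, s0 + length]

    manifest = {
        "seed": seed,
        "id": spec.id,
        "length": spec.length,
        "gc_target": spec.gc,
        "at_skew_target": spec.at_skew,
        "gc_skew_target": spec.gc_skew,
        "gene_order": [[g.name, g.strand] for g in genes],
        "genes": manifest_genes,
        "introns": manifest_introns,
        "duplications": [
            {
                "intervals": [
                    _spacer_iv(*d["spacers"][0], d["length"]),
                    _spacer_iv(*d["spacers"][1], d["length"]),
                ],
                "length": d["length"],
                "inverted": d["inverted"],
            }
            for d in planted_dups
        ],
        "tandems": [
            {
                "interval": _spacer_iv(*t["spacer"], t["period"] * t["copies"]),
                "period": t["period"],
                "copies": t["copies"],
            }
            for t in planted_tandems
        ],
    }
    genome = MitoGenome(
        id=spec.id,
        sequence=sequence,
        circular=True,
        features=features,
        introns=intron_feats,
        source="synthetic",
    )
    return genome, manifest


# ---------------------------------------------------------------------------
# mutation


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_base(rng: np.random.Generator, cur: str, tstv: float) -> str:
    """Candidate substitution with transition weight ``tstv``."""
    others = [b for b in "ACGT" if b != cur]
    weights = np.array(
        [tstv if b == _TRANSITION[cur] else 1.0 for b in others]
    )
    weights /= weights.sum()
    return others[rng.choice(3, p=weights)]


def mutate_genome(
    ancestor: MitoGenome,
    rates: Mapping[str, Mapping[str, float]],
    seed: int,
    new_id: str | None = None,
    noncoding_rate: float = 0.0,
    tstv: float = 2.0,
    table: int = 4,
) -> tuple[MitoGenome, dict]:
    """Codon-aware mutated copy of a genome, with realized counts.

    ``rates`` maps gene name to ``{"syn": ds, "nonsyn": dn}`` acceptance
    probabilities per attempted site change; non-coding positions mutate
    at ``noncoding_rate``.  Substitution-only, so coordinates and features
    are unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seq = list(ancestor.sequence)
    realized: dict[str, dict] = {}
    coding_mask = np.zeros(len(seq), dtype=bool)

    for gene, rate in rates.items():
        ds = float(rate.get("syn", 0.0))
        dn = float(rate.get("nonsyn", 0.0))
        kappa = float(rate.get("tstv", tstv))
        if max(ds, dn) > 0.75:
            import logging

            logging.getLogger(__name__).warning(
                "%s: rates imply >75%% of sites hit; expect saturation", gene
            )
        feat = ancestor.get(gene)
        # genomic positions of the spliced CDS, in coding order
        positions: list[int] = []
        for s, e in feat.exons:
            positions.extend(range(s - 1, e))
        if feat.strand == "-":
            positions = positions[::-1]
        for p in positions:
            coding_mask[p] = True
        get = (
            (lambda p: seq[p])
            if feat.strand == "+"
            else (lambda p: reverse_complement(seq[p]))
        )
        n_codons = len(positions) // 3
        syn_count = nonsyn_count = 0
        for c in range(1, n_codons - 1):  # keep start and stop codons intact
            idxs = positions[3 * c : 3 * c + 3]
            codon = "".join(get(p) for p in idxs)
            if translate_codon(codon, table) is None:
                continue
            # at most one substitution per codon, so the syn/nonsyn label of
            # the realized change matches its NG86 classification exactly
            for k in rng.permutation(3):
                cand = _draw_base(rng, codon[k], kappa)
                mut = codon[:k] + cand + codon[k + 1 :]
                if translate_codon(mut, table) is None:
                    continue
                syn = translate_codon(mut, table) == translate_codon(codon, table)
                if rng.random() < (ds if syn else dn):
                    base = cand if feat.strand == "+" else reverse_complement(cand)
                    seq[idxs[k]] = base
                    syn_count += syn
                    nonsyn_count += not syn
                    break
        realized[gene] = {"syn": syn_count, "nonsyn": nonsyn_count}

    nc_count = 0
    if noncoding_rate > 0:
        draws = rng.random(len(seq))
        for p in np.flatnonzero(draws < noncoding_rate):
            if coding_mask[p] or seq[p] == "N":
                continue
            seq[p] = _draw_base(rng, seq[p], tstv)
            nc_count += 1
    realized["noncoding"] = {"count": nc_count}

    out = MitoGenome(
        id=new_id or f"{ancestor.id}_mut",
        sequence="".join(seq),
        circular=ancestor.circular,
        features=copy.deepcopy(ancestor.features),
        introns=copy.deepcopy(ancestor.introns),
        source="synthetic",
    )
    return out, realized


# ---------------------------------------------------------------------------
# cohorts


def apply_order_edit(genes: list[GeneSpec], edit: tuple) -> list[GeneSpec]:
    """One gene-order edit: ('swap', i) / ('invert', i, j) / ('move', i, j)."""
    genes = list(genes)
    op = edit[0]
    if op == "swap":
        i = edit[1]
        genes[i], genes[i + 1] = genes[i + 1], genes[i]
    elif op == "invert":
        i, j = edit[1], edit[2]
        block = [
            GeneSpec(g.name, g.kind, "-" if g.strand == "+" else "+", g.length)
            for g in reversed(genes[i : j + 1])
        ]
        genes[i : j + 1] = block
    elif op == "move":
        i, j = edit[1], edit[2]
        g = genes.pop(i)
        genes.insert(j, g)
    elif op == "permute":
        perm = list(edit[1])
        perm += list(range(len(perm), len(genes)))
        genes = [genes[k] for k in perm]
    else:
        raise ValueError(f"unknown order edit {op!r}")
    return genes


def generate_cohort(
    n: int,
    spec: GenomeSpec,
    rates: Sequence[Mapping[str, Mapping[str, float]]] | None,
    seed: int,
    order_edits: Mapping[int, Sequence[tuple]] | None = None,
    noncoding_rate: float = 0.0,
) -> tuple[list[MitoGenome], dict]:
    """One ancestor plus n-1 descendants with per-branch rates/order edits.

    ``rates[i]`` gives the per-gene rates of descendant i (0-based among
    the n-1 descendants); ``order_edits[i]`` optionally rearranges that
    descendant's gene order (edits recorded in the manifest).
    """
    if n < 2:
        raise SpecError("cohort needs n >= 2")
    genes = spec.genes or default_gene_specs()
    spec = copy.deepcopy(spec)
    spec.genes = genes
    ancestor, anc_manifest = generate_genome(spec, seed)
    gene_seqs = {
        name: rec["cds"]
        for name, rec in anc_manifest["genes"].items()
        if rec["cds"] is not None
    }
    for g in genes:
        if g.kind != KIND_PCG:
            # reuse the realized RNA/tRNA sequences too
            feat = ancestor.get(g.name)
            sub = ancestor.sequence[feat.start - 1 : feat.end]
            gene_seqs[g.name] = sub if g.strand == "+" else reverse_complement(sub)

    genomes = [ancestor]
    manifest = {
        "seed": seed,
        "ancestor": anc_manifest,
        "descendants": {},
    }
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(2 * (n - 1))
    for i in range(n - 1):
        gid = f"{spec.id}_d{i + 1}"
        edits = list(order_edits.get(i, [])) if order_edits else []
        g_list = genes
        for e in edits:
            g_list = apply_order_edit(g_list, e)
        if edits:
            dspec = copy.deepcopy(spec)
            dspec.id = gid
            dspec.genes = g_list
            base, base_manifest = generate_genome(
                dspec, int(child_seeds[2 * i].generate_state(1)[0]), gene_seqs
            )
        else:
            base, base_manifest = ancestor, None
        r = rates[i] if rates else {}
        mut, realized = mutate_genome(
            base,
            r,
            int(child_seeds[2 * i + 1].generate_state(1)[0]),
            new_id=gid,
            noncoding_rate=noncoding_rate,
        )
        genomes.append(mut)
        manifest["descendants"][gid] = {
            "order_edits": [list(e) for e in edits],
            "gene_order": [[g.name, g.strand] for g in g_list],
            "rates": {k: dict(v) for k, v in r.items()},
            "realized": realized,
        }
    return genomes, manifest


def generate_pcl_cohort(
    pcl_table: Mapping[str, Sequence[int]],
    seed: int,
    host: str = "cox1",
    intron_length: int = 150,
) -> tuple[list[MitoGenome], "object", dict]:
    """Small genomes with introns planted at given reference CDS positions.

    All species share a reference-identical host CDS, so mapped insertion
    positions must recover ``pcl_table`` exactly.  Returns (genomes,
    reference CodingSequence, manifest).
    """
    from .mito_io import extract_cds

    ss = np.random.SeedSequence(seed)
    anc_seed = int(ss.generate_state(1)[0]) % (2**32)
    host_len = _DEFAULT_PCG_LEN.get(host, 1608)
    max_pos = max((p for ps in pcl_table.values() for p in ps), default=0)
    if max_pos >= host_len - 3:
        host_len = 3 * ((max_pos + 60) // 3 + 1)
    base_genes = [
        GeneSpec(host, KIND_PCG, "+", host_len),
        GeneSpec("rns", KIND_RRNA, "+", 600),
        GeneSpec("trnA", KIND_TRNA, "+", 72),
    ]
    ref_spec = GenomeSpec(id="ref", length=host_len + 1200, genes=base_genes)
    ref_genome, ref_manifest = generate_genome(ref_spec, anc_seed)
    host_cds = ref_manifest["genes"][host]["cds"]
    reference = extract_cds(ref_genome, host)

    genomes: list[MitoGenome] = []
    manifest: dict = {"seed": seed, "host": host, "table": {}}
    for sp_i, (species, positions) in enumerate(sorted(pcl_table.items())):
        positions = sorted(set(int(p) for p in positions))
        for p in positions:
            if not (0 < p < host_len):
                raise SpecError(f"{species}: Pcl position {p} outside host CDS")
        spec = GenomeSpec(
            id=species,
            length=host_len + 1200 + intron_length * len(positions),
            genes=base_genes,
            introns=[IntronSpec(host, p, intron_length) for p in positions],
        )
        g, _ = generate_genome(spec, anc_seed + 1 + sp_i, gene_seqs={host: host_cds})
        genomes.append(g)
        manifest["table"][species] = positions
    return genomes, reference, manifest


# ---------------------------------------------------------------------------
# spec loading (JSON/YAML) and manifest output


def load_spec(path: str) -> GenomeSpec:
    """Load a GenomeSpec from a JSON or YAML file."""
    with open(path) as fh:
        if path.endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(fh)
        else:
            raw = json.load(fh)
    genes = [GeneSpec(**g) for g in raw.pop("genes", [])]
    introns = [IntronSpec(**i) for i in raw.pop("introns", [])]
    dups = [DuplicationSpec(**d) for d in raw.pop("duplications", [])]
    tandems = [TandemSpec(**t) for t in raw.pop("tandems", [])]
    return GenomeSpec(
        genes=genes, introns=introns, duplications=dups, tandems=tandems, **raw
    )


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
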