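"""Synthetic pan-genomes with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the pipeline's real
inputs: a class/family/genus/species taxonomy, per-species gene tables with
KO labels and conserved 3-gene neighborhoods, domain-hit tables realising
the registry architectures (tandem copies, motifs), planted per-genus
signatures and phenotypes, hidden intergenic genes for the rescue stage, and
binary characters evolved on a tree under known gain/loss rates.

Protein sequences are motif templates embedded in random background — enough
to exercise motif checks and the mock profile backend (a substring lookup
standing in for a real scanner behind the same interface); no attempt is
made to imitate real Firmicutes composition. Planted probable orthologs
carry a valid architecture and at least one RCKO neighbor; decoys violate
exactly one rule each, in known counts. Everything is deterministic per
seed, and emitted files round-trip through ``io_formats`` unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import dendropy

from .architectures import Architecture, default_registry, target_proteins
from .io_formats import (
    DomainHit,
    GeneRecord,
    Taxonomy,
    write_domain_table,
    write_gene_table,
)
from .rescue import ProfileBackend

AA_BACKGROUND = "ACDEFGHIKLMNPQRSTVWY"

# Motif template strings matching the default motif patterns.
MOTIF_STRINGS = {
    "WalkerA": "GPSGSGKS",
    "WalkerB": "LLDE",
    "HisBox": "HAAH",
    "AspBox": "DAADAD",
}

# One distinctive 10-aa tag per profile token; the mock backend keys on these.
_PROFILES = [
    "PF03266", "PF00004", "PF00437", "PLH_SpoIIIAB", "PF06686",
    "PLH_SpoIIIAE", "PF09581", "SpoIIIAG_custom", "PLH_SpoIIIAH",
    "M23_peptidase", "PLH_SpoIID", "PLH_SpoIIM", "PLH_SpoIIP",
    "PLH_SpoIIB", "PF10646",
]


def _make_tag(index: int) -> str:
    rng = np.random.default_rng(10_000 + index)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))


PROFILE_TAGS: dict[str, str] = {p: _make_tag(i) for i, p in enumerate(_PROFILES)}

# Canonical planted architecture per target protein.
CANONICAL_ARCH = {
    "SpoIIIAA": "SpoIIIAA_2",
    "SpoIIIAB": "SpoIIIAB",
    "SpoIIIAC": "SpoIIIAC",
    "SpoIIIAD": "SpoIIIAD",
    "SpoIIIAE": "SpoIIIAE",
    "SpoIIIAF": "SpoIIIAF",
    "SpoIIIAG": "SpoIIIAG",
    "SpoIIIAH": "SpoIIIAH",
    "SpoIIQ": "SpoIIQ",
    "SpoIID": "SpoIID",
    "SpoIIM": "SpoIIM",
    "SpoIIP": "SpoIIP",
    "SpoIIB": "SpoIIB",
    "GerM": "GerM",
}

# Focal KO and the planted contextual KO per target. SpoIIIAG carries the
# K06396 label and SpoIIIAH sits upstream of an acetyl-CoA carboxylase
# (K01961) in real operons; the rest are synthetic tokens.
KO_MAP = {t: f"K064{i:02d}" for i, t in enumerate(CANONICAL_ARCH)}
KO_MAP["SpoIIIAG"] = "K06396"
RCKO_MAP = {t: f"K070{i:02d}" for i, t in enumerate(CANONICAL_ARCH)}
RCKO_MAP["SpoIIIAH"] = "K01961"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(aa_seq: str) -> str:
    return "".join(_CODON[a] for a in aa_seq)


class MockProfileBackend:
    """Substring-lookup profile scanner for synthetic fixtures.

    Finds every occurrence of each profile's tag in a peptide and reports it
    as a hit with a strong E-value; real deployments plug an hmmscan-backed
    adapter into the same interface.
    """

    def __init__(self, tags: Mapping[str, str] | None = None, evalue: float = 1e-8):
        self.tags = dict(tags or PROFILE_TAGS)
        self.evalue = evalue

    def scan(self, gene_id: str, peptide: str) -> list[DomainHit]:
        hits = []
        for profile, tag in sorted(self.tags.items()):
            start = 0
            while True:
                i = peptide.find(tag, start)
                if i < 0:
                    break
                hits.append(
                    DomainHit(gene_id, profile, i + 1, i + len(tag), self.evalue)
                )
                start = i + 1
        hits.sort(key=lambda h: (h.ali_start, h.profile))
        return hits


@dataclass
class SynthConfig:
    """Study conditions for the synthetic pan-genome (desk scale by default)."""

    rng_seed: int
    n_classes: int = 4
    n_families: int = 8
    n_genera: int = 16
    n_species: int = 64
    sporulating_fraction: float = 0.5
    checkerboard_genera: int = 2  # genera planted WITHOUT an aggregated profile
    noise_rate: float = 0.0  # per planted gene: drop a required domain hit
    n_decoys_per_species: int = 3
    ko_present_prob: float = 0.7  # focal KO labels are not required by the rules
    rcko_plant_prob: float = 1.0
    hidden_gene_count: int = 0
    hidden_gene_target: str = "SpoIIIAH"
    signature_dropouts: tuple[tuple[str, ...], ...] = (
        (), ("SpoIIB",), ("GerM",), ("SpoIIB", "GerM"), ("SpoIIM",), ("SpoIIP",),
    )
    registry: Sequence[Architecture] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        for p in (self.sporulating_fraction, self.noise_rate,
                  self.ko_present_prob, self.rcko_plant_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        targets = set(target_proteins(self.registry))
        for drop in self.signature_dropouts:
            unknown = set(drop) - targets
            if unknown:
                raise ValueError(f"signature references unknown proteins {unknown}")
        if self.n_species % self.n_genera:
            raise ValueError("n_species must be divisible by n_genera")


@dataclass
class GroundTruth:
    planted_cells: set[tuple[str, str]]  # (species_id, protein)
    planted_signatures: dict[str, frozenset[str]]
    checkerboard_genera: set[str]
    spo0a: dict[str, int]
    phenotypes: dict[str, str]
    taxonomy: dict[str, Taxonomy]
    decoys: list[dict]
    deviant_species: set[str]  # inferred/unknown species deviating from signature
    hidden_genes: list[dict] = field(default_factory=list)
    tree: Optional[str] = None
    rates: Optional[tuple[float, float]] = None


@dataclass
class Bundle:
    genes: list[GeneRecord]
    hits: list[DomainHit]
    truth: GroundTruth
    contig_seqs: dict[tuple[str, str], str] = field(default_factory=dict)
    contig_lengths: dict[tuple[str, str], int] = field(default_factory=dict)


def _junk_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_BACKGROUND), size=n))


def _focal_protein(rng, arch: Architecture) -> tuple[str, list[tuple[str, int, int]]]:
    """A protein realising one architecture: (aa_seq, [(profile, start, end)])."""
    seq = "M" + _junk_aa(rng, 15)
    if arch.motif_requirements:
        for name in ("WalkerA", "HisBox"):
            seq += MOTIF_STRINGS[name] + _junk_aa(rng, 4)
    spans: list[tuple[str, int, int]] = []
    for profile, copies in arch.components:
        tag = PROFILE_TAGS[profile]
        for _ in range(copies):
            seq += _junk_aa(rng, 5)
            start = len(seq) + 1
            seq += tag
            spans.append((profile, start, start + len(tag) - 1))
    if arch.motif_requirements:
        for name in ("WalkerB", "AspBox"):
            seq += _junk_aa(rng, 4) + MOTIF_STRINGS[name]
    seq += _junk_aa(rng, 10)
    return seq, spans


def generate_pangenome(
    config: SynthConfig, outdir: Optional[str | Path] = None
) -> Bundle:
    """Build the full synthetic bundle; optionally write it to ``outdir``.

    Emitted files: ``genes.tsv``, ``proteins.faa``, ``domhits.domtbl``,
    ``taxonomy.tsv``, ``phenotypes.tsv``, ``spo0a.tsv`` and, when hidden
    genes are planted, ``contigs.fna`` (plus ``ground_truth.json``).
    """
    rng = np.random.default_rng(config.rng_seed)
    registry_by_name = {a.name: a for a in config.registry}
    targets = target_proteins(config.registry)
    universe = ["Spo0A"] + targets

    per_genus = config.n_species // config.n_genera
    genera = [f"G{i:02d}" for i in range(config.n_genera)]
    genus_family = {g: f"F{i % config.n_families}" for i, g in enumerate(genera)}
    family_class = {
        f"F{i}": f"C{i % config.n_classes}" for i in range(config.n_families)
    }

    checker = set(genera[: config.checkerboard_genera])
    signatures: dict[str, frozenset[str]] = {}
    for i, g in enumerate(genera):
        drop = config.signature_dropouts[i % len(config.signature_dropouts)]
        # checkerboard genera start from the full complement so the planted
        # SpoIIB/GerM alternation is a true segregation, not a nesting
        signatures[g] = frozenset(universe) if g in checker else frozenset(universe) - set(drop)

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    planted: set[tuple[str, str]] = set()
    decoys: list[dict] = []
    phenotypes: dict[str, str] = {}
    taxonomy: dict[str, Taxonomy] = {}
    spo0a: dict[str, int] = {}
    deviants: set[str] = set()
    junk_counter = 0

    def next_junk_ko() -> str:
        nonlocal junk_counter
        junk_counter += 1
        return f"K9{junk_counter:05d}"

    # at least 2 confirmed spore formers per genus (signatures need n >= 2),
    # one nonsporulating member, the rest inferred/unknown by genus parity
    n_spor = max(2, int(round(config.sporulating_fraction * per_genus)))

    for g_idx, genus in enumerate(genera):
        fam = genus_family[genus]
        cls = family_class[fam]
        for s_idx in range(per_genus):
            sp = f"{genus}_sp{s_idx}"
            taxonomy[sp] = Taxonomy(sp, cls, fam, genus)
            if s_idx < n_spor:
                pheno = "sporulating"
            elif s_idx == n_spor:
                pheno = "nonsporulating"
            else:
                pheno = "sporulating_inferred" if g_idx % 2 == 0 else "unknown"
            phenotypes[sp] = pheno

            sporulating_like = pheno != "nonsporulating"
            profile = set(signatures[genus]) if sporulating_like else set()
            if sporulating_like and genus in checker:
                # segregated genus: alternate members miss SpoIIB vs GerM
                profile -= {"SpoIIB"} if s_idx % 2 == 0 else {"GerM"}
            if pheno == "sporulating_inferred" and g_idx == config.n_genera - 2:
                # one planted deviant for the phenotype-prediction stage
                victim = sorted(profile - {"Spo0A"})[0]
                profile.discard(victim)
                deviants.add(sp)

            spo0a[sp] = 1 if "Spo0A" in profile else 0
            gene_counter = 0
            pos = 1000
            contig = f"{sp}_c1"

            def add_gene(ko, aa_seq=None, length_nt=900, product="") -> GeneRecord:
                nonlocal gene_counter, pos
                gene_counter += 1
                if aa_seq is not None:
                    length_nt = 3 * len(aa_seq)
                rec = GeneRecord(
                    species_id=sp,
                    gene_id=f"{sp}_g{gene_counter:04d}",
                    contig_id=contig,
                    start=pos,
                    end=pos + length_nt - 1,
                    strand="+" if rng.random() < 0.8 else "-",
                    ko=ko,
                    product=product,
                    aa_seq=aa_seq,
                )
                genes.append(rec)
                pos = rec.end + 101
                return rec

            def neighbor_ko(i: int) -> Optional[str]:
                # neighbors other than the planted RCKO carrier: half junk KO
                return next_junk_ko() if i % 2 == 0 else None

            for target in sorted(profile - {"Spo0A"}):
                arch = registry_by_name[CANONICAL_ARCH[target]]
                for i in range(3):
                    add_gene(neighbor_ko(i))
                aa_seq, spans = _focal_protein(rng, arch)
                focal_ko = KO_MAP[target] if rng.random() < config.ko_present_prob else None
                focal = add_gene(focal_ko, aa_seq=aa_seq, product=target)
                dropped = config.noise_rate > 0 and rng.random() < config.noise_rate
                for j, (profile_token, a, b) in enumerate(spans):
                    if dropped and j == 0:
                        continue  # noise: lose a required domain hit
                    hits.append(DomainHit(focal.gene_id, profile_token, a, b, 1e-8))
                if not dropped:
                    planted.add((sp, target))
                if rng.random() < config.rcko_plant_prob:
                    add_gene(RCKO_MAP[target])
                else:
                    add_gene(neighbor_ko(1))
                for i in range(2):
                    add_gene(neighbor_ko(i + 1))
                pos += 2000  # spacer between operon blocks

            for d in range(config.n_decoys_per_species):
                kind = ("arch_no_context", "arch_junk_context", "context_no_arch")[
                    d % 3
                ]
                target = targets[(g_idx + d) % len(targets)]
                arch = registry_by_name[CANONICAL_ARCH[target]]
                if kind == "context_no_arch":
                    for _ in range(2):
                        add_gene(None)
                    decoy = add_gene(None, aa_seq="M" + _junk_aa(rng, 80), product="decoy")
                    add_gene(RCKO_MAP[target])
                else:
                    label = (lambda: None) if kind == "arch_no_context" else next_junk_ko
                    for _ in range(3):
                        add_gene(label() if kind == "arch_junk_context" else None)
                    aa_seq, spans = _focal_protein(rng, arch)
                    decoy = add_gene(None, aa_seq=aa_seq, product="decoy")
                    for profile_token, a, b in spans:
                        hits.append(DomainHit(decoy.gene_id, profile_token, a, b, 1e-8))
                    for _ in range(3):
                        add_gene(label() if kind == "arch_junk_context" else None)
                decoys.append(
                    {"species_id": sp, "gene_id": decoy.gene_id,
                     "target": target, "violation": kind}
                )
                pos += 2000

    truth = GroundTruth(
        planted_cells=planted,
        planted_signatures=signatures,
        checkerboard_genera=checker,
        spo0a=spo0a,
        phenotypes=phenotypes,
        taxonomy=taxonomy,
        decoys=decoys,
        deviant_species=deviants,
    )
    bundle = Bundle(genes=genes, hits=hits, truth=truth)

    if config.hidden_gene_count > 0:
        plant_hidden_genes(bundle, config)

    _audit(bundle)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _audit(bundle: Bundle) -> None:
    """Ground truth and emitted objects must never disagree."""
    gene_ids = {(g.species_id, g.gene_id) for g in bundle.genes}
    if len(gene_ids) != len(bundle.genes):
        raise AssertionError("duplicate gene ids in synthetic bundle")
    by_gene = {g.gene_id for g in bundle.genes}
    for h in bundle.hits:
        if h.gene_id not in by_gene:
            raise AssertionError(f"domain hit for unknown gene {h.gene_id}")
    for hg in bundle.truth.hidden_genes:
        if hg["gene_id"] in by_gene:
            raise AssertionError("hidden gene still annotated")


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "fasta": outdir / "proteins.faa",
        "domtbl": outdir / "domhits.domtbl",
        "taxonomy": outdir / "taxonomy.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "spo0a": outdir / "spo0a.tsv",
    }
    write_gene_table(bundle.genes, paths["genes"], fasta_path=paths["fasta"])
    qlen = {g.gene_id: len(g.aa_seq) for g in bundle.genes if g.aa_seq}
    write_domain_table(bundle.hits, paths["domtbl"], qlen=qlen)
    tax = bundle.truth.taxonomy
    pd.DataFrame(
        [
            {"species_id": s, "class": t.class_, "family": t.family, "genus": t.genus}
            for s, t in sorted(tax.items())
        ]
    ).to_csv(paths["taxonomy"], sep="\t", index=False)
    pd.DataFrame(
        [{"species_id": s, "phenotype": p} for s, p in sorted(bundle.truth.phenotypes.items())]
    ).to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        [{"species_id": s, "Spo0A": v} for s, v in sorted(bundle.truth.spo0a.items())]
    ).to_csv(paths["spo0a"], sep="\t", index=False)
    if bundle.contig_seqs:
        paths["contigs"] = outdir / "contigs.fna"
        with open(paths["contigs"], "w") as fh:
            for (sp, contig), seq in sorted(bundle.contig_seqs.items()):
                fh.write(f">{sp}|{contig}\n{seq}\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        t = bundle.truth
        json.dump(
            {
                "planted_cells": sorted(map(list, t.planted_cells)),
                "planted_signatures": {g: sorted(s) for g, s in t.planted_signatures.items()},
                "checkerboard_genera": sorted(t.checkerboard_genera),
                "deviant_species": sorted(t.deviant_species),
                "decoys": t.decoys,
                "hidden_genes": t.hidden_genes,
            },
            fh,
            indent=1,
        )
    return paths


def plant_hidden_genes(bundle: Bundle, config: SynthConfig) -> None:
    """Hide planted genes in intergenic DNA for the rescue stage.

    Removes up to ``hidden_gene_count`` planted genes of the configured
    target from the annotation while writing their coding sequence (reverse
    complemented on minus-strand picks) into freshly generated contig DNA;
    true coordinates, strand and frame are recorded in the ground truth.
    """
    rng = np.random.default_rng(config.rng_seed + 777)
    target = config.hidden_gene_target
    candidates = [
        g for g in bundle.genes if g.product == target and g.aa_seq
    ]
    picked = candidates[: config.hidden_gene_count]
    if len(picked) < config.hidden_gene_count:
        raise ValueError("not enough planted genes to hide")
    hidden_ids = {g.gene_id for g in picked}

    for hg in picked:
        key = (hg.species_id, hg.contig_id)
        contig_genes = [g for g in bundle.genes if (g.species_id, g.contig_id) == key]
        length = max(g.end for g in contig_genes) + 500
        dna = "".join(rng.choice(list("ACGT"), size=length))
        cds = reverse_translate(hg.aa_seq)
        if hg.end - hg.start + 1 != len(cds):
            raise ValueError("hidden gene slot does not fit its coding sequence")
        if hg.strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            cds = "".join(comp[c] for c in reversed(cds))
        dna = dna[: hg.start - 1] + cds + dna[hg.end:]
        bundle.contig_seqs[key] = dna
        bundle.contig_lengths[key] = length
        bundle.truth.hidden_genes.append(
            {
                "species_id": hg.species_id,
                "contig_id": hg.contig_id,
                "gene_id": hg.gene_id,
                "target": target,
                "start": hg.start,
                "end": hg.end,
                "strand": hg.strand,
                "aa_seq": hg.aa_seq,
            }
        )
        bundle.truth.planted_cells.discard((hg.species_id, target))

    bundle.genes = [g for g in bundle.genes if g.gene_id not in hidden_ids]
    bundle.hits = [h for h in bundle.hits if h.gene_id not in hidden_ids]


def simulate_profiles(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    n_chars: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate binary characters on a tree; record every transition.

    The root draws from the stationary distribution g/(g+l); each branch then
    runs the two-state chain for its length. Returns (tip matrix indexed by
    taxon, per-branch true event counts summed over characters with columns
    branch_id/gains/losses).
    """
    if gain_rate < 0 or loss_rate < 0 or gain_rate + loss_rate <= 0:
        raise ValueError("rates must be non-negative with a positive sum")
    from .gainloss import label_nodes

    label_nodes(tree)
    rng = np.random.default_rng(seed)
    tips = [n for n in tree.leaf_node_iter()]
    branch_nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    gains = {n.label: 0 for n in branch_nodes}
    losses = {n.label: 0 for n in branch_nodes}
    pi1 = gain_rate / (gain_rate + loss_rate)
    rates = (gain_rate, loss_rate)

    data: dict[str, list[int]] = {t.taxon.label: [] for t in tips}
    for _ in range(n_chars):
        states = {tree.seed_node: int(rng.random() < pi1)}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            state, clock = states[node.parent_node], 0.0
            t = node.edge.length or 0.0
            while True:
                if rates[state] == 0:
                    break  # absorbing under a zero exit rate
                clock += rng.exponential(1.0 / rates[state])
                if clock >= t:
                    break
                if state == 0:
                    gains[node.label] += 1
                    state = 1
                else:
                    losses[node.label] += 1
                    state = 0
            states[node] = state
        for tip in tips:
            data[tip.taxon.label].append(states[tip])

    matrix = pd.DataFrame.from_dict(data, orient="index",
                                    columns=[f"char{i}" for i in range(n_chars)])
    events = pd.DataFrame(
        [{"branch_id": b, "gains": gains[b], "losses": losses[b]} for b in gains]
    )
    return matrix, events
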