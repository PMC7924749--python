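"""Recovery of unannotated spoIIIA-operon genes from intergenic DNA.

Incomplete genome annotations leave sizeable intergenic gaps that can hide
real sporulation genes. The rescue procedure: find unannotated intervals of
at least ``min_gap`` nucleotides, translate each in all six frames, scan the
peptides with the profile backend at a relaxed E <= 0.01, and accept a
rescued gene only when the architecture matches, the SpoIIIAA motif gate
passes (Walker A/B plus His/Asp boxes on the whole translated frame), and at
least one flanking gene carries a representative contextual KO. Rescue never
modifies the original gene table; its outputs are additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

from Bio.Seq import Seq

from . import architectures as arch_mod
from .architectures import Architecture, ArchitectureCall, MotifSpec
from .context import RCKOTable
from .io_formats import DomainHit, GeneRecord

_NUCS = set("ACGTN")


@dataclass(frozen=True)
class IntergenicRegion:
    species_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    flank_left: Optional[str] = None  # gene_id upstream in coordinates
    flank_right: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RescuedGene:
    region: IntergenicRegion
    frame: int  # +1..+3, -1..-3
    aa_seq: str
    architecture_call: ArchitectureCall
    motif_report: dict[str, bool]
    context_support: set[str]
    accepted: bool


class ProfileBackend(Protocol):
    """Maps a peptide to domain hits; pluggable (real scanner or a mock)."""

    def scan(self, gene_id: str, peptide: str) -> list[DomainHit]: ...


def find_intergenic_gaps(
    genes: Sequence[GeneRecord],
    contig_lengths: Mapping[tuple[str, str], int] | Mapping[str, int],
    min_gap: int = 200,
) -> list[IntergenicRegion]:
    """Maximal unannotated intervals of length >= min_gap per contig.

    ``contig_lengths`` is keyed by (species_id, contig_id) or plain contig_id.
    Contig ends count as gap boundaries. Overlapping gene annotations are
    merged before gap extraction, so regions are disjoint from every gene.
    """
    def contig_len(sp: str, contig: str) -> int:
        if (sp, contig) in contig_lengths:
            return contig_lengths[(sp, contig)]  # type: ignore[index]
        return contig_lengths[contig]  # type: ignore[index]

    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault((g.species_id, g.contig_id), []).append(g)

    regions: list[IntergenicRegion] = []
    for (sp, contig), recs in sorted(by_contig.items()):
        length = contig_len(sp, contig)
        recs = sorted(recs, key=lambda g: (g.start, g.end))
        for g in recs:
            if g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end} beyond contig length {length}"
                )
        # merge covered intervals
        merged: list[list] = []
        for g in recs:
            if merged and g.start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], g.end)
                merged[-1][3] = g.gene_id
            else:
                merged.append([g.start, g.end, g.gene_id, g.gene_id])
        prev_end, prev_gene = 0, None
        for start, end, first_gene, last_gene in merged + [[length + 1, length + 1, None, None]]:
            gap_start, gap_end = prev_end + 1, start - 1
            if gap_end - gap_start + 1 >= min_gap:
                regions.append(
                    IntergenicRegion(sp, contig, gap_start, gap_end, prev_gene, first_gene)
                )
            prev_end, prev_gene = end, last_gene
    return regions


def six_frame_translate(dna: str) -> dict[int, str]:
    """Plain six-frame translation (standard code, stops as '*', N -> X).

    Frames +1..+3 read the given strand at offsets 0..2; frames -1..-3 read
    the reverse complement the same way. No start-codon handling.
    """
    dna = dna.upper()
    bad = set(dna) - _NUCS
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    frames: dict[int, str] = {}
    rc = str(Seq(dna).reverse_complement())
    for off in range(3):
        for sign, seq in ((1, dna), (-1, rc)):
            sub = seq[off: off + 3 * ((len(seq) - off) // 3)]
            frames[sign * (off + 1)] = str(Seq(sub).translate()) if sub else ""
    return frames


def rescue_scan(
    regions: Sequence[IntergenicRegion],
    profile_backend: ProfileBackend,
    registry: Sequence[Architecture],
    contig_seqs: Mapping[tuple[str, str], str],
    genes: Sequence[GeneRecord] = (),
    rckos: Mapping[str, RCKOTable] | None = None,
    e_max: float = 0.01,
    motif_config: Mapping[str, MotifSpec] | None = None,
    neighborhood_k: int = 3,
) -> list[RescuedGene]:
    """Scan every frame of every region and gate candidates like first-pass POs.

    ``rckos`` maps target protein -> its RCKO table; context support is the
    RCKOs carried by up to ``neighborhood_k`` annotated genes on each side of
    the region. Architecture detection reuses the first-pass engine with the
    relaxed E cutoff; SpoIIIAA candidates are motif-gated on the translated
    frame. Backend failures propagate with the region identity attached.
    """
    rckos = rckos or {}
    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault((g.species_id, g.contig_id), []).append(g)

    rescued: list[RescuedGene] = []
    for region in regions:
        dna = contig_seqs[(region.species_id, region.contig_id)][
            region.start - 1: region.end
        ]
        contig_genes = sorted(
            by_contig.get((region.species_id, region.contig_id), []),
            key=lambda g: g.start,
        )
        left = [g for g in contig_genes if g.end < region.start][-neighborhood_k:]
        right = [g for g in contig_genes if g.start > region.end][:neighborhood_k]
        flank_kos = {g.ko for g in left + right if g.ko}

        for frame, peptide in sorted(six_frame_translate(dna).items()):
            if not peptide:
                continue
            gene_id = f"{region.species_id}:{region.contig_id}:{region.start}-{region.end}:f{frame:+d}"
            try:
                hits = profile_backend.scan(gene_id, peptide)
            except Exception as exc:
                raise RuntimeError(f"profile backend failed on {gene_id}") from exc
            hits = arch_mod.filter_hits(hits, e_max=e_max)
            hits = arch_mod.resolve_overlaps(hits)
            for call in arch_mod.detect_architecture(
                hits, registry, aa_seq=peptide, motif_config=motif_config
            ):
                selected = rckos.get(call.target_protein)
                support = flank_kos & selected.selected if selected else set()
                accepted = bool(call.accepted and support)
                rescued.append(
                    RescuedGene(
                        region=region,
                        frame=frame,
                        aa_seq=peptide,
                        architecture_call=call,
                        motif_report=call.motif_report,
                        context_support=support,
                        accepted=accepted,
                    )
                )
    return rescued
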