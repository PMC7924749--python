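"""Protein-architecture assignment from profile-domain hits.

A protein architecture is an ordered multiset of profile domains, possibly in
tandem copies, plus sequence-motif requirements. The engulfment machinery of
spore-forming Firmicutes (the SpoIIQ:SpoIIIAA-AH channel, the
SpoIID-SpoIIM-SpoIIP peptidoglycan-degrading complex, and the accessory
proteins SpoIIB and GerM) is described here by a registry of 17 such
architectures covering 14 target proteins.

The assignment procedure: keep hits at E <= 0.001 (the Pfam significance
cutoff; a relaxed 0.01 is used in annotation rescue), resolve overlapping
domains in favour of the longest span, then match each registered
architecture against the surviving, coordinate-ordered hits. SpoIIIAA is an
ATPase and its candidates must additionally carry Walker A/B motifs and the
His and Asp boxes somewhere in the full protein sequence — the whole
sequence, not just the domain envelope, because profile hits frequently
cover only one of the motifs while the others sit outside the envelope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align

from .io_formats import DomainHit


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str
    required: bool = True

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise ConfigurationError(f"motif {self.name}: bad pattern: {exc}") from exc


@dataclass(frozen=True)
class Architecture:
    """A named domain pattern assigned to a target protein.

    ``components`` is an ordered list of (profile, copy_count); ``copy_count``
    > 1 means tandem, i.e. that many non-overlapping colinear hits of the same
    profile. ``motif_requirements`` names entries of a motif config.
    """

    name: str
    target_protein: str
    components: tuple[tuple[str, int], ...]
    motif_requirements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError(f"{self.name}: architecture needs >=1 component")
        for profile, copies in self.components:
            if copies < 1:
                raise ConfigurationError(f"{self.name}: copy_count {copies} < 1")


@dataclass
class ArchitectureCall:
    gene_id: str
    architecture: str
    target_protein: str
    supporting_hits: list[DomainHit]
    motif_report: dict[str, bool] = field(default_factory=dict)
    accepted: bool = False


# Default motif patterns. Walker A/B are the standard P-loop NTPase motifs;
# the His and Asp box patterns are configurable placeholders (the canonical
# literature cites the boxes without printing a consensus).
DEFAULT_MOTIFS: dict[str, MotifSpec] = {
    "WalkerA": MotifSpec("WalkerA", r"[AG].{4}GK[ST]"),
    "WalkerB": MotifSpec("WalkerB", r"[ILVFM]{2,4}D[ED]"),
    "HisBox": MotifSpec("HisBox", r"H.{2,4}H"),
    "AspBox": MotifSpec("AspBox", r"D.{2}[DE].D"),
}

_SPOIIIAA_MOTIFS = ("WalkerA", "WalkerB", "HisBox", "AspBox")

# Profile tokens: Pfam accessions where established, descriptive placeholder
# tokens (PLH_*) where only a figure names the accession — both are plain
# config strings and can be edited in the registry.
def default_registry(extended: bool = False) -> list[Architecture]:
    """The default 17-architecture registry covering the 14 target proteins.

    SpoIIIAA is described by four alternative architectures (NTPase_1 single
    and tandem, AAA, T2SSE); SpoIIIAD requires the SpoIIIAC domain in tandem;
    GerM requires two Germane-domain copies; SpoIIQ is recognised by the M23
    peptidase family domain (which spans the RnfC barrel-sandwich domain in
    the same protein, hence wins overlap resolution). ``extended=True`` adds
    the alternative SpoIIIAA profiles occasionally seen in rescue
    (PF05621/PF13401/PF13191/PF13481), off by default.
    """
    regs = [
        Architecture("SpoIIIAA_1", "SpoIIIAA", (("PF03266", 1),), _SPOIIIAA_MOTIFS),
        Architecture("SpoIIIAA_2", "SpoIIIAA", (("PF03266", 2),), _SPOIIIAA_MOTIFS),
        Architecture("SpoIIIAA_3", "SpoIIIAA", (("PF00004", 1),), _SPOIIIAA_MOTIFS),
        Architecture("SpoIIIAA_4", "SpoIIIAA", (("PF00437", 1),), _SPOIIIAA_MOTIFS),
        Architecture("SpoIIIAB", "SpoIIIAB", (("PLH_SpoIIIAB", 1),)),
        Architecture("SpoIIIAC", "SpoIIIAC", (("PF06686", 1),)),
        Architecture("SpoIIIAD", "SpoIIIAD", (("PF06686", 2),)),
        Architecture("SpoIIIAE", "SpoIIIAE", (("PLH_SpoIIIAE", 1),)),
        Architecture("SpoIIIAF", "SpoIIIAF", (("PF09581", 1),)),
        Architecture("SpoIIIAG", "SpoIIIAG", (("SpoIIIAG_custom", 1),)),
        Architecture("SpoIIIAH", "SpoIIIAH", (("PLH_SpoIIIAH", 1),)),
        Architecture("SpoIIQ", "SpoIIQ", (("M23_peptidase", 1),)),
        Architecture("SpoIID", "SpoIID", (("PLH_SpoIID", 1),)),
        Architecture("SpoIIM", "SpoIIM", (("PLH_SpoIIM", 1),)),
        Architecture("SpoIIP", "SpoIIP", (("PLH_SpoIIP", 1),)),
        Architecture("SpoIIB", "SpoIIB", (("PLH_SpoIIB", 1),)),
        Architecture("GerM", "GerM", (("PF10646", 2),)),
    ]
    if extended:
        for i, acc in enumerate(("PF05621", "PF13401", "PF13191", "PF13481"), start=5):
            regs.append(
                Architecture(f"SpoIIIAA_{i}", "SpoIIIAA", ((acc, 1),), _SPOIIIAA_MOTIFS)
            )
    return regs


def target_proteins(registry: Sequence[Architecture]) -> list[str]:
    seen: list[str] = []
    for arch in registry:
        if arch.target_protein not in seen:
            seen.append(arch.target_protein)
    return seen


def filter_hits(hits: Sequence[DomainHit], e_max: float = 0.001) -> list[DomainHit]:
    """Keep hits with E-value <= ``e_max`` (inclusive boundary), order preserved."""
    if e_max <= 0:
        raise ConfigurationError(f"e_max must be positive, got {e_max}")
    return [h for h in hits if h.evalue <= e_max]


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Collapse overlapping hits on one protein to the longest-spanning one.

    Within each maximal cluster of mutually-overlapping intervals the hit with
    the longest span wins; ties break toward the smaller E-value, then the
    lexicographically smaller profile token. Output is coordinate-sorted and
    is an antichain under interval overlap.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.ali_start, h.ali_end))
    clusters: list[list[DomainHit]] = [[ordered[0]]]
    cluster_end = ordered[0].ali_end
    for h in ordered[1:]:
        if h.ali_start <= cluster_end:  # overlaps the running cluster
            clusters[-1].append(h)
            cluster_end = max(cluster_end, h.ali_end)
        else:
            clusters.append([h])
            cluster_end = h.ali_end
    kept: list[DomainHit] = []
    for cluster in clusters:
        remaining = sorted(cluster, key=lambda h: (-h.span, h.evalue, h.profile))
        while remaining:
            winner = remaining.pop(0)
            kept.append(winner)
            # anything overlapping the winner is discarded; disjoint leftovers
            # (possible in chain-shaped clusters) are resolved recursively
            remaining = [
                h
                for h in remaining
                if h.ali_start > winner.ali_end or h.ali_end < winner.ali_start
            ]
            remaining.sort(key=lambda h: (-h.span, h.evalue, h.profile))
    kept.sort(key=lambda h: h.ali_start)
    return kept


def check_motifs(aa_seq: str, specs: Sequence[MotifSpec]) -> dict[str, bool]:
    """Search each motif pattern anywhere in the full protein sequence."""
    report: dict[str, bool] = {}
    for spec in specs:
        report[spec.name] = bool(spec.compiled().search(aa_seq or ""))
    return report


def _match_components(
    arch: Architecture, hits: Sequence[DomainHit]
) -> Optional[list[DomainHit]]:
    """Greedy in-order matching of architecture components against sorted hits."""
    ordered = sorted(hits, key=lambda h: (h.ali_start, h.ali_end, h.profile))
    used: list[DomainHit] = []
    cursor = 0
    for profile, copies in arch.components:
        found = 0
        while cursor < len(ordered) and found < copies:
            h = ordered[cursor]
            cursor += 1
            if h.profile == profile:
                if used and h.ali_start <= used[-1].ali_end:
                    continue  # tandem copies must not overlap
                used.append(h)
                found += 1
        if found < copies:
            return None
    return used


def detect_architecture(
    gene_hits: Sequence[DomainHit],
    registry: Sequence[Architecture],
    aa_seq: Optional[str] = None,
    motif_config: Mapping[str, MotifSpec] | None = None,
) -> list[ArchitectureCall]:
    """Report every registered architecture matched by one gene's hits.

    ``gene_hits`` must already be E-filtered and overlap-resolved. Alternative
    architectures for the same target (the four SpoIIIAA forms) are all
    reported, each with its own accepted flag after motif checking. A gene
    with no match yields an empty list. Deterministic and invariant to the
    order of ``gene_hits``.
    """
    names = [a.name for a in registry]
    if len(set(names)) != len(names):
        raise ConfigurationError("registry contains duplicate architecture names")
    motifs = dict(DEFAULT_MOTIFS)
    if motif_config:
        motifs.update(motif_config)

    calls: list[ArchitectureCall] = []
    if not gene_hits:
        return calls
    gene_id = gene_hits[0].gene_id
    for arch in registry:
        used = _match_components(arch, gene_hits)
        if used is None:
            continue
        specs = []
        for name in arch.motif_requirements:
            if name not in motifs:
                raise ConfigurationError(f"{arch.name}: unknown motif {name!r}")
            specs.append(motifs[name])
        report = check_motifs(aa_seq or "", specs) if specs else {}
        accepted = all(report[s.name] for s in specs if s.required)
        calls.append(
            ArchitectureCall(
                gene_id=gene_id,
                architecture=arch.name,
                target_protein=arch.target_protein,
                supporting_hits=used,
                motif_report=report,
                accepted=accepted,
            )
        )
    return calls


def _pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Fraction of identical positions over a global pairwise alignment."""
    if not a or not b:
        return 0.0
    aln = aligner.align(a, b)[0]
    ident = sum(
        1
        for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1])
        for i in range(qe - qs)
        if a[qs + i] == b[ts + i]
    )
    return ident / min(len(a), len(b))


def cluster_reduce(
    seqs: Sequence[tuple[str, str]], identity_threshold: float = 0.80
) -> list[str]:
    """Greedy longest-first redundancy reduction (CD-HIT-style).

    Sequences sorted by decreasing length; each joins the first cluster whose
    representative shares >= threshold identity over a global alignment, else
    founds a new cluster. Returns the representatives' ids. Used to prepare
    nonredundant seed sets for custom profile construction (e.g. the 73 -> 27
    SpoIIIAG seeds at 80% identity).
    """
    if not 0 < identity_threshold <= 1:
        raise ConfigurationError("identity_threshold must be in (0, 1]")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    ordered = sorted(seqs, key=lambda item: (-len(item[1]), item[0]))
    reps: list[tuple[str, str]] = []
    for name, seq in ordered:
        for rep_name, rep_seq in reps:
            if _pairwise_identity(seq, rep_seq, aligner) >= identity_threshold:
                break
        else:
            reps.append((name, seq))
    return [name for name, _ in reps]
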