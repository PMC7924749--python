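# Methods

This note documents the models and procedures implemented in `sporesig`,
the defaults they ship with, the numerical choices behind them, and what
the synthetic-data tests do and do not establish about real data.

## Ortholog calling from architectures and genomic context

A *probable ortholog* (PO) of an engulfment protein is a gene that passes
two independent gates.

**Architecture gate.** Domain hits on a protein (from an external profile
scanner in HMMER3 per-domain table format, or from the mock backend in
synthetic runs) are filtered at E ≤ 0.001 — the boundary is inclusive, and
a relaxed E ≤ 0.01 is used only in annotation rescue. Overlapping hits are
resolved per maximal overlap cluster in favour of the longest aligned span,
with ties broken by smaller E-value and then lexicographic profile token;
the canonical example is SpoIIQ, where the M23 peptidase family domain
spans and therefore displaces the RnfC barrel-sandwich domain. The
surviving, coordinate-ordered hits are matched against a registry of 17
architectures covering 14 target proteins: the eight spoIIIA-operon
proteins, SpoIIQ, the DMP complex (SpoIID, SpoIIM, SpoIIP), SpoIIB and
GerM. SpoIIIAA — a P-loop ATPase — is described by four alternative
architectures (NTPase_1 ×1, NTPase_1 tandem, AAA, T2SSE); SpoIIIAD requires
the SpoIIIAC domain in tandem; GerM requires two Germane-domain copies.
Tandem copies must be non-overlapping and colinear; no maximum spacer is
imposed. SpoIIIAA candidates must additionally carry the Walker A and
Walker B motifs and the His and Asp boxes. Motifs are evaluated on the
**whole protein sequence**, not the domain envelope, because profiles
frequently cover only one Walker motif while the remaining motifs sit
outside the matched region. Defaults: Walker A `[AG].{4}GK[ST]`, Walker B
`[ILVFM]{2,4}D[ED]` (the standard P-loop consensi); the His/Asp box
patterns are configurable placeholders (`H.{2,4}H`, `D.{2}[DE].D`) since no
printed consensus is canonical — deployments against real proteomes should
set them from the relevant structural literature. Several profile tokens
in the default registry (prefixed `PLH_`) are likewise placeholders to be
replaced with the exact Pfam accessions used by a given scanner run; all
of this lives in editable configuration, not code.

**Context gate.** For each target the neighborhoods — up to three genes on
either side of every architecture-bearing candidate, by genomic coordinate
order (a strand-relative mode exists; operonic neighbors are co-oriented so
the two agree where it matters) — are pooled **across all genomes**, and
every KO label is counted once per gene occurrence. KOs with ≥ 8
occurrences are the representative contextual KOs (RCKOs). A candidate is
accepted iff at least one neighbor carries an RCKO and at least one
neighbor carries any KO at all; a candidate whose entire neighborhood is
KO-less is *dismissed* (context undefined) rather than rejected on
evidence. The focal gene's own KO is recorded but never required. Accepted
POs fill a binary species × protein matrix; repeated paralogous hits never
raise a cell above 1, and the Spo0A column — a stage-0 sporulation marker
predicted by other means — is imported verbatim, never computed here.

## Per-genus signatures and the checkerboard score

For each genus with ≥ 2 confirmed spore formers the Stone–Roberts
checkerboard score is computed over the genus submatrix with **species as
rows**:

C = 2/(R(R−1)) · Σ_{i<j} (r_i − S_ij)(r_j − S_ij),

where r_i is species i's protein count and S_ij the number of proteins
shared by species i and j. C = 0 iff every species pair is nested or
identical in content; checkerboard pairs (each species has a protein the
other lacks) raise it. The species-rows orientation is a deliberate
calibration: on a five-species genus in which one member lacks
SpoIIIAA+SpoIID and two others lack GerM it yields C = 0.4 (the published
per-genus value for that pattern), whereas the transposed orientation gives
≈ 0.04. A flag flips the orientation for sensitivity analyses. The raw
score is not normalised, matching the published 0 / 0.1 / 0.4 / 1 scale.
All-zero protein columns are retained.

Significance is a fixed threshold on the **observed** score — C ≤ 0.2 with
n ≥ 2 — not a permutation p-value; the fixed-margins swap null is computed
and reported alongside (mean, sd, one-sided P(null ≤ observed)) but does
not gate the call. The null ("sim9") is a sequential-swap Markov chain over
2×2 checkerboard submatrices, which preserves all row and column sums
exactly; defaults are a burn-in of 10×(#ones) attempted swaps and one
retained sample per (#ones) attempts, with a mandatory seed. A matrix with
no swappable unit yields a degenerate (constant) null, reported as such.

The signature of a significant genus is the set of proteins present in
≥ 95% of its members. The 0.95 default is chosen so that a protein absent
from roughly one member in ten is excluded while a protein absent from one
member in twenty or more is kept — the regime the published genus tables
occupy. Singleton genera are reported without a signature. Phenotype
prediction for inferred/unknown species is strict set-containment: a
species consistent with sporulation possesses *every* signature protein;
missing any one predicts a nonsporulating phenotype; genera without a
significant signature give no call.

## Annotation rescue

Intergenic gaps ≥ `min_gap` (default 200 nt — no published value exists;
the shortest spoIIIA genes run ≈ 100 codons and fragments matter, so the
default errs low and is configurable) are translated in all six frames
(plain standard-code translation, stops as `*`, N-codons as X, no
start-codon requirement — the scanned unit is the whole frame). Frames are
scanned through the pluggable profile backend at E ≤ 0.01, architecture
detection is reused unchanged, SpoIIIAA candidates are motif-gated on the
translated frame, and context support is the RCKOs carried by up to three
annotated genes on each side of the gap. An external best-BLAST-hit
criterion used in manual curation is replaced by this architecture + motif
+ RCKO gate, with a hook for externally computed best-hit labels. Rescue
never modifies the input annotation; outputs are additive.

## Species selection, BDBH and the mega-alignment

Within each taxonomic family, one species is kept per distinct phyletic
profile (ties to the lexicographically smallest species id). Orthology
between selected proteomes is reciprocal best hits with E < 1e-4 (strict)
and an aligned region covering ≥ 50% of the shorter protein, computed from
a pluggable pairwise-scoring backend (a built-in global-alignment scorer
with a monotone pseudo-E-value serves tests and examples; real runs plug in
an external aligner's table). Multi-species groups are single-linkage
components of the accepted pair graph with a one-gene-per-species cap —
conflicts keep the gene with the best mean pair E-value; this clique
relaxation is the standard BDBH extension and is a documented choice, not a
published rule. Groups in ≥ 90% of organisms are aligned per group, missing
species are dash-padded, columns with < 90% informative positions
("informative" = non-gap residue) are removed, and the filtered blocks are
concatenated with a partition map. Maximum-likelihood tree inference is out
of scope: the mega-alignment is exported in FASTA/relaxed-PHYLIP for
external tools, and the in-package neighbor-joining tree (scikit-bio) is a
deterministic test-scale fallback only.

## Gain/loss mapping

Presence/absence of each protein evolves as a two-state continuous-time
Markov chain with gain rate g (0→1) and loss rate l (1→0), shared across
characters — a deliberate single-rate simplification of mixture-model
machinery with gamma rate variation, which is out of scope; for this reason
no published per-quartile event totals are reproduced, and the engine is
validated by properties (exact pruning likelihood, parsimony lower bounds,
simulation recovery) instead. The root prior defaults to the stationary
distribution (π₁ = g/(g+l)) and can be set to (½, ½). Rates are estimated
by maximising the pruning-algorithm log-likelihood with L-BFGS-B in
log-rate space, box [-7, 4] in ln units, from three fixed starting points
(0.1/0.1, 1/1, 0.5/2) — deterministic given the data. All-absent data is
rejected as unidentifiable; estimates pinned at the box are flagged.

Per-branch expected gains and losses come from stochastic mapping: node
states are drawn top-down from the pruning partials, then each branch's
path is sampled conditional on its endpoints by rejection from forward
simulation (500 attempts; on exhaustion — only plausible at extreme
rate×length — the minimal consistent history is used). Every sampled
history's event count is ≥ the Fitch small-parsimony minimum, which the
tests enforce. Branches are binned by root distance measured to the
branch's **child node** (a midpoint mode exists; which convention published
figures used is not stated) into quartiles at the 25/50/75 percentiles,
ties to the lower bin, so equal distances all land in q1; quartile sums
conserve per-character totals exactly.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth for every stage: a 4-class / 8-family /
16-genus / 64-species taxonomy (desk scale; the full chain runs in seconds),
per-genus signatures drawn from the 15-protein universe (14 targets +
Spo0A), operon-like blocks in which each planted ortholog carries a valid
architecture and one RCKO neighbor among three up/downstream genes, decoys
violating exactly one rule each, optional hidden genes whose CDS remains in
intergenic DNA, and characters simulated under known (g, l) with per-branch
event counts recorded. Junk neighbor KOs are globally unique so they can
never reach the RCKO cutoff by collision; two genera are planted with
segregated (checkerboard) profiles and must not be called significant.
Protein sequences are motif templates in random background and domain-hit
tables are written directly — the profile-backend interface is mocked with
a substring lookup, so the suite exercises every decision rule but says
nothing about profile-HMM sensitivity, alignment quality, real sequence
composition, or KO annotation error rates on real genomes. Acceptance
checks that need real curated data (the 954-species compendium statistics)
run only when that supplement is supplied under `data/`.

Problem sizes used by the test suite and the acceptance script: the
64-species bundle for ortholog/signature/rescue checks; 6×8 random matrices
(100 draws) against the brute-force C-score oracle; ≤ 6-tip trees for exact
likelihood enumeration; a 32-tip balanced tree with 500 characters for rate
recovery (observed relative errors are a few percent, against a ±25%
acceptance band); 20-character stochastic mapping for the parsimony bound
and quartile conservation.

## Known limitations

* Profile scanning, BLAST, MUSCLE/MAFFT alignment and ML tree inference are
  integration points, not reimplementations; the package validates the
  decision logic around them.
* The His/Asp box defaults and the placeholder Pfam tokens must be
  configured before use on real proteomes.
* RCKO selection pools neighborhoods across all genomes; a per-clade mode
  is not implemented.
* The gain/loss model is single-rate; rate variation across characters or
  branches, HGT-vs-duplication discrimination, and ancestral-state
  uncertainty beyond the sampled maps are out of scope.
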