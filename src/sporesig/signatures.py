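"""Per-genus checkerboard analysis of phyletic profiles and phenotype calls.

The Stone–Roberts checkerboard score (C-score) of a binary matrix is the
mean, over all pairs of rows, of ``(r_i - S_ij)(r_j - S_ij)`` where ``r_i``
is row i's total and ``S_ij`` the number of columns where both rows are 1.
It is 0 when every row pair is nested or identical in support (maximal
aggregation) and grows with segregation. Applied to one genus at a time
— species as rows, proteins as columns — a low C-score means the genus's
confirmed spore formers share an aggregated profile, and the proteins present
in (almost) every member constitute that genus's *phyletic profile
signature*. Significance here is a threshold on the observed score
(C <= 0.2 with >= 2 species); a fixed-margins swap null ("sim9") is computed
and reported alongside but does not gate the call.

Orientation note: species-as-rows is the default because it is the
orientation under which the published per-genus scores (e.g. a 5-species
Desulfitobacterium genus scoring 0.4) are reproduced; a flag flips it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .context import PhyleticMatrix
from .io_formats import Taxonomy

CONSISTENT = "consistent_sporulating"
DEVIATES = "deviates_nonsporulating"
NO_CALL = "no_call"


@dataclass
class SignatureResult:
    genus: str
    n_species: int
    c_score: Optional[float]
    significant: bool
    signature_set: frozenset[str]
    null_summary: Optional[tuple[float, float, float]] = None  # (mean, sd, p)

    def signature_string(self) -> str:
        """Compact field notation, e.g. ``Spo0A-Q:AH-DMP-SpoIIB-GerM``."""
        return compact_signature(self.signature_set)


_QAH = [
    "SpoIIIAA", "SpoIIIAB", "SpoIIIAC", "SpoIIIAD",
    "SpoIIIAE", "SpoIIIAF", "SpoIIIAG", "SpoIIIAH", "SpoIIQ",
]
_DMP = {"D": "SpoIID", "M": "SpoIIM", "P": "SpoIIP"}


def compact_signature(proteins: frozenset[str] | set[str]) -> str:
    """Render a protein set in the compact Q:AH / DMP shorthand."""
    parts: list[str] = []
    rest = set(proteins)
    if "Spo0A" in rest:
        parts.append("Spo0A")
        rest.discard("Spo0A")
    if all(p in rest for p in _QAH):
        parts.append("Q:AH")
        rest.difference_update(_QAH)
    dmp = "".join(letter for letter, name in _DMP.items() if name in rest)
    if dmp:
        parts.append(dmp)
        rest.difference_update(_DMP[l] for l in dmp)
    for p in sorted(rest):
        parts.append(p)
    return "-".join(parts) if parts else "(none)"


def c_score(matrix) -> float:
    """Stone–Roberts C-score over the rows of a binary matrix.

    ``matrix`` is anything ``np.asarray`` accepts with {0,1} entries and at
    least two rows. Exact up to float arithmetic (all quantities are small
    integers divided by the pair count).
    """
    m = np.asarray(matrix, dtype=int)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("C-score needs a 2-D matrix with >= 2 rows")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("C-score input must be binary")
    r = m.sum(axis=1)
    shared = m @ m.T  # S_ij
    diff = r[:, None] - shared
    prod = diff * diff.T
    iu = np.triu_indices(m.shape[0], k=1)
    n_pairs = len(iu[0])
    return float(prod[iu].sum() / n_pairs)


def sim9_swap_null(
    matrix,
    n_samples: int,
    burn_in: Optional[int] = None,
    rng_seed: int = 0,
    thin: Optional[int] = None,
    return_matrices: bool = False,
) -> list[float] | tuple[list[float], list[np.ndarray]]:
    """C-scores sampled from the fixed-margins (sim9) swap chain.

    A sequential-swap Markov chain over 2x2 checkerboard submatrices
    (``[[1,0],[0,1]] <-> [[0,1],[1,0]]``); every visited matrix preserves all
    row and column sums exactly. Defaults: ``burn_in`` = 10 x (#ones)
    attempted swaps, one retained sample per (#ones) attempts. A matrix with
    no swappable unit yields a degenerate distribution (all samples equal the
    observed score). Reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    m = np.asarray(matrix, dtype=int).copy()
    n_ones = max(1, int(m.sum()))
    burn = 10 * n_ones if burn_in is None else burn_in
    step = n_ones if thin is None else thin
    rng = np.random.default_rng(rng_seed)
    R, C = m.shape

    def attempt_swap() -> None:
        if R < 2 or C < 2:
            return
        i, j = rng.choice(R, size=2, replace=False)
        a, b = rng.choice(C, size=2, replace=False)
        sub = m[np.ix_((i, j), (a, b))]
        if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
            m[np.ix_((i, j), (a, b))] = sub[:, ::-1]

    for _ in range(burn):
        attempt_swap()
    samples: list[float] = []
    matrices: list[np.ndarray] = []
    for _ in range(n_samples):
        for _ in range(step):
            attempt_swap()
        samples.append(c_score(m))
        if return_matrices:
            matrices.append(m.copy())
    return (samples, matrices) if return_matrices else samples


def call_signatures(
    matrix: PhyleticMatrix,
    taxonomy: Mapping[str, Taxonomy] | Sequence[Taxonomy] | None = None,
    threshold: float = 0.2,
    min_species: int = 2,
    prevalence: float = 0.95,
    sporulating_only: bool = True,
    orientation: str = "species_rows",
    n_null: int = 0,
    rng_seed: int = 0,
    include_spo0a: bool = True,
) -> list[SignatureResult]:
    """One SignatureResult per genus of the phyletic matrix.

    Only confirmed-sporulating species enter the genus matrices by default.
    A genus is significant iff its observed C-score <= ``threshold`` and it
    has >= ``min_species`` members; its signature set is the proteins present
    in >= ``prevalence`` of its species. Singleton genera are reported with
    ``significant=False`` and an empty signature. With ``n_null`` > 0 the
    sim9 null mean/sd and the one-sided p-value P(null <= observed) are
    attached.
    """
    if taxonomy is None:
        tax_map = matrix.taxonomy
    elif isinstance(taxonomy, Mapping):
        tax_map = dict(taxonomy)
    else:
        tax_map = {t.species_id: t for t in taxonomy}

    df = matrix.df
    if not include_spo0a and "Spo0A" in df.columns:
        df = df.drop(columns=["Spo0A"])
    species = list(df.index)
    if sporulating_only:
        species = [s for s in species if matrix.phenotype.get(s) == "sporulating"]

    by_genus: dict[str, list[str]] = {}
    for s in species:
        if s not in tax_map:
            raise KeyError(f"species {s!r} missing from taxonomy")
        by_genus.setdefault(tax_map[s].genus, []).append(s)

    results: list[SignatureResult] = []
    for genus in sorted(by_genus):
        members = sorted(by_genus[genus])
        sub = df.loc[members]
        if len(members) < max(2, min_species):
            results.append(
                SignatureResult(genus, len(members), None, False, frozenset())
            )
            continue
        data = sub.values if orientation == "species_rows" else sub.values.T
        score = c_score(data)
        significant = score <= threshold
        sig: frozenset[str] = frozenset()
        if significant:
            prev = sub.mean(axis=0)
            sig = frozenset(prev.index[prev >= prevalence])
        null_summary = None
        if n_null > 0:
            samples = sim9_swap_null(data, n_null, rng_seed=rng_seed)
            arr = np.asarray(samples)
            p = float((arr <= score).mean())
            null_summary = (float(arr.mean()), float(arr.std()), p)
        results.append(
            SignatureResult(genus, len(members), score, significant, sig, null_summary)
        )
    return results


def predict_phenotype(profile: Mapping[str, int], signature: SignatureResult) -> str:
    """Judge one species' profile against its genus signature.

    ``consistent_sporulating`` iff the species possesses every signature
    protein; ``deviates_nonsporulating`` otherwise; ``no_call`` when the
    genus has no significant signature.
    """
    if not signature.significant or not signature.signature_set:
        return NO_CALL
    if all(profile.get(p, 0) == 1 for p in signature.signature_set):
        return CONSISTENT
    return DEVIATES


def signatures_to_tsv(results: Sequence[SignatureResult], taxonomy, path) -> None:
    """Export genus results in the published table layout."""
    if isinstance(taxonomy, Mapping):
        genus_class = {t.genus: t.class_ for t in taxonomy.values()}
    else:
        genus_class = {t.genus: t.class_ for t in taxonomy}
    rows = []
    for r in results:
        rows.append(
            {
                "genus": r.genus,
                "class": genus_class.get(r.genus, "unknown"),
                "n_species": r.n_species,
                "c_score": "" if r.c_score is None else round(r.c_score, 3),
                "signature": r.signature_string() if r.significant else "Not significant",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
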