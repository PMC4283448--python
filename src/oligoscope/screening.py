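"""Checkerboard / togetherness screening of oligotype occurrence matrices.

For every pair of oligotypes within an OTU, the checkerboard score
C_ij = (r_i − S_ij)(r_j − S_ij) counts 2×2 mutually-exclusive site
sub-matrices and the togetherness score T_ij = S_ij · A_ij counts
jointly-present × jointly-absent site pairs (r = occupied sites,
S = shared presences, A = shared absences).  OTUs whose mean C and mean T
both strictly exceed the third quartile of the respective score
distribution across all OTUs are flagged as carrying 'resolving'
oligotypes.  Both scores are computed on presence/absence only.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from oligoscope.oligotyping import OligotypeTable
from oligoscope.ordination import hellinger


class UndefinedScoreError(ValueError):
    """Raised when a score needs at least two oligotype rows."""


@dataclass(frozen=True)
class PairOccurrence:
    """Presence/absence summary of one oligotype pair across sites."""

    r_i: int
    r_j: int
    s_ij: int
    a_ij: int
    n_sites: int

    def __post_init__(self) -> None:
        if min(self.r_i, self.r_j, self.s_ij, self.a_ij, self.n_sites) < 0:
            raise ValueError("all occurrence counts must be non-negative")
        if self.s_ij > min(self.r_i, self.r_j):
            raise ValueError("shared presences exceed an occupancy count")
        if self.a_ij > self.n_sites - max(self.r_i, self.r_j):
            raise ValueError("shared absences exceed the possible maximum")

    @classmethod
    def from_vectors(cls, x, y) -> "PairOccurrence":
        x = np.asarray(x) > 0
        y = np.asarray(y) > 0
        if x.shape != y.shape:
            raise ValueError("presence vectors must share a site set")
        return cls(
            r_i=int(x.sum()),
            r_j=int(y.sum()),
            s_ij=int((x & y).sum()),
            a_ij=int((~x & ~y).sum()),
            n_sites=int(x.size),
        )


def pair_c_score(p: PairOccurrence) -> int:
    """Checkerboard units for one pair: (r_i − S)(r_j − S)."""
    return (p.r_i - p.s_ij) * (p.r_j - p.s_ij)


def pair_t_score(p: PairOccurrence) -> int:
    """Togetherness units for one pair: S · A."""
    return p.s_ij * p.a_ij


def mean_scores(table: OligotypeTable | pd.DataFrame) -> tuple[float, float]:
    """Mean C and T score over all unordered oligotype pairs of one matrix.

    Presence is ``count > 0``; scores are raw (unnormalised) unit counts.
    Requires at least two rows.
    """
    counts = table.counts if isinstance(table, OligotypeTable) else table
    presence = (counts.to_numpy() > 0).astype(int)
    n = presence.shape[0]
    if n < 2:
        raise UndefinedScoreError("mean C/T scores need at least 2 oligotypes")
    r = presence.sum(axis=1)
    shared = presence @ presence.T  # S_ij
    both_absent = (1 - presence) @ (1 - presence).T  # A_ij
    iu = np.triu_indices(n, k=1)
    c = (r[:, None] - shared) * (r[None, :] - shared)
    t = shared * both_absent
    return float(c[iu].mean()), float(t[iu].mean())


def screen_by_quartile(
    scores: pd.DataFrame, c_col: str = "mean_c", t_col: str = "mean_t"
) -> tuple[list[str], float, float]:
    """Select OTUs whose mean C and T both strictly exceed the third quartile.

    ``scores`` is one row per OTU (index = OTU id).  Quartiles use linear
    interpolation.  Returns (selected OTU ids, Q3 of C, Q3 of T).
    """
    if scores.shape[0] < 4:
        raise ValueError("quartile screening needs at least 4 OTUs")
    q3_c = float(np.percentile(scores[c_col], 75))
    q3_t = float(np.percentile(scores[t_col], 75))
    sel = scores[(scores[c_col] > q3_c) & (scores[t_col] > q3_t)]
    return list(sel.index), q3_c, q3_t


def screening_report(
    tables_by_otu: dict[str, OligotypeTable],
    meta_by_otu: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Per-OTU screening table: taxonomy, n oligotypes, mean C, mean T.

    OTUs with fewer than two oligotypes cannot be scored and are omitted.
    """
    rows = []
    for otu, tab in tables_by_otu.items():
        if tab.n_oligotypes < 2:
            continue
        c, t = mean_scores(tab)
        m = (meta_by_otu or {}).get(otu, {})
        rows.append(
            {
                "otu_id": otu,
                "phylum": m.get("phylum", "-"),
                "class": m.get("class", "-"),
                "n_oligotypes": tab.n_oligotypes,
                "mean_c": round(c, 2),
                "mean_t": round(t, 2),
            }
        )
    return pd.DataFrame(rows).set_index("otu_id") if rows else pd.DataFrame(
        columns=["phylum", "class", "n_oligotypes", "mean_c", "mean_t"]
    )


def order_rows(table: OligotypeTable | pd.DataFrame) -> np.ndarray:
    """Row permutation for heatmap display.

    Rows are Hellinger-transformed, pairwise Bray–Curtis dissimilarities are
    computed, and the UPGMA (average-linkage) dendrogram leaf order is
    returned as an index permutation.
    """
    counts = table.counts if isinstance(table, OligotypeTable) else table
    x = hellinger(counts.to_numpy(float))
    n = x.shape[0]
    if n < 2:
        return np.arange(n)
    d = pdist(x, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero rows compare as identical
    return np.asarray(leaves_list(linkage(d, method="average")))
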