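"""Entropy-based decomposition of OTU alignments into oligotypes.

An OTU's aligned reads are recursively split at the alignment position with
the greatest Shannon entropy (base 2, over the characters ``A C G T -``).
A split is performed only while the group holds at least
``min_reads_for_round`` sequences and its maximum column entropy strictly
exceeds ``min_entropy``; terminal groups are the oligotypes, labelled by the
concatenated characters at the discriminant positions along their path.

Two alignment characters are distinguished throughout: ``-`` is an internal
gap, a legitimate oligotype character, while ``.`` marks missing terminal
coverage.  ``.`` is excluded from entropy frequencies, and a read carrying
``.`` at a discriminant position cannot be assigned a character there and is
set aside (see :func:`drop_incomplete`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Characters that participate in entropy computation and oligotype labels.
ALPHABET = ("A", "C", "G", "T", "-")
#: Missing-coverage marker, never part of an oligotype label.
MISSING = "."


class UndefinedEntropyError(ValueError):
    """Raised when a column holds no informative (non-missing) characters."""


class OTUTooSmallError(ValueError):
    """Raised when an OTU has too few reads to be oligotyped."""


class LabelingError(KeyError):
    """Raised when a read's site label is not in the requested site order."""


@dataclass
class AlignedReadSet:
    """Per-OTU gapped alignment with per-read sample labels.

    Parameters
    ----------
    otu_id : str
        OTU identifier.
    reads : ndarray of shape (n_reads, n_positions), dtype ``<U1``
        Character matrix over ``{A, C, G, T, -, .}``.
    site_of_read : ndarray of str, length n_reads
        Sampling-site label of each read.
    read_ids : ndarray of str, optional
        Stable per-read identifiers; generated if omitted.
    taxonomy : dict, optional
        Lineage fields, e.g. ``{"phylum": ..., "class": ..., "order": ...}``.
    """

    otu_id: str
    reads: np.ndarray
    site_of_read: np.ndarray
    read_ids: np.ndarray | None = None
    taxonomy: dict | None = None

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype="<U1")
        if self.reads.ndim != 2:
            raise ValueError("reads must be a 2-D character matrix")
        self.site_of_read = np.asarray(self.site_of_read)
        if self.site_of_read.shape[0] != self.reads.shape[0]:
            raise ValueError("site_of_read length must match number of reads")
        if self.read_ids is None:
            self.read_ids = np.array(
                [f"{self.otu_id}|{s}|{i}" for i, s in enumerate(self.site_of_read)]
            )

    @property
    def n_reads(self) -> int:
        return self.reads.shape[0]

    @property
    def length(self) -> int:
        return self.reads.shape[1]


@dataclass(frozen=True)
class OligotypingParams:
    """Thresholds steering the recursive decomposition.

    ``min_reads_for_round`` and ``min_entropy`` gate each round (a group is
    split only if it holds at least ``min_reads_for_round`` sequences AND its
    maximum column entropy strictly exceeds ``min_entropy`` bits);
    ``min_otu_reads`` gates whole OTUs (strictly more reads required).
    """

    min_reads_for_round: int = 21
    min_entropy: float = 0.6
    min_otu_reads: int = 100

    def __post_init__(self) -> None:
        if self.min_reads_for_round < 1 or self.min_otu_reads < 1:
            raise ValueError("count thresholds must be positive")
        if not 0.0 < self.min_entropy <= np.log2(6):
            raise ValueError("min_entropy must be in (0, log2 6]")


@dataclass
class Oligotype:
    """A terminal read group of the decomposition."""

    otu_id: str
    label: str
    positions: tuple[int, ...]
    read_indices: np.ndarray
    site_of_read: np.ndarray
    incomplete_derived: bool = False
    taxonomy: dict | None = None

    @property
    def n_reads(self) -> int:
        return self.read_indices.size

    @property
    def qualified_label(self) -> str:
        return f"{self.otu_id}:{self.label}" if self.label else f"{self.otu_id}:*"


@dataclass
class OligotypeTable:
    """Oligotype × site read-count matrix with per-row metadata.

    ``counts`` is indexed by qualified oligotype labels
    (``<otu>:<characters>``) with one column per site; ``meta`` shares the
    index and carries the parent OTU, the plain label, the discriminant
    positions and optional taxonomy fields.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share an index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_oligotypes(self) -> int:
        return self.counts.shape[0]

    @property
    def sites(self) -> list[str]:
        return list(self.counts.columns)

    def for_otu(self, otu_id: str) -> "OligotypeTable":
        mask = self.meta["otu_id"] == otu_id
        return OligotypeTable(self.counts.loc[mask], self.meta.loc[mask])

    @staticmethod
    def concat(tables: list["OligotypeTable"]) -> "OligotypeTable":
        if not tables:
            return OligotypeTable(pd.DataFrame(), pd.DataFrame())
        return OligotypeTable(
            pd.concat([t.counts for t in tables]),
            pd.concat([t.meta for t in tables]),
        )


# ---------------------------------------------------------------------------
# column statistics


def _char_counts(column: np.ndarray) -> np.ndarray:
    column = np.asarray(column, dtype="<U1")
    return np.array([(column == c).sum() for c in ALPHABET], dtype=float)


def column_entropy(column) -> float:
    """Shannon entropy (bits) of one alignment column.

    Missing-coverage characters (``.``) are excluded before frequencies are
    formed; the entropy is computed over ``{A, C, G, T, -}`` in log base 2,
    so it is 0 for monomorphic columns and at most log2(5).
    """
    counts = _char_counts(np.asarray(column))
    total = counts.sum()
    if total == 0:
        raise UndefinedEntropyError("column has no non-missing characters")
    freqs = counts[counts > 0] / total
    return float(-(freqs * np.log2(freqs)).sum())


def dominant_fraction(column) -> float:
    """Percent occurrence of the dominant character in a column.

    Returns ``100 * max(count) / total`` over non-missing characters.
    """
    counts = _char_counts(np.asarray(column))
    total = counts.sum()
    if total == 0:
        raise UndefinedEntropyError("column has no non-missing characters")
    return float(100.0 * counts.max() / total)


def _matrix_entropies(reads: np.ndarray) -> np.ndarray:
    """Column entropies for a read matrix; empty columns yield 0."""
    n_pos = reads.shape[1]
    counts = np.empty((len(ALPHABET), n_pos))
    for k, c in enumerate(ALPHABET):
        counts[k] = (reads == c).sum(axis=0)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
        terms = np.where(freqs > 0, -freqs * np.log2(freqs), 0.0)
    return terms.sum(axis=0)


def max_entropy_position(alignment: np.ndarray) -> tuple[int, float]:
    """Leftmost alignment position attaining the maximum column entropy."""
    alignment = np.asarray(alignment, dtype="<U1")
    if alignment.size == 0:
        raise ValueError("empty alignment")
    ent = _matrix_entropies(alignment)
    pos = int(np.argmax(ent))  # argmax returns the leftmost maximum
    return pos, float(ent[pos])


# ---------------------------------------------------------------------------
# recursive decomposition


@dataclass
class DecompositionLog:
    """Per-OTU record of the rounds performed."""

    otu_id: str
    rounds: list[dict] = field(default_factory=list)
    n_reads_in: int = 0
    n_reads_retained: int = 0
    n_reads_incomplete: int = 0


def decompose(
    reads: AlignedReadSet, params: OligotypingParams | None = None
) -> tuple[list[Oligotype], DecompositionLog]:
    """Decompose an OTU alignment into oligotypes.

    Recursion: while a group holds at least ``params.min_reads_for_round``
    sequences and a position with entropy > ``params.min_entropy`` exists,
    the group is split by character at the (leftmost) maximum-entropy
    position and each subgroup is recursed on.  Reads with ``.`` at a chosen
    position cannot be assigned and are set aside; every descendant
    oligotype of such a split is flagged ``incomplete_derived``.

    Raises
    ------
    OTUTooSmallError
        If the OTU holds ``min_otu_reads`` reads or fewer.
    """
    if params is None:
        params = OligotypingParams()
    if reads.n_reads <= params.min_otu_reads:
        raise OTUTooSmallError(
            f"OTU {reads.otu_id}: {reads.n_reads} reads "
            f"(> {params.min_otu_reads} required)"
        )
    log = DecompositionLog(otu_id=reads.otu_id, n_reads_in=reads.n_reads)
    oligotypes: list[Oligotype] = []
    # stack entries: (read index array, label-so-far, positions, incomplete flag)
    stack: list[tuple[np.ndarray, str, tuple[int, ...], bool]] = [
        (np.arange(reads.n_reads), "", (), False)
    ]
    while stack:
        idx, label, positions, flagged = stack.pop()
        if idx.size == 0:
            continue
        sub = reads.reads[idx]
        split = False
        if idx.size >= params.min_reads_for_round:
            pos, ent = max_entropy_position(sub)
            if ent > params.min_entropy:
                split = True
                log.rounds.append(
                    {
                        "label": label,
                        "position": int(pos),
                        "entropy": float(ent),
                        "n_reads": int(idx.size),
                    }
                )
                col = sub[:, pos]
                incomplete = idx[col == MISSING]
                child_flag = flagged or incomplete.size > 0
                log.n_reads_incomplete += int(incomplete.size)
                for c in ALPHABET:
                    child = idx[col == c]
                    if child.size:
                        stack.append(
                            (child, label + c, positions + (pos,), child_flag)
                        )
        if not split:
            oligotypes.append(
                Oligotype(
                    otu_id=reads.otu_id,
                    label=label,
                    positions=positions,
                    read_indices=idx,
                    site_of_read=reads.site_of_read[idx],
                    incomplete_derived=flagged,
                    taxonomy=reads.taxonomy,
                )
            )
    # deterministic order: by first discriminant characters, root group last
    oligotypes.sort(key=lambda o: (len(o.label) == 0, o.label))
    log.n_reads_retained = int(sum(o.n_reads for o in oligotypes))
    return oligotypes, log


def drop_incomplete(
    oligotypes: list[Oligotype],
    site_of_all_reads: np.ndarray | None = None,
    policy: str = "retain_complete",
) -> tuple[list[Oligotype], pd.Series | None]:
    """Apply the incomplete-alignment removal rule.

    With ``policy="retain_complete"`` (default) an oligotype survives as long
    as it holds at least one read with concrete characters at every
    discriminant position — reads with ``.`` there were already set aside
    during :func:`decompose`.  With ``policy="drop_oligotype"`` any oligotype
    descending from a split that set reads aside is removed wholly.

    Returns the surviving oligotypes and, when ``site_of_all_reads`` is
    given, the per-site retained-read fraction (retained / total reads of
    the OTU at that site).
    """
    if policy not in ("retain_complete", "drop_oligotype"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "retain_complete":
        kept = [o for o in oligotypes if o.n_reads > 0]
    else:
        kept = [o for o in oligotypes if o.n_reads > 0 and not o.incomplete_derived]
    fill = None
    if site_of_all_reads is not None:
        total = pd.Series(site_of_all_reads).value_counts()
        retained = pd.Series(
            np.concatenate([o.site_of_read for o in kept])
            if kept
            else np.array([], dtype=total.index.dtype)
        ).value_counts()
        fill = (retained.reindex(total.index, fill_value=0) / total).sort_index()
    return kept, fill


# ---------------------------------------------------------------------------
# tabulation

#: Column order used for the two-transect sampling design: bathymetric
#: stations shallowest→deepest, then latitudinal stations north→south.
CANONICAL_SITE_ORDER = (
    "HGI",
    "HGII",
    "HGIII",
    "HGIV",
    "HGV",
    "HGVI",
    "N4",
    "N3",
    "N2",
    "N1",
    "S1",
    "S2",
    "S3",
)


def canonical_site_order(sites) -> list[str]:
    """Order site labels along the transects where recognised, else sorted."""
    sites = list(sites)
    known = [s for s in CANONICAL_SITE_ORDER if s in sites]
    rest = sorted(s for s in sites if s not in CANONICAL_SITE_ORDER)
    return known + rest


def tabulate(oligotypes: list[Oligotype], site_order=None) -> OligotypeTable:
    """Build the oligotype × site count matrix.

    ``site_order`` fixes the column order and must cover every read label;
    by default the transect order of :data:`CANONICAL_SITE_ORDER` is used
    for recognised labels.
    """
    if not oligotypes:
        cols = list(site_order) if site_order is not None else []
        return OligotypeTable(
            pd.DataFrame(columns=cols, dtype=int),
            pd.DataFrame(columns=["otu_id", "label", "positions"]),
        )
    observed = sorted({s for o in oligotypes for s in o.site_of_read})
    if site_order is None:
        site_order = canonical_site_order(observed)
    else:
        site_order = list(site_order)
        unknown = set(observed) - set(site_order)
        if unknown:
            raise LabelingError(f"site labels not in site order: {sorted(unknown)}")
    rows, meta_rows, index = [], [], []
    for o in oligotypes:
        vc = pd.Series(o.site_of_read).value_counts()
        rows.append(vc.reindex(site_order, fill_value=0).astype(int))
        index.append(o.qualified_label)
        m = {
            "otu_id": o.otu_id,
            "label": o.label,
            "positions": ",".join(map(str, o.positions)),
        }
        if o.taxonomy:
            m.update(o.taxonomy)
        meta_rows.append(m)
    counts = pd.DataFrame(rows, index=index)
    counts.columns.name = "site"
    return OligotypeTable(counts, pd.DataFrame(meta_rows, index=index))


def remove_singletons(table: OligotypeTable) -> tuple[OligotypeTable, int]:
    """Remove absolute singletons (rows with total read count ≤ 1).

    Returns the filtered table and the number of rows removed.
    """
    if table.n_oligotypes == 0:
        return table, 0
    keep = table.counts.sum(axis=1) > 1
    removed = int((~keep).sum())
    return OligotypeTable(table.counts.loc[keep], table.meta.loc[keep]), removed
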