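"""miRNA-target interaction tables.

An :class:`InteractionSet` is a bipartite incidence between miRNAs and genes
(lncRNAs or mRNAs), each interaction carrying an evidence label
(``predicted`` or ``supported``).  The per-gene miRNA sets are the substrate
of the shared-miRNA hypergeometric test: the miRNA universe size N, and the
per-gene set sizes K (lncRNA) and M (mRNA).

Evidence filtering mirrors the common ceRNA workflow in which predicted
miRNA-lncRNA interactions are intersected with AGO-CLIP support (encoded
here as ``evidence == supported``) while curated miRNA-mRNA interactions
are accepted with either label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "mRNA")
EVIDENCE_LEVELS = ("predicted", "supported")

#: Default classes whose interactions require experimental support.
DEFAULT_FILTER_CLASSES = frozenset({"lncRNA"})

_CLASS_NORM = {c.lower(): c for c in GENE_CLASSES}
_EVIDENCE_NORM = {e.lower(): e for e in EVIDENCE_LEVELS}


@dataclass(frozen=True)
class InteractionSet:
    """Deduplicated miRNA-gene interactions with evidence labels.

    Parameters
    ----------
    table
        One row per (miRNA, gene) interaction with columns
        ``mirna_id, gene_id, gene_class, evidence``.
    """

    table: pd.DataFrame
    _sets: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["mirna_id", "gene_id"])
        if dup.any():
            raise ValueError("duplicate (miRNA, gene) records in InteractionSet")
        classes = self.table.groupby("gene_id")["gene_class"].nunique()
        multi = classes[classes > 1]
        if len(multi):
            raise ValueError(
                f"genes with more than one gene_class: {sorted(multi.index)[:5]}"
            )

    @property
    def universe(self) -> frozenset:
        """All distinct miRNA ids present (N of the hypergeometric test)."""
        return frozenset(self.table["mirna_id"])

    @property
    def n_mirnas(self) -> int:
        return len(self.universe)

    def genes(self, gene_class: str) -> list:
        cls = normalize_gene_class(gene_class)
        mask = self.table["gene_class"] == cls
        return sorted(self.table.loc[mask, "gene_id"].unique())

    def mirna_sets(self, gene_class: str) -> dict:
        """Map gene id -> frozenset of interacting miRNA ids, for one class."""
        cls = normalize_gene_class(gene_class)
        if cls not in self._sets:
            sub = self.table[self.table["gene_class"] == cls]
            self._sets[cls] = {
                g: frozenset(grp) for g, grp in sub.groupby("gene_id")["mirna_id"]
            }
        return self._sets[cls]


def normalize_gene_class(value: str) -> str:
    try:
        return _CLASS_NORM[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown gene_class {value!r}; expected one of {GENE_CLASSES}"
        ) from None


def normalize_evidence(value: str) -> str:
    try:
        return _EVIDENCE_NORM[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown evidence {value!r}; expected one of {EVIDENCE_LEVELS}"
        ) from None


def interaction_set_from_frame(table: pd.DataFrame) -> InteractionSet:
    """Validate, normalize and deduplicate a raw interaction table."""
    required = ["mirna_id", "gene_id", "gene_class", "evidence"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("interaction table is empty")
    table = table.loc[:, required].copy()
    for i, row in enumerate(table.itertuples(index=False)):
        # normalization errors must name the offending row
        try:
            normalize_gene_class(row.gene_class)
            normalize_evidence(row.evidence)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    table["gene_class"] = table["gene_class"].map(normalize_gene_class)
    table["evidence"] = table["evidence"].map(normalize_evidence)
    n_raw = len(table)
    # "supported" wins when the same interaction appears under both labels
    table["evidence"] = pd.Categorical(table["evidence"], EVIDENCE_LEVELS, ordered=True)
    table = (
        table.sort_values(["mirna_id", "gene_id", "evidence"])
        .drop_duplicates(subset=["mirna_id", "gene_id"], keep="last")
        .reset_index(drop=True)
    )
    table["evidence"] = table["evidence"].astype(str)
    if len(table) < n_raw:
        logger.info("collapsed %d duplicate interaction rows", n_raw - len(table))
    logger.info(
        "loaded %d interactions, %d miRNAs, %d genes",
        len(table),
        table["mirna_id"].nunique(),
        table["gene_id"].nunique(),
    )
    return InteractionSet(table)


def load_interactions(path) -> InteractionSet:
    """Read an interaction TSV (mirna_id, gene_id, gene_class, evidence)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if len(table) == 0:
        raise ValueError(f"empty interaction file: {path}")
    return interaction_set_from_frame(table)


def write_interactions(iset: InteractionSet, path) -> None:
    iset.table.to_csv(path, sep="\t", index=False)


def filter_supported(
    iset: InteractionSet, classes_to_filter=DEFAULT_FILTER_CLASSES
) -> InteractionSet:
    """Keep only ``supported`` interactions for the given gene classes.

    Other classes pass through untouched; the miRNA universe is recomputed
    from the retained rows (it never grows).  Genes whose sets become empty
    simply drop out of the table; downstream pair testing skips them.
    Idempotent.
    """
    classes = {normalize_gene_class(c) for c in classes_to_filter}
    t = iset.table
    keep = ~t["gene_class"].isin(classes) | (t["evidence"] == "supported")
    filtered = t[keep].reset_index(drop=True)
    if len(filtered) == 0:
        raise ValueError("no interactions left after evidence filtering")
    logger.info(
        "evidence filter on %s: %d -> %d interactions, universe %d -> %d",
        sorted(classes) or "{}",
        len(t),
        len(filtered),
        iset.n_mirnas,
        filtered["mirna_id"].nunique(),
    )
    return InteractionSet(filtered)
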