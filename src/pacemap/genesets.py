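"""Deterministic set algebra over differential-expression result tables:
threshold filtering, biotype selection, marker intersection, two-region
partitioning, the log10(TPM+1) display transform, and ortholog-mediated
disease-term tallies."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_DE_COLUMNS = ("gene_id", "log2FC", "padj")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    provenance: str

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    def __len__(self):
        return len(self.members)


def _check_schema(table: pd.DataFrame, columns=REQUIRED_DE_COLUMNS) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"DE table missing columns: {missing}")


def filter_de(table: pd.DataFrame, lfc_min: float = 2.0,
              padj_max: float = 0.05, direction: str = "enriched") -> GeneSet:
    """Genes passing strict thresholds: enriched means log2FC > lfc_min
    AND padj < padj_max; depleted mirrors with log2FC < −lfc_min; "both"
    is their union.  Boundary rows (log2FC == lfc_min or padj == padj_max)
    are excluded."""
    _check_schema(table)
    if lfc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be > 0")
    sig = table["padj"] < padj_max
    if direction == "enriched":
        keep = sig & (table["log2FC"] > lfc_min)
    elif direction == "depleted":
        keep = sig & (table["log2FC"] < -lfc_min)
    elif direction == "both":
        keep = sig & (table["log2FC"].abs() > lfc_min)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return GeneSet(name=f"de_{direction}",
                   members=frozenset(table.loc[keep, "gene_id"]),
                   provenance=f"|log2FC| > {lfc_min} ({direction}), "
                              f"padj < {padj_max}")


def select_by_biotype(table: pd.DataFrame, biotype: str = "lincRNA") -> GeneSet:
    _check_schema(table, ("gene_id", "biotype"))
    if biotype not in set(table["biotype"]):
        warnings.warn(f"biotype {biotype!r} absent from the table "
                      "(labels are case-sensitive)")
    keep = table["biotype"] == biotype
    return GeneSet(name=f"biotype_{biotype}",
                   members=frozenset(table.loc[keep, "gene_id"]),
                   provenance=f"biotype == {biotype!r}")


def intersect_markers(genes: GeneSet, markers: GeneSet | set
                      ) -> tuple[GeneSet, int]:
    marker_members = markers.members if isinstance(markers, GeneSet) else frozenset(markers)
    marker_name = markers.name if isinstance(markers, GeneSet) else "markers"
    common = genes.members & marker_members
    gs = GeneSet(name=f"{genes.name}∩{marker_name}", members=frozenset(common),
                 provenance=f"intersection of {genes.name} with {marker_name}")
    return gs, len(common)


def partition_regions(set_a: GeneSet, set_b: GeneSet
                      ) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Disjoint (A-unique, B-unique, common) partition of two region
    transcriptomes; |A_unique| + |common| = |A| and symmetrically for B."""
    a, b = set_a.members, set_b.members
    mk = lambda name, members, prov: GeneSet(name=name,
                                             members=frozenset(members),
                                             provenance=prov)
    return (mk(f"{set_a.name}_unique", a - b, f"{set_a.name} minus {set_b.name}"),
            mk(f"{set_b.name}_unique", b - a, f"{set_b.name} minus {set_a.name}"),
            mk("common", a & b, f"{set_a.name} ∩ {set_b.name}"))


def log_tpm(values) -> np.ndarray:
    """Elementwise log10(TPM + 1) display transform."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("TPM values must be non-negative")
    return np.log10(values + 1.0)


def annotate_disease(genes: GeneSet, orthomap: pd.DataFrame,
                     terms: pd.DataFrame) -> dict:
    """Ortholog-mediated disease-term tally.

    ``orthomap`` has columns (zebrafish_id, human_symbol), possibly
    many-to-many; ``terms`` has columns (human_symbol, term).  A gene
    counts toward a term if any of its orthologs carries it, once per
    term; the "unique" tally deduplicates zebrafish gene ids across all
    terms.  Genes with no ortholog are reported as unmapped, not counted.
    """
    for df, cols in ((orthomap, ("zebrafish_id", "human_symbol")),
                     (terms, ("human_symbol", "term"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"table missing columns: {missing}")
    symbols_of = (orthomap[orthomap["zebrafish_id"].isin(genes.members)]
                  .groupby("zebrafish_id")["human_symbol"].apply(set))
    unmapped = sorted(set(genes.members) - set(symbols_of.index))
    symbols_with = terms.groupby("term")["human_symbol"].apply(set)
    per_term: dict[str, list[str]] = {}
    hit_any: set[str] = set()
    for term, term_syms in symbols_with.items():
        hits = sorted(g for g, syms in symbols_of.items() if syms & term_syms)
        per_term[term] = hits
        hit_any.update(hits)
    return {"per_term": per_term,
            "unique_gene_count": len(hit_any),
            "unique_genes": sorted(hit_any),
            "unmapped": unmapped}
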