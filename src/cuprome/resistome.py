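"""Per-species copper-resistome counting from profile-HMM hit tables.

Raw search hits are resolved so that a protein matched by several models is
assigned to the model with the smallest e-value, then counted per model and
per system category (Cue, Cus, CopPco, Multisystem).  A sensitivity sweep
re-runs the filter/dedup/count pipeline across a range of e-value
thresholds.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .catalog import CATEGORIES, ModelCatalog

HIT_COLUMNS = ["protein_id", "model_accession", "bit_score", "evalue", "ali_start", "ali_end"]


def deduplicate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per protein: the hit with the smallest e-value.

    Proteins hit by more than one model are assigned to the model with the
    smallest e-value; exact ties go to the lexicographically smallest model
    accession so the result is deterministic.
    """
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["protein_id", "evalue", "model_accession"], kind="mergesort"
    )
    return ordered.drop_duplicates("protein_id", keep="first").reset_index(drop=True)


def tabulate(hits: pd.DataFrame, catalog: ModelCatalog, species_label: str) -> pd.DataFrame:
    """Count deduplicated hits per model and category for one proteome.

    Every catalog model appears in the output, with a count of 0 when it
    drew no hits.  A hit to an accession absent from the catalog is an
    error.
    """
    if not hits.empty:
        unknown = sorted(set(hits["model_accession"]) - set(catalog.accessions))
        if unknown:
            raise ValueError(f"hits reference accessions absent from catalog: {unknown}")
        per_model = hits.groupby("model_accession").size()
    else:
        per_model = pd.Series(dtype=int)
    rows = [
        {
            "species": species_label,
            "system_category": catalog.category(acc),
            "model_accession": acc,
            "count": int(per_model.get(acc, 0)),
        }
        for acc in catalog.accessions
    ]
    return pd.DataFrame(rows)


def category_totals(count_table: pd.DataFrame) -> pd.Series:
    """Sum model counts within each category (all four categories present)."""
    totals = count_table.groupby("system_category")["count"].sum()
    return totals.reindex(CATEGORIES, fill_value=0)


def evalue_sweep(
    raw_hits: pd.DataFrame,
    catalog: ModelCatalog,
    thresholds: Sequence[float],
    species_label: str = "",
) -> pd.DataFrame:
    """Filter/dedup/count at each threshold of an e-value sensitivity sweep.

    For each threshold t, hits with ``evalue <= t`` are deduplicated
    independently and counted.  Returns one row per threshold with the four
    category totals and the total number of distinct proteins hit (which is
    non-decreasing as the threshold loosens).
    """
    if len(thresholds) == 0:
        raise ValueError("at least one threshold is required")
    rows = []
    for t in thresholds:
        passing = raw_hits[raw_hits["evalue"] <= t] if not raw_hits.empty else raw_hits
        deduped = deduplicate_hits(passing)
        counts = tabulate(deduped, catalog, species_label)
        totals = category_totals(counts)
        row = {"threshold": t, "total_proteins": int(deduped["protein_id"].nunique()) if not deduped.empty else 0}
        row.update({cat: int(totals[cat]) for cat in CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows)
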