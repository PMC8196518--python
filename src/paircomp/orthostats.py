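"""Orthogroup classification and duplication statistics for a two-species
(two-cultivar) gene set.

Orthogroup inference itself (e.g. OrthoFinder output) is consumed as a
table of (gene_id, species, group_id); "-" marks an unassigned gene.
Groups are classified by per-species gene counts:

* one gene from each side            -> single-copy pair
* one gene in A, several in B        -> the A gene is duplicated in B
* genes from one species only, or
  unassigned genes                   -> species-specific
* several genes on both sides        -> multi-multi

A *duplication event* is a group where one species has more than twice
as many genes as the other (strict), both sides non-empty.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

UNASSIGNED = "-"

_CLASSES = ("A_specific", "B_specific", "single_copy_pair",
            "A_single_B_dup", "B_single_A_dup", "multi_multi")


def read_ortho_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["gene_id", "species", "group_id"], header=0)
    return df


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    species = set(table["species"])
    if not species <= {"A", "B"} or len(species) == 0:
        raise ValueError("species labels must be 'A' and 'B'")
    return table


def classify_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group class.  Unassigned genes form singleton pseudo-groups and
    are species-specific, as are single-species groups."""
    table = validate_table(table)
    rows = []
    assigned = table[table["group_id"] != UNASSIGNED]
    for group_id, sub in assigned.groupby("group_id", sort=True):
        n_a = int((sub["species"] == "A").sum())
        n_b = int((sub["species"] == "B").sum())
        if n_b == 0:
            cls = "A_specific"
        elif n_a == 0:
            cls = "B_specific"
        elif n_a == 1 and n_b == 1:
            cls = "single_copy_pair"
        elif n_a == 1:
            cls = "A_single_B_dup"
        elif n_b == 1:
            cls = "B_single_A_dup"
        else:
            cls = "multi_multi"
        rows.append((group_id, n_a, n_b, cls))
    unassigned = table[table["group_id"] == UNASSIGNED]
    for _, row in unassigned.iterrows():
        n_a = int(row["species"] == "A")
        n_b = 1 - n_a
        rows.append((f"unassigned:{row['gene_id']}", n_a, n_b,
                     "A_specific" if n_a else "B_specific"))
    return pd.DataFrame(rows, columns=["group_id", "n_A", "n_B", "class"])


def duplication_events(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group flag: one species has strictly more than twice the genes
    of the other, both present."""
    groups = classify_groups(table)
    groups = groups[~groups["group_id"].str.startswith("unassigned:")].copy()
    groups["duplication_event"] = (
        ((groups["n_A"] > 2 * groups["n_B"]) | (groups["n_B"] > 2 * groups["n_A"]))
        & (groups["n_A"] >= 1) & (groups["n_B"] >= 1))
    return groups


def duplication_summary(table: pd.DataFrame) -> dict:
    """Tallies per class; duplication ratios = duplicated genes per
    single-copy counterpart gene, 2 decimals (None when no such groups)."""
    groups = classify_groups(table)
    a1bd = groups[groups["class"] == "A_single_B_dup"]
    b1ad = groups[groups["class"] == "B_single_A_dup"]
    mm = groups[groups["class"] == "multi_multi"]
    n_a1bd = len(a1bd)
    n_b1ad = len(b1ad)
    dup_b = int(a1bd["n_B"].sum())
    dup_a = int(b1ad["n_A"].sum())
    by_class = groups["class"].value_counts().to_dict()
    gene_totals = {
        cls: int(groups.loc[groups["class"] == cls, ["n_A", "n_B"]].to_numpy().sum())
        for cls in _CLASSES}
    return {
        "groups_per_class": {cls: by_class.get(cls, 0) for cls in _CLASSES},
        "genes_per_class": gene_totals,
        "n_A_single_B_dup_groups": n_a1bd,
        "total_B_dup_genes": dup_b,
        "ratio_B": round(dup_b / n_a1bd, 2) if n_a1bd else None,
        "n_B_single_A_dup_groups": n_b1ad,
        "total_A_dup_genes": dup_a,
        "ratio_A": round(dup_a / n_b1ad, 2) if n_b1ad else None,
        "n_multi_multi_groups": len(mm),
        "multi_multi_genes_A": int(mm["n_A"].sum()),
        "multi_multi_genes_B": int(mm["n_B"].sum()),
        "n_genes": int(len(table)),
    }
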