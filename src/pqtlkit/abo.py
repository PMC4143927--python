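"""ABO blood-group assignment from four tag SNPs.

Four variants in the ABO region tag the major haplotype lineages:
rs505922 (minor allele marks the O lineage), rs8176746 (B), rs8176704
(the A2 split of A) and rs574347 (the O02 split of O).  Each haplotype has
a unique tag signature, so an unphased genotype — the per-SNP count of tag
alleles — resolves to a diplotype whenever exactly one unordered haplotype
pair reproduces it.  Missing genotypes or combinations outside the table
yield an unassigned call rather than a guess.  The tag table is plain data
and can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping

import numpy as np
import pandas as pd

TAG_SNPS = ("rs505922", "rs8176746", "rs8176704", "rs574347")

#: haplotype -> tag-allele presence at (rs505922, rs8176746, rs8176704, rs574347)
DEFAULT_TAG_TABLE: dict[str, tuple[int, int, int, int]] = {
    "A1": (0, 0, 0, 0),
    "A2": (0, 0, 1, 0),
    "B": (0, 1, 0, 0),
    "O01": (1, 0, 0, 0),
    "O02": (1, 0, 0, 1),
}

_GROUP_OF = {"A1": "A", "A2": "A", "B": "B", "O01": "O", "O02": "O"}


def haplotype_signature(name: str, tag_table: Mapping[str, tuple[int, ...]] | None = None):
    return (tag_table or DEFAULT_TAG_TABLE)[name]


def _group(h1: str, h2: str) -> str:
    g = {_GROUP_OF[h1], _GROUP_OF[h2]}
    if g == {"A", "B"}:
        return "AB"
    if "A" in g:
        return "A"
    if "B" in g:
        return "B"
    return "O"


@dataclass(frozen=True)
class ABOCall:
    individual: str
    diplotype: str | None   # e.g. "A1/O01"; None when unassigned
    group: str              # "A" | "B" | "AB" | "O" | "unassigned"
    subtypes: tuple[str, ...] = ()


def _pair_lookup(tag_table: Mapping[str, tuple[int, ...]]) -> dict[tuple[int, ...], list[tuple[str, str]]]:
    table: dict[tuple[int, ...], list[tuple[str, str]]] = {}
    for h1, h2 in combinations_with_replacement(sorted(tag_table), 2):
        sig = tuple(a + b for a, b in zip(tag_table[h1], tag_table[h2]))
        table.setdefault(sig, []).append((h1, h2))
    return table


def assign_abo(
    genotypes: pd.DataFrame,
    tag_table: Mapping[str, tuple[int, ...]] | None = None,
) -> list[ABOCall]:
    """Call blood groups from tag-allele counts at the four SNPs.

    ``genotypes``: individuals x four tag SNPs (columns in TAG_SNPS order or
    named), hard-call tag-allele counts with NaN for missing.  A call is
    made only when the genotype matches exactly one unordered haplotype
    pair; A and B are codominant over O.
    """
    tag_table = dict(tag_table or DEFAULT_TAG_TABLE)
    if list(genotypes.columns) != list(TAG_SNPS):
        missing = [s for s in TAG_SNPS if s not in genotypes.columns]
        if missing:
            raise ValueError(f"genotypes missing tag SNPs: {missing}")
        genotypes = genotypes[list(TAG_SNPS)]
    lookup = _pair_lookup(tag_table)
    calls = []
    for iid, row in genotypes.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.isnan(vals).any():
            calls.append(ABOCall(str(iid), None, "unassigned"))
            continue
        sig = tuple(int(v) for v in vals)
        pairs = lookup.get(sig, [])
        if len(pairs) != 1:
            calls.append(ABOCall(str(iid), None, "unassigned"))
            continue
        h1, h2 = pairs[0]
        calls.append(
            ABOCall(str(iid), f"{h1}/{h2}", _group(h1, h2), subtypes=(h1, h2))
        )
    return calls


def assignment_rate(calls: list[ABOCall]) -> float:
    if not calls:
        raise ValueError("no calls")
    return sum(c.group != "unassigned" for c in calls) / len(calls)


def calls_to_frame(calls: list[ABOCall]) -> pd.DataFrame:
    """Tabular view: individual, diplotype, group — group usable as covariate."""
    return pd.DataFrame(
        {
            "individual": [c.individual for c in calls],
            "diplotype": [c.diplotype or "" for c in calls],
            "group": [c.group for c in calls],
        }
    ).set_index("individual")
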