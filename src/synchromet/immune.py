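"""Immune scoring from expression, flow-cytometry fractions, and IHC summaries.

The immune score is the geometric mean of expression over five immune gene
sets (cytolytic effectors, HLA molecules, IFN-γ pathway, chemokines, adhesion
molecules).  Raw digital counts can be zero, so a pseudocount (default 1) is
added before taking logs; the mean is taken over the pooled union of the five
sets by default, with a per-set mode available.

Flow results are expressed as subset percentages of CD45+ cells; IHC markers
are summarized either as an H-score (intensity-weighted percent positive,
0-300) or as mean positive-cell density per mm², averaged over five areas.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IMMUNE_GENE_SETS",
    "immune_gene_union",
    "cd45_subset_fractions",
    "immune_score",
    "h_score",
    "ihc_density_summary",
]

#: The five immune gene sets scored by the immune score.
IMMUNE_GENE_SETS: dict[str, tuple[str, ...]] = {
    "cytolytic": ("GZMA", "GZMB", "PRF1", "GNLY"),
    "hla": (
        "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G", "HLA-H",
        "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB", "HLA-DPA1", "HLA-DPB1",
        "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DRA", "HLA-DRB1",
    ),
    "ifn_gamma": ("IFNG", "IFNGR1", "IFNGR2", "IRF1", "STAT1", "PSMB9"),
    "chemokines": ("CCR5", "CCL3", "CCL4", "CCL5", "CXCL9", "CXCL10", "CXCL11"),
    "adhesion": ("ICAM1", "ICAM2", "ICAM3", "ICAM4", "ICAM5", "VCAM1"),
}


def immune_gene_union(
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[str, ...]:
    """All genes in the five sets, in stable definition order."""
    sets = gene_sets if gene_sets is not None else IMMUNE_GENE_SETS
    seen: list[str] = []
    for genes in sets.values():
        for g in genes:
            if g not in seen:
                seen.append(g)
    return tuple(seen)


def cd45_subset_fractions(
    counts: Mapping[str, float], cd45_total: float
) -> dict[str, float]:
    """Subset percentages of CD45+ cells: 100 * count / cd45_total."""
    if cd45_total <= 0:
        raise ValueError("cd45_total must be positive")
    out = {}
    for subset, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for subset {subset!r}")
        if n > cd45_total:
            raise ValueError(f"subset {subset!r} count exceeds CD45 total")
        out[subset] = 100.0 * n / cd45_total
    return out


def immune_score(
    expr: Mapping[str, float],
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    pseudocount: float = 1.0,
    per_set: bool = False,
) -> float | dict[str, float]:
    """Geometric mean of (expression + pseudocount) over the immune gene sets.

    With ``per_set=True`` returns one geometric mean per named set instead of
    a single pooled value.  Missing genes raise, listing them; negative
    expression raises.
    """
    sets = gene_sets if gene_sets is not None else IMMUNE_GENE_SETS
    union = immune_gene_union(sets)
    missing = [g for g in union if g not in expr]
    if missing:
        raise ValueError(f"expression is missing immune-score genes: {missing}")
    for g in union:
        if expr[g] < 0:
            raise ValueError(f"negative expression for gene {g!r}")

    def geo(genes: Sequence[str]) -> float:
        vals = np.asarray([expr[g] + pseudocount for g in genes], dtype=float)
        if np.any(vals <= 0):
            raise ValueError("geometric mean undefined: zero expression with zero pseudocount")
        return float(np.exp(np.mean(np.log(vals))))

    if per_set:
        return {name: geo(genes) for name, genes in sets.items()}
    return geo(union)


def h_score(pct_at_intensity: Mapping[int, float]) -> float:
    """IHC H-score: sum of intensity x percent positive, range [0, 300].

    ``pct_at_intensity`` maps staining intensity (1, 2, 3) to the percentage
    of cells staining at that intensity; unstained cells are the remainder.
    """
    bad = set(pct_at_intensity) - {1, 2, 3}
    if bad:
        raise ValueError(f"intensities must be in {{1,2,3}}, got {sorted(bad)}")
    pcts = {i: float(pct_at_intensity.get(i, 0.0)) for i in (1, 2, 3)}
    if any(v < 0 for v in pcts.values()):
        raise ValueError("percentages must be non-negative")
    total = sum(pcts.values())
    if total > 100 + 1e-9:
        raise ValueError(f"percent positive sums to {total} > 100")
    return float(sum(i * v for i, v in pcts.items()))


def ihc_density_summary(values: Sequence[float], n_areas: int = 5) -> float:
    """Mean positive-cell density over the analyzed areas (default five)."""
    if len(values) != n_areas:
        raise ValueError(f"expected {n_areas} area values, got {len(values)}")
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("densities must be non-negative")
    return float(vals.mean())
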