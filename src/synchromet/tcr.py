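"""TCR-repertoire statistics: clonality, clone sharing, top-clone analyses.

A repertoire is a clone table: one row per distinct clone (identified by its
CDR3 amino-acid sequence) with a read/template count and a productive flag.
All statistics are computed over productive clones only.

Clonality is ``1 - H / log2(U)`` where ``H`` is the Shannon entropy (bits) of
the clone frequency distribution and ``U`` the number of productive unique
clones: 0 for a perfectly even repertoire, 1 for a monoclonal one.  A
single-clone repertoire is assigned clonality 1.0 by convention (the formula
is 0/0 there).

Clone sharing between two lesions is the Jaccard percentage
``100 * |A ∩ B| / |A ∪ B|`` over productive clone identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RepertoireSummary",
    "make_clone_table",
    "clonality",
    "shared_clone_fraction",
    "top_clones",
    "top_clone_restriction",
    "top_clone_rank_correlation",
    "read_immunoseq_tsv",
    "write_immunoseq_tsv",
]

_COLUMNS = ("clone_id", "count", "productive")


def make_clone_table(
    clone_ids: Sequence[str],
    counts: Sequence[int],
    productive: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build a validated clone table."""
    if productive is None:
        productive = [True] * len(clone_ids)
    df = pd.DataFrame(
        {"clone_id": list(clone_ids), "count": list(counts), "productive": list(productive)}
    )
    return validate_clone_table(df)


def validate_clone_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clone table missing columns {missing}")
    if table["clone_id"].duplicated().any():
        dup = table.loc[table["clone_id"].duplicated(), "clone_id"].iloc[0]
        raise ValueError(f"duplicate clone_id {dup!r}")
    if (table["count"] < 1).any():
        raise ValueError("clone counts must be >= 1")
    return table


def _productive(table: pd.DataFrame) -> pd.DataFrame:
    validate_clone_table(table)
    return table[table["productive"].astype(bool)]


@dataclass(frozen=True)
class RepertoireSummary:
    """Productive-clone diversity summary."""

    unique_clones: int
    entropy_bits: float
    clonality: float


def clonality(table: pd.DataFrame) -> RepertoireSummary:
    """Shannon entropy (bits) and clonality over productive clones."""
    prod = _productive(table)
    if len(prod) == 0:
        raise ValueError("repertoire has no productive clones")
    counts = prod["count"].to_numpy(dtype=float)
    freqs = counts / counts.sum()
    H = float(-(freqs * np.log2(freqs)).sum())
    U = len(prod)
    if U == 1:
        clon = 1.0  # monoclonal convention: log2(1)=0 makes the formula 0/0
    else:
        clon = 1.0 - H / np.log2(U)
    return RepertoireSummary(unique_clones=U, entropy_bits=H, clonality=float(clon))


def shared_clone_fraction(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> float:
    """Shared-clone percentage: 100 * |A ∩ B| / |A ∪ B| over productive clones."""
    a = set(_productive(rep_a)["clone_id"])
    b = set(_productive(rep_b)["clone_id"])
    if not a or not b:
        raise ValueError("both repertoires must contain productive clones")
    return 100.0 * len(a & b) / len(a | b)


def top_clones(
    table: pd.DataFrame,
    percent: float | None = None,
    rank: int | None = None,
    percentile_mode: str = "mass",
) -> list[str]:
    """Select the dominant productive clones of a repertoire.

    Exactly one of ``percent`` / ``rank`` must be given.  ``rank=n`` takes the
    n highest-frequency clones.  ``percent=x`` with ``percentile_mode="mass"``
    (the repertoire convention) takes the minimal set of highest-frequency
    clones whose cumulative frequency reaches x%; ``percentile_mode="rank"``
    instead takes the top x% of clones by rank count.  Ties in frequency are
    broken by clone_id for determinism.
    """
    if (percent is None) == (rank is None):
        raise ValueError("specify exactly one of percent or rank")
    prod = _productive(table)
    if len(prod) == 0:
        raise ValueError("repertoire has no productive clones")
    ordered = prod.sort_values(
        ["count", "clone_id"], ascending=[False, True], kind="mergesort"
    )
    ids = ordered["clone_id"].tolist()
    if rank is not None:
        if rank < 1:
            raise ValueError("rank cutoff must be >= 1")
        if rank > len(ids):
            raise ValueError(f"rank cutoff {rank} exceeds clone count {len(ids)}")
        return ids[:rank]
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    if percentile_mode == "mass":
        freqs = ordered["count"].to_numpy(dtype=float)
        freqs = freqs / freqs.sum()
        cum = np.cumsum(freqs)
        n_take = int(np.searchsorted(cum, percent / 100.0 - 1e-12) + 1)
        return ids[: min(n_take, len(ids))]
    if percentile_mode == "rank":
        n_take = max(1, int(np.ceil(len(ids) * percent / 100.0)))
        return ids[:n_take]
    raise ValueError("percentile_mode must be 'mass' or 'rank'")


def top_clone_restriction(
    lesions: Mapping[str, pd.DataFrame],
    percent: float | None = None,
    rank: int | None = None,
    percentile_mode: str = "mass",
) -> dict[str, dict[str, int]]:
    """Count each lesion's top clones that are absent from every sibling lesion.

    A top clone of lesion L is *restricted* iff its clone_id does not occur
    (productive) anywhere in any other lesion of the same patient.
    """
    if len(lesions) < 2:
        raise ValueError("top_clone_restriction requires >= 2 lesions")
    all_ids = {
        name: set(_productive(tab)["clone_id"]) for name, tab in lesions.items()
    }
    out: dict[str, dict[str, int]] = {}
    for name, tab in lesions.items():
        top = top_clones(tab, percent=percent, rank=rank, percentile_mode=percentile_mode)
        others: set[str] = set()
        for other, ids in all_ids.items():
            if other != name:
                others |= ids
        restricted = [c for c in top if c not in others]
        out[name] = {"n_top": len(top), "n_restricted": len(restricted)}
    return out


def top_clone_rank_correlation(
    lesion_a: pd.DataFrame,
    lesion_b: pd.DataFrame,
    n: int = 10,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Spearman correlation between top-n clone frequencies of A and B.

    The top n clones of lesion A (by frequency) are paired with their
    frequencies in lesion B (0 if absent).  Ties are mid-ranked.  The p-value
    is a two-sided permutation p (permuting the B frequencies) with the +1
    correction.
    """
    from scipy import stats

    prod_a = _productive(lesion_a)
    if n > len(prod_a):
        raise ValueError(f"n={n} exceeds productive clone count {len(prod_a)}")
    top = top_clones(lesion_a, rank=n)
    fa = prod_a.set_index("clone_id")["count"].astype(float)
    fa = fa / fa.sum()
    prod_b = _productive(lesion_b)
    fb_all = prod_b.set_index("clone_id")["count"].astype(float)
    fb_all = fb_all / fb_all.sum()
    x = np.array([fa[c] for c in top])
    y = np.array([fb_all.get(c, 0.0) for c in top])

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(yr: np.ndarray) -> float:
        rxc = rx - rx.mean()
        ryc = yr - yr.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        if denom == 0:
            raise ValueError("zero rank variance: cannot compute Spearman rho")
        return float((rxc * ryc).sum() / denom)

    rho = rho_of(ry)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(rho_of(rng.permutation(ry))) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return rho, float(p)


def read_immunoseq_tsv(
    path: str | Path,
    clone_col: str = "cdr3_aa",
    count_col: str = "count",
    productive_col: str = "productive",
) -> pd.DataFrame:
    """Read an ImmunoSeq-style TSV into a clone table (configurable columns)."""
    df = pd.read_csv(path, sep="\t")
    for col in (clone_col, count_col, productive_col):
        if col not in df.columns:
            raise ValueError(f"repertoire TSV missing column {col!r}")
    table = pd.DataFrame(
        {
            "clone_id": df[clone_col].astype(str),
            "count": df[count_col].astype(int),
            "productive": df[productive_col].astype(bool),
        }
    )
    return validate_clone_table(table)


def write_immunoseq_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a clone table as TSV (columns: clone_id, cdr3_aa, count, productive)."""
    validate_clone_table(table)
    out = pd.DataFrame(
        {
            "clone_id": table["clone_id"],
            "cdr3_aa": table["clone_id"],
            "count": table["count"].astype(int),
            "productive": table["productive"].astype(bool),
        }
    )
    out.to_csv(path, sep="\t", index=False)
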