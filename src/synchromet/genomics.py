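"""Somatic-call filtering, mutation overlap, mutational spectrum and neoepitopes.

Post-calling filters operate on already-called somatic SNVs (one
:class:`VariantCall` per candidate), mirroring the standard practice of
retaining calls with adequate tumor/normal coverage, a detectable tumor
variant allele fraction (VAF), a clean matched normal, and no membership in
germline polymorphism databases (dbSNP, 1000 Genomes, ESP-6500).

Overlap statistics treat a mutation as a genomic key ``(chrom, pos, ref,
alt)``: two synchronous lesions share a non-synonymous exonic mutation (NSEM)
only when the identical substitution is called in both.  The shared
percentage uses the union of the two lesions' NSEM sets as denominator.

Neoepitope enumeration emits every 8- to 12-mer peptide window spanning a
missense change, paired with its wild-type counterpart; binding calls are
delegated to a pluggable IC50 oracle (binder: IC50 < 500 nM, high-affinity:
IC50 < 100 nM, both strict).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "VariantCall",
    "FilterThresholds",
    "OverlapSummary",
    "NeoPeptide",
    "BinderSets",
    "filter_somatic_calls",
    "nsem_overlap",
    "patient_overlap",
    "ct_fraction",
    "enumerate_neopeptides",
    "classify_and_overlap_binders",
    "SyntheticAffinityOracle",
    "read_affinity_tsv",
    "write_vcf",
    "read_vcf",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One somatic single-nucleotide variant with its filter-relevant evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int
    normal_depth: int
    tumor_vaf: float
    normal_vaf: float
    gene: str = ""
    effect: str = "NSEM"  # one of {"NSEM", "silent", "other"}
    in_known_db: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError("read depths must be non-negative")
        for name in ("tumor_vaf", "normal_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity used for overlap statistics."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_ct(self) -> bool:
        """True if the pyrimidine-strand substitution is C>T (G>A counts)."""
        return (self.ref, self.alt) in {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class FilterThresholds:
    """Post-calling somatic filter thresholds.

    ``normal_vaf_keep`` selects the comparator on the matched normal VAF:
    ``"le"`` (default) keeps calls with normal VAF <= ``max_normal_vaf``;
    ``"ge"`` keeps the opposite side, matching the direction some reports
    print verbatim.
    """

    min_tumor_depth: int = 20
    min_normal_depth: int = 10
    min_tumor_vaf: float = 0.01
    max_normal_vaf: float = 0.01
    drop_known_db: bool = True
    normal_vaf_keep: str = "le"

    def __post_init__(self) -> None:
        if min(self.min_tumor_depth, self.min_normal_depth) < 0:
            raise ValueError("depth thresholds must be non-negative")
        if self.min_tumor_vaf < 0 or self.max_normal_vaf < 0:
            raise ValueError("VAF thresholds must be non-negative")
        if self.normal_vaf_keep not in ("le", "ge"):
            raise ValueError("normal_vaf_keep must be 'le' or 'ge'")


@dataclass(frozen=True)
class OverlapSummary:
    """Shared/unique decomposition of two lesions' mutation (or peptide) sets."""

    shared_count: int
    unique_a_count: int
    unique_b_count: int

    @property
    def union_count(self) -> int:
        return self.shared_count + self.unique_a_count + self.unique_b_count

    @property
    def shared_pct(self) -> float:
        """100 * |A ∩ B| / |A ∪ B|; 0.0 when both sets are empty."""
        if self.union_count == 0:
            return 0.0
        return 100.0 * self.shared_count / self.union_count


def filter_somatic_calls(
    calls: Sequence[VariantCall], thresholds: FilterThresholds | None = None
) -> list[VariantCall]:
    """Apply the post-calling somatic filters, preserving input order.

    A call is retained iff tumor depth >= ``min_tumor_depth``, normal depth
    >= ``min_normal_depth``, tumor VAF >= ``min_tumor_vaf``, the normal-VAF
    condition holds, and (if ``drop_known_db``) it is absent from the known
    germline databases.
    """
    t = thresholds or FilterThresholds()
    kept = []
    for c in calls:
        if c.tumor_depth < t.min_tumor_depth:
            continue
        if c.normal_depth < t.min_normal_depth:
            continue
        if c.tumor_vaf < t.min_tumor_vaf:
            continue
        if t.normal_vaf_keep == "le":
            if c.normal_vaf > t.max_normal_vaf:
                continue
        else:
            if c.normal_vaf < t.max_normal_vaf:
                continue
        if t.drop_known_db and c.in_known_db:
            continue
        kept.append(c)
    return kept


def nsem_overlap(lesion_a: Iterable, lesion_b: Iterable) -> OverlapSummary:
    """Shared/unique counts between two lesions' NSEM key sets."""
    a, b = set(lesion_a), set(lesion_b)
    shared = a & b
    return OverlapSummary(
        shared_count=len(shared),
        unique_a_count=len(a - b),
        unique_b_count=len(b - a),
    )


def patient_overlap(lesions: Sequence[Iterable]) -> float:
    """Unweighted mean pairwise shared percentage over all lesion pairs."""
    sets = [set(les) for les in lesions]
    if len(sets) < 2:
        raise ValueError("patient_overlap requires at least two lesions")
    pcts = [
        nsem_overlap(a, b).shared_pct for a, b in itertools.combinations(sets, 2)
    ]
    return float(sum(pcts) / len(pcts))


def ct_fraction(calls: Sequence[VariantCall]) -> float:
    """Fraction of SNVs whose pyrimidine-strand substitution is C>T.

    G>A calls are counted as C>T (same event read off the opposite strand).
    The denominator is all SNVs passed in.
    """
    if not calls:
        raise ValueError("ct_fraction undefined for an empty call set")
    return sum(c.is_ct for c in calls) / len(calls)


@dataclass(frozen=True)
class NeoPeptide:
    """A mutant/wild-type peptide pair spanning a missense change."""

    mutant_seq: str
    wildtype_seq: str
    mut_offset: int  # 0-based position of the altered residue in the peptide
    ic50_mut: float | None = None

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.wildtype_seq):
            raise ValueError("mutant and wild-type peptides differ in length")
        diffs = [
            i
            for i, (m, w) in enumerate(zip(self.mutant_seq, self.wildtype_seq))
            if m != w
        ]
        if diffs != [self.mut_offset]:
            raise ValueError(
                "peptide pair must differ exactly at mut_offset "
                f"(found differences at {diffs}, expected [{self.mut_offset}])"
            )

    def with_ic50(self, ic50: float) -> "NeoPeptide":
        return replace(self, ic50_mut=float(ic50))


def enumerate_neopeptides(
    protein_seq: str,
    mut_pos_1based: int,
    mut_aa: str,
    kmin: int = 8,
    kmax: int = 12,
) -> list[NeoPeptide]:
    """Emit every k-mer window (k in [kmin, kmax]) covering the mutated residue.

    For each k, windows start at every position such that the window lies
    fully inside the protein and contains ``mut_pos_1based``; the number of
    windows is ``min(p, L-k+1) - max(1, p-k+1) + 1`` (can be 0 for short
    proteins).
    """
    L = len(protein_seq)
    p = mut_pos_1based
    if not 1 <= p <= L:
        raise ValueError(f"mut_pos {p} outside protein of length {L}")
    if protein_seq[p - 1] == mut_aa:
        raise ValueError(
            f"mutant residue {mut_aa!r} equals the reference residue at position {p}"
        )
    mut_protein = protein_seq[: p - 1] + mut_aa + protein_seq[p:]
    out: list[NeoPeptide] = []
    for k in range(kmin, kmax + 1):
        start_lo = max(1, p - k + 1)
        start_hi = min(p, L - k + 1)
        for s in range(start_lo, start_hi + 1):
            out.append(
                NeoPeptide(
                    mutant_seq=mut_protein[s - 1 : s - 1 + k],
                    wildtype_seq=protein_seq[s - 1 : s - 1 + k],
                    mut_offset=p - s,
                )
            )
    return out


AffinityOracle = Callable[[str, str], float]


class SyntheticAffinityOracle:
    """Deterministic stand-in for an MHC binding predictor (synthetic).

    Maps (peptide, allele) to an IC50 in nM via a salted BLAKE2 hash pushed
    through a log-normal quantile (median ~5000 nM, log10-sd 0.8), so the
    same peptide/allele pair always receives the same affinity in and across
    processes and roughly one peptide in ten is a < 500 nM binder.  It
    encodes no biochemistry; it exists so the binder-classification and
    overlap machinery can run without an external predictor.
    """

    def __init__(self, salt: str = "synchromet", log10_median: float = 3.7,
                 log10_sd: float = 0.8):
        self.salt = salt
        self.log10_median = log10_median
        self.log10_sd = log10_sd

    def __call__(self, peptide: str, allele: str) -> float:
        from statistics import NormalDist

        h = hashlib.blake2b(
            f"{self.salt}|{allele}|{peptide}".encode(), digest_size=8
        ).digest()
        u = (int.from_bytes(h, "big") + 0.5) / 2**64
        z = NormalDist().inv_cdf(u)
        return float(min(max(10.0 ** (self.log10_median + self.log10_sd * z), 0.1), 5e4))


def read_affinity_tsv(path: str | Path) -> dict[tuple[str, str], float]:
    """Read (peptide, allele, ic50_nM) rows; returns a lookup dict."""
    table: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("peptide", "allele", "ic50_nM"):
            if col not in idx:
                raise ValueError(f"affinity TSV missing column {col!r}")
        for line in fh:
            row = line.rstrip("\n").split("\t")
            table[(row[idx["peptide"]], row[idx["allele"]])] = float(
                row[idx["ic50_nM"]]
            )
    return table


@dataclass(frozen=True)
class BinderSets:
    """Per-lesion binder classification results."""

    binders: frozenset[str]
    high_affinity: frozenset[str]


def classify_and_overlap_binders(
    peptides_per_lesion: Mapping[str, Sequence[NeoPeptide]],
    affinity_oracle: AffinityOracle | Mapping[tuple[str, str], float],
    allele: str = "HLA-A*02:01",
    binder_nM: float = 500.0,
    high_nM: float = 100.0,
) -> tuple[dict[str, BinderSets], dict[tuple[str, str], OverlapSummary]]:
    """Score peptides, classify binders, and compute pairwise binder overlap.

    Binder: IC50 strictly below ``binder_nM``; high-affinity: strictly below
    ``high_nM``.  Overlap is computed on mutant peptide strings among
    binders.  A missing affinity raises, naming the peptide.
    """
    if isinstance(affinity_oracle, Mapping):
        lookup = affinity_oracle

        def oracle(pep: str, al: str) -> float:
            try:
                return lookup[(pep, al)]
            except KeyError:
                raise KeyError(
                    f"no affinity for peptide {pep!r} with allele {al!r}"
                ) from None

    else:
        oracle = affinity_oracle

    sets: dict[str, BinderSets] = {}
    for lesion, peptides in peptides_per_lesion.items():
        binders, high = set(), set()
        for pep in peptides:
            ic50 = pep.ic50_mut
            if ic50 is None:
                ic50 = oracle(pep.mutant_seq, allele)
            if ic50 < binder_nM:
                binders.add(pep.mutant_seq)
                if ic50 < high_nM:
                    high.add(pep.mutant_seq)
        sets[lesion] = BinderSets(frozenset(binders), frozenset(high))

    overlaps = {
        (a, b): nsem_overlap(sets[a].binders, sets[b].binders)
        for a, b in itertools.combinations(sets, 2)
    }
    return sets, overlaps


# --- VCF dialect -----------------------------------------------------------
#
# Variants are exchanged as plain VCF 4.2 with per-call evidence in INFO:
# TDP/NDP (depths), TVAF/NVAF (allele fractions), GENE, EFFECT, and the DB
# flag for known-database membership.

_CONTIG_LINES = "".join(f"##contig=<ID=chr{i}>\n" for i in list(range(1, 23)) + ["X", "Y"])

_VCF_HEADER = f"""\
##fileformat=VCFv4.2
##source=synchromet
{_CONTIG_LINES}""" + """\
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Total read depth in tumor">
##INFO=<ID=NDP,Number=1,Type=Integer,Description="Total read depth in matched normal">
##INFO=<ID=TVAF,Number=1,Type=String,Description="Variant allele fraction in tumor (full-precision decimal)">
##INFO=<ID=NVAF,Number=1,Type=String,Description="Variant allele fraction in matched normal (full-precision decimal)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class (NSEM/silent/other)">
##INFO=<ID=DB,Number=0,Type=Flag,Description="Present in dbSNP/1000G/ESP-6500">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a plain-text VCF (sorted by chrom, pos)."""
    rows = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in rows:
            info = (
                f"TDP={c.tumor_depth};NDP={c.normal_depth};"
                f"TVAF={c.tumor_vaf!r};NVAF={c.normal_vaf!r};"
                f"GENE={c.gene or '.'};EFFECT={c.effect}"
            )
            if c.in_known_db:
                info += ";DB"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read SNVs from a VCF written in (or compatible with) the dialect above."""
    from cyvcf2 import VCF

    calls = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else ""
        if len(rec.REF) != 1 or len(alt) != 1:
            continue  # SNVs only
        info = dict(rec.INFO)
        calls.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                tumor_depth=int(info.get("TDP", 0)),
                normal_depth=int(info.get("NDP", 0)),
                tumor_vaf=float(info.get("TVAF", 0.0)),
                normal_vaf=float(info.get("NVAF", 0.0)),
                gene="" if info.get("GENE") in (None, ".") else str(info["GENE"]),
                effect=str(info.get("EFFECT", "NSEM")),
                in_known_db=bool(info.get("DB", False)),
            )
        )
    return calls
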