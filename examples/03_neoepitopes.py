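"""Enumerate neoepitope candidates for a missense mutation and classify binders.

Every 8- to 12-mer peptide window spanning the substituted residue is paired
with its wild-type counterpart; a pluggable IC50 oracle scores each mutant
peptide and binders are called at the strict < 500 nM (binder) and < 100 nM
(high-affinity) thresholds.  The bundled oracle is a deterministic synthetic
stand-in; NetMHC-style predictions can be imported from TSV instead.
"""

from synchromet import SyntheticAffinityOracle, classify_and_overlap_binders, enumerate_neopeptides

protein = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGET"
peptides = enumerate_neopeptides(protein, mut_pos_1based=12, mut_aa="D")
print(f"{len(peptides)} mutant/wild-type peptide pairs span the G12D change")
print("first pair:", peptides[0].wildtype_seq, "->", peptides[0].mutant_seq)

oracle = SyntheticAffinityOracle()
sets, overlaps = classify_and_overlap_binders(
    {"lesion_A": peptides, "lesion_B": peptides[: len(peptides) // 2]},
    oracle,
    allele="HLA-A*02:01",
)
for lesion, bs in sets.items():
    print(f"{lesion}: {len(bs.binders)} binders (<500 nM), "
          f"{len(bs.high_affinity)} high-affinity (<100 nM)")
ov = overlaps[("lesion_A", "lesion_B")]
print(f"binder overlap: {ov.shared_pct:.1f}% shared "
      "(lesion_B carries a subset of lesion_A's mutations here)")
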