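"""TCR repertoire heterogeneity: clonality, clone sharing, top-clone restriction.

Clonality is 1 - H/log2(U) over productive clones (0 = perfectly even,
1 = monoclonal).  Clone sharing between two lesions is the percentage of the
union of productive clones found in both.  A top clone of one lesion is
"restricted" when it is absent from every sibling lesion of the same patient.
"""

from synchromet import (
    CohortConfig,
    clonality,
    generate_cohort,
    shared_clone_fraction,
    top_clone_rank_correlation,
    top_clone_restriction,
)

cohort = generate_cohort(
    CohortConfig(n_patients_per_arm=1, arms=("checkpoint",), n_clones_per_lesion=500, seed=19)
)
patient = cohort.patients[0]
lesions = {l.lesion_id: l.repertoire for l in patient.lesions}
names = list(lesions)

for name, table in lesions.items():
    s = clonality(table)
    print(f"{name}: {s.unique_clones} productive clones, "
          f"H = {s.entropy_bits:.2f} bits, clonality = {s.clonality:.3f}")

share = shared_clone_fraction(lesions[names[0]], lesions[names[1]])
print(f"\nshared clones between {names[0]} and {names[1]}: {share:.1f}% of the union")

restricted = top_clone_restriction(lesions, rank=10)
for name, counts in restricted.items():
    print(f"{name}: {counts['n_restricted']} of its top-{counts['n_top']} clones "
          "found in no sibling lesion")

rho, p = top_clone_rank_correlation(lesions[names[0]], lesions[names[1]], n=10, seed=0)
print(f"\ntop-10 clone frequency rank correlation: rho = {rho:.2f} (perm p = {p:.3f})")
print("(low rho means the dominant T-cell hierarchy differs between the lesions)")
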