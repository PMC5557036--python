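"""End-to-end analysis pipeline over a (synthetic or loaded) multi-lesion cohort.

Runs every stage in order — somatic filtering and NSEM overlap, mutational
spectrum, neoepitope binder classification, immune scoring and flow
fractions, TCR clonality/sharing/top-clone restriction, GLCM texture
profiling, response metrics, Ward-clustering branch lengths, marker-response
association, median-dichotomy Fisher tests, random-forest importance, and the
headline cross-feature correlations — and writes one CSV per stage plus a
seeded JSON run report.  With a fixed config (including its seed) the report
and CSVs are bitwise reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomics, immune, integrate, radiomics, tcr
from .synthetic_cohort import CohortBundle, CohortConfig, generate_cohort, write_cohort

__all__ = ["run_pipeline", "build_feature_table", "lesion_summaries"]

#: Immune-block variables (log-transformed downstream), genomic and radiomic blocks.
FEATURE_BLOCKS = {
    "genomic": ("nsem_count", "n_binders", "n_high_binders"),
    "immune": ("immune_score", "cd8_pct", "clonality"),
    "radiomic": ("entropy", "energy", "homogeneity", "dissimilarity", "contrast"),
}


def lesion_summaries(bundle: CohortBundle) -> pd.DataFrame:
    """Per-lesion summary statistics across all modalities (one row per lesion)."""
    thresholds = genomics.FilterThresholds()
    oracle = genomics.SyntheticAffinityOracle()
    rows = []
    for patient in bundle.patients:
        peptides_per_lesion = {}
        for les in patient.lesions:
            kept = genomics.filter_somatic_calls(les.variants, thresholds)
            nsem = [c for c in kept if c.effect == "NSEM"]
            # one synthetic protein context per NSEM; the peptide windows all
            # span the substituted residue
            peps = []
            for c in nsem:
                peps.extend(_peptides_for_call(c))
            peptides_per_lesion[les.lesion_id] = peps
            rep = tcr.clonality(les.repertoire)
            profile, _ = radiomics.lesion_texture_profile(les.image, les.mask)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "lesion_id": les.lesion_id,
                    "arm": patient.arm,
                    "n_calls_raw": len(les.variants),
                    "n_calls_filtered": len(kept),
                    "nsem_count": len(nsem),
                    "ct_fraction": genomics.ct_fraction(kept) if kept else np.nan,
                    "immune_score": immune.immune_score(les.expression.to_dict()),
                    "cd8_pct": les.immune_fractions["CD8_T"],
                    "cd4_pct": les.immune_fractions["CD4_T"],
                    "treg_pct": les.immune_fractions["Treg"],
                    "clonality": rep.clonality,
                    "tcr_entropy_bits": rep.entropy_bits,
                    "unique_clones": rep.unique_clones,
                    "baseline_size": les.baseline_size,
                    "followup_size": les.followup_size,
                    "percent_change": les.percent_change,
                    **profile.as_dict(),
                }
            )
        binder_sets, _ = genomics.classify_and_overlap_binders(
            peptides_per_lesion, oracle
        )
        for row in rows[-len(patient.lesions):]:
            bs = binder_sets[row["lesion_id"]]
            row["n_binders"] = len(bs.binders)
            row["n_high_binders"] = len(bs.high_affinity)
    return pd.DataFrame(rows)


_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _peptides_for_call(call: genomics.VariantCall) -> list[genomics.NeoPeptide]:
    """Deterministic synthetic protein context for a somatic call.

    Derives a 25-residue protein from the call's genomic key and emits the
    8-12-mer windows spanning the (central) substituted residue.  Purely a
    reproducible stand-in for a transcript lookup.
    """
    import hashlib

    key = f"{call.chrom}:{call.pos}:{call.ref}>{call.alt}"
    h = hashlib.blake2b(key.encode(), digest_size=32).digest()
    protein = "".join(_AA_ORDER[b % 20] for b in h[:25])
    pos = 13
    ref_aa = protein[pos - 1]
    mut_aa = _AA_ORDER[(_AA_ORDER.index(ref_aa) + 1 + h[30] % 19) % 20]
    if mut_aa == ref_aa:
        mut_aa = _AA_ORDER[(_AA_ORDER.index(ref_aa) + 1) % 20]
    return genomics.enumerate_neopeptides(protein, pos, mut_aa)


def build_feature_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Lesion x variable feature table; immune block log10(x+1)-transformed."""
    df = summaries.set_index("lesion_id")
    cols = {}
    for block, names in FEATURE_BLOCKS.items():
        for name in names:
            vals = df[name].astype(float)
            if block == "immune":
                vals = np.log10(vals + 1.0)
            cols[name] = vals
    out = pd.DataFrame(cols)
    out.attrs["blocks"] = {
        name: block for block, names in FEATURE_BLOCKS.items() for name in names
    }
    return out


def _patient_pair_stats(bundle: CohortBundle) -> pd.DataFrame:
    """Per-patient overlap statistics: shared NSEM %, shared clones %, binder overlap %."""
    thresholds = genomics.FilterThresholds()
    oracle = genomics.SyntheticAffinityOracle()
    rows = []
    for patient in bundle.patients:
        nsem_sets, reps, peptides = [], [], {}
        for les in patient.lesions:
            kept = genomics.filter_somatic_calls(les.variants, thresholds)
            nsem = [c for c in kept if c.effect == "NSEM"]
            nsem_sets.append({c.key for c in nsem})
            reps.append(les.repertoire)
            peps = []
            for c in nsem:
                peps.extend(_peptides_for_call(c))
            peptides[les.lesion_id] = peps
        shared_nsem = genomics.patient_overlap(nsem_sets)
        clone_pcts = [
            tcr.shared_clone_fraction(a, b)
            for i, a in enumerate(reps)
            for b in reps[i + 1:]
        ]
        _, binder_overlaps = genomics.classify_and_overlap_binders(peptides, oracle)
        binder_pcts = [ov.shared_pct for ov in binder_overlaps.values()]
        rows.append(
            {
                "patient_id": patient.patient_id,
                "arm": patient.arm,
                "n_lesions": len(patient.lesions),
                "shared_nsem_pct": shared_nsem,
                "shared_clone_pct": float(np.mean(clone_pcts)),
                "shared_binder_pct": float(np.mean(binder_pcts)),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: CohortConfig,
    outdir: str | Path,
    n_perm: int = 2000,
    write_cohort_files: bool = False,
) -> dict:
    """Generate a cohort from ``config``, run every analysis stage, and write
    per-stage CSVs plus ``report.json`` under ``outdir``.  Returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(config)
    if write_cohort_files:
        write_cohort(bundle, outdir / "cohort")

    summaries = lesion_summaries(bundle)
    summaries.to_csv(outdir / "lesion_summaries.csv", index=False)

    pair_stats = _patient_pair_stats(bundle)
    pair_stats.to_csv(outdir / "patient_overlap.csv", index=False)

    # --- responses
    sizes = summaries[["patient_id", "lesion_id", "baseline_size", "followup_size"]]
    lesion_resp, patient_resp = integrate.response_metrics(sizes)
    lesion_resp.to_csv(outdir / "responses.csv", index=False)
    patient_resp.to_csv(outdir / "response_heterogeneity.csv", index=False)

    # --- TCR sharing / top-clone restriction
    restriction_rows = []
    for patient in bundle.patients:
        lesions = {l.lesion_id: l.repertoire for l in patient.lesions}
        n_min = min(len(t[t["productive"]]) for t in lesions.values())
        counts = tcr.top_clone_restriction(lesions, rank=min(10, n_min))
        for lid, c in counts.items():
            restriction_rows.append(
                {"patient_id": patient.patient_id, "lesion_id": lid, **c}
            )
    pd.DataFrame(restriction_rows).to_csv(outdir / "top_clone_restriction.csv", index=False)

    # --- clustering branch lengths (genomic vs immune, per patient and arm)
    features = build_feature_table(summaries)
    blocks = features.attrs["blocks"]
    genomic_cols = [c for c, b in blocks.items() if b == "genomic"]
    immune_cols = [c for c, b in blocks.items() if b == "immune"]
    dg = integrate.cluster_samples(features[genomic_cols], block="genomic")
    # immune block clusters on correlation distance over the immune gene panel
    expr = pd.DataFrame(
        {l.lesion_id: np.log10(l.expression + 1.0) for l in bundle.lesions()}
    ).T
    di = integrate.cluster_samples(expr, block="immune")
    branch_rows = []
    lesion_to_patient = {l.lesion_id: p.patient_id for p in bundle.patients for l in p.lesions}
    for patient in bundle.patients:
        ids = [l.lesion_id for l in patient.lesions]
        branch_rows.append(
            {
                "patient_id": patient.patient_id,
                "arm": patient.arm,
                "genomic_branch_length": integrate.average_branch_length(dg, ids),
                "immune_branch_length": integrate.average_branch_length(di, ids),
            }
        )
    branch_df = pd.DataFrame(branch_rows)
    branch_df.to_csv(outdir / "branch_lengths.csv", index=False)

    # --- marker-response association (best-response indicator)
    best = {
        row["patient_id"]: row["best_lesion"] for _, row in patient_resp.iterrows()
    }
    indicator = [
        1 if lid == best[lesion_to_patient[lid]] else 0 for lid in features.index
    ]
    assoc = integrate.marker_response_association(
        features,
        indicator,
        [lesion_to_patient[lid] for lid in features.index],
        n_perm=n_perm,
        seed=config.seed + 1,
    )
    assoc_df = pd.DataFrame(
        [
            {"marker": a.marker, "effect": a.effect, "p": a.p_value, "q": a.q_value}
            for a in assoc
        ]
    )
    assoc_df.to_csv(outdir / "associations.csv", index=False)

    # --- Fisher median dichotomy on the classic markers
    responder = (lesion_resp.set_index("lesion_id").loc[features.index, "recist_class"]
                 .isin(["CR", "PR"]).to_numpy())
    fisher_rows = []
    for marker in ("nsem_count", "cd8_pct", "clonality"):
        try:
            odds, p, _ = integrate.fisher_median_dichotomy(
                features[marker].to_numpy(), responder
            )
        except ValueError:
            odds, p = np.nan, np.nan
        fisher_rows.append({"marker": marker, "odds_ratio": odds, "p": p})
    pd.DataFrame(fisher_rows).to_csv(outdir / "fisher_dichotomy.csv", index=False)

    # --- random forest importance (responder labels)
    rf_imp, oob = integrate.rf_importance(features, responder.astype(int), seed=config.seed + 2)
    rf_imp.rename("importance").to_csv(outdir / "rf_importance.csv")

    # --- cross-feature correlations
    corr_rows = []
    for name, (xcol, ycol) in {
        "nsem_vs_cd8": ("nsem_count", "cd8_pct"),
        "cd8_vs_clonality": ("cd8_pct", "clonality"),
        "nsem_vs_clonality": ("nsem_count", "clonality"),
        "entropy_vs_response": ("entropy", None),
    }.items():
        x = features[xcol].to_numpy()
        y = (
            summaries.set_index("lesion_id").loc[features.index, "percent_change"].to_numpy()
            if ycol is None
            else features[ycol].to_numpy()
        )
        r, p = integrate.correlate(x, y, method="spearman", n_perm=n_perm, seed=config.seed + 3)
        corr_rows.append({"pair": name, "spearman_rho": r, "p": p})
    corr_df = pd.DataFrame(corr_rows)
    corr_df.to_csv(outdir / "correlations.csv", index=False)

    # --- variable heatmap prep
    zmat, _ = integrate.variable_heatmap_prep(features)
    zmat.to_csv(outdir / "heatmap_zscores.csv")

    arm_branch = branch_df.groupby("arm")[["genomic_branch_length", "immune_branch_length"]].mean()
    report = {
        "seed": config.seed,
        "n_patients": len(bundle.patients),
        "n_lesions": len(summaries),
        "pct_patients_heterogeneous_ge_10": float(
            100.0 * patient_resp["heterogeneous_ge_10"].mean()
        ),
        "pct_patients_heterogeneous_ge_20": float(
            100.0 * patient_resp["heterogeneous_ge_20"].mean()
        ),
        "pct_patients_heterogeneous_ge_50": float(
            100.0 * patient_resp["heterogeneous_ge_50"].mean()
        ),
        "median_intrapatient_diff_pct": float(patient_resp["max_pairwise_diff"].median()),
        "mean_shared_nsem_pct": float(pair_stats["shared_nsem_pct"].mean()),
        "mean_shared_clone_pct": float(pair_stats["shared_clone_pct"].mean()),
        "mean_shared_binder_pct": float(pair_stats["shared_binder_pct"].mean()),
        "mean_ct_fraction": float(summaries["ct_fraction"].mean()),
        "entropy_response_spearman": float(
            corr_df.set_index("pair").loc["entropy_vs_response", "spearman_rho"]
        ),
        "mean_branch_length_by_arm": {
            arm: {
                "genomic": float(arm_branch.loc[arm, "genomic_branch_length"]),
                "immune": float(arm_branch.loc[arm, "immune_branch_length"]),
            }
            for arm in arm_branch.index
        },
        "rf_oob_error": float(oob),
        "top_rf_marker": str(rf_imp.idxmax()),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
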