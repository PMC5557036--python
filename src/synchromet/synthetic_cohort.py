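"""Synthetic multi-lesion cohort generator.

Emulates the data layout of a synchronous-metastasis study: each patient
carries two or more co-existing lesions, and each lesion contributes

* a somatic SNV table (trunk mutations shared across the patient's lesions,
  private mutations confined to one lesion, with configurable C>T spectrum
  fraction, depths, VAFs and database-contamination rate),
* a TCR repertoire (Zipf-distributed clone abundances with a configurable
  fraction of clones present in every lesion of the patient),
* a gene-expression vector and flow-cytometry immune fractions driven by a
  per-lesion latent immune factor,
* a 2-D grayscale image patch + binary mask whose high-frequency content is
  controlled by a latent complexity, and
* a percent-change-from-baseline response coupled (rank-wise) to that
  complexity.

All distributional choices (negative-binomial depths, Beta VAFs, log-normal
expression, Gaussian latent factors) are generator conventions — stand-ins
chosen to be realistic for the field, not claims about any measured dataset.
The generator is fully seeded: the same config yields a byte-identical
cohort.

Two calibrations keep the configured fractions recoverable downstream, where
shared percentages use a pairwise *union* denominator:

* a mutation is trunk with probability ``p = 2s / (L(1-s) + 2s)`` (``s`` the
  target shared fraction, ``L`` the lesion count), which makes the expected
  pairwise shared-NSEM percentage equal ``s`` for any ``L``;
* the per-patient shared clone set has size ``k = round(2nf / (1+f))`` so the
  pairwise clone Jaccard equals the configured sharing fraction ``f`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import tcr as tcr_mod
from .genomics import VariantCall, read_vcf, write_vcf
from .immune import IMMUNE_GENE_SETS, immune_gene_union

__all__ = [
    "CohortConfig",
    "LesionRecord",
    "PatientRecord",
    "CohortBundle",
    "generate_cohort",
    "simulate_lesion_variants",
    "simulate_repertoires",
    "simulate_expression_and_flow",
    "simulate_lesion_image_and_response",
    "replicate_expression",
    "write_cohort",
    "read_cohort",
    "cohorts_equal",
    "FLOW_SUBSETS",
]

FLOW_SUBSETS = (
    "CD4_T", "CD8_T", "Treg", "gd_T", "B", "NK",
    "DC", "macrophage", "mast", "neutrophil", "eosinophil", "basophil",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_SUBSTITUTIONS = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a and (r, a) not in (("C", "T"), ("G", "A"))
]


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``n_trunk_mutations + n_private_mutations`` sets the per-patient mutation
    pool size.  When ``shared_nsem_fraction`` is given (default) the
    trunk/private split is drawn per mutation with the calibrated trunk
    probability; when it is None the counts are used verbatim (exactly
    ``n_trunk_mutations`` trunk, the rest assigned to single lesions).
    """

    n_patients_per_arm: int = 5
    arms: tuple[str, ...] = ("targeted", "checkpoint", "naive")
    lesions_per_patient: tuple[int, int] = (2, 3)
    n_trunk_mutations: int = 120
    n_private_mutations: int = 80
    shared_nsem_fraction: float | None = 0.55
    ct_fraction: float = 0.79
    nsem_fraction: float = 0.8
    db_contamination: float = 0.05
    depth_mean: float = 150.0
    depth_dispersion: float = 10.0
    tumor_vaf_beta: tuple[float, float] = (5.0, 15.0)
    normal_vaf_beta: tuple[float, float] = (1.0, 2000.0)
    shared_clone_fraction: float = 0.08
    n_clones_per_lesion: int = 300
    zipf_exponent: float = 1.1
    productive_fraction: float = 0.9
    total_templates: float = 1000.0
    expr_mu: float = 4.0
    expr_sigma: float = 0.6
    immune_latent_sd: float = 0.8
    arm_immune_sd_scale: dict[str, float] = field(
        default_factory=lambda: {"targeted": 1.0, "checkpoint": 0.4, "naive": 1.0}
    )
    replicate_sigma: float = 0.15
    n_genes: int = 200
    image_size: int = 64
    texture_response_rho: float = 0.6
    response_scale: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_fraction", "nsem_fraction", "db_contamination",
                     "shared_clone_fraction", "productive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.shared_nsem_fraction is not None and not 0.0 <= self.shared_nsem_fraction <= 1.0:
            raise ValueError("shared_nsem_fraction outside [0, 1]")
        if not -1.0 <= self.texture_response_rho <= 1.0:
            raise ValueError("texture_response_rho outside [-1, 1]")
        for name in ("n_patients_per_arm", "n_trunk_mutations", "n_private_mutations",
                     "n_clones_per_lesion", "n_genes", "image_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.lesions_per_patient
        if lo < 2 or hi < lo:
            raise ValueError("lesions_per_patient must satisfy 2 <= lo <= hi")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be non-negative")


@dataclass
class LesionRecord:
    """Everything simulated (or loaded) for one metastatic lesion."""

    lesion_id: str
    patient_id: str
    variants: list[VariantCall]
    repertoire: pd.DataFrame
    expression: pd.Series
    immune_fractions: dict[str, float]
    image: np.ndarray
    mask: np.ndarray
    baseline_size: float
    followup_size: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.followup_size - self.baseline_size) / self.baseline_size

    @property
    def nsem_keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants if v.effect == "NSEM"}


@dataclass
class PatientRecord:
    patient_id: str
    arm: str
    lesions: list[LesionRecord]


@dataclass
class CohortBundle:
    patients: list[PatientRecord]
    truth: dict
    config: CohortConfig

    def lesions(self) -> list[LesionRecord]:
        return [les for p in self.patients for les in p.lesions]


def _trunk_probability(s: float, n_lesions: int) -> float:
    # calibrated so expected pairwise shared% (union denominator) equals s
    if s >= 1.0:
        return 1.0
    return 2.0 * s / (n_lesions * (1.0 - s) + 2.0 * s)


def _draw_substitution(rng: np.random.Generator, ct_fraction: float) -> tuple[str, str]:
    if rng.random() < ct_fraction:
        return ("C", "T") if rng.random() < 0.5 else ("G", "A")
    return _SUBSTITUTIONS[rng.integers(len(_SUBSTITUTIONS))]


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB parameterized by size r and p = r/(r+mean)
    r = dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p)) + 1  # avoid zero-depth calls


def simulate_lesion_variants(
    config: CohortConfig, n_lesions: int, rng: np.random.Generator
) -> tuple[list[list[VariantCall]], dict]:
    """Per-lesion somatic SNV tables for one patient.

    Trunk mutations are identical (same genomic key and evidence draws per
    lesion are independent) across lesions; private mutations are disjoint
    between lesions.
    """
    n_pool = config.n_trunk_mutations + config.n_private_mutations
    # distinct genomic positions for the pool
    positions = rng.choice(50_000_000, size=n_pool, replace=False) + 1
    chroms = rng.integers(1, 23, size=n_pool)
    if config.shared_nsem_fraction is not None:
        p_trunk = _trunk_probability(config.shared_nsem_fraction, n_lesions)
        is_trunk = rng.random(n_pool) < p_trunk
    else:
        is_trunk = np.zeros(n_pool, dtype=bool)
        is_trunk[: config.n_trunk_mutations] = True
    owner = rng.integers(0, n_lesions, size=n_pool)  # lesion owning each private mutation

    defs = []
    for m in range(n_pool):
        ref, alt = _draw_substitution(rng, config.ct_fraction)
        defs.append(
            {
                "chrom": f"chr{chroms[m]}",
                "pos": int(positions[m]),
                "ref": ref,
                "alt": alt,
                "gene": f"GENE{m:05d}",
                "effect": "NSEM" if rng.random() < config.nsem_fraction else "silent",
                "in_known_db": bool(rng.random() < config.db_contamination),
            }
        )

    a_t, b_t = config.tumor_vaf_beta
    a_n, b_n = config.normal_vaf_beta
    lesions: list[list[VariantCall]] = []
    for les in range(n_lesions):
        calls = []
        for m in range(n_pool):
            if not is_trunk[m] and owner[m] != les:
                continue
            calls.append(
                VariantCall(
                    tumor_depth=_nb_depth(rng, config.depth_mean, config.depth_dispersion),
                    normal_depth=_nb_depth(rng, config.depth_mean, config.depth_dispersion),
                    tumor_vaf=float(np.clip(rng.beta(a_t, b_t), 1e-6, 1.0)),
                    normal_vaf=float(min(rng.beta(a_n, b_n), 1.0)),
                    **defs[m],
                )
            )
        lesions.append(calls)
    truth = {
        "n_pool": n_pool,
        "n_trunk": int(is_trunk.sum()),
        "trunk_probability": float(is_trunk.mean()),
    }
    return lesions, truth


def _random_cdr3(rng: np.random.Generator) -> str:
    middle = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=int(rng.integers(6, 12))))
    return f"CASS{middle}F"


def simulate_repertoires(
    config: CohortConfig, n_lesions: int, rng: np.random.Generator
) -> tuple[list[pd.DataFrame], dict]:
    """Per-lesion clone tables with Zipf abundances and controlled sharing.

    ``k = round(2nf/(1+f))`` clones are present in every lesion; each lesion
    additionally carries ``n - k`` clones private to it.  Within a lesion,
    clone ranks are shuffled, then counts decay as ``ceil(C / rank^a)``.
    """
    n = config.n_clones_per_lesion
    f = config.shared_clone_fraction
    k = int(round(2 * n * f / (1 + f))) if f > 0 else 0
    k = min(k, n)

    def new_ids(count: int, existing: set[str]) -> list[str]:
        out: list[str] = []
        while len(out) < count:
            c = _random_cdr3(rng)
            if c not in existing:
                existing.add(c)
                out.append(c)
        return out

    seen: set[str] = set()
    shared_ids = new_ids(k, seen)
    productive_flags = {c: bool(rng.random() < config.productive_fraction) for c in shared_ids}

    tables = []
    for _ in range(n_lesions):
        private_ids = new_ids(n - k, seen)
        for c in private_ids:
            productive_flags[c] = bool(rng.random() < config.productive_fraction)
        ids = shared_ids + private_ids
        ranks = rng.permutation(n) + 1
        counts = np.ceil(config.total_templates / ranks.astype(float) ** config.zipf_exponent)
        tables.append(
            tcr_mod.make_clone_table(
                ids, counts.astype(int), [productive_flags[c] for c in ids]
            )
        )
    return tables, {"n_shared_clones": k, "n_clones": n}


def simulate_expression_and_flow(
    config: CohortConfig,
    n_lesions: int,
    rng: np.random.Generator,
    latent_sd: float | None = None,
) -> tuple[list[pd.Series], list[dict[str, float]], dict]:
    """Expression vectors and CD45-subset fractions for one patient's lesions.

    Expression is log-normal around patient-level gene baselines; a per-lesion
    latent immune factor ``z`` shifts the immune-score genes (and only those),
    so with ``latent_sd == 0`` all lesions of a patient have identical immune
    scores.  CD8 flow fractions are positively coupled to the same ``z``.
    """
    sd = config.immune_latent_sd if latent_sd is None else latent_sd
    immune_genes = list(immune_gene_union())
    n_filler = max(0, config.n_genes - len(immune_genes))
    genes = immune_genes + [f"FILLER{i:04d}" for i in range(n_filler)]
    baselines = config.expr_mu + config.expr_sigma * rng.standard_normal(len(genes))
    is_immune = np.array([g in set(immune_genes) for g in genes])

    z_vals = sd * rng.standard_normal(n_lesions)
    expr_list, flow_list = [], []
    alpha0 = np.full(len(FLOW_SUBSETS), 2.0)
    cd8_idx = FLOW_SUBSETS.index("CD8_T")
    for z in z_vals:
        vals = np.exp(baselines + np.where(is_immune, z, 0.0))
        expr_list.append(pd.Series(vals, index=genes, dtype=float))
        alpha = alpha0.copy()
        alpha[cd8_idx] *= float(np.exp(z))
        w = rng.dirichlet(alpha)
        total = 100.0 * rng.uniform(0.85, 1.0)
        flow_list.append({s: float(total * w[i]) for i, s in enumerate(FLOW_SUBSETS)})
    truth = {"latents": [float(z) for z in z_vals], "latent_sd": float(sd)}
    return expr_list, flow_list, truth


def replicate_expression(
    expression: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.Series:
    """A technical/within-lesion replicate: the lesion's expression plus
    log-normal measurement noise of sd ``replicate_sigma``."""
    noise = config.replicate_sigma * rng.standard_normal(len(expression))
    return expression * np.exp(noise)


def _lesion_image(
    config: CohortConfig, complexity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = config.image_size
    smooth = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=6.0)
    smooth /= max(smooth.std(), 1e-12)
    noise = rng.standard_normal((n, n))
    # cubing the complexity linearizes GLCM entropy in the latent rank:
    # entropy saturates quickly once noise dominates the smooth field
    w = complexity**3
    img = (1.0 - w) * smooth + w * noise
    lo, hi = img.min(), img.max()
    scaled = (img - lo) / max(hi - lo, 1e-12)
    image = np.round(scaled * 60000).astype(np.uint16)
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (0.38 * n) ** 2
    return image, mask


def simulate_lesion_image_and_response(
    config: CohortConfig, n_lesions: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray], list[float], list[float], dict]:
    """Images, masks, baseline sizes and percent changes for one patient.

    The latent complexity ``c ~ U(0.02, 0.98)`` mixes a smooth random field
    with white noise (weight ``c**3``, which keeps GLCM entropy approximately
    rank-linear in ``c``); the response percent change is generated through a
    Gaussian copula on ``c`` with correlation ``texture_response_rho``, so
    cohort-wide GLCM entropy and response have approximately the target
    Spearman rho.
    """
    rho = config.texture_response_rho
    images, masks, baselines, pct_changes, complexities = [], [], [], [], []
    for _ in range(n_lesions):
        c = float(rng.uniform(0.02, 0.98))
        complexities.append(c)
        img, mask = _lesion_image(config, c, rng)
        images.append(img)
        masks.append(mask)
        z_c = stats.norm.ppf(c)
        score = rho * z_c + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
        pct = float(np.clip(config.response_scale * score, -95.0, 180.0))
        pct_changes.append(pct)
        baselines.append(float(np.exp(np.log(25.0) + 0.4 * rng.standard_normal())))
    truth = {"complexities": complexities}
    return images, masks, baselines, pct_changes, truth


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full multi-arm cohort; deterministic under config.seed."""
    root_ss = np.random.SeedSequence(config.seed)
    patients: list[PatientRecord] = []
    truth: dict = {"seed": config.seed, "patients": {}}
    lo, hi = config.lesions_per_patient
    idx = 0
    for arm in config.arms:
        arm_scale = config.arm_immune_sd_scale.get(arm, 1.0)
        for _ in range(config.n_patients_per_arm):
            idx += 1
            pid = f"P{idx:03d}"
            rng = np.random.default_rng(root_ss.spawn(1)[0])
            n_lesions = int(rng.integers(lo, hi + 1))
            variants, var_truth = simulate_lesion_variants(config, n_lesions, rng)
            reps, rep_truth = simulate_repertoires(config, n_lesions, rng)
            exprs, flows, imm_truth = simulate_expression_and_flow(
                config, n_lesions, rng, latent_sd=config.immune_latent_sd * arm_scale
            )
            images, masks, bases, pcts, img_truth = simulate_lesion_image_and_response(
                config, n_lesions, rng
            )
            lesions = []
            for i in range(n_lesions):
                lid = f"{pid}_L{i + 1}"
                followup = bases[i] * (1.0 + pcts[i] / 100.0)
                lesions.append(
                    LesionRecord(
                        lesion_id=lid,
                        patient_id=pid,
                        variants=variants[i],
                        repertoire=reps[i],
                        expression=exprs[i],
                        immune_fractions=flows[i],
                        image=images[i],
                        mask=masks[i],
                        baseline_size=bases[i],
                        followup_size=followup,
                    )
                )
            patients.append(PatientRecord(patient_id=pid, arm=arm, lesions=lesions))
            truth["patients"][pid] = {
                "arm": arm,
                "n_lesions": n_lesions,
                "variants": var_truth,
                "repertoire": rep_truth,
                "immune": imm_truth,
                "image": img_truth,
                "percent_changes": [float(p) for p in pcts],
            }
    return CohortBundle(patients=patients, truth=truth, config=config)


# --- cohort I/O -------------------------------------------------------------


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = asdict(config)
    d["arms"] = list(d["arms"])
    d["lesions_per_patient"] = list(d["lesions_per_patient"])
    d["tumor_vaf_beta"] = list(d["tumor_vaf_beta"])
    d["normal_vaf_beta"] = list(d["normal_vaf_beta"])
    return d


def _config_from_jsonable(d: dict) -> CohortConfig:
    d = dict(d)
    d["arms"] = tuple(d["arms"])
    d["lesions_per_patient"] = tuple(d["lesions_per_patient"])
    d["tumor_vaf_beta"] = tuple(d["tumor_vaf_beta"])
    d["normal_vaf_beta"] = tuple(d["normal_vaf_beta"])
    return CohortConfig(**d)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write the cohort to disk: per-lesion VCF, repertoire TSV, flow CSV,
    image/mask PNGs; per-patient expression CSV (genes x lesions); cohort-wide
    sizes CSV and a JSON manifest echoing config, seed and generator truth."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    size_rows = []
    for patient in bundle.patients:
        pdir = outdir / "patients" / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        expr = pd.DataFrame({les.lesion_id: les.expression for les in patient.lesions})
        expr.index.name = "gene"
        expr.to_csv(pdir / "expression.csv", float_format="%.17g")
        for les in patient.lesions:
            ldir = pdir / les.lesion_id
            ldir.mkdir(exist_ok=True)
            write_vcf(les.variants, ldir / "variants.vcf")
            tcr_mod.write_immunoseq_tsv(les.repertoire, ldir / "repertoire.tsv")
            flow = pd.DataFrame(
                {"subset": list(les.immune_fractions), "pct_of_cd45": list(les.immune_fractions.values())}
            )
            flow.to_csv(ldir / "flow.csv", index=False, float_format="%.17g")
            iio.imwrite(ldir / "image.png", les.image)
            iio.imwrite(ldir / "mask.png", les.mask.astype(np.uint8) * 255)
            size_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "lesion_id": les.lesion_id,
                    "arm": patient.arm,
                    "baseline_size": les.baseline_size,
                    "followup_size": les.followup_size,
                }
            )
    pd.DataFrame(size_rows).to_csv(outdir / "sizes.csv", index=False, float_format="%.17g")
    manifest = {
        "config": _config_to_jsonable(bundle.config),
        "truth": bundle.truth,
        "patients": {p.patient_id: {"arm": p.arm, "lesions": [l.lesion_id for l in p.lesions]} for p in bundle.patients},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_cohort(outdir: str | Path) -> CohortBundle:
    """Reload a cohort written by :func:`write_cohort`."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    config = _config_from_jsonable(manifest["config"])
    sizes = pd.read_csv(outdir / "sizes.csv", float_precision="round_trip").set_index("lesion_id")
    patients = []
    for pid, pinfo in manifest["patients"].items():
        pdir = outdir / "patients" / pid
        expr = pd.read_csv(pdir / "expression.csv", index_col="gene", float_precision="round_trip")
        lesions = []
        for lid in pinfo["lesions"]:
            ldir = pdir / lid
            flow_df = pd.read_csv(ldir / "flow.csv", float_precision="round_trip")
            lesions.append(
                LesionRecord(
                    lesion_id=lid,
                    patient_id=pid,
                    variants=read_vcf(ldir / "variants.vcf"),
                    repertoire=tcr_mod.read_immunoseq_tsv(ldir / "repertoire.tsv"),
                    expression=expr[lid],
                    immune_fractions=dict(zip(flow_df["subset"], flow_df["pct_of_cd45"].astype(float))),
                    image=np.asarray(iio.imread(ldir / "image.png"), dtype=np.uint16),
                    mask=np.asarray(iio.imread(ldir / "mask.png")) > 0,
                    baseline_size=float(sizes.loc[lid, "baseline_size"]),
                    followup_size=float(sizes.loc[lid, "followup_size"]),
                )
            )
        patients.append(PatientRecord(patient_id=pid, arm=pinfo["arm"], lesions=lesions))
    return CohortBundle(patients=patients, truth=manifest["truth"], config=config)


def cohorts_equal(a: CohortBundle, b: CohortBundle, strict_floats: bool = True) -> bool:
    """Field-wise equality of two cohorts (used for determinism/round-trip checks)."""

    def close(x: float, y: float) -> bool:
        return x == y if strict_floats else abs(x - y) < 1e-9

    if len(a.patients) != len(b.patients):
        return False
    for pa, pb in zip(a.patients, b.patients):
        if (pa.patient_id, pa.arm) != (pb.patient_id, pb.arm):
            return False
        if len(pa.lesions) != len(pb.lesions):
            return False
        for la, lb in zip(pa.lesions, pb.lesions):
            if la.lesion_id != lb.lesion_id:
                return False
            if sorted(v.key for v in la.variants) != sorted(v.key for v in lb.variants):
                return False
            va = {v.key: v for v in la.variants}
            vb = {v.key: v for v in lb.variants}
            for key, call in va.items():
                other = vb[key]
                if (call.tumor_depth, call.normal_depth, call.gene, call.effect,
                        call.in_known_db) != (other.tumor_depth, other.normal_depth,
                                              other.gene, other.effect, other.in_known_db):
                    return False
                if not (close(call.tumor_vaf, other.tumor_vaf) and close(call.normal_vaf, other.normal_vaf)):
                    return False
            ra = la.repertoire.sort_values("clone_id").reset_index(drop=True)
            rb = lb.repertoire.sort_values("clone_id").reset_index(drop=True)
            if not ra.equals(rb):
                return False
            ea = la.expression.sort_index()
            eb = lb.expression.sort_index()
            if list(ea.index) != list(eb.index):
                return False
            if not all(close(x, y) for x, y in zip(ea.values, eb.values)):
                return False
            if la.immune_fractions.keys() != lb.immune_fractions.keys():
                return False
            if not all(close(la.immune_fractions[k], lb.immune_fractions[k]) for k in la.immune_fractions):
                return False
            if not np.array_equal(la.image, lb.image) or not np.array_equal(la.mask, lb.mask):
                return False
            if not (close(la.baseline_size, lb.baseline_size) and close(la.followup_size, lb.followup_size)):
                return False
    return True
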