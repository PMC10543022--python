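"""Synthetic-data generators with known ground truth.

Two generators cover the pipeline's inputs:

* :func:`simulate_cohort` builds a multi-wave untargeted-metabolomics study:
  log-normal metabolite abundances with run-day/batch multiplicative
  structure, pooled reference samples with controlled technical CV, MNAR-
  weighted missingness, family-clustered subjects with a probit liability
  model for depression status, covariates, and known phenotype- and
  antidepressant-driven effects on disjoint metabolite subsets.

* :func:`simulate_sumstats` builds paired two-sample GWAS summary
  statistics: per-metabolite exposure GWAS with configurable instrument
  strength, an outcome (depression) GWAS with a known causal effect per
  metabolite and tunable horizontal pleiotropy, palindromic variants, LD
  proxies and a matching pairwise LD map.

Defaults are sized for desk scale (600 subjects, 200 metabolites, 4
batches, 20 SNPs per metabolite) while echoing the magnitudes of a large
clinical depression cohort: a 30/30/40 control/remitted/current mix,
exposure GWAS of 14,000 and an outcome GWAS of ~246k cases / ~561k
controls with a causal log-odds of 0.09 per SD of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, CohortTruth, MrTruth, ValidationError

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort.

    Effect sizes (``assoc_delta``, ``ad_delta``, covariate effects) are in
    within-metabolite SD units on the log2 scale.  ``mnar_weight`` moves the
    missingness mechanism from fully random (0) to fully low-abundance
    driven (1).
    """

    n_subjects: int = 600
    n_families: int = 260
    family_size_probs: tuple = (0.45, 0.35, 0.15, 0.05)  # P(size = 1..4) before rebalancing
    n_metabolites: int = 200
    n_waves: int = 2
    followup_fraction: float = 0.8
    n_batches: int = 4
    run_days_per_batch: int = 3
    plates_per_batch: int = 2
    n_reference_samples: int = 40
    cv_log_median: float = 0.08  # median technical CV of the log-normal CV distribution
    cv_log_sigma: float = 0.6
    missing_rate: float = 0.03
    mnar_weight: float = 0.5
    n_assoc_true: int = 20
    assoc_delta: float = 0.5  # current-MDD shift, SD units on log2 scale
    remitted_ratio: float = 0.7  # remitted shift as a fraction of the current shift
    frac_downregulated: float = 0.6
    n_ad_true: int = 1
    ad_delta: float = 1.5  # TCA-driven shift for AD-affected metabolites
    n_cov_affected: int = 30
    cov_delta: float = 0.15  # sex/age/BMI effects on affected metabolites
    status_props: tuple = (0.30, 0.30, 0.40)  # control, remitted, current at baseline
    family_liability_corr: float = 0.3
    wave_persistence: float = 0.6  # subject-level correlation of biological noise across waves
    runday_log_sd: float = 0.20
    batch_log_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_subjects, self.n_families, self.n_metabolites, self.n_waves,
            self.n_batches, self.run_days_per_batch, self.plates_per_batch,
            self.n_reference_samples,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all cohort counts must be positive")
        if self.n_families > self.n_subjects:
            raise ValidationError(
                f"infeasible family partition: {self.n_families} families for "
                f"{self.n_subjects} subjects"
            )
        if not 0.0 <= self.mnar_weight <= 1.0:
            raise ValidationError("mnar_weight must be in [0, 1]")
        if self.n_assoc_true + self.n_ad_true > self.n_metabolites:
            raise ValidationError("n_assoc_true + n_ad_true exceeds n_metabolites")
        if self.n_waves > 3:
            raise ValidationError("at most three waves are supported")
        if not 0 < sum(self.status_props) <= 1 + 1e-9 or len(self.status_props) != 3:
            raise ValidationError("status_props must be three fractions summing to 1")


def _family_sizes(cfg: CohortSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw family sizes for n_families families summing exactly to n_subjects."""
    sizes = rng.choice(
        np.arange(1, len(cfg.family_size_probs) + 1),
        size=cfg.n_families,
        p=np.asarray(cfg.family_size_probs) / sum(cfg.family_size_probs),
    ).astype(int)
    diff = cfg.n_subjects - int(sizes.sum())
    while diff != 0:
        i = rng.integers(cfg.n_families)
        if diff > 0:
            sizes[i] += 1
            diff -= 1
        elif sizes[i] > 1:
            sizes[i] -= 1
            diff += 1
    return sizes


def _simulate_phenotypes(cfg: CohortSimConfig, rng: np.random.Generator):
    """Subjects, families, liabilities, baseline status and covariates."""
    sizes = _family_sizes(cfg, rng)
    family_id = np.repeat([f"F{i:04d}" for i in range(cfg.n_families)], sizes)
    subject_id = np.array([f"S{i:04d}" for i in range(cfg.n_subjects)])

    # probit liability with a family-level random effect
    rho = cfg.family_liability_corr
    fam_eff = np.repeat(rng.standard_normal(cfg.n_families), sizes)
    liability = np.sqrt(rho) * fam_eff + np.sqrt(1.0 - rho) * rng.standard_normal(cfg.n_subjects)
    # thresholds hit the configured control/remitted/current proportions
    p_ctrl, p_rem, _ = cfg.status_props
    t1 = stats.norm.ppf(p_ctrl)
    t2 = stats.norm.ppf(p_ctrl + p_rem)
    status = np.where(liability < t1, "control", np.where(liability < t2, "remitted", "current"))

    sex = rng.choice(["female", "male"], size=cfg.n_subjects, p=[0.65, 0.35])
    age = np.clip(rng.normal(43, 13, cfg.n_subjects), 18, 65).round(1)
    education = np.clip(rng.normal(12, 3, cfg.n_subjects), 5, 22).round(0)
    physical_activity = np.clip(rng.lognormal(8.0, 0.8, cfg.n_subjects), 0, 30000).round(0)
    smoking = rng.choice(["never", "ex", "current"], size=cfg.n_subjects, p=[0.45, 0.3, 0.25])
    alcohol = np.clip(rng.lognormal(1.2, 1.0, cfg.n_subjects), 0, 60).round(1)
    n_chronic = rng.poisson(0.7, cfg.n_subjects)
    # BMI mildly higher with depression liability
    bmi = np.clip(26 + 0.6 * liability + rng.normal(0, 4.8, cfg.n_subjects), 16, 45).round(1)
    shipment = rng.choice([1, 2], size=cfg.n_subjects, p=[0.6, 0.4])
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "family_id": family_id,
            "mdd_status": status,
            "sex": sex,
            "age": age,
            "education": education,
            "physical_activity": physical_activity,
            "smoking": smoking,
            "alcohol": alcohol,
            "n_chronic_diseases": n_chronic,
            "bmi": bmi,
            "shipment": shipment,
        }
    ), pd.Series(liability, index=subject_id, name="liability")


_IDS_BY_STATUS = {"control": (8.0, 5.0), "remitted": (15.0, 7.0), "current": (30.0, 9.0)}


def _ids_scores(status: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = np.array([_IDS_BY_STATUS[s][0] for s in status])
    sd = np.array([_IDS_BY_STATUS[s][1] for s in status])
    return np.clip(np.round(rng.normal(mu, sd)), 0, 84).astype(int)


def _assign_ad_use(status: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Antidepressant class flags, concentrated in (and driven by) current MDD."""
    n = len(status)
    cur = status == "current"
    rem = status == "remitted"
    p_ssri = np.where(cur, 0.27, np.where(rem, 0.10, 0.0))
    p_tca = np.where(cur, 0.10, np.where(rem, 0.03, 0.0))
    p_snri = np.where(cur, 0.11, np.where(rem, 0.04, 0.0))
    u = rng.random((n, 3))
    return pd.DataFrame(
        {"ad_ssri": u[:, 0] < p_ssri, "ad_tca": u[:, 1] < p_tca, "ad_snri": u[:, 2] < p_snri}
    )


_TRANSITION = {
    # baseline status -> probabilities of (control, remitted, current) at follow-up
    "control": (0.85, 0.10, 0.05),
    "remitted": (0.10, 0.72, 0.18),
    "current": (0.05, 0.55, 0.40),
}


def simulate_cohort(config: CohortSimConfig | None = None):
    """Generate a full synthetic cohort.

    Returns
    -------
    (AbundanceMatrix, PhenotypeTable, PathwayAnnotation, CohortTruth)
        Raw-scale abundances (experimental + reference samples) with
        technical metadata; one phenotype row per subject per wave;
        a pathway annotation table; and the ground truth.
    """
    cfg = config or CohortSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    base, liability = _simulate_phenotypes(cfg, rng)
    met_ids = np.array([f"M{i:04d}" for i in range(cfg.n_metabolites)])

    # --- metabolite-level parameters ------------------------------------
    mu = rng.normal(17.0, 2.0, cfg.n_metabolites)  # log2 abundance level
    bio_sd = rng.lognormal(np.log(0.5), 0.3, cfg.n_metabolites)  # biological log2 SD
    cv = rng.lognormal(np.log(cfg.cv_log_median), cfg.cv_log_sigma, cfg.n_metabolites)
    tech_log_sd = np.sqrt(np.log1p(cv**2))  # natural-log SD of multiplicative noise
    total_sd = np.sqrt(bio_sd**2 + (tech_log_sd / LN2) ** 2)  # total log2 SD

    # disjoint truly-affected subsets
    perm = rng.permutation(cfg.n_metabolites)
    assoc_idx = perm[: cfg.n_assoc_true]
    ad_idx = perm[cfg.n_assoc_true: cfg.n_assoc_true + cfg.n_ad_true]
    signs = np.where(rng.random(cfg.n_assoc_true) < cfg.frac_downregulated, -1.0, 1.0)
    assoc_effects = pd.Series(0.0, index=met_ids)
    assoc_effects.iloc[assoc_idx] = signs * cfg.assoc_delta
    ad_effects = pd.Series(0.0, index=met_ids)
    ad_effects.iloc[ad_idx] = cfg.ad_delta * np.where(rng.random(cfg.n_ad_true) < 0.5, -1, 1)

    cov_idx = rng.choice(cfg.n_metabolites, size=min(cfg.n_cov_affected, cfg.n_metabolites),
                         replace=False)
    cov_beta = np.zeros((cfg.n_metabolites, 3))  # columns: sex(female), age(z), bmi(z)
    cov_beta[cov_idx] = rng.normal(0, cfg.cov_delta, (len(cov_idx), 3))

    # --- technical structure --------------------------------------------
    batches = [f"B{b:02d}" for b in range(cfg.n_batches)]
    rundays = [f"{b}-D{d}" for b in batches for d in range(cfg.run_days_per_batch)]
    plates = [f"{b}-P{p}" for b in batches for p in range(cfg.plates_per_batch)]
    runday_f = pd.Series(rng.lognormal(0.0, cfg.runday_log_sd, len(rundays)), index=rundays)
    batch_f = pd.Series(rng.lognormal(0.0, cfg.batch_log_sd, len(batches)), index=batches)

    # --- per-wave phenotype rows and samples ----------------------------
    wave_labels = ["baseline", "follow-up-6y", "follow-up-9y"][: cfg.n_waves]
    phen_rows, sample_ids, meta_rows = [], [], []
    log2_signal = []
    subj_latent = rng.standard_normal((cfg.n_subjects, cfg.n_metabolites))
    status_by_wave: dict[str, np.ndarray] = {}
    in_wave: dict[str, np.ndarray] = {}

    status = base["mdd_status"].to_numpy().copy()
    present = np.ones(cfg.n_subjects, dtype=bool)
    for w, wave in enumerate(wave_labels):
        if w > 0:
            present = present & (rng.random(cfg.n_subjects) < cfg.followup_fraction)
            probs = np.array([_TRANSITION[s] for s in status])
            u = rng.random(cfg.n_subjects)
            cum = probs.cumsum(axis=1)
            status = np.where(u < cum[:, 0], "control",
                              np.where(u < cum[:, 1], "remitted", "current"))
        status_by_wave[wave] = status.copy()
        in_wave[wave] = present.copy()
        ids_total = _ids_scores(status, rng)
        ad = _assign_ad_use(status, rng)

        idx = np.flatnonzero(present)
        wave_phen = base.iloc[idx].copy()
        wave_phen["wave"] = wave
        wave_phen["mdd_status"] = status[idx]
        wave_phen["ids_total"] = ids_total[idx]
        wave_phen[["ad_ssri", "ad_tca", "ad_snri"]] = ad.iloc[idx].to_numpy()
        if w > 0:
            wave_phen["age"] = (wave_phen["age"] + 3 * w).round(1)
        phen_rows.append(wave_phen)

        # log2 biological signal for each present subject
        eps = (np.sqrt(cfg.wave_persistence) * subj_latent
               + np.sqrt(1 - cfg.wave_persistence)
               * rng.standard_normal((cfg.n_subjects, cfg.n_metabolites)))
        stat_eff = np.zeros((cfg.n_subjects, cfg.n_metabolites))
        cur = (status == "current")[:, None]
        rem = (status == "remitted")[:, None]
        delta_vec = (assoc_effects.to_numpy() * total_sd)[None, :]
        stat_eff = cur * delta_vec + rem * cfg.remitted_ratio * delta_vec
        ad_vec = (ad_effects.to_numpy() * total_sd)[None, :]
        ad_eff = ad["ad_tca"].to_numpy()[:, None] * ad_vec
        female = (base["sex"].to_numpy() == "female").astype(float)
        age_z = (base["age"].to_numpy() - 43) / 13
        bmi_z = (base["bmi"].to_numpy() - 26) / 5
        cov_eff = (np.outer(female, cov_beta[:, 0]) + np.outer(age_z, cov_beta[:, 1])
                   + np.outer(bmi_z, cov_beta[:, 2])) * total_sd[None, :]
        sig = mu[None, :] + bio_sd[None, :] * eps + stat_eff + ad_eff + cov_eff
        log2_signal.append(sig[idx])
        for i in idx:
            sample_ids.append(f"S{i:04d}-{wave}")

    phen = pd.concat(phen_rows, ignore_index=True)
    phen = phen[
        ["subject_id", "family_id", "wave", "mdd_status", "ids_total", "sex", "age",
         "education", "physical_activity", "smoking", "alcohol", "n_chronic_diseases",
         "bmi", "shipment", "ad_ssri", "ad_tca", "ad_snri"]
    ]

    # --- experimental + reference samples with technical structure ------
    n_exp = len(sample_ids)
    exp_signal = np.vstack(log2_signal)
    ref_ids = [f"REF{i:04d}" for i in range(cfg.n_reference_samples)]
    ref_signal = np.tile(mu, (cfg.n_reference_samples, 1))  # one fixed plasma profile

    all_ids = sample_ids + ref_ids
    n_all = n_exp + cfg.n_reference_samples
    sample_batch = np.array(batches)[rng.integers(0, cfg.n_batches, n_all)]
    # references evenly across batches so every batch carries some
    sample_batch[n_exp:] = np.array(batches)[np.arange(cfg.n_reference_samples) % cfg.n_batches]
    sample_runday = np.array(
        [f"{b}-D{rng.integers(cfg.run_days_per_batch)}" for b in sample_batch]
    )
    sample_plate = np.array(
        [f"{b}-P{rng.integers(cfg.plates_per_batch)}" for b in sample_batch]
    )
    wave_of_sample = [sid.split("-", 1)[1] for sid in sample_ids] + ["baseline"] * cfg.n_reference_samples

    signal = np.vstack([exp_signal, ref_signal])
    tech = rng.lognormal(
        -0.5 * tech_log_sd[None, :] ** 2, np.tile(tech_log_sd, (n_all, 1))
    )
    raw = (
        np.exp2(signal)
        * runday_f.loc[sample_runday].to_numpy()[:, None]
        * batch_f.loc[sample_batch].to_numpy()[:, None]
        * tech
    )

    # --- MNAR-weighted missingness --------------------------------------
    if cfg.missing_rate > 0:
        w = cfg.mnar_weight
        ranks = pd.DataFrame(raw).rank(axis=0, method="average").to_numpy()
        u_rank = (ranks - 0.5) / n_all  # in (0,1), small = low abundance
        p_cell = cfg.missing_rate * ((1 - w) + 2.0 * w * (1.0 - u_rank))
        miss = rng.random(raw.shape) < p_cell
        raw = np.where(miss, np.nan, raw)

    values = pd.DataFrame(raw, index=all_ids, columns=met_ids)
    meta = pd.DataFrame(
        {
            "batch": sample_batch,
            "plate": sample_plate,
            "run_day": sample_runday,
            "wave": wave_of_sample,
            "is_reference": [False] * n_exp + [True] * cfg.n_reference_samples,
            "subject_id": [sid.split("-", 1)[0] for sid in sample_ids]
            + [None] * cfg.n_reference_samples,
        },
        index=all_ids,
    )
    matrix = AbundanceMatrix(values, meta, scale="raw")

    annotation = _simulate_annotation(met_ids, rng)
    truth = CohortTruth(
        assoc_effects=assoc_effects,
        ad_effects=ad_effects,
        liability=liability,
        family_liability_corr=cfg.family_liability_corr,
        technical_cv=pd.Series(cv, index=met_ids),
        runday_factors=runday_f,
        batch_factors=batch_f,
        log2_sd=pd.Series(total_sd, index=met_ids),
    )
    return matrix, phen, annotation, truth


_SUPER_PATHWAYS = {
    "Lipid": ["Lysophospholipid", "Long Chain Monounsaturated Fatty Acid",
              "Long Chain Saturated Fatty Acid", "Phosphatidylcholine", "Sphingomyelins"],
    "Amino Acid": ["Glycine Serine and Threonine Metabolism", "Tryptophan Metabolism",
                   "Branched Chain Amino Acid"],
    "Carbohydrate": ["Glycolysis and Gluconeogenesis", "Fructose Mannose and Galactose"],
    "Cofactors and Vitamins": ["Hemoglobin and Porphyrin Metabolism", "Tocopherol Metabolism"],
    "Energy": ["TCA Cycle"],
    "Nucleotide": ["Purine Metabolism"],
    "Xenobiotics": ["Food Component/Plant", "Xanthine Metabolism"],
}


def _simulate_annotation(met_ids: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Assign super/sub pathways to ~83% of metabolites, leave the rest unclassified."""
    supers = list(_SUPER_PATHWAYS)
    sup_p = np.array([0.45, 0.15, 0.08, 0.07, 0.05, 0.08, 0.12])
    rows = []
    for mid in met_ids:
        if rng.random() < 0.17:
            rows.append({"metabolite_id": mid, "super_pathway": None, "sub_pathway": None})
        else:
            sp = supers[rng.choice(len(supers), p=sup_p / sup_p.sum())]
            sub = _SUPER_PATHWAYS[sp][rng.integers(len(_SUPER_PATHWAYS[sp]))]
            rows.append({"metabolite_id": mid, "super_pathway": sp, "sub_pathway": sub})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GWAS summary-statistics simulation
# ---------------------------------------------------------------------------

@dataclass
class MrSimConfig:
    """Parameters of the paired exposure/outcome GWAS simulation.

    ``theta`` is the causal log-odds of the outcome per SD of exposure,
    applied to the first ``n_causal`` metabolites; the rest are null.
    ``pleiotropy_frac`` of each metabolite's instruments get a direct
    outcome effect drawn per ``pleiotropy_mode``.
    """

    n_metabolites: int = 20
    snps_per_metabolite: int = 20
    r2_per_snp: float = 0.01  # exposure variance explained per instrument (F ~ 140)
    n_exposure: int = 14000
    n_cases: int = 246363
    n_controls: int = 561190
    theta: float = 0.09
    n_causal: int = 2
    pleiotropy_frac: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.02
    maf_range: tuple = (0.05, 0.5)
    palindromic_frac: float = 0.2
    n_null_snps: int = 30  # extra non-associated SNPs per exposure file
    ld_proxies_per_snp: int = 0
    proxy_r2: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValidationError("pleiotropy_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie in (0, 0.5]")
        if not 0.0 < self.r2_per_snp < 1.0:
            raise ValidationError("r2_per_snp must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _binary_se(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Log-odds SE approximation: 1/sqrt(2 maf (1-maf) n_eff v), v = 1/4."""
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff * 0.25)


def simulate_sumstats(config: MrSimConfig | None = None):
    """Generate per-metabolite exposure GWAS, one outcome GWAS, an LD map
    and the ground truth.

    Returns
    -------
    (dict[str, DataFrame], DataFrame, dict, MrTruth)
        Exposure summary statistics keyed by metabolite id, the outcome
        summary statistics covering every exposure variant, a pairwise LD
        r² lookup, and the ground truth.
    """
    cfg = config or MrSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    met_ids = [f"M{i:04d}" for i in range(cfg.n_metabolites)]
    theta = pd.Series(0.0, index=met_ids)
    theta.iloc[: cfg.n_causal] = cfg.theta

    exposures: dict[str, pd.DataFrame] = {}
    outcome_rows = []
    ld_map: dict[frozenset, float] = {}
    pleio_records, bx_records = {}, {}
    snp_counter = 0

    for mi, mid in enumerate(met_ids):
        k = cfg.snps_per_metabolite
        n_tot = k * (1 + cfg.ld_proxies_per_snp) + cfg.n_null_snps
        maf = rng.uniform(*cfg.maf_range, n_tot)
        # positions far apart so instruments are distance-independent
        chrom = (np.arange(snp_counter, snp_counter + n_tot) % 22) + 1
        pos = 1_000_000 + 20_000_000 * np.arange(n_tot)
        ids = [f"rs{snp_counter + j:07d}" for j in range(n_tot)]
        snp_counter += n_tot

        b_true = np.zeros(n_tot)
        b_true[:k] = (np.sqrt(cfg.r2_per_snp / (2 * maf[:k] * (1 - maf[:k])))
                      * rng.choice([-1.0, 1.0], k))
        # LD proxies sit right next to their index SNP, sharing most of its signal
        for j in range(k):
            for q in range(cfg.ld_proxies_per_snp):
                pj = k + j * cfg.ld_proxies_per_snp + q
                pos[pj] = pos[j] + 25_000 * (q + 1)
                chrom[pj] = chrom[j]
                b_true[pj] = np.sqrt(cfg.proxy_r2) * b_true[j]
                ld_map[frozenset((ids[j], ids[pj]))] = cfg.proxy_r2

        se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure)
        beta_x = rng.normal(b_true, se_x)
        p_x = 2 * stats.norm.sf(np.abs(beta_x / se_x))

        pal = rng.random(n_tot) < cfg.palindromic_frac
        pair_idx = rng.integers(len(_ALLELE_PAIRS), size=n_tot)
        pal_idx = rng.integers(len(_PALINDROMES), size=n_tot)
        ea = np.where(pal, [_PALINDROMES[i][0] for i in pal_idx],
                      [_ALLELE_PAIRS[i][0] for i in pair_idx])
        oa = np.where(pal, [_PALINDROMES[i][1] for i in pal_idx],
                      [_ALLELE_PAIRS[i][1] for i in pair_idx])

        exposures[mid] = pd.DataFrame(
            {
                "variant_id": ids, "chr": chrom.astype(str), "pos": pos,
                "effect_allele": ea, "other_allele": oa, "eaf": maf,
                "beta": beta_x, "se": se_x, "pvalue": np.clip(p_x, 1e-300, 1.0),
                "n": cfg.n_exposure,
            }
        )

        # pleiotropy on a fraction of the true instruments
        alpha = np.zeros(n_tot)
        if cfg.pleiotropy_mode != "none" and cfg.pleiotropy_frac > 0:
            chosen = rng.random(k) < cfg.pleiotropy_frac
            if cfg.pleiotropy_mode == "balanced":
                alpha[:k][chosen] = rng.normal(0.0, cfg.pleiotropy_sd, chosen.sum())
            else:
                # directional: positive-mean direct effects in the orientation
                # of the exposure-increasing allele (the orientation MR-Egger
                # fits in), otherwise sign-flipping would re-balance them
                alpha[:k][chosen] = (
                    cfg.pleiotropy_sd
                    * np.abs(1.0 + 0.25 * rng.standard_normal(chosen.sum()))
                    * np.sign(b_true[:k][chosen])
                )
        b_y = theta.iloc[mi] * b_true + alpha
        se_y = _binary_se(maf, cfg.n_cases, cfg.n_controls)
        beta_y = rng.normal(b_y, se_y)
        p_y = 2 * stats.norm.sf(np.abs(beta_y / se_y))

        # outcome file sometimes lists the swapped allele order; harmonization
        # must undo this
        swap = rng.random(n_tot) < 0.3
        out_ea = np.where(swap, oa, ea)
        out_oa = np.where(swap, ea, oa)
        out_beta = np.where(swap, -beta_y, beta_y)
        out_eaf = np.where(swap, 1 - maf, maf)
        outcome_rows.append(pd.DataFrame(
            {
                "variant_id": ids, "chr": chrom.astype(str), "pos": pos,
                "effect_allele": out_ea, "other_allele": out_oa, "eaf": out_eaf,
                "beta": out_beta, "se": se_y, "pvalue": np.clip(p_y, 1e-300, 1.0),
                "n": cfg.n_cases + cfg.n_controls,
            }
        ))
        pleio_records.update(dict(zip(ids, alpha)))
        bx_records.update(dict(zip(ids, b_true)))

    outcome = pd.concat(outcome_rows, ignore_index=True)
    truth = MrTruth(
        theta=theta,
        pleiotropy=pd.Series(pleio_records),
        true_beta_exposure=pd.Series(bx_records),
    )
    return exposures, outcome, ld_map, truth


__all__ = ["CohortSimConfig", "MrSimConfig", "simulate_cohort", "simulate_sumstats"]
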