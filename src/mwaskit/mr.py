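"""Two-sample Mendelian randomization from GWAS summary statistics.

Implemented from first principles: instrument selection (variant filters,
MAF, strand ambiguity, genome-wide significance, greedy LD clumping),
allele harmonization between exposure and outcome studies, the
inverse-variance-weighted (IVW), weighted-median and MR-Egger estimators,
and the Cochran Q, Egger-intercept and global outlier (residual
sum-of-squares simulation) heterogeneity/pleiotropy diagnostics, plus
single-SNP and leave-one-out scans.

Conventions: IVW is the fixed-effect estimator with multiplicative
variance inflation max(1, Q/(k-1)); the Egger regression flips instruments
so all exposure effects are non-negative and uses a t(k-2) reference with
multiplicative overdispersion; the weighted-median SE comes from a seeded
parametric bootstrap.  Causal estimates for a binary outcome are log-odds
per SD of exposure; odds ratios are exp(estimate) with Wald 95% CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .datatypes import ValidationError, validate_sumstats

logger = logging.getLogger("mwaskit")

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_VALID = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------------

def select_instruments(
    exp: pd.DataFrame,
    maf_min: float = 0.01,
    p_max: float = 5.0e-8,
    clump_kb: float = 10_000,
    clump_r2: float = 0.001,
    ld: dict | None = None,
) -> pd.DataFrame:
    """Filter and clump exposure summary statistics down to instruments.

    Keeps biallelic SNVs, drops strand-ambiguous (A/T, C/G) variants and
    minor-allele frequency < ``maf_min``, keeps p < ``p_max``, then greedily
    clumps by p-value: a variant survives iff no already-kept variant on the
    same chromosome lies within ``clump_kb`` kb with LD r² >= ``clump_r2``.
    Without an LD map the clumping is distance-only (any pair within the
    window conflicts).
    """
    validate_sumstats(exp)
    df = exp.copy()
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    snv = ea.isin(_VALID) & oa.isin(_VALID) & (ea != oa)
    pal = [frozenset((a, b)) in _PALINDROMIC for a, b in zip(ea, oa)]
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = snv & ~np.asarray(pal) & (maf >= maf_min) & (df["pvalue"] < p_max)
    df = df[keep].sort_values("pvalue", kind="stable")

    if len(df) and df["pos"].isna().any():
        raise ValidationError("positions required for clumping")
    kept_rows = []
    kept_by_chr: dict[str, list[tuple[float, str]]] = {}
    window = clump_kb * 1_000.0
    for row in df.itertuples(index=False):
        conflict = False
        for pos, vid in kept_by_chr.get(row.chr, ()):
            if abs(row.pos - pos) <= window:
                if ld is None:
                    conflict = True
                else:
                    r2 = ld.get(frozenset((row.variant_id, vid)), 0.0)
                    conflict = r2 >= clump_r2
                if conflict:
                    break
        if not conflict:
            kept_rows.append(row)
            kept_by_chr.setdefault(row.chr, []).append((row.pos, row.variant_id))
    return pd.DataFrame(kept_rows, columns=df.columns).reset_index(drop=True)


def harmonize(exp: pd.DataFrame, out: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele per variant.

    Where the outcome lists the alleles swapped, the outcome beta flips sign
    (and eaf becomes 1-eaf); variants whose alleles cannot be reconciled are
    dropped with a logged reason.  Returns the harmonized per-SNP table with
    columns bx, sx, by, sy, eaf, palindromic, f_statistic.
    """
    shared = exp.merge(out, on="variant_id", suffixes=("_x", "_y"))
    if shared.empty:
        raise ValidationError("no shared variants between exposure and outcome")
    rows = []
    for r in shared.itertuples(index=False):
        ea_x, oa_x = str(r.effect_allele_x).upper(), str(r.other_allele_x).upper()
        ea_y, oa_y = str(r.effect_allele_y).upper(), str(r.other_allele_y).upper()
        if (ea_x, oa_x) == (ea_y, oa_y):
            by, eaf_y = r.beta_y, r.eaf_y
        elif (ea_x, oa_x) == (oa_y, ea_y):
            by, eaf_y = -r.beta_y, 1.0 - r.eaf_y
        else:
            logger.warning("variant %s dropped: allele mismatch", r.variant_id)
            continue
        rows.append(
            {
                "variant_id": r.variant_id,
                "bx": r.beta_x,
                "sx": r.se_x,
                "by": by,
                "sy": r.se_y,
                "eaf": r.eaf_x,
                "palindromic": frozenset((ea_x, oa_x)) in _PALINDROMIC,
                "f_statistic": (r.beta_x / r.se_x) ** 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "bx", "sx", "by", "sy", "eaf", "palindromic", "f_statistic"],
    )


def _arrays(h: pd.DataFrame):
    return (h["bx"].to_numpy(float), h["sx"].to_numpy(float),
            h["by"].to_numpy(float), h["sy"].to_numpy(float))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _wald_ci(est: float, se: float) -> dict:
    return {
        "estimate": est,
        "se": se,
        "pvalue": 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan,
        "odds_ratio": float(np.exp(est)),
        "ci_low": float(np.exp(est - 1.959963984540054 * se)),
        "ci_high": float(np.exp(est + 1.959963984540054 * se)),
    }


def ivw(h: pd.DataFrame, allow_single: bool = False) -> dict:
    """Inverse-variance-weighted estimate.

    estimate = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effect SE
    sqrt(1/sum(bx^2/sy^2)) inflated by sqrt(max(1, Q/(k-1))) when the
    instruments are over-dispersed.  Reports both the fixed-effect and
    inflated SEs.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 2 and not allow_single:
        raise ValidationError("insufficient instruments: IVW needs >= 2 SNPs")
    w = bx**2 / sy**2
    est = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    if k >= 2:
        q = float(np.sum(w * (by / bx - est) ** 2))
        phi = max(1.0, q / (k - 1))
    else:
        phi = 1.0
    se = se_fe * float(np.sqrt(phi))
    out = _wald_ci(est, se)
    out.update({"se_fixed": se_fe, "n_snps": k, "inflation": phi})
    return out


def weighted_median(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> dict:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratio estimates are ordered and the 50% point of the normalized
    cumulative IVW weights is linearly interpolated; consistent when at
    least half the weight comes from valid instruments.
    """
    bx, sx, by, sy = _arrays(h)
    if len(bx) < 3:
        raise ValidationError("weighted median needs >= 3 SNPs")
    est = _weighted_median_point(bx, by, sy)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        boots[b] = _weighted_median_point(bxb, byb, sy)
    se = float(boots.std(ddof=1))
    out = _wald_ci(est, se)
    out["n_snps"] = len(bx)
    return out


def _weighted_median_point(bx, by, sy) -> float:
    theta = by / bx
    w = bx**2 / sy**2
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention
    cum /= w.sum()
    return float(np.interp(0.5, cum, theta))


def mr_egger(h: pd.DataFrame) -> dict:
    """MR-Egger regression: weighted by-on-bx fit with an intercept.

    Instruments are oriented so bx >= 0; weights 1/sy^2; slope is the causal
    estimate and the intercept tests directional pleiotropy.  SEs use
    multiplicative overdispersion max(1, RSS/(k-2)) and a t(k-2) reference.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise ValidationError("MR-Egger needs >= 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    yv = by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), x])
    WX = X * w[:, None]
    A = X.T @ WX
    coef = np.linalg.solve(A, WX.T @ yv)
    resid = yv - X @ coef
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (k - 2)))
    cov = np.linalg.inv(A) * sigma2
    se = np.sqrt(np.diag(cov))
    tdist = stats.t(df=k - 2)
    p = 2.0 * tdist.sf(np.abs(coef / se))
    out = _wald_ci(float(coef[1]), float(se[1]))
    out["pvalue"] = float(p[1])
    out.update(
        {
            "intercept": float(coef[0]),
            "intercept_se": float(se[0]),
            "intercept_pvalue": float(p[0]),
            "n_snps": k,
        }
    )
    return out


def cochran_q(h: pd.DataFrame, estimate: float | None = None) -> dict:
    """Cochran's Q heterogeneity test on the per-SNP Wald ratios.

    Weights are first-order: w_j = bx_j^2/sy_j^2 (i.e. 1/var(theta_j) with
    var(theta_j) ~= sy_j^2/bx_j^2); chi-square with k-1 df.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 2:
        raise ValidationError("Cochran's Q needs >= 2 SNPs")
    theta = by / bx
    w = bx**2 / sy**2
    if estimate is None:
        estimate = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - estimate) ** 2))
    return {"Q": q, "df": k - 1, "pvalue": float(stats.chi2.sf(q, k - 1))}


def presso_global(h: pd.DataFrame, n_sim: int = 1000, seed: int = 0) -> dict:
    """Global outlier test: observed residual sum of squares of by around
    leave-one-out IVW predictions, against a simulated null.

    Null replicates draw by_j ~ Normal(bx_j * theta_loo(-j), sy_j^2); the
    p-value is the add-one-smoothed fraction of simulated RSS >= observed,
    bounded in [1/(n_sim+1), 1].
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 4:
        logger.warning("global outlier test skipped: %d < 4 SNPs", k)
        return {"rss_obs": np.nan, "pvalue": np.nan, "n_sim": n_sim}
    w = bx**2 / sy**2
    num = bx * by / sy**2
    theta_loo = (num.sum() - num) / (w.sum() - w)  # LOO IVW per left-out SNP
    resid = (by - bx * theta_loo) / sy
    rss_obs = float(np.sum(resid**2))
    rng = np.random.default_rng(seed)
    by_sim = rng.normal(bx * theta_loo, sy, size=(n_sim, k))
    num_s = bx * by_sim / sy**2
    theta_loo_s = (num_s.sum(axis=1, keepdims=True) - num_s) / (w.sum() - w)
    rss_sim = np.sum(((by_sim - bx * theta_loo_s) / sy) ** 2, axis=1)
    p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return {"rss_obs": rss_obs, "pvalue": float(p), "n_sim": n_sim}


def loo_and_single_snp(h: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP Wald ratios with CIs and leave-one-out IVW estimates."""
    bx, _, by, sy = _arrays(h)
    ids = h["variant_id"].to_numpy()
    ok = bx != 0
    if (~ok).any():
        logger.warning("%d SNP(s) with bx = 0 excluded from ratio estimates", int((~ok).sum()))
    theta = by[ok] / bx[ok]
    se = sy[ok] / np.abs(bx[ok])
    single = pd.DataFrame(
        {
            "variant_id": ids[ok],
            "estimate": theta,
            "se": se,
            "ci_low": theta - 1.959963984540054 * se,
            "ci_high": theta + 1.959963984540054 * se,
        }
    )
    loo_rows = []
    if ok.sum() >= 3:
        for j in np.flatnonzero(ok):
            rest = h.iloc[[i for i in range(len(h)) if i != j and ok[i]]]
            res = ivw(rest, allow_single=True)
            loo_rows.append(
                {"left_out": ids[j], "estimate": res["estimate"], "se": res["se"]}
            )
    loo = pd.DataFrame(loo_rows, columns=["left_out", "estimate", "se"])
    return single, loo


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class MrConfig:
    maf_min: float = 0.01
    p_max: float = 5.0e-8
    clump_kb: float = 10_000
    clump_r2: float = 0.001
    min_instruments: int = 2
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0


def mr_pipeline(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: dict | None = None,
    config: MrConfig | None = None,
):
    """Run the full MR suite per metabolite.

    Metabolites with fewer than ``min_instruments`` surviving instruments
    are listed with a reason instead of estimates.  BH q-values are computed
    across metabolites on the IVW p-values.

    Returns
    -------
    (results table, per-metabolite diagnostics dict, skipped table)
        Diagnostics hold the harmonized set, single-SNP and leave-one-out
        tables per metabolite.
    """
    cfg = config or MrConfig()
    rows, skipped, details = [], [], {}
    for mid, exp in exposures.items():
        inst = select_instruments(
            exp, cfg.maf_min, cfg.p_max, cfg.clump_kb, cfg.clump_r2, ld
        )
        if len(inst) < cfg.min_instruments:
            skipped.append(
                {"metabolite_id": mid,
                 "reason": f"{len(inst)} instrument(s) < {cfg.min_instruments}"}
            )
            continue
        h = harmonize(inst, outcome)
        if len(h) < cfg.min_instruments:
            skipped.append(
                {"metabolite_id": mid,
                 "reason": f"{len(h)} harmonized instrument(s) < {cfg.min_instruments}"}
            )
            continue
        res_ivw = ivw(h)
        rec = {
            "metabolite_id": mid,
            "n_snps": len(h),
            "ivw_estimate": res_ivw["estimate"],
            "ivw_se": res_ivw["se"],
            "ivw_pvalue": res_ivw["pvalue"],
            "ivw_or": res_ivw["odds_ratio"],
            "ivw_ci_low": res_ivw["ci_low"],
            "ivw_ci_high": res_ivw["ci_high"],
            "ivw_se_fixed": res_ivw["se_fixed"],
            "min_f_statistic": float(h["f_statistic"].min()),
        }
        qres = cochran_q(h, res_ivw["estimate"])
        rec.update({"cochran_q": qres["Q"], "cochran_q_pvalue": qres["pvalue"]})
        if len(h) >= 3:
            wm = weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed)
            eg = mr_egger(h)
            rec.update(
                {
                    "wm_estimate": wm["estimate"], "wm_se": wm["se"],
                    "wm_pvalue": wm["pvalue"], "wm_or": wm["odds_ratio"],
                    "wm_ci_low": wm["ci_low"], "wm_ci_high": wm["ci_high"],
                    "egger_estimate": eg["estimate"], "egger_se": eg["se"],
                    "egger_pvalue": eg["pvalue"], "egger_or": eg["odds_ratio"],
                    "egger_ci_low": eg["ci_low"], "egger_ci_high": eg["ci_high"],
                    "egger_intercept": eg["intercept"],
                    "egger_intercept_pvalue": eg["intercept_pvalue"],
                }
            )
        pres = presso_global(h, n_sim=cfg.n_presso_sim, seed=cfg.seed)
        rec["presso_global_pvalue"] = pres["pvalue"]
        single, loo = loo_and_single_snp(h)
        details[mid] = {"harmonized": h, "single_snp": single, "leave_one_out": loo}
        rows.append(rec)
    results = pd.DataFrame(rows)
    if len(results):
        results["qvalue"] = bh_fdr(results["ivw_pvalue"].to_numpy())
    else:
        logger.warning("no metabolite passed the instrument gate; empty MR table")
        results = pd.DataFrame(columns=["metabolite_id", "n_snps", "ivw_estimate", "qvalue"])
    skipped_df = pd.DataFrame(skipped, columns=["metabolite_id", "reason"])
    return results, details, skipped_df


__all__ = [
    "MrConfig",
    "select_instruments",
    "harmonize",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "presso_global",
    "loo_and_single_snp",
    "mr_pipeline",
]
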