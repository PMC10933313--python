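"""Individual-level dose-response simulation and the stratified-phenotype
diagnostic for dosage-dependent (J-shaped) causal effects.

The simulated cohort carries independent biallelic variants, a heritable
exposure x (unit variance, SNP heritability h2_x) and an outcome y that
is either linear (y = b_xy x + e) or quadratic (y = b_xy (x + x^2) + e)
in the exposure.  The diagnostic mirrors the stratified design used for
coffee/tea intake: split x into quantile groups with the lowest group as
never-consumer controls, locate the turning point of the per-group mean
outcome, define moderate (below the turning point) and heavy (above)
intake strata, run case-control GWAS of each stratum against the
controls, and estimate the genetic correlation between stratum
membership and disease within each stratum.  Opposite-sign per-stratum
genetic correlations indicate a dosage-dependent effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import AuditLog, SummaryStats

__all__ = [
    "DoseConfig", "DoseCohort", "RgEstimate", "DoseReport",
    "simulate_dose_cohort", "assign_quantile_groups", "find_turning_point",
    "derive_contrast_phenotypes", "gwas_scan", "rg_no_ld",
    "stratified_dose_regression", "dose_pipeline",
]


class DoseError(ValueError):
    pass


@dataclass
class DoseConfig:
    """Parameters of the dose-response simulation.

    The defaults encode the simulation design: ten exposure quantiles
    with the first as the control group, a causal effect b_xy = 0.2, and
    a quadratic option y = b_xy (x + x^2) + e.  ``noise_sd_y=None``
    chooses the residual SD so the outcome has (approximately) unit
    variance.  ``heavy_cutpoint=None`` uses the turning-point rule to
    separate moderate from heavy intake.
    """

    n: int = 10_000
    m_snps: int = 50
    h2_x: float = 0.3
    effect_shape: str = "linear"        # linear | quadratic
    b_xy: float = 0.2
    noise_sd_y: float | None = None
    n_quantiles: int = 10
    heavy_cutpoint: float | None = None
    disease_quantile: float = 0.8       # y above this quantile = disease
    scale_quadratic: bool = True        # False: y = x^2 + x + b_xy-free form
    seed: int = 0

    def __post_init__(self):
        if self.n_quantiles < 3:
            raise DoseError("n_quantiles must be >= 3")
        if not (0 < self.h2_x < 1):
            raise DoseError("h2_x must lie in (0,1)")
        if self.m_snps < 1:
            raise DoseError("m_snps must be >= 1")
        if self.effect_shape not in ("linear", "quadratic"):
            raise DoseError(f"unknown effect shape {self.effect_shape!r}")
        if self.n < self.n_quantiles:
            raise DoseError("cohort smaller than the number of quantiles")

    def resolved_noise_sd(self) -> float:
        if self.noise_sd_y is not None:
            return self.noise_sd_y
        # var(x) = 1; var(x + x^2) = 3 for x ~ N(0,1)
        shape_var = 1.0 if self.effect_shape == "linear" else 3.0
        scale = self.b_xy if self.scale_quadratic or self.effect_shape == "linear" else 1.0
        return float(np.sqrt(max(1.0 - scale ** 2 * shape_var, 0.05)))


@dataclass
class DoseCohort:
    """Simulated cohort: genotype dosages (n x m), exposure, outcome and
    the generative truth."""

    genotypes: np.ndarray
    x: np.ndarray
    y: np.ndarray
    freqs: np.ndarray
    beta_x: np.ndarray              # per standardized-genotype effects
    cfg: DoseConfig
    snp_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


def simulate_dose_cohort(cfg: DoseConfig) -> DoseCohort:
    """Draw one cohort under the configured dose-response model."""
    rng = np.random.default_rng(cfg.seed)
    f = rng.uniform(0.05, 0.5, size=cfg.m_snps)
    g = rng.binomial(2, f, size=(cfg.n, cfg.m_snps)).astype(np.float64)
    sd = g.std(axis=0, ddof=0)
    if np.any(sd == 0):
        # resample monomorphic columns once; with n in the thousands this
        # is effectively unreachable
        bad = sd == 0
        g[:, bad] = rng.binomial(2, 0.5, size=(cfg.n, bad.sum()))
        sd = g.std(axis=0, ddof=0)
    g_std = (g - g.mean(axis=0)) / sd
    beta = rng.normal(size=cfg.m_snps)
    beta *= np.sqrt(cfg.h2_x / np.sum(beta ** 2))
    genetic = g_std @ beta
    x = genetic + rng.normal(0.0, np.sqrt(1.0 - cfg.h2_x), size=cfg.n)
    noise_sd = cfg.resolved_noise_sd()
    eps = rng.normal(0.0, noise_sd, size=cfg.n)
    if cfg.effect_shape == "linear":
        y = cfg.b_xy * x + eps
    else:
        if cfg.scale_quadratic:
            y = cfg.b_xy * (x + x ** 2) + eps
        else:
            y = x ** 2 + x + eps
    ids = [f"snp{j + 1}" for j in range(cfg.m_snps)]
    return DoseCohort(g, x, y, f, beta, cfg, ids)


def assign_quantile_groups(x: np.ndarray, n_quantiles: int) -> np.ndarray:
    """Rank-based quantile groups, 1 (lowest) .. n_quantiles (highest).

    Groups are equal size up to +-1; ties broken by stable input order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < n_quantiles:
        raise DoseError("fewer subjects than quantile groups")
    if np.ptp(x) == 0:
        raise DoseError("constant exposure: quantile groups are undefined")
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    bounds = np.linspace(0, n, n_quantiles + 1).round().astype(int)
    for gidx in range(n_quantiles):
        labels[order[bounds[gidx]:bounds[gidx + 1]]] = gidx + 1
    return labels


def find_turning_point(per_group_mean: np.ndarray) -> tuple[int, bool]:
    """Index (1-based) of the minimum of the per-group mean-outcome
    profile, and whether it is an interior turning point.

    A monotone profile puts the minimum at a boundary; the flag is then
    False ("no interior turning point").
    """
    prof = np.asarray(per_group_mean, dtype=float)
    if len(prof) < 3:
        raise DoseError("need at least 3 groups to find a turning point")
    idx = int(np.argmin(prof)) + 1
    interior = 1 < idx < len(prof)
    return idx, interior


def derive_contrast_phenotypes(dose: np.ndarray, cutpoint: float,
                               control: np.ndarray | None = None
                               ) -> pd.DataFrame:
    """Moderate-vs-never and heavy-vs-never binary contrast traits.

    Never-consumers (``dose == 0`` unless an explicit ``control`` mask is
    given) are the controls of both traits; consumers with ``dose >=
    cutpoint`` are heavy cases, consumers below it moderate cases.  Each
    trait column holds 1 (case), 0 (control) or NaN (excluded subject).
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DoseError("doses must be non-negative")
    control = (dose == 0) if control is None else np.asarray(control, dtype=bool)
    if not control.any():
        raise DoseError("no never-consumer controls")
    consumer = ~control
    if not consumer.any():
        raise DoseError("all subjects are never-consumer controls; no cases")
    heavy = consumer & (dose >= cutpoint)
    moderate = consumer & (dose < cutpoint)
    mod_trait = np.full(len(dose), np.nan)
    mod_trait[control] = 0.0
    mod_trait[moderate] = 1.0
    hev_trait = np.full(len(dose), np.nan)
    hev_trait[control] = 0.0
    hev_trait[heavy] = 1.0
    return pd.DataFrame({"moderate": mod_trait, "heavy": hev_trait})


def gwas_scan(cohort: DoseCohort, trait: np.ndarray,
              include: np.ndarray | None = None) -> SummaryStats:
    """Per-SNP simple linear regression of ``trait`` on genotype dosage.

    ``trait`` may be quantitative or a 0/1 contrast (fitted on the
    observed scale); NaN entries and subjects outside ``include`` are
    excluded.  SNPs monomorphic among the included subjects are dropped
    and flagged in the returned object's audit log.
    """
    trait = np.asarray(trait, dtype=float)
    mask = np.isfinite(trait)
    if include is not None:
        mask &= np.asarray(include, dtype=bool)
    t = trait[mask]
    g = cohort.genotypes[mask]
    n = len(t)
    if n < 3 or len(np.unique(t)) < 2:
        raise DoseError("need >= 3 included subjects with >= 2 trait values")
    gc = g - g.mean(axis=0)
    tc = t - t.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ tc
    syy = float(tc @ tc)
    audit = AuditLog()
    poly = sxx > 0
    for j in np.nonzero(~poly)[0]:
        audit.drop(cohort.snp_ids[j], "monomorphic among included subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        resid_ss = syy - beta * sxy
        sigma2 = np.maximum(resid_ss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
    z = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "SNP": cohort.snp_ids, "A1": "A", "A2": "G",
        "freq": g.mean(axis=0) / 2.0, "b": beta, "se": se, "p": p, "N": n,
    })[poly]
    df["freq"] = df["freq"].clip(1e-6, 1 - 1e-6)
    return SummaryStats(df, validate=False, audit=audit)


# ---------------------------------------------------------------------------
# Genetic correlation (no-LD moment estimator)


@dataclass
class RgEstimate:
    """Genetic correlation with its building blocks.

    ``cov``/``cov_se`` is the genetic covariance and its jackknife se:
    it carries the sign of r_g but stays well-defined even when a
    per-trait heritability estimate is non-positive (in which case
    ``rg`` is NaN and flagged).
    """

    rg: float
    se: float
    h2_a: float
    h2_b: float
    cov: float = np.nan
    cov_se: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def zvalue(self) -> float:
        return self.rg / self.se if self.se else np.nan

    @property
    def cov_zvalue(self) -> float:
        return self.cov / self.cov_se if self.cov_se else np.nan


def _rg_point(ba, sa, bb, sb):
    h2a = float(np.sum(ba ** 2 - sa ** 2))
    h2b = float(np.sum(bb ** 2 - sb ** 2))
    cov = float(np.sum(ba * bb))
    if h2a <= 0 or h2b <= 0:
        return np.nan, h2a, h2b, cov
    return cov / np.sqrt(h2a * h2b), h2a, h2b, cov


def rg_no_ld(a: SummaryStats, b: SummaryStats, n_blocks: int = 20
             ) -> RgEstimate:
    """Moment estimator of genetic correlation from summary statistics of
    independent (LD-free) variants.

    On the standardized scale each squared estimate decomposes as
    E[b^2] = beta^2 + se^2, so sum(b^2 - se^2) estimates the variance
    explained per trait and sum(b_a b_b) the genetic covariance (samples
    assumed non-overlapping).  The standard error is a delete-one-block
    jackknife over ``n_blocks`` variant blocks.  Estimates outside [-1,1]
    are reported but flagged (and clipped at +-1.5).
    """
    da = a.df.set_index("SNP")
    db = b.df.set_index("SNP")
    shared = [v for v in a.df["SNP"] if v in db.index]
    if len(shared) < n_blocks:
        n_blocks = max(2, len(shared) // 2)
    if len(shared) < 4:
        raise DoseError("need at least 4 shared variants for r_g")
    ba = da.loc[shared, "b"].to_numpy()
    sa = da.loc[shared, "se"].to_numpy()
    bb = db.loc[shared, "b"].to_numpy()
    sb = db.loc[shared, "se"].to_numpy()

    flags: list[str] = []
    rg, h2a, h2b, cov = _rg_point(ba, sa, bb, sb)
    m = len(shared)
    blocks = np.array_split(np.arange(m), n_blocks)
    pseudo, pseudo_cov = [], []
    for blk in blocks:
        keep = np.setdiff1d(np.arange(m), blk)
        r, _, _, cv = _rg_point(ba[keep], sa[keep], bb[keep], sb[keep])
        # rescale the leave-block covariance to the full panel size
        pseudo.append(r)
        pseudo_cov.append(cv * m / len(keep))
    pseudo = np.asarray(pseudo, dtype=float)
    pc = np.asarray(pseudo_cov, dtype=float)
    nb = len(pc)
    cov_se = float(np.sqrt((nb - 1) / nb * np.sum((pc - pc.mean()) ** 2)))
    if not np.isfinite(rg):
        return RgEstimate(np.nan, np.nan, h2a, h2b, cov, cov_se,
                          ["non-positive heritability estimate"])
    finite = np.isfinite(pseudo)
    if finite.sum() < 2:
        flags.append("jackknife degenerate")
        se = np.nan
    else:
        if not finite.all():
            flags.append("jackknife blocks with non-positive heritability")
        ps = pseudo[finite]
        nf = len(ps)
        se = float(np.sqrt((nf - 1) / nf * np.sum((ps - ps.mean()) ** 2)))
    if abs(rg) > 1.0:
        flags.append("estimate outside [-1,1]")
    if abs(rg) > 1.5:
        flags.append("clipped at +-1.5")
        rg = float(np.clip(rg, -1.5, 1.5))
    return RgEstimate(float(rg), se, h2a, h2b, cov, cov_se, flags)


# ---------------------------------------------------------------------------
# Stratified regression


def stratified_dose_regression(disease: np.ndarray, groups: np.ndarray,
                               control_group: int = 1) -> pd.DataFrame:
    """Per-dose-group odds ratios against the control group.

    Each non-control group is compared to the control group through the
    2x2 table (equivalently, a logistic regression on a single binary
    group indicator): OR = (a d)/(b c) with Wald CI from
    se(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  Empty cells receive the
    Haldane-Anscombe 0.5 correction and are flagged.
    """
    disease = np.asarray(disease).astype(int)
    groups = np.asarray(groups)
    ctrl = groups == control_group
    if not ctrl.any():
        raise DoseError("empty control group")
    c = int(disease[ctrl].sum())
    d = int((~disease[ctrl].astype(bool)).sum())
    if c == 0 or d == 0:
        raise DoseError("control group carries a single outcome class")
    rows = []
    for gval in sorted(set(groups.tolist()) - {control_group}):
        sel = groups == gval
        a_ = int(disease[sel].sum())
        b_ = int(sel.sum() - a_)
        haldane = 0 in (a_, b_)
        aa, bb_, cc, dd = (v + 0.5 if haldane else v for v in (a_, b_, c, d))
        log_or = np.log((aa * dd) / (bb_ * cc))
        se = np.sqrt(1 / aa + 1 / bb_ + 1 / cc + 1 / dd)
        z = log_or / se
        rows.append({
            "group": gval, "n": int(sel.sum()), "cases": a_,
            "or": float(np.exp(log_or)), "log_or": float(log_or),
            "se": float(se),
            "ci_low": float(np.exp(log_or - 1.959963984540054 * se)),
            "ci_high": float(np.exp(log_or + 1.959963984540054 * se)),
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "haldane": haldane,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class DoseReport:
    """Aggregate of the stratified dose-response diagnostic over
    replicates."""

    per_rep: pd.DataFrame               # one row per replicate
    per_quantile: pd.DataFrame          # mean outcome / log-OR profile
    verdict_rate: float                 # fraction of reps flagging dosage dependence
    verdict: bool                       # majority verdict
    opposite_sign_rate: float           # sign discordance regardless of significance
    cfg: DoseConfig
    reps: int
    example_contrast_gwas: dict | None = None

    def summary(self) -> str:
        pr = self.per_rep
        lines = [
            f"Dose-response diagnostic ({self.cfg.effect_shape} effect, "
            f"b_xy={self.cfg.b_xy}, {self.reps} replicates)",
            "=" * 60,
            f"{'turning point (median group)':>34}  "
            f"{np.nanmedian(pr['turning_point']):.0f}",
            f"{'mean r_g moderate stratum':>34}  "
            f"{np.nanmean(pr['rg_moderate']): .3f}",
            f"{'mean r_g heavy stratum':>34}  "
            f"{np.nanmean(pr['rg_heavy']): .3f}",
            f"{'opposite-sign rate':>34}  {self.opposite_sign_rate:.2f}",
            f"{'dosage-dependence verdict rate':>34}  {self.verdict_rate:.2f}",
            f"{'verdict (majority of reps)':>34}  {self.verdict}",
        ]
        return "\n".join(lines)


def _strata_from_turning_point(groups: np.ndarray, tp: int, interior: bool,
                               n_quantiles: int):
    """Moderate = groups between control and the turning point, heavy =
    groups above it.  Without an interior turning point the consumer
    groups are split at their midpoint so both strata remain defined."""
    if interior and tp >= 2:
        split = tp
    else:
        split = (n_quantiles + 1) // 2
    split = int(np.clip(split, 2, n_quantiles - 1))
    moderate = (groups >= 2) & (groups <= split)
    heavy = groups > split
    return moderate, heavy, split


def dose_pipeline(cfg: DoseConfig, reps: int = 100,
                  rg_target: str = "disease") -> DoseReport:
    """Replicate the stratified dose-response diagnostic.

    Per replicate: simulate a cohort; assign exposure quantile groups
    (group 1 = never-consumer controls); dichotomize the outcome at its
    ``disease_quantile`` to a disease indicator; run the stratified
    per-group logistic contrast; locate the turning point of the
    per-group mean outcome; define moderate/heavy strata; run the
    contrast GWAS (stratum vs controls) and a disease GWAS over the same
    subjects; estimate the within-stratum genetic correlation between
    stratum membership and disease.  The dosage-dependence verdict for a
    replicate requires opposite-sign per-stratum r_g with both estimates
    individually significant (|rg/se| >= 1.96).

    ``rg_target="outcome"`` correlates against the continuous outcome
    instead of the disease indicator.
    """
    if reps < 1:
        raise DoseError("reps must be >= 1")
    rows = []
    profile_acc = np.zeros(cfg.n_quantiles)
    logor_acc = np.zeros(cfg.n_quantiles - 1)
    logor_n = 0
    example = None
    for rep in range(reps):
        rcfg = DoseConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
        cohort = simulate_dose_cohort(rcfg)
        groups = assign_quantile_groups(cohort.x, cfg.n_quantiles)
        thresh = np.quantile(cohort.y, cfg.disease_quantile)
        disease = (cohort.y > thresh).astype(int)
        strat = stratified_dose_regression(disease, groups)
        prof = np.array([cohort.y[groups == gq].mean()
                         for gq in range(1, cfg.n_quantiles + 1)])
        tp, interior = find_turning_point(prof)
        moderate, heavy, split = _strata_from_turning_point(
            groups, tp, interior, cfg.n_quantiles)
        ctrl = groups == 1

        def _stratum_rg(stratum_mask):
            include = stratum_mask | ctrl
            contrast = np.where(stratum_mask, 1.0, np.where(ctrl, 0.0, np.nan))
            gw_c = gwas_scan(cohort, contrast, include=include)
            target = disease.astype(float) if rg_target == "disease" else cohort.y
            gw_t = gwas_scan(cohort, target, include=include)
            return rg_no_ld(gw_c, gw_t), gw_c, gw_t

        rg_m, gwc_m, gwt_m = _stratum_rg(moderate)
        rg_h, gwc_h, gwt_h = _stratum_rg(heavy)
        # the genetic covariance carries the sign of r_g and stays
        # well-defined when a stratum heritability estimate is noisy
        zs = np.array([rg_m.cov_zvalue, rg_h.cov_zvalue])
        opposite = (np.isfinite(rg_m.cov) and np.isfinite(rg_h.cov)
                    and rg_m.cov * rg_h.cov < 0)
        verdict = bool(opposite and np.all(np.isfinite(zs))
                       and np.all(np.abs(zs) >= 1.959963984540054))
        rows.append({
            "rep": rep, "turning_point": tp, "interior": interior,
            "split_group": split,
            "rg_moderate": rg_m.rg, "rg_moderate_se": rg_m.se,
            "rg_heavy": rg_h.rg, "rg_heavy_se": rg_h.se,
            "cov_moderate": rg_m.cov, "cov_moderate_se": rg_m.cov_se,
            "cov_heavy": rg_h.cov, "cov_heavy_se": rg_h.cov_se,
            "opposite_sign": opposite, "verdict": verdict,
        })
        profile_acc += prof
        logor_acc += strat["log_or"].to_numpy()
        logor_n += 1
        if rep == reps - 1:
            example = {"moderate_contrast": gwc_m, "heavy_contrast": gwc_h,
                       "moderate_target": gwt_m, "heavy_target": gwt_h,
                       "stratified_table": strat}
    per_rep = pd.DataFrame(rows)
    per_quant = pd.DataFrame({
        "group": np.arange(1, cfg.n_quantiles + 1),
        "mean_outcome": profile_acc / reps,
        "mean_log_or_vs_control": np.concatenate([[0.0], logor_acc / logor_n]),
    })
    verdict_rate = float(per_rep["verdict"].mean())
    return DoseReport(per_rep, per_quant, verdict_rate,
                      verdict_rate > 0.5,
                      float(per_rep["opposite_sign"].mean()), cfg, reps,
                      example_contrast_gwas=example)
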