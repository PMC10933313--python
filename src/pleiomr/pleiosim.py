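"""Two-sample GWAS summary-statistic simulator and benchmarking harness.

The generative model works on the standardized scale (unit-variance
genotypes and phenotypes), so that a GWAS estimate for a variant with
true effect beta and sample size n is distributed N(beta, 1/n) with
standard error 1/sqrt(n).  The scenario axes are the proportion of
invalid (horizontally pleiotropic) instruments, the share of exposure
heritability they carry, and the magnitude/direction of their direct
outcome effects:

    beta_y_i = b_xy * beta_x_i + alpha_i

with alpha_i = 0 for valid IVs and, for invalid IVs, alpha drawn with
mean ``alpha_mean`` (0 = balanced pleiotropy, >0 = directional), SD
``alpha_sd`` and correlation ``rho_dir`` with the exposure effects.
Exposure effects are rescaled deterministically so the valid/invalid
subsets explain exactly their target shares of h2_x in every replicate.
Sample overlap between the two GWAS enters as a correlation
``overlap_corr`` between the per-variant sampling errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import get_method
from .results import MRResult
from .sumstats import HarmonizedSet, SummaryStats, select_instruments

__all__ = ["ScenarioConfig", "simulate_summary_stats", "make_harmonized",
           "run_scenario_grid", "adjust_fdr"]


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Generative parameters of one pleiotropy scenario."""

    k: int = 100                      # number of candidate IVs
    pi_invalid: float = 0.0           # proportion of invalid IVs
    h2_x: float = 0.1                 # exposure variance explained by all IVs
    invalid_var_share: float = 0.0    # share of h2_x carried by invalid IVs
    pleiotropy: str = "balanced"      # balanced | directional
    alpha_sd: float = 0.0             # SD of direct IV->outcome effects
    alpha_mean: float = 0.0           # mean direct effect (0 when balanced)
    rho_dir: float = 0.0              # cor(alpha, beta_x) among invalid IVs
    b_xy: float = 0.0                 # generative causal effect
    n_x: int = 100_000
    n_y: int = 100_000
    overlap_corr: float = 0.0         # correlation of sampling errors
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        for name in ("pi_invalid", "invalid_var_share", "overlap_corr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name} must lie in [0,1], got {v}")
        if not (0.0 < self.h2_x < 1.0):
            raise ScenarioError("h2_x must lie in (0,1)")
        if self.n_x < 2 or self.n_y < 2:
            raise ScenarioError("sample sizes must be >= 2")
        if self.pleiotropy not in ("balanced", "directional"):
            raise ScenarioError(f"unknown pleiotropy kind {self.pleiotropy!r}")
        if self.pleiotropy == "balanced" and self.alpha_mean != 0.0:
            raise ScenarioError("alpha_mean must be 0 under balanced pleiotropy")
        if not (-1.0 <= self.rho_dir <= 1.0):
            raise ScenarioError("rho_dir must lie in [-1,1]")
        if self.k < 2:
            raise ScenarioError("k must be >= 2")

    def replace(self, **kw) -> "ScenarioConfig":
        d = asdict(self)
        d.update(kw)
        return ScenarioConfig(**d)


def _scaled_effects(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale so sum(beta^2) equals target_var exactly."""
    total = np.sum(raw ** 2)
    if total == 0:
        raise ScenarioError("degenerate zero draw for effect sizes")
    return raw * np.sqrt(target_var / total)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def simulate_summary_stats(cfg: ScenarioConfig
                           ) -> tuple[SummaryStats, SummaryStats, pd.DataFrame]:
    """Draw one replicate of exposure/outcome GWAS summary statistics.

    Returns (exposure, outcome, truth ledger); the ledger records each
    variant's validity, true effects and direct (pleiotropic) outcome
    effect.  Deterministic given ``cfg`` (the seed is part of the
    config).
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    n_invalid = int(round(k * cfg.pi_invalid))
    n_valid = k - n_invalid
    share_inv = cfg.invalid_var_share if n_invalid > 0 else 0.0
    if n_valid == 0 and share_inv < 1.0:
        raise ScenarioError("no valid IVs to carry the valid variance share")

    beta_x = np.zeros(k)
    valid = np.zeros(k, dtype=bool)
    valid[:n_valid] = True
    if n_valid:
        beta_x[valid] = _scaled_effects(rng.normal(size=n_valid),
                                        (1.0 - share_inv) * cfg.h2_x)
    if n_invalid:
        beta_x[~valid] = _scaled_effects(rng.normal(size=n_invalid),
                                         share_inv * cfg.h2_x)

    alpha = np.zeros(k)
    if n_invalid and (cfg.alpha_sd > 0 or cfg.alpha_mean != 0):
        # alpha hits its mean/SD/correlation targets in expectation: the
        # draw-to-draw randomness of the pleiotropic effects is what
        # inflates estimator FPR, so it must not be standardized away
        if n_invalid >= 2 and cfg.alpha_sd > 0 and cfg.rho_dir != 0:
            z = _standardize(beta_x[~valid])
        else:
            z = np.zeros(n_invalid)
        eps = rng.normal(size=n_invalid)
        a = cfg.rho_dir * z + np.sqrt(1.0 - cfg.rho_dir ** 2) * eps
        alpha[~valid] = cfg.alpha_mean + cfg.alpha_sd * a

    beta_y = cfg.b_xy * beta_x + alpha

    se_x = np.full(k, cfg.n_x ** -0.5)
    se_y = np.full(k, cfg.n_y ** -0.5)
    if cfg.overlap_corr > 0:
        ex = rng.normal(size=k)
        e2 = rng.normal(size=k)
        ey = cfg.overlap_corr * ex + np.sqrt(1 - cfg.overlap_corr ** 2) * e2
    else:
        ex = rng.normal(size=k)
        ey = rng.normal(size=k)
    bhat_x = beta_x + se_x * ex
    bhat_y = beta_y + se_y * ey

    freqs = rng.uniform(0.05, 0.5, size=k)
    ids = [f"rs{i + 1}" for i in range(k)]
    alleles = pd.DataFrame({"A1": ["A"] * k, "A2": ["G"] * k})

    def _trait(bhat, se, n):
        p = 2.0 * stats.norm.sf(np.abs(bhat / se))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        return SummaryStats(pd.DataFrame({
            "SNP": ids, "A1": alleles["A1"], "A2": alleles["A2"],
            "freq": freqs, "b": bhat, "se": se, "p": p,
            "N": np.full(k, n, dtype=int)}), validate=False)

    ledger = pd.DataFrame({
        "SNP": ids, "valid": valid, "beta_x": beta_x, "beta_y": beta_y,
        "alpha": alpha, "b_xy": cfg.b_xy})
    return _trait(bhat_x, se_x, cfg.n_x), _trait(bhat_y, se_y, cfg.n_y), ledger


def make_harmonized(exposure: SummaryStats, outcome: SummaryStats,
                    ids: list[str]) -> HarmonizedSet:
    """Assemble a HarmonizedSet for an already-aligned simulated pair."""
    ex = exposure.df.set_index("SNP").loc[ids]
    ou = outcome.df.set_index("SNP").loc[ids]
    return HarmonizedSet(list(ids), ex["b"].to_numpy(), ex["se"].to_numpy(),
                         ou["b"].to_numpy(), ou["se"].to_numpy(),
                         eaf=ex["freq"].to_numpy())


# ---------------------------------------------------------------------------
# Benchmark harness


def run_scenario_grid(grid: list[ScenarioConfig], methods: list[str],
                      reps: int = 100, alpha: float = 0.05,
                      base_seed: int = 0, p_threshold: float = 5e-8,
                      method_options: dict | None = None) -> pd.DataFrame:
    """False-positive rate / power / bias benchmark over a scenario grid.

    For each scenario x method: ``reps`` replicate datasets are simulated
    (replicate i uses seed ``base_seed + i``), instruments are selected
    from the exposure statistics alone (truth-agnostic, p <
    ``p_threshold``), the method is run, and the rejection rate at
    ``alpha``, mean estimate, bias, empirical SD and mean model se are
    tabulated.  Replicates where a method fails (e.g. too few
    instruments) are counted in ``n_failed`` and excluded from the
    summaries, never silently dropped.
    """
    method_options = method_options or {}
    rows = []
    for s_idx, cfg in enumerate(grid):
        sid = cfg.label or f"scenario{s_idx}"
        results: dict[str, list[MRResult]] = {m: [] for m in methods}
        failures: dict[str, int] = {m: 0 for m in methods}
        for rep in range(reps):
            rcfg = cfg.replace(seed=base_seed + rep)
            expo, outc, _ = simulate_summary_stats(rcfg)
            ids = select_instruments(expo, p_threshold=p_threshold)
            for m in methods:
                fn = get_method(m)
                opts = dict(method_options.get(m, {}))
                if m in ("weighted_median", "mode", "weighted_mode"):
                    opts.setdefault("seed", base_seed + 7919 * (rep + 1))
                try:
                    if len(ids) < 2:
                        raise ValueError("too few instruments")
                    h = make_harmonized(expo, outc, ids)
                    res = fn(h, **opts)
                    if not np.isfinite(res.b_xy) or not np.isfinite(res.p):
                        raise ValueError("non-finite result")
                except Exception:
                    failures[m] += 1
                    continue
                results[m].append(res)
        for m in methods:
            ok = results[m]
            est = np.array([r.b_xy for r in ok])
            ses = np.array([r.se for r in ok])
            pv = np.array([r.p for r in ok])
            rows.append({
                "scenario": sid, "method": m, "reps": reps,
                "n_used": len(ok), "n_failed": failures[m],
                "rejection_rate": float(np.mean(pv < alpha)) if len(ok) else np.nan,
                "mean_est": float(est.mean()) if len(ok) else np.nan,
                "bias": float(est.mean() - cfg.b_xy) if len(ok) else np.nan,
                "empirical_sd": float(est.std(ddof=1)) if len(ok) > 1 else np.nan,
                "mean_model_se": float(ses.mean()) if len(ok) else np.nan,
                "b_xy_true": cfg.b_xy,
            })
    return pd.DataFrame(rows)


def adjust_fdr(pvalues: pd.DataFrame, method: str = "bh",
               levels: tuple[float, float] = (0.01, 0.05)) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within each exposure-wise family.

    ``pvalues`` must carry columns ``exposure`` and ``p``; returns the
    input with ``q`` plus boolean significance calls at the given levels
    (defaults: significant < 0.01, suggestive < 0.05).  BH is a
    step-up FDR procedure standing in for local-FDR/q-value estimation,
    which needs a large p-value ensemble to fit its null component.
    """
    if method != "bh":
        raise ScenarioError(f"unknown FDR method {method!r}")
    if "exposure" not in pvalues.columns or "p" not in pvalues.columns:
        raise ScenarioError("adjust_fdr needs columns 'exposure' and 'p'")
    if len(pvalues) == 0:
        raise ScenarioError("empty p-value family")
    out = pvalues.reset_index(drop=True).copy()
    q = np.empty(len(out))
    for _, sub in out.groupby("exposure"):
        fam = sub["p"].to_numpy(dtype=float)
        if np.any((fam <= 0) | (fam > 1)):
            raise ScenarioError("p-values must lie in (0,1]")
        q[sub.index.to_numpy()] = multipletests(fam, method="fdr_bh")[1]
    out["q"] = q
    for lev in levels:
        out[f"call_{lev:g}"] = out["q"] < lev
    return out
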