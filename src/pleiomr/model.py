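"""Model-object front end over the MR estimators.

``MRModel`` holds the harmonized instrument panel (the data); ``fit``
dispatches to any registered estimator and returns the shared
:class:`~pleiomr.results.MRResult`, which carries the estimate, its
uncertainty, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import get_method, available_methods
from .results import MRResult
from .sumstats import (HarmonizedSet, SummaryStats, harmonize, per_iv_profile,
                       read_sumstats, select_instruments)

__all__ = ["MRModel"]


class MRModel:
    """Two-sample Mendelian-randomization model.

    Parameters
    ----------
    data : HarmonizedSet
        Allele-aligned exposure/outcome effects over the instrument panel
        (optionally with an LD correlation matrix).
    exposure_name, outcome_name : str
        Labels used in summaries only.
    """

    def __init__(self, data: HarmonizedSet, exposure_name: str = "exposure",
                 outcome_name: str = "outcome"):
        self.data = data
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_sumstats(cls, exposure: SummaryStats, outcome: SummaryStats,
                      p_threshold: float = 5e-8, r2_threshold: float = 0.01,
                      ld: np.ndarray | None = None,
                      ld_ids: list[str] | None = None,
                      palindromic_eaf_window: float = 0.08,
                      **names) -> "MRModel":
        """Select instruments from the exposure at ``p_threshold`` (with
        greedy LD clumping when an LD matrix is supplied), then harmonize
        the outcome onto the selected panel."""
        ids = select_instruments(exposure, p_threshold=p_threshold,
                                 ld=ld, ld_ids=ld_ids,
                                 r2_threshold=r2_threshold)
        ids = [v for v in ids if v in set(outcome.variant_ids)]
        if not ids:
            raise ValueError("no instruments pass selection in the outcome panel")
        h = harmonize(exposure.subset(ids), outcome.subset(ids),
                      palindromic_eaf_window=palindromic_eaf_window,
                      ld=ld, ld_ids=ld_ids)
        return cls(h, **names)

    @classmethod
    def from_files(cls, exposure_path, outcome_path, **kwargs) -> "MRModel":
        """Build from two ``.ma`` summary-statistic files."""
        expo, _ = read_sumstats(exposure_path)
        outc, _ = read_sumstats(outcome_path)
        return cls.from_sumstats(expo, outc, **kwargs)

    # -- fitting ---------------------------------------------------------
    @property
    def k(self) -> int:
        return self.data.k

    def fit(self, method: str = "ivw", **options) -> MRResult:
        """Fit one estimator; ``method`` is any registered name
        (:func:`pleiomr.estimators.available_methods`)."""
        return get_method(method)(self.data, **options)

    def fit_all(self, methods: list[str] | None = None,
                method_options: dict | None = None, seed: int = 0
                ) -> pd.DataFrame:
        """Fit several estimators; one row per method."""
        methods = methods or ["ivw", "egger", "weighted_median", "mode", "gsmr2"]
        method_options = method_options or {}
        rows = []
        for m in methods:
            opts = dict(method_options.get(m, {}))
            if m in ("weighted_median", "mode", "weighted_mode"):
                opts.setdefault("seed", seed)
            try:
                res = self.fit(m, **opts)
                rows.append(res.to_dict())
            except Exception as exc:
                rows.append({"method": m, "b_xy": np.nan, "se": np.nan,
                             "p": np.nan, "n_iv_used": self.k,
                             "note": f"failed: {exc}"})
        return pd.DataFrame(rows)

    def per_iv(self, second_order: bool = False) -> pd.DataFrame:
        """Univariate (per-instrument) MR diagnostics."""
        return per_iv_profile(self.data, second_order=second_order)

    def plot_per_iv(self, ax=None):
        """Scatter of instrument strength (exposure z) against the
        per-instrument causal estimate."""
        import matplotlib.pyplot as plt
        prof = self.per_iv()
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(prof["exposure_z"], prof["wald_ratio"],
                    yerr=prof["wald_se"], fmt="o", ms=4, alpha=0.7)
        ax.set_xlabel("instrument strength (exposure z-score)")
        ax.set_ylabel("per-IV causal estimate (Wald ratio)")
        ax.axhline(0.0, color="grey", lw=0.8)
        return ax

    def __repr__(self) -> str:
        return (f"MRModel({self.exposure_name} -> {self.outcome_name}, "
                f"k={self.k}, ld={'yes' if self.data.ld is not None else 'no'})")
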