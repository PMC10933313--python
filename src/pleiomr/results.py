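"""Result container shared by every MR estimator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MRResult:
    """One method's causal-effect estimate with uncertainty and diagnostics.

    Attributes
    ----------
    method : str
        Estimator name.
    b_xy : float
        Causal-effect estimate (outcome units per exposure SD); NaN when
        the method could not run (see ``note``).
    se, p : float
        Standard error and two-sided p-value under the method's reference
        distribution (normal, or t with k-2 df for Egger).
    n_iv_used : int
        Instruments contributing to the final estimate.
    removed_ids : list of str
        Instruments excluded by the method's own filtering.
    intercept, intercept_se : float, optional
        Egger intercept (average directional pleiotropy) and its se.
    het_q, het_p : float, optional
        Global heterogeneity statistic and p-value, when computed.
    removal_ledger : list of (variant_id, stage, p_at_removal)
        Per-removal record for filtering estimators.
    note : str
        Free-text status, e.g. ``"no-instrument"``.
    """

    method: str
    b_xy: float
    se: float
    p: float
    n_iv_used: int
    removed_ids: list = field(default_factory=list)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    het_q: float | None = None
    het_p: float | None = None
    removal_ledger: list = field(default_factory=list)
    note: str = ""

    @property
    def zvalue(self) -> float:
        return self.b_xy / self.se if self.se else np.nan

    def conf_int(self, alpha: float = 0.05):
        from scipy import stats
        z = stats.norm.isf(alpha / 2.0)
        return self.b_xy - z * self.se, self.b_xy + z * self.se

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "b_xy": self.b_xy,
            "se": self.se,
            "p": self.p,
            "n_iv_used": self.n_iv_used,
            "n_removed": len(self.removed_ids),
            "removed_ids": list(self.removed_ids),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "het_q": self.het_q,
            "het_p": self.het_p,
            "note": self.note,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"Two-sample MR: {self.method}",
            "=" * 44,
            f"{'b_xy':>12}  {self.b_xy: .6g}",
            f"{'se':>12}  {self.se: .6g}",
            f"{'z':>12}  {self.zvalue: .4g}",
            f"{'p':>12}  {self.p: .4g}",
            f"{'95% CI':>12}  [{lo: .6g}, {hi: .6g}]",
            f"{'IVs used':>12}  {self.n_iv_used}",
            f"{'IVs removed':>12}  {len(self.removed_ids)}",
        ]
        if self.intercept is not None:
            lines.append(f"{'intercept':>12}  {self.intercept: .6g} "
                         f"(se {self.intercept_se:.6g}, p {self.intercept_p:.4g})")
        if self.het_q is not None:
            lines.append(f"{'het Q':>12}  {self.het_q: .6g} (p {self.het_p:.4g})")
        if self.note:
            lines.append(f"{'note':>12}  {self.note}")
        return "\n".join(lines)


def no_instrument_result(method: str) -> MRResult:
    """Explicit marker for a direction with no usable instruments."""
    return MRResult(method=method, b_xy=np.nan, se=np.nan, p=np.nan,
                    n_iv_used=0, note="no-instrument")
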