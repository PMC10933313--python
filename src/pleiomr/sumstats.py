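"""GWAS summary statistics: container, .ma file I/O, allele harmonization,
instrument selection, and per-instrument diagnostics.

The on-disk dialect is the COJO ``.ma`` format used throughout the
GCTA/GSMR ecosystem: a whitespace-delimited table with header columns
``SNP A1 A2 freq b se p N`` (any order).  ``A1`` is the effect allele,
``b`` the additive per-A1-allele effect (per-SD units for quantitative
traits, log-odds for binary contrasts), ``se`` its standard error, ``p``
the association p-value and ``N`` the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "HarmonizedSet",
    "AuditLog",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "harmonize",
    "select_instruments",
    "p_to_chisq",
    "per_iv_profile",
]

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
_CANON = {"snp": "SNP", "a1": "A1", "a2": "A2", "freq": "freq",
          "b": "b", "se": "se", "p": "p", "n": "N"}
_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# p-value vs |beta/se| mutual-consistency tolerance (relative, z scale)
_Z_CONSISTENCY_RTOL = 0.10


class SumstatsError(ValueError):
    """Malformed or empty summary-statistic input."""


@dataclass
class AuditLog:
    """Line-oriented record of rows dropped/modified during validation."""

    lines: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(1 for ln in self.lines if ln.startswith("DROP"))

    def drop(self, variant_id: str, reason: str) -> None:
        self.lines.append(f"DROP\t{variant_id}\t{reason}")

    def note(self, message: str) -> None:
        self.lines.append(f"NOTE\t{message}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + ("\n" if self.lines else ""))

    def __len__(self) -> int:
        return len(self.lines)


class SummaryStats:
    """Per-variant association records for a single trait.

    Wraps a validated :class:`pandas.DataFrame` with the canonical ``.ma``
    columns.  Construction enforces the record invariants (positive se,
    frequency in (0,1), distinct A/C/G/T alleles, unique variant ids, and
    p consistent with ``|b/se|``); offending rows are dropped and logged.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True,
                 audit: AuditLog | None = None):
        df = df.rename(columns={c: _CANON.get(str(c).lower(), c) for c in df.columns})
        missing = [c for c in MA_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsError(f"missing mandatory column(s): {missing}")
        df = df[MA_COLUMNS].copy()
        self.audit = audit if audit is not None else AuditLog()
        if validate:
            df = self._validate(df, self.audit)
        if len(df) == 0:
            raise SumstatsError("no valid summary-statistic rows")
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame, audit: AuditLog) -> pd.DataFrame:
        for col in ("freq", "b", "se", "p"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["N"] = pd.to_numeric(df["N"], errors="coerce")
        df["A1"] = df["A1"].astype(str).str.upper()
        df["A2"] = df["A2"].astype(str).str.upper()

        keep = np.ones(len(df), dtype=bool)
        reasons = [""] * len(df)

        def _flag(mask, reason):
            for i in np.nonzero(mask & keep)[0]:
                reasons[i] = reason
            keep[mask] = False

        numeric = df[["freq", "b", "se", "p", "N"]].notna().all(axis=1).to_numpy()
        _flag(~numeric, "non-numeric field")
        with np.errstate(invalid="ignore"):
            _flag(~(df["se"].to_numpy() > 0), "se <= 0")
            _flag(~((df["freq"].to_numpy() > 0) & (df["freq"].to_numpy() < 1)),
                  "eaf outside (0,1)")
            _flag(~((df["p"].to_numpy() > 0) & (df["p"].to_numpy() <= 1)),
                  "p outside (0,1]")
            _flag(~(df["N"].to_numpy() > 0), "non-positive N")
        bad_allele = (~df["A1"].isin(_VALID_ALLELES) | ~df["A2"].isin(_VALID_ALLELES)
                      | (df["A1"] == df["A2"])).to_numpy()
        _flag(bad_allele, "invalid allele pair")
        dup = df["SNP"].duplicated(keep="first").to_numpy()
        _flag(dup, "duplicate variant id")

        # p and |b/se| must agree (10% relative tolerance on the z scale);
        # guards against mismatched columns in hand-edited files.
        with np.errstate(divide="ignore", invalid="ignore"):
            z_obs = np.abs(df["b"].to_numpy() / df["se"].to_numpy())
            z_p = stats.norm.isf(df["p"].to_numpy(dtype=float) / 2.0)
        checkable = keep & np.isfinite(z_p) & (z_p > 1e-8) & (z_obs > 1e-8)
        mismatch = checkable & (np.abs(z_obs - z_p) > _Z_CONSISTENCY_RTOL * z_p)
        _flag(mismatch, "p inconsistent with |b/se|")

        for i in np.nonzero(~keep)[0]:
            audit.drop(str(df["SNP"].iloc[i]), reasons[i])
        out = df.loc[keep].copy()
        out["N"] = out["N"].astype(np.int64)
        return out

    # -- convenience accessors -------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return self.df["SNP"].tolist()

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def zscores(self) -> np.ndarray:
        return (self.df["b"] / self.df["se"]).to_numpy()

    def subset(self, ids) -> "SummaryStats":
        sub = self.df[self.df["SNP"].isin(set(ids))]
        return SummaryStats(sub, validate=False)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SummaryStats({len(self.df)} variants)"


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared, allele-aligned panel.

    Effect alleles are identical between the two traits; ``ld``, when
    present, is the instrument correlation matrix in panel order.
    """

    variant_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    ld: np.ndarray | None = None
    eaf: np.ndarray | None = None
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.variant_ids)
        if k < 1:
            raise SumstatsError("harmonized set must contain at least one instrument")
        for arr in (self.bx, self.se_x, self.by, self.se_y):
            if arr.shape != (k,):
                raise SumstatsError("harmonized arrays must share one length")
        if self.ld is not None:
            self.ld = np.asarray(self.ld, dtype=float)
            if self.ld.shape != (k, k):
                raise SumstatsError(f"LD matrix shape {self.ld.shape} != ({k},{k})")
            if not np.allclose(self.ld, self.ld.T, atol=1e-8):
                raise SumstatsError("LD matrix is not symmetric")
            if not np.allclose(np.diag(self.ld), 1.0, atol=1e-6):
                raise SumstatsError("LD matrix diagonal must be 1")
            if np.any(np.abs(self.ld) > 1 + 1e-8):
                raise SumstatsError("LD entries must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def subset(self, idx) -> "HarmonizedSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return HarmonizedSet(
            [self.variant_ids[i] for i in idx],
            self.bx[idx], self.se_x[idx], self.by[idx], self.se_y[idx],
            ld=None if self.ld is None else self.ld[np.ix_(idx, idx)],
            eaf=None if self.eaf is None else np.asarray(self.eaf)[idx],
            effect_allele=None if self.effect_allele is None
            else [self.effect_allele[i] for i in idx],
            other_allele=None if self.other_allele is None
            else [self.other_allele[i] for i in idx],
        )

    def wald_ratios(self) -> np.ndarray:
        return self.by / self.bx

    def ratio_variances(self, second_order: bool = True) -> np.ndarray:
        """Delta-method variances of the per-IV Wald ratios."""
        v = self.se_y ** 2 / self.bx ** 2
        if second_order:
            v = v + self.by ** 2 * self.se_x ** 2 / self.bx ** 4
        return v


# ---------------------------------------------------------------------------
# File I/O


def read_sumstats(path, dialect: str = "ma") -> tuple[SummaryStats, AuditLog]:
    """Read a ``.ma``-dialect summary-statistics file.

    Tab- or space-delimited; header must name SNP, A1, A2, freq, b, se,
    p, N (case-insensitive, any order).  Rows violating the record
    invariants are dropped and reported in the returned audit log.
    """
    if dialect != "ma":
        raise SumstatsError(f"unknown summary-statistics dialect: {dialect!r}")
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    lowered = {str(c).lower() for c in df.columns}
    missing = [k for k in _CANON if k not in lowered]
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {missing}; header must "
            f"contain {MA_COLUMNS}")
    audit = AuditLog()
    ss = SummaryStats(df, validate=True, audit=audit)
    return ss, audit


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write in the canonical tab-delimited ``.ma`` layout (inverse of
    :func:`read_sumstats`; full float precision)."""
    df = ss.df.copy()
    with open(path, "w") as fh:
        fh.write("\t".join(MA_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.SNP}\t{row.A1}\t{row.A2}\t{row.freq!r}\t"
                     f"{row.b!r}\t{row.se!r}\t{row.p!r}\t{row.N}\n")


def write_empty_sumstats(path) -> None:
    """Header-only ``.ma`` file (an empty record set)."""
    with open(path, "w") as fh:
        fh.write("\t".join(MA_COLUMNS) + "\n")


def read_ld_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a whitespace-delimited LD correlation matrix with a header row
    of variant ids; returns (ids, square matrix)."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise SumstatsError(f"LD matrix is not square: {mat.shape}")
    return ids, mat


# ---------------------------------------------------------------------------
# Harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindromic_eaf_window: float = 0.08,
              ld: np.ndarray | None = None,
              ld_ids: list[str] | None = None,
              audit: AuditLog | None = None) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    Intersects on variant id, then per variant tries, in order: exact
    allele match, swapped alleles (flip the outcome beta sign and replace
    eaf by 1-eaf), strand complement, complement+swap; anything else is
    dropped and logged.  Palindromic (A/T or C/G) variants whose exposure
    eaf lies within ``palindromic_eaf_window`` of 0.5 are excluded, since
    strand cannot be resolved from frequency there.
    """
    audit = audit if audit is not None else AuditLog()
    ex = exposure.df.set_index("SNP")
    ou = outcome.df.set_index("SNP")
    shared = [v for v in exposure.df["SNP"] if v in ou.index]
    if not shared:
        raise SumstatsError("no overlapping variants between exposure and outcome")

    rows = []
    for vid in shared:
        e = ex.loc[vid]
        o = ou.loc[vid]
        ea1, ea2 = e["A1"], e["A2"]
        if _is_palindromic(ea1, ea2) and abs(e["freq"] - 0.5) < palindromic_eaf_window:
            audit.drop(vid, f"palindromic with exposure eaf {e['freq']:.3f} near 0.5")
            continue
        oa1, oa2 = o["A1"], o["A2"]
        ca1, ca2 = _COMPLEMENT[oa1], _COMPLEMENT[oa2]
        if (oa1, oa2) == (ea1, ea2) or (ca1, ca2) == (ea1, ea2):
            by, eaf_o = o["b"], o["freq"]
        elif (oa2, oa1) == (ea1, ea2) or (ca2, ca1) == (ea1, ea2):
            by, eaf_o = -o["b"], 1.0 - o["freq"]
        else:
            audit.drop(vid, f"allele mismatch {oa1}/{oa2} vs {ea1}/{ea2}")
            continue
        rows.append((vid, e["b"], e["se"], by, o["se"], e["freq"], ea1, ea2))

    if not rows:
        raise SumstatsError("no variants survived harmonization")
    vids = [r[0] for r in rows]
    ld_sub = None
    if ld is not None:
        if ld_ids is None:
            if ld.shape[0] != len(vids):
                raise SumstatsError("LD matrix without ids must match the "
                                    "harmonized panel size")
            ld_sub = ld
        else:
            pos = {v: i for i, v in enumerate(ld_ids)}
            missing = [v for v in vids if v not in pos]
            if missing:
                raise SumstatsError(f"LD matrix missing variants: {missing[:5]}")
            idx = [pos[v] for v in vids]
            ld_sub = ld[np.ix_(idx, idx)]
    return HarmonizedSet(
        vids,
        bx=np.array([r[1] for r in rows]),
        se_x=np.array([r[2] for r in rows]),
        by=np.array([r[3] for r in rows]),
        se_y=np.array([r[4] for r in rows]),
        ld=ld_sub,
        eaf=np.array([r[5] for r in rows]),
        effect_allele=[r[6] for r in rows],
        other_allele=[r[7] for r in rows],
    )


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(ss: SummaryStats, p_threshold: float = 5e-8,
                       ld: np.ndarray | None = None,
                       ld_ids: list[str] | None = None,
                       r2_threshold: float = 0.01) -> list[str]:
    """Genome-wide-significant, LD-independent instrument panel.

    Keeps variants with ``p`` strictly below ``p_threshold`` (the printed
    convention: P < 5e-8), then greedily clumps by ascending p, dropping
    any variant whose squared correlation with an already-kept variant is
    ``>= r2_threshold`` (default r^2 < 0.01 kept).  Returned ids are in
    ascending-p order.
    """
    if not (0 < p_threshold < 1):
        raise SumstatsError("p_threshold must lie in (0,1)")
    if not (0 < r2_threshold <= 1):
        raise SumstatsError("r2_threshold must lie in (0,1]")
    df = ss.df
    sig = df[df["p"] < p_threshold]
    if sig.empty:
        return []
    # stable tie-break on variant id keeps the output row-order invariant
    sig = sig.sort_values(["p", "SNP"], kind="mergesort")
    if ld is None:
        return sig["SNP"].tolist()
    if ld_ids is not None:
        pos = {v: i for i, v in enumerate(ld_ids)}
        try:
            order = [pos[v] for v in sig["SNP"]]
        except KeyError as exc:
            raise SumstatsError(f"LD matrix missing variant {exc}") from exc
    else:
        if ld.shape[0] != len(df):
            raise SumstatsError(
                f"LD matrix dimension {ld.shape[0]} != {len(df)} variants")
        pos = {v: i for i, v in enumerate(df["SNP"])}
        order = [pos[v] for v in sig["SNP"]]
    kept: list[str] = []
    kept_idx: list[int] = []
    for vid, i in zip(sig["SNP"], order):
        if all(ld[i, j] ** 2 < r2_threshold for j in kept_idx):
            kept.append(vid)
            kept_idx.append(i)
    return kept


def p_to_chisq(p) -> float | np.ndarray:
    """1-df chi-squared value whose upper-tail probability equals ``p``
    (e.g. p = 5e-8 corresponds to chi^2 = 29.7)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise SumstatsError("p must lie in (0,1]")
    out = stats.chi2.isf(p, df=1)
    return float(out) if out.ndim == 0 else out


def per_iv_profile(h: HarmonizedSet, second_order: bool = False) -> pd.DataFrame:
    """Univariate (single-instrument) MR diagnostics.

    One row per instrument: the exposure z-score and the Wald-ratio causal
    estimate with its delta-method se (first-order ``se_y/|bx|`` by
    default; ``second_order`` adds the ``by^2 se_x^2 / bx^4`` term).
    Instruments with ``bx == 0`` are flagged, not raised.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = h.by / h.bx
        var = h.ratio_variances(second_order=second_order)
        se = np.sqrt(var)
    undefined = h.bx == 0
    ratio = np.where(undefined, np.nan, ratio)
    se = np.where(undefined, np.nan, se)
    return pd.DataFrame({
        "variant_id": h.variant_ids,
        "exposure_z": h.bx / h.se_x,
        "wald_ratio": ratio,
        "wald_se": se,
        "undefined": undefined,
    })
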