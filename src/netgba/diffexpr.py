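"""Quantile normalization and empirical-Bayes moderated-t differential expression.

The moderated t-statistic shrinks each gene's sample variance toward a
pooled prior estimated from all genes.  Sample variances are modelled as
scaled F/chi-square draws around a prior variance ``s0^2`` with ``d0`` prior
degrees of freedom; the posterior variance for a gene with residual variance
``s^2`` on ``d`` degrees of freedom is

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t is the ordinary two-sample t with ``s`` replaced by
``s_post`` and ``d0 + d`` total degrees of freedom.  The hyperparameters
(d0, s0^2) are estimated by method of moments on the log sample variances,
matching the standard empirical-Bayes practice for microarray data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 intensities (no missing values)."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            n_bad = int(self.values.isna().any(axis=1).sum())
            logger.warning("dropping %d genes with missing values", n_bad)
            self.values = self.values.dropna(axis=0)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression_tsv(path) -> ExpressionMatrix:
    """First column gene symbol, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    return ExpressionMatrix(df)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Columns: sample_id, group (case|control), tissue."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's order statistics are replaced by the across-column mean of
    order statistics; ties within a column receive the average of the target
    values they span (average-rank convention), so within-column order is
    preserved up to ties.
    """
    x = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires >=2 samples")
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    ranks = np.empty_like(x)
    for j in range(n_samples):
        ranks[:, j] = stats.rankdata(x[:, j], method="average")
    # fractional (tied) ranks interpolate between adjacent order statistics
    out = np.interp(ranks - 1.0, np.arange(n_genes), mean_sorted)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameter estimation (method of moments on log s^2)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from observed variances ``s2`` on ``df`` df each.

    Moment-matching on z = log(s2): E[z] and Var[z] are known functions of
    (d0, s0^2, df) through digamma/trigamma; invert them.  Returns
    ``d0 = inf`` when the observed spread of log-variances does not exceed
    the sampling noise (all shrinkage, no gene-specific component).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >=2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    n = len(e)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


def squeeze_var(s2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + df * s2) / (d0 + df)


# ---------------------------------------------------------------------------
# moderated t


def moderated_t(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    contrast: str = "diagnosis",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group (case vs control) moderated-t table for one contrast.

    ``contrast="diagnosis"`` pools all tissues; a tissue label restricts to
    that tissue's samples.  ``prior_df`` overrides the estimated d0 (0 gives
    the ordinary pooled-variance t; ``inf`` full shrinkage to s0^2).

    Returns a DataFrame indexed by gene with columns
    ``logFC, s2, t_mod, p, df_total`` (p two-sided, unadjusted).
    """
    meta = validate_metadata(meta)
    if contrast != "diagnosis":
        meta = meta[meta["tissue"] == contrast]
        if meta.empty:
            raise ValueError(f"no samples for tissue {contrast!r}")
    meta = meta[meta["sample_id"].isin(matrix.samples)]
    case_ids = meta.loc[meta["group"] == "case", "sample_id"].tolist()
    ctrl_ids = meta.loc[meta["group"] == "control", "sample_id"].tolist()
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"contrast {contrast!r}: need >=2 samples per group (got {n1} vs {n2})")

    x1 = matrix.values[case_ids].to_numpy(dtype=float)
    x2 = matrix.values[ctrl_ids].to_numpy(dtype=float)
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    unscaled_se = math.sqrt(1.0 / n1 + 1.0 / n2)

    if prior_df is None:
        d0, s02 = fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s02 = 0.0, float("nan")
    else:
        d0 = float(prior_df)
        _, s02 = fit_f_dist(s2, df_resid)

    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = squeeze_var(s2, df_resid, d0, s02)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / (np.sqrt(s2_post) * unscaled_se)
    t_mod = np.where(s2_post > 0, t_mod, np.nan)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "t_mod": t_mod,
            "p": p,
            "df_total": df_total,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )
    out.attrs["contrast"] = contrast
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    out.attrs["n_case"] = n1
    out.attrs["n_control"] = n2
    return out


def collapse_probes(de: pd.DataFrame, probe_to_symbol: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level table to gene symbols, keeping the best-p probe."""
    mapped = de.join(probe_to_symbol.rename("symbol"), how="inner")
    mapped["symbol"] = mapped["symbol"].str.strip().str.upper()
    best = mapped.sort_values("p", kind="mergesort").groupby("symbol").head(1)
    return best.set_index("symbol").sort_index()


def adjust_pvalues(de: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Append an adjusted-p column (optional post hoc; seed selection uses raw p)."""
    from statsmodels.stats.multitest import multipletests

    out = de.copy()
    out["p_adj"] = multipletests(out["p"].to_numpy(), method=method)[1]
    return out
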