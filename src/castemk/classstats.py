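"""Class-level statistics: mean-age GLM, contingency residuals, GO tests.

Three independent looks at how gene classes (reproductive- vs
worker-upregulated vs NDE) relate to gene age and function:

* a log-link Poisson GLM of the stratum value on the class indicator
  (switching to quasi-Poisson standard errors when the Pearson dispersion
  exceeds a configurable threshold),
* an omnibus chi-square on the class x condensed-category contingency
  table with standardized Pearson residuals per cell (|r| > 2 ~ p < 0.05,
  |r| > 4 ~ p < 0.001),
* hypergeometric over-representation of GO terms in a gene set against a
  background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMStratumResult",
    "ContingencyResult",
    "glm_mean_stratum",
    "contingency_residuals",
    "go_enrichment",
]

DISPERSION_SWITCH = 1.2


@dataclass
class GLMStratumResult:
    """Poisson / quasi-Poisson GLM contrast of mean stratum between classes."""

    coefficient: float       # log rate ratio, second class vs reference
    std_error: float         # under family_used
    z: float
    p_value: float
    df: int                  # residual degrees of freedom (n - p)
    dispersion: float        # Pearson X^2 / df
    family_used: str         # "poisson" | "quasipoisson"
    poisson_se: float        # unscaled SE, always reported
    quasipoisson_se: float
    reference_class: str
    contrast_class: str
    n: int

    def summary(self) -> str:
        return (
            f"GLM mean stratum: {self.contrast_class} vs {self.reference_class}\n"
            f"  coefficient = {self.coefficient:.4f} (log rate ratio)\n"
            f"  SE ({self.family_used}) = {self.std_error:.4f}, "
            f"z = {self.z:.2f}, p = {self.p_value:.3g}\n"
            f"  df = {self.df}, dispersion = {self.dispersion:.3f}"
        )


def glm_mean_stratum(table: pd.DataFrame, class_col: str = "class_label",
                     value_col: str = "stratum",
                     reference: Optional[str] = None,
                     dispersion_switch: float = DISPERSION_SWITCH) -> GLMStratumResult:
    """Compare mean stratum between two gene classes with a Poisson GLM.

    The response is the (positive integer) stratum value, the predictor a
    two-level class indicator; the fit is by IRLS.  When the Pearson
    dispersion exceeds ``dispersion_switch`` the reported SE/z switch to
    quasi-Poisson (SE scaled by sqrt(dispersion)); both flavours are
    retained on the result.
    """
    df = table[[class_col, value_col]].dropna()
    classes = sorted(df[class_col].unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if reference is None:
        reference = classes[0]
    if reference not in classes:
        raise ValueError(f"reference {reference!r} not among classes {classes}")
    contrast = [c for c in classes if c != reference][0]
    counts = df.groupby(class_col)[value_col].agg(["count", "var"])
    if (counts["count"] < 2).any():
        raise ValueError("each class needs at least 2 genes")
    if (df[value_col] <= 0).any():
        raise ValueError("stratum values must be positive integers")
    if df[value_col].nunique() == 1:
        raise ValueError("zero-variance response: all stratum values identical")
    y = df[value_col].to_numpy(dtype=float)
    x = (df[class_col] == contrast).to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    df_resid = int(fit.df_resid)
    dispersion = float(fit.pearson_chi2 / df_resid)
    poisson_se = float(fit.bse[1])
    quasi_se = poisson_se * float(np.sqrt(dispersion))
    family_used = "quasipoisson" if dispersion > dispersion_switch else "poisson"
    se = quasi_se if family_used == "quasipoisson" else poisson_se
    coef = float(fit.params[1])
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return GLMStratumResult(
        coefficient=coef, std_error=se, z=float(z), p_value=float(p),
        df=df_resid, dispersion=dispersion, family_used=family_used,
        poisson_se=poisson_se, quasipoisson_se=quasi_se,
        reference_class=str(reference), contrast_class=str(contrast),
        n=len(df),
    )


@dataclass
class ContingencyResult:
    """Omnibus chi-square plus per-cell standardized Pearson residuals."""

    chi_square: float
    df: int
    p_value: float
    cells: pd.DataFrame  # row, col, observed, expected, residual, flag, direction

    def to_mosaic_frame(self) -> pd.DataFrame:
        """Cell table with areas proportional to observed counts (for mosaics)."""
        out = self.cells.copy()
        out["area"] = out["observed"] / out["observed"].sum()
        return out


def _residual_flag(r: float) -> str:
    a = abs(r)
    if a > 4:
        return "p<0.001"
    if a > 2:
        return "p<0.05"
    return "none"


def contingency_residuals(counts) -> ContingencyResult:
    """Chi-square test of independence with standardized Pearson residuals.

    ``counts`` is a class x category matrix (DataFrame preferred: labels are
    carried through).  Expected counts are the usual margin products; the
    standardized residual for cell (i, j) is
    ``(O - E) / sqrt(E * (1 - row_i/n) * (1 - col_j/n))``.  All margins must
    be positive.  No continuity correction is applied.
    """
    if isinstance(counts, pd.DataFrame):
        obs = counts.to_numpy(dtype=float)
        row_labels = list(counts.index)
        col_labels = list(counts.columns)
    else:
        obs = np.asarray(counts, dtype=float)
        row_labels = list(range(obs.shape[0]))
        col_labels = list(range(obs.shape[1]))
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = obs.sum()
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"zero margin in row {row_labels[i]!r}")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"zero margin in column {col_labels[j]!r}")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    denom = np.sqrt(
        expected
        * (1.0 - row_sums[:, None] / n)
        * (1.0 - col_sums[None, :] / n)
    )
    resid = (obs - expected) / denom
    rows = []
    for i, rl in enumerate(row_labels):
        for j, cl in enumerate(col_labels):
            r = float(resid[i, j])
            rows.append(
                {
                    "row": rl,
                    "col": cl,
                    "observed": float(obs[i, j]),
                    "expected": float(expected[i, j]),
                    "std_pearson_residual": r,
                    "flag": _residual_flag(r),
                    "direction": "over" if r > 0 else "under",
                }
            )
    return ContingencyResult(
        chi_square=float(chi2), df=int(df), p_value=float(p),
        cells=pd.DataFrame(rows),
    )


def go_enrichment(gene_set: Iterable[str], background: Iterable[str],
                  annotations: Mapping[str, Iterable[str]] | pd.DataFrame,
                  p_cutoff: float = 0.05, bh_correct: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    For each term, with N background genes, K of them annotated, a set of
    size n and k annotated set members, the p-value is the upper tail
    P[X >= k] of Hypergeom(N, K, n).  Raw p-values are compared against
    ``p_cutoff`` (the Benjamini-Hochberg option is off by default).
    ``annotations`` maps gene_id to terms, or is a DataFrame with columns
    gene_id, term_id (term_name optional).
    """
    background = set(map(str, background))
    gene_set = set(map(str, gene_set))
    missing = gene_set - background
    if missing:
        raise ValueError(
            f"gene set members absent from background: {sorted(missing)[:10]}"
        )
    if isinstance(annotations, pd.DataFrame):
        ann = {}
        names = {}
        for r in annotations.itertuples():
            ann.setdefault(str(r.gene_id), set()).add(str(r.term_id))
            if hasattr(r, "term_name"):
                names[str(r.term_id)] = str(r.term_name)
    else:
        ann = {str(g): set(map(str, ts)) for g, ts in annotations.items()}
        names = {}
    term_bg = {}
    term_set = {}
    for g in background:
        for t in ann.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in gene_set:
                term_set[t] = term_set.get(t, 0) + 1
    N, n = len(background), len(gene_set)
    rows = []
    for t, K in sorted(term_bg.items()):
        k = term_set.get(t, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": t,
                "term_name": names.get(t, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "enriched"]
        )
        return out
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["enriched"] = out["p_adjusted"] < p_cutoff
    else:
        out["enriched"] = out["p_value"] < p_cutoff
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
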