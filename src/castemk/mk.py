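"""Maximum-likelihood estimation of the adaptive substitution proportion alpha.

The McDonald-Kreitman contrast compares, per gene, nonsynonymous and
synonymous counts of within-species polymorphism (Pn, Ps) and between-species
divergence (Dn, Ds).  Under the model implemented here each gene *i* carries
its own synonymous polymorphism and divergence intensities (theta_i,
lambda_i), while the selective constraint ``f`` (the fraction of
nonsynonymous mutations behaving neutrally) and the adaptive proportion
``alpha`` are shared across the genes of a class::

    Ps_i ~ Poisson(theta_i)
    Pn_i ~ Poisson(f * theta_i)
    Ds_i ~ Poisson(lambda_i)
    Dn_i ~ Poisson(f * lambda_i / (1 - alpha))

Profiling out the per-gene nuisance intensities at their closed-form MLEs,

    theta_i = (Ps_i + Pn_i) / (1 + f)
    lambda_i = (Ds_i + Dn_i) / (1 + f / (1 - alpha)),

collapses the log-likelihood, up to a data-only constant, to two binomial
terms in the column sums: with ``g = f / (1 - alpha)``,

    ll(alpha, f) = SPn*log(qp) + SPs*log(1-qp) + SDn*log(qd) + SDs*log(1-qd),
    qp = f / (1 + f),   qd = g / (1 + g).

This makes the fit cheap and yields a closed-form interior optimum
(f = SPn/SPs when that ratio is <= 1, and alpha matching the pooled
estimator 1 - SDs*SPn / (SDn*SPs)); the constrained boundary f = 1 gives
alpha = 1 - SDs/SDn.  ``MKAlphaModel.fit`` additionally scans a coarse
(alpha, f) grid and polishes with Nelder-Mead, so the reported optimum never
falls below any evaluated grid point.

``alpha`` may be negative: an excess of (often mildly deleterious)
nonsynonymous polymorphism relative to divergence drives the estimate below
zero, a well-known feature of MK-based estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import hypergeom

__all__ = [
    "MKAlphaModel",
    "MKAlphaResults",
    "GeneMKStats",
    "ClassComparison",
    "mk_test",
    "pooled_alpha",
    "ml_alpha",
    "bootstrap_alpha",
    "compare_classes",
    "UndefinedEstimateError",
]

COUNT_COLUMNS = ("Pn", "Ps", "Dn", "Ds")

_F_MIN = 1e-6
_ALPHA_MIN = -5.0
_ALPHA_MAX = 1.0 - 1e-9


class UndefinedEstimateError(ValueError):
    """A count sum required by an estimator is zero."""


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMKStats:
    """Per-gene MK summary: neutrality index, Fisher exact p, direction."""

    gene_id: str
    ni: float  # NaN when undefined (any of Ps, Dn, Ds zero)
    fisher_p: float
    direction: str  # excess_divergence | excess_polymorphism | balanced


def _fisher_exact_two_sided(pn: int, ps: int, dn: int, ds: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[Pn, Ps], [Dn, Ds]].

    Convention: sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table (with a relative guard of 1e-7 against floating-point ties).
    """
    n = pn + ps + dn + ds
    if n == 0:
        return 1.0
    row1 = pn + ps
    col1 = pn + dn
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(pn)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def mk_test(counts) -> GeneMKStats:
    """McDonald-Kreitman test for one gene's (Pn, Ps, Dn, Ds) counts.

    ``counts`` may be an ``MKCounts``-like object / mapping / Series with
    fields Pn, Ps, Dn, Ds and optionally gene_id.  The neutrality index
    NI = (Pn/Ps)/(Dn/Ds) is NaN whenever Ps, Dn or Ds is zero.
    """
    pn, ps, dn, ds = (int(_get(counts, c)) for c in COUNT_COLUMNS)
    if min(pn, ps, dn, ds) < 0:
        raise ValueError("MK counts must be nonnegative")
    gene_id = str(_get(counts, "gene_id", ""))
    ni = (pn / ps) / (dn / ds) if ps > 0 and dn > 0 and ds > 0 else math.nan
    # direction from the cross products, defined even when NI is not
    cross_p, cross_d = pn * ds, dn * ps
    if cross_p < cross_d:
        direction = "excess_divergence"
    elif cross_p > cross_d:
        direction = "excess_polymorphism"
    else:
        direction = "balanced"
    return GeneMKStats(gene_id, ni, _fisher_exact_two_sided(pn, ps, dn, ds), direction)


def _get(obj, name, default=None):
    if isinstance(obj, dict):
        return obj.get(name, default) if default is not None else obj[name]
    if hasattr(obj, name):
        return getattr(obj, name)
    try:
        return obj[name]
    except (KeyError, IndexError, TypeError):
        if default is not None:
            return default
        raise


# ---------------------------------------------------------------------------
# pooled estimator
# ---------------------------------------------------------------------------

def pooled_alpha(genes) -> float:
    """Pooled-counts alpha: 1 - (sum Ds * sum Pn) / (sum Dn * sum Ps).

    Sums run over genes.  Requires sum Dn > 0 and sum Ps > 0; raises
    :class:`UndefinedEstimateError` naming the offending zero sum otherwise.
    """
    s = _count_sums(genes)
    if s["Dn"] == 0:
        raise UndefinedEstimateError("pooled alpha undefined: sum of Dn is zero")
    if s["Ps"] == 0:
        raise UndefinedEstimateError("pooled alpha undefined: sum of Ps is zero")
    return 1.0 - (s["Ds"] * s["Pn"]) / (s["Dn"] * s["Ps"])


def _count_sums(genes) -> dict:
    df = _as_frame(genes)
    return {c: int(df[c].sum()) for c in COUNT_COLUMNS}


def _as_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        df = genes
    else:
        df = pd.DataFrame(list(genes))
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MK count table lacks columns: {missing}")
    if (df[list(COUNT_COLUMNS)] < 0).any().any():
        raise ValueError("MK counts must be nonnegative")
    return df


# ---------------------------------------------------------------------------
# profile log-likelihood machinery
# ---------------------------------------------------------------------------

def _profile_ll_sums(alpha, f, spn, sps, sdn, sds):
    """Collapsed profile log-likelihood (up to a data-only constant).

    Vectorised over ``alpha``/``f`` arrays.  Returns -inf outside the
    admissible region (alpha < 1, 0 < f <= 1).
    """
    alpha = np.asarray(alpha, dtype=float)
    f = np.asarray(f, dtype=float)
    bad = (alpha >= 1.0) | (f <= 0.0) | (f > 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = f / (1.0 - alpha)
        qp = f / (1.0 + f)
        qd = g / (1.0 + g)
        ll = (
            _xlogy(spn, qp)
            + _xlogy(sps, 1.0 - qp)
            + _xlogy(sdn, qd)
            + _xlogy(sds, 1.0 - qd)
        )
    ll = np.where(bad, -np.inf, ll)
    return ll if ll.shape else float(ll)


def _xlogy(x, y):
    from scipy.special import xlogy

    return xlogy(x, y)


def _ll_constant(df: pd.DataFrame) -> float:
    """Data-only part of the profiled Poisson log-likelihood.

    Per gene, with P = Pn+Ps and D = Dn+Ds:
    P*log(P) - P - log(Pn! Ps!) and the analogue for divergence.
    """
    from scipy.special import gammaln, xlogy

    pn = df["Pn"].to_numpy(float)
    ps = df["Ps"].to_numpy(float)
    dn = df["Dn"].to_numpy(float)
    ds = df["Ds"].to_numpy(float)
    p, d = pn + ps, dn + ds
    const = (
        xlogy(p, p) - p - gammaln(pn + 1) - gammaln(ps + 1)
        + xlogy(d, d) - d - gammaln(dn + 1) - gammaln(ds + 1)
    )
    return float(const.sum())


def _closed_form_sums(spn, sps, sdn, sds):
    """Closed-form maximiser of the collapsed profile likelihood.

    Returns (alpha, f, ok) where ok is False for degenerate sums (no
    divergence or no synonymous polymorphism information).
    """
    if sdn + sds == 0 or sps + spn == 0:
        return math.nan, math.nan, False
    if sps > 0:
        f = min(1.0, max(_F_MIN, spn / sps))
    else:  # all polymorphism nonsynonymous: constraint at the upper bound
        f = 1.0
    if sdn == 0:
        # g -> 0: alpha -> -inf; clamp at the search floor
        return _ALPHA_MIN, f, False
    if sds == 0:
        g_hat = np.inf
        alpha = _ALPHA_MAX
    else:
        g_hat = sdn / sds
        alpha = 1.0 - f / g_hat
    alpha = min(_ALPHA_MAX, max(_ALPHA_MIN, alpha))
    return alpha, f, True


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class MKAlphaResults:
    """Fit results for a class of genes: alpha, constraint f, inference.

    Mirrors the fields a results object usually carries: point estimates,
    log-likelihood, bootstrap percentile CI (filled by
    :meth:`MKAlphaModel.bootstrap`) and the bootstrap draws themselves.
    """

    class_label: str
    alpha_hat: float
    f_hat: float
    log_likelihood: float
    n_genes: int
    n_dropped_allzero: int = 0
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_bootstrap: int = 0
    n_bootstrap_dropped: int = 0
    seed: int | None = None
    bootstrap_draws: np.ndarray | None = field(default=None, repr=False)
    converged: bool = True

    def summary(self) -> str:
        lines = [
            "MK alpha maximum-likelihood fit",
            "=" * 46,
            f"class:            {self.class_label}",
            f"n genes:          {self.n_genes} "
            f"({self.n_dropped_allzero} all-zero dropped)",
            f"alpha_hat:        {self.alpha_hat: .4f}",
            f"f_hat:            {self.f_hat: .4f}",
            f"log-likelihood:   {self.log_likelihood: .3f}",
        ]
        if self.n_bootstrap:
            lines += [
                f"95% CI (perc.):   [{self.ci_low: .4f}, {self.ci_high: .4f}]",
                f"bootstrap:        B={self.n_bootstrap} "
                f"(dropped {self.n_bootstrap_dropped}), seed={self.seed}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "class_label": self.class_label,
            "alpha_hat": self.alpha_hat,
            "f_hat": self.f_hat,
            "log_likelihood": self.log_likelihood,
            "n_genes": self.n_genes,
            "n_dropped_allzero": self.n_dropped_allzero,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "n_bootstrap_dropped": self.n_bootstrap_dropped,
            "seed": self.seed,
            "converged": self.converged,
        }
        return d


class MKAlphaModel:
    """Shared-(alpha, f) Poisson MK model with per-gene nuisance intensities.

    Parameters
    ----------
    counts
        DataFrame (or iterable of records) with columns Pn, Ps, Dn, Ds and
        optionally gene_id.  Genes whose four counts are all zero carry no
        likelihood information and are dropped (the number is reported on
        the results).
    label
        Class label carried through to the results (e.g. "worker").
    """

    #: coarse grid used before local refinement
    ALPHA_GRID = np.linspace(_ALPHA_MIN, 0.99, 61)
    F_GRID = np.linspace(0.01, 1.0, 50)

    def __init__(self, counts, label: str = "all"):
        df = _as_frame(counts).reset_index(drop=True)
        nonzero = df[list(COUNT_COLUMNS)].sum(axis=1) > 0
        self.n_dropped_allzero = int((~nonzero).sum())
        self.counts = df.loc[nonzero].reset_index(drop=True)
        if len(self.counts) < 1:
            raise ValueError("no genes with nonzero MK counts")
        self.label = label
        self._arr = self.counts[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64)
        self._const = _ll_constant(self.counts)

    @classmethod
    def from_tsv(cls, path, label: str = "all") -> "MKAlphaModel":
        return cls(pd.read_csv(path, sep="\t"), label=label)

    # -- likelihood ---------------------------------------------------------

    def profile_loglike(self, alpha, f):
        """Profile log-likelihood at (alpha, f), nuisances at their MLEs."""
        spn, sps, sdn, sds = self._arr.sum(axis=0)
        return _profile_ll_sums(alpha, f, spn, sps, sdn, sds) + self._const

    # -- fitting ------------------------------------------------------------

    def fit(self, tol: float = 1e-8, fix_f: float | None = None) -> MKAlphaResults:
        """Maximise the profile likelihood over (alpha, f).

        Coarse grid scan, closed-form candidate, then Nelder-Mead polish;
        ties within ``tol`` of the maximum are broken toward smaller |alpha|.
        ``fix_f`` pins the constraint parameter (used for diagnostics such
        as the single-gene equivalence with the pooled estimator).
        """
        spn, sps, sdn, sds = (int(x) for x in self._arr.sum(axis=0))
        alpha, f, ll, converged = _fit_sums(
            spn, sps, sdn, sds, tol=tol, fix_f=fix_f,
            alpha_grid=self.ALPHA_GRID, f_grid=self.F_GRID,
        )
        return MKAlphaResults(
            class_label=self.label,
            alpha_hat=alpha,
            f_hat=f,
            log_likelihood=ll + self._const,
            n_genes=len(self.counts),
            n_dropped_allzero=self.n_dropped_allzero,
            converged=converged,
        )

    def bootstrap(self, B: int = 1000, seed: int | None = None,
                  keep_draws: bool = True) -> MKAlphaResults:
        """Gene-resampling percentile bootstrap for alpha.

        Resamples genes with replacement ``B`` times and refits each
        replicate (closed-form profile optimum).  Degenerate replicates
        (no divergence counts or no polymorphism counts) are dropped and
        counted; a warning is attached when more than 5% drop.
        """
        if B < 100:
            raise ValueError("bootstrap requires B >= 100")
        res = self.fit()
        rng = np.random.default_rng(seed)
        draws = _bootstrap_draws(self._arr, B, rng)
        n_dropped = B - draws.size
        if draws.size == 0:
            warnings.warn("all bootstrap replicates degenerate; CI unavailable")
            return res
        if n_dropped > 0.05 * B:
            warnings.warn(
                f"{n_dropped}/{B} bootstrap replicates dropped as degenerate"
            )
        lo, hi = np.percentile(draws, [2.5, 97.5])
        res.ci_low, res.ci_high = float(lo), float(hi)
        res.n_bootstrap = B
        res.n_bootstrap_dropped = n_dropped
        res.seed = seed
        if keep_draws:
            res.bootstrap_draws = draws
        return res


def _fit_sums(spn, sps, sdn, sds, tol=1e-8, fix_f=None,
              alpha_grid=MKAlphaModel.ALPHA_GRID, f_grid=MKAlphaModel.F_GRID):
    """Grid + closed form + Nelder-Mead on the collapsed profile likelihood."""
    def ll(a, f):
        return _profile_ll_sums(a, f, spn, sps, sdn, sds)

    if fix_f is not None:
        f_candidates = np.array([fix_f])
    else:
        f_candidates = f_grid
    aa, ff = np.meshgrid(alpha_grid, f_candidates, indexing="ij")
    grid_ll = _profile_ll_sums(aa, ff, spn, sps, sdn, sds)
    best_flat = np.flatnonzero(grid_ll.ravel() >= grid_ll.max() - tol)
    # tie-break toward smaller |alpha|
    best_idx = best_flat[np.argmin(np.abs(aa.ravel()[best_flat]))]
    a0, f0 = aa.ravel()[best_idx], ff.ravel()[best_idx]
    best = (float(a0), float(f0), float(grid_ll.ravel()[best_idx]))

    if fix_f is None:
        a_cf, f_cf, ok = _closed_form_sums(spn, sps, sdn, sds)
        if ok:
            ll_cf = ll(a_cf, f_cf)
            if ll_cf > best[2] + tol or (
                ll_cf >= best[2] - tol and abs(a_cf) < abs(best[0])
            ):
                best = (a_cf, f_cf, ll_cf)

    # local polish (Nelder-Mead with the admissible region enforced by -inf)
    converged = True
    if fix_f is None:
        x0 = np.array([best[0], best[1]])
        opt = optimize.minimize(
            lambda x: -ll(x[0], x[1]), x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol, "maxiter": 400},
        )
        if np.isfinite(opt.fun) and -opt.fun > best[2] + tol:
            best = (float(opt.x[0]), float(min(1.0, max(_F_MIN, opt.x[1]))),
                    float(-opt.fun))
        converged = bool(opt.success or -opt.fun <= best[2] + tol)
    else:
        opt = optimize.minimize_scalar(
            lambda a: -ll(a, fix_f),
            bounds=(_ALPHA_MIN, _ALPHA_MAX), method="bounded",
        )
        if np.isfinite(opt.fun) and -opt.fun > best[2] + tol:
            best = (float(opt.x), float(fix_f), float(-opt.fun))
    return best[0], best[1], best[2], converged


def _bootstrap_draws(arr: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """Alpha estimates over B gene-resampling replicates (degenerate dropped)."""
    n = arr.shape[0]
    out = np.empty(B)
    k = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        spn, sps, sdn, sds = arr[idx].sum(axis=0)
        alpha, _f, ok = _closed_form_sums(int(spn), int(sps), int(sdn), int(sds))
        if ok:
            out[k] = alpha
            k += 1
    return out[:k]


# ---------------------------------------------------------------------------
# functional wrappers and class comparison
# ---------------------------------------------------------------------------

def ml_alpha(genes, label: str = "all") -> MKAlphaResults:
    """ML estimate of (alpha, f) for a set of genes; CI fields left empty."""
    return MKAlphaModel(genes, label=label).fit()


def bootstrap_alpha(genes, B: int = 1000, seed: int | None = None,
                    label: str = "all") -> MKAlphaResults:
    """ML estimate plus gene-resampling percentile 95% CI."""
    return MKAlphaModel(genes, label=label).bootstrap(B=B, seed=seed)


@dataclass
class ClassComparison:
    """Bootstrap comparison of alpha between two gene classes."""

    label_a: str
    label_b: str
    alpha_a: float
    alpha_b: float
    delta_hat: float
    bootstrap_p: float
    n_bootstrap: int
    seed: int | None
    delta_draws: np.ndarray | None = field(default=None, repr=False)


def compare_classes(genes_a, genes_b=None, B: int = 1000,
                    seed: int | None = None, label_a: str = "a",
                    label_b: str = "b", keep_draws: bool = False) -> ClassComparison:
    """Two-tailed bootstrap test of alpha_a - alpha_b.

    Each replicate independently resamples genes within each class and
    re-estimates alpha; the two-tailed p-value is
    ``2 * min(frac(delta <= 0), frac(delta >= 0))`` capped at 1.  Passing
    ``genes_b=None`` (or an empty table) compares alpha_a against zero.
    """
    if B < 100:
        raise ValueError("bootstrap requires B >= 100")
    rng = np.random.default_rng(seed)
    model_a = MKAlphaModel(genes_a, label=label_a)
    alpha_a = model_a.fit().alpha_hat
    have_b = genes_b is not None and len(_as_frame(genes_b)) > 0
    if have_b:
        model_b = MKAlphaModel(genes_b, label=label_b)
        alpha_b = model_b.fit().alpha_hat
    else:
        alpha_b = 0.0
    draws_a = _bootstrap_draws(model_a._arr, B, rng)
    draws_b = _bootstrap_draws(model_b._arr, B, rng) if have_b else np.zeros(B)
    m = min(draws_a.size, draws_b.size)
    if m == 0:
        raise UndefinedEstimateError("all bootstrap replicates degenerate")
    delta = draws_a[:m] - draws_b[:m]
    p = 2.0 * min(np.mean(delta <= 0.0), np.mean(delta >= 0.0))
    return ClassComparison(
        label_a=label_a, label_b=label_b, alpha_a=alpha_a, alpha_b=alpha_b,
        delta_hat=alpha_a - alpha_b, bootstrap_p=float(min(1.0, p)),
        n_bootstrap=m, seed=seed,
        delta_draws=delta if keep_draws else None,
    )
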