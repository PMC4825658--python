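"""Negative-binomial differential-abundance testing and phenotype calls.

Each sorted pool is compared against the presorted library with a
conditioned NB exact test on per-gene group totals: samples are put on a
common scale with median-of-ratios size factors, per-gene overdispersion is
estimated by method of moments across replicate groups and stabilized with
a fitted mean-dispersion trend, and the two-sided p-value sums the
probabilities of all splits of the observed total that are no more likely
than the observed split.  Genes significantly enriched in characteristic
pool combinations are classified into reporter phenotype classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

POOL_GFP_NEG_UN = "Un_Gfp_neg"
POOL_GFP_PLUS_UN = "Un_Gfp_plus"
POOL_GFP_NEG_IN = "In_Gfp_neg"
POOL_BASAL_IN = "In_Gfp_basal"
POOL_PLUSPLUS_IN = "In_Gfp_plusplus"


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(
    counts: pd.DataFrame, method: str = "median-of-ratios"
) -> pd.Series:
    """Median-of-ratios size factors.

    ``s_j = median_g k_gj / (prod_j k_gj)^(1/m)`` over genes whose
    geometric mean is positive (i.e. genes with no zero count).  If no gene
    is positive in every sample, the strict estimator is undefined: an
    error points at the ``"positive"`` fallback, which uses per-gene
    geometric means over positive counts only, restricted to genes present
    in at least half the samples.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValueError("empty count table")
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    if method == "median-of-ratios":
        all_pos = (mat > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every sample; strict "
                "median-of-ratios is undefined — rerun with method='positive'"
            )
        loggeo = logmat[all_pos].mean(axis=1)
        logratios = logmat[all_pos] - loggeo[:, None]
    elif method == "positive":
        present = mat > 0
        keep = present.sum(axis=1) >= mat.shape[1] / 2
        if not keep.any():
            raise ValueError("no gene present in at least half the samples")
        loggeo = np.array([
            logmat[g, present[g]].mean() for g in np.flatnonzero(keep)
        ])
        logratios = np.where(
            present[keep], logmat[keep] - loggeo[:, None], np.nan
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmedian(np.exp(logratios), axis=0)
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise ValueError("size factor estimation produced non-positive factors")
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionModel:
    """Per-gene raw, trend and working NB dispersions.

    working = max(raw, trend, floor); raw is NaN where no replicate group
    supports a method-of-moments estimate.  The trend is the parametric
    curve ``alpha(mu) = a0 + a1 / mu`` fitted to positive raw estimates.
    """

    raw: pd.Series
    trend: pd.Series
    working: pd.Series
    coefficients: tuple[float, float]
    mode: str  # "pooled" or "trend-only"
    floor: float = 1e-8

    def for_genes(self, genes) -> np.ndarray:
        return self.working.reindex(genes).to_numpy()


def _fit_trend(mean: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Parametric dispersion trend alpha(mu) = a0 + a1/mu.

    Gamma-family GLM with identity link on the positive raw estimates,
    iterated with exclusion of extreme outliers (ratio to the current
    curve outside [1e-4, 15]), as in the classic parametric fit for count
    data.  Falls back to ordinary least squares if the GLM fails.
    """
    import statsmodels.api as sm  # heavy import, keep local

    x = 1.0 / mean
    X = np.column_stack([np.ones_like(x), x])
    keep = np.ones(len(x), dtype=bool)
    a0, a1 = float(np.median(alpha)), 0.0
    for _ in range(10):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # identity-link domain warning
                model = sm.GLM(alpha[keep], X[keep],
                               family=sm.families.Gamma(sm.families.links.Identity()))
                fit = model.fit(start_params=[max(a0, 1e-6), max(a1, 1e-6)])
            a0_new, a1_new = float(fit.params[0]), float(fit.params[1])
        except Exception:  # noqa: BLE001 - singular fits fall back to OLS
            coef, *_ = np.linalg.lstsq(X[keep], alpha[keep], rcond=None)
            a0_new, a1_new = float(coef[0]), float(coef[1])
        a0_new, a1_new = max(a0_new, 0.0), max(a1_new, 0.0)
        pred = np.clip(a0_new + a1_new * x, 1e-12, None)
        new_keep = (alpha / pred > 1e-4) & (alpha / pred < 15.0)
        converged = (abs(a0_new - a0) < 1e-8 * max(a0, 1e-8)
                     and np.array_equal(new_keep, keep))
        a0, a1, keep = a0_new, a1_new, new_keep
        if converged or keep.sum() < 5:
            break
    return a0, a1


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: list[list[str]],
    floor: float = 1e-8,
) -> DispersionModel:
    """Method-of-moments dispersions pooled across replicate groups, with trend.

    Common-scale counts ``q = k/s`` are formed per sample; within each
    group of >= 2 replicates the per-gene sample variance and mean give
    ``alpha = (s^2 - z) / mean^2`` where ``z = mean * avg(1/s_j)`` is the
    shot-noise term (equal to the mean when all size factors are 1).
    Variances are pooled across groups by degrees of freedom.  Groups with
    a single sample contribute nothing; if no group has replicates the
    model falls back to trend-only mode only when another source of raw
    estimates exists, otherwise it raises.
    """
    q = counts.div(size_factors, axis=1)
    rep_groups = [g for g in groups if len(g) >= 2]
    if not rep_groups:
        raise ValueError(
            "no replicate group with >= 2 samples: dispersion cannot be "
            "estimated; supply a DispersionModel explicitly"
        )
    if len(rep_groups) < len(groups):
        logger.warning(
            "dispersion: %d group(s) have a single sample and are excluded "
            "from estimation (trend/pooled values will be used for their test)",
            len(groups) - len(rep_groups),
        )
    num = np.zeros(len(counts))
    dof = 0
    means = []
    inv_s = []
    for g in rep_groups:
        sub = q[g]
        var = sub.var(axis=1, ddof=1).to_numpy()
        num += var * (len(g) - 1)
        dof += len(g) - 1
        means.append(sub.mean(axis=1).to_numpy())
        inv_s.append((1.0 / size_factors[g]).mean())
    pooled_var = num / dof
    base_mean = np.mean(means, axis=0)
    z = base_mean * np.mean(inv_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_mom = (pooled_var - z) / base_mean**2
    raw_mom = np.where(base_mean > 0, raw_mom, np.nan)
    raw = np.clip(raw_mom, 0, None)  # alpha-hat = max(0, (s^2 - z)/mu^2)
    raw_clipped = raw

    usable = np.isfinite(raw_mom) & (base_mean > 0) & (raw_mom > 0)
    if usable.sum() >= 10:
        a0, a1 = _fit_trend(base_mean[usable], raw_mom[usable])
    else:
        med = float(np.nanmedian(raw_clipped)) if np.isfinite(
            np.nanmedian(raw_clipped)) else 0.0
        a0, a1 = max(med, 0.0), 0.0
        logger.warning("dispersion trend: too few usable genes; flat trend %.4g", a0)
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a0 + a1 / base_mean, a0)
    working = np.fmax(np.fmax(raw_clipped, trend), floor)
    working = np.where(np.isnan(working), np.fmax(trend, floor), working)
    idx = counts.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="raw"),
        trend=pd.Series(trend, index=idx, name="trend"),
        working=pd.Series(working, index=idx, name="working"),
        coefficients=(a0, a1),
        mode="pooled",
        floor=floor,
    )


# ---------------------------------------------------------------------------
# the exact test


def _nb_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of NB (or Poisson when var <= mu) with given mean/variance."""
    x = np.asarray(x, dtype=float)
    if mu <= 0:
        out = np.full_like(x, -np.inf)
        out[x == 0] = 0.0
        return out
    if var <= mu * (1 + 1e-12):  # Poisson limit
        return x * np.log(mu) - mu - gammaln(x + 1)
    # size r = mu^2/(var-mu), success prob p = r/(r+mu)
    r = mu * mu / (var - mu)
    logp = np.log(r) - np.log(r + mu)
    log1mp = np.log(mu) - np.log(r + mu)
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1) + r * logp + x * log1mp


def nb_test(
    k_a: np.ndarray | list[int],
    k_b: np.ndarray | list[int],
    sf_a: np.ndarray | list[float],
    sf_b: np.ndarray | list[float],
    dispersion: float,
) -> float:
    """Conditioned two-sided NB exact test of group A counts vs group B.

    With observed totals ``K_A`` and ``K_B`` (``K_S = K_A + K_B``) and the
    common-scale abundance estimate ``q = K_S / (sum sf_A + sum sf_B)``,
    each group total is modelled as NB with mean ``q * sum(sf)`` and
    variance ``q * sum(sf) + dispersion * q^2 * sum(sf^2)``.  The p-value
    sums, over all splits ``a + b = K_S``, the joint probabilities no
    larger than the observed one, normalized by the total over all splits.
    Exchanging the groups (with their size factors) gives the same p.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    k_a = np.asarray(k_a, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    if (k_a < 0).any() or (k_b < 0).any():
        raise ValueError("counts must be >= 0")
    K_A, K_B = float(k_a.sum()), float(k_b.sum())
    K_S = K_A + K_B
    if K_S == 0:
        return 1.0
    s_a, s_b = float(sf_a.sum()), float(sf_b.sum())
    q = K_S / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    var_a = mu_a + dispersion * q * q * float((sf_a**2).sum())
    var_b = mu_b + dispersion * q * q * float((sf_b**2).sum())
    a = np.arange(int(K_S) + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(K_S - a, mu_b, var_b)
    log_obs = _nb_logpmf(np.array([K_A]), mu_a, var_a)[0] + _nb_logpmf(
        np.array([K_B]), mu_b, var_b
    )[0]
    keep = logp <= log_obs + 1e-8  # tolerance against float ties
    p = np.exp(logsumexp(logp[keep]) - logsumexp(logp))
    # p is at least the observed split's own probability; floor it above 0
    # so extreme splits survive downstream (0,1] validation
    return float(min(max(p, np.exp(log_obs - logsumexp(logp)), 1e-300), 1.0))


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# per-pool testing and ranking


@dataclass(frozen=True)
class EnrichmentParams:
    pseudocount: float = 0.5  # common-scale, display-only (log2FC)
    dispersion_floor: float = 1e-8
    size_factor_method: str = "median-of-ratios"


RESULT_COLUMNS = ["baseMean", "log2FC", "pvalue", "padj", "rank"]


def test_enrichment(
    counts: pd.DataFrame,
    pool_samples: list[str],
    presorted_samples: list[str],
    params: EnrichmentParams = EnrichmentParams(),
    size_factors: pd.Series | None = None,
    dispersions: DispersionModel | None = None,
    genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene enrichment of a sorted pool versus the presorted library.

    Returns a DataFrame indexed by gene with ``baseMean`` (mean common-scale
    count), ``log2FC`` (pseudocount-stabilized pool/presorted ratio),
    ``pvalue``, BH-adjusted ``padj`` and a deterministic ``rank`` ordered by
    (padj, p, |log2FC| descending, gene name).  ``genes`` restricts testing
    to a pre-filtered universe (e.g. the minimum-read set).
    """
    if not pool_samples or not presorted_samples:
        raise ValueError("both design groups must be non-empty")
    design = list(pool_samples) + list(presorted_samples)
    missing = [s for s in design if s not in counts.columns]
    if missing:
        raise KeyError(f"samples missing from count table: {missing}")
    sub = counts[design]
    if genes is not None:
        sub = sub.loc[sub.index.isin(genes)]
    if sub.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS, index=pd.Index([], name="gene"))
    if size_factors is None:
        size_factors = estimate_size_factors(sub, method=params.size_factor_method)
    if dispersions is None:
        dispersions = estimate_dispersions(
            sub, size_factors, [list(pool_samples), list(presorted_samples)],
            floor=params.dispersion_floor,
        )
    q = sub.div(size_factors, axis=1)
    mean_pool = q[pool_samples].mean(axis=1)
    mean_pre = q[presorted_samples].mean(axis=1)
    c = params.pseudocount
    log2fc = np.log2((mean_pool + c) / (mean_pre + c))
    base_mean = q.mean(axis=1)
    alpha = dispersions.for_genes(sub.index)
    sf_a = size_factors[pool_samples].to_numpy()
    sf_b = size_factors[presorted_samples].to_numpy()
    ka = sub[pool_samples].to_numpy()
    kb = sub[presorted_samples].to_numpy()
    pvals = np.array([
        nb_test(ka[i], kb[i], sf_a, sf_b, float(alpha[i]))
        for i in range(len(sub))
    ])
    padj = benjamini_hochberg(pvals)
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvals,
            "padj": padj,
        },
        index=sub.index.rename("gene"),
    )
    order = res.reset_index().sort_values(
        by=["padj", "pvalue", "log2FC", "gene"],
        ascending=[True, True, False, True],
        key=lambda col: col.abs() if col.name == "log2FC" else col,
    )["gene"]
    res.loc[order, "rank"] = np.arange(1, len(res) + 1)
    res["rank"] = res["rank"].astype(int)
    return res


# ---------------------------------------------------------------------------
# phenotype classification


@dataclass(frozen=True)
class ClassifyThresholds:
    padj_max: float = 0.05
    lfc_min: float = 1.0


REQUIRED_POOLS = (
    POOL_GFP_NEG_UN, POOL_GFP_PLUS_UN, POOL_GFP_NEG_IN, POOL_BASAL_IN, POOL_PLUSPLUS_IN
)


def classify_phenotypes(
    results: dict[str, pd.DataFrame],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> pd.Series:
    """Call a phenotype class per gene from per-pool enrichment patterns.

    Significant positive enrichment (padj <= padj_max and log2FC >= lfc_min)
    in both dark-reporter pools calls a pathway-null (GFP_NEG); in the
    induced-basal pool a NON_INDUCER; in the uninduced-high pool a
    HIGH_BASAL (with or without the super-induced pool); in the
    super-induced pool alone a HYPER_INDUCER.  Overlapping patterns resolve
    in that priority order; anything else is unclassified.
    """
    missing = [p for p in REQUIRED_POOLS if p not in results]
    if missing:
        raise KeyError(f"missing pools in results: {missing}")
    genes: pd.Index | None = None
    sig: dict[str, pd.Series] = {}
    for pool in REQUIRED_POOLS:
        df = results[pool]
        if genes is None:
            genes = df.index
        elif set(genes) != set(df.index):  # order may differ (rank-sorted files)
            raise ValueError(f"gene universe differs in pool {pool!r}")
        sig[pool] = ((df["padj"] <= thresholds.padj_max) & (
            df["log2FC"] >= thresholds.lfc_min
        )).reindex(genes)
    calls = pd.Series("unclassified", index=genes, name="phenotype_call")
    calls[sig[POOL_PLUSPLUS_IN]] = "HYPER_INDUCER"
    calls[sig[POOL_GFP_PLUS_UN]] = "HIGH_BASAL"
    calls[sig[POOL_BASAL_IN]] = "NON_INDUCER"
    calls[sig[POOL_GFP_NEG_UN] & sig[POOL_GFP_NEG_IN]] = "GFP_NEG"
    return calls
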