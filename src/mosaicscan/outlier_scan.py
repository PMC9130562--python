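"""Gene-centric outlier detection and inference.

Each statistic is regressed on the mean recombination rate per gene
(ordinary least squares); genes are flagged as outliers when their
Cook's distance exceeds k * mean(Cook's distance) AND their residual
lies on the configured side of the fitted value. dN/dS uses an upper
empirical-quantile rule instead. Candidate-gene enrichment is a 2x2
Pearson chi-square, and candidate-vs-background contrasts use label
permutation of the per-gene statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from mosaicscan.errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

#: residual side that makes a gene interesting, per statistic
DEFAULT_DIRECTIONS = {
    "pi": "below",
    "fst_P3_P1": "above",
    "fst_P3_P2": "above",
    "dxy_P3_P1": "above",
    "dxy_P3_P2": "above",
    "fdm": "both",
}

#: permutation tail per statistic
DEFAULT_TAILS = {
    "pi": "lower",
    "omega": "upper",
    "fst_P3_P1": "two-sided",
    "fst_P3_P2": "two-sided",
    "dxy_P3_P1": "two-sided",
    "dxy_P3_P2": "two-sided",
    "fdm": "two-sided",
}


@dataclass
class RegressionFit:
    statistic: str
    gene_ids: list[str]
    slope: float
    intercept: float
    fitted: np.ndarray
    residual: np.ndarray
    leverage: np.ndarray
    cooksd: np.ndarray
    s2: float
    n: int
    r2: float = 0.0
    slope_p: float = 1.0


@dataclass
class OutlierCall:
    gene_id: str
    statistic: str
    is_outlier: bool
    direction: str  # 'above' | 'below' (residual side)
    rule: str  # 'cooksd' | 'quantile'
    value: float
    fitted: float | None = None
    cooksd: float | None = None


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    replicates: np.ndarray
    n_perm: int
    tail: str
    p_value: float
    p_value_add_one: float
    n_candidate: int = 0
    n_background: int = 0


def _clean_pairs(gene_ids, values, rates):
    gene_ids = list(gene_ids)
    values = np.asarray(values, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if not (len(gene_ids) == len(values) == len(rates)):
        raise ValidationError("gene_ids / values / rates length mismatch")
    keep = np.isfinite(values) & np.isfinite(rates)
    return [g for g, k in zip(gene_ids, keep) if k], values[keep], rates[keep]


def fit_rate_regression(
    gene_ids: Sequence[str],
    values: Sequence[float],
    rates: Sequence[float],
    statistic: str = "stat",
) -> RegressionFit:
    """OLS of a per-gene statistic on recombination rate, with leverage
    and Cook's distance per gene (p = 2 parameters)."""
    gene_ids, y, x = _clean_pairs(gene_ids, values, rates)
    n = len(y)
    if n < 3:
        raise ValidationError(f"{statistic}: need >= 3 complete (value, rate) pairs")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValidationError(f"{statistic}: zero rate variance, regression undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted
    rss = float((resid**2).sum())
    dof = n - 2
    s2 = rss / dof if dof > 0 else np.nan
    lev = 1.0 / n + (x - x.mean()) ** 2 / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        cooks = np.where(
            (s2 > 0) & (lev < 1),
            resid**2 * lev / (2 * s2 * (1 - lev) ** 2),
            0.0,
        )
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else 0.0
    if dof > 0 and s2 > 0:
        se = np.sqrt(s2 / sxx)
        slope_p = float(2 * sps.t.sf(abs(slope) / se, dof))
    else:
        slope_p = 1.0
    return RegressionFit(
        statistic=statistic,
        gene_ids=gene_ids,
        slope=slope,
        intercept=intercept,
        fitted=fitted,
        residual=resid,
        leverage=lev,
        cooksd=cooks,
        s2=s2,
        n=n,
        r2=r2,
        slope_p=slope_p,
    )


def call_cooksd_outliers(
    fit: RegressionFit,
    direction: str | None = None,
    k: float = 3.0,
    require_direction: bool = True,
) -> list[OutlierCall]:
    """Flag genes with cooksd > k * mean(cooksd) on the configured
    residual side ('above', 'below', or 'both').

    ``require_direction=False`` drops the residual-side condition.
    """
    if direction is None:
        direction = DEFAULT_DIRECTIONS.get(fit.statistic)
        if direction is None:
            raise ConfigurationError(
                f"no outlier direction configured for {fit.statistic!r}"
            )
    if direction not in ("above", "below", "both"):
        raise ConfigurationError(f"bad direction {direction!r}")
    thresh = k * float(fit.cooksd.mean())
    calls = []
    for i, gid in enumerate(fit.gene_ids):
        side = "above" if fit.residual[i] > 0 else "below"
        hit = fit.cooksd[i] > thresh
        if require_direction and direction != "both" and side != direction:
            hit = False
        calls.append(
            OutlierCall(
                gene_id=gid,
                statistic=fit.statistic,
                is_outlier=bool(hit),
                direction=side,
                rule="cooksd",
                value=float(fit.fitted[i] + fit.residual[i]),
                fitted=float(fit.fitted[i]),
                cooksd=float(fit.cooksd[i]),
            )
        )
    return calls


def call_quantile_outliers(
    gene_ids: Sequence[str],
    omega: Sequence[float],
    q: float = 0.05,
    statistic: str = "omega",
) -> list[OutlierCall]:
    """Flag genes at or above the empirical (1-q) quantile (ties included)."""
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    gene_ids = list(gene_ids)
    vals = np.asarray(omega, dtype=float)
    keep = np.isfinite(vals)
    gene_ids = [g for g, kk in zip(gene_ids, keep) if kk]
    vals = vals[keep]
    if len(vals) < 1 / q:
        raise ValidationError(
            f"need >= {int(np.ceil(1 / q))} genes for the {q:.0%} rule, got {len(vals)}"
        )
    cutoff = float(np.quantile(vals, 1 - q))
    return [
        OutlierCall(
            gene_id=g,
            statistic=statistic,
            is_outlier=bool(v >= cutoff),
            direction="above",
            rule="quantile",
            value=float(v),
        )
        for g, v in zip(gene_ids, vals)
    ]


def enrichment_chisq(
    outlier_flags: Sequence[bool],
    candidate_flags: Sequence[bool],
    correction: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Pearson chi-square on the 2x2 candidate x outlier table.

    Returns (statistic, p, observed table). Raises on zero margins;
    warns via logging when an expected count is below 5.
    """
    o = np.asarray(outlier_flags, dtype=bool)
    c = np.asarray(candidate_flags, dtype=bool)
    if len(o) != len(c):
        raise ValidationError("flag vectors length mismatch")
    table = np.array(
        [
            [np.sum(c & o), np.sum(c & ~o)],
            [np.sum(~c & o), np.sum(~c & ~o)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError(
            f"degenerate 2x2 table (zero margin): {table.tolist()}"
        )
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        log.warning("chi-square expected count below 5: %s", expected.tolist())
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue), table


def permutation_mean_diff(
    values: Sequence[float],
    candidate_flags: Sequence[bool],
    n_perm: int = 100,
    tail: str = "two-sided",
    seed: int = 0,
) -> PermutationResult:
    """Observed candidate-minus-background mean difference and its
    label-permutation distribution.

    The reported p is the raw fraction of replicates as or more extreme
    under the tail (may be exactly 0); the (k+1)/(n+1) estimator is
    reported alongside.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(candidate_flags, dtype=bool)
    if len(v) != len(c):
        raise ValidationError("values / flags length mismatch")
    keep = np.isfinite(v)
    v, c = v[keep], c[keep]
    if not c.any():
        raise ValidationError("empty candidate set")
    if c.all():
        raise ValidationError("empty background set")
    if tail not in ("lower", "upper", "two-sided"):
        raise ValidationError(f"bad tail {tail!r}")
    nc = int(c.sum())
    obs = float(v[c].mean() - v[~c].mean())
    rng = np.random.default_rng(seed)
    reps = np.empty(n_perm)
    total = v.sum()
    n = len(v)
    for r in range(n_perm):
        pick = rng.choice(n, size=nc, replace=False)
        m_c = v[pick].mean()
        reps[r] = m_c - (total - v[pick].sum()) / (n - nc)
    if tail == "lower":
        k = int(np.sum(reps <= obs))
    elif tail == "upper":
        k = int(np.sum(reps >= obs))
    else:
        k = int(np.sum(np.abs(reps) >= abs(obs)))
    return PermutationResult(
        statistic="",
        observed=obs,
        replicates=reps,
        n_perm=n_perm,
        tail=tail,
        p_value=k / n_perm,
        p_value_add_one=(k + 1) / (n_perm + 1),
        n_candidate=nc,
        n_background=n - nc,
    )


def male_female_contrast(
    values: Mapping[str, float],
    male_set: Sequence[str],
    female_set: Sequence[str],
    n_perm: int = 100,
    seed: int = 0,
    drop_shared: bool = False,
) -> PermutationResult:
    """Two-sided permutation contrast of male-set vs female-set means.

    Genes present in both sets are kept in both by default; with
    ``drop_shared`` they are removed from both. Genes missing a value
    are removed set-wise.
    """
    male = [g for g in male_set if g in values and np.isfinite(values[g])]
    female = [g for g in female_set if g in values and np.isfinite(values[g])]
    if drop_shared:
        shared = set(male) & set(female)
        male = [g for g in male if g not in shared]
        female = [g for g in female if g not in shared]
    if not male or not female:
        raise ValidationError("empty male or female set after filtering")
    vm = np.array([values[g] for g in male])
    vf = np.array([values[g] for g in female])
    obs = float(vm.mean() - vf.mean())
    pooled = np.concatenate([vm, vf])
    nm = len(vm)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(pooled)
        reps[r] = perm[:nm].mean() - perm[nm:].mean()
    k = int(np.sum(np.abs(reps) >= abs(obs)))
    return PermutationResult(
        statistic="",
        observed=obs,
        replicates=reps,
        n_perm=n_perm,
        tail="two-sided",
        p_value=k / n_perm,
        p_value_add_one=(k + 1) / (n_perm + 1),
        n_candidate=nm,
        n_background=len(vf),
    )
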