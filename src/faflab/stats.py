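"""Genotype-association statistics.

Covers the inference battery of a frequency-altered-feedback genotype
study: a Hardy-Weinberg equilibrium chi-square on genotype counts, mixed
(split-plot) repeated-measures ANOVAs with Greenhouse-Geisser sphericity
correction and partial eta-squared, Bonferroni-adjusted pairwise post hoc
comparisons, Pearson correlations, and a contingency chi-square for
demographic checks.

The split-plot ANOVA decomposes each subject's within-cell profile onto
orthonormal within-subject contrasts: for every within-effect stratum the
contrast scores are submitted to a one-way between-group analysis whose
residuals supply both the error term and the covariance from which the
Greenhouse-Geisser epsilon is estimated. Between-group (Type III) sums of
squares handle the unbalanced genotype groups; with a two-level within
factor the correction factor is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeCounts",
    "CorrelationResult",
    "hwe_chisq",
    "mixed_rm_anova",
    "bonferroni_pairwise",
    "pearson_correlation",
    "contingency_chisq",
    "replicate_study_analyses",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed counts of the three biallelic genotypes."""

    n_AA: int
    n_AG: int
    n_GG: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AG, self.n_GG) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_AA + self.n_AG + self.n_GG == 0:
            raise ValueError("total genotype count must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    degenerate: bool = False


def hwe_chisq(counts: GenotypeCounts) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (df = 1).

    The allele frequency p = (2 n_AA + n_AG) / 2n is estimated from the
    sample; expected genotype counts are (n p^2, 2 n p q, n q^2). One
    degree of freedom remains (three classes, one estimated frequency,
    one total constraint).
    """
    n = counts.n_AA + counts.n_AG + counts.n_GG
    p = (2 * counts.n_AA + counts.n_AG) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_AA, counts.n_AG, counts.n_GG], dtype=float)
    if np.any(expected == 0):
        # monomorphic sample: observed equals expected by construction
        nz = expected > 0
        chi2 = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    else:
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(t: int) -> np.ndarray:
    """t x (t-1) orthonormal contrast matrix (Helmert-style), plus unit."""
    h = np.zeros((t, t - 1))
    for j in range(1, t):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
    return h / np.linalg.norm(h, axis=0, keepdims=True)


def _unit(t: int) -> np.ndarray:
    return np.full((t, 1), 1.0 / np.sqrt(t))


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    between: str,
    subject: str,
) -> pd.DataFrame:
    """Split-plot ANOVA: within-subject factor(s) crossed with one
    between-subjects factor, subjects nested in groups.

    ``data`` is long-format with one row per subject x within-cell. The
    within design must be complete per subject (one observation per cell);
    group sizes may differ (Type III between-group sums of squares).

    Returns one row per effect with columns ``effect, ss_effect, ss_error,
    df1, df2, F, p_unc, eps_gg, p_gg, partial_eta_sq``. ``p_gg`` applies
    the Greenhouse-Geisser correction (identical to ``p_unc`` when the
    stratum has a single contrast, e.g. a two-level within factor).
    """
    within = [within] if isinstance(within, str) else list(within)
    cols = [subject, between, dv, *within]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    df = data[cols].copy()
    if df[dv].isna().any():
        raise ValueError("dependent variable contains missing values")

    levels = {w: sorted(df[w].unique().tolist()) for w in within}
    cells = pd.MultiIndex.from_product([levels[w] for w in within], names=within)
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if len(within) == 1:
        wide.columns = pd.MultiIndex.from_arrays([wide.columns], names=within)
    counts = df.groupby(subject, observed=True)[dv].size()
    expected_cells = len(cells)
    offenders = sorted(counts.index[counts != expected_cells].tolist()
                       + wide.index[wide.isna().any(axis=1)].tolist())
    if offenders:
        raise ValueError(f"incomplete within-design for subjects: {offenders}")
    wide = wide.reindex(columns=cells)

    grp_map = df.groupby(subject, observed=True)[between].agg(lambda s: s.unique())
    if any(np.size(g) != 1 for g in grp_map):
        raise ValueError("each subject must have exactly one between-group level")
    groups = np.array([np.atleast_1d(grp_map.loc[s])[0] for s in wide.index])
    glevels = sorted(pd.unique(groups).tolist())
    G = len(glevels)
    gsizes = np.array([(groups == g).sum() for g in glevels])
    if np.any(gsizes < 2):
        raise ValueError("each between-group level needs at least 2 subjects")
    gidx = [np.where(groups == g)[0] for g in glevels]

    Y = wide.to_numpy(dtype=float)
    n = Y.shape[0]
    tlev = [len(levels[w]) for w in within]

    # map each subject to its group row index
    g_of_subj = np.array([glevels.index(g) for g in groups])

    rows = []

    # between-subjects stratum: scores on the unit contrast
    u_all = _unit(tlev[0])
    for t in tlev[1:]:
        u_all = np.kron(u_all, _unit(t))
    b = (Y @ u_all).ravel()
    m_g = np.array([b[ix].mean() for ix in gidx])
    grand_w = float(np.sum(gsizes * m_g) / n)
    ss_between = float(np.sum(gsizes * (m_g - grand_w) ** 2))
    ss_err_b = float(sum(np.sum((b[ix] - m_g[i]) ** 2) for i, ix in enumerate(gidx)))
    df1, df2 = G - 1, n - G
    F = (ss_between / df1) / (ss_err_b / df2) if ss_err_b > 0 else np.inf
    rows.append(dict(effect=between, ss_effect=ss_between, ss_error=ss_err_b,
                     df1=df1, df2=df2, F=F, p_unc=float(sps.f.sf(F, df1, df2)),
                     eps_gg=1.0, p_gg=float(sps.f.sf(F, df1, df2)),
                     partial_eta_sq=ss_between / (ss_between + ss_err_b)
                     if ss_between + ss_err_b > 0 else 0.0))

    # within strata: every non-empty subset of within factors
    for S_fac in chain.from_iterable(combinations(range(len(within)), k)
                                     for k in range(1, len(within) + 1)):
        M = np.ones((1, 1))
        for i, t in enumerate(tlev):
            M = np.kron(M, _orthonormal_contrasts(t) if i in S_fac else _unit(t))
        q = M.shape[1]
        S = Y @ M                                                  # (n, q)
        m = np.vstack([S[ix].mean(axis=0) for ix in gidx])          # (G, q)
        resid = S - m[g_of_subj]
        ss_err = float(np.sum(resid**2))
        df_err = q * (n - G)

        # Greenhouse-Geisser epsilon from the pooled residual covariance
        if q > 1:
            sigma = resid.T @ resid / (n - G)
            tr = np.trace(sigma)
            eps = float(tr**2 / (q * np.sum(sigma * sigma))) if tr > 0 else 1.0
            eps = min(1.0, max(eps, 1.0 / q))
        else:
            eps = 1.0

        name = " * ".join(within[i] for i in S_fac)

        # within-effect main term: unweighted (Type III) mean across groups
        psi = m.mean(axis=0)                                       # (q,)
        h = np.sum(1.0 / gsizes) / G**2
        ss_main = float(np.sum(psi**2) / h)
        df1 = q
        F = (ss_main / df1) / (ss_err / df_err) if ss_err > 0 else np.inf
        rows.append(dict(effect=name, ss_effect=ss_main, ss_error=ss_err,
                         df1=df1, df2=df_err, F=F,
                         p_unc=float(sps.f.sf(F, df1, df_err)), eps_gg=eps,
                         p_gg=float(sps.f.sf(F, eps * df1, eps * df_err)),
                         partial_eta_sq=ss_main / (ss_main + ss_err)
                         if ss_main + ss_err > 0 else 0.0))

        # within x between interaction
        grand = (gsizes[:, None] * m).sum(axis=0) / n
        ss_int = float(np.sum(gsizes[:, None] * (m - grand) ** 2))
        df1 = q * (G - 1)
        F = (ss_int / df1) / (ss_err / df_err) if ss_err > 0 else np.inf
        rows.append(dict(effect=f"{name} * {between}", ss_effect=ss_int,
                         ss_error=ss_err, df1=df1, df2=df_err, F=F,
                         p_unc=float(sps.f.sf(F, df1, df_err)), eps_gg=eps,
                         p_gg=float(sps.f.sf(F, eps * df1, eps * df_err)),
                         partial_eta_sq=ss_int / (ss_int + ss_err)
                         if ss_int + ss_err > 0 else 0.0))

    return pd.DataFrame(rows)


def bonferroni_pairwise(
    group_values: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons with Bonferroni-adjusted p values.

    t statistics use the error term pooled over all groups (the ANOVA
    mean-square error), df = N - G; p_adj = min(1, m * p) with m the
    number of pairs.
    """
    names = list(group_values)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    vals = {k: np.asarray(v, dtype=float) for k, v in group_values.items()}
    for k, v in vals.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    N = sum(v.size for v in vals.values())
    G = len(names)
    mse = sum(np.sum((v - v.mean()) ** 2) for v in vals.values()) / (N - G)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = vals[a], vals[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(mse * (1 / va.size + 1 / vb.size))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p = float(2 * sps.t.sf(abs(t), N - G))
        rows.append(dict(group_a=a, group_b=b, mean_diff=float(diff), t=float(t),
                         df=N - G, p_unc=p, p_adj=min(1.0, m * p),
                         significant=min(1.0, m * p) < alpha))
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-based p value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), x.size, float("nan"), degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), int(x.size), float(p))


def contingency_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r x c count table
    (no continuity correction); df = (r-1)(c-1)."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0) or tab.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# full study battery
# ---------------------------------------------------------------------------

def replicate_study_analyses(
    vocal_summary: pd.DataFrame,
    erp_summary: pd.DataFrame | None,
    genotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Run the study's inference battery on pipeline summary tables.

    Expects ``vocal_summary`` with columns (subject_id, genotype,
    magnitude_cents_shift, magnitude_cents, latency_ms, baseline_sd_cents),
    optional ``erp_summary`` with (subject_id, genotype,
    magnitude_cents_shift, electrode, n1_amp_uv, n1_lat_ms, p2_amp_uv,
    p2_lat_ms), and a ``genotypes`` table with a ``genotype`` column.
    Emits HWE, the two-way vocal ANOVAs (magnitude + latency), three-way
    ERP ANOVAs, Bonferroni post hocs on the -200 cents vocal magnitudes,
    and the per-genotype correlations between compensation magnitude and
    the baseline-variability index.
    """
    if vocal_summary is None or len(vocal_summary) == 0:
        raise ValueError("missing input: vocal summary")
    out: dict = {}
    counts = genotypes["genotype"].value_counts()
    gc = GenotypeCounts(int(counts.get("AA", 0)), int(counts.get("AG", 0)),
                        int(counts.get("GG", 0)))
    chi2, p = hwe_chisq(gc)
    out["hwe"] = {"chi2": chi2, "p": p,
                  "counts": {"AA": gc.n_AA, "AG": gc.n_AG, "GG": gc.n_GG}}

    v = vocal_summary.rename(columns={"magnitude_cents_shift": "shift"})
    out["vocal_magnitude_anova"] = mixed_rm_anova(
        v, dv="magnitude_cents", within="shift", between="genotype",
        subject="subject_id")
    out["vocal_latency_anova"] = mixed_rm_anova(
        v, dv="latency_ms", within="shift", between="genotype",
        subject="subject_id")

    big = v[v["shift"] == v["shift"].min()]
    out["vocal_posthoc_largest_shift"] = bonferroni_pairwise(
        {g: grp["magnitude_cents"].to_numpy()
         for g, grp in big.groupby("genotype", observed=True)}, alpha=alpha)

    # per-genotype correlation: mean compensation across shifts vs baseline SD
    per_subj = (v.groupby(["subject_id", "genotype"], observed=True)
                [["magnitude_cents", "baseline_sd_cents"]].mean().reset_index())
    def _corr(x, y):
        if len(x) < 3:
            return CorrelationResult(float("nan"), len(x), float("nan"),
                                     degenerate=True)
        return pearson_correlation(x, y)

    cors = {}
    for g, grp in per_subj.groupby("genotype", observed=True):
        cors[g] = _corr(grp["baseline_sd_cents"], grp["magnitude_cents"])
    out["compensation_vs_variability"] = cors
    cors_by_shift: dict = {}
    for (g, s), grp in v.groupby(["genotype", "shift"], observed=True):
        cors_by_shift[(g, s)] = _corr(grp["baseline_sd_cents"],
                                      grp["magnitude_cents"])
    out["compensation_vs_variability_by_shift"] = cors_by_shift

    if erp_summary is not None and len(erp_summary):
        e = erp_summary.rename(columns={"magnitude_cents_shift": "shift"})
        for comp in ("n1", "p2"):
            out[f"{comp}_amplitude_anova"] = mixed_rm_anova(
                e, dv=f"{comp}_amp_uv", within=["shift", "electrode"],
                between="genotype", subject="subject_id")
            out[f"{comp}_latency_anova"] = mixed_rm_anova(
                e, dv=f"{comp}_lat_ms", within=["shift", "electrode"],
                between="genotype", subject="subject_id")
    return out
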