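"""Independent brute-force oracles used by the test suite.

The split-plot ANOVA oracle builds the full long-format design matrix with
sum-to-zero coding (subjects nested in groups, every within term crossed
with both the group and the subject factors) and computes Type III sums of
squares by projection-model comparison: SS(effect) equals the residual sum
of squares of the saturated model with the effect's columns removed. Error
terms are the subject-interaction terms of the matching stratum. This path
shares no code with the package's contrast-score implementation.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def _sum_code(levels: list) -> dict:
    """level -> sum-to-zero row vector of length len(levels)-1."""
    k = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        v = np.zeros(k - 1)
        if i < k - 1:
            v[i] = 1.0
        else:
            v[:] = -1.0
        rows[lev] = v
    return rows


def _subject_code(subjects_by_group: dict) -> dict:
    """subject -> sum-coded indicator within its group, zero elsewhere."""
    cols = sum(max(0, len(s) - 1) for s in subjects_by_group.values())
    rows = {}
    offset = 0
    for g in sorted(subjects_by_group):
        subs = sorted(subjects_by_group[g])
        code = _sum_code(subs)
        for s in subs:
            v = np.zeros(cols)
            v[offset : offset + len(subs) - 1] = code[s]
            rows[s] = v
        offset += len(subs) - 1
    return rows


def _columns(df, term, codes):
    """Row-wise Khatri-Rao product of the coded factors in ``term``."""
    n = len(df)
    mats = []
    for fac in term:
        mats.append(np.vstack([codes[fac][v] for v in df[fac]]))
    out = np.ones((n, 1))
    for m in mats:
        out = np.einsum("ij,ik->ijk", out, m).reshape(n, -1)
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def oracle_mixed_anova(data: pd.DataFrame, dv: str, within, between: str,
                       subject: str) -> pd.DataFrame:
    """Brute-force split-plot ANOVA (F, dfs, p) via Type III projections."""
    within = [within] if isinstance(within, str) else list(within)
    df = data.copy()
    y = df[dv].to_numpy(float)

    glevels = sorted(df[between].unique())
    codes = {between: _sum_code(glevels)}
    for w in within:
        codes[w] = _sum_code(sorted(df[w].unique()))
    groups_of = df.groupby(subject, observed=True)[between].first()
    subjects_by_group = {g: list(groups_of.index[groups_of == g]) for g in glevels}
    codes[subject] = _subject_code(subjects_by_group)

    # every model term of the saturated split-plot design
    w_subsets = list(chain.from_iterable(combinations(within, k)
                                         for k in range(1, len(within) + 1)))
    terms = {"(intercept)": ()}
    terms[between] = (between,)
    terms["S(G)"] = (subject,)
    for ws in w_subsets:
        name = " * ".join(ws)
        terms[name] = ws
        terms[f"{name} * {between}"] = (*ws, between)
        terms[f"{name} * S(G)"] = (*ws, subject)

    blocks = {name: _columns(df, term, codes) if term else np.ones((len(df), 1))
              for name, term in terms.items()}
    X_full = np.hstack(list(blocks.values()))
    rss_full = _rss(X_full, y)

    def ss_drop(name: str) -> float:
        X = np.hstack([b for k, b in blocks.items() if k != name])
        return _rss(X, y) - rss_full

    n_subj = int(df[subject].nunique())
    G = len(glevels)
    rows = []
    ss_b = ss_drop(between)
    ss_sg = ss_drop("S(G)")
    F = (ss_b / (G - 1)) / (ss_sg / (n_subj - G))
    rows.append(dict(effect=between, ss_effect=ss_b, ss_error=ss_sg,
                     df1=G - 1, df2=n_subj - G, F=F,
                     p_unc=float(sps.f.sf(F, G - 1, n_subj - G))))
    for ws in w_subsets:
        name = " * ".join(ws)
        q = int(np.prod([len(codes[w]) - 1 + 0 for w in ws])
                ) if False else int(np.prod([len(set(df[w])) - 1 for w in ws]))
        ss_err = ss_drop(f"{name} * S(G)")
        df_err = q * (n_subj - G)
        for eff_name, dfe in ((name, q), (f"{name} * {between}", q * (G - 1))):
            ss = ss_drop(eff_name)
            F = (ss / dfe) / (ss_err / df_err)
            rows.append(dict(effect=eff_name, ss_effect=ss, ss_error=ss_err,
                             df1=dfe, df2=df_err, F=F,
                             p_unc=float(sps.f.sf(F, dfe, df_err))))
    return pd.DataFrame(rows)


def random_split_plot_dataset(rng: np.random.Generator,
                              max_group_size: int = 5,
                              two_within: bool = False) -> pd.DataFrame:
    """A random small unbalanced split-plot dataset in long format."""
    sizes = rng.integers(2, max_group_size + 1, size=3)
    wlevels = {"w1": list(range(int(rng.integers(2, 4))))}
    if two_within:
        wlevels["w2"] = list(range(int(rng.integers(2, 4))))
    rows = []
    sid = 0
    for gi, g in enumerate(["g1", "g2", "g3"]):
        for _ in range(sizes[gi]):
            sid += 1
            base = rng.normal(scale=2.0)
            for a in wlevels["w1"]:
                for b in wlevels.get("w2", [0]):
                    rec = dict(subject=f"s{sid:02d}", group=g, w1=a,
                               value=base + rng.normal())
                    if two_within:
                        rec["w2"] = b
                    rows.append(rec)
    return pd.DataFrame(rows)
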