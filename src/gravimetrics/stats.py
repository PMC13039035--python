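"""Statistical layer: mixed (split-plot) ANCOVA/ANOVA, correlations, t-tests.

The primary design has one between-subject factor (age group), one
within-subject factor (task type) and, optionally, movement duration as a
covariate that varies within subjects. The analysis splits into the two
classical error strata of a split-plot design:

* between stratum - subject means, the group effect tested against the
  subject-level residual (adjusted for the between-subject part of the
  covariate);
* within stratum - the within-subject effects (task, group x task
  interaction, and the within-subject part of the covariate) tested against
  the within-subject residual, with subject intercepts absorbed.

Sums of squares are Type III with effect (sum-to-zero) coding and a
mean-centered covariate. Partial eta-squared is SS_effect /
(SS_effect + SS_error-of-its-stratum). For within factors with 3 levels a
Greenhouse-Geisser-corrected p is reported alongside the uncorrected one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "mixed_ancova",
    "pearson_correlation",
    "independent_ttest",
]


def _effect_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: one column per non-reference level."""
    levels = sorted(pd.unique(labels).tolist())
    ref = levels[-1]
    cols = []
    for lev in levels[:-1]:
        c = np.where(labels == lev, 1.0, np.where(labels == ref, -1.0, 0.0))
        cols.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(labels), 0))
    return X, levels


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank via least squares."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the subjects x levels data matrix."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def mixed_ancova(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    covariate: str | None = None,
) -> pd.DataFrame:
    """Split-plot ANCOVA (between x within, optional within-varying covariate).

    ``table`` is long-format with one row per subject x within-level cell.
    Every subject must have every within level. Returns a tidy table with one
    row per effect (between, within, interaction, covariate): F, df, p,
    partial eta-squared, and a GG-corrected p for 3+-level within factors.
    """
    cols = [subject, between, within, dv] + ([covariate] if covariate else [])
    df = table[cols].copy()
    if df[dv].isna().any():
        df = df.dropna(subset=[dv])
    piv = df.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    if piv.isna().any().any():
        bad = piv.index[piv.isna().any(axis=1)].get_level_values(0).tolist()
        raise ValueError(f"missing within-level cell(s) for subject(s): {bad}")
    subjects = piv.index.get_level_values(0).to_numpy()
    groups = piv.index.get_level_values(1).to_numpy()
    levels = list(piv.columns)
    T = len(levels)
    n = len(subjects)
    Y = piv.to_numpy()  # (n, T)

    if covariate:
        pivx = df.pivot_table(index=[subject, between], columns=within, values=covariate, aggfunc="mean")
        X_cov = pivx.reindex(piv.index).to_numpy()
        if np.isnan(X_cov).any():
            raise ValueError("covariate missing for some subject x level cell")
        X_cov = X_cov - X_cov.mean()  # grand-mean centering
    else:
        X_cov = None

    out_rows = []

    # ---- between stratum: subject means -----------------------------------
    ybar = Y.mean(axis=1)
    Gcode, _ = _effect_code(groups)
    design_b = [np.ones(n), Gcode]
    cov_between = None
    if X_cov is not None:
        xbar = X_cov.mean(axis=1)
        if np.var(xbar) > 1e-12:
            cov_between = xbar
            design_b.append(xbar[:, None])
    Xb_full = np.column_stack(design_b)
    rss_full_b, rank_b = _rss(Xb_full, ybar)
    df_err_b = n - rank_b
    # drop group columns
    keep = [np.ones((n, 1))] + ([cov_between[:, None]] if cov_between is not None else [])
    rss_red_b, _ = _rss(np.column_stack(keep), ybar)
    ss_group = max(rss_red_b - rss_full_b, 0.0)
    df_group = Gcode.shape[1]
    F_group = (ss_group / df_group) / (rss_full_b / df_err_b)
    out_rows.append(
        dict(
            effect="between",
            F=F_group,
            df_num=df_group,
            df_den=df_err_b,
            p=float(sstats.f.sf(F_group, df_group, df_err_b)),
            partial_eta_sq=ss_group / (ss_group + rss_full_b) if ss_group + rss_full_b > 0 else 0.0,
            p_gg=np.nan,
        )
    )

    # ---- within stratum ----------------------------------------------------
    N = n * T
    y = Y.reshape(-1)  # subject-major order
    subj_idx = np.repeat(np.arange(n), T)
    within_lab = np.tile(np.array(levels, dtype=object), n)
    group_lab = np.repeat(groups, T)

    Dsubj = np.zeros((N, n - 1))
    for i in range(n - 1):
        Dsubj[subj_idx == i, i] = 1.0
        Dsubj[subj_idx == n - 1, i] = -1.0
    Wcode, _ = _effect_code(within_lab)
    Gc_full, _ = _effect_code(group_lab)
    inter = np.column_stack(
        [Gc_full[:, i] * Wcode[:, j] for i in range(Gc_full.shape[1]) for j in range(Wcode.shape[1])]
    )
    blocks = {"within": Wcode, "interaction": inter}
    if X_cov is not None:
        x_within = (X_cov - X_cov.mean(axis=1, keepdims=True)).reshape(-1)
        if np.var(x_within) > 1e-12:
            blocks["covariate"] = x_within[:, None]
    base = [np.ones((N, 1)), Dsubj]
    Xw_full = np.column_stack(base + list(blocks.values()))
    rss_full_w, rank_w = _rss(Xw_full, y)
    df_err_w = N - rank_w
    if df_err_w <= 0:
        raise ValueError("no residual degrees of freedom in the within stratum")
    gg_eps = _gg_epsilon(Y) if T > 2 else 1.0
    for name, block in blocks.items():
        others = [b for k, b in blocks.items() if k != name]
        Xr = np.column_stack(base + others) if others else np.column_stack(base)
        rss_red, _ = _rss(Xr, y)
        ss = max(rss_red - rss_full_w, 0.0)
        dfe = block.shape[1]
        F = (ss / dfe) / (rss_full_w / df_err_w)
        p = float(sstats.f.sf(F, dfe, df_err_w))
        if name in ("within", "interaction") and T > 2:
            p_gg = float(sstats.f.sf(F, dfe * gg_eps, df_err_w * gg_eps))
        else:
            p_gg = np.nan
        out_rows.append(
            dict(
                effect=name,
                F=F,
                df_num=dfe,
                df_den=df_err_w,
                p=p,
                partial_eta_sq=ss / (ss + rss_full_w) if ss + rss_full_w > 0 else 0.0,
                p_gg=p_gg,
            )
        )
    return pd.DataFrame(out_rows)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def independent_ttest(a, b) -> dict:
    """Two-sided independent-samples t-test with Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sstats.ttest_ind(a, b)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else np.nan
    return {"t": float(t), "p": float(p), "cohen_d": float(d), "df": na + nb - 2}
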