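"""Within-subject (repeated-measures) ANOVA with Greenhouse–Geisser correction.

Implements the full factorial within-subject decomposition for an arbitrary
number of crossed within factors on a balanced design: each effect is tested
against its interaction with subjects, degrees of freedom are scaled by the
Greenhouse–Geisser epsilon estimated from the covariance of the
contrast-transformed subject cell means, and effect sizes are eta-squared
relative to the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "rm_anova"]


@dataclass
class AnovaResult:
    """RM-ANOVA table plus the cumulative explained variance."""

    table: pd.DataFrame  # effect, F, df1, df2, epsilon, p, p_corrected, eta2
    eta2_cumulative: float
    ss_total: float

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast matrix (orthogonal complement of 1/sqrt(k))."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return q[:, 1:]


def _effect_means(y: np.ndarray, effect_axes: tuple[int, ...]) -> np.ndarray:
    other = tuple(ax for ax in range(y.ndim) if ax not in effect_axes)
    return y.mean(axis=other, keepdims=True)


def _inclusion_exclusion(y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Interaction-effect estimates for the cells of ``axes`` (zero-sum in each)."""
    out = np.zeros_like(_effect_means(y, axes))
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            sign = (-1) ** (len(axes) - len(sub))
            out = out + sign * _effect_means(y, sub)
    return out


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
) -> AnovaResult:
    """Repeated-measures ANOVA on a long-format balanced table.

    Parameters
    ----------
    data : long table with one row per subject x cell.
    dv : dependent-variable column (e.g. RAU score).
    within : within-subject factor columns, each with >= 2 levels.
    subject : subject identifier column.

    Each effect's F is MS_effect / MS_(effect x subject); the corrected p uses
    Greenhouse–Geisser epsilon from the covariance matrix of the
    contrast-transformed per-subject cell means.  eta2 = SS_effect / SS_total.
    """
    subjects = np.sort(data[subject].unique())
    levels = {f: np.sort(data[f].unique()) for f in within}
    shape = (subjects.size,) + tuple(levels[f].size for f in within)
    if any(s < 2 for s in shape):
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    idx = data.set_index([subject] + within)[dv]
    if idx.index.duplicated().any():
        raise ValueError("duplicate subject x cell rows; design must be balanced")
    try:
        y = idx.unstack(within) if len(within) > 1 else idx.unstack(within[0])
    except Exception as e:  # pragma: no cover
        raise ValueError(f"could not pivot design: {e}")
    full = pd.MultiIndex.from_product([levels[f] for f in within], names=within) \
        if len(within) > 1 else pd.Index(levels[within[0]], name=within[0])
    y = y.reindex(index=subjects, columns=full)
    if y.isna().any().any():
        raise ValueError("unbalanced design: missing subject x cell combinations")
    y = y.to_numpy(float).reshape(shape)

    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    n_sub = subjects.size
    n_cells_total = int(np.prod(shape[1:]))

    rows = []
    eta2_sum = 0.0
    factor_axis = {f: i + 1 for i, f in enumerate(within)}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            axes = tuple(factor_axis[f] for f in combo)
            k_prod = int(np.prod([levels[f].size for f in combo]))
            df1 = int(np.prod([levels[f].size - 1 for f in combo]))
            df2 = df1 * (n_sub - 1)

            eff = _inclusion_exclusion(y, axes)
            mult = n_sub * n_cells_total / k_prod
            ss_eff = float(mult * np.sum(eff**2))

            # error: effect x subject interaction
            eff_s = _inclusion_exclusion(y, (0,) + axes)
            ss_err = float((n_cells_total / k_prod) * np.sum(eff_s**2))

            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            f_val = ms_eff / ms_err if ms_err > 0 else np.inf

            # Greenhouse–Geisser epsilon from contrast-transformed cell means
            z = y
            contrast = np.ones((1, 1))
            for f in within:
                k = levels[f].size
                m = _orthonormal_contrast(k) if f in combo else np.full((k, 1), 1 / np.sqrt(k))
                contrast = np.kron(contrast, m)
            flat = y.reshape(n_sub, -1)
            z = flat @ contrast  # (n_sub, df1)
            sigma = np.cov(z, rowvar=False)
            sigma = np.atleast_2d(sigma)
            tr = np.trace(sigma)
            eps = 1.0 if df1 == 1 else float(tr**2 / (df1 * np.sum(sigma * sigma.T)))
            eps = min(1.0, max(eps, 1.0 / df1))

            p_unc = float(sps.f.sf(f_val, df1, df2))
            p_cor = float(sps.f.sf(f_val, eps * df1, eps * df2))
            eta2 = ss_eff / ss_total
            eta2_sum += eta2
            rows.append(
                {
                    "effect": " * ".join(combo),
                    "SS": ss_eff,
                    "F": f_val,
                    "df1": df1,
                    "df2": df2,
                    "epsilon": eps,
                    "p_uncorrected": p_unc,
                    "p_corrected": p_cor,
                    "eta2": eta2,
                }
            )
    table = pd.DataFrame(rows)
    return AnovaResult(table=table, eta2_cumulative=eta2_sum, ss_total=ss_total)
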