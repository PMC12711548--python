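"""Group-level contrasts and FVC correlations with multiplicity control.

Condition contrasts (on PSD maps, PLV edges, or network metrics) use
per-feature t-tests with family-wise error control by max-statistic
permutation (default) or Bonferroni.  FVC-edge associations use Pearson
correlation with Benjamini-Hochberg FDR control across the full test
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContrastResult:
    """Per-feature t statistics with raw p-values and a corrected mask."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    threshold: float
    label: str = ""
    band: str = ""
    method: str = ""
    feature_names: tuple[str, ...] = ()


def contrast_ttest(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature t statistic and two-sided p, A minus B.

    ``values_*`` are subjects x features.  Two-sample (pooled variance) by
    default; ``paired`` switches to the within-subject paired test
    (recommended when both conditions come from the same subjects).
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ between groups")
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0) & (a.mean(axis=0) == b.mean(axis=0))
    if degenerate.any():
        raise ValueError(
            f"zero variance in both groups at feature(s) {np.flatnonzero(degenerate).tolist()}"
        )
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test needs equal group sizes")
        res = stats.ttest_rel(a, b, axis=0)
    else:
        res = stats.ttest_ind(a, b, axis=0)
    t = np.nan_to_num(np.asarray(res.statistic, dtype=float), nan=0.0)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    return t, p


def _perm_maxt_two_sample(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null max-|t| distribution by shuffling group membership (vectorised)."""
    x = np.vstack([a, b])
    n, na = x.shape[0], a.shape[0]
    x2 = x**2
    maxt = np.empty(n_perm)
    sel = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
    member = np.zeros((n_perm, n))
    np.put_along_axis(member, sel, 1.0, axis=1)
    nb = n - na
    sum_all, sumsq_all = x.sum(axis=0), x2.sum(axis=0)
    sa = member @ x
    sa2 = member @ x2
    ma, mb = sa / na, (sum_all - sa) / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = (sumsq_all - sa2 - nb * mb**2) / (nb - 1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1), 0.0)
    maxt[:] = np.abs(t).max(axis=1)
    return maxt


def _perm_maxt_paired(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null max-|t| by flipping condition labels within subject (sign flips)."""
    d = a - b
    n = d.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    m = (signs @ d) / n
    m2 = (d**2).sum(axis=0) / n  # sign flips leave d^2 unchanged
    var = (m2 - m**2) * n / (n - 1)
    denom = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, m / np.where(denom > 0, denom, 1), 0.0)
    return np.abs(t).max(axis=1)


def fwe_correct(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "maxT",
    alpha: float = 0.01,
    n_perm: int = 5000,
    seed: int = 0,
    paired: bool = False,
) -> ContrastResult:
    """Family-wise-error-corrected condition contrast.

    ``"maxT"`` builds the null distribution of the maximum |t| over
    features by permuting group labels (two-sample) or flipping condition
    labels within subject (paired); features with |t| above the (1 - alpha)
    quantile are flagged.  ``"bonferroni"`` flags raw p < alpha / m.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    t, p = contrast_ttest(a, b, paired=paired)
    m = t.size
    if method == "bonferroni":
        mask = p < alpha / m
        return ContrastResult(t, p, mask, float(alpha / m), method="bonferroni")
    if method != "maxT":
        raise ValueError(f"unknown FWE method {method!r}")
    if n_perm < int(np.ceil(1.0 / alpha)):
        warnings.warn(
            f"n_perm={n_perm} is small for alpha={alpha}; the threshold is noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if paired:
        null_max = _perm_maxt_paired(a, b, n_perm, rng)
    else:
        null_max = _perm_maxt_two_sample(a, b, n_perm, rng)
    thr = float(np.quantile(null_max, 1.0 - alpha))
    mask = np.abs(t) > thr
    return ContrastResult(t, p, mask, thr, method="maxT")


def bh_fdr(pvals: Sequence[float], alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (discovery mask, adjusted p-values).

    Flags all ranks up to the largest k with p_(k) <= k * alpha / m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj, 0.0, 1.0)
    return mask, adjusted


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of ``x`` against ``y``, with two-sided p."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (yc @ xc) / np.where(denom > 0, denom, 1), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def fvc_correlation(
    plv_vectors: Mapping[tuple[str, str], np.ndarray],
    fvc: np.ndarray,
    alpha: float = 0.01,
    edge_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson FVC-edge correlations with BH-FDR across the whole family.

    ``plv_vectors[(condition, band)]`` is subjects x edges (either the
    120-edge unique-pair or the 256-entry full-matrix vectorization); the
    FDR family spans all supplied (condition, band) blocks jointly.
    Returns a table with columns band, condition, edge, r, p, p_adj,
    significant.
    """
    fvc = np.asarray(fvc, dtype=float)
    if fvc.size < 4:
        raise ValueError("need at least 4 subjects with FVC")
    if fvc.std() == 0:
        raise ValueError("FVC vector is constant")
    frames = []
    for (cond, band), x in plv_vectors.items():
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != fvc.size:
            raise ValueError(f"{(cond, band)}: {x.shape[0]} subjects but {fvc.size} FVC values")
        r, p = pearson_with_p(x, fvc)
        names = (
            list(edge_names)
            if edge_names is not None and len(edge_names) == x.shape[1]
            else [str(i) for i in range(x.shape[1])]
        )
        frames.append(
            pd.DataFrame({"band": band, "condition": cond, "edge": names, "r": r, "p": p})
        )
    table = pd.concat(frames, ignore_index=True)
    mask, adjusted = bh_fdr(table["p"].to_numpy(), alpha=alpha)
    table["p_adj"] = adjusted
    table["significant"] = mask
    return table


def contrast_table(result: ContrastResult) -> pd.DataFrame:
    names = (
        result.feature_names
        if result.feature_names
        else tuple(str(i) for i in range(result.t.size))
    )
    return pd.DataFrame(
        {
            "contrast": result.label,
            "band": result.band,
            "feature": names,
            "t": result.t,
            "p": result.p,
            "significant": result.mask,
        }
    )
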