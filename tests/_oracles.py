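"""Independent oracles used by the test suite.

These re-derive expected values by brute force or closed form along paths
that share no code with the implementation being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def grid_search_ae(pairs: pd.DataFrame, step: float = 0.001,
                   hi: float = 1.5) -> tuple[float, float, float]:
    """Exhaustive AE maximum likelihood over path coefficients a, e.

    The grid covers a, e in [0, hi] at the given step; the common mean is
    profiled in closed form at each node (the exact ML of the mean for fixed
    covariance).  Returns (best logL, a2, e2).
    """
    mz = pairs[pairs["zygosity"] == "MZ"][["value1", "value2"]].to_numpy(float)
    dz = pairs[pairs["zygosity"] == "DZ"][["value1", "value2"]].to_numpy(float)
    groups = []
    for vals in (mz, dz):
        n = len(vals)
        groups.append((n, vals[:, 0].sum() + vals[:, 1].sum(),
                       (vals ** 2).sum(), (vals[:, 0] * vals[:, 1]).sum()))

    a = np.arange(0.0, hi + step / 2, step)
    e = np.arange(0.0, hi + step / 2, step)
    A2, E2 = np.meshgrid(a ** 2, e ** 2, indexing="ij")
    var = A2 + E2
    covs = (A2, 0.5 * A2)  # MZ, DZ off-diagonals

    # profiled mean: mu = sum_g T_g/(var+cov_g) / sum_g 2 n_g/(var+cov_g)
    num = np.zeros_like(var)
    den = np.zeros_like(var)
    for (n, t, _, _), cov in zip(groups, covs):
        vc = var + cov
        with np.errstate(divide="ignore", invalid="ignore"):
            num += np.where(vc > 0, t / np.where(vc > 0, vc, 1.0), 0.0)
            den += np.where(vc > 0, 2 * n / np.where(vc > 0, vc, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(den > 0, num / den, 0.0)

    ll = np.zeros_like(var)
    ok = np.ones_like(var, dtype=bool)
    for (n, t, q, p), cov in zip(groups, covs):
        det = var ** 2 - cov ** 2
        valid = (det > 0) & (var > 0)
        ok &= valid
        qq = q - 2 * mu * t + 2 * n * mu ** 2
        pp = p - mu * t + n * mu ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ll += np.where(
                valid,
                -n * np.log(2 * np.pi) - 0.5 * n * np.log(np.where(valid, det, 1))
                - (var * qq - 2 * cov * pp) / (2 * np.where(valid, det, 1)),
                -np.inf,
            )
    ll = np.where(ok, ll, -np.inf)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i, j]), float(a[i] ** 2), float(e[j] ** 2)


def icc_anova(v1, v2) -> float:
    """One-way ANOVA intraclass correlation, written out long-hand."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    n = len(v1)
    pair_means = (v1 + v2) / 2
    grand = np.concatenate([v1, v2]).mean()
    msb = sum(2 * (m - grand) ** 2 for m in pair_means) / (n - 1)
    msw = sum((a - m) ** 2 + (b - m) ** 2
              for a, b, m in zip(v1, v2, pair_means)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        return (msb - msw) / (msb + msw)


def pearson_by_hand(x, y) -> float:
    """Sample Pearson correlation from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
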