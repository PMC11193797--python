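"""Asset-wealth index, quintiles, change outcomes and regional inequality.

The wealth score is the first principal component of the standardised asset
items, computed on the *pooled* two-wave household-by-item matrix so that the
two waves share one scale.  Households are assigned pooled quintiles (1 =
poorest, 5 = wealthiest).  The household outcome is a binary indicator of a
quintile change between waves; the regional outcome binarises the change in a
Gini-style inequality score computed on within-region quintile values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

OUTCOME_MODES = ("any_change", "up", "down", "stable")

#: ΔInq threshold above which a region counts as experiencing rising inequality.
DELTA_INQ_THRESHOLD = 0.02


def pca_index(wave1: pd.DataFrame, wave2: pd.DataFrame) -> pd.DataFrame:
    """First-principal-component wealth score and pooled quintiles per wave.

    Parameters
    ----------
    wave1, wave2
        Household-by-item matrices indexed by household id.  Households
        missing from one wave get NaN score/quintile for that wave.

    Returns
    -------
    DataFrame indexed by household id with columns
    ``score_w1, score_w2, q_w1, q_w2``.

    Notes
    -----
    Items are standardised (mean 0, sd 1) on the pooled household-wave matrix;
    constant items are dropped with a warning.  The component sign is oriented
    so the score correlates positively with the unweighted item sum.  Quintile
    boundaries are pooled empirical quantiles of all household-waves, ties
    broken by stable (wave, household-id) order, so each pooled quintile holds
    20% (+/-1) of household-waves.
    """
    common_items = [c for c in wave1.columns if c in set(wave2.columns)]
    if len(common_items) < 2:
        raise ValueError("waves share fewer than 2 asset items")
    pooled = pd.concat(
        [wave1[common_items], wave2[common_items]],
        keys=[1, 2],
        names=["wave", "household_id"],
    )
    X = pooled.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(common_items, keep) if not k]
        logger.warning("dropping %d constant asset items: %s", len(dropped), dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 asset items with nonzero variance")
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X[:, :].std(axis=0)
    score = PCA(n_components=1, svd_solver="full").fit_transform(Xs)[:, 0]
    item_sum = X.sum(axis=1)
    orient = np.corrcoef(score, item_sum)[0, 1]
    if orient < 0:
        score = -score

    pooled_scores = pd.Series(score, index=pooled.index, name="score")
    # stable rank: sort by score then by original (wave, household) position
    order = np.argsort(score, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(score))
    quintile = (rank * 5) // len(score) + 1
    pooled_q = pd.Series(quintile, index=pooled.index, name="q")

    out = pd.DataFrame(index=wave1.index.union(wave2.index, sort=False))
    out.index.name = "household_id"
    for w, wave_idx in ((1, wave1.index), (2, wave2.index)):
        out[f"score_w{w}"] = pooled_scores.loc[w].reindex(out.index)
        out[f"q_w{w}"] = pooled_q.loc[w].reindex(out.index)
    return out


def household_outcome(index: pd.DataFrame, mode: str = "any_change") -> pd.Series:
    """Binary household outcome from the between-wave quintile change.

    ``mode`` selects the main definition (``any_change``: quintile moved in
    either direction) or one of the sensitivity definitions (``up``: moved up;
    ``down``: moved down; ``stable``: unchanged).  Households missing either
    wave get NaN (a missingness mask, never a silent 0).
    """
    if mode not in OUTCOME_MODES:
        raise ValueError(f"unknown outcome mode {mode!r}; choose from {OUTCOME_MODES}")
    delta = index["q_w2"] - index["q_w1"]
    y = pd.Series(np.nan, index=index.index, name=f"y_{mode}")
    obs = delta.notna()
    d = delta[obs]
    if mode == "any_change":
        y[obs] = (d != 0).astype(float)
    elif mode == "up":
        y[obs] = (d > 0).astype(float)
    elif mode == "down":
        y[obs] = (d < 0).astype(float)
    else:
        y[obs] = (d == 0).astype(float)
    return y


def regional_gini(values) -> float:
    """Gini mean-difference index of quintile values in one region.

    G = sum_i sum_j |x_i - x_j| / (2 n^2 xbar).  0 for a single household or
    a region where all quintiles are equal; invariant to household order and
    to rescaling all values by a positive constant.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        raise ValueError("regional_gini of an empty region")
    if n == 1:
        return 0.0
    xbar = x.mean()
    if xbar == 0:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    # sum_ij |xi-xj| = 2 * sum_i (2i - n - 1) x_(i)
    mad_total = 2.0 * np.sum((2 * i - n - 1) * xs)
    return float(mad_total / (2.0 * n * n * xbar))


def regional_inequality(index: pd.DataFrame, affiliation) -> pd.DataFrame:
    """Per-region inequality score for each wave and its change.

    Households missing a wave are excluded from that wave's score.  Returns a
    DataFrame indexed by region with ``inq_w1, inq_w2, delta_inq``.
    """
    aff = pd.Series(dict(affiliation), name="region")
    df = index.join(aff.rename("region"), how="inner")
    unmapped = index.index.difference(aff.index)
    if len(unmapped):
        raise KeyError(f"{len(unmapped)} households lack a region affiliation")
    rows = {}
    for region, grp in df.groupby("region", sort=True):
        inq1 = regional_gini(grp["q_w1"].dropna())
        inq2 = regional_gini(grp["q_w2"].dropna())
        rows[region] = {"inq_w1": inq1, "inq_w2": inq2, "delta_inq": inq2 - inq1}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out


@dataclass
class RegionalOutcome:
    Y: pd.Series  # binary per region
    selected_regions: list
    threshold: float
    percentile_cut: float  # diagnostic mu + 0.675 sigma cut of the delta distribution


def regional_outcome(
    inequality: pd.DataFrame, threshold: float = DELTA_INQ_THRESHOLD
) -> RegionalOutcome:
    """Binarise the regional inequality change.

    Y_v = 1 iff delta_inq >= ``threshold`` (default 2 percentage points of the
    inequality score).  The mu + 0.675 sigma (upper-quartile under normality)
    cut of the delta distribution is reported as a diagnostic but not used for
    selection.
    """
    delta = inequality["delta_inq"]
    Y = (delta >= threshold).astype(int).rename("Y")
    cut = float(delta.mean() + 0.675 * delta.std())
    return RegionalOutcome(
        Y=Y,
        selected_regions=list(Y.index[Y == 1]),
        threshold=threshold,
        percentile_cut=cut,
    )
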