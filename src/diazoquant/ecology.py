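"""Station-level ecological summaries.

Community dissimilarity (Bray–Curtis), rank correlation between imaging
and molecular quantifications (Spearman with a seeded permutation
p-value), taxon co-occurrence, latitudinal binning, and quantile-based
hotspot flagging.  Ordination of the exported distance matrices is left
to standard ecology packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) ∈ [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(composition: pd.DataFrame) -> pd.DataFrame:
    """Square Bray–Curtis distance matrix for a stations × taxa table."""
    values = composition.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("every station needs at least one non-zero abundance")
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=composition.index, columns=composition.index)


def spearman(
    x,
    y,
    n_permutations: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Spearman's rho with a one-sided permutation p-value.

    Ranks use average-rank tie handling.  The p-value permutes the labels
    of *y* ``n_permutations`` times under a fixed seed and reports the
    add-one estimate P(rho_perm ≥ rho_obs) (``alternative="greater"``) or
    the ≤ analogue (``"less"``).  Constant input leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho is undefined for a constant vector")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rho = float(spearmanr(x, y).statistic)

    # permutation distribution of rho == Pearson correlation of ranks
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rng = np.random.default_rng(seed)
    n = x.size
    perm_rhos = np.empty(n_permutations)
    for k in range(n_permutations):
        perm_rhos[k] = rx @ ry[rng.permutation(n)] / n
    if alternative == "greater":
        extreme = np.count_nonzero(perm_rhos >= rho - 1e-12)
    else:
        extreme = np.count_nonzero(perm_rhos <= rho + 1e-12)
    p = (1 + extreme) / (n_permutations + 1)
    return rho, float(p)


def cooccurrence(presence: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise co-detection counts and Jaccard indices per taxon pair.

    *presence* is a binary stations × taxa matrix.  Returns two symmetric
    taxa × taxa frames: co-detection counts (diagonal = per-taxon
    detection counts) and Jaccard indices (|A∩B| / |A∪B|; self-comparison
    of a detected taxon is 1).
    """
    values = presence.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix must be binary (0/1)")
    values = values.astype(int)
    counts = values.T @ values
    detections = np.diag(counts)
    union = detections[:, None] + detections[None, :] - counts
    with np.errstate(invalid="ignore", divide="ignore"):
        jaccard = np.where(union > 0, counts / np.maximum(union, 1), 0.0)
    taxa = presence.columns
    return (
        pd.DataFrame(counts, index=taxa, columns=taxa),
        pd.DataFrame(jaccard, index=taxa, columns=taxa),
    )


def latitudinal_profile(
    abundances,
    latitudes,
    band_width: float = 10.0,
) -> pd.DataFrame:
    """Per-latitude-band summary of abundances.

    Bands are half-open intervals [lo, lo + band_width) anchored at −90°,
    so every station falls in exactly one band.  Returns one row per
    occupied band with ``band_lo``, ``band_hi``, ``n``, ``median``,
    ``mean`` and ``detection_rate`` (share of stations with abundance > 0).
    """
    if band_width <= 0:
        raise ValueError("band_width must be > 0")
    a = np.asarray(abundances, dtype=float)
    lat = np.asarray(latitudes, dtype=float)
    if a.shape != lat.shape:
        raise ValueError("abundances and latitudes must have equal length")
    band_index = np.floor((lat + 90.0) / band_width).astype(int)
    rows = []
    for b in sorted(set(band_index)):
        sel = a[band_index == b]
        rows.append(
            {
                "band_lo": -90.0 + b * band_width,
                "band_hi": -90.0 + (b + 1) * band_width,
                "n": int(sel.size),
                "median": float(np.median(sel)),
                "mean": float(sel.mean()),
                "detection_rate": float((sel > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def hotspot_flag(abundances: pd.Series | dict, quantile: float = 0.9) -> list[str]:
    """Stations with abundance strictly above the q-quantile of non-zero values.

    Operationalises "hotspot" as an upper-quantile exceedance; all-zero
    input flags nothing.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    s = pd.Series(abundances, dtype=float)
    if s.empty:
        raise ValueError("abundances must be non-empty")
    nonzero = s[s > 0]
    if nonzero.empty:
        return []
    threshold = float(np.quantile(nonzero.to_numpy(), quantile))
    return [str(k) for k in s.index[s > threshold]]
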