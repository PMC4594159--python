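"""Object-based and intensity-based two-channel co-localization.

Object-based: for each focus in one channel, the Euclidean distance to the
nearest focus of the other channel; foci closer than a resolution-limit
threshold (default 0.272 um, the PSF FWHM of the reference optics) count as
co-localized. The two directional fractions are independent quantities:
channel A can co-localize strongly with B while B rarely co-localizes with A.

Intensity-based: Pearson correlation with Costes automatic thresholding
(orthogonal regression of channel 2 on channel 1; thresholds walked down from
the maximum until the below-threshold pixels are uncorrelated).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .containers import Focus

#: Default co-localization distance threshold (um): PSF FWHM of the optics.
DEFAULT_THRESHOLD_UM = 0.272


def _positions_um(foci: list[Focus], pixel_size_um: float) -> np.ndarray:
    return np.array([[f.x * pixel_size_um, f.y * pixel_size_um] for f in foci],
                    dtype=float).reshape(len(foci), 2)


def reciprocal_nn_distances(foci_a: list[Focus], foci_b: list[Focus],
                            pixel_size_um: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour distances (um) A->B and B->A.

    A direction with an empty opposite set yields an empty distance array.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    pa = _positions_um(foci_a, pixel_size_um)
    pb = _positions_um(foci_b, pixel_size_um)
    if len(pa) == 0 or len(pb) == 0:
        return np.zeros(0), np.zeros(0)
    dist_a = cKDTree(pb).query(pa)[0]
    dist_b = cKDTree(pa).query(pb)[0]
    return np.asarray(dist_a, dtype=float), np.asarray(dist_b, dtype=float)


def mutual_nn_pairs(foci_a: list[Focus], foci_b: list[Focus],
                    pixel_size_um: float, threshold_um: float
                    ) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs closer than the threshold.

    Each focus appears in at most one pair; used for Venn-style counts.
    """
    pa = _positions_um(foci_a, pixel_size_um)
    pb = _positions_um(foci_b, pixel_size_um)
    if len(pa) == 0 or len(pb) == 0:
        return []
    da, ia = cKDTree(pb).query(pa)
    db, ib = cKDTree(pa).query(pb)
    pairs = []
    for i, (d, j) in enumerate(zip(da, ia)):
        if d < threshold_um and ib[j] == i:
            pairs.append((i, int(j)))
    return pairs


@dataclass
class ColocSummary:
    """Reciprocal-NN co-localization summary between a red and a green channel."""

    dist_red_to_green: np.ndarray
    dist_green_to_red: np.ndarray
    threshold_um: float
    n_red: int
    n_green: int
    frac_red_coloc: float | None
    frac_green_coloc: float | None
    ratio_red_to_green: float | None
    hist_bins_um: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    hist_red_to_green: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    hist_green_to_red: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    n_pairs: int = 0
    n_red_only: int = 0
    n_green_only: int = 0
    flags: list[str] = dc_field(default_factory=list)


def coloc_summary(dist_red_to_green: np.ndarray, dist_green_to_red: np.ndarray,
                  threshold_um: float = DEFAULT_THRESHOLD_UM,
                  n_red: int | None = None, n_green: int | None = None,
                  pairs: list[tuple[int, int]] | None = None,
                  hist_bin_um: float = 0.1, hist_max_um: float = 2.0
                  ) -> ColocSummary:
    """Directional co-localized fractions, distance histograms and Venn counts.

    A focus is co-localized when its NN distance is strictly below the
    threshold. An empty distance list gives an undefined (None) fraction.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    d_rg = np.asarray(dist_red_to_green, dtype=float)
    d_gr = np.asarray(dist_green_to_red, dtype=float)
    n_red = len(d_rg) if n_red is None else n_red
    n_green = len(d_gr) if n_green is None else n_green
    flags = []

    def frac(d: np.ndarray, name: str) -> float | None:
        if len(d) == 0:
            flags.append(f"no distances for {name}: fraction undefined")
            return None
        return float(np.mean(d < threshold_um))

    bins = np.arange(0.0, hist_max_um + hist_bin_um, hist_bin_um)
    n_pairs = len(pairs) if pairs is not None else 0
    return ColocSummary(
        dist_red_to_green=d_rg,
        dist_green_to_red=d_gr,
        threshold_um=threshold_um,
        n_red=n_red,
        n_green=n_green,
        frac_red_coloc=frac(d_rg, "red->green"),
        frac_green_coloc=frac(d_gr, "green->red"),
        ratio_red_to_green=(n_red / n_green) if n_green else None,
        hist_bins_um=bins,
        hist_red_to_green=np.histogram(d_rg, bins=bins)[0],
        hist_green_to_red=np.histogram(d_gr, bins=bins)[0],
        n_pairs=n_pairs,
        n_red_only=n_red - n_pairs if pairs is not None else 0,
        n_green_only=n_green - n_pairs if pairs is not None else 0,
        flags=flags,
    )


def colocalize(foci_red: list[Focus], foci_green: list[Focus],
               pixel_size_um: float,
               threshold_um: float = DEFAULT_THRESHOLD_UM) -> ColocSummary:
    """Full object-based co-localization between two focus lists."""
    d_rg, d_gr = reciprocal_nn_distances(foci_red, foci_green, pixel_size_um)
    pairs = mutual_nn_pairs(foci_red, foci_green, pixel_size_um, threshold_um)
    return coloc_summary(d_rg, d_gr, threshold_um,
                         n_red=len(foci_red), n_green=len(foci_green),
                         pairs=pairs)


@dataclass
class CostesResult:
    pearson_r: float
    threshold_ch1: float
    threshold_ch2: float
    regression_slope: float
    regression_intercept: float
    flags: list[str] = dc_field(default_factory=list)


def _orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a*x + b via the principal axis."""
    mx, my = x.mean(), y.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    if abs(v[0]) < 1e-12:
        slope = np.inf
    else:
        slope = v[1] / v[0]
    intercept = my - slope * mx if np.isfinite(slope) else 0.0
    return float(slope), float(intercept)


def pearson_costes(ch1: np.ndarray, ch2: np.ndarray,
                   mask: np.ndarray | None = None,
                   n_steps: int = 256) -> CostesResult:
    """Pearson correlation with Costes automatic thresholding.

    Candidate thresholds T walk down from max(ch1) in steps of 1/``n_steps``
    of the ch1 range, with the paired ch2 threshold on the orthogonal
    regression line. The Costes thresholds are the first pair at which the
    pixels below both thresholds are uncorrelated (r <= 0); the reported
    Pearson coefficient is computed over the pixels above both thresholds.
    If no crossing is found the thresholds fall to the channel minima
    (flagged); if too few pixels lie above the thresholds the coefficient is
    computed over all pixels (flagged).
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must be congruent")
    if mask is not None:
        a, b = a[np.asarray(mask, dtype=bool)], b[np.asarray(mask, dtype=bool)]
    a, b = a.ravel(), b.ravel()
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("each channel needs >= 2 distinct values")

    slope, intercept = _orthogonal_regression(a, b)
    flags: list[str] = []
    lo, hi = a.min(), a.max()
    step = (hi - lo) / n_steps
    t1, t2 = None, None
    t = hi - step
    while t > lo:
        t2_cand = slope * t + intercept if np.isfinite(slope) else b.min()
        below = (a < t) & (b < t2_cand)
        if below.sum() >= 2:
            xa, xb = a[below], b[below]
            if xa.std() > 0 and xb.std() > 0:
                r_below = pearsonr(xa, xb)[0]
                if r_below <= 0:
                    t1, t2 = t, t2_cand
                    break
        t -= step
    if t1 is None:
        t1 = float(lo)
        t2 = float(slope * lo + intercept) if np.isfinite(slope) else float(b.min())
        flags.append("no threshold found: thresholds set to minimum intensity")

    above = (a > t1) & (b > t2)
    sel_a, sel_b = a[above], b[above]
    if len(sel_a) < 2 or sel_a.std() == 0 or sel_b.std() == 0:
        flags.append("insufficient pixels above thresholds: "
                     "Pearson computed over all pixels")
        sel_a, sel_b = a, b
    r = float(pearsonr(sel_a, sel_b)[0])
    return CostesResult(pearson_r=r, threshold_ch1=float(t1),
                        threshold_ch2=float(t2), regression_slope=slope,
                        regression_intercept=intercept, flags=flags)
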