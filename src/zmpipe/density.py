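"""One-dimensional Gaussian kernel density estimation.

Used both for per-window methylation differences and for transcriptional
fold-change distributions. The bandwidth defaults to Silverman's rule; an
explicit bandwidth admits single-observation input (the density is then a
single Gaussian bump).
"""

from __future__ import annotations

import numpy as np


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 * min(sd, IQR/1.34) * n^-1/5."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("Silverman bandwidth needs at least 2 values")
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("bandwidth undefined for constant input")
    return 0.9 * spread * n ** (-1 / 5)


def gaussian_kde_1d(
    values,
    grid=None,
    bandwidth: float | None = None,
    lo: float = -1.0,
    hi: float = 1.0,
    n_grid: int = 512,
):
    """Evaluate a Gaussian-kernel density on a grid.

    Returns ``(grid, density)``. With no explicit ``bandwidth`` at least two
    values are required (Silverman's rule needs a spread).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("KDE needs at least one value")
    if bandwidth is None:
        h = silverman_bandwidth(values)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return grid, dens
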