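"""Independent oracles used to cross-check the implementation."""

import numpy as np


def grid_hill_rss(doses, response, top=1.0, bottom=0.0,
                  n_ec50=200, h_lo=0.5, h_hi=4.0, h_step=0.05):
    """Best RSS of a Hill curve over an exhaustive (ec50, h) log-grid.

    ec50 spans [min dose / 100, max dose * 100] on 200 log-spaced points; h
    spans [h_lo, h_hi] in h_step increments; top/bottom are held fixed.
    Returns (best_rss, best_ec50, best_h).
    """
    doses = np.asarray(doses, float)
    response = np.asarray(response, float)
    ec50_grid = np.geomspace(doses.min() / 100.0, doses.max() * 100.0, n_ec50)
    h_grid = np.arange(h_lo, h_hi + h_step / 2.0, h_step)
    E, H = np.meshgrid(ec50_grid, h_grid, indexing="ij")
    model = bottom + (top - bottom) / (1.0 + (E[..., None] / doses) ** H[..., None])
    rss = np.sum((model - response) ** 2, axis=-1)
    k = np.unravel_index(np.argmin(rss), rss.shape)
    return float(rss[k]), float(E[k]), float(H[k])


def pearson_direct(x, y):
    """Textbook covariance-formula Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
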