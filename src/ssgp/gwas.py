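"""Window-variance GWAS from posterior draws of marker effects.

For each retained draw, the genetic value of every 1-Mb window is the
centered window genotypes times the window effects; a window's proportion of
genetic variance is its across-animal variance normalized over windows.
Posterior means of the per-draw proportions describe the architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorSummary
from .genotypes import GenotypeMatrix, MarkerMap

__all__ = ["WindowVarianceTable", "window_variance"]

log = logging.getLogger(__name__)


@dataclass
class WindowVarianceTable:
    table: pd.DataFrame  # chrom, start_bp, end_bp, n_markers, mean_prop_var, rank
    window_bp: int
    n_draws_used: int

    def top(self, k: int) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank")


def window_variance(
    chains: PosteriorSummary,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    window_bp: int = 1_000_000,
) -> WindowVarianceTable:
    """Posterior mean proportion of genetic variance per non-overlapping window."""
    draws = chains.alpha_draws
    if draws is None or len(draws) == 0:
        raise ValueError("no retained marker-effect draws; rerun the fit with store_draws")
    if len(marker_map) != genotypes.n_markers:
        raise ValueError("marker map does not cover the genotype matrix")
    if chains.marker_ids is not None and not np.array_equal(
        chains.marker_ids, genotypes.marker_ids
    ):
        raise ValueError("marker order of chains and genotypes differs")

    T = genotypes.codes - genotypes.codes.mean(axis=0, keepdims=True)
    win_start = (marker_map.position_bp // window_bp) * window_bp
    keys = list(zip(marker_map.chromosome.tolist(), win_start.tolist()))
    uniq = sorted(set(keys))
    w_index = {wk: i for i, wk in enumerate(uniq)}
    col_window = np.array([w_index[k] for k in keys])
    n_windows = len(uniq)

    cols_of = [np.flatnonzero(col_window == w) for w in range(n_windows)]
    prop_sum = np.zeros(n_windows)
    used = 0
    for alpha in draws:
        if not np.any(alpha):
            log.warning("all-zero effect draw skipped (window proportions undefined)")
            continue
        var_w = np.zeros(n_windows)
        for w, cols in enumerate(cols_of):
            if len(cols):
                var_w[w] = (T[:, cols] @ alpha[cols]).var()
        total = var_w.sum()
        if total <= 0:
            log.warning("draw with zero genetic variance skipped")
            continue
        prop_sum += var_w / total
        used += 1
    if used == 0:
        raise ValueError("every draw was degenerate; no window variances computed")

    mean_prop = prop_sum / used
    counts = np.bincount(col_window, minlength=n_windows)
    table = pd.DataFrame(
        {
            "chrom": [c for c, _ in uniq],
            "start_bp": [s for _, s in uniq],
            "end_bp": [s + window_bp for _, s in uniq],
            "n_markers": counts,
            "mean_prop_var": mean_prop,
        }
    )
    table["rank"] = table["mean_prop_var"].rank(ascending=False, method="first").astype(int)
    return WindowVarianceTable(table=table, window_bp=window_bp, n_draws_used=used)
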