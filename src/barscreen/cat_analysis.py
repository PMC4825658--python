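"""Concordance-at-the-top (CAT) comparison of two ranked gene lists.

The CAT curve is, per depth d, the proportion of genes shared by the two
lists' top-d sets.  Under the null of no correspondence (two independent
uniform orderings of the same universe) the top-d overlap is hypergeometric
(population G, d successes, d draws), giving an analytic critical band at
any confidence level; a curve escaping the band — above at the top, as for
concordant response profiles — rejects the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class RankedList:
    """Ordered unique gene names, best first."""

    genes: tuple[str, ...]
    key: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("ranked list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_results(cls, results: pd.DataFrame, key: str = "log2FC",
                     absolute: bool = True) -> "RankedList":
        """Rank genes by a results column (|value| descending by default)."""
        col = results[key].abs() if absolute else results[key]
        order = col.sort_values(ascending=False, kind="stable").index
        return cls(genes=tuple(order), key=f"{'|' if absolute else ''}{key}"
                   f"{'|' if absolute else ''} descending")


@dataclass(frozen=True)
class CatCurve:
    depths: np.ndarray
    concordance: np.ndarray
    null_lower: np.ndarray | None = None
    null_upper: np.ndarray | None = None
    level: float | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"depth": self.depths, "concordance": self.concordance}
        if self.null_lower is not None:
            data["null_lower"] = self.null_lower
            data["null_upper"] = self.null_upper
            data["flag"] = np.select(
                [self.concordance > self.null_upper,
                 self.concordance < self.null_lower],
                ["above", "below"], default="inside",
            )
        return pd.DataFrame(data)


def default_depths(universe_size: int, step: int = 10, max_depth: int = 1000
                   ) -> np.ndarray:
    """Depth grid step, 2*step, ... up to min(universe, max_depth), plus G."""
    top = min(universe_size, max_depth)
    depths = list(range(step, top + 1, step))
    if universe_size not in depths:
        depths.append(universe_size)
    return np.array(sorted(set(depths)))


def _check_universe(a: RankedList, b: RankedList) -> int:
    sa, sb = set(a.genes), set(b.genes)
    if sa != sb:
        only_a = sorted(sa - sb)[:10]
        only_b = sorted(sb - sa)[:10]
        raise ValueError(
            f"ranked lists cover different gene universes; e.g. only in "
            f"first: {only_a}, only in second: {only_b}"
        )
    return len(sa)


def cat_curve(a: RankedList, b: RankedList, depths=None) -> CatCurve:
    """Concordance |top_d(A) ∩ top_d(B)| / d at each depth."""
    G = _check_universe(a, b)
    depths = default_depths(G) if depths is None else np.asarray(depths, dtype=int)
    if (depths <= 0).any() or (depths > G).any():
        raise ValueError("depths must lie in [1, universe size]")
    pos_b = {g: i for i, g in enumerate(b.genes)}
    rank_in_b = np.array([pos_b[g] for g in a.genes])
    conc = np.empty(len(depths), dtype=float)
    for i, d in enumerate(depths):
        conc[i] = np.count_nonzero(rank_in_b[:d] < d) / d
    return CatCurve(depths=depths, concordance=conc)


def cat_null_band(
    universe_size: int, depths, level: float = 0.999
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided hypergeometric critical band for the null CAT curve.

    At depth d the null overlap is Hypergeom(M=G, n=d, N=d); the band is
    the central ``level`` probability interval of overlap/d, endpoints at
    the (1-level)/2 and 1-(1-level)/2 quantiles.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    depths = np.asarray(depths, dtype=int)
    if (depths <= 0).any() or (depths > universe_size).any():
        raise ValueError("depths must lie in [1, universe size]")
    alpha = 1.0 - level
    lower = hypergeom.ppf(alpha / 2, universe_size, depths, depths)
    upper = hypergeom.ppf(1 - alpha / 2, universe_size, depths, depths)
    return lower / depths, upper / depths


def cat_compare(
    a: RankedList, b: RankedList, depths=None, level: float = 0.999
) -> tuple[CatCurve, str]:
    """CAT curve with null band and a verdict.

    Verdict is ``"indistinguishable"`` iff no evaluated depth exits the
    band; otherwise the direction(s) of exit are reported (above = more
    concordant than chance, below = anti-concordant).
    """
    G = _check_universe(a, b)
    base = cat_curve(a, b, depths)
    lower, upper = cat_null_band(G, base.depths, level)
    curve = CatCurve(
        depths=base.depths, concordance=base.concordance,
        null_lower=lower, null_upper=upper, level=level,
    )
    above = (curve.concordance > upper).any()
    below = (curve.concordance < lower).any()
    if not above and not below:
        verdict = "indistinguishable"
    elif above and below:
        verdict = "distinguishable (mixed)"
    elif above:
        verdict = "distinguishable (high concordance)"
    else:
        verdict = "distinguishable (low concordance)"
    return curve, verdict
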