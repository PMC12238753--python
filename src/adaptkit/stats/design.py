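"""Sum-coded factorial design matrices (Type III testable parameterization).

Factors are encoded with sum (deviation) contrasts so that each term's
coefficients are orthogonal to the intercept under balance and term tests
correspond to Type III hypotheses.  The builder also encodes arbitrary
factor-level cells into prediction rows, which is what the estimated
marginal means machinery consumes.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd

__all__ = ["FactorDesign"]


class FactorDesign:
    """Full-factorial design over named factors with sum coding.

    Parameters
    ----------
    levels : dict
        factor name -> ordered list of levels (order fixes the coding).
    max_order : int, optional
        Highest interaction order to include (default: all interactions).
    """

    def __init__(self, levels: dict[str, list], max_order: int | None = None):
        self.levels = {f: list(lv) for f, lv in levels.items()}
        for f, lv in self.levels.items():
            if len(lv) < 2:
                raise ValueError(f"factor {f!r} needs >= 2 levels")
        names = list(self.levels)
        order = max_order or len(names)
        self.terms: list[tuple[str, ...]] = []
        for k in range(1, order + 1):
            self.terms.extend(combinations(names, k))
        self.columns: list[str] = ["intercept"]
        self.term_slices: dict[tuple[str, ...], slice] = {}
        pos = 1
        for term in self.terms:
            width = int(np.prod([len(self.levels[f]) - 1 for f in term]))
            self.term_slices[term] = slice(pos, pos + width)
            self.columns.extend(
                ":".join(f"{f}[{i}]" for f, i in zip(term, idx))
                for idx in product(*[range(len(self.levels[f]) - 1) for f in term]))
            pos += width
        self.n_params = pos

    def _factor_codes(self, f: str, values) -> np.ndarray:
        """Sum-coded columns for one factor: (n, k-1)."""
        lv = self.levels[f]
        k = len(lv)
        index = {l: i for i, l in enumerate(lv)}
        out = np.zeros((len(values), k - 1))
        for r, v in enumerate(values):
            try:
                i = index[v]
            except KeyError:
                raise ValueError(f"unknown level {v!r} for factor {f!r}") from None
            if i < k - 1:
                out[r, i] = 1.0
            else:
                out[r, :] = -1.0
        return out

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Model matrix for observed data (one row per observation)."""
        n = len(df)
        codes = {f: self._factor_codes(f, df[f].tolist()) for f in self.levels}
        X = [np.ones((n, 1))]
        for term in self.terms:
            block = codes[term[0]]
            for f in term[1:]:
                # row-wise Kronecker product of the component codings
                block = (block[:, :, None] * codes[f][:, None, :]).reshape(n, -1)
            X.append(block)
        return np.hstack(X)

    def row(self, cell: dict) -> np.ndarray:
        """Prediction row for a single factor-level combination."""
        df = pd.DataFrame({f: [cell[f]] for f in self.levels})
        return self.matrix(df)[0]

    def grid(self) -> pd.DataFrame:
        """All factor-level combinations."""
        names = list(self.levels)
        rows = list(product(*[self.levels[f] for f in names]))
        return pd.DataFrame(rows, columns=names)
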