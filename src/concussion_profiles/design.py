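"""Fixed-effect design matrices: numeric/categorical terms, natural cubic splines, interactions.

Terms are declared as strings:

* ``"x"`` — a numeric column, or a categorical column (dummy coded, first
  level as reference) when the dtype is object/category/bool;
* ``"ns(x, 3)"`` — natural (restricted) cubic spline of ``x`` with 3 basis
  columns, knots at quantiles of the training data;
* ``"a:b"`` — interaction (all pairwise products of the two terms' columns);
* ``"a*b"`` — shorthand for ``a``, ``b`` and ``a:b``.

An intercept column is always included.  Builders are stateful: knots and
category levels are frozen at :meth:`DesignBuilder.fit` so prediction grids
are encoded identically to the training data.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["spline_basis", "natural_spline_knots", "DesignBuilder"]


def natural_spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Knot vector (df + 1 knots) at quantiles of ``x`` for a df-column basis."""
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError(f"spline df must be >= 1, got {df}")
    if not np.isfinite(x).all():
        raise ValueError("spline covariate contains non-finite values")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("spline covariate is constant")
    if df == 1:
        return np.array([lo, hi])
    n_knots = df + 1
    knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_knots)))
    if len(knots) < n_knots:
        # heavy ties (e.g. small-count covariates): fall back to even spacing
        knots = np.unique(np.concatenate([knots, np.linspace(lo, hi, n_knots)]))
        knots = np.quantile(knots, np.linspace(0.0, 1.0, n_knots))
        knots = np.unique(knots)
    if len(knots) < 3:
        raise ValueError(
            f"cannot place {n_knots} distinct spline knots on this covariate"
        )
    return knots


def spline_basis(
    x: np.ndarray, df: int, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis with ``df`` columns (restricted cubic spline).

    Harrell's parameterization: column 1 is ``x`` itself; the remaining
    columns are cubic terms restricted to be linear beyond the boundary knots,
    scaled by the squared knot range for conditioning.  ``df == 1`` degenerates
    to the single linear column.  Returns ``(basis, knots)``; pass the training
    knots back in to encode new data consistently.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = natural_spline_knots(x, df)
    knots = np.asarray(knots, dtype=float)
    if df == 1:
        return x.reshape(-1, 1), knots
    k = len(knots)
    t_k, t_km1 = knots[-1], knots[-2]
    scale = (knots[-1] - knots[0]) ** 2

    def cube(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        t_j = knots[j]
        term = (
            cube(x - t_j)
            - cube(x - t_km1) * (t_k - t_j) / (t_k - t_km1)
            + cube(x - t_k) * (t_km1 - t_j) / (t_k - t_km1)
        ) / scale
        cols.append(term)
    basis = np.column_stack(cols)
    if basis.shape[1] != df:
        raise ValueError(
            f"requested df={df} but knot vector supports {basis.shape[1]} columns"
        )
    return basis, knots


_NS_RE = re.compile(r"^ns\(\s*([A-Za-z_]\w*)\s*,\s*(\d+)\s*\)$")


@dataclass
class _Atom:
    """One multiplicative factor of a term: numeric, categorical or spline."""

    name: str
    kind: str = "auto"  # auto -> numeric/categorical at fit; or "spline"
    df: int = 0
    knots: np.ndarray | None = None
    levels: tuple | None = None

    @classmethod
    def parse(cls, text: str) -> "_Atom":
        text = text.strip()
        m = _NS_RE.match(text)
        if m:
            return cls(name=m.group(1), kind="spline", df=int(m.group(2)))
        if not re.match(r"^[A-Za-z_]\w*$", text):
            raise ValueError(f"cannot parse design term {text!r}")
        return cls(name=text)

    def fit(self, data: pd.DataFrame) -> None:
        if self.name not in data.columns:
            raise ValueError(f"design term references missing column {self.name!r}")
        col = data[self.name]
        if self.kind == "spline":
            _, self.knots = spline_basis(col.to_numpy(float), self.df)
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            self.kind = "categorical"
            self.levels = tuple(sorted(pd.unique(col.astype(str))))
            if len(self.levels) < 2:
                raise ValueError(
                    f"categorical term {self.name!r} has a single level "
                    f"({self.levels}); the effect is inestimable"
                )
        else:
            self.kind = "numeric"

    def transform(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        col = data[self.name]
        if self.kind == "spline":
            x = col.to_numpy(float)
            if x.min() < self.knots[0] or x.max() > self.knots[-1]:
                warnings.warn(
                    f"spline term {self.name!r}: values outside the training "
                    f"range [{self.knots[0]:g}, {self.knots[-1]:g}]; "
                    "linear extrapolation applied",
                    stacklevel=3,
                )
            basis, _ = spline_basis(x, self.df, knots=self.knots)
            names = [f"ns({self.name},{self.df})[{i}]" for i in range(basis.shape[1])]
            return basis, names
        if self.kind == "categorical":
            values = col.astype(str)
            unseen = set(pd.unique(values)) - set(self.levels)
            if unseen:
                raise ValueError(
                    f"categorical term {self.name!r}: unseen level(s) {sorted(unseen)}"
                )
            cols = [
                (values == lev).to_numpy(float) for lev in self.levels[1:]
            ]
            names = [f"{self.name}[{lev}]" for lev in self.levels[1:]]
            return np.column_stack(cols), names
        return col.to_numpy(float).reshape(-1, 1), [self.name]


@dataclass
class _Term:
    atoms: list[_Atom]

    def fit(self, data: pd.DataFrame) -> None:
        for atom in self.atoms:
            atom.fit(data)

    def transform(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        block, names = self.atoms[0].transform(data)
        for atom in self.atoms[1:]:
            other, other_names = atom.transform(data)
            cols, new_names = [], []
            for i in range(block.shape[1]):
                for j in range(other.shape[1]):
                    cols.append(block[:, i] * other[:, j])
                    new_names.append(f"{names[i]}:{other_names[j]}")
            block, names = np.column_stack(cols), new_names
        return block, names


def _expand_terms(terms: Sequence[str]) -> list[str]:
    out: list[str] = []
    for term in terms:
        if "*" in term:
            parts = [p.strip() for p in term.split("*")]
            out.extend(parts)
            out.append(":".join(parts))
        else:
            out.append(term.strip())
    seen: set[str] = set()
    unique = []
    for t in out:
        if t not in seen:
            seen.add(t)
            unique.append(t)
    return unique


class DesignBuilder:
    """Builds a fixed-effect design matrix from term strings; stateful for prediction."""

    def __init__(self, terms: Sequence[str]):
        self.term_strings = _expand_terms(terms)
        self.terms = [
            _Term([_Atom.parse(a) for a in t.split(":")]) for t in self.term_strings
        ]
        self.column_names: list[str] = []
        self.term_slices: dict[str, slice] = {}
        self._fitted = False

    def fit(self, data: pd.DataFrame) -> np.ndarray:
        for term in self.terms:
            term.fit(data)
        self._fitted = True
        return self.transform(data)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("DesignBuilder.transform called before fit")
        blocks = [np.ones((len(data), 1))]
        names = ["Intercept"]
        slices = {"Intercept": slice(0, 1)}
        start = 1
        for term_str, term in zip(self.term_strings, self.terms):
            block, block_names = term.transform(data)
            blocks.append(block)
            names.extend(block_names)
            slices[term_str] = slice(start, start + block.shape[1])
            start += block.shape[1]
        X = np.hstack(blocks)
        self.column_names = names
        self.term_slices = slices
        return X
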