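"""Apomict vs sexual trait-syndrome comparison.

Redundancy analysis (RDA) with a single binary constraint reduces to a
projection of the standardized trait matrix Y onto the centered group
indicator x.  The pseudo-F statistic is

    pseudo-F = (SS_explained / q) / (SS_residual / (n - q - 1)),   q = 1,

with SS taken over all trait columns; for a single trait this is exactly the
classical two-group one-way ANOVA F.  Significance is assessed by Monte
Carlo permutation of the group labels, p = (1 + #{F_perm >= F_obs}) / (1 +
n_perm), so the smallest attainable p is 1/(n_perm + 1).

Univariate summaries in the style of a trait table report group means with
significance stars: a two-sided permutation test on the mean difference for
continuous traits and Fisher's exact test for binary indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTable",
    "RDAResult",
    "rda_pseudo_f",
    "permutation_test",
    "table1_summary",
    "stars",
]


@dataclass
class TraitTable:
    """Species x trait table with a binary reproductive-mode label.

    ``data`` holds one row per species with a ``mode_label`` column; every
    trait column is assigned to exactly one named group (whole-plant, organ,
    clonal, ecological, ...).  Binary columns must be 0/1.
    """

    data: pd.DataFrame
    trait_groups: Mapping[str, str]  # trait name -> group
    mode_column: str = "mode_label"
    apomict_label: str = "apomict"

    def __post_init__(self) -> None:
        if self.mode_column not in self.data.columns:
            raise ValueError(f"missing mode column {self.mode_column!r}")
        if self.data[self.mode_column].isna().any():
            raise ValueError("mode_label must have no missing values")
        missing = [t for t in self.trait_groups if t not in self.data.columns]
        if missing:
            raise ValueError(f"trait columns not in table: {missing}")
        if self.data[self.mode_column].nunique() < 2:
            raise ValueError("both reproductive-mode groups must be present")

    @property
    def traits(self) -> list[str]:
        return list(self.trait_groups)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.trait_groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def group_traits(self, group: str) -> list[str]:
        return [t for t, g in self.trait_groups.items() if g == group]

    def indicator(self) -> np.ndarray:
        return (self.data[self.mode_column] == self.apomict_label).to_numpy(int)

    def matrix(self, traits: Sequence[str] | None = None) -> np.ndarray:
        cols = list(traits) if traits is not None else self.traits
        return self.data[cols].to_numpy(float)

    def is_binary(self, trait: str) -> bool:
        vals = set(pd.unique(self.data[trait].dropna()))
        return vals <= {0, 1, 0.0, 1.0, True, False}


@dataclass(frozen=True)
class RDAResult:
    """Permutation-tested RDA outcome for one trait set."""

    pseudo_F: float
    p_value: float
    variance_explained: float
    n_permutations: int
    rng_seed: int


def _standardize(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant trait column(s) before RDA",
            stacklevel=3,
        )
        Yc, sd = Yc[:, keep], sd[keep]
    if Yc.shape[1] == 0:
        raise ValueError("no non-constant trait columns remain")
    return Yc / sd


def _check_x(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != n:
        raise ValueError("x length must match the number of rows of Y")
    if np.unique(x).size < 2:
        raise ValueError("the binary predictor must contain both groups")
    return x


def _ss_explained(Z: np.ndarray, xc: np.ndarray) -> float:
    # projection of Z onto span(xc): SS = ||xc (xc'Z)/(xc'xc)||^2
    return float(np.sum((xc @ Z) ** 2) / (xc @ xc))


def rda_pseudo_f(Y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and explained-variance proportion of a one-predictor RDA.

    Trait columns are centered and scaled to unit variance (constant columns
    dropped with a warning); the indicator coding of the groups is
    irrelevant because x is centered.  Returns ``(pseudo_F,
    variance_explained)``.
    """
    Z = _standardize(Y)
    n = Z.shape[0]
    if n < 4:
        raise ValueError("at least 4 rows are required")
    x = _check_x(x, n)
    xc = x - x.mean()
    ss_tot = float(np.sum(Z**2))
    ss_exp = _ss_explained(Z, xc)
    ss_res = max(ss_tot - ss_exp, 0.0)
    df_res = n - 2
    f = ss_exp / (ss_res / df_res) if ss_res > 0 else np.inf
    return f, ss_exp / ss_tot


def permutation_test(
    Y: np.ndarray,
    x: np.ndarray,
    n_perm: int = 9999,
    rng_seed: int = 0,
) -> RDAResult:
    """Monte Carlo permutation test of the RDA pseudo-F.

    Rows of ``x`` are permuted ``n_perm`` times; the permutation F-statistics
    are computed in one vectorized pass.  p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) — valid and reproducible for a fixed ``rng_seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful test")
    Z = _standardize(Y)
    n = Z.shape[0]
    x = _check_x(x, n)
    xc = x - x.mean()
    ss_tot = float(np.sum(Z**2))
    xx = float(xc @ xc)
    df_res = n - 2

    def f_of(ss_exp):
        ss_res = np.maximum(ss_tot - ss_exp, 1e-300)
        return ss_exp / (ss_res / df_res)

    ss_obs = _ss_explained(Z, xc)
    f_obs = float(f_of(ss_obs))

    rng = np.random.default_rng(rng_seed)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = rng.permutation(xc)
    ss_perm = np.sum((perms @ Z) ** 2, axis=1) / xx
    f_perm = f_of(ss_perm)
    p = (1 + int(np.sum(f_perm >= f_obs))) / (1 + n_perm)
    return RDAResult(f_obs, p, ss_obs / ss_tot, n_perm, rng_seed)


def stars(p: float) -> str:
    """Significance stars: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if np.isnan(p):
        return "nt"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _perm_mean_diff_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    pooled = np.concatenate([a, b])
    na = a.size
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:na].mean() - pooled[na:].mean()) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def table1_summary(
    table: TraitTable,
    n_perm: int = 999,
    rng_seed: int = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-trait group means/proportions with significance stars.

    Continuous traits get a two-sided permutation test on the mean
    difference; binary traits get Fisher's exact test on the 2x2 incidence
    table.  Traits with fewer than two observations in either group are
    marked not-testable ('nt').  Stars are unadjusted by default; ``holm``
    applies a Holm step-down correction across all testable traits.
    """
    rng = np.random.default_rng(rng_seed)
    apo = table.indicator().astype(bool)
    rows = []
    for trait in table.traits:
        col = table.data[trait].to_numpy(float)
        a, b = col[apo], col[~apo]
        binary = table.is_binary(trait)
        if min(a.size, b.size) < 2:
            p = np.nan
        elif binary:
            tab = [
                [int(a.sum()), int(a.size - a.sum())],
                [int(b.sum()), int(b.size - b.sum())],
            ]
            _, p = stats.fisher_exact(tab)
        else:
            p = _perm_mean_diff_p(a.copy(), b.copy(), n_perm, rng)
        rows.append(
            {
                "trait": trait,
                "group": table.trait_groups[trait],
                "kind": "binary" if binary else "continuous",
                "mean_apomict": a.mean(),
                "mean_sexual": b.mean(),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        mask = out["p_value"].notna()
        p = out.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        out.loc[mask, "p_value"] = adj
    out["significance"] = out["p_value"].map(stars)
    return out
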