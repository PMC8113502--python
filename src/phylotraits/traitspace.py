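"""Trait-space summaries: species means, PCA, and Tukey HSD site contrasts.

The ordination operates on species-mean traits standardized to zero mean and
unit variance across species, i.e. a PCA of the trait correlation matrix.
Site comparisons treat species as the replication unit (one mean per species
per site) to avoid pseudo-replicating individuals, run on log-transformed
values, and are summarized with a compact letter display.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import DesignError, ValidationError
from .io import TRAIT_COLUMNS, TraitTable

__all__ = ["species_means", "pca_traits", "tukey_site_comparison", "PCAResult", "GroupComparison"]


def species_means(table: TraitTable, traits: list[str] | None = None) -> pd.DataFrame:
    """Arithmetic species means per trait on the raw scale.

    Returns a DataFrame indexed by species with a ``site`` column (every
    species belongs to one site) followed by one column per trait.  A species
    with no data at all for a trait yields NaN with a warning.
    """
    traits = traits or list(TRAIT_COLUMNS)
    df = table.data
    site_of = df.groupby("species")["site"].first()
    means = df.groupby("species")[traits].mean()
    empty = means.columns[means.isna().any()]
    for col in empty:
        missing = means.index[means[col].isna()].tolist()
        warnings.warn(
            f"species {missing} have no data for trait {col!r}; excluded as NaN",
            stacklevel=2,
        )
    out = pd.concat([site_of, means], axis=1)
    out.index.name = "species"
    return out


@dataclasses.dataclass
class PCAResult:
    """Eigendecomposition of the trait correlation matrix.

    ``loadings`` (trait x component) holds orthonormal eigenvectors ordered by
    decreasing eigenvalue, with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).  ``scores`` are
    the z-scored species projected onto the components.
    """

    traits: list[str]
    loadings: np.ndarray
    explained: np.ndarray
    scores: pd.DataFrame

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.traits, columns=cols)


def pca_traits(means: pd.DataFrame, traits: list[str] | None = None) -> PCAResult:
    """PCA of species-mean traits on the correlation scale.

    Traits are z-scored across species (mean 0, SD 1) and the correlation
    matrix eigendecomposed, so explained-variance proportions sum to one over
    all components.
    """
    traits = traits or [c for c in means.columns if c in TRAIT_COLUMNS]
    if not traits:
        traits = [c for c in means.columns if c != "site"]
    M = means[traits].to_numpy(dtype=float)
    if M.shape[0] < 3:
        raise DesignError("PCA requires at least 3 species")
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [traits[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant trait column(s) {bad}; PCA undefined")
    Z = (M - M.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (M.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    explained = eigval / eigval.sum()
    scores = pd.DataFrame(
        Z @ eigvec,
        index=means.index,
        columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])],
    )
    if "site" in means.columns:
        scores.insert(0, "site", means["site"].to_numpy())
    return PCAResult(list(traits), eigvec, explained, scores)


@dataclasses.dataclass
class GroupComparison:
    """Tukey HSD site comparison for one trait."""

    trait: str
    group_means: pd.Series  # raw-scale means by site
    pairwise: pd.DataFrame  # (group1, group2, meandiff, p_adj, reject)
    letters: dict[int, str]  # compact letter display

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait,
                "site": self.group_means.index,
                "mean": self.group_means.to_numpy(),
                "letters": [self.letters[s] for s in self.group_means.index],
            }
        )


def _compact_letters(groups: list, pairwise: pd.DataFrame) -> dict:
    """Insert-and-absorb compact letter display at the comparison's alpha.

    Groups sharing a letter are not significantly different.  Deterministic:
    groups are processed in sorted order, letters assigned alphabetically.
    """
    different = {
        frozenset((r["group1"], r["group2"]))
        for _, r in pairwise.iterrows()
        if r["reject"]
    }
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in different for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop sets fully contained in another
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in sorted(s):
            out[g] += letter
    return out


def tukey_site_comparison(
    table: TraitTable, trait: str, alpha: float = 0.05
) -> GroupComparison:
    """Tukey HSD comparison of a trait across sites.

    One log-scale mean per species per site is the replication unit.
    Pairwise p-values use the studentized-range distribution; raw-scale group
    means are reported alongside the letters.
    """
    means = species_means(table, [trait])
    sub = means.dropna(subset=[trait])
    counts = sub.groupby("site").size()
    small = counts[counts < 2]
    if len(counts) < 2 or len(small):
        raise DesignError(
            f"trait {trait!r}: every site needs >=2 species with data "
            f"(counts: {counts.to_dict()})"
        )
    y = np.log(sub[trait].to_numpy(dtype=float))
    g = sub["site"].to_numpy()
    res = pairwise_tukeyhsd(y, g, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = list(itertools.combinations(uniq, 2))
    pw = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject.astype(bool),
        }
    )
    groups = sorted(set(g))
    letters = _compact_letters(groups, pw)
    raw_means = sub.groupby("site")[trait].mean()
    return GroupComparison(trait, raw_means, pw, letters)
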