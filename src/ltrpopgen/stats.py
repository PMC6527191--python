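"""Nonparametric comparison of insertion-time distributions across groups.

Kruskal-Wallis rank ANOVA over cluster / admixed groups, Dunn's post-hoc
pairwise z tests on the joint ranks (tie-corrected, optionally Bonferroni
adjusted), and a compact letter display in which two groups share a letter
iff their pairwise comparison is non-significant at the chosen alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupedAges:
    """Ages (years) per group label (cluster id or "admixed")."""

    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        self.groups = {
            g: [float(v) for v in vals]
            for g, vals in self.groups.items()
            if len(vals) > 0
        }
        for g, vals in self.groups.items():
            if any(v < 0 for v in vals):
                raise ValueError(f"negative age in group {g!r}")

    def summary(self) -> dict[str, tuple[int, float, float]]:
        """Per group: (n, mean, SD with n-1) in the stored units."""
        out = {}
        for g, vals in self.groups.items():
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            out[g] = (len(arr), float(arr.mean()), sd)
        return out


def kruskal_wallis(grouped: GroupedAges) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, degrees of freedom and p-value.

    All-identical observations give H = 0 with a warning (the tie
    correction degenerates).
    """
    samples = list(grouped.groups.values())
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need total N >= 3")
    df = len(samples) - 1
    flat = np.concatenate([np.asarray(s) for s in samples])
    if np.all(flat == flat[0]):
        warnings.warn("all observations identical: H = 0, p = 1")
        return 0.0, df, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), df, float(p)


def dunn_posthoc(
    grouped: GroupedAges, alpha: float = 0.05, bonferroni: bool = False
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's pairwise z tests on the joint ranks.

    z = (Rbar_a - Rbar_b) / sqrt(S2 (1/n_a + 1/n_b)) with S2 the
    tie-corrected rank variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    Returns {(group_a, group_b): (z, p)} with unadjusted p by default.
    """
    labels = list(grouped.groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {g: len(grouped.groups[g]) for g in labels}
    flat = np.concatenate([np.asarray(grouped.groups[g]) for g in labels])
    ranks = sps.rankdata(flat)
    n_total = len(flat)

    mean_rank: dict[str, float] = {}
    pos = 0
    for g in labels:
        n = sizes[g]
        mean_rank[g] = float(ranks[pos:pos + n].mean())
        pos += n

    _, counts = np.unique(flat, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    s2 = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    n_pairs = len(labels) * (len(labels) - 1) // 2
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if s2 <= 0.0:
                z, p = 0.0, 1.0
            else:
                se = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
                z = (mean_rank[a] - mean_rank[b]) / se
                p = 2.0 * sps.norm.sf(abs(z))
                if bonferroni:
                    p = min(1.0, p * n_pairs)
            out[(a, b)] = (float(z), float(p))
    return out


def mean_rank_order(grouped: GroupedAges) -> list[str]:
    """Group labels ordered by mean joint rank (ascending)."""
    labels = list(grouped.groups)
    flat = np.concatenate([np.asarray(grouped.groups[g]) for g in labels])
    ranks = sps.rankdata(flat)
    means, pos = {}, 0
    for g in labels:
        n = len(grouped.groups[g])
        means[g] = float(ranks[pos:pos + n].mean())
        pos += n
    return sorted(labels, key=lambda g: (means[g], g))


@dataclass
class LetterDisplay:
    """Compact letter display: groups sharing a letter do not differ at alpha."""

    letters: dict[str, str]
    alpha: float = 0.05
    order: list[str] = field(default_factory=list)


def letter_display(
    pairwise_p: dict[tuple[str, str], float],
    group_order: list[str] | None = None,
    alpha: float = 0.05,
) -> LetterDisplay:
    """Insert-and-absorb compact letter display from a pairwise p matrix.

    Starts from a single letter spanning all groups; every significant pair
    splits each letter set containing both members into two subsets, and
    redundant (contained) sets are absorbed.  The construction guarantees
    the sharing rule exactly: two groups share >= 1 letter iff their p is
    >= alpha.  Letters are labelled in ``group_order`` (e.g. by mean rank).
    """
    pmat: dict[frozenset[str], float] = {}
    groups: set[str] = set()
    for (a, b), p in pairwise_p.items():
        key = frozenset((a, b))
        if key in pmat and abs(pmat[key] - p) > 1e-12:
            raise ValueError(f"inconsistent p matrix for pair {a!r}, {b!r}")
        pmat[key] = float(p)
        groups.update((a, b))
    order = list(group_order) if group_order is not None else sorted(groups)
    if not groups.issubset(order):
        raise ValueError("group_order inconsistent with the p matrix")
    for a, b in itertools.combinations(order, 2):
        if frozenset((a, b)) not in pmat:
            raise ValueError(f"missing pairwise p for {a!r}, {b!r}")

    sets: list[frozenset[str]] = [frozenset(order)]
    for pair, p in pmat.items():
        if p >= alpha:
            continue
        a, b = tuple(pair)
        new_sets: list[frozenset[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend((s - {a}, s - {b}))
            else:
                new_sets.append(s)
        # absorb sets contained in another; drop duplicates and empties
        sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        sets = list(dict.fromkeys(sets))

    # stable letter order: sets sorted by their earliest group in `order`
    rank = {g: i for i, g in enumerate(order)}
    sets.sort(key=lambda s: sorted(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for idx, s in enumerate(sets):
        lab = alphabet[idx] if idx < 26 else f"l{idx}"
        for g in s:
            letters[g].append(lab)
    display = {g: "".join(v) for g, v in letters.items()}

    for a, b in itertools.combinations(order, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share == (pmat[frozenset((a, b))] < alpha):
            raise RuntimeError(
                f"letter assignment failed the sharing rule for {a!r}, {b!r}"
            )
    return LetterDisplay(letters=display, alpha=alpha, order=order)
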