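"""Model selection over K and consensus across replicate runs.

Three steps downstream of the sampler: (1) the Evanno delta-K statistic
over replicate ln Pr(X|K) values to pick the most probable number of
populations, (2) label-switching alignment of replicate Q matrices by
optimal column assignment (CLUMPP-style), and (3) averaging of the aligned
runs plus classification of each element as admixed (>= cutoff membership
in two or more clusters) or full-membership.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class EvannoTable:
    """Per-K summary of ln Pr(X|K) and the delta-K statistic.

    ``delta_k[K] = |L''(K)| / sd(K)`` with second differences taken on the
    per-K means; defined only at interior K (both neighbours present) and
    when sd(K) > 0.
    """

    k_values: list[int]
    lnp_runs: dict[int, list[float]]
    mean_lnp: dict[int, float]
    sd_lnp: dict[int, float]
    l_prime: dict[int, float]
    l_second: dict[int, float]
    delta_k: dict[int, float]
    selected_k: int


def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> EvannoTable:
    """Compute the Evanno table and select K = argmax delta-K.

    Requires >= 3 consecutive K values with >= 2 runs each.  Interior K
    with zero replicate variance get an undefined delta-K (excluded from
    the argmax with a warning); ties break toward smaller K with a warning.
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3:
        raise ValueError("delta-K needs >= 3 K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("delta-K needs consecutive K values")
    for k in ks:
        if len(lnp_by_k[k]) < 2:
            raise ValueError(f"delta-K needs >= 2 runs per K (K={k})")

    mean_lnp = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd_lnp = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    l_prime = {k: mean_lnp[k] - mean_lnp[k - 1] for k in ks[1:]}
    l_second = {
        k: abs(l_prime[k + 1] - l_prime[k]) for k in ks[1:-1]
    }
    delta_k: dict[int, float] = {}
    for k in ks[1:-1]:
        if sd_lnp[k] == 0.0:
            warnings.warn(
                f"delta-K undefined at K={k}: zero replicate variance"
            )
            continue
        delta_k[k] = l_second[k] / sd_lnp[k]
    if not delta_k:
        raise ValueError(
            "degenerate replicate variance: delta-K undefined at every "
            "interior K"
        )
    best = max(delta_k.values())
    candidates = [k for k, v in delta_k.items() if v == best]
    if len(candidates) > 1:
        warnings.warn(
            f"delta-K tie among K={candidates}; selecting the smallest"
        )
    selected = min(candidates)
    logger.info("delta-K selected K=%d (delta_k=%.3f)", selected, best)
    return EvannoTable(
        k_values=ks,
        lnp_runs={k: list(map(float, lnp_by_k[k])) for k in ks},
        mean_lnp=mean_lnp,
        sd_lnp=sd_lnp,
        l_prime=l_prime,
        l_second=l_second,
        delta_k=delta_k,
        selected_k=selected,
    )


def align_runs(
    q_runs: list[np.ndarray],
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Undo label switching across replicate Q matrices.

    The first run is the reference; every other run receives the column
    permutation minimizing the summed L1 distance to the reference,
    found by optimal assignment on the K x K column-pair cost matrix.
    Returns the permuted runs and the permutation applied to each
    (``perm[k]`` = source column of output column ``k``).
    """
    if not q_runs:
        raise ValueError("no runs to align")
    ref = np.asarray(q_runs[0], dtype=float)
    n, K = ref.shape
    aligned = [ref.copy()]
    perms = [np.arange(K)]
    for q in q_runs[1:]:
        q = np.asarray(q, dtype=float)
        if q.shape != (n, K):
            raise ValueError(
                f"shape mismatch: expected {(n, K)}, got {q.shape}"
            )
        # cost[a, b] = L1 distance between reference column a and run column b
        cost = np.abs(ref[:, :, None] - q[:, None, :]).sum(axis=0)
        _, cols = linear_sum_assignment(cost)
        aligned.append(q[:, cols])
        perms.append(cols)
    return aligned, perms


def align_runs_bruteforce(q_runs: list[np.ndarray]) -> list[np.ndarray]:
    """Exhaustive-permutation alignment; reference oracle for small K."""
    ref = np.asarray(q_runs[0], dtype=float)
    K = ref.shape[1]
    out = [ref.copy()]
    for q in q_runs[1:]:
        q = np.asarray(q, dtype=float)
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(K)):
            c = np.abs(ref - q[:, perm]).sum()
            if c < best_cost - 1e-12:
                best_cost = c
                best = q[:, perm]
        out.append(best)
    return out


@dataclass
class MembershipProfile:
    """Run-averaged memberships with the admixed / full-membership call.

    An element is *admixed* when it holds at least ``cutoff`` membership
    (default 1%, inclusive) in two or more clusters; otherwise it has
    full membership in its single assigned cluster.
    """

    element_ids: list[str]
    q_mean: np.ndarray                 # (N, K), rows sum to 1
    assigned_clusters: list[list[int]]  # 0-based cluster indices, >= cutoff
    classification: list[str]          # "admixed" | "full_membership"
    cutoff: float


def average_and_classify(
    aligned_runs: list[np.ndarray],
    element_ids: list[str],
    cutoff: float = 0.01,
) -> MembershipProfile:
    """Average aligned runs and classify elements by the membership cutoff."""
    if not aligned_runs:
        raise ValueError("need at least one aligned run")
    if not (0.0 < cutoff <= 0.5):
        raise ValueError("cutoff must lie in (0, 0.5]")
    q_mean = np.mean([np.asarray(q, dtype=float) for q in aligned_runs], axis=0)
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    assigned: list[list[int]] = []
    classification: list[str] = []
    for row in q_mean:
        clusters = [k for k, v in enumerate(row) if v >= cutoff]
        if not clusters:  # guard: everything below cutoff, keep the argmax
            clusters = [int(np.argmax(row))]
        assigned.append(clusters)
        classification.append(
            "admixed" if len(clusters) >= 2 else "full_membership"
        )
    return MembershipProfile(
        element_ids=list(element_ids),
        q_mean=q_mean,
        assigned_clusters=assigned,
        classification=classification,
        cutoff=cutoff,
    )
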