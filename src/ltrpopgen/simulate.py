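"""Synthetic data with retained ground truth for parameter-recovery tests.

Three generators mirror the three data modalities of the analysis:

* structured lineages — aligned amino-acid rows drawn from a K-population
  admixture model, with per-population allele-frequency simplices, Dirichlet
  (or one-hot) memberships and independent gap dropout;
* LTR pairs — a random 5' LTR and a copy mutated at a target per-site
  divergence, emulating post-insertion divergence of initially identical
  repeats;
* family sets — groups of sequences mutated from family roots so that
  within-family identity clears the 80-80-80 threshold and between-family
  identity does not.

Every generator is a pure function of its arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AlignedLineage

AA_STATES = "ACDEFGHIKLMNPQRSTVWY*"  # 21 allele states; column index = state
NUC = "ACGT"


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside generated data."""

    true_K: int
    q_true: np.ndarray            # (N, K)
    p_true: np.ndarray            # (K, L, 21)
    alpha_true: float | None
    gap_rate: float
    seed: int
    ltr_divergence: dict[str, float] = field(default_factory=dict)
    family_plan: dict[str, int] = field(default_factory=dict)


def simulate_structured_lineage(
    N: int,
    K: int,
    L: int = 200,
    alpha_true: float | None = None,
    separation: float = 0.9,
    gap_rate: float = 0.02,
    seed: int = 0,
    lineage_name: str = "synthetic",
    n_admixed: int = 0,
    admixed_q: tuple[float, ...] | None = None,
    baseline_support: int = 4,
) -> tuple[AlignedLineage, SyntheticTruth]:
    """Simulate an aligned lineage from a K-population admixture model.

    Each population's allele-frequency simplex at a locus is a mixture
    ``s * onehot(modal_k) + (1 - s) * b_l`` where the modal residues are
    distinct across populations and ``b_l`` is a shared baseline simplex
    supported on a few residues (real alignment columns rarely show more
    than a handful of states).  ``s = 1`` gives population-disjoint modal
    supports; ``s = 0`` gives identical frequencies everywhere.

    Memberships are one-hot (balanced round-robin) when ``alpha_true`` is
    ``None`` (the no-admixture limit), else ``Dirichlet(alpha_true, ...)``.
    The first ``n_admixed`` individuals can instead be given the fixed
    profile ``admixed_q``.  Gaps are inserted independently at ``gap_rate``.
    """
    if N < 2 or K < 1 or L < 1:
        raise ValueError("need N >= 2, K >= 1, L >= 1")
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must lie in [0, 1]")
    if not (0.0 <= gap_rate < 1.0):
        raise ValueError("gap_rate must lie in [0, 1)")
    if n_admixed and (admixed_q is None or len(admixed_q) != K):
        raise ValueError("admixed_q must be a length-K profile")
    rng = np.random.default_rng(seed)

    # population allele frequencies
    p_true = np.zeros((K, L, 21))
    for l in range(L):
        support = rng.choice(21, size=min(baseline_support, 21), replace=False)
        b = np.zeros(21)
        b[support] = rng.dirichlet(np.ones(len(support)))
        modal = rng.choice(21, size=K, replace=False)
        for k in range(K):
            p_true[k, l] = (1.0 - separation) * b
            p_true[k, l, modal[k]] += separation

    # memberships
    q_true = np.zeros((N, K))
    if alpha_true is None:
        for i in range(N):
            q_true[i, i % K] = 1.0
    else:
        q_true[:] = rng.dirichlet(np.full(K, alpha_true), size=N)
    for i in range(n_admixed):
        q_true[i] = np.asarray(admixed_q, dtype=float)

    # sequences: one residue per (i, l) from the mixture, gaps on top
    rows: list[str] = []
    for i in range(N):
        chars = []
        for l in range(L):
            if rng.random() < gap_rate:
                chars.append("-")
                continue
            z = rng.choice(K, p=q_true[i])
            a = rng.choice(21, p=p_true[z, l])
            chars.append(AA_STATES[a])
        rows.append("".join(chars))

    width = len(str(N))
    ids = [f"{lineage_name}_{i + 1:0{width}d}" for i in range(N)]
    aln = AlignedLineage(lineage_name, ids, rows)
    truth = SyntheticTruth(
        true_K=K, q_true=q_true, p_true=p_true,
        alpha_true=alpha_true, gap_rate=gap_rate, seed=seed,
    )
    return aln, truth


def simulate_ltr_pair(
    length: int, target_divergence: float, seed: int = 0
) -> tuple[str, str, float]:
    """Simulate a diverged LTR pair; returns (ltr5, ltr3, realized divergence).

    The 3' LTR is a copy of the random 5' LTR with each site substituted to
    a uniformly chosen different base with probability ``target_divergence``
    (no indels).  Realized divergence is the Hamming fraction.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= target_divergence <= 0.75):
        raise ValueError("target divergence must lie in [0, 0.75]")
    rng = np.random.default_rng(seed)
    ltr5 = rng.integers(0, 4, size=length)
    hit = rng.random(length) < target_divergence
    shift = rng.integers(1, 4, size=length)
    ltr3 = np.where(hit, (ltr5 + shift) % 4, ltr5)
    realized = float(np.mean(ltr5 != ltr3))
    to_s = np.array(list(NUC))
    return "".join(to_s[ltr5]), "".join(to_s[ltr3]), realized


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, size=len(seq))
    return np.where(hit, (seq + shift) % 4, seq)


def simulate_family_set(
    n_families: int,
    members_per_family: int,
    within_identity: float = 0.95,
    between_identity: float = 0.5,
    length: int = 500,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Simulate RT nucleotide sequences with planned family structure.

    One random root per family, mutually diverged to the between-family
    identity target; members are the root mutated to the within-family
    target.  Returns ``(sequences by id, planned family index by id)``.
    """
    if not (within_identity > 0.8 > between_identity):
        raise ValueError(
            "inconsistent identity ordering: need within > 0.8 > between"
        )
    if length < 80:
        raise ValueError("length must be >= 80 bp for the 80-80-80 rule")
    if n_families < 1 or members_per_family < 1:
        raise ValueError("need >= 1 family and >= 1 member per family")
    rng = np.random.default_rng(seed)
    to_s = np.array(list(NUC))
    base = rng.integers(0, 4, size=length)
    seqs: dict[str, str] = {}
    plan: dict[str, int] = {}
    for f in range(n_families):
        root = base if f == 0 else _mutate(base, 1.0 - between_identity, rng)
        for j in range(members_per_family):
            member = _mutate(root, 1.0 - within_identity, rng)
            sid = f"fam{f}_mem{j}"
            seqs[sid] = "".join(to_s[member])
            plan[sid] = f
    return seqs, plan
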