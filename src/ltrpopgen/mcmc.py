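"""Bayesian admixture-model MCMC on multilocus genotype matrices.

The model is the classic model-based clustering of individuals into K
populations from multilocus genotypes: each individual i carries a
membership simplex q_i (admixture proportions), each population k holds a
per-locus allele-frequency simplex p_kl, and each allele copy originates
from population k with probability q_ik.  Inference is by Gibbs sampling
over the latent origins Z, Q and P, with Metropolis steps for the admixture
concentration alpha and, under the correlated-frequency prior ("F-model"),
the per-population drift parameters F_k and the ancestral frequencies.

Every element is coded as a homozygous diploid (two identical allele
copies per locus), so the sampler draws two independent origins per
non-missing site.  Missing sites contribute nothing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._gibbs import gibbs_kernel
from .encoding import MISSING, N_ALLELE_STATES, GenotypeMatrix, compact_allele_coding

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Sampler settings.

    ``frequency_model`` selects the prior on population allele frequencies:
    ``"correlated"`` ties the populations to a shared ancestral pool through
    drift parameters F_k (appropriate for closely related populations),
    ``"independent"`` gives each population its own Dirichlet(lambda) prior.
    Defaults for the F-model hyperpriors and proposal widths mirror the
    documented defaults of the original clustering program.
    """

    K: int
    burn_in: int = 5_000
    iterations: int = 10_000
    frequency_model: str = "correlated"
    lam: float = 1.0
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.025
    infer_alpha: bool = True
    f_prior_mean: float = 0.01
    f_prior_sd: float = 0.05
    f_proposal_sd: float = 0.05
    pa_proposal_step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in <= 0 or self.iterations <= 0:
            raise ValueError("burn_in and iterations must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (0.0 < self.f_prior_mean < 1.0):
            raise ValueError("F prior mean must lie in (0, 1)")
        if self.frequency_model not in ("correlated", "independent"):
            raise ValueError(
                f"unknown frequency model {self.frequency_model!r}"
            )

    @property
    def f_gamma_shape(self) -> float:
        return (self.f_prior_mean / self.f_prior_sd) ** 2

    @property
    def f_gamma_rate(self) -> float:
        return self.f_prior_mean / self.f_prior_sd**2


@dataclass
class LatentState:
    """One full state of the sampler, for likelihood evaluation.

    ``Z[i, l, c]`` is the population of origin of allele copy ``c`` (0-based
    population index, -1 at missing sites); ``P[k, l, a]`` is indexed by
    allele code ``a+1`` on the 1..21 code scale.
    """

    Z: np.ndarray  # (N, L, 2) int
    Q: np.ndarray  # (N, K)
    P: np.ndarray  # (K, L, 21)
    alpha: float = 1.0

    def validate(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        psums = self.P.sum(axis=2)
        if not np.allclose(psums[psums > 0], 1.0, atol=1e-9):
            raise ValueError("each nonempty p_kl must sum to 1")


@dataclass
class MCMCRun:
    """Posterior summaries of one sampler run."""

    config: ModelConfig
    element_ids: list[str]
    locus_columns: list[int]
    q_mean: np.ndarray          # (N, K)
    p_mean: np.ndarray          # (K, L, 21), allele-code indexed
    f_mean: np.ndarray          # (K,)
    alpha_mean: float
    alpha_sd: float
    loglik_trace: np.ndarray    # (iterations,)
    ln_prob_data: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loglik_trace)):
            raise ValueError("non-finite log-likelihood trace (sampler bug)")
        if not np.allclose(self.q_mean.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("posterior-mean Q rows must sum to 1")


def run_mcmc(gm: GenotypeMatrix, cfg: ModelConfig) -> MCMCRun:
    """Run the admixture Gibbs sampler on a genotype matrix.

    Returns posterior means accumulated after burn-in, the complete-data
    log-likelihood trace, and the ln Pr(X|K) estimate used for model
    selection.
    """
    if gm.n_loci < 1:
        raise ValueError("genotype matrix has no loci")
    X, J, code_maps = compact_allele_coding(gm)
    logger.info(
        "MCMC: N=%d L=%d K=%d model=%s burn_in=%d iterations=%d seed=%d",
        gm.n_elements, gm.n_loci, cfg.K, cfg.frequency_model,
        cfg.burn_in, cfg.iterations, cfg.seed,
    )
    q_mean, p_dense, loglik, alpha_trace, f_mean = gibbs_kernel(
        np.ascontiguousarray(X.T), J, cfg.K, cfg.burn_in, cfg.iterations, cfg.lam,
        cfg.alpha_init, cfg.alpha_max, cfg.alpha_proposal_sd,
        cfg.infer_alpha, cfg.frequency_model == "correlated",
        cfg.f_gamma_shape, cfg.f_gamma_rate, cfg.f_proposal_sd,
        cfg.pa_proposal_step, np.uint64(cfg.seed),
    )
    if not np.all(np.isfinite(loglik)):
        raise RuntimeError("non-finite likelihood encountered (sampler bug)")
    # renormalize against accumulated rounding
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)

    # map dense per-locus allele indices back to the 1..21 code space
    L = gm.n_loci
    p_mean = np.zeros((cfg.K, L, N_ALLELE_STATES))
    for l, codes in enumerate(code_maps):
        for j, code in enumerate(codes):
            p_mean[:, l, int(code) - 1] = p_dense[l, j, :]

    return MCMCRun(
        config=cfg,
        element_ids=list(gm.element_ids),
        locus_columns=list(gm.locus_columns),
        q_mean=q_mean,
        p_mean=p_mean,
        f_mean=f_mean,
        alpha_mean=float(np.mean(alpha_trace)),
        alpha_sd=float(np.std(alpha_trace, ddof=1)) if len(alpha_trace) > 1 else 0.0,
        loglik_trace=loglik,
        ln_prob_data=estimate_ln_prob_data(loglik),
        seed=cfg.seed,
    )


def complete_data_loglik(gm: GenotypeMatrix, state: LatentState) -> float:
    """ln P(X | Z, P) under homozygous-diploid coding.

    Sums ``ln p_{z,l,x}`` over both allele copies of every non-missing site
    (``2 * ln p`` when the copies share an origin).  A zero-probability
    observed allele yields -inf with a warning.
    """
    N, L = gm.codes.shape
    if state.Z.shape != (N, L, 2):
        raise ValueError("Z shape inconsistent with genotype matrix")
    ll = 0.0
    for i in range(N):
        for l in range(L):
            x = gm.codes[i, l]
            if x == MISSING:
                continue
            for c in range(2):
                z = state.Z[i, l, c]
                p = state.P[z, l, int(x) - 1]
                if p <= 0.0:
                    warnings.warn(
                        "observed allele has zero probability in its "
                        "assigned population; log-likelihood is -inf"
                    )
                    return -math.inf
                ll += math.log(p)
    return ll


def estimate_ln_prob_data(loglik_trace: np.ndarray) -> float:
    """Estimate ln Pr(X|K) as mean(trace) - var(trace)/2.

    The standard harmonic-style estimator of the clustering program,
    assuming an approximately normal log-likelihood at stationarity;
    the sample variance uses n-1.
    """
    trace = np.asarray(loglik_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("ln Pr(X|K) estimation needs a trace of length >= 2")
    return float(np.mean(trace) - np.var(trace, ddof=1) / 2.0)
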