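"""Randomization test for the significance of pairwise correlations.

The null model destroys inter-column dependence while preserving each
column's composition: both columns are independently permuted, the
statistic is recomputed, and a small number of such draws (25 by default)
is summarized by a Gumbel extreme-value model fitted by the method of
moments,

    beta = sigma * sqrt(6) / pi,        mu = mean - gamma * beta,

with gamma the Euler–Mascheroni constant. A Bonferroni-corrected cut-off
for N = L(L+1)/2 tests converts a target p-value into a threshold on the
observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gumbel_r

from .alignment_io import Alignment
from .alphabet import N_PAIR_STATES
from .entropy_core import u_vne_value
from .errors import DegenerateColumnError, DegenerateNullError
from .pair_similarity import SimilarityMatrix

#: Euler–Mascheroni constant.
EULER_GAMMA = float(np.euler_gamma)


@dataclass
class GumbelModel:
    """Method-of-moments Gumbel fit of a null sample."""

    mu: float
    beta: float
    mean: float
    std: float
    n_samples: int

    def __post_init__(self):
        if self.beta <= 0:
            raise DegenerateNullError("Gumbel scale must be positive")
        if self.n_samples < 2:
            raise ValueError("a Gumbel fit requires at least 2 samples")


@dataclass
class PairCorrelation:
    """Observed statistic, null model and significance call for one pair."""

    k: int
    l: int
    statistic: float
    mode: str
    null: GumbelModel | None
    p_value: float
    cutoff: float | None
    significant: bool
    n_tests: int
    degenerate: bool = False


def fit_gumbel(samples) -> GumbelModel:
    """Fit Gumbel location/scale from sample mean and standard deviation.

    The sample standard deviation uses the n-1 denominator. A sample with
    zero spread admits no extreme-value model and raises
    :class:`DegenerateNullError`.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    std = float(x.std(ddof=1))
    if std == 0.0:
        raise DegenerateNullError("all null samples identical")
    mean = float(x.mean())
    beta = std * np.sqrt(6.0) / np.pi
    mu = mean - EULER_GAMMA * beta
    return GumbelModel(mu=mu, beta=beta, mean=mean, std=std, n_samples=x.size)


def gumbel_cdf(x: float, model: GumbelModel) -> float:
    """F(x) = exp(-exp(-(x - mu)/beta))."""
    return float(gumbel_r.cdf(x, loc=model.mu, scale=model.beta))


def bonferroni_cutoff(model: GumbelModel, p: float, n_tests: int) -> float:
    """Statistic threshold whose tail probability is p / n_tests.

    c_o = mu - beta * ln ln(1 / (1 - p/N)) solves 1 - F(c_o) = p/N.
    """
    frac = p / n_tests
    if not 0.0 < frac < 1.0:
        raise ValueError("p / n_tests must lie in (0, 1)")
    return model.mu - model.beta * np.log(np.log(1.0 / (1.0 - frac)))


def pair_rng(seed: int, k: int, l: int) -> np.random.Generator:
    """Deterministic per-pair random stream derived from (seed, k, l).

    Makes results independent of pair-evaluation order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k), int(l)]))


def _statistic_from_codes(ck: np.ndarray, cl: np.ndarray,
                          a_values: np.ndarray, mode: str) -> float:
    valid = (ck >= 0) & (cl >= 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateColumnError("no canonical residue pair in these columns")
    codes = 20 * ck[valid].astype(np.int64) + cl[valid]
    counts = np.bincount(codes, minlength=N_PAIR_STATES)
    p = counts / n_valid
    if mode == "vne":
        return u_vne_value(p, a_values)
    # Shannon baseline: 2 (H(k)+H(l)-H(k,l)) / (H(k)+H(l))
    joint = p.reshape(20, 20)

    def _h(q):
        nz = q[q > 0]
        return float(-(nz * np.log(nz)).sum())

    h_k, h_l = _h(joint.sum(axis=1)), _h(joint.sum(axis=0))
    if h_k + h_l == 0.0:
        return 0.0
    return 2.0 * (h_k + h_l - _h(p)) / (h_k + h_l)


def shuffled_statistic(aln: Alignment, k: int, l: int, A: SimilarityMatrix,
                       rng: np.random.Generator, mode: str = "vne") -> float:
    """Statistic of 1-based columns k, l after independent column shuffles.

    Each column's content is permuted by a fresh uniform permutation, so
    single-column compositions (and entropies) are preserved while the
    pairing is randomized. The input alignment is not modified.
    """
    enc = aln.encoded()
    ck = rng.permutation(enc[:, k - 1])
    cl = rng.permutation(enc[:, l - 1])
    return _statistic_from_codes(ck, cl, A.values, mode)


def observed_statistic(aln: Alignment, k: int, l: int, A: SimilarityMatrix,
                       mode: str = "vne") -> float:
    """Statistic of the unaltered pairing of 1-based columns k, l."""
    enc = aln.encoded()
    return _statistic_from_codes(enc[:, k - 1], enc[:, l - 1], A.values, mode)


def assess_pair(aln: Alignment, k: int, l: int, A: SimilarityMatrix,
                p: float = 1e-4, n_samples: int = 25,
                rng: np.random.Generator | None = None,
                seed: int | None = None, mode: str = "vne") -> PairCorrelation:
    """Full significance assessment of one column pair.

    Draws ``n_samples`` shuffled statistics, fits the Gumbel null, and
    reports the per-pair p-value 1 - F(observed) together with the
    Bonferroni-corrected cut-off at target ``p`` over N = L(L+1)/2 tests.
    A null without variance (e.g. a conserved column) is reported as
    non-significant with p-value 1.
    """
    if rng is None:
        if seed is None:
            raise ValueError("provide either rng or seed")
        rng = pair_rng(seed, k, l)
    A.validate()
    observed = observed_statistic(aln, k, l, A, mode)
    samples = np.array([
        shuffled_statistic(aln, k, l, A, rng, mode) for _ in range(n_samples)
    ])
    n_tests = aln.L * (aln.L + 1) // 2
    try:
        model = fit_gumbel(samples)
    except DegenerateNullError:
        return PairCorrelation(
            k=k, l=l, statistic=observed, mode=mode, null=None,
            p_value=1.0, cutoff=None, significant=False,
            n_tests=n_tests, degenerate=True,
        )
    cutoff = bonferroni_cutoff(model, p, n_tests)
    return PairCorrelation(
        k=k, l=l, statistic=observed, mode=mode, null=model,
        p_value=1.0 - gumbel_cdf(observed, model),
        cutoff=cutoff, significant=bool(observed >= cutoff),
        n_tests=n_tests,
    )
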