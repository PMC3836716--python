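"""Permutation-based pathway weight tuning.

Under a permuted (null) phenotype an unbiased model should give every
pathway the same chance of being the first to enter as the penalty is
relaxed from ``lambda_max``.  Differences in pathway size, LD and overlap
break this.  The tuner measures the empirical first-entry distribution over
``Q`` phenotype permutations (phenotype, not genotype, labels are shuffled
so LD structure is preserved) and rescales the weights until the
distribution is uniform within tolerance.

The multiplicative update is ``w_l <- w_l * (1 + eta * L * delta_l)^2``
with ``delta_l = rho_l - 1/L``: a pathway never selected under the null
(``delta_l = -1/L``) is shrunk by at most ``(1 - eta)^2`` per iteration,
over-selected pathways are up-weighted, and the square makes large
deviations move faster.  The rule is isolated in :func:`weight_update` so
an alternative adjustment can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sgl import SGLConfig, SGLProblem, _entry_lambda_from_scores

__all__ = [
    "NullSelectionDistribution",
    "WeightTuningState",
    "first_selected_pathway",
    "null_first_selection",
    "tune_weights",
    "weight_update",
]


@dataclass
class NullSelectionDistribution:
    """First-entry frequencies over Q phenotype permutations."""

    rho: np.ndarray
    Q: int
    seed: int

    def __post_init__(self) -> None:
        if (self.rho < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if abs(self.rho.sum() - 1.0) > 1e-9:
            raise ValueError("each permutation selects exactly one first pathway")

    @property
    def max_deviation(self) -> float:
        L = self.rho.size
        return float(np.max(np.abs(self.rho - 1.0 / L)))


@dataclass
class WeightTuningState:
    """Weights and convergence diagnostics of the tuning loop."""

    weights: np.ndarray
    n_iter: int
    delta_max_trace: list[float] = field(default_factory=list)
    converged: bool = False
    eta: float = 0.3
    eps: float = 0.02
    final_rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.weights > 0).all():
            raise ValueError("weights must remain strictly positive")


def _entry_values(
    problem: SGLProblem, config: SGLConfig, y: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    c = problem.X.T @ y
    return np.array(
        [
            _entry_lambda_from_scores(np.abs(c[g]), config.alpha, weights[l])
            for l, g in enumerate(problem.pathways.groups)
        ]
    )


def first_selected_pathway(
    problem: SGLProblem, config: SGLConfig, permuted_y: np.ndarray
) -> int:
    """Index of the pathway that enters first as lambda decreases.

    The first pathway to enter is the one with the largest entry value
    against the (permuted) response; entry values are compared directly, so
    the result does not depend on any final lambda choice.  Ties break to
    the smallest index.
    """
    vals = _entry_values(problem, config, permuted_y, problem.pathways.weights)
    return int(np.argmax(vals))


def null_first_selection(
    problem: SGLProblem,
    config: SGLConfig,
    Q: int = 200,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> NullSelectionDistribution:
    """First-entry distribution over Q uniform phenotype permutations."""
    if Q <= 0:
        raise ValueError("Q must be positive")
    rng = np.random.default_rng(seed)
    w = problem.pathways.weights if weights is None else np.asarray(weights, float)
    counts = np.zeros(problem.pathways.n_pathways)
    for _ in range(Q):
        y_perm = problem.y[rng.permutation(problem.n_samples)]
        vals = _entry_values(problem, config, y_perm, w)
        counts[int(np.argmax(vals))] += 1
    return NullSelectionDistribution(counts / Q, Q, seed)


def weight_update(weights: np.ndarray, rho: np.ndarray, eta: float) -> np.ndarray:
    """One multiplicative adjustment step toward a uniform null distribution."""
    L = weights.size
    delta = rho - 1.0 / L
    return weights * (1.0 + eta * L * delta) ** 2


def tune_weights(
    problem: SGLProblem,
    config: SGLConfig,
    Q: int = 200,
    eta: float = 0.3,
    eps: float = 0.02,
    max_iter: int = 50,
    seed: int = 0,
) -> WeightTuningState:
    """Iteratively rescale pathway weights until null first-entry is uniform.

    Stops when the maximum deviation from 1/L drops to ``eps`` or after
    ``max_iter`` iterations; aborts if the deviation increases for five
    consecutive iterations (divergence guard).
    """
    if not (0 < eta < 1):
        raise ValueError("eta must lie in (0, 1)")
    if eps <= 0:
        raise ValueError("eps must be positive")
    w = problem.pathways.weights.astype(float).copy()
    trace: list[float] = []
    rho = None
    rising = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = null_first_selection(
            problem, config, Q=Q, seed=seed + it, weights=w
        )
        rho = dist.rho
        dmax = dist.max_deviation
        if trace and dmax > trace[-1]:
            rising += 1
            if rising >= 5:
                raise RuntimeError(
                    "weight tuning diverging: max deviation increased for 5 "
                    f"consecutive iterations (last {dmax:.4f})"
                )
        else:
            rising = 0
        trace.append(dmax)
        if dmax <= eps:
            converged = True
            break
        w = weight_update(w, rho, eta)
    return WeightTuningState(
        weights=w,
        n_iter=it,
        delta_max_trace=trace,
        converged=converged,
        eta=eta,
        eps=eps,
        final_rho=rho,
    )
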