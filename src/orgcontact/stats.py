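"""Permutation tests, bootstrap confidence intervals, frequency distributions.

The inference layer matches how per-organelle metrics are compared between
conditions: per-object values are pooled from the cells of each condition
group, an observed statistic (default: difference of means) is computed, and
group labels are permuted — at the object level by default, or at the cell
level to respect within-cell correlation — to build the null. The empirical
p-value uses the add-one correction

    p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1),

two-sided by default, so p is never 0 and is bounded below by 1/(n_perm+1).
Effect sizes are summarized with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GroupedSamples",
    "PermutationResult",
    "BootstrapCI",
    "permutation_test",
    "bootstrap_ci",
    "freq_distribution",
]


@dataclass
class GroupedSamples:
    """Per-object metric values for one condition, organized by cell."""

    condition: str
    cells: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"condition {self.condition!r} has no cells")
        self.cells = [np.asarray(c, dtype=float) for c in self.cells]
        if any(len(c) == 0 for c in self.cells):
            raise ValueError(f"condition {self.condition!r} has an empty cell")

    @classmethod
    def from_values(cls, condition: str, values) -> "GroupedSamples":
        """Wrap a flat value array as a single-cell group."""
        return cls(condition, [np.asarray(values, dtype=float)])

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.cells)


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    alternative: str
    unit: str
    seed: int | None = None


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int | None = None


def _diff_of_means(x: np.ndarray, y: np.ndarray) -> float:
    return float(x.mean() - y.mean())


def permutation_test(
    a: GroupedSamples | Sequence[float],
    b: GroupedSamples | Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] = _diff_of_means,
    n_perm: int = 100_000,
    unit: str = "object",
    alternative: str = "two-sided",
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test between two condition groups.

    Values are pooled within each group; the observed statistic is computed
    on the pooled samples and compared with ``n_perm`` random relabelings.
    ``unit='object'`` permutes individual values; ``unit='cell'`` permutes
    whole cells between the groups, preserving within-cell correlation.
    ``alternative`` is ``two-sided`` (|T|), ``greater`` or ``less``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if not isinstance(a, GroupedSamples):
        a = GroupedSamples.from_values("a", a)
    if not isinstance(b, GroupedSamples):
        b = GroupedSamples.from_values("b", b)

    if statistic is _diff_of_means and unit == "object":
        return permutation_test_mean_diff(
            a, b, n_perm=n_perm, seed=seed, alternative=alternative
        )

    rng = np.random.default_rng(seed)
    obs = statistic(a.pooled(), b.pooled())

    if unit == "object":
        pooled = np.concatenate([a.pooled(), b.pooled()])
        n_a = len(a.pooled())
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t = statistic(perm[:n_a], perm[n_a:])
            exceed += _exceeds(t, obs, alternative)
    elif unit == "cell":
        cells = a.cells + b.cells
        n_cells_a = len(a.cells)
        idx = np.arange(len(cells))
        exceed = 0
        for _ in range(n_perm):
            rng.shuffle(idx)
            xa = np.concatenate([cells[i] for i in idx[:n_cells_a]])
            xb = np.concatenate([cells[i] for i in idx[n_cells_a:]])
            t = statistic(xa, xb)
            exceed += _exceeds(t, obs, alternative)
    else:
        raise ValueError(f"unit must be 'object' or 'cell', got {unit!r}")

    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed=obs,
        n_perm=n_perm,
        p_value=float(p),
        alternative=alternative,
        unit=unit,
        seed=seed,
    )


def _exceeds(t: float, obs: float, alternative: str) -> bool:
    if alternative == "two-sided":
        return abs(t) >= abs(obs)
    if alternative == "greater":
        return t >= obs
    return t <= obs


def permutation_test_mean_diff(
    a, b, n_perm: int = 100_000, seed: int | None = None, **kw
) -> PermutationResult:
    """Vectorized object-level difference-of-means permutation test.

    Semantics identical to :func:`permutation_test` with the default
    statistic and ``unit='object'``, but permutations are drawn in batches,
    which matters at n_perm = 1e5 on large pooled samples.
    """
    if not isinstance(a, GroupedSamples):
        a = GroupedSamples.from_values("a", a)
    if not isinstance(b, GroupedSamples):
        b = GroupedSamples.from_values("b", b)
    alternative = kw.pop("alternative", "two-sided")
    if kw:
        raise TypeError(f"unexpected arguments {sorted(kw)}")
    xa, xb = a.pooled(), b.pooled()
    pooled = np.concatenate([xa, xb])
    n_a, n = len(xa), len(pooled)
    obs = float(xa.mean() - xb.mean())
    total = pooled.sum()
    rng = np.random.default_rng(seed)

    exceed = 0
    batch = max(1, min(n_perm, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        keys = rng.random((m, n))
        order = np.argsort(keys, axis=1)[:, :n_a]
        sums_a = pooled[order].sum(axis=1)
        t = sums_a / n_a - (total - sums_a) / (n - n_a)
        if alternative == "two-sided":
            exceed += int((np.abs(t) >= abs(obs)).sum())
        elif alternative == "greater":
            exceed += int((t >= obs).sum())
        else:
            exceed += int((t <= obs).sum())
        done += m
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed=obs,
        n_perm=n_perm,
        p_value=float(p),
        alternative=alternative,
        unit="object",
        seed=seed,
    )


def bootstrap_ci(
    values,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 20,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap confidence interval.

    Resamples with replacement ``n_boot`` times and takes the percentile
    interval at (1 ± level)/2 with linear interpolation across the ordered
    replicate statistics. The default ``n_boot=20`` mirrors the effect-size
    summaries this layer was built for, but is coarse for percentile CIs;
    raise it (>= 1000) when the interval itself is the inference target.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap_ci requires at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    if statistic is np.mean:
        replicates = values[idx].mean(axis=1)
    else:
        replicates = np.apply_along_axis(statistic, 1, values[idx])
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(replicates, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        estimate=float(statistic(values)),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def freq_distribution(values, bin_edges) -> dict:
    """Histogram with half-open bins [e_i, e_{i+1}), last bin closed.

    Returns counts and relative frequencies (counts / number of values);
    frequencies sum to 1 when every value falls in range. Edges must be
    strictly increasing.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    values = np.asarray(values, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    n = len(values)
    freqs = counts / n if n else np.zeros_like(counts, dtype=float)
    return {"bin_edges": edges, "counts": counts, "frequencies": freqs}
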