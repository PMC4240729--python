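"""Monte-Carlo experiments on uniformly random genomes.

For two independent uniform random genomes of length n, the number of
shared adjacencies eps_n = |A(x) & A(y)| has mean and variance both close
to 2 for large n, so the bp distance concentrates near its maximum n-1.
Consequences checked here by simulation:

* *moments*: sample mean/variance of eps_n (and of d) against the
  asymptotic value 2;
* *epsilon convergence*: eps_n / a_n -> 0 in probability for any
  divergent sequence a_n;
* *median gap*: for k random genomes the gap
  e* = (k-1)(n-1) - median_value obeys 0 <= e* <= C(k,2) * alpha on every
  sample, where alpha is the largest pairwise eps — a deterministic bound,
  checked replicate by replicate with the exact brute-force median;
* *accessible distance*: every class accessible from k random genomes has
  total distance within C(k,2) * alpha of (k-1)(n-1), again deterministic
  per sample.

Uniform sampling on classes is the push-forward of uniform sampling on
permutations (both orientations are equally likely, fibers have size 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import _classtable as ct
from .genome_core import (
    ENUMERATION_CAP,
    GenomeClass,
    Permutation,
    ResourceLimitError,
    class_of,
)
from .median import _patch_closure

__all__ = [
    "A_N_CHOICES",
    "SimConfig",
    "SimReport",
    "sample_permutation",
    "sample_class",
    "distance_moments",
    "epsilon_convergence",
    "median_gap_experiment",
    "accessible_distance_experiment",
]

#: Named divergent rescaling sequences a_n.  Anything registered here must
#: be positive and diverge as n -> infinity (a bounded choice would make
#: the eps_n / a_n -> 0 statements false, so none is offered).
A_N_CHOICES: dict[str, Callable[[float], float]] = {
    "sqrt": lambda n: math.sqrt(n),
    "log": lambda n: math.log(n + 1.0),
    "linear": lambda n: float(n),
}

_CHUNK = 1000  # replicates drawn per RNG stream in vectorized experiments


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one Monte-Carlo experiment."""

    n: int
    reps: int
    seed: int
    k: int = 2
    a_n: str | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"need n >= 2, got n={self.n}")
        if self.reps < 1:
            raise ValueError(f"need reps >= 1, got {self.reps}")
        if self.k < 2:
            raise ValueError(f"need k >= 2, got k={self.k}")
        if self.a_n is not None and self.a_n not in A_N_CHOICES:
            raise ValueError(
                f"a_n must be one of {sorted(A_N_CHOICES)} (all divergent); "
                f"got {self.a_n!r}"
            )

    def a_n_func(self) -> Callable[[float], float]:
        if self.a_n is None:
            raise ValueError("no a_n sequence configured")
        return A_N_CHOICES[self.a_n]


@dataclass(frozen=True)
class SimReport:
    """Tidy result of a Monte-Carlo experiment.

    ``statistics`` holds the scalar summaries; ``replicates`` one row per
    replicate (or per grid point) for downstream analysis.
    """

    experiment: str
    config: SimConfig
    statistics: dict[str, float]
    replicates: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def summary(self) -> dict:
        out = {
            "experiment": self.experiment,
            "n": self.config.n,
            "k": self.config.k,
            "reps": self.config.reps,
            "seed": self.config.seed,
        }
        if self.config.a_n is not None:
            out["a_n"] = self.config.a_n
        out.update(self.statistics)
        return out


def sample_permutation(n: int, rng: np.random.Generator) -> Permutation:
    """One uniform random genome of length n."""
    return Permutation(rng.permutation(n) + 1)


def sample_class(n: int, rng: np.random.Generator) -> GenomeClass:
    """One uniform random genome class (push-forward of uniform on S_n)."""
    return class_of(sample_permutation(n, rng))


def _eps_block(n: int, m: int, rng: np.random.Generator, identity_ref: bool) -> np.ndarray:
    """eps for m independent pairs, vectorized.

    With an identity reference, eps counts positions where consecutive
    entries of a random permutation differ by exactly 1.  For two random
    genomes, relabelling through the first one reduces to the same count
    (bp distance is invariant under composition), and the relabelled
    genome is again uniform.
    """
    P = rng.permuted(np.tile(np.arange(1, n + 1, dtype=np.int32), (m, 1)), axis=1)
    if not identity_ref:
        X = rng.permuted(np.tile(np.arange(n, dtype=np.int32), (m, 1)), axis=1)
        pos = np.argsort(X, axis=1)  # position of each gene in x
        P = np.take_along_axis(pos, P - 1, axis=1)
    return (np.abs(np.diff(P, axis=1)) == 1).sum(axis=1)


def _eps_samples(
    n: int, reps: int, seed_seq: np.random.SeedSequence, identity_ref: bool
) -> np.ndarray:
    out = np.empty(reps, dtype=np.int64)
    n_chunks = (reps + _CHUNK - 1) // _CHUNK
    streams = seed_seq.spawn(n_chunks)
    for c in range(n_chunks):
        lo, hi = c * _CHUNK, min((c + 1) * _CHUNK, reps)
        rng = np.random.Generator(np.random.PCG64(streams[c]))
        out[lo:hi] = _eps_block(n, hi - lo, rng, identity_ref)
    return out


def distance_moments(
    n: int,
    reps: int,
    seed: int,
    reference: str = "random",
) -> SimReport:
    """Sample moments of the shared-adjacency count and of bp distance.

    ``reference="random"`` draws independent genome pairs;
    ``reference="identity"`` fixes the identity genome and draws one
    random genome per replicate (the two settings are equidistributed by
    invariance of the distance).  For large n both the mean and the
    variance of eps_n approach 2.
    """
    if reference not in ("random", "identity"):
        raise ValueError(f"reference must be 'random' or 'identity', got {reference!r}")
    if reps < 2:
        raise ValueError("need reps >= 2 for a sample variance")
    cfg = SimConfig(n=n, reps=reps, seed=seed)
    eps = _eps_samples(n, reps, np.random.SeedSequence(seed), reference == "identity")
    d = (n - 1) - eps
    stats = {
        "mean_eps": float(eps.mean()),
        "var_eps": float(eps.var(ddof=1)),
        "mean_d": float(d.mean()),
        "var_d": float(d.var(ddof=1)),
        "se_mean_eps": float(eps.std(ddof=1) / math.sqrt(reps)),
    }
    frame = pd.DataFrame({"replicate": np.arange(reps), "eps": eps, "d": d})
    return SimReport("distance_moments", cfg, stats, frame)


def exact_eps_moments(n: int, cap: int = ENUMERATION_CAP) -> tuple[float, float]:
    """Exact mean and variance of eps over all ordered class pairs of
    length n, by exhaustive enumeration (independent oracle for the
    simulation at small n)."""
    table = ct.class_table(n)
    masks = table.masks
    N = len(masks)
    tot = 0.0
    tot2 = 0.0
    for i in range(0, N, 256):  # row chunks keep the pair matrix small
        eps = ct.popcount(masks[i : i + 256, None] & masks[None, :]).astype(np.float64)
        tot += eps.sum()
        tot2 += (eps * eps).sum()
    mean = tot / (N * N)
    return mean, tot2 / (N * N) - mean * mean


def epsilon_convergence(
    n_grid: Sequence[int],
    reps: int,
    seed: int,
    a_n: str = "sqrt",
    deltas: Sequence[float] = (0.5, 0.1),
) -> SimReport:
    """Empirical tail probabilities P(eps_n / a_n > delta) along a grid of n.

    With any divergent a_n the tails vanish as n grows (Chebyshev:
    P <= Var[eps] / (delta * a_n)^2 ~ 2 / (delta^2 a_n^2)).
    """
    if not n_grid:
        raise ValueError("need a nonempty n grid")
    cfg = SimConfig(n=int(max(n_grid)), reps=reps, seed=seed, a_n=a_n)
    fa = cfg.a_n_func()
    root = np.random.SeedSequence(seed)
    rows = []
    for n, ss in zip(n_grid, root.spawn(len(n_grid))):
        eps = _eps_samples(int(n), reps, ss, identity_ref=False)
        ratio = eps / fa(n)
        row = {"n": int(n), "a_n": fa(n), "mean_ratio": float(ratio.mean())}
        for delta in deltas:
            row[f"tail_{delta}"] = float((ratio > delta).mean())
        rows.append(row)
    frame = pd.DataFrame(rows)
    stats = {}
    for delta in deltas:
        col = frame[f"tail_{delta}"]
        stats[f"first_tail_{delta}"] = float(col.iloc[0])
        stats[f"last_tail_{delta}"] = float(col.iloc[-1])
    return SimReport("epsilon_convergence", cfg, stats, frame)


def _sample_class_indices(
    table: ct.ClassTable, k: int, rng: np.random.Generator
) -> list[int]:
    idx = []
    for _ in range(k):
        genes = tuple(int(v) for v in rng.permutation(table.n) + 1)
        idx.append(table.index[genes])
    return idx


def _pairwise_alpha(masks: Sequence[int], n: int) -> int:
    return max(
        int(ct.popcount(np.uint64(masks[i] & masks[j])))
        for i in range(len(masks))
        for j in range(i + 1, len(masks))
    )


def median_gap_experiment(
    n: int,
    k: int,
    reps: int,
    seed: int,
    cap: int = ENUMERATION_CAP,
) -> SimReport:
    """Exact median-value gap for k random genomes, replicate by replicate.

    Each replicate draws k classes, computes the exact median value m_n by
    brute force, the gap e* = (k-1)(n-1) - m_n, and alpha = max pairwise
    eps; the bound 0 <= e* <= C(k,2) * alpha is deterministic and any
    violation is counted (none can occur if the solver is correct).
    """
    if n > cap:
        raise ResourceLimitError(f"exact medians need n <= {cap}, got n={n}")
    cfg = SimConfig(n=n, reps=reps, seed=seed, k=k)
    table = ct.class_table(n)
    all_masks = table.masks
    kC2 = k * (k - 1) // 2
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(reps)):
        rng = np.random.Generator(np.random.PCG64(ss))
        idx = _sample_class_indices(table, k, rng)
        ms = [int(all_masks[i]) for i in idx]
        totals = np.zeros(len(table), dtype=np.int64)
        for m in ms:
            totals += (n - 1) - ct.popcount(all_masks & np.uint64(m)).astype(np.int64)
        m_n = int(totals.min())
        e_star = (k - 1) * (n - 1) - m_n
        alpha = _pairwise_alpha(ms, n)
        rows.append(
            {
                "replicate": rep,
                "m_n": m_n,
                "e_star": e_star,
                "alpha": alpha,
                "bound_ok": 0 <= e_star <= kC2 * alpha,
                "n_medians": int((totals == m_n).sum()),
            }
        )
    frame = pd.DataFrame(rows)
    stats = {
        "mean_e_star": float(frame["e_star"].mean()),
        "max_e_star": float(frame["e_star"].max()),
        "mean_alpha": float(frame["alpha"].mean()),
        "bound_violations": int((~frame["bound_ok"]).sum()),
    }
    return SimReport("median_gap", cfg, stats, frame)


def accessible_distance_experiment(
    n: int,
    k: int,
    reps: int,
    seed: int,
    cap: int = ENUMERATION_CAP,
) -> SimReport:
    """Total distance of accessible classes from k random genomes.

    Each replicate draws k classes X, computes the full accessibility
    closure Z-bar(X) by patch hopping, and records the largest gap
    (k-1)(n-1) - d(z, X) over z in the closure.  Every accessible class
    has all its adjacencies inside the union of the inputs', so the gap
    lies in [0, C(k,2) * alpha] deterministically; violations of either
    side are counted.
    """
    if n > cap:
        raise ResourceLimitError(f"accessibility closure needs n <= {cap}, got n={n}")
    cfg = SimConfig(n=n, reps=reps, seed=seed, k=k)
    table = ct.class_table(n)
    all_masks = table.masks
    kC2 = k * (k - 1) // 2
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(reps)):
        rng = np.random.Generator(np.random.PCG64(ss))
        idx = _sample_class_indices(table, k, rng)
        ms = [int(all_masks[i]) for i in idx]
        alpha = _pairwise_alpha(ms, n)
        in_c = _patch_closure(table, idx, anchors=None)
        z_idx = in_c.nonzero()[0]
        totals = np.zeros(len(z_idx), dtype=np.int64)
        for m in ms:
            totals += (n - 1) - ct.popcount(
                all_masks[z_idx] & np.uint64(m)
            ).astype(np.int64)
        gaps = (k - 1) * (n - 1) - totals
        rows.append(
            {
                "replicate": rep,
                "alpha": alpha,
                "closure_size": int(len(z_idx)),
                "max_gap": int(gaps.max()),
                "min_gap": int(gaps.min()),
                "bound_ok": bool((gaps >= 0).all() and (gaps <= kC2 * alpha).all()),
            }
        )
    frame = pd.DataFrame(rows)
    stats = {
        "mean_max_gap": float(frame["max_gap"].mean()),
        "mean_closure_size": float(frame["closure_size"].mean()),
        "bound_violations": int((~frame["bound_ok"]).sum()),
    }
    return SimReport("accessible_distance", cfg, stats, frame)
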