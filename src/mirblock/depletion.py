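"""In-silico depletion and library evaluation statistics.

Counts are treated as physical reads: down-sampling draws reads without
replacement (multivariate hypergeometric), blocking thins each targeted
species binomially with survival probability 1 - efficiency, and
replicate averaging follows a three-step count-preserving procedure
(down-sample both replicates to a common total, sum, down-sample the
sum back to that total).  Every stochastic operation takes a seed or a
numpy Generator and is bit-reproducible; a deterministic expected-value
mode is provided for exact tests.

The dispersion and fold-change statistics here are deliberately simple
stand-ins (method-of-moments overdispersion, pseudocount log2 fold
changes) — they characterize reproducibility of the count data and are
not a differential-expression engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .offtarget import JunctionCall
from .sequence_io import CountMatrix


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _as_array(library: pd.Series | Sequence[int]) -> np.ndarray:
    arr = np.asarray(library, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _deterministic_round(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative expectations to integers preserving the total
    (largest-remainder apportionment)."""
    base = np.floor(expected).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        frac = expected - np.floor(expected)
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def downsample(
    library: pd.Series | Sequence[int],
    depth: int,
    seed: int | np.random.Generator = 0,
    *,
    with_replacement: bool = False,
    deterministic: bool = False,
) -> pd.Series | np.ndarray:
    """Randomly select ``depth`` reads from a count vector.

    Without replacement (default) this is a multivariate hypergeometric
    draw; ``with_replacement=True`` switches to a multinomial draw at
    the library's proportions (faster at extreme depths).  The output
    always sums to exactly ``depth``.
    """
    arr = _as_array(library)
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"requested depth {depth} exceeds library total {total}")
    if deterministic:
        out = _deterministic_round(arr * (depth / total), depth) if total else arr
    elif depth == total and not with_replacement:
        out = arr.copy()
    elif with_replacement:
        out = _rng(seed).multinomial(depth, arr / total)
    else:
        out = _rng(seed).multivariate_hypergeometric(arr, depth, method="marginals")
    if isinstance(library, pd.Series):
        return pd.Series(out, index=library.index, name=library.name)
    return out


def average_replicates(
    rep1: pd.Series | Sequence[int],
    rep2: pd.Series | Sequence[int],
    seed: int | np.random.Generator = 0,
    *,
    common: int | None = None,
    deterministic: bool = False,
) -> pd.Series | np.ndarray:
    """Count-preserving replicate average.

    Both replicates are down-sampled to a common total (default: the
    smaller of the two library totals), summed per species, and the sum
    down-sampled back to the same total, so the result remains a count
    vector at the common depth.
    """
    a, b = _as_array(rep1), _as_array(rep2)
    if a.shape != b.shape:
        raise ValueError("replicates cover mismatched species sets")
    if isinstance(rep1, pd.Series) and isinstance(rep2, pd.Series):
        if not rep1.index.equals(rep2.index):
            raise ValueError("replicates cover mismatched species sets")
    if common is None:
        common = int(min(a.sum(), b.sum()))
    if common <= 0:
        raise ValueError("cannot average replicates down to a zero total")
    rng = _rng(seed)
    da = downsample(a, common, rng, deterministic=deterministic)
    db = downsample(b, common, rng, deterministic=deterministic)
    pooled = downsample(da + db, common, rng, deterministic=deterministic)
    if isinstance(rep1, pd.Series):
        return pd.Series(pooled, index=rep1.index, name=rep1.name)
    return pooled


def pool_replicates(
    reps: Sequence[pd.Series],
    seed: int | np.random.Generator = 0,
    *,
    deterministic: bool = False,
) -> pd.Series:
    """Generalize replicate averaging to one or more libraries."""
    if not reps:
        raise ValueError("no replicate libraries supplied")
    if len(reps) == 1:
        return reps[0]
    rng = _rng(seed)
    out = reps[0]
    for nxt in reps[1:]:
        out = average_replicates(out, nxt, rng, deterministic=deterministic)
    return out


def apply_blocking(
    library: pd.Series | Sequence[int],
    calls: Iterable[JunctionCall] | Mapping[str, float],
    seed: int | np.random.Generator = 0,
    *,
    deterministic: bool = False,
) -> pd.Series:
    """Thin each called species binomially with survival 1 - efficiency.

    Species without a call are untouched.  ``calls`` may be JunctionCalls
    or a plain {species: efficiency} mapping.
    """
    if not isinstance(library, pd.Series):
        library = pd.Series(_as_array(library))
    eff = (
        dict(calls)
        if isinstance(calls, Mapping)
        else {c.species: c.efficiency for c in calls}
    )
    for sp, e in eff.items():
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"efficiency for {sp!r} outside [0, 1]: {e}")
    rng = _rng(seed)
    out = library.copy()
    for sp, e in eff.items():
        if sp not in out.index:
            continue
        n = int(out[sp])
        if deterministic:
            out[sp] = int(np.rint(n * (1.0 - e)))
        else:
            out[sp] = int(rng.binomial(n, 1.0 - e))
    return out


def apply_blocking_matrix(
    matrix: CountMatrix,
    calls: Iterable[JunctionCall] | Mapping[str, float],
    seed: int | np.random.Generator = 0,
    *,
    deterministic: bool = False,
    suffix: str = "_blocked",
) -> CountMatrix:
    """Apply blocking to every library of a matrix; the result is
    relabelled condition=blocked with library names suffixed."""
    eff = (
        dict(calls)
        if isinstance(calls, Mapping)
        else {c.species: c.efficiency for c in calls}
    )
    rng = _rng(seed)
    cols = {}
    meta = {}
    for lib in matrix.libraries:
        new = f"{lib}{suffix}"
        cols[new] = apply_blocking(matrix.library(lib), eff, rng, deterministic=deterministic)
        old = matrix.metadata[lib]
        meta[new] = type(old)(condition="blocked", replicate=old.replicate, sample=old.sample)
    return CountMatrix(pd.DataFrame(cols, index=matrix.counts.index), meta)


def dominant_fraction(library: pd.Series, species: str) -> float:
    """Fraction of the library's reads belonging to one species."""
    total = int(library.sum())
    if total <= 0:
        raise ValueError("library has no reads")
    if species not in library.index:
        raise KeyError(f"unknown species {species!r}")
    return float(library[species]) / total


@dataclass
class DetectionGainCurve:
    """Per-threshold detection difference (blocked - unblocked) at a
    common down-sampled depth."""

    depth: int
    thresholds: tuple[int, ...]
    per_sample_delta: pd.DataFrame  # rows = samples, columns = thresholds
    mean_delta: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean_delta = self.per_sample_delta.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_sample_delta.T
        out.index.name = "threshold"
        out["mean"] = self.mean_delta
        return out


def _matched_samples(unblocked: CountMatrix, blocked: CountMatrix) -> list[str]:
    su = {unblocked.metadata[l].sample for l in unblocked.libraries}
    sb = {blocked.metadata[l].sample for l in blocked.libraries}
    return sorted(su & sb)


def _sample_library(
    matrix: CountMatrix,
    sample: str,
    rng: np.random.Generator,
    deterministic: bool,
) -> pd.Series:
    libs = [l for l in matrix.libraries if matrix.metadata[l].sample == sample]
    return pool_replicates(
        [matrix.library(l) for l in libs], rng, deterministic=deterministic
    )


def detection_gain(
    unblocked: CountMatrix,
    blocked: CountMatrix,
    thresholds: Sequence[int],
    depth: int,
    seed: int | np.random.Generator = 0,
    *,
    deterministic: bool = False,
) -> DetectionGainCurve:
    """Detected-species difference per count threshold at equal depth.

    Samples present in both conditions are paired; replicates within a
    condition are averaged with the count-preserving procedure, each
    side is down-sampled to ``depth``, and the number of species with
    count >= threshold is compared (blocked minus unblocked).
    """
    samples = _matched_samples(unblocked, blocked)
    if not samples:
        raise ValueError("no samples present in both conditions")
    rng = _rng(seed)
    thresholds = tuple(int(t) for t in thresholds)
    rows = {}
    for sample in samples:
        u = downsample(
            _sample_library(unblocked, sample, rng, deterministic),
            depth, rng, deterministic=deterministic,
        )
        b = downsample(
            _sample_library(blocked, sample, rng, deterministic),
            depth, rng, deterministic=deterministic,
        )
        rows[sample] = [
            int((b >= t).sum()) - int((u >= t).sum()) for t in thresholds
        ]
    per_sample = pd.DataFrame.from_dict(rows, orient="index", columns=list(thresholds))
    return DetectionGainCurve(depth=depth, thresholds=thresholds, per_sample_delta=per_sample)


@dataclass
class DispersionProfile:
    """Per-species method-of-moments overdispersion.

    alpha solves var = mean + alpha * mean**2 with the sample variance
    plugged in, clamped at zero (NOT a shrinkage/likelihood estimate).
    """

    table: pd.DataFrame  # columns: base_mean, dispersion


def dispersion_profile(replicates: CountMatrix) -> DispersionProfile:
    """Method-of-moments dispersion across >= 2 replicate libraries."""
    df = replicates.counts
    if df.shape[1] < 2:
        raise ValueError("need at least 2 replicate libraries")
    mean = df.mean(axis=1)
    var = df.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = alpha.where(mean > 0, 0.0).clip(lower=0.0)
    return DispersionProfile(
        table=pd.DataFrame({"base_mean": mean, "dispersion": alpha})
    )


def spearman_replicates(
    rep1: pd.Series | Sequence[int], rep2: pd.Series | Sequence[int]
) -> float:
    """Spearman rho between two replicate count vectors (average ranks
    for ties); NaN when either vector is constant."""
    a, b = _as_array(rep1), _as_array(rep2)
    if a.shape != b.shape:
        raise ValueError("replicates cover mismatched species sets")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class ConcordanceResult:
    per_pair: pd.DataFrame  # columns: sample_a, sample_b, rho, n_species
    mean_rho: float
    sd_rho: float


def foldchange_concordance(
    unblocked: CountMatrix,
    blocked: CountMatrix,
    base_mean_min: float = 10.0,
    depth: int | None = None,
    seed: int | np.random.Generator = 0,
    *,
    pseudocount: float = 0.5,
    deterministic: bool = False,
) -> ConcordanceResult:
    """Rank concordance of between-sample fold changes across conditions.

    For every pair of samples, per-species log2 fold changes are
    computed within each condition on depth-matched counts with a
    pseudocount, restricted to species whose pair-mean count exceeds
    ``base_mean_min`` in both conditions; the Spearman rho between the
    two conditions' fold-change vectors is reported per pair.
    """
    samples = _matched_samples(unblocked, blocked)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples with both conditions")
    rng = _rng(seed)
    vecs: dict[tuple[str, str], pd.Series] = {}
    for sample in samples:
        for cond, matrix in (("unblocked", unblocked), ("blocked", blocked)):
            v = _sample_library(matrix, sample, rng, deterministic)
            if depth is not None:
                v = downsample(v, depth, rng, deterministic=deterministic)
            vecs[(cond, sample)] = v
    rows = []
    for sa, sb in combinations(samples, 2):
        ua, ub = vecs[("unblocked", sa)], vecs[("unblocked", sb)]
        ba, bb = vecs[("blocked", sa)], vecs[("blocked", sb)]
        keep = ((ua + ub) / 2 > base_mean_min) & ((ba + bb) / 2 > base_mean_min)
        n = int(keep.sum())
        if n >= 2:
            lfc_u = np.log2((ua[keep] + pseudocount) / (ub[keep] + pseudocount))
            lfc_b = np.log2((ba[keep] + pseudocount) / (bb[keep] + pseudocount))
            rho = float(stats.spearmanr(lfc_u, lfc_b).statistic)
        else:
            rho = float("nan")
        rows.append({"sample_a": sa, "sample_b": sb, "rho": rho, "n_species": n})
    per_pair = pd.DataFrame(rows)
    return ConcordanceResult(
        per_pair=per_pair,
        mean_rho=float(per_pair["rho"].mean()),
        sd_rho=float(per_pair["rho"].std(ddof=1)) if len(per_pair) > 1 else 0.0,
    )
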