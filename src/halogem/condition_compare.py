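"""Statistical comparison of flux distributions between two conditions.

The screen is a per-reaction two-sample Wilcoxon rank-sum test between the
sampled flux vectors of the two conditions, with the normal (tie-corrected)
approximation of the statistic.  With ~20,000 samples per side, biologically
shifted reactions produce enormous deviates, so the selection bar is
deliberately extreme: |Z| > 50 and p < 0.01.

The magnitude of each shift is estimated separately: k = 2000 sample points
are drawn without replacement from each condition's flux vector
independently, subtracted, and averaged.  Because the two sample sets are
independent, any pairing is arbitrary and the estimator simply targets the
difference of marginal means (high minus low by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flux_sampling import FluxSampleSet

Z_MIN = 50.0
P_MAX = 0.01
K_PAIRS = 2000


class CompareError(ValueError):
    pass


def _check_same_reactions(a: FluxSampleSet, b: FluxSampleSet) -> None:
    if a.reaction_ids != b.reaction_ids:
        only_a = sorted(set(a.reaction_ids) - set(b.reaction_ids))
        only_b = sorted(set(b.reaction_ids) - set(a.reaction_ids))
        raise CompareError(
            f"sample sets cover different reactions (only in A: {only_a}, "
            f"only in B: {only_b}, or ordering differs)"
        )


def rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal deviate of y's rank sum against x, and its p-value.

    Z > 0 means the second sample tends to larger values; swapping the
    arguments negates Z and leaves p unchanged.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[n1:].sum()  # rank sum of y
    mean_w = n2 * (n1 + n2 + 1) / 2.0
    # tie correction to the rank-sum variance
    _, counts = np.unique(pooled, return_counts=True)
    ntot = n1 + n2
    tie_term = (counts**3 - counts).sum() / ((ntot) * (ntot - 1)) if ntot > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((ntot + 1) - tie_term)
    if var_w <= 0:
        return 0.0, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class FluxComparison:
    """Per-reaction Wilcoxon screen + paired-difference effect sizes."""

    table: pd.DataFrame  # index reaction; Z, p_value, mean_diff, significant, q_value
    z_min: float
    p_max: float
    k_pairs: int
    seed: int | None
    condition_a: str
    condition_b: str

    @property
    def significant(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])


def wilcoxon_compare(
    sample_a: FluxSampleSet,
    sample_b: FluxSampleSet,
    z_min: float = Z_MIN,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Rank-sum Z and p per reaction; flag |Z| > z_min and p < p_max.

    No multiplicity correction is applied by default (the Z bar already sits
    far outside null fluctuation); Benjamini-Hochberg q-values are emitted as
    an extra column for users who want them.
    """
    _check_same_reactions(sample_a, sample_b)
    rows = []
    for j, rid in enumerate(sample_a.reaction_ids):
        z, p = rank_sum_z(sample_a.matrix[:, j], sample_b.matrix[:, j])
        rows.append({"reaction": rid, "Z": z, "p_value": p})
    df = pd.DataFrame(rows).set_index("reaction")
    df["significant"] = (df["Z"].abs() > z_min) & (df["p_value"] < p_max)
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def mean_paired_difference(
    sample_a: FluxSampleSet,
    sample_b: FluxSampleSet,
    k: int = K_PAIRS,
    seed: int = 0,
) -> pd.Series:
    """Average of k random subtractions (B - A) per reaction.

    Indices are drawn without replacement, independently for each condition;
    the estimate is unbiased for the difference of marginal means.
    """
    _check_same_reactions(sample_a, sample_b)
    if k > sample_a.n_samples or k > sample_b.n_samples:
        raise CompareError(
            f"k={k} exceeds sample sizes ({sample_a.n_samples}, {sample_b.n_samples})"
        )
    rng = np.random.Generator(np.random.Philox(seed))
    ia = rng.choice(sample_a.n_samples, size=k, replace=False)
    ib = rng.choice(sample_b.n_samples, size=k, replace=False)
    diff = sample_b.matrix[ib] - sample_a.matrix[ia]
    return pd.Series(diff.mean(axis=0), index=sample_a.reaction_ids)


def compare_conditions(
    sample_a: FluxSampleSet,
    sample_b: FluxSampleSet,
    z_min: float = Z_MIN,
    p_max: float = P_MAX,
    k: int = K_PAIRS,
    seed: int = 0,
) -> FluxComparison:
    """Full comparison: Wilcoxon screen plus paired-difference estimates."""
    table = wilcoxon_compare(sample_a, sample_b, z_min=z_min, p_max=p_max)
    table["mean_diff"] = mean_paired_difference(sample_a, sample_b, k=k, seed=seed)
    return FluxComparison(
        table=table,
        z_min=z_min,
        p_max=p_max,
        k_pairs=k,
        seed=seed,
        condition_a=sample_a.condition,
        condition_b=sample_b.condition,
    )
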