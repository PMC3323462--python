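"""Scoring candidate substrate labels against flux hypotheses.

An experimental hypothesis is a two-way partition of a flux sample set —
samples where a target flux (or flux ratio) is above vs below a threshold,
by default the sample median so the classes are balanced.  A label is good
for a hypothesis when the simulated measurement distributions of the two
classes separate: per measurement element i,

    Z_i = |xbar_hi - xbar_lo| / sqrt(s2_hi + s2_lo + sigma^2)

with sigma (default 0.014) a floor at the order of the measurement
uncertainty, and the experiment score Z = sum_i Z_i.  Random partitions
estimate the noise level of the score.

Data dimensionality is measured by SVD of the (elements x points)
measurement matrix: after row centering, singular values are scaled by
1/sqrt(n_points) so a threshold reads as a per-measurement RMS uncertainty,
and dimensions are counted while they stay above the instrument threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import FluxSampleSet

#: default measurement-noise floor in the Z denominator
SIGMA_DEFAULT = 0.014

#: default instrument-uncertainty thresholds for dimensionality counting
SVD_THRESHOLDS = (0.05, 0.02, 0.01)


class DegenerateHypothesisError(ValueError):
    """The partition statistic is constant across samples."""


@dataclass
class HypothesisPartition:
    kind: str  # reaction_hi_lo | ratio_hi_lo | random
    target: object
    threshold: float | None
    mask: np.ndarray  # boolean, True = "hi"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if self.mask.all() or not self.mask.any():
            raise DegenerateHypothesisError(
                f"partition {self.kind}:{self.target} has an empty class")

    @property
    def n_hi(self) -> int:
        return int(self.mask.sum())

    @property
    def n_lo(self) -> int:
        return int((~self.mask).sum())


@dataclass
class ZScoreReport:
    per_element_z: np.ndarray
    total_z: float
    sigma_floor: float
    partition: HypothesisPartition
    row_labels: list | None = None


@dataclass
class DimensionalityReport:
    scaled_singular_values: np.ndarray
    counts: dict[float, int]
    n_points: int
    n_elements: int


def _balanced_median_mask(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Median-threshold hi/lo mask with deterministic tie handling.

    Samples equal to the threshold go to "lo"; if ties leave the classes
    unbalanced by more than one, boundary ties are promoted to "hi" in
    sorted sample-index order until |n_hi - n_lo| <= 1.
    """
    x = np.asarray(x, float)
    if np.ptp(x) < 1e-12:
        raise DegenerateHypothesisError(
            "statistic is constant across samples")
    thr = float(np.median(x))
    mask = x > thr
    ties = np.flatnonzero(np.isclose(x, thr))
    # promote ties (lowest index first) while "hi" is short by 2 or more
    for i in ties:
        if mask.sum() >= (~mask).sum() - 1:
            break
        mask[i] = True
    return thr, mask


def partition_hi_lo(samples: FluxSampleSet, reaction: str) -> HypothesisPartition:
    """Hi/lo hypothesis on one reaction at its sample-median flux."""
    if samples.n_points < 4:
        raise ValueError("need at least 4 samples to partition")
    thr, mask = _balanced_median_mask(samples.column(reaction))
    return HypothesisPartition("reaction_hi_lo", reaction, thr, mask)


def partition_ratio(
    samples: FluxSampleSet, num: str, den: str,
    threshold: float | None = None,
) -> HypothesisPartition:
    """Hi/lo hypothesis on the flux ratio v_num / v_den."""
    if samples.n_points < 4:
        raise ValueError("need at least 4 samples to partition")
    vn, vd = samples.column(num), samples.column(den)
    tiny = np.abs(vd) < 1e-9
    if tiny.mean() > 0.05:
        raise ValueError(
            f"denominator {den} is ~0 in {tiny.mean():.0%} of samples")
    r = vn / np.where(tiny, np.nan, vd)
    r = np.where(np.isnan(r), np.nanmedian(r), r)
    if threshold is None:
        thr, mask = _balanced_median_mask(r)
    else:
        if np.ptp(r) < 1e-12:
            raise DegenerateHypothesisError("ratio constant across samples")
        thr, mask = float(threshold), r > threshold
    return HypothesisPartition("ratio_hi_lo", (num, den), thr, mask)


def partition_random(samples: FluxSampleSet, seed: int) -> HypothesisPartition:
    """Uniformly random balanced split; estimates the scoring noise floor."""
    if samples.n_points < 4:
        raise ValueError("need at least 4 samples to partition")
    rng = np.random.default_rng(seed)
    n = samples.n_points
    order = rng.permutation(n)
    mask = np.zeros(n, bool)
    mask[order[: n // 2]] = True
    return HypothesisPartition("random", seed, None, mask)


def z_score(
    M: np.ndarray,
    partition: HypothesisPartition,
    sigma: float = SIGMA_DEFAULT,
    row_labels: list | None = None,
    drop_m0: bool = False,
) -> ZScoreReport:
    """Per-element and total Z-score of a measurement matrix under a
    partition.

    Rows are fragment MDV elements, columns are flux samples.  ``drop_m0``
    excludes M+0 rows (requires ``row_labels`` of (fragment, mass) tuples)
    to avoid double counting under normalization.
    """
    M = np.asarray(M, float)
    if M.shape[1] != partition.mask.size:
        raise ValueError("matrix columns do not align with partition mask")
    if partition.n_hi < 2 or partition.n_lo < 2:
        raise ValueError("each class needs >= 2 columns (variance undefined)")
    rows = np.ones(M.shape[0], bool)
    if drop_m0:
        if row_labels is None:
            raise ValueError("drop_m0 requires row_labels")
        rows = np.array([m != 0 for _, m in row_labels])
    hi, lo = M[np.ix_(rows, partition.mask)], M[np.ix_(rows, ~partition.mask)]
    diff = np.abs(hi.mean(axis=1) - lo.mean(axis=1))
    denom = np.sqrt(hi.var(axis=1, ddof=1) + lo.var(axis=1, ddof=1)
                    + sigma ** 2)
    z = diff / denom
    labels = None
    if row_labels is not None:
        labels = [l for l, keep in zip(row_labels, rows) if keep]
    return ZScoreReport(z, float(z.sum()), sigma, partition, labels)


def noise_level(
    M: np.ndarray,
    samples: FluxSampleSet,
    n_random: int = 20,
    sigma: float = SIGMA_DEFAULT,
    seed: int = 0,
) -> float:
    """Mean total Z over random balanced partitions."""
    rng = np.random.default_rng(seed)
    totals = [
        z_score(M, partition_random(samples, int(rng.integers(2**31))),
                sigma).total_z
        for _ in range(n_random)
    ]
    return float(np.mean(totals))


def score_label_panel(
    net,
    samples: FluxSampleSet,
    labels: dict[str, "SubstrateMixture"],
    hypotheses: list[tuple],
    fragments,
    sigma: float = SIGMA_DEFAULT,
    n_random: int = 20,
    seed: int = 0,
):
    """Score every (hypothesis, label) pair.

    ``hypotheses`` entries are ("reaction", rid) or ("ratio", num, den).
    Returns (raw, normalized) DataFrames with hypothesis rows (plus a
    "random" noise row) and label columns; normalized scores divide each row
    by its max over labels.  Simulation failures leave NaN cells.
    """
    from .isotopomer import simulate_experiment_matrix

    matrices = {}
    for name, label in labels.items():
        M, row_labels, statuses = simulate_experiment_matrix(
            samples, label, fragments, net)
        ok = np.array([s is None for s in statuses])
        matrices[name] = (M[:, ok], ok)

    def hyp_name(h):
        return f"{h[1]}" if h[0] == "reaction" else f"{h[1]}/{h[2]}"

    raw = pd.DataFrame(index=[hyp_name(h) for h in hypotheses] + ["random"],
                       columns=list(labels), dtype=float)
    for name in labels:
        M, ok = matrices[name]
        sub = FluxSampleSet(samples.points[ok], samples.reaction_ids,
                            samples.seed, samples.n_steps_per_point,
                            samples.network_id)
        for h in hypotheses:
            try:
                if h[0] == "reaction":
                    part = partition_hi_lo(sub, h[1])
                else:
                    part = partition_ratio(sub, h[1], h[2])
                raw.loc[hyp_name(h), name] = z_score(M, part, sigma).total_z
            except (DegenerateHypothesisError, ValueError):
                pass
        raw.loc["random", name] = noise_level(M, sub, n_random, sigma, seed)
    rowmax = raw.max(axis=1)
    normalized = raw.div(rowmax.where(rowmax > 0, 1.0), axis=0)
    return raw, normalized


def determinability(
    score_table: pd.DataFrame,
    noise: float,
    fva_ranges: dict[str, tuple[float, float]],
    subsystems: dict[str, str] | None = None,
    width_tol: float = 1e-7,
):
    """Classify each reaction by how its flux can be pinned down.

    Zero-width FVA -> "constraint_determined"; otherwise a max-over-labels
    Z of at least twice the noise level -> "c13_determinable"; else
    "undeterminable".  A reaction whose best Z is zero carries no labeling
    signal at all and is never 13C-determinable, even when the noise
    estimate is also zero.  Returns (per-reaction dict, per-subsystem
    fraction DataFrame or None).
    """
    classes = {}
    for rid, (lo, hi) in fva_ranges.items():
        if hi - lo <= width_tol:
            classes[rid] = "constraint_determined"
        elif rid in score_table.index and \
                score_table.loc[rid].max() > 1e-12 and \
                score_table.loc[rid].max() >= 2 * noise:
            classes[rid] = "c13_determinable"
        else:
            classes[rid] = "undeterminable"
    frac = None
    if subsystems:
        df = pd.DataFrame(
            [(subsystems.get(r, ""), c) for r, c in classes.items()],
            columns=["subsystem", "class"])
        frac = (df.groupby("subsystem")["class"]
                  .value_counts(normalize=True).unstack(fill_value=0.0))
    return classes, frac


def svd_dimensionality(
    M: np.ndarray,
    thresholds=SVD_THRESHOLDS,
    center: bool = True,
    scale: bool = True,
) -> DimensionalityReport:
    """Effective dimensionality of a measurement matrix at instrument
    thresholds.

    Rows are centered by their mean and singular values scaled by
    1/sqrt(n_points) so they read as per-measurement RMS; the dimension at a
    threshold is the number of scaled singular values above it.
    """
    M = np.asarray(M, float)
    if not np.isfinite(M).all():
        raise ValueError("measurement matrix contains non-finite entries")
    n_elements, n_points = M.shape
    X = M - M.mean(axis=1, keepdims=True) if center else M
    sv = np.linalg.svd(X, compute_uv=False)
    if scale:
        sv = sv / np.sqrt(n_points)
    counts = {float(t): int(np.sum(sv > t)) for t in thresholds}
    return DimensionalityReport(sv, counts, n_points, n_elements)
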