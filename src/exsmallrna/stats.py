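"""Normalization and cohort statistics for small-RNA count matrices.

Covers RPM scaling, median-of-ratios library-size factors, detection
matrices over sample-fraction grids, depth/saturation curves, the
coefficient-of-variation analysis comparing within-subject to
between-subject miRNA variability (two-sided Wilcoxon rank-sum), and
PCA of log-normalized miRNA counts.

All count inputs are plain pandas DataFrames with features as rows and
samples as columns; raw (un-normalized) integer counts are expected
everywhere except where noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

DETECTION_THRESHOLDS = (10, 50)
#: Sample-fraction grid of the detection matrix ("at least one sample" + 10%..100%).
DETECTION_FRACTIONS = tuple(f / 10 for f in range(1, 11))


@dataclass(frozen=True)
class CountMatrix:
    """Features x samples raw counts plus per-sample metadata.

    ``samples`` is indexed by sample id with columns such as
    fluid, subject, input_reads and genome_mapped.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")


def rpm_normalize(count: float | np.ndarray | pd.Series, genome_mapped_total: int) -> float | np.ndarray | pd.Series:
    """Reads per million of a stated denominator (genome-mapped reads)."""
    if genome_mapped_total <= 0:
        raise ValueError("genome_mapped_total must be positive")
    return count * 1e6 / genome_mapped_total


def median_ratio_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For sample j, ``s_j = median_i k_ij / g_i`` where ``g_i`` is the
    geometric mean of feature i across samples; features with a zero
    count in any sample are excluded from the median (they have no
    geometric-mean pseudo-reference).
    """
    counts = matrix.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=matrix.columns, name="size_factor")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; median-of-ratios "
            "size factors are undefined (filter samples or use RPM instead)"
        )
    pos = counts[all_positive]
    log_geo_mean = np.log(pos).mean(axis=1)
    factors = np.exp(np.median(np.log(pos) - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize_counts(matrix: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = median_ratio_size_factors(matrix)
    return matrix / size_factors


def detection_summary(
    matrix: pd.DataFrame, thresholds: tuple[int, ...] = DETECTION_THRESHOLDS
) -> pd.DataFrame:
    """Number of features detected strictly above each count threshold.

    Rows: detected in at least one sample, then in >=10%..100% of
    samples; columns: one per threshold.  Thresholds are strict
    (a count of exactly 10 is not ">10").  Raw counts expected.
    """
    if matrix.empty:
        raise ValueError("empty count matrix")
    n = matrix.shape[1]
    rows = {}
    for thr in thresholds:
        above = (matrix > thr).sum(axis=1)
        col = {"at_least_1": int((above >= 1).sum())}
        for frac in DETECTION_FRACTIONS:
            need = int(np.ceil(frac * n))
            col[f"{int(frac * 100)}%"] = int((above >= need).sum())
        rows[f">{thr}"] = col
    return pd.DataFrame(rows)


def saturation_curve(
    matrix: pd.DataFrame,
    input_reads: pd.Series,
    thresholds: tuple[int, ...] = (1, 10, 50),
    bin_million: float = 1.0,
) -> pd.DataFrame:
    """Median detected-feature count per depth bin.

    Samples are binned by ``bin_million``-million input-read increments
    (bin k covers [k, k+1) million); per bin and threshold the median
    number of features detected strictly above the threshold is
    reported.  Even-sized bins use the midpoint-of-central-pair median.
    """
    detected = pd.DataFrame(
        {thr: (matrix > thr).sum(axis=0) for thr in thresholds}
    )
    bins = (input_reads.loc[detected.index] // (bin_million * 1e6)).astype(int)
    out = detected.groupby(bins).median()
    out.index.name = "depth_bin_million"
    return out


def subsample_counts(counts: pd.Series, depth: int, rng: np.random.Generator) -> pd.Series:
    """Sampling-without-replacement (multivariate hypergeometric) subsample."""
    total = int(counts.sum())
    if depth >= total:
        return counts.copy()
    draw = rng.multivariate_hypergeometric(counts.astype(int).to_numpy(), depth)
    return pd.Series(draw, index=counts.index)


def subsampled_saturation(
    counts: pd.Series,
    depths: list[int],
    seed: int,
    thresholds: tuple[int, ...] = (1, 10, 50),
) -> pd.DataFrame:
    """Saturation re-estimated from one deep sample by subsampling reads."""
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        sub = subsample_counts(counts, depth, rng)
        rows.append({thr: int((sub > thr).sum()) for thr in thresholds})
    return pd.DataFrame(rows, index=pd.Index(depths, name="depth"))


# ------------------------------------------------------------- Wilcoxon

EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration (over midranks) when both groups have
    at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie correction.  The exact two-sided p-value is
    ``P(|T - mu| >= |t_obs - mu|)`` over all label assignments, where T
    is the group-1 rank sum and ``mu`` its permutation mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    t_obs = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev = abs(t_obs - mu) - 1e-9
        hits = sum(
            1 for idx in combinations(range(n1 + n2), n1) if abs(ranks[list(idx)].sum() - mu) >= dev
        )
        return hits / comb(n1 + n2, n1)
    tie_correction = sps.tiecorrect(ranks)
    if tie_correction == 0:
        return 1.0  # all values identical
    sigma = sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0 * tie_correction)
    z = (t_obs - mu) / sigma
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------- CV analysis

@dataclass
class CVReport:
    """Within- vs between-subject miRNA variability."""

    per_mirna: pd.DataFrame  # mean, sd, cv over the full analysis set
    subject_cvs: dict[str, pd.Series]  # per qualifying subject: CV per miRNA
    inter_cv: pd.Series  # CV per miRNA, one sample per subject
    inter_samples: list[str]
    wilcoxon_p: dict[str, float]  # subject -> two-sided rank-sum p-value
    lowest_cv: pd.DataFrame
    highest_cv: pd.DataFrame


def _cv(frame: pd.DataFrame) -> pd.Series:
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    return (sd / mean.where(mean > 0)).rename("cv")


def cv_analysis(
    matrix: pd.DataFrame,
    sample_to_subject: pd.Series,
    size_factors: pd.Series | None = None,
    min_count: int = 50,
    min_fraction: float = 0.8,
    min_samples_per_subject: int = 5,
    inter_choice: str = "first",
    seed: int | None = None,
    top_n: int = 15,
) -> CVReport:
    """Coefficient-of-variation analysis of well-expressed miRNAs.

    miRNAs are kept when their raw count exceeds ``min_count`` in at
    least ``min_fraction`` of the analysis samples; CVs are computed on
    median-ratio-normalized counts.  Each subject with at least
    ``min_samples_per_subject`` samples contributes an intra-subject CV
    distribution (over miRNAs); the inter-subject distribution uses one
    sample per subject (first by column order, or seeded random with
    ``inter_choice='random'``).  Each subject's distribution is compared
    to the inter-subject one with a two-sided Wilcoxon rank-sum test.
    """
    subjects = sample_to_subject.loc[matrix.columns]
    sizes = subjects.value_counts()
    qualifying = sorted(sizes.index[sizes >= min_samples_per_subject])
    if not qualifying:
        raise ValueError(
            f"no subject has >= {min_samples_per_subject} samples; cannot run CV analysis"
        )

    keep = (matrix > min_count).mean(axis=1) >= min_fraction
    if not keep.any():
        raise ValueError("no miRNA passes the expression filter")
    norm = normalize_counts(matrix, size_factors).loc[keep]

    per_mirna = pd.DataFrame(
        {
            "mean": norm.mean(axis=1),
            "sd": norm.std(axis=1, ddof=1),
        }
    )
    per_mirna["cv"] = _cv(norm)

    if inter_choice == "first":
        chosen = [matrix.columns[subjects.values == s][0] for s in qualifying]
    elif inter_choice == "random":
        rng = np.random.default_rng(seed)
        chosen = [
            str(rng.choice(matrix.columns[subjects.values == s])) for s in qualifying
        ]
    else:
        raise ValueError("inter_choice must be 'first' or 'random'")
    inter_cv = _cv(norm[chosen]).dropna()

    subject_cvs: dict[str, pd.Series] = {}
    wilcoxon_p: dict[str, float] = {}
    for s in qualifying:
        cols = list(matrix.columns[subjects.values == s])
        cv_s = _cv(norm[cols]).dropna()
        subject_cvs[s] = cv_s
        wilcoxon_p[s] = wilcoxon_rank_sum(cv_s.to_numpy(), inter_cv.to_numpy())

    ranked = per_mirna.dropna(subset=["cv"]).sort_values("cv")
    return CVReport(
        per_mirna=per_mirna,
        subject_cvs=subject_cvs,
        inter_cv=inter_cv,
        inter_samples=list(chosen),
        wilcoxon_p=wilcoxon_p,
        lowest_cv=ranked.head(top_n),
        highest_cv=ranked.tail(top_n).iloc[::-1],
    )


# ------------------------------------------------------------------ PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # features x PCs
    variance_explained: pd.Series
    top_loadings: dict[str, pd.Series]  # PC -> top-|loading| features


def pca_mirna(
    matrix: pd.DataFrame,
    size_factors: pd.Series | None = None,
    n_components: int = 2,
    top_n: int = 10,
) -> PCAResult:
    """PCA of centered log2(normalized count + 1) miRNA profiles.

    Sign convention: within each component the largest-magnitude loading
    is made positive, so scores are reproducible across runs.  Variance
    fractions of numerically degenerate components are clamped to 0.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 features")
    norm = normalize_counts(matrix, size_factors)
    logged = np.log2(norm + 1.0)
    x = logged.T.to_numpy()  # samples x features; PCA centers features
    n_components = min(n_components, min(x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()  # features x PCs
    for j in range(n_components):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    var = np.clip(pca.explained_variance_ratio_, 0.0, 1.0)
    var[pca.explained_variance_ < 1e-12] = 0.0
    loadings_df = pd.DataFrame(loadings, index=matrix.index, columns=pcs)
    top = {
        pc: loadings_df[pc].abs().sort_values(ascending=False).head(top_n)
        for pc in pcs
    }
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=pcs),
        loadings=loadings_df,
        variance_explained=pd.Series(var, index=pcs, name="variance_explained"),
        top_loadings=top,
    )
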