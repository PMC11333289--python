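"""Methylation count I/O, beta matrices, coverage filtering and PCA.

Per-CpG methylated/total read counts are the substrate of every analysis
stage.  Counts are held in a :class:`CountMatrix` (sites x samples integer
arrays plus a coordinate frame); methylation proportions ("beta values",
methylated / total) live in a :class:`BetaMatrix` with NaN marking sites
without coverage.

Coordinate conventions
----------------------
Internally every position is 0-based and regions are half-open ``[start,
end)``, i.e. BED-compatible.  Bismark-style coverage files on disk are
1-based inclusive; :func:`read_coverage` / :func:`write_coverage` convert at
the boundary.  Input is assumed strand-collapsed per CpG dyad; no dyad
merging is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "BetaMatrix",
    "read_coverage",
    "write_coverage",
    "write_bedgraph",
    "compute_beta",
    "filter_coverage",
    "global_methylation",
    "variable_site_pca",
    "site_ids",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_sorted(sites: pd.DataFrame) -> None:
    key = sites[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"], ignore_index=True)):
        raise ValueError("sites must be sorted by (chrom, pos)")


@dataclass
class CountMatrix:
    """Per-CpG (methylated, total) read counts across samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str) and ``pos`` (0-based int),
        sorted by (chrom, pos), one row per CpG.
    samples
        Ordered sample identifiers, one per column of the count arrays.
    meth, total
        ``(n_sites, n_samples)`` nonnegative integer arrays with
        ``meth <= total`` elementwise.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = list(self.samples)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n, m = self.meth.shape
        if self.total.shape != (n, m):
            raise ValueError("meth and total shapes differ")
        if n != len(self.sites) or m != len(self.samples):
            raise ValueError("count array shape does not match sites/samples")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative counts")
        if (self.meth > self.total).any():
            raise ValueError("methylated count exceeds total coverage")
        _check_sorted(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> pd.Index:
        return site_ids(self.sites)

    def subset_sites(self, mask_or_index) -> "CountMatrix":
        idx = np.arange(self.n_sites)[mask_or_index]
        return CountMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.samples,
            self.meth[idx],
            self.total[idx],
        )


@dataclass
class BetaMatrix:
    """Methylation proportions per site and sample; NaN where total == 0."""

    sites: pd.DataFrame
    samples: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = list(self.samples)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.sites), len(self.samples)):
            raise ValueError("beta shape does not match sites/samples")
        with np.errstate(invalid="ignore"):
            bad = (self.beta < 0) | (self.beta > 1)
        if bad.any():
            raise ValueError("beta values outside [0, 1]")
        _check_sorted(self.sites)

    def site_ids(self) -> pd.Index:
        return site_ids(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.site_ids(), columns=self.samples)


def site_ids(sites: pd.DataFrame) -> pd.Index:
    """``chrom:pos`` identifiers (0-based position)."""
    return pd.Index(sites["chrom"].astype(str) + ":" + sites["pos"].astype(str))


# ---------------------------------------------------------------------------
# coverage-file I/O (Bismark coverage format, 1-based inclusive)
# ---------------------------------------------------------------------------

_COV_COLUMNS = ["chrom", "start", "end", "pct_meth", "count_meth", "count_unmeth"]


def _read_one_coverage(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_COV_COLUMNS,
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "pct_meth": float,
                "count_meth": np.int64,
                "count_unmeth": np.int64,
            },
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed coverage file {path}: {exc}") from None
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        bad = int(np.flatnonzero((df["count_meth"] < 0) | (df["count_unmeth"] < 0))[0]) + 1
        raise ValueError(f"negative count in {path} at line {bad}")
    return df


def read_coverage(paths: Sequence, sample_ids: Sequence[str]) -> CountMatrix:
    """Read one Bismark-style coverage file per sample into a CountMatrix.

    The union of CpG sites across files is taken; a (site, sample) pair
    absent from a file gets ``total = 0``.  On-disk 1-based inclusive
    positions are converted to the internal 0-based convention.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("need exactly one path per sample id")
    per_sample = {}
    for path, sid in zip(paths, sample_ids):
        df = _read_one_coverage(path)
        df["pos"] = df["start"] - 1  # 1-based -> 0-based
        per_sample[sid] = df.set_index(["chrom", "pos"])

    union = None
    for sid, df in per_sample.items():
        idx = df.index
        union = idx if union is None else union.union(idx)
    if union is None or len(union) == 0:
        sites = pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
        z = np.zeros((0, len(sample_ids)), dtype=np.int64)
        return CountMatrix(sites, list(sample_ids), z, z.copy())
    union = union.sortlevel()[0]

    n = len(union)
    meth = np.zeros((n, len(sample_ids)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, sid in enumerate(sample_ids):
        df = per_sample[sid].reindex(union)
        m = df["count_meth"].to_numpy()
        u = df["count_unmeth"].to_numpy()
        present = ~np.isnan(m)
        meth[present, j] = m[present].astype(np.int64)
        total[present, j] = (m[present] + u[present]).astype(np.int64)

    sites = pd.DataFrame(
        {"chrom": union.get_level_values(0), "pos": union.get_level_values(1).astype(np.int64)}
    )
    return CountMatrix(sites, list(sample_ids), meth, total)


def write_coverage(cm: CountMatrix, directory, suffix: str = ".cov") -> list[Path]:
    """Write one Bismark coverage file per sample; rows with total 0 are omitted.

    Returns the written paths in sample order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    chrom = cm.sites["chrom"].to_numpy()
    start1 = cm.sites["pos"].to_numpy() + 1  # 0-based -> 1-based inclusive
    for j, sid in enumerate(cm.samples):
        covered = cm.total[:, j] > 0
        m = cm.meth[covered, j]
        t = cm.total[covered, j]
        out = pd.DataFrame(
            {
                "chrom": chrom[covered],
                "start": start1[covered],
                "end": start1[covered],
                "pct": np.round(100.0 * m / t, 6),
                "meth": m,
                "unmeth": t - m,
            }
        )
        path = directory / f"{sid}{suffix}"
        out.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def write_bedgraph(bm: BetaMatrix, sample: str, path) -> None:
    """Write one sample's beta values as bedGraph (0-based half-open)."""
    j = bm.samples.index(sample)
    keep = ~np.isnan(bm.beta[:, j])
    out = pd.DataFrame(
        {
            "chrom": bm.sites["chrom"].to_numpy()[keep],
            "start": bm.sites["pos"].to_numpy()[keep],
            "end": bm.sites["pos"].to_numpy()[keep] + 1,
            "beta": np.round(bm.beta[keep, j], 6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# beta computation and filtering
# ---------------------------------------------------------------------------

def compute_beta(cm: CountMatrix) -> BetaMatrix:
    """beta = meth / total, NaN where total == 0.  No smoothing, no pseudocount."""
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(cm.total > 0, cm.meth / np.maximum(cm.total, 1), np.nan)
    return BetaMatrix(cm.sites, cm.samples, beta)


def filter_coverage(cm: CountMatrix, min_exclusive: int = 5) -> CountMatrix:
    """Keep sites with coverage strictly greater than ``min_exclusive`` in every sample.

    The default reproduces the common "more than five reads in all samples"
    rule.  Idempotent; larger thresholds select subsets.
    """
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    mask = (cm.total > min_exclusive).all(axis=1)
    if not mask.any():
        warnings.warn("coverage filter removed every site", stacklevel=2)
    return cm.subset_sites(mask)


def global_methylation(bm: BetaMatrix) -> pd.DataFrame:
    """Per-sample unweighted mean and median beta over covered sites.

    Samples with no covered site get NaN summaries.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(bm.beta, axis=0)
        median = np.nanmedian(bm.beta, axis=0)
        n_cov = np.sum(~np.isnan(bm.beta), axis=0)
    return pd.DataFrame(
        {"sample_id": bm.samples, "mean_beta": mean, "median_beta": median, "n_sites": n_cov}
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# variable-site PCA
# ---------------------------------------------------------------------------

def variable_site_pca(
    bm: BetaMatrix, n_top: int = 3000, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray, pd.Index]:
    """PCA on the most variable CpG sites.

    Sites containing any missing beta are excluded, the remaining sites are
    ranked by across-sample variance (ties broken by genomic order) and the
    top ``n_top`` are centered per site (no unit-variance scaling) and
    decomposed by SVD.  Each component's loading vector is oriented so its
    sum is nonnegative.

    Returns ``(scores, variance_explained, chosen_site_ids)`` where scores is
    a (samples x components) DataFrame and variance_explained the fraction of
    the selected-site variance captured per component.
    """
    if bm.beta.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = ~np.isnan(bm.beta).any(axis=1)
    beta = bm.beta[complete]
    ids = bm.site_ids()[complete]
    var = beta.var(axis=1, ddof=1)
    # stable sort on -var keeps (chrom, pos) order among ties
    order = np.argsort(-var, kind="stable")[: min(n_top, len(var))]
    order = np.sort(order)  # keep genomic order of the chosen sites
    X = beta[order].T  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(X.shape))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    scores = (U * S) * flip
    total_var = (S**2).sum()
    varexp = (S**2 / total_var) if total_var > 0 else np.zeros_like(S)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    score_df = pd.DataFrame(scores[:, :n_components], index=bm.samples, columns=cols)
    return score_df, varexp[:n_components], ids[order]
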