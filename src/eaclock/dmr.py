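"""Two-group differential methylation testing and DMR segmentation.

The per-CpG test is a Wald test on arcsine-square-root transformed
methylation proportions with coverage-weighted group means and a pooled,
moment-estimated biological variance.  It approximates the behaviour of
dispersion-shrinkage beta-binomial tests used for WGBS two-group
comparisons but is deliberately simple and closed-form:

    y_ij = arcsin( sqrt( (meth_ij + 0.5) / (total_ij + 1) ) )

On this scale the sampling variance of y is approximately 1/(4 n) for
coverage n, independent of the methylation level, which makes a z statistic
with an additive biological-variance term well calibrated.

Candidate CpGs (p below a threshold) are segmented into differentially
methylated regions (DMRs): maximal same-sign runs with bounded genomic gaps,
a minimum CpG count, and a merge step for nearby same-sign regions.  Each
DMR carries a signed *area statistic* — the sum of member z values — and the
signature program is the top-K DMRs by absolute area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methio import CountMatrix

__all__ = [
    "SiteStats",
    "Dmr",
    "SignatureProgram",
    "test_sites",
    "call_dmrs",
    "select_top",
    "region_p_value",
    "rank_metric",
    "score_regions",
    "dmrs_to_bed",
    "read_bed",
]

#: floor for the moment-estimated biological variance on the arcsine scale
BIO_VAR_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# per-site testing
# ---------------------------------------------------------------------------

SiteStats = pd.DataFrame
"""Per-site statistics frame: chrom, pos, mean_a, mean_b (transformed scale),
raw_mean_a, raw_mean_b, delta (raw beta difference B - A), z, p."""


def _transform(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt((meth + 0.5) / (total + 1.0)))


def _group_summaries(meth, total):
    """Weighted mean, unweighted residual variance and mean sampling variance."""
    y = _transform(meth, total)
    w = total.astype(float)
    wsum = w.sum(axis=1)
    ok = wsum > 0
    ybar = np.full(len(y), np.nan)
    ybar[ok] = (y * w).sum(axis=1)[ok] / wsum[ok]
    n = meth.shape[1]
    yc = y - y.mean(axis=1, keepdims=True)
    var_emp = (yc**2).sum(axis=1) / (n - 1)
    samp = (1.0 / (4.0 * (total + 0.5))).mean(axis=1)
    raw = np.full(len(y), np.nan)
    raw[ok] = meth.sum(axis=1)[ok] / wsum[ok]
    return ybar, var_emp, samp, raw, ok


def test_sites(
    cm: CountMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> SiteStats:
    """Per-CpG Wald test of group B versus group A methylation.

    Positive z means higher methylation in group B (conventionally the
    older / high-division group).  Sites with zero total coverage across all
    samples of either group get NaN statistics.
    """
    ia = [cm.samples.index(s) for s in group_a]
    ib = [cm.samples.index(s) for s in group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 samples")

    ya, va, sa, raw_a, ok_a = _group_summaries(cm.meth[:, ia], cm.total[:, ia])
    yb, vb, sb, raw_b, ok_b = _group_summaries(cm.meth[:, ib], cm.total[:, ib])
    na, nb = len(ia), len(ib)

    # pooled moment estimate of biological variance on the transformed scale
    bio_a = va - sa
    bio_b = vb - sb
    bio = ((na - 1) * bio_a + (nb - 1) * bio_b) / (na + nb - 2)
    bio = np.maximum(bio, BIO_VAR_FLOOR)

    se = np.sqrt((sa + bio) / na + (sb + bio) / nb)
    ok = ok_a & ok_b
    z = np.full(cm.n_sites, np.nan)
    z[ok] = (yb[ok] - ya[ok]) / se[ok]
    p = np.full(cm.n_sites, np.nan)
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "chrom": cm.sites["chrom"],
            "pos": cm.sites["pos"],
            "mean_a": ya,
            "mean_b": yb,
            "raw_mean_a": raw_a,
            "raw_mean_b": raw_b,
            "delta": raw_b - raw_a,
            "z": z,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class Dmr:
    """A differentially methylated region (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    area_stat: float  # sum of member z values
    mean_diff: float  # mean raw beta difference over members
    member_pos: tuple[int, ...] = field(default_factory=tuple, repr=False)
    gene: str | None = None

    @property
    def direction(self) -> str:
        return "gain" if self.area_stat > 0 else "loss"


def call_dmrs(
    stats_df: SiteStats,
    p_thresh: float = 0.01,
    max_gap_bp: int = 300,
    min_cpg: int = 3,
    merge_dist_bp: int = 100,
) -> list[Dmr]:
    """Segment candidate CpGs into DMRs.

    Candidates are sites with ``p < p_thresh``.  Maximal runs of same-sign
    candidates whose consecutive genomic gaps are at most ``max_gap_bp``
    become proto-regions; regions with fewer than ``min_cpg`` candidates are
    dropped, then surviving same-sign regions separated by less than
    ``merge_dist_bp`` are merged.  The region end is the last member
    position + 1.
    """
    df = stats_df
    key = df[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"], ignore_index=True).astype(key.dtypes)):
        raise ValueError("site statistics must be sorted by (chrom, pos)")

    cand = df[(df["p"] < p_thresh) & df["z"].notna() & (df["z"] != 0)]
    out: list[Dmr] = []
    for chrom, sub in cand.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        z = sub["z"].to_numpy()
        delta = sub["delta"].to_numpy()
        if len(pos) == 0:
            continue
        # break runs at sign changes or gaps beyond max_gap_bp
        brk = np.flatnonzero(
            (np.diff(pos) > max_gap_bp) | (np.sign(z[:-1]) != np.sign(z[1:]))
        )
        starts = np.concatenate(([0], brk + 1))
        ends = np.concatenate((brk + 1, [len(pos)]))
        regions = [
            (int(pos[s]), int(pos[e - 1]) + 1, s, e)
            for s, e in zip(starts, ends)
            if e - s >= min_cpg
        ]
        # merge nearby same-sign surviving regions
        merged: list[list[int]] = []
        for r in regions:
            if (
                merged
                and r[0] - merged[-1][1] < merge_dist_bp
                and np.sign(z[r[2]]) == np.sign(z[merged[-1][2]])
            ):
                merged[-1][1] = r[1]
                merged[-1][3] = r[3]
            else:
                merged.append(list(r))
        for start, end, s, e in merged:
            out.append(
                Dmr(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_cpgs=e - s,
                    area_stat=float(z[s:e].sum()),
                    mean_diff=float(delta[s:e].mean()),
                    member_pos=tuple(int(x) for x in pos[s:e]),
                )
            )
    return out


@dataclass
class SignatureProgram:
    """Top-K DMRs by absolute area statistic plus the derivation parameters."""

    dmrs: list[Dmr]
    k: int
    direction: str = "both"
    params: dict = field(default_factory=dict)
    name: str = "signature"

    def __len__(self) -> int:
        return len(self.dmrs)

    def regions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [d.chrom for d in self.dmrs],
                "start": [d.start for d in self.dmrs],
                "end": [d.end for d in self.dmrs],
                "area_stat": [d.area_stat for d in self.dmrs],
                "n_cpgs": [d.n_cpgs for d in self.dmrs],
                "direction": [d.direction for d in self.dmrs],
            }
        )


def select_top(
    dmrs: Sequence[Dmr], k: int = 150, direction: str = "both", **params
) -> SignatureProgram:
    """Keep the K DMRs with the largest |area statistic|.

    ``direction`` restricts to gain or loss regions first; ties in |area|
    break by (chrom, start).
    """
    if direction not in ("both", "gain", "loss"):
        raise ValueError("direction must be both, gain or loss")
    pool = [d for d in dmrs if direction == "both" or d.direction == direction]
    pool.sort(key=lambda d: (-abs(d.area_stat), d.chrom, d.start))
    return SignatureProgram(dmrs=pool[:k], k=k, direction=direction, params=dict(params))


# ---------------------------------------------------------------------------
# gene-level rank metric (preranked-GSEA input)
# ---------------------------------------------------------------------------

def region_p_value(dmr: Dmr) -> float:
    """Stouffer-style region p: two-sided normal tail of area / sqrt(n_cpgs)."""
    zr = dmr.area_stat / math.sqrt(dmr.n_cpgs)
    p = 2.0 * stats.norm.sf(abs(zr))
    return max(p, np.finfo(float).tiny)


def rank_metric(dmrs: Sequence[Dmr]) -> pd.Series:
    """Per-gene rank value: sign(methylation change) x -log10(region p).

    Each DMR must carry a gene label.  A gene with several DMRs is
    represented by the single DMR with the largest absolute rank.
    """
    best: dict[str, float] = {}
    for d in dmrs:
        if d.gene is None:
            raise ValueError(f"DMR {d.chrom}:{d.start}-{d.end} has no gene label")
        r = math.copysign(-math.log10(region_p_value(d)), d.mean_diff if d.mean_diff != 0 else d.area_stat)
        if d.gene not in best or abs(r) > abs(best[d.gene]):
            best[d.gene] = r
    return pd.Series(best, name="rank").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# region scoring
# ---------------------------------------------------------------------------

def _region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, SignatureProgram):
        regions = regions.dmrs
    if isinstance(regions, pd.DataFrame):
        return regions[["chrom", "start", "end"]].copy()
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )


def score_regions(
    cm: CountMatrix, regions
) -> tuple[pd.DataFrame, pd.Series]:
    """Pooled region methylation per sample, and the per-sample mean score.

    For each region, methylation is the pooled ratio sum(meth)/sum(total)
    over member CpGs.  A region without covered CpGs in a sample is NaN and
    excluded from that sample's mean.  The per-sample mean over regions is
    the signature score.
    """
    reg = _region_frame(regions)
    if len(reg) == 0:
        raise ValueError("empty region set")
    chrom = cm.sites["chrom"].to_numpy()
    pos = cm.sites["pos"].to_numpy()
    n_reg = len(reg)
    meth_sum = np.zeros((n_reg, cm.n_samples))
    tot_sum = np.zeros((n_reg, cm.n_samples))
    # sites are sorted by (chrom, pos): binary-search per chromosome block
    chrom_bounds = {}
    for c in pd.unique(chrom):
        lo = np.searchsorted(chrom, c, side="left")
        hi = np.searchsorted(chrom, c, side="right")
        chrom_bounds[c] = (lo, hi)
    for i, row in enumerate(reg.itertuples(index=False)):
        if row.chrom not in chrom_bounds:
            continue
        lo, hi = chrom_bounds[row.chrom]
        s = lo + np.searchsorted(pos[lo:hi], row.start, side="left")
        e = lo + np.searchsorted(pos[lo:hi], row.end, side="left")
        meth_sum[i] = cm.meth[s:e].sum(axis=0)
        tot_sum[i] = cm.total[s:e].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(tot_sum > 0, meth_sum / np.maximum(tot_sum, 1), np.nan)
    names = [f"{c}:{s}-{e}" for c, s, e in reg.itertuples(index=False)]
    level_df = pd.DataFrame(level, index=names, columns=cm.samples)
    score = level_df.mean(axis=0, skipna=True)
    score.name = "score"
    return level_df, score


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def dmrs_to_bed(dmrs: Sequence[Dmr], path, program: SignatureProgram | None = None) -> None:
    """Write DMRs as BED6+3 (name=rank, score=|area| clamped to 0-1000,
    strand '.', extra columns n_cpgs, mean_diff, direction).  If the DMRs
    come from a signature program, a JSON sidecar records the derivation
    parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        for rank, d in enumerate(dmrs, start=1):
            score = int(min(abs(d.area_stat), 1000.0))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tdmr_{rank}\t{score}\t.\t"
                f"{d.n_cpgs}\t{d.mean_diff:.6g}\t{d.direction}\n"
            )
    if program is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "k": program.k,
                    "direction": program.direction,
                    "params": program.params,
                    "n_dmrs": len(program.dmrs),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a (chrom, start, end, ...) frame."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    names = ["chrom", "start", "end", "name", "score", "strand", "n_cpgs", "mean_diff", "direction"]
    df.columns = names[: df.shape[1]] + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    return df
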