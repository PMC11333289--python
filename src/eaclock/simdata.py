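"""Synthetic WGBS-like cohorts with methylation drift tied to cell divisions.

The generator emulates a serial-transplant T cell aging design: memory cells
accumulate divisions (``D``, the experiential-age axis) across boost/rest
cycles while living in hosts of some chronological age (``A``, months).
Methylation drift is coupled to ``D`` at planted "clock" loci and only
weakly, at a separate small set of loci, to ``A`` — so recovery analyses can
ask whether a derived signature tracks replicative history rather than host
age.

Site classes and their mean-methylation surfaces:

* ``gain``    — mu(D) = b + (1 - b) * (1 - exp(-k * D)); low baseline b,
  saturating gain with divisions.  Gain sites are planted in contiguous runs
  (default 8 CpGs within 400 bp) so region callers can find them.
* ``loss``    — mu(D) = b * exp(-loss_rate * D); high baseline, global
  demethylation with divisions.
* ``hostage`` — saturating gain in host age A (small amplitude), independent
  of D.
* ``stable``  — constant baseline drawn from a bimodal WGBS-like mixture.

Counts are beta-binomial around mu with intraclass correlation ``phi``;
per-record coverage is negative binomial.  The same seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methio import CountMatrix

__all__ = [
    "SampleSpec",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "write_truth",
    "read_truth",
    "gain_mu",
    "loss_mu",
    "rate_for_delta",
    "two_group_design",
    "ladder_design",
    "crossed_design",
    "rest_design",
    "MONTHS_PER_LT",
    "months_to_lt",
]

#: One organismal lifetime in months (mouse lifespan of 2.5 years).
MONTHS_PER_LT = 30.0

#: Nominal divisions induced per boost cycle (a free design parameter).
DIVISIONS_PER_BOOST = 10.0


def months_to_lt(months: float) -> float:
    return months / MONTHS_PER_LT


# ---------------------------------------------------------------------------
# drift surfaces
# ---------------------------------------------------------------------------

def gain_mu(b, k, d):
    """Saturating gain: b + (1 - b)(1 - exp(-k d)); bounded by 1."""
    return b + (1.0 - b) * (1.0 - np.exp(-k * np.asarray(d, dtype=float)))


def loss_mu(b, rate, d):
    """Exponential demethylation: b * exp(-rate d)."""
    return b * np.exp(-rate * np.asarray(d, dtype=float))


def rate_for_delta(delta: float, baseline: float, d: float) -> float:
    """Saturation rate k giving a methylation gain of ``delta`` at ``d`` divisions.

    Solves (1 - baseline)(1 - exp(-k d)) = delta.
    """
    frac = delta / (1.0 - baseline)
    if not 0 < frac < 1:
        raise ValueError("delta must lie in (0, 1 - baseline)")
    return -math.log(1.0 - frac) / d


#: default per-division gain rate: +0.4 beta at D = 16 from baseline 0.05
DEFAULT_GAIN_RATE = rate_for_delta(0.4, 0.05, 16.0)
#: default host-age rate: +0.1 beta over one 30-month lifespan from baseline 0.05
DEFAULT_HOSTAGE_RATE = rate_for_delta(0.1, 0.05, MONTHS_PER_LT)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """One simulated sample: a T cell population with a division history."""

    sample_id: str
    group: str
    divisions: float  # cumulative division count D (experiential age proxy)
    host_age: float = 6.0  # months
    rest_days: int = 60  # metadata only (30 or 60 in the source design)
    replicate: int = 0

    def __post_init__(self):
        if self.divisions < 0 or self.host_age < 0:
            raise ValueError("divisions and host_age must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_sites: int = 20_000
    n_chroms: int = 2
    samples: tuple[SampleSpec, ...] = ()
    frac_gain: float = 0.08  # 200 runs of 8 CpGs at the default n_sites
    frac_loss: float = 0.10
    frac_hostage: float = 0.01
    gain_rate: float = DEFAULT_GAIN_RATE
    loss_rate: float = 0.02
    hostage_rate: float = DEFAULT_HOSTAGE_RATE
    baseline_beta_gain: float = 0.05
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0
    bio_dispersion: float = 0.02  # beta-binomial intraclass correlation phi
    run_len: int = 8  # CpGs per planted gain run
    run_span_bp: int = 400  # genomic span of a planted run
    site_spacing_bp: int = 1000  # background CpG spacing
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        fracs = (self.frac_gain, self.frac_loss, self.frac_hostage)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("site-class fractions must be in [0,1] and sum to <= 1")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not self.samples:
            raise ValueError("at least one sample is required")
        if min(self.gain_rate, self.loss_rate, self.hostage_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0 <= self.bio_dispersion < 0.5:
            raise ValueError("bio_dispersion must be in [0, 0.5)")
        if self.run_len < 1:
            raise ValueError("run_len must be >= 1")


@dataclass
class SimTruth:
    """Planted ground truth: site classes, the mu(D, A) surface and gain regions."""

    site_class: np.ndarray  # per-site label: gain | loss | hostage | stable
    mu: np.ndarray  # (n_sites, n_samples) expected beta
    gain_regions: pd.DataFrame  # chrom, start, end (0-based half-open), sorted

    def class_mask(self, label: str) -> np.ndarray:
        return self.site_class == label


# ---------------------------------------------------------------------------
# sample-design factories
# ---------------------------------------------------------------------------

def two_group_design(
    d_a: float = 0.0, d_b: float = 16.0, n: int = 3, host_age: float = 6.0
) -> tuple[SampleSpec, ...]:
    """n vs n comparison at low vs high division counts (same host age)."""
    young = [
        SampleSpec(f"young_{i}", "young", d_a, host_age, replicate=i) for i in range(n)
    ]
    aged = [SampleSpec(f"ml_{i}", "ml", d_b, host_age, replicate=i) for i in range(n)]
    return tuple(young + aged)


def ladder_design(
    divisions: Sequence[float] = (0, 2, 4, 8, 16), n: int = 2, host_age: float = 6.0
) -> tuple[SampleSpec, ...]:
    """Division ladder: n replicates at each division count."""
    out = []
    for d in divisions:
        for i in range(n):
            out.append(SampleSpec(f"d{d:g}_{i}", f"d{d:g}", float(d), host_age, replicate=i))
    return tuple(out)


def crossed_design(
    d_levels: tuple[float, float] = (2.0, 16.0),
    age_levels: tuple[float, float] = (3.0, 30.0),
    n: int = 3,
) -> tuple[SampleSpec, ...]:
    """2x2 design crossing division count with host age (decoupling test)."""
    out = []
    for d_lab, d in zip(("dlo", "dhi"), d_levels):
        for a_lab, a in zip(("young", "old"), age_levels):
            for i in range(n):
                out.append(
                    SampleSpec(f"{d_lab}_{a_lab}_{i}", f"{d_lab}_{a_lab}", d, a, replicate=i)
                )
    return tuple(out)


def rest_design(
    d_short: float = 10.0, d_long: float = 16.0, n: int = 3, host_age: float = 24.0
) -> tuple[SampleSpec, ...]:
    """30-day vs 60-day rest arms after equally many boosts.

    Longer rests allow fuller homeostatic recovery and larger proliferative
    bursts, so the 60-day arm accumulates more divisions.
    """
    arm30 = [
        SampleSpec(f"rest30_{i}", "rest30", d_short, host_age, rest_days=30, replicate=i)
        for i in range(n)
    ]
    arm60 = [
        SampleSpec(f"rest60_{i}", "rest60", d_long, host_age, rest_days=60, replicate=i)
        for i in range(n)
    ]
    return tuple(arm30 + arm60)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _layout_sites(cfg: SimConfig, rng: np.random.Generator):
    """Place CpGs on chromosomes; plant gain runs as tight clusters.

    Returns (sites frame, site_class array, gain_regions frame).
    """
    n = cfg.n_sites
    per_chrom = [n // cfg.n_chroms] * cfg.n_chroms
    per_chrom[-1] += n - sum(per_chrom)

    n_gain = int(round(cfg.frac_gain * n))
    n_runs = n_gain // cfg.run_len
    n_gain = n_runs * cfg.run_len
    run_gap = max(1, cfg.run_span_bp // max(cfg.run_len - 1, 1))

    chroms, positions = [], []
    site_class = np.full(n, "stable", dtype=object)
    regions = []

    # spread runs across chromosomes proportionally to site counts
    runs_per_chrom = [int(round(n_runs * c / n)) for c in per_chrom]
    runs_per_chrom[-1] += n_runs - sum(runs_per_chrom)

    offset = 0
    for ci, (n_c, n_r) in enumerate(zip(per_chrom, runs_per_chrom)):
        name = f"chr{ci + 1}"
        run_starts: list[int] = []
        if n_r > 0 and n_c >= cfg.run_len:
            # one run per equal-width block of site indices, random offset inside
            block = n_c // n_r
            for b in range(n_r):
                lo = b * block
                hi = min((b + 1) * block, n_c) - cfg.run_len
                if hi < lo:
                    continue
                run_starts.append(int(rng.integers(lo, hi + 1)))
        in_run = np.zeros(n_c, dtype=bool)
        run_id = np.full(n_c, -1, dtype=np.int64)
        for s in run_starts:
            in_run[s : s + cfg.run_len] = True
            run_id[s : s + cfg.run_len] = s

        # tight spacing only between consecutive members of the same run
        steps = np.full(n_c, cfg.site_spacing_bp, dtype=np.int64)
        if n_c > 1:
            same = (run_id[:-1] == run_id[1:]) & (run_id[:-1] >= 0)
            steps[:-1][same] = run_gap
        pos = 1000 + np.concatenate(([0], np.cumsum(steps[:-1])))
        chroms.append(np.full(n_c, name, dtype=object))
        positions.append(pos)
        site_class[offset : offset + n_c][in_run] = "gain"
        for s in run_starts:
            regions.append((name, int(pos[s]), int(pos[s + cfg.run_len - 1]) + 1))
        offset += n_c

    sites = pd.DataFrame(
        {"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)}
    )
    # scatter loss and host-age sites among the remaining singletons
    free = np.flatnonzero(site_class == "stable")
    n_loss = int(round(cfg.frac_loss * n))
    n_host = int(round(cfg.frac_hostage * n))
    picked = rng.choice(free, size=min(n_loss + n_host, len(free)), replace=False)
    site_class[picked[:n_loss]] = "loss"
    site_class[picked[n_loss : n_loss + n_host]] = "hostage"

    gain_regions = (
        pd.DataFrame(regions, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"], ignore_index=True)
    )
    return sites, site_class, gain_regions


def _baselines(cfg: SimConfig, site_class: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-site baseline beta: gain loci start low, loss loci high, stable bimodal."""
    n = len(site_class)
    b = np.empty(n)
    b[site_class == "gain"] = cfg.baseline_beta_gain
    b[site_class == "hostage"] = cfg.baseline_beta_gain
    loss = site_class == "loss"
    b[loss] = rng.beta(9, 1, size=loss.sum())
    stable = site_class == "stable"
    ns = stable.sum()
    comp = rng.choice(3, size=ns, p=[0.6, 0.3, 0.1])
    vals = np.empty(ns)
    vals[comp == 0] = rng.beta(9, 1, size=(comp == 0).sum())  # mostly methylated
    vals[comp == 1] = rng.beta(1, 9, size=(comp == 1).sum())  # mostly unmethylated
    vals[comp == 2] = rng.uniform(0.2, 0.8, size=(comp == 2).sum())  # intermediate
    b[stable] = vals
    return b


def _mu_surface(cfg: SimConfig, site_class: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    d = np.array([s.divisions for s in cfg.samples])
    a = np.array([s.host_age for s in cfg.samples])
    n, m = len(site_class), len(cfg.samples)
    mu = np.tile(baseline[:, None], (1, m))
    gain = site_class == "gain"
    mu[gain] = gain_mu(baseline[gain, None], cfg.gain_rate, d[None, :])
    loss = site_class == "loss"
    mu[loss] = loss_mu(baseline[loss, None], cfg.loss_rate, d[None, :])
    host = site_class == "hostage"
    mu[host] = gain_mu(baseline[host, None], cfg.hostage_rate, a[None, :])
    return np.clip(mu, 0.0, 1.0)


def simulate_cohort(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw a full synthetic cohort.

    Returns the count matrix, a sample metadata table (sample_id, group,
    divisions, host_age, age_lt, rest_days, replicate) and the planted truth.
    """
    rng = np.random.default_rng(cfg.seed)
    sites, site_class, gain_regions = _layout_sites(cfg, rng)
    baseline = _baselines(cfg, site_class, rng)
    mu = _mu_surface(cfg, site_class, baseline)

    n, m = mu.shape
    r = cfg.coverage_dispersion
    p_nb = r / (r + cfg.coverage_mean)
    total = rng.negative_binomial(r, p_nb, size=(n, m)).astype(np.int64)

    phi = cfg.bio_dispersion
    if phi > 0:
        # beta-binomial via a latent per-(site, sample) methylation proportion
        conc = (1.0 - phi) / phi
        alpha = np.clip(mu * conc, 1e-9, None)
        beta_par = np.clip((1.0 - mu) * conc, 1e-9, None)
        p_lat = rng.beta(alpha, beta_par)
    else:
        p_lat = mu
    meth = rng.binomial(total, p_lat).astype(np.int64)

    cm = CountMatrix(sites, [s.sample_id for s in cfg.samples], meth, total)
    table = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cfg.samples],
            "group": [s.group for s in cfg.samples],
            "divisions": [s.divisions for s in cfg.samples],
            "host_age": [s.host_age for s in cfg.samples],
            "age_lt": [months_to_lt(s.host_age) for s in cfg.samples],
            "rest_days": [s.rest_days for s in cfg.samples],
            "replicate": [s.replicate for s in cfg.samples],
        }
    )
    truth = SimTruth(site_class=site_class, mu=mu, gain_regions=gain_regions)
    return cm, table, truth


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, sites: pd.DataFrame, directory) -> tuple[Path, Path]:
    """Write planted gain regions as BED and per-site classes as TSV.

    Returns (bed_path, tsv_path).  Round-trips losslessly via
    :func:`read_truth`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bed_path = directory / "planted_regions.bed"
    regions = truth.gain_regions.sort_values(["chrom", "start"])
    with open(bed_path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tgain\n")
    tsv_path = directory / "site_classes.tsv"
    pd.DataFrame(
        {"chrom": sites["chrom"], "pos": sites["pos"], "site_class": truth.site_class}
    ).to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def read_truth(bed_path, tsv_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back what :func:`write_truth` wrote."""
    try:
        regions = pd.read_csv(
            bed_path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
        )
    except pd.errors.EmptyDataError:
        regions = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    classes = pd.read_csv(tsv_path, sep="\t")
    return regions, classes
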