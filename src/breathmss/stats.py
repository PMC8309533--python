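"""Purge-RH subgrouping and nonparametric group comparisons.

Measurements are binned by the relative humidity of their purge gas
(default edges 20/30/40/50 %RH, left-closed bins with the last bin closed).
Group differences are assessed with the Mann-Whitney U test (exact for
small tie-free samples, tie-corrected normal approximation otherwise) and
the Kruskal-Wallis test; families of pairwise comparisons are Bonferroni
corrected.  Two-tailed p < 0.01 is the default significance level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RHBinning",
    "TestResult",
    "assign_rh_subgroup",
    "mann_whitney_u",
    "kruskal_wallis",
    "bonferroni",
    "subgroup_analysis",
]


@dataclass(frozen=True)
class RHBinning:
    """Breakpoints for the purge-RH subgroups.

    Bins are left-closed/right-open except the last, which is closed, so
    30.0 falls in "30-40" and 50.0 in "40-50".
    """

    edges: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")

    @property
    def labels(self) -> list[str]:
        return [
            f"{self.edges[i]:g}-{self.edges[i + 1]:g}"
            for i in range(len(self.edges) - 1)
        ]


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with its multiplicity context."""

    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    family_size: int = 1

    def adjust(self, m: int) -> "TestResult":
        self.family_size = m
        self.p_adjusted = min(1.0, m * self.p_value)
        return self


def assign_rh_subgroup(
    rh_purge: float, binning: RHBinning | None = None
) -> str | None:
    """Label a measurement by its purge-gas RH bin.

    Values outside the binned range return ``None`` with a logged warning
    (such measurements are excluded from subgroup analyses).
    """
    binning = binning or RHBinning()
    edges = binning.edges
    if not (edges[0] <= rh_purge <= edges[-1]):
        logger.warning("rh_purge=%s outside binned range %s; unbinned", rh_purge, edges)
        return None
    if rh_purge == edges[-1]:
        return binning.labels[-1]
    i = int(np.searchsorted(edges, rh_purge, side="right")) - 1
    return binning.labels[i]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 8
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    The exact null distribution is used when the smaller sample has at most
    ``exact_threshold`` observations and the data are tie-free; otherwise
    the tie-corrected normal approximation with continuity correction.
    The two-sided p is symmetric in the two samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = min(x.size, y.size) <= exact_threshold and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        n_per_group=(int(x.size), int(y.size)),
    )


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H test with tie correction and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    # guard: a pooled spread at round-off level is no between-group variation
    # (ranking machine-epsilon residue would manufacture a spurious H)
    scale = max(1.0, float(np.max(np.abs(pooled))))
    if float(np.ptp(pooled)) <= 1e-9 * scale:
        return TestResult(
            statistic=0.0, p_value=1.0, n_per_group=tuple(a.size for a in arrays)
        )
    res = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=tuple(int(a.size) for a in arrays),
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than {len(p_values)} tests")
    return [min(1.0, m * p) for p in p_values]


@dataclass
class SubgroupAnalysis:
    """Result bundle of :func:`subgroup_analysis`."""

    results: pd.DataFrame
    representative_areas: dict[int, str]
    bin_counts: pd.DataFrame
    alpha: float


def _bin_metadata(metadata: pd.DataFrame, binning: RHBinning) -> pd.DataFrame:
    md = metadata.copy()
    md["rh_bin"] = [assign_rh_subgroup(rh, binning) for rh in md["rh_purge"]]
    unbinned = md["rh_bin"].isna()
    if unbinned.any():
        logger.warning("excluding %d unbinned measurements", int(unbinned.sum()))
    return md[~unbinned]


def subgroup_analysis(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    binning: RHBinning | None = None,
    method: str = "start_point_offset",
    waveform: str = "T1",
    alpha: float = 0.01,
) -> SubgroupAnalysis:
    """RH-subgroup statistics for every (channel, area).

    ``metadata`` needs columns ``measurement_id, sample_type, rh_purge``.
    Per (channel, area) this runs the Kruskal-Wallis test across the three
    RH bins (within breath and within reference), all pairwise Mann-Whitney
    comparisons between bins within each sample type, and breath-vs-
    reference comparisons within each bin.  The pairwise tests of one
    (channel, area) form one Bonferroni family (m = number of comparisons
    performed).  The lowest-p extraction area of the breath Kruskal-Wallis
    test is reported as representative for each channel.
    """
    binning = binning or RHBinning()
    md = _bin_metadata(metadata, binning)
    sub = table[(table["method"] == method) & (table["waveform"] == waveform)]
    merged = sub.merge(
        md[["measurement_id", "sample_type", "rh_bin"]], on="measurement_id"
    )
    bin_counts = (
        md.groupby(["sample_type", "rh_bin"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )

    rows = []
    for (ch, area), g in merged.groupby(["channel", "area"], observed=True):
        by_type = {t: gg for t, gg in g.groupby("sample_type", observed=True)}
        # overall tests across bins, per sample type
        for stype, gg in by_type.items():
            groups = {b: bb["value"].to_numpy() for b, bb in gg.groupby("rh_bin", observed=True)}
            if len(groups) >= 2:
                res = kruskal_wallis(*groups.values())
                rows.append(
                    {
                        "channel": ch,
                        "area": area,
                        "test": "kruskal_wallis",
                        "comparison": f"{stype}:rh_bins",
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "n": sum(res.n_per_group),
                    }
                )
        # pairwise family
        pairwise = []
        for stype, gg in by_type.items():
            groups = {b: bb["value"].to_numpy() for b, bb in gg.groupby("rh_bin", observed=True)}
            for b1, b2 in itertools.combinations(sorted(groups), 2):
                res = mann_whitney_u(groups[b1], groups[b2])
                pairwise.append((f"{stype}:{b1} vs {b2}", res))
        if {"breath", "reference"} <= set(by_type):
            gb = by_type["breath"].groupby("rh_bin", observed=True)
            gr = by_type["reference"].groupby("rh_bin", observed=True)
            bins_b = {b: bb["value"].to_numpy() for b, bb in gb}
            bins_r = {b: bb["value"].to_numpy() for b, bb in gr}
            for b in sorted(set(bins_b) & set(bins_r)):
                res = mann_whitney_u(bins_b[b], bins_r[b])
                pairwise.append((f"breath vs reference:{b}", res))
        m = len(pairwise)
        for name, res in pairwise:
            res.adjust(m)
            rows.append(
                {
                    "channel": ch,
                    "area": area,
                    "test": "mann_whitney_u",
                    "comparison": name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "p_adj": res.p_adjusted,
                    "m": m,
                    "n": sum(res.n_per_group),
                }
            )

    results = pd.DataFrame(rows)
    results["significant"] = (
        results["p_adj"].fillna(results["p"]) < alpha
    )

    rep: dict[int, str] = {}
    kw_breath = results[
        (results["test"] == "kruskal_wallis")
        & (results["comparison"] == "breath:rh_bins")
    ]
    for ch, g in kw_breath.groupby("channel"):
        rep[int(ch)] = str(g.loc[g["p"].idxmin(), "area"])

    return SubgroupAnalysis(
        results=results,
        representative_areas=rep,
        bin_counts=bin_counts,
        alpha=alpha,
    )
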