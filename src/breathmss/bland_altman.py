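"""RH-matched pairing and Bland-Altman reproducibility analysis.

Measurements taken under near-identical purge-gas humidity (difference no
more than 0.1 %RH by default) are paired by a deterministic greedy match,
and the agreement of their feature values is summarized per (channel, area)
by the bias (mean paired difference), the 95% limits of agreement
(bias +/- 1.96 SD of the differences) and the study's bespoke acceptance
band of bias +/- 1 x SD (its "30% confidence interval").  The assay is
called reproducible for a channel when zero lies inside that band in every
extraction area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairSet",
    "BlandAltmanResult",
    "pair_by_rh",
    "bland_altman",
    "reproducibility_decision",
    "plot_bland_altman",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass
class PairSet:
    """RH-matched measurement pairs.

    Each measurement appears in at most one pair and members of a pair
    differ in purge RH by at most ``rh_tolerance``.
    """

    pairs: list[tuple[str, str]]
    rh_tolerance: float = 0.1

    def __len__(self) -> int:
        return len(self.pairs)


def pair_by_rh(metadata: pd.DataFrame, rh_tolerance: float = 0.1) -> PairSet:
    """Greedy deterministic RH matching.

    ``metadata`` needs columns ``measurement_id, rh_purge`` (``date`` is
    used as a tie-break when present).  Measurements are sorted by purge RH
    (then date, then id) and scanned in order; an unused measurement is
    paired with the next unused one — its closest RH neighbour — when their
    RH difference is within tolerance.  The same metadata always yields the
    same pairs.
    """
    cols = ["rh_purge", "date", "measurement_id"]
    sort_cols = [c for c in cols if c in metadata.columns]
    md = metadata.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    ids = md["measurement_id"].tolist()
    rhs = md["rh_purge"].to_numpy(dtype=float)
    used = np.zeros(len(md), dtype=bool)
    pairs: list[tuple[str, str]] = []
    i = 0
    while i < len(md):
        if used[i]:
            i += 1
            continue
        j = i + 1
        while j < len(md) and used[j]:
            j += 1
        if j < len(md) and rhs[j] - rhs[i] <= rh_tolerance:
            pairs.append((ids[i], ids[j]))
            used[i] = used[j] = True
        i += 1
    return PairSet(pairs=pairs, rh_tolerance=rh_tolerance)


@dataclass
class BlandAltmanResult:
    """Agreement summary for one (channel, area).

    ``criterion_low/high`` is the study's acceptance band, bias +/- k x SD
    of the paired differences (k = 1 by default); ``zero_in_criterion`` is
    True when 0 lies inside it.
    """

    channel: int
    area: str
    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    criterion_low: float
    criterion_high: float
    zero_in_criterion: bool
    fraction_within_loa: float
    k: float = 1.0
    differences: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    means: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def bland_altman(
    pairs: PairSet,
    table: pd.DataFrame,
    channel: int,
    area: str,
    k: float = 1.0,
    method: str = "start_point_offset",
    waveform: str = "T1",
) -> BlandAltmanResult:
    """Bland-Altman statistics of the paired feature differences.

    Differences are first-listed minus second-listed pair member; the SD
    uses the n-1 denominator.  Requires at least 2 pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs (SD undefined otherwise)")
    sub = table[
        (table["channel"] == channel)
        & (table["area"] == area)
        & (table["method"] == method)
        & (table["waveform"] == waveform)
    ]
    values = dict(zip(sub["measurement_id"], sub["value"]))
    diffs, means = [], []
    for a, b in pairs.pairs:
        if a not in values or b not in values:
            raise KeyError(f"feature value missing for pair ({a}, {b})")
        diffs.append(values[a] - values[b])
        means.append(0.5 * (values[a] + values[b]))
    d = np.asarray(diffs)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    crit_low, crit_high = bias - k * sd, bias + k * sd
    return BlandAltmanResult(
        channel=channel,
        area=area,
        n_pairs=len(d),
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        criterion_low=crit_low,
        criterion_high=crit_high,
        zero_in_criterion=bool(crit_low <= 0.0 <= crit_high),
        fraction_within_loa=float(np.mean((d >= loa_low) & (d <= loa_high))),
        k=k,
        differences=d,
        means=np.asarray(means),
    )


def reproducibility_decision(
    results: dict[tuple[int, str], BlandAltmanResult],
    channels: tuple[int, ...] = (1, 2, 3),
    areas: tuple[str, ...] | None = None,
) -> dict:
    """Per-channel and overall reproducibility verdict.

    A channel is reproducible iff zero lies within the acceptance band in
    every extraction area; the assay overall iff every channel is.
    """
    if areas is None:
        areas = tuple(sorted({a for (_, a) in results}))
    per_channel: dict[int, bool] = {}
    for ch in channels:
        flags = []
        for area in areas:
            if (ch, area) not in results:
                raise KeyError(f"missing Bland-Altman result for channel {ch}, area {area}")
            flags.append(results[(ch, area)].zero_in_criterion)
        per_channel[ch] = all(flags)
    return {
        "per_channel": per_channel,
        "overall": all(per_channel.values()),
        "areas": list(areas),
    }


def plot_bland_altman(result: BlandAltmanResult, ax=None):
    """Mean-vs-difference plot with bias, LoA and the acceptance band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(result.means, result.differences, s=14, color="k", zorder=3)
    ax.axhspan(result.criterion_low, result.criterion_high, alpha=0.25, color="tab:blue")
    ax.axhline(result.bias, color="k")
    ax.axhline(result.loa_low, color="k", linestyle="--")
    ax.axhline(result.loa_high, color="k", linestyle="--")
    ax.axhline(0.0, color="tab:red", linewidth=0.8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference of pair")
    ax.set_title(f"Ch {result.channel}, area {result.area}")
    return ax
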