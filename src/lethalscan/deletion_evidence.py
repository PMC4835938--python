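"""Orthogonal evidence for a chromosomal deletion.

A hemizygous deletion corrupts array data in characteristic ways: every SNP
inside the deleted interval is called homozygous for the single present
allele (producing a heterozygote deficit against Hardy-Weinberg
proportions), the Log2R intensity drops below zero, and sequencing read
depth is roughly halved.  This module scans for those signatures and
cross-tabulates carrier calls between evidence channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (GenotypeData, IntensityMatrix, MISSING,
                         hardy_weinberg_test, parse_region)

CARRIER = "carrier"
NONCARRIER = "noncarrier"
AMBIGUOUS = "ambiguous"
HOMOZYGOTE = "homozygote"  # anomalous under a recessive lethal


@dataclass
class CarrierCallSet:
    """Per-animal carrier calls from one evidence channel, with the support
    values the call was based on."""

    channel: str
    calls: pd.Series  # sample id -> carrier/noncarrier/ambiguous/homozygote
    support: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(str)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.calls.index]

    def carriers(self) -> list[str]:
        return [str(s) for s in self.calls.index[self.calls == CARRIER]]

    def carrier_frequency(self) -> float:
        informative = self.calls.isin([CARRIER, NONCARRIER, HOMOZYGOTE])
        if informative.sum() == 0:
            return float("nan")
        return float((self.calls == CARRIER).sum() / informative.sum())


# ---------------------------------------------------------------------------
# Hardy-Weinberg deviation scan
# ---------------------------------------------------------------------------

def hwp_scan(g: GenotypeData, region=None, method: str = "chi2") -> pd.DataFrame:
    """Per-marker test against Hardy-Weinberg proportions.

    Returns a table with genotype counts, chi2, p and the deviation
    direction ('het_deficit' marks the excess-homozygosity signature of a
    deletion).  ``region`` optionally restricts to chrom:start-end.  The
    default is the 1-df chi-square without continuity correction;
    ``method='exact'`` substitutes the exact conditional p-value, preferable
    for small samples (the chi-square statistic and direction are still
    reported).
    """
    if method not in ("chi2", "exact"):
        raise ValueError("method must be 'chi2' or 'exact'")
    gg = g
    if region is not None:
        chrom, start, end = parse_region(region)
        pos = g.markers["pos"].to_numpy()
        mask = ((g.markers["chrom"].astype(str) == chrom).to_numpy()
                & (pos >= start) & (pos <= end))
        gg = g.subset_markers(mask)
    counts = gg.genotype_counts()
    chi2, p, direction = hardy_weinberg_test(
        counts["n_ref_hom"].to_numpy(), counts["n_het"].to_numpy(),
        counts["n_alt_hom"].to_numpy())
    if method == "exact":
        from .io_formats import hardy_weinberg_exact

        p = np.array([hardy_weinberg_exact(a, h, b)
                      for a, h, b in zip(counts["n_ref_hom"],
                                         counts["n_het"],
                                         counts["n_alt_hom"])])
    return pd.DataFrame({
        "marker": gg.markers["id"].to_numpy(),
        "pos": gg.markers["pos"].to_numpy(),
        "n_ref_hom": counts["n_ref_hom"].to_numpy(),
        "n_het": counts["n_het"].to_numpy(),
        "n_alt_hom": counts["n_alt_hom"].to_numpy(),
        "chi2": np.atleast_1d(chi2),
        "p": np.atleast_1d(p),
        "direction": np.atleast_1d(direction),
    })


# ---------------------------------------------------------------------------
# Intensity-based carrier calling
# ---------------------------------------------------------------------------

def call_intensity_carriers(intensity: IntensityMatrix, g: GenotypeData,
                            region, mean_threshold: float = 0.0,
                            homozygous_fraction: float = 0.97) -> CarrierCallSet:
    """Call deletion carriers from array intensity plus in-region homozygosity.

    An animal is a carrier iff (a) its mean in-region Log2R is below
    ``mean_threshold`` and (b) at least ceil(homozygous_fraction * m) of the
    m in-region markers are called homozygous (a hemizygote is called
    homozygous everywhere inside the deletion, with a small aberration
    allowed for genotyping error).  Everything else is a noncarrier.
    """
    chrom, start, end = parse_region(region)
    pos = g.markers["pos"].to_numpy()
    in_region = ((g.markers["chrom"].astype(str) == chrom).to_numpy()
                 & (pos >= start) & (pos <= end))
    region_ids = [m for m in g.markers.loc[in_region, "id"]]
    int_index = {m: i for i, m in enumerate(intensity.marker_ids)}
    shared = [m for m in region_ids if m in int_index]
    if len(shared) < 10:
        raise ValueError(
            f"region contains only {len(shared)} markers present in both the "
            "intensity matrix and the genotypes (>= 10 required)")

    g_idx = g.marker_index(shared)
    i_idx = np.array([int_index[m] for m in shared])
    m = len(shared)
    need_hom = math.ceil(homozygous_fraction * m)

    sample_g = {s: i for i, s in enumerate(g.samples)}
    samples = [s for s in intensity.samples if s in sample_g]
    rows_g = np.array([sample_g[s] for s in samples])
    rows_i = np.array([intensity.samples.index(s) for s in samples])

    mean_l2r = intensity.values[np.ix_(i_idx, rows_i)].mean(axis=0)
    dos = g.dosages[np.ix_(rows_g, g_idx)]
    n_hom = ((dos == 0) | (dos == 2)).sum(axis=1)

    is_carrier = (mean_l2r < mean_threshold) & (n_hom >= need_hom)
    calls = pd.Series(np.where(is_carrier, CARRIER, NONCARRIER), index=samples)
    support = pd.DataFrame({
        "mean_log2r": mean_l2r,
        "n_homozygous": n_hom,
        "homozygous_fraction": n_hom / m,
        "n_markers": m,
    }, index=samples)
    return CarrierCallSet(channel="intensity", calls=calls, support=support)


# ---------------------------------------------------------------------------
# Read-depth ratio
# ---------------------------------------------------------------------------

def depth_ratio(depth: pd.DataFrame, region,
                carrier_below: float = 0.7,
                noncarrier_above: float = 0.85) -> CarrierCallSet:
    """Per-animal ratio of mean in-region to mean off-region depth per bp.

    A hemizygous deletion halves coverage, so the ratio concentrates near
    0.5 for carriers and 1.0 for noncarriers; calls are carrier below
    ``carrier_below``, noncarrier above ``noncarrier_above``, ambiguous in
    between.  Windows straddling the region boundary are excluded from both
    means.  A sample with zero off-region depth is uninformative and raises.
    """
    _, start, end = parse_region(region)
    ws = depth["window_start"].to_numpy()
    we = depth["window_end"].to_numpy()
    inside = (ws >= start) & (we <= end)
    outside = (we < start) | (ws > end)
    length = (we - ws + 1).astype(float)

    ratios, calls = {}, {}
    for sample, grp_idx in depth.groupby("sample", sort=False).indices.items():
        idx = np.asarray(grp_idx)
        r_in = depth["reads"].to_numpy()[idx]
        m_in = inside[idx]
        m_out = outside[idx]
        out_len = length[idx][m_out].sum()
        out_reads = r_in[m_out].sum()
        if out_reads == 0 or out_len == 0:
            raise ValueError(f"sample {sample}: zero off-region depth (uninformative)")
        in_len = length[idx][m_in].sum()
        if in_len == 0:
            raise ValueError(f"sample {sample}: no depth windows inside the region")
        ratio = (r_in[m_in].sum() / in_len) / (out_reads / out_len)
        ratios[sample] = ratio
        calls[sample] = (CARRIER if ratio < carrier_below
                         else NONCARRIER if ratio > noncarrier_above
                         else AMBIGUOUS)
    calls_s = pd.Series(calls)
    support = pd.DataFrame({"depth_ratio": pd.Series(ratios)})
    return CarrierCallSet(channel="depth", calls=calls_s, support=support)


# ---------------------------------------------------------------------------
# Cross-channel concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # 2x2 carrier/noncarrier cross-tabulation
    proportion_agreeing: float
    carrier_conditional: float  # among channel-a carriers, fraction b-carriers
    n_compared: int
    n_excluded: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.table}\nagreement {self.proportion_agreeing:.3f}, "
                f"carrier-conditional {self.carrier_conditional:.3f} "
                f"({self.n_excluded} excluded)")


def concordance(a: CarrierCallSet, b: CarrierCallSet) -> ConcordanceResult:
    """2x2 agreement between two carrier-call channels over the animals called
    carrier or noncarrier in both; ambiguous/anomalous calls are excluded and
    counted."""
    shared = [s for s in a.calls.index if s in set(b.calls.index)]
    ca = a.calls.loc[shared]
    cb = b.calls.loc[shared]
    informative = ca.isin([CARRIER, NONCARRIER]) & cb.isin([CARRIER, NONCARRIER])
    n_excluded = int((~informative).sum())
    ca, cb = ca[informative], cb[informative]
    levels = [CARRIER, NONCARRIER]
    table = pd.crosstab(ca, cb).reindex(index=levels, columns=levels,
                                        fill_value=0)
    table.index.name = a.channel
    table.columns.name = b.channel
    n = int(table.to_numpy().sum())
    agree = int(table.loc[CARRIER, CARRIER] + table.loc[NONCARRIER, NONCARRIER])
    a_carriers = int(table.loc[CARRIER].sum())
    cc = (table.loc[CARRIER, CARRIER] / a_carriers) if a_carriers else float("nan")
    return ConcordanceResult(
        table=table,
        proportion_agreeing=agree / n if n else float("nan"),
        carrier_conditional=float(cc),
        n_compared=n,
        n_excluded=n_excluded,
    )
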