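"""Missing-homozygote scan over phased haplotype windows.

A recessive lethal allele leaves a characteristic hole in the population: a
haplotype that tags it is common among live animals yet never observed in
homozygous state.  Under Hardy-Weinberg proportions a haplotype with
frequency q among N genotyped animals should produce about N*q^2
homozygotes; the probability of seeing as few as were observed is evaluated
under a Poisson model with that mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_scan import haplotype_strings
from .deletion_evidence import (CARRIER, CarrierCallSet, HOMOZYGOTE,
                                NONCARRIER)
from .io_formats import GenotypeData


@dataclass
class HaplotypeWindow:
    """Haplotype alleles of one marker window, enumerated from phased data."""

    marker_ids: list[str]
    start_pos: int
    end_pos: int
    samples: list[str]
    strings: np.ndarray        # (n_samples, 2) haplotype allele strings
    frequencies: pd.Series     # haplotype -> population frequency (sums to 1)

    @property
    def k(self) -> int:
        return len(self.marker_ids)

    @property
    def n_possible(self) -> int:
        """Size of the allele space for a biallelic window: 2^k."""
        return 2 ** self.k

    def homozygote_count(self, haplotype: str) -> int:
        return int(((self.strings[:, 0] == haplotype)
                    & (self.strings[:, 1] == haplotype)).sum())

    def copy_count(self, haplotype: str) -> np.ndarray:
        return ((self.strings == haplotype).sum(axis=1)).astype(int)


def make_window(g: GenotypeData, marker_ids) -> HaplotypeWindow:
    """Enumerate the haplotype alleles of one designated marker window."""
    idx = g.marker_index(marker_ids)
    strings = haplotype_strings(g, marker_ids)
    flat = strings.reshape(-1)
    haps, counts = np.unique(flat, return_counts=True)
    freq = pd.Series(counts / flat.size, index=haps).sort_values(ascending=False)
    pos = g.markers["pos"].to_numpy()[idx]
    return HaplotypeWindow(
        marker_ids=list(marker_ids), start_pos=int(pos.min()),
        end_pos=int(pos.max()), samples=list(g.samples), strings=strings,
        frequencies=freq,
    )


def window_haplotypes(g: GenotypeData, k: int = 10, step: int = 1
                      ) -> list[HaplotypeWindow]:
    """Sliding windows of k consecutive markers advancing by ``step``."""
    if k < 2:
        raise ValueError("window size k must be >= 2")
    if g.haplotypes is None:
        raise ValueError("phased haplotypes are required")
    ids = g.markers["id"].tolist()
    return [make_window(g, ids[i:i + k])
            for i in range(0, g.n_markers - k + 1, step)]


def expected_homozygotes(n_animals: int, q: float) -> tuple[float, int]:
    """Expected homozygote count under Hardy-Weinberg: lambda = N * q^2.

    Returns the exact value and its nearest-integer rounding (analyses of
    published counts are often stated with the rounded mean; the exact value
    is the default for new analyses).
    """
    if n_animals < 0 or not 0.0 <= q <= 1.0:
        raise ValueError("need n_animals >= 0 and q in [0, 1]")
    lam = n_animals * q * q
    return lam, int(round(lam))


def missing_homozygote_test(observed_homozygotes: int, lam: float) -> float:
    """P(X <= observed) under Poisson(lambda) -- the probability of seeing so
    few homozygotes by chance if the haplotype were not lethal.  For
    observed = 0 this is exp(-lambda)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    obs = int(observed_homozygotes)
    if obs < 0 or obs != observed_homozygotes:
        raise ValueError("observed_homozygotes must be a non-negative integer")
    return float(stats.poisson.cdf(obs, lam))


def assign_haplotype_carriers(window: HaplotypeWindow,
                              target_haplotype: str) -> CarrierCallSet:
    """Label each animal by its copy count of the target haplotype: one copy
    = carrier, two copies = homozygote (an anomaly under full lethality),
    zero = noncarrier."""
    copies = window.copy_count(target_haplotype)
    labels = np.where(copies == 2, HOMOZYGOTE,
                      np.where(copies == 1, CARRIER, NONCARRIER))
    calls = pd.Series(labels, index=window.samples)
    support = pd.DataFrame({"target_copies": copies}, index=window.samples)
    return CarrierCallSet(channel="haplotype", calls=calls, support=support)


def scan_windows(g: GenotypeData, k: int = 10, step: int = 1,
                 q_min: float = 0.01) -> pd.DataFrame:
    """Missing-homozygote scan: every haplotype allele with frequency >= q_min
    in every k-marker window, with per-allele Poisson p-values and a
    Bonferroni-adjusted column over the total number of tested alleles."""
    rows = []
    n = g.n_samples
    for win in window_haplotypes(g, k=k, step=step):
        for hap, q in win.frequencies.items():
            if q < q_min:
                continue
            lam, _ = expected_homozygotes(n, float(q))
            obs = win.homozygote_count(hap)
            rows.append({
                "window_start": win.start_pos, "window_end": win.end_pos,
                "first_marker": win.marker_ids[0], "haplotype": hap,
                "q": float(q), "n_carriers": int((win.copy_count(hap) == 1).sum()),
                "observed_homozygotes": obs, "expected_homozygotes": lam,
                "p": missing_homozygote_test(obs, lam),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
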