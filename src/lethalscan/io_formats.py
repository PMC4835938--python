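"""Interchange formats and shared marker QC.

Readers/writers for the formats the pipeline exchanges between stages:
phased VCF 4.2 genotypes, pedigree/DRP/calving CSV tables, a marker-by-sample
Log2R intensity TSV and a windowed read-depth CSV.  Also houses the two small
pieces of statistics shared by several stages: reliability-based DRP weights
and the Hardy-Weinberg chi-square used both for marker QC and for the
deletion-evidence scan.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # missing-dosage sentinel
RELIABILITY_CAP = 0.98  # reliabilities above this are truncated before weighting


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


class UnphasedGenotypeError(VcfParseError):
    """Phased genotypes were required but an unphased call was found."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Marker map plus called allele-dosage matrix (0/1/2, -1 = missing).

    ``markers`` must have columns id, chrom, pos, ref, alt; a ``maf`` column
    is (re)computed from the dosages on construction.  ``haplotypes`` is an
    optional (n_samples, 2, n_markers) phased allele matrix (0 = ref,
    1 = alt) for stages that need haplotypes.
    """

    markers: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        pos = self.markers["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("marker positions must be sorted ascending")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self.markers["maf"] = self._compute_maf()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def _compute_maf(self) -> np.ndarray:
        d = self.dosages
        called = d != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of ref-hom / het / alt-hom calls."""
        d = self.dosages
        return pd.DataFrame(
            {
                "n_ref_hom": (d == 0).sum(axis=0),
                "n_het": (d == 1).sum(axis=0),
                "n_alt_hom": (d == 2).sum(axis=0),
            },
            index=self.markers["id"],
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask, dtype=bool)
        haps = self.haplotypes[:, :, mask] if self.haplotypes is not None else None
        return GenotypeData(
            markers=self.markers.loc[mask].drop(columns=["maf"]).copy(),
            samples=list(self.samples),
            dosages=self.dosages[:, mask].copy(),
            haplotypes=haps,
        )

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.markers["id"])}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"marker {exc.args[0]!r} not present") from exc


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, require_phased: bool = False) -> GenotypeData:
    """Read a biallelic-SNP VCF 4.2 into a :class:`GenotypeData`.

    Phased haplotypes are retained when every called genotype in the file is
    phased; with ``require_phased=True`` an unphased call raises
    :class:`UnphasedGenotypeError` naming the record.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dos, haps = [], [], []
        all_phased = True
        for i, var in enumerate(vcf, start=1):
            if len(var.ALT) != 1:
                raise VcfParseError(
                    f"record {i} ({var.CHROM}:{var.POS}): only biallelic sites are supported"
                )
            gts = var.genotypes  # [a0, a1, phased] per sample
            d = np.empty(len(samples), dtype=np.int8)
            h = np.zeros((len(samples), 2), dtype=np.int8)
            for j, g in enumerate(gts):
                a0, a1, phased = g[0], g[1], bool(g[-1])
                if a0 < 0 or a1 < 0:
                    d[j] = MISSING
                    all_phased = False
                else:
                    d[j] = a0 + a1
                    h[j, 0], h[j, 1] = a0, a1
                    if not phased and a0 != a1:
                        if require_phased:
                            raise UnphasedGenotypeError(
                                f"record {i} ({var.CHROM}:{var.POS}), sample "
                                f"{samples[j]}: unphased genotype where phase is required"
                            )
                        all_phased = False
            rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                         var.REF, var.ALT[0]))
            dos.append(d)
            haps.append(h)
    except (VcfParseError, UnphasedGenotypeError):
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path}: {exc}") from exc

    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = (np.vstack(dos).T if dos
               else np.zeros((len(samples), 0), dtype=np.int8))
    haplotypes = None
    if all_phased and haps:
        haplotypes = np.stack(haps, axis=2)  # (n_samples, 2, n_markers)
    return GenotypeData(markers=markers, samples=samples, dosages=dosages,
                        haplotypes=haplotypes)


def write_vcf(g: GenotypeData, path) -> None:
    """Write VCF 4.2; phased ``a|b`` genotypes when haplotypes are present."""
    chroms = g.markers["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lethalscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        unphased_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for k, row in enumerate(g.markers.itertuples(index=False)):
            if g.haplotypes is not None:
                gts = ["./." if d == MISSING else f"{a}|{b}"
                       for (a, b), d in zip(g.haplotypes[:, :, k],
                                            g.dosages[:, k])]
            else:
                gts = [unphased_gt[int(d)] for d in g.dosages[:, k]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# DRP weights and phenotype table
# ---------------------------------------------------------------------------

def drp_weight(r2):
    """Residual weight for a de-regressed proof: w = r2/(1-r2), r2 capped at 0.98.

    The cap keeps the weight of heavily progeny-tested sires bounded (w <= 49).
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliability must be in (0, 1]")
    r2c = np.minimum(r2, RELIABILITY_CAP)
    w = r2c / (1.0 - r2c)
    return float(w) if w.ndim == 0 else w


def prepare_phenotypes(drp: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Turn a DRP table (id, trait, drp, reliability) into a weighted phenotype
    table with columns id, y, r2, w."""
    t = drp if trait is None else drp[drp["trait"] == trait]
    out = pd.DataFrame({
        "id": t["id"].astype(str).to_numpy(),
        "y": t["drp"].astype(float).to_numpy(),
        "r2": t["reliability"].astype(float).to_numpy(),
    })
    out["w"] = drp_weight(out["r2"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg test (shared by QC and the deletion-evidence scan)
# ---------------------------------------------------------------------------

def hardy_weinberg_test(n_ref_hom, n_het, n_alt_hom):
    """1-df chi-square test of genotype counts against Hardy-Weinberg
    proportions at the sample allele frequency (no continuity correction).

    Returns (chi2, p, direction) where direction is 'het_deficit',
    'het_excess' or 'none'.  Vectorised over arrays of counts.
    """
    nAA = np.asarray(n_ref_hom, dtype=float)
    nAa = np.asarray(n_het, dtype=float)
    naa = np.asarray(n_alt_hom, dtype=float)
    n = nAA + nAa + naa
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = (2 * nAA + nAa) / (2 * n)
        q = 1.0 - p_ref
        eAA, eAa, eaa = n * p_ref**2, 2 * n * p_ref * q, n * q**2
        chi2 = np.zeros_like(n)
        for obs, exp in ((nAA, eAA), (nAa, eAa), (naa, eaa)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 = chi2 + term
    pval = stats.chi2.sf(chi2, df=1)
    null = chi2 <= 1e-10  # exact HWP up to floating round-off
    if chi2.ndim == 0:
        direction = ("none" if null
                     else "het_deficit" if nAa < eAa else "het_excess")
        return float(chi2), float(pval), direction
    direction = np.where(null, "none",
                         np.where(nAa < eAa, "het_deficit", "het_excess"))
    return chi2, pval, direction


def hardy_weinberg_exact(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test for one marker (small-sample alternative to
    the chi-square).

    Conditional on the observed allele counts, the heterozygote count under
    HWP follows a known distribution; the p-value sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    from scipy.special import gammaln

    n = int(n_ref_hom + n_het + n_alt_hom)
    n_rare = int(2 * min(n_ref_hom, n_alt_hom) + n_het)
    if n == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(het = h | n, rare-allele count) up to the shared normaliser
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        return (h * math.log(2.0)
                - gammaln(h + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1))

    hs = [h for h in range(n_rare % 2, n_rare + 1, 2) if n - h - (n_rare - h) // 2 >= 0]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(int(n_het))]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def parse_region(region) -> tuple[str, int, int]:
    """Accept 'chrom:start-end' strings or (chrom, start, end) tuples."""
    if isinstance(region, str):
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region.strip())
        if not m:
            raise ValueError(f"cannot parse region {region!r}; expected chrom:start-end")
        return m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    chrom, start, end = region
    return str(chrom), int(start), int(end)


@dataclass
class FilterReport:
    n_input: int
    removed_maf: int
    removed_hwp: int
    removed_region: int
    n_retained: int


def filter_markers(g: GenotypeData, maf_min: float = 0.01,
                   hwp_p_min: float = 1e-5,
                   exclude_region=None,
                   hwp_direction: str = "both") -> tuple[GenotypeData, FilterReport]:
    """Marker QC: drop markers with MAF < maf_min, Hardy-Weinberg p < hwp_p_min,
    or position inside ``exclude_region``.

    Criteria are applied in the order MAF -> HWP -> region and each removed
    marker is tallied once, under the first criterion it fails, so the
    reported tallies are disjoint.  Missing genotypes are excluded pairwise
    from both the MAF and the HWP computation.

    ``hwp_direction='deficit_only'`` restricts the HWP criterion to
    heterozygote-deficit deviations (the genotyping-artifact signature).  In
    a very large sample the SNPs tagging a recessive lethal themselves show
    a heterozygote *excess* strong enough to fail an undirected HWP filter,
    which would discard the signal a missing-homozygote scan looks for.
    """
    if hwp_direction not in ("both", "deficit_only"):
        raise ValueError("hwp_direction must be 'both' or 'deficit_only'")
    maf = g.markers["maf"].to_numpy()
    fail_maf = np.isnan(maf) | (maf < maf_min)

    counts = g.genotype_counts()
    _, hwp_p, direction = hardy_weinberg_test(
        counts["n_ref_hom"].to_numpy(),
        counts["n_het"].to_numpy(),
        counts["n_alt_hom"].to_numpy(),
    )
    fail_hwp = hwp_p < hwp_p_min
    if hwp_direction == "deficit_only":
        fail_hwp &= np.asarray(direction) == "het_deficit"

    fail_region = np.zeros(g.n_markers, dtype=bool)
    if exclude_region is not None:
        chrom, start, end = parse_region(exclude_region)
        pos = g.markers["pos"].to_numpy()
        fail_region = ((g.markers["chrom"].astype(str) == chrom).to_numpy()
                       & (pos >= start) & (pos <= end))

    tally_maf = int(fail_maf.sum())
    tally_hwp = int((fail_hwp & ~fail_maf).sum())
    tally_region = int((fail_region & ~fail_maf & ~fail_hwp).sum())
    keep = ~(fail_maf | fail_hwp | fail_region)

    report = FilterReport(
        n_input=g.n_markers,
        removed_maf=tally_maf,
        removed_hwp=tally_hwp,
        removed_region=tally_region,
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        import warnings

        warnings.warn("marker QC removed every marker", stacklevel=2)
    return g.subset_markers(keep), report


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Per-marker, per-sample Log2R array intensities (markers x samples)."""

    marker_ids: list[str]
    samples: list[str]
    values: np.ndarray  # (n_markers, n_samples)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.marker_ids), len(self.samples)):
            raise ValueError("intensity matrix shape mismatch")


def write_intensity(m: IntensityMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=pd.Index(m.marker_ids, name="marker"),
                      columns=m.samples)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_intensity(path) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IntensityMatrix(marker_ids=[str(i) for i in df.index],
                           samples=[str(c) for c in df.columns],
                           values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Plain CSV tables
# ---------------------------------------------------------------------------

def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    for col in ("sire", "dam"):
        ped[col] = ped[col].fillna("")
    return ped


def write_drp(drp: pd.DataFrame, path) -> None:
    drp.to_csv(path, index=False, float_format="%.6g")


def read_drp(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


def write_calving(calving: pd.DataFrame, path) -> None:
    calving.to_csv(path, index=False)


def read_calving(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"calf": str, "sire": str, "dam": str, "mgs": str})
    df["mgs"] = df["mgs"].fillna("")
    return df


def write_depth(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, index=False)


def read_depth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sample": str})
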