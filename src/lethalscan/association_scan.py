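"""Single-marker association scans and the random haplotype model.

Two scan models are provided, mirroring a two-stage mapping design:

* sire model -- DRP regressed on allele dosage with a random half-sib
  (sire-family) effect and reliability weights; used genome-wide;
* animal model -- the same regression with a pedigree-structured polygenic
  effect u ~ N(0, A sigma_u^2); used to dissect a target region, optionally
  with a haplotype count as a fixed cofactor.

Both scans share one random-effect covariance K across markers, so the scan
rotates the data once by the eigenvectors of W^1/2 K W^1/2 and then
re-estimates the variance ratio per marker by an exact 1-D profiled REML on
the diagonalised problem (cheap).  A "fast" mode instead profiles the ratio
once under the no-marker null and holds it fixed, which is score-test-like;
results carry a mode label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeData, MISSING
from .mixed_models import (FitResult, RandomTerm, RelationshipMatrix, lrt,
                           reml_fit, wald_test)

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

SCAN_COLUMNS = ["marker", "pos", "maf", "beta", "se", "p", "mlog10p", "note"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance line on the -log10(p) scale:
    -log10(alpha / n_tests)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return -math.log10(alpha / n_tests)


class _EigenLmmScanEngine:
    """Exact weighted REML for y = X b + u + e with a fixed random-effect
    covariance K shared across markers.

    Rotating by the eigenvectors of W^1/2 K W^1/2 diagonalises the marginal
    covariance, after which each marker costs one O(n) 1-D optimisation.
    """

    def __init__(self, y, w, K):
        self.n = len(y)
        self.wh = np.sqrt(np.asarray(w, dtype=float))
        B = self.wh[:, None] * np.asarray(K, dtype=float) * self.wh[None, :]
        s, U = np.linalg.eigh(B)
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.yt = U.T @ (self.wh * y)
        self.const = -float(np.log(np.asarray(w, dtype=float)).sum())

    def rotate(self, X: np.ndarray) -> np.ndarray:
        return self.U.T @ (self.wh[:, None] * X)

    def _m2ll(self, theta, Xt, yt):
        n, p = self.n, Xt.shape[1]
        d = 1.0 + math.exp(theta) * self.s
        Xd = Xt / d[:, None]
        XtViX = Xt.T @ Xd
        XtViy = Xd.T @ yt
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e30, None, None, None
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = float(yt @ (yt / d) - XtViy @ beta)
        if yPy <= 0:
            return 1e30, None, None, None
        sigma_e2 = yPy / (n - p)
        m2ll = ((n - p) * math.log(sigma_e2) + float(np.log(d).sum())
                + self.const + logdetXVX + (n - p) * (1.0 + _LOG2PI))
        return m2ll, beta, XtViX, sigma_e2

    def fit(self, Xt: np.ndarray, theta: float | None = None):
        """REML fit on rotated design Xt; optimises the log variance ratio
        unless ``theta`` is supplied (fast mode)."""
        if theta is None:
            res = optimize.minimize_scalar(
                lambda t: self._m2ll(t, Xt, self.yt)[0],
                bounds=(-25.0, 15.0), method="bounded",
                options={"xatol": 1e-8})
            theta = float(res.x)
        m2ll, beta, XtViX, sigma_e2 = self._m2ll(theta, Xt, self.yt)
        if beta is None:
            raise np.linalg.LinAlgError("degenerate marker design")
        cov_beta = sigma_e2 * np.linalg.inv(XtViX)
        return beta, np.sqrt(np.diag(cov_beta)), -0.5 * m2ll, theta


def _align(g: GenotypeData, pheno: pd.DataFrame):
    """Restrict the phenotype table to genotyped samples; return row indices
    into the dosage matrix plus y and w arrays."""
    sample_idx = {s: i for i, s in enumerate(g.samples)}
    keep = pheno["id"].isin(sample_idx).to_numpy()
    ph = pheno.loc[keep]
    rows = np.array([sample_idx[s] for s in ph["id"]], dtype=int)
    return ph, rows


def _impute_dosages(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages column-wise (float output)."""
    x = d.astype(float)
    miss = d == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, x).astype(float)
        means = np.nanmean(col_mean, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        x[miss] = np.broadcast_to(means, x.shape)[miss]
    return x


def _run_scan(g, pheno, K, cofactor=None, fast=False, mode_label="exact"):
    ph, rows = _align(g, pheno)
    y = ph["y"].to_numpy(dtype=float)
    w = ph["w"].to_numpy(dtype=float)
    engine = _EigenLmmScanEngine(y, w, K)

    base_cols = [np.ones(len(y))]
    if cofactor is not None:
        base_cols.append(np.asarray(cofactor, dtype=float))
    base = np.column_stack(base_cols)
    base_t = engine.rotate(base)

    theta_fixed = None
    if fast:
        _, _, _, theta_fixed = engine.fit(base_t)

    X = _impute_dosages(g.dosages[rows, :])
    out = []
    for j in range(g.n_markers):
        x = X[:, j]
        row = dict(marker=g.markers["id"].iat[j], pos=int(g.markers["pos"].iat[j]),
                   maf=float(g.markers["maf"].iat[j]), beta=np.nan, se=np.nan,
                   p=np.nan, mlog10p=np.nan, note="")
        if np.ptp(x) == 0.0:
            row["note"] = "monomorphic"
            logger.info("marker %s skipped: monomorphic", row["marker"])
            out.append(row)
            continue
        if cofactor is not None:
            cof = base[:, 1]
            r = np.corrcoef(x, cof)[0, 1]
            if abs(r) > 1 - 1e-10:
                row["note"] = "collinear_with_cofactor"
                logger.info("marker %s skipped: collinear with cofactor",
                            row["marker"])
                out.append(row)
                continue
        xt = engine.rotate(x[:, None])
        Xt = np.hstack([base_t, xt])
        try:
            beta, se, _, _ = engine.fit(Xt, theta=theta_fixed)
        except np.linalg.LinAlgError:
            row["note"] = "not_estimable"
            out.append(row)
            continue
        est, e_se = float(beta[-1]), float(se[-1])
        z = est / e_se if e_se > 0 else math.inf
        log_p = math.log(2.0) + stats.norm.logsf(abs(z))
        row.update(beta=est, se=e_se, p=min(math.exp(log_p), 1.0),
                   mlog10p=max(-log_p / math.log(10.0), 0.0))
        out.append(row)
    res = pd.DataFrame(out, columns=SCAN_COLUMNS)
    res.attrs["mode"] = mode_label if not fast else "fast"
    res.attrs["n"] = len(y)
    return res


def scan_sire_model(g: GenotypeData, pheno: pd.DataFrame,
                    pedigree: pd.DataFrame, fast: bool = False) -> pd.DataFrame:
    """Whole-chromosome scan with a random half-sib (sire) family effect.

    ``pheno`` is a weighted phenotype table (id, y, r2, w); every phenotyped
    animal must have a sire in ``pedigree``.  Variance components are
    re-estimated per marker unless ``fast=True``.
    """
    ph, rows = _align(g, pheno)
    sire_of = dict(zip(pedigree["id"].astype(str), pedigree["sire"].astype(str)))
    sires = []
    for ident in ph["id"]:
        s = sire_of.get(str(ident), "")
        if not s or pd.isna(s):
            raise ValueError(f"phenotyped animal {ident} has no sire in the pedigree")
        sires.append(s)
    levels = sorted(set(sires))
    idx = {s: j for j, s in enumerate(levels)}
    Z = np.zeros((len(sires), len(levels)))
    Z[np.arange(len(sires)), [idx[s] for s in sires]] = 1.0
    return _run_scan(g, pheno, Z @ Z.T, fast=fast)


def scan_animal_model(g: GenotypeData, pheno: pd.DataFrame,
                      A: RelationshipMatrix, fast: bool = False) -> pd.DataFrame:
    """Target-region scan with a pedigree-structured polygenic effect."""
    ph, _ = _align(g, pheno)
    K = A.subset(ph["id"].tolist()).A
    return _run_scan(g, pheno, K, fast=fast)


def cofactor_scan(g: GenotypeData, pheno: pd.DataFrame, A: RelationshipMatrix,
                  cofactor_dosage, fast: bool = False) -> pd.DataFrame:
    """Animal-model scan with a designated haplotype count (0/1/2 per
    phenotyped animal, in phenotype-table order) as an additional fixed
    regression.  Markers perfectly collinear with the cofactor are reported
    as non-estimable."""
    cof = np.asarray(cofactor_dosage, dtype=float)
    ph, _ = _align(g, pheno)
    if len(cof) != len(ph):
        raise ValueError("cofactor_dosage length must match the phenotyped sample count")
    K = A.subset(ph["id"].tolist()).A
    if np.ptp(cof) == 0.0:
        # a constant cofactor carries no information (absorbed by the mean)
        return _run_scan(g, pheno, K, fast=fast)
    return _run_scan(g, pheno, K, cofactor=cof, fast=fast)


def select_top_snps(scan: pd.DataFrame, n: int = 10) -> list[str]:
    """The n most strongly associated markers, ranked by p ascending with
    position as the tie-break."""
    ranked = scan.dropna(subset=["p"]).sort_values(["p", "pos"], kind="mergesort")
    return ranked["marker"].head(n).tolist()


# ---------------------------------------------------------------------------
# Random haplotype model
# ---------------------------------------------------------------------------

@dataclass
class RhmResult:
    """Random-haplotype-model output for one marker window."""

    window_markers: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    effects: np.ndarray  # BLUP of each haplotype allele's effect
    hap_qtl: str         # most-negative-effect haplotype allele
    lrt_statistic: float
    lrt_p: float
    n_possible: int
    full: FitResult
    null: FitResult


def haplotype_strings(g: GenotypeData, marker_ids) -> np.ndarray:
    """Base-string haplotype alleles over a marker window, shape (n, 2)."""
    if g.haplotypes is None:
        raise ValueError("phased haplotypes are required for this window")
    idx = g.marker_index(marker_ids)
    ref = g.markers["ref"].to_numpy()[idx]
    alt = g.markers["alt"].to_numpy()[idx]
    alleles = g.haplotypes[:, :, idx]  # (n, 2, k)
    bases = np.where(alleles == 1, alt[None, None, :], ref[None, None, :])
    n = bases.shape[0]
    return np.array(["".join(bases[i, c]) for i in range(n) for c in (0, 1)]
                    ).reshape(n, 2)


def fit_rhm(g: GenotypeData, pheno: pd.DataFrame, A: RelationshipMatrix,
            window: list[str]) -> RhmResult:
    """Random haplotype model over a marker window.

    Fits y = mu + q_h1 + q_h2 + u + e with the two window haplotypes of each
    animal as iid random effects sharing one variance and a pedigree
    polygenic term, tests sigma_h^2 = 0 by a 1-df likelihood-ratio test
    against the polygenic-only null, and designates the haplotype allele with
    the most negative BLUP effect as the putative lethal-tagging allele.
    """
    ph, rows = _align(g, pheno)
    y = ph["y"].to_numpy(dtype=float)
    w = ph["w"].to_numpy(dtype=float)
    strings = haplotype_strings(g, window)[rows]
    flat = strings.reshape(-1)
    haps, inv = np.unique(flat, return_inverse=True)
    H = len(haps)
    freqs = np.bincount(inv, minlength=H) / flat.size
    Zh = np.zeros((len(y), H))
    inv2 = inv.reshape(-1, 2)
    np.add.at(Zh, (np.arange(len(y))[:, None], inv2), 1.0)

    K = A.subset(ph["id"].tolist()).A
    X = np.ones((len(y), 1))
    poly = RandomTerm("polygenic", np.eye(len(y)), cov=K)
    full = reml_fit(y, X, [RandomTerm("haplotype", Zh), poly], weights=w,
                    fixed_names=["(intercept)"])
    null = reml_fit(y, X, [RandomTerm("polygenic", np.eye(len(y)), cov=K)],
                    weights=w, fixed_names=["(intercept)"])
    stat, p = lrt(full, null)
    effects = full.blups["haplotype"]
    hap_qtl = haps[int(np.argmin(effects))]
    return RhmResult(
        window_markers=list(window), haplotypes=haps.tolist(),
        frequencies=freqs, effects=effects, hap_qtl=str(hap_qtl),
        lrt_statistic=stat, lrt_p=p, n_possible=2 ** len(window),
        full=full, null=null,
    )
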