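"""End-to-end orchestration: simulate -> QC -> scans -> RHM -> lethal scan ->
deletion evidence -> mating analysis, with a single config, per-stage
logging, a run manifest and a summary report.

Each stage is a pure function of its inputs plus the config, so a rerun with
the same seed reproduces every artifact byte for byte.  A stage failure is
logged with the stage name and downstream stages are skipped; the report
records the failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association_scan as scans
from . import deletion_evidence as evidence
from . import io_formats as io
from . import lethal_scan as lethal
from . import mating_analysis as mating
from .mixed_models import build_A
from .simulate import (SimulationConfig, call_genotypes, simulate_depth,
                       simulate_intensity, simulate_population,
                       simulate_records_and_drp)

logger = logging.getLogger(__name__)

@dataclass
class PipelineConfig:
    """Thresholds and window sizes for a full run.

    ``region`` (chrom:start-end) is the putative deleted interval used for
    intensity/depth evidence and excluded from lethal-scan phasing input; on
    simulated data it defaults to the simulated deletion.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    maf_min: float = 0.01
    hwp_p_min: float = 1e-5
    window_k: int = 10
    alpha: float = 0.05
    region: str | None = None
    n_sequenced: int = 83
    fast_scan: bool = False

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 < self.hwp_p_min < 1:
            raise ValueError("hwp_p_min must be in (0, 1)")
        if self.window_k < 2:
            raise ValueError("window_k must be >= 2")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    def resolved_region(self) -> str:
        if self.region:
            return self.region
        s = self.simulation
        return f"{s.chrom}:{s.deletion_start_bp}-{s.deletion_end_bp}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def spanning_window(g: io.GenotypeData, region, k: int = 10) -> list[str]:
    """k/2 retained markers immediately upstream and downstream of a region
    (the deletion-spanning tag window of the lethal scan)."""
    _, start, end = io.parse_region(region)
    pos = g.markers["pos"].to_numpy()
    up = np.flatnonzero(pos < start)
    down = np.flatnonzero(pos > end)
    half = k // 2
    if len(up) < half or len(down) < half:
        raise ValueError("too few retained markers flanking the region")
    idx = np.concatenate([up[-half:], down[:half]])
    return g.markers["id"].to_numpy()[idx].tolist()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated population and write all artifacts.

    Returns the summary report (also written as summary.json / summary.md in
    ``outdir``).  Raises nothing for stage failures; the report's
    ``stages`` block carries per-stage status and downstream stages are
    skipped after a failure.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": config.to_dict()}
    artifacts: dict[str, str] = {}
    state: dict = {}

    def write_df(df: pd.DataFrame, name: str, sep=","):
        path = out / name
        df.to_csv(path, sep=sep, index=False, float_format="%.10g")
        artifacts[name] = _sha256(path)
        return path

    def run_stage(name, fn):
        try:
            fn()
            report["stages"][name] = "ok"
            return True
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.exception("stage %s failed", name)
            report["stages"][name] = f"failed: {exc}"
            return False

    region = config.resolved_region()
    alpha = config.alpha

    # ----- simulate ---------------------------------------------------------
    def stage_simulate():
        pop = simulate_population(config.simulation)
        g = call_genotypes(pop)
        intensity = simulate_intensity(pop)
        rng = np.random.default_rng(config.simulation.seed + 5)
        live = pop.live_ids
        seq = sorted(rng.choice(live, size=min(config.n_sequenced, len(live)),
                                replace=False).tolist())
        depth = simulate_depth(pop, samples=seq)
        calving, drp = simulate_records_and_drp(pop)

        io.write_vcf(g, out / "genotypes.vcf")
        artifacts["genotypes.vcf"] = _sha256(out / "genotypes.vcf")
        io.write_pedigree(pop.pedigree(), out / "pedigree.csv")
        artifacts["pedigree.csv"] = _sha256(out / "pedigree.csv")
        write_df(drp, "drp.csv")
        write_df(calving, "calving.csv")
        io.write_intensity(intensity, out / "intensity.tsv")
        artifacts["intensity.tsv"] = _sha256(out / "intensity.tsv")
        write_df(depth, "depth.csv")

        state.update(pop=pop, g=g, intensity=intensity, depth=depth,
                     calving=calving, drp=drp)
        report["simulate"] = {
            "n_individuals": int(pop.n),
            "n_live": int(pop.alive.sum()),
            "n_markers": int(g.n_markers),
            "live_deletion_homozygotes": int(
                ((pop.deletion_copies == 2) & pop.alive).sum()),
            "tag_haplotype": pop.tag_haplotype,
        }

    # ----- QC ---------------------------------------------------------------
    def stage_qc():
        g = state["g"]
        g_scan, rep_scan = io.filter_markers(g, config.maf_min, config.hwp_p_min)
        g_lethal, rep_lethal = io.filter_markers(
            g, config.maf_min, config.hwp_p_min, exclude_region=region)
        state.update(g_scan=g_scan, g_lethal=g_lethal)
        report["qc"] = {
            "scan_panel": dataclasses.asdict(rep_scan),
            "lethal_panel": dataclasses.asdict(rep_lethal),
        }

    # ----- association scans ------------------------------------------------
    def stage_scan():
        g_scan = state["g_scan"]
        pop = state["pop"]
        pheno = io.prepare_phenotypes(state["drp"], trait="SB")
        state["pheno"] = pheno
        ped = pop.pedigree()
        scan = scans.scan_sire_model(g_scan, pheno, ped, fast=config.fast_scan)
        write_df(scan, "scan_sire.tsv", sep="\t")
        line = scans.bonferroni_threshold(alpha, int(scan["p"].notna().sum()))
        peak = scan.loc[scan["p"].idxmin()]
        state.update(scan=scan, ped=ped)
        report["scan"] = {
            "model": "sire",
            "bonferroni_mlog10p": round(line, 2),
            "peak_marker": peak["marker"],
            "peak_pos": int(peak["pos"]),
            "peak_mlog10p": float(peak["mlog10p"]),
            "n_significant": int((scan["mlog10p"] > line).sum()),
        }

    # ----- random haplotype model + cofactor re-scan -------------------------
    def stage_rhm():
        g_scan = state["g_scan"]
        pop = state["pop"]
        pheno = state["pheno"]
        A = build_A(pop.pedigree())
        state["A"] = A
        top = scans.select_top_snps(state["scan"], n=config.window_k)
        top = sorted(top, key=lambda m: int(
            g_scan.markers.set_index("id").loc[m, "pos"]))
        rhm = scans.fit_rhm(g_scan, pheno, A, top)
        state["rhm"] = rhm

        # cofactor re-scan with the designated haplotype's count
        win = lethal.make_window(g_scan, top)
        copies_all = pd.Series(win.copy_count(rhm.hap_qtl), index=win.samples)
        ph, _ = scans._align(g_scan, pheno)
        cof = copies_all.loc[ph["id"]].to_numpy()
        rescan = scans.cofactor_scan(g_scan, pheno, A, cof, fast=config.fast_scan)
        write_df(rescan, "scan_cofactor.tsv", sep="\t")
        line = scans.bonferroni_threshold(alpha, int(rescan["p"].notna().sum()))
        report["rhm"] = {
            "window": top,
            "n_haplotypes_observed": len(rhm.haplotypes),
            "n_haplotypes_possible": rhm.n_possible,
            "hap_qtl": rhm.hap_qtl,
            "hap_qtl_matches_simulated_tag": rhm.hap_qtl == pop.tag_haplotype,
            "lrt_statistic": rhm.lrt_statistic,
            "lrt_p": rhm.lrt_p,
            "cofactor_rescan_n_significant": int((rescan["mlog10p"] > line).sum()),
        }

    # ----- lethal haplotype scan ---------------------------------------------
    def stage_lethal():
        g_lethal = state["g_lethal"]
        pop = state["pop"]
        window = spanning_window(g_lethal, region, k=config.window_k)
        win = lethal.make_window(g_lethal, window)
        n = g_lethal.n_samples
        rows = []
        for hap, q in win.frequencies.items():
            if q < config.maf_min:
                continue
            lam, lam_round = lethal.expected_homozygotes(n, float(q))
            obs = win.homozygote_count(hap)
            rows.append({"haplotype": hap, "q": float(q),
                         "observed_homozygotes": obs,
                         "expected_homozygotes": lam,
                         "p": lethal.missing_homozygote_test(obs, lam)})
        table = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
        write_df(table, "lethal_windows.tsv", sep="\t")
        hap50k = table.iloc[0]
        calls = lethal.assign_haplotype_carriers(win, hap50k["haplotype"])
        state.update(hap_calls=calls, hap50k=str(hap50k["haplotype"]))
        report["lethal_scan"] = {
            "window": window,
            "hap_50k": str(hap50k["haplotype"]),
            "q": float(hap50k["q"]),
            "n_genotyped": n,
            "observed_homozygotes": int(hap50k["observed_homozygotes"]),
            "expected_homozygotes": float(hap50k["expected_homozygotes"]),
            "missing_homozygote_p": float(hap50k["p"]),
            "carrier_frequency": calls.carrier_frequency(),
            "matches_simulated_tag": str(hap50k["haplotype"]) == pop.tag_haplotype,
        }

    # ----- orthogonal deletion evidence --------------------------------------
    def stage_evidence():
        g = state["g"]
        pop = state["pop"]
        hw = evidence.hwp_scan(g)
        _, start, end = io.parse_region(region)
        in_region = (hw["pos"] >= start) & (hw["pos"] <= end)
        deficit = hw["direction"] == "het_deficit"
        sig = hw["p"] < config.hwp_p_min

        calls_int = evidence.call_intensity_carriers(
            state["intensity"], g, region)
        calls_depth = evidence.depth_ratio(state["depth"], region)
        hap_calls = state["hap_calls"]

        conc_int = evidence.concordance(calls_int, hap_calls)
        shared_depth = [s for s in calls_depth.samples if s in set(hap_calls.samples)]
        conc_depth = evidence.concordance(calls_depth, hap_calls)

        rows = []
        for cs in (hap_calls, calls_int, calls_depth):
            sup = cs.support.round(6)
            for sample, call in cs.calls.items():
                rows.append({"animal": sample, "channel": cs.channel,
                             "call": call,
                             "support": json.dumps(
                                 sup.loc[sample].to_dict(), sort_keys=True)})
        write_df(pd.DataFrame(rows), "carrier_calls.tsv", sep="\t")

        truth = pop.carrier_truth()
        def against_truth(cs):
            labels = cs.calls[cs.calls.isin([evidence.CARRIER, evidence.NONCARRIER])]
            t = truth.loc[labels.index].to_numpy()
            pred = (labels == evidence.CARRIER).to_numpy()
            return float((pred == t).mean())

        report["evidence"] = {
            "hwp_in_region_deficit": int((in_region & deficit & sig).sum()),
            "hwp_in_region_markers": int(in_region.sum()),
            "hwp_flanking_flagged": int((~in_region & sig).sum()),
            "intensity_carriers": len(calls_int.carriers()),
            "depth_samples": len(shared_depth),
            "concordance_intensity_vs_haplotype": conc_int.proportion_agreeing,
            "concordance_depth_vs_haplotype": conc_depth.proportion_agreeing,
            "truth_agreement": {
                "haplotype": against_truth(hap_calls),
                "intensity": against_truth(calls_int),
                "depth": against_truth(calls_depth),
            },
        }

    # ----- mating analysis ----------------------------------------------------
    def stage_mating():
        pop = state["pop"]
        hap_calls = state["hap_calls"]
        status = hap_calls.calls.isin([evidence.CARRIER, evidence.HOMOZYGOTE])
        records = mating.build_mating_records(state["calving"], status)
        A = state.get("A")
        mgs_ids = sorted(set(records["mgs"]))
        A_s = A.subset(mgs_ids) if A is not None else None
        res = mating.fit_mating_model(records, A_s)
        table = mating.stillbirth_rate_table(records)
        table.to_csv(out / "stillbirth_rates.tsv", sep="\t",
                     float_format="%.10g")
        artifacts["stillbirth_rates.tsv"] = _sha256(out / "stillbirth_rates.tsv")
        with open(out / "mating_contrasts.json", "w") as fh:
            json.dump({k: list(v) for k, v in res.contrasts.items()}, fh,
                      indent=2, sort_keys=True)
        artifacts["mating_contrasts.json"] = _sha256(out / "mating_contrasts.json")
        p = config.simulation.causative_allele_freq
        report["mating"] = {
            "n_records": int(len(records)),
            "records_per_type": {t: int((records["mating_type"] == t).sum())
                                 for t in mating.MATING_TYPES},
            "contrasts": {k: [float(v[0]), float(v[1])]
                          for k, v in res.contrasts.items()},
            "expected_type_iv_fraction":
                mating.expected_homozygote_fraction("IV", p),
        }

    stage_fns = [("simulate", stage_simulate), ("qc", stage_qc),
                 ("scan", stage_scan), ("rhm", stage_rhm),
                 ("lethal_scan", stage_lethal), ("evidence", stage_evidence),
                 ("mating", stage_mating)]
    for name, fn in stage_fns:
        logger.info("running stage %s", name)
        if not run_stage(name, fn):
            for later, _ in stage_fns[stage_fns.index((name, fn)) + 1:]:
                report["stages"][later] = "skipped"
            break

    report["ok"] = all(v == "ok" for v in report["stages"].values())
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "artifacts": artifacts,
        "stages": report["stages"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    (out / "summary.md").write_text(_render_summary(report))
    return report


def _render_summary(report: dict) -> str:
    lines = ["# Run summary", ""]
    for stage, status in report["stages"].items():
        lines.append(f"- **{stage}**: {status}")
    lines.append("")
    if "simulate" in report:
        s = report["simulate"]
        lines += [f"Simulated {s['n_individuals']} animals "
                  f"({s['n_live']} live), {s['n_markers']} markers; "
                  f"live deletion homozygotes: {s['live_deletion_homozygotes']}.",
                  ""]
    if "scan" in report:
        s = report["scan"]
        lines += [f"Sire-model peak at {s['peak_marker']} "
                  f"(-log10 p = {s['peak_mlog10p']:.2f}); Bonferroni line "
                  f"{s['bonferroni_mlog10p']:.2f}; "
                  f"{s['n_significant']} markers significant.", ""]
    if "rhm" in report:
        s = report["rhm"]
        lines += [f"RHM: {s['n_haplotypes_observed']} of "
                  f"{s['n_haplotypes_possible']} possible window haplotypes "
                  f"observed; lethal-tagging allele {s['hap_qtl']} "
                  f"(matches simulated tag: {s['hap_qtl_matches_simulated_tag']}); "
                  f"cofactor re-scan leaves "
                  f"{s['cofactor_rescan_n_significant']} significant markers.",
                  ""]
    if "lethal_scan" in report:
        s = report["lethal_scan"]
        lines += [f"Missing-homozygote test: haplotype {s['hap_50k']} at "
                  f"q = {s['q']:.4f}; expected homozygotes "
                  f"{s['expected_homozygotes']:.2f}, observed "
                  f"{s['observed_homozygotes']}; p = "
                  f"{s['missing_homozygote_p']:.3g}.", ""]
    if "evidence" in report:
        s = report["evidence"]
        lines += [f"Evidence: {s['hwp_in_region_deficit']} of "
                  f"{s['hwp_in_region_markers']} in-region markers show a "
                  f"heterozygote deficit; channel agreement with simulated "
                  f"truth: {s['truth_agreement']}.", ""]
    if "mating" in report:
        s = report["mating"]
        lines += ["Mating-type stillbirth contrasts (vs type I): "
                  + ", ".join(f"{k} = {v[0]:.4f} (SE {v[1]:.4f})"
                              for k, v in s["contrasts"].items()),
                  f"Expected type-IV homozygote fraction: "
                  f"{s['expected_type_iv_fraction']:.4f}", ""]
    return "\n".join(lines)
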