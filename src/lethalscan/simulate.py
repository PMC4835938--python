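"""Gene-drop simulator for a recessive lethal deletion in a half-sib pedigree.

Generates a multi-generation cattle-like population in which a chromosomal
deletion segregates at a chosen causative-allele frequency, tagged by a
designated SNP haplotype in complete founder linkage disequilibrium, and
produces every downstream observable the analysis stages consume:

* phased SNP genotypes, with hemizygous calls inside the deletion miscalled
  as homozygous for the single present allele;
* per-marker Log2R array intensities, depressed in deletion carriers inside
  the deleted interval;
* windowed sequencing read depth, halved for carriers inside the deletion;
* calving records with stillbirth of homozygous-deletion conceptuses at a
  configurable penetrance (which also absorbs recording completeness);
* per-bull de-regressed proofs (DRPs) with reliability-dependent noise.

Ground truth (deletion copies per animal, the tag haplotype) is retained so
that every downstream stage can be validated against planted truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeData, IntensityMatrix, MISSING

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Study conditions for the gene drop.

    Defaults emulate the scale of a national dairy-cattle half-sib study on a
    20-Mb chromosome carrying a 0.5-Mb deletion (12.3-12.8 Mb).  Carrier
    frequencies of such lethals range from ~4 % to ~16 % across populations;
    the default causative-allele frequency 0.08 (carrier frequency ~15 %)
    matches the high-frequency population that contributed the array
    intensity evidence and keeps every evidence channel informative at a
    few-thousand-animal scale.  ``penetrance`` is the probability that a
    homozygous-deletion conceptus is recorded as a stillbirth; it absorbs
    both late-gestation loss and farmer under-reporting.
    """

    n_founders: int = 600
    n_generations: int = 2
    n_sires_per_gen: int = 40
    progeny_per_sire: int = 30
    n_markers: int = 400
    chrom_length_bp: int = 20_000_000
    deletion_start_bp: int = 12_300_000
    deletion_end_bp: int = 12_800_000
    causative_allele_freq: float = 0.08
    baseline_stillbirth: float = 0.04
    penetrance: float = 1.0
    genotype_error: float = 0.01
    intensity_mean_carrier: float = -0.35
    intensity_sd: float = 0.15
    mean_depth: float = 10.0
    depth_window_bp: int = 50_000
    drp_h2_proxy: float = 0.04
    recomb_rate_cm_per_mb: float = 1.0
    tag_window_size: int = 10
    chrom: str = "23"
    seed: int = 2016

    def validate(self) -> None:
        counts = ("n_founders", "n_generations", "n_sires_per_gen",
                  "progeny_per_sire", "n_markers", "chrom_length_bp",
                  "depth_window_bp")
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        fractions = ("baseline_stillbirth", "penetrance", "genotype_error",
                     "drp_h2_proxy")
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.causative_allele_freq < 0.5:
            raise ConfigError("causative_allele_freq must be in [0, 0.5)")
        if not self.deletion_start_bp < self.deletion_end_bp <= self.chrom_length_bp:
            raise ConfigError(
                "deletion_start_bp must be < deletion_end_bp <= chrom_length_bp")
        if self.intensity_sd < 0:
            raise ConfigError("intensity_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.recomb_rate_cm_per_mb < 0:
            raise ConfigError("recomb_rate_cm_per_mb must be >= 0")
        if self.tag_window_size < 2 or self.tag_window_size % 2:
            raise ConfigError("tag_window_size must be an even integer >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Individual:
    """One animal (view onto the vectorised population storage)."""

    id: str
    sire_id: str | None
    dam_id: str | None
    sex: str
    generation: int
    haplotypes: np.ndarray  # (2, n_markers) alt-allele indicators
    deletion_copies: int
    alive_at_birth: bool


@dataclass
class Population:
    """Simulated population with ground truth retained.

    ``individuals`` columns: id, sire, dam, sex, generation, deletion_copies,
    alive, polygenic, parity, ins_ym.  ``haplotypes`` is
    (n, 2, n_markers) with alt-allele indicators; ``del_flags`` marks which of
    the two chromosomes carries the deletion.  ``tag_haplotype`` is the base
    string over the tag window that is in complete LD with the deletion among
    founders.
    """

    config: SimulationConfig
    individuals: pd.DataFrame
    haplotypes: np.ndarray
    del_flags: np.ndarray
    markers: pd.DataFrame
    tag_window_ids: list[str]
    tag_haplotype: str

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def deletion_copies(self) -> np.ndarray:
        return self.individuals["deletion_copies"].to_numpy()

    @property
    def alive(self) -> np.ndarray:
        return self.individuals["alive"].to_numpy(dtype=bool)

    @property
    def live_ids(self) -> list[str]:
        return self.individuals.loc[self.alive, "id"].tolist()

    def carrier_truth(self, ids=None) -> pd.Series:
        """Ground-truth carrier status (exactly one deletion copy) by id."""
        s = pd.Series(self.deletion_copies == 1,
                      index=self.individuals["id"].to_numpy())
        return s if ids is None else s.loc[list(ids)]

    def individual(self, ident: str) -> Individual:
        idx = self.individuals.index[self.individuals["id"] == ident]
        if len(idx) == 0:
            raise KeyError(ident)
        i = int(idx[0])
        row = self.individuals.iloc[i]
        return Individual(
            id=row["id"],
            sire_id=row["sire"] or None,
            dam_id=row["dam"] or None,
            sex=row["sex"],
            generation=int(row["generation"]),
            haplotypes=self.haplotypes[i],
            deletion_copies=int(row["deletion_copies"]),
            alive_at_birth=bool(row["alive"]),
        )

    def pedigree(self) -> pd.DataFrame:
        return self.individuals[["id", "sire", "dam", "sex", "generation"]].copy()

    def in_deletion_mask(self) -> np.ndarray:
        pos = self.markers["pos"].to_numpy()
        return (pos >= self.config.deletion_start_bp) & (pos <= self.config.deletion_end_bp)

    def deletion_region(self) -> tuple[str, int, int]:
        return (self.config.chrom, self.config.deletion_start_bp,
                self.config.deletion_end_bp)


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def _make_markers(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    # Evenly spaced positions keep the in-deletion marker count deterministic
    # for a given config (array designs aim for even spacing).
    pos = np.linspace(cfg.chrom_length_bp / (cfg.n_markers + 1),
                      cfg.chrom_length_bp * cfg.n_markers / (cfg.n_markers + 1),
                      cfg.n_markers).round().astype(np.int64)
    pos = np.unique(pos)
    ref_idx = rng.integers(0, 4, size=len(pos))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
    return pd.DataFrame({
        "id": [f"SNP{cfg.chrom}_{p:09d}" for p in pos],
        "chrom": cfg.chrom,
        "pos": pos,
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "alt_freq": rng.uniform(0.08, 0.92, size=len(pos)),
    })


def _tag_window_indices(markers: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray:
    """k/2 markers immediately upstream and k/2 immediately downstream of the
    deletion (in-deletion markers are excluded, as the deletion corrupts their
    calls)."""
    pos = markers["pos"].to_numpy()
    k = cfg.tag_window_size // 2
    up = np.flatnonzero(pos < cfg.deletion_start_bp)
    down = np.flatnonzero(pos > cfg.deletion_end_bp)
    if len(up) < k or len(down) < k:
        raise ConfigError(
            "n_markers leaves too few markers flanking the deletion for the tag window")
    return np.concatenate([up[-k:], down[:k]])


def _meiosis(haps: np.ndarray, dels: np.ndarray, positions: np.ndarray,
             del_mid: float, morgans: float, length_bp: int,
             rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """One Haldane-model meiosis: Poisson crossover count, uniform positions,
    random start phase.  The deletion travels with the segment containing the
    deletion midpoint."""
    start = int(rng.integers(2))
    n_xo = int(rng.poisson(morgans)) if morgans > 0 else 0
    if n_xo == 0:
        return haps[start].copy(), bool(dels[start])
    xo = np.sort(rng.uniform(0, length_bp, size=n_xo))
    phase = (start + np.searchsorted(xo, positions)) % 2
    gamete = np.where(phase == 0, haps[0], haps[1]).astype(np.int8)
    del_phase = (start + int(np.searchsorted(xo, del_mid))) % 2
    return gamete, bool(dels[del_phase])


def simulate_population(config: SimulationConfig) -> Population:
    """Run the gene drop and return the population with ground truth.

    Founders receive the deletion on an exact count of round(2 * n_founders *
    p) chromosomes, each stamped with the tag haplotype; non-deleted founder
    chromosomes are perturbed away from the tag string if they collide, so the
    tag is in complete LD with the deletion at generation 0.  Matings are
    sire-by-dam within the previous generation; homozygous-deletion
    conceptuses are recorded stillborn with probability ``penetrance`` and all
    other conceptuses with probability ``baseline_stillbirth``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    markers = _make_markers(cfg, rng)
    m = len(markers)
    positions = markers["pos"].to_numpy().astype(float)
    freqs = markers["alt_freq"].to_numpy()
    tag_idx = _tag_window_indices(markers, cfg)
    # A deletion arises once, on a single founder haplotype, so in real data
    # it is tagged by alleles that are rare on the non-deleted background:
    # give the tag-window SNPs a rare alt allele carried by the deletion
    # haplotype, which puts the tag alleles in near-complete LD (r^2 ~ 1)
    # with the deletion, as observed for tagging haplotypes of real lethals.
    freqs[tag_idx] = rng.uniform(0.01, 0.04, size=len(tag_idx))
    markers["alt_freq"] = freqs
    del_mid = 0.5 * (cfg.deletion_start_bp + cfg.deletion_end_bp)
    morgans = cfg.chrom_length_bp / 1e6 * cfg.recomb_rate_cm_per_mb / 100.0

    # --- founders -----------------------------------------------------------
    nf = cfg.n_founders
    founder_haps = (rng.random((nf, 2, m)) < freqs).astype(np.int8)
    founder_dels = np.zeros((nf, 2), dtype=bool)
    n_del = int(round(2 * nf * cfg.causative_allele_freq))
    tag_alleles = np.ones(len(tag_idx), dtype=np.int8)  # all-alt = the rare tag
    if n_del > 0:
        flat = founder_haps.reshape(nf * 2, m)
        # Founders are live animals: a founder drawn homozygous for the
        # deletion would have died at birth with probability `penetrance`,
        # so such draws are thinned accordingly (none remain at penetrance 1,
        # Hardy-Weinberg proportions remain at penetrance 0).
        chosen = rng.choice(nf * 2, size=n_del, replace=False)
        taken = np.zeros(nf * 2, dtype=bool)
        taken[chosen] = True
        chosen = list(chosen)
        pair = lambda c: c ^ 1  # the founder's other chromosome
        for ci in list(chosen):
            if taken[pair(ci)] and ci < pair(ci) and rng.random() < cfg.penetrance:
                free = np.flatnonzero(~taken & ~taken[np.arange(nf * 2) ^ 1])
                if len(free) == 0:
                    raise ConfigError(
                        "causative_allele_freq too high for n_founders")
                new = int(rng.choice(free))
                taken[ci] = False
                taken[new] = True
                chosen.remove(ci)
                chosen.append(new)
        chosen = np.array(sorted(chosen))
        flat[np.ix_(chosen, tag_idx)] = tag_alleles
        founder_dels.reshape(-1)[chosen] = True
        # break accidental tag matches on non-deleted chromosomes
        others = np.setdiff1d(np.arange(nf * 2), chosen)
        collide = others[(flat[np.ix_(others, tag_idx)] == tag_alleles).all(axis=1)]
        flat[collide, tag_idx[0]] = 1 - tag_alleles[0]

    ids = [f"A{i:06d}" for i in range(1, nf + 1)]
    sires: list[str] = [""] * nf
    dams: list[str] = [""] * nf
    sex = list(np.where(np.arange(nf) % 2 == 0, "M", "F"))
    gen = [0] * nf
    polygenic = list(rng.normal(0.0, 1.0, size=nf))
    alive = list(np.ones(nf, dtype=bool))
    parity = [0] * nf
    ins_ym = [""] * nf
    hap_list = [founder_haps]
    del_list = [founder_dels]
    del_copies = list(founder_dels.sum(axis=1).astype(int))

    id_index = {ident: i for i, ident in enumerate(ids)}
    all_haps = founder_haps
    all_dels = founder_dels
    dam_parity: dict[str, int] = {}

    next_id = nf + 1
    for g in range(1, cfg.n_generations + 1):
        prev = [i for i in range(len(ids)) if gen[i] == g - 1 and alive[i]]
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ConfigError(
                "n_founders/progeny_per_sire leave no breeders for generation "
                f"{g}")
        n_sires = min(cfg.n_sires_per_gen, len(males))
        gen_sires = rng.choice(males, size=n_sires, replace=False)

        new_haps = np.empty((n_sires * cfg.progeny_per_sire, 2, m), dtype=np.int8)
        new_dels = np.empty((n_sires * cfg.progeny_per_sire, 2), dtype=bool)
        k = 0
        for s_idx in gen_sires:
            mates = rng.choice(females, size=cfg.progeny_per_sire,
                               replace=len(females) < cfg.progeny_per_sire)
            for d_idx in mates:
                pat, pat_del = _meiosis(all_haps[s_idx], all_dels[s_idx],
                                        positions, del_mid, morgans,
                                        cfg.chrom_length_bp, rng)
                mat, mat_del = _meiosis(all_haps[d_idx], all_dels[d_idx],
                                        positions, del_mid, morgans,
                                        cfg.chrom_length_bp, rng)
                new_haps[k, 0], new_haps[k, 1] = pat, mat
                new_dels[k, 0], new_dels[k, 1] = pat_del, mat_del
                copies = int(pat_del) + int(mat_del)
                if copies == 2:
                    is_alive = rng.random() >= cfg.penetrance
                else:
                    is_alive = rng.random() >= cfg.baseline_stillbirth

                ident = f"A{next_id:06d}"
                next_id += 1
                dam_id = ids[d_idx]
                dam_parity[dam_id] = dam_parity.get(dam_id, 0) + 1
                ids.append(ident)
                sires.append(ids[s_idx])
                dams.append(dam_id)
                sex.append("M" if rng.random() < 0.5 else "F")
                gen.append(g)
                polygenic.append(0.5 * (polygenic[s_idx] + polygenic[d_idx])
                                 + rng.normal(0.0, math.sqrt(0.5)))
                alive.append(bool(is_alive))
                parity.append(dam_parity[dam_id])
                ins_ym.append(f"{2000 + g}-{int(rng.integers(1, 13)):02d}")
                del_copies.append(copies)
                k += 1
        hap_list.append(new_haps)
        del_list.append(new_dels)
        all_haps = np.concatenate(hap_list, axis=0)
        all_dels = np.concatenate(del_list, axis=0)
        hap_list = [all_haps]
        del_list = [all_dels]

    individuals = pd.DataFrame({
        "id": ids, "sire": sires, "dam": dams, "sex": sex, "generation": gen,
        "deletion_copies": del_copies, "alive": alive, "polygenic": polygenic,
        "parity": parity, "ins_ym": ins_ym,
    })
    base_map = dict(zip(_BASES, range(4)))
    ref_b = markers["ref"].to_numpy()
    alt_b = markers["alt"].to_numpy()
    tag_str = "".join(
        (alt_b if a else ref_b)[j] for j, a in zip(tag_idx, tag_alleles))
    return Population(
        config=cfg,
        individuals=individuals,
        haplotypes=all_haps,
        del_flags=all_dels,
        markers=markers.drop(columns=["alt_freq"]),
        tag_window_ids=markers["id"].to_numpy()[tag_idx].tolist(),
        tag_haplotype=tag_str,
    )


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def call_genotypes(pop: Population, config: SimulationConfig | None = None,
                   seed: int | None = None) -> GenotypeData:
    """Array genotype calls for live animals.

    Inside the deletion a hemizygote (one deleted chromosome) is called
    homozygous for its single present allele; an (unrecorded, live)
    homozygous-deletion animal has no allele present and is called missing.
    Outside the deletion the call equals the true dosage.  A per-call error
    rate turns homozygous calls heterozygous and heterozygous calls
    homozygous (random side) -- the dominant array error mode.
    """
    cfg = config or pop.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    live = pop.alive
    haps = pop.haplotypes[live]
    dels = pop.del_flags[live]
    n, _, m = haps.shape
    in_del = pop.in_deletion_mask()
    copies = dels.sum(axis=1)

    # Called haplotypes: a hemizygote appears homozygous, so both strands show
    # the present allele inside the deletion (phase errors are not modelled).
    called = haps.copy()
    hemi = copies == 1
    if hemi.any() and in_del.any():
        present = np.where(dels[hemi, 0][:, None], haps[hemi, 1, :],
                           haps[hemi, 0, :])
        for strand in (0, 1):
            blk = called[hemi, strand, :]
            blk[:, in_del] = present[:, in_del]
            called[hemi, strand, :] = blk

    dosage = called.sum(axis=1).astype(np.int8)

    if cfg.genotype_error > 0:
        err = rng.random(dosage.shape) < cfg.genotype_error
        if err.any():
            ei, ej = np.nonzero(err)
            rnd = rng.integers(0, 2, size=len(ei)).astype(np.int8)
            het = dosage[ei, ej] == 1
            # het miscalled homozygous (random side)
            called[ei[het], 0, ej[het]] = rnd[het]
            called[ei[het], 1, ej[het]] = rnd[het]
            # homozygous miscalled het (flip a random strand)
            oi, oj, os_ = ei[~het], ej[~het], rnd[~het]
            called[oi, os_, oj] = 1 - called[oi, os_, oj]
            dosage = called.sum(axis=1).astype(np.int8)

    # an (unrecorded, live) homozygous-deletion animal has no allele present
    hom_del = copies == 2
    if hom_del.any() and in_del.any():
        block = dosage[hom_del]
        block[:, in_del] = MISSING
        dosage[hom_del] = block

    samples = pop.individuals.loc[live, "id"].tolist()
    return GenotypeData(markers=pop.markers.copy(), samples=samples,
                        dosages=dosage, haplotypes=called)


def simulate_intensity(pop: Population, config: SimulationConfig | None = None,
                       seed: int | None = None) -> IntensityMatrix:
    """Log2R intensities for live animals: Normal(0, sd) everywhere except
    in-deletion markers of deletion carriers, where the mean drops by
    ``intensity_mean_carrier`` per deleted copy (single-copy loss ~ -0.35)."""
    cfg = config or pop.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    live = pop.alive
    copies = pop.deletion_copies[live]
    n = int(live.sum())
    m = len(pop.markers)
    in_del = pop.in_deletion_mask()
    mean = np.zeros((m, n))
    mean[np.ix_(in_del, copies > 0)] = (cfg.intensity_mean_carrier
                                        * copies[copies > 0][None, :])
    values = mean + (rng.standard_normal((m, n)) * cfg.intensity_sd
                     if cfg.intensity_sd > 0 else 0.0)
    return IntensityMatrix(marker_ids=pop.markers["id"].tolist(),
                           samples=pop.individuals.loc[live, "id"].tolist(),
                           values=values)


def simulate_depth(pop: Population, config: SimulationConfig | None = None,
                   samples: list[str] | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Windowed WGS read depth: counts ~ Poisson(mean_depth * window_len),
    with the in-deletion portion of a window contributing at half rate per
    deleted copy (a carrier is halved, a homozygote has zero coverage).

    Returns a tidy table (sample, window_start, window_end, reads); windows
    are 1-based inclusive.
    """
    cfg = config or pop.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    live_df = pop.individuals.loc[pop.alive]
    if samples is None:
        samples = live_df["id"].tolist()
    copies = live_df.set_index("id").loc[samples, "deletion_copies"].to_numpy()

    w = cfg.depth_window_bp
    starts = np.arange(1, cfg.chrom_length_bp + 1, w, dtype=np.int64)
    ends = np.minimum(starts + w - 1, cfg.chrom_length_bp)
    lengths = (ends - starts + 1).astype(float)
    ovl = (np.minimum(ends, cfg.deletion_end_bp)
           - np.maximum(starts, cfg.deletion_start_bp) + 1).clip(min=0).astype(float)

    frames = []
    for ident, c in zip(samples, copies):
        lam = cfg.mean_depth * (lengths - 0.5 * c * ovl)
        reads = rng.poisson(lam)
        frames.append(pd.DataFrame({
            "sample": ident, "window_start": starts, "window_end": ends,
            "reads": reads,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_records_and_drp(pop: Population,
                             config: SimulationConfig | None = None,
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calving records for every conceptus and DRPs for live non-founder bulls.

    The calving table has one row per non-founder conceptus (dead calves are
    recorded): calf, sire, dam, mgs, parity, ins_ym, survived (1 = alive at
    birth).  DRPs are the bull's true transmitting ability in additive
    genetic SD units -- polygenic value minus delta for deletion carriers --
    plus noise with variance (1 - r2)/r2; delta defaults to half the mate
    carrier frequency times penetrance, converted from the phenotypic
    stillbirth scale to additive-genetic SD via ``drp_h2_proxy``.
    """
    cfg = config or pop.config
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    ind = pop.individuals
    sire_of = dict(zip(ind["id"], ind["sire"]))

    offspring = ind[ind["generation"] > 0]
    calving = pd.DataFrame({
        "calf": offspring["id"].to_numpy(),
        "sire": offspring["sire"].to_numpy(),
        "dam": offspring["dam"].to_numpy(),
        "mgs": [sire_of.get(d, "") for d in offspring["dam"]],
        "parity": offspring["parity"].to_numpy(),
        "ins_ym": offspring["ins_ym"].to_numpy(),
        "survived": offspring["alive"].to_numpy().astype(int),
    })

    p = cfg.causative_allele_freq
    mate_carrier_freq = 2 * p / (1 + p)
    base = min(max(cfg.baseline_stillbirth, 0.01), 0.99)
    sigma_p = math.sqrt(base * (1 - base))
    sigma_a = math.sqrt(max(cfg.drp_h2_proxy, 1e-4)) * sigma_p
    # carrier DRP depression in additive-genetic SD units: the phenotypic
    # stillbirth shift 0.5 * c * penetrance divided by sigma_a.
    delta = 0.5 * mate_carrier_freq * cfg.penetrance / sigma_a

    bulls = ind[(ind["generation"] > 0) & (ind["sex"] == "M") & ind["alive"]]
    carrier = (bulls["deletion_copies"] == 1).to_numpy().astype(float)
    r2 = rng.uniform(0.80, 0.995, size=len(bulls))
    noise_sd = np.sqrt((1 - r2) / r2)
    drp_val = (bulls["polygenic"].to_numpy() - delta * carrier
               + rng.standard_normal(len(bulls)) * noise_sd)
    drp = pd.DataFrame({
        "id": bulls["id"].to_numpy(),
        "trait": "SB",
        "drp": drp_val,
        "reliability": r2,
    })
    return calving, drp
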