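"""Synthetic breeding-program generator.

Emulates the statistical structure the analysis pipeline assumes:

* a multi-decade pedigree of inbred lines built by single / three-way /
  backcrosses among recycled elite material and founder introductions,
  with additive (infinitesimal-model) true breeding values.  A genetic
  trend is injected as a per-cross gain proportional to the breeding years
  elapsed since the parents' cohorts (the aggregate effect of within-cross
  selection), with the within-cross variance reduced to conserve the
  Mendelian second moment; under the default (no truncation selection)
  configuration the realized genetic trend of true breeding values then
  equals the injected rate in expectation and parameter recovery is well
  defined;
* multi-environment yield trials under RCBD / alpha-lattice / row-column /
  p-rep designs with blocking effects and heterogeneous plot error driven
  by the number of hills harvested;
* gene-dropped SNP genotypes through the pedigree (interval recombination
  under a kb-per-cM map; terminal lines doubled-haploid or selfed), giving
  realistic LD for the marker analyses;
* a discrete Wright–Fisher population with recombination as an oracle for
  the LD-based effective-population-size estimator.

One root seed yields byte-identical outputs; per-component streams are
spawned deterministically from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mixed_models import TrialTable
from .pedigree import EntryType, Pedigree, PedigreeRecord, build_pedigree
from .snp import GenotypeMatrix, MarkerMap

logger = logging.getLogger("ricegain")


@dataclass
class MapConfig:
    """Marker map for gene drop / Wright-Fisher simulation."""

    n_chrom: int = 12
    markers_per_chrom: int = 60
    chrom_length_bp: int = 25_000_000
    kb_per_cm: float = 250.0


@dataclass
class TrialPlan:
    n_environments: int = 40
    envs_per_line: int = 2
    n_checks: int = 5
    reps: int = 2
    design_mix: dict = field(
        default_factory=lambda: {
            "rcbd": 0.4, "alpha_lattice": 0.25, "row_column": 0.25, "p_rep": 0.10,
        }
    )
    hills_max: int = 20
    stand_loss_rate: float = 0.15  # expected fraction of hills lost per plot
    hills_missing_rate: float = 0.05  # hills value itself unrecorded
    yield_missing_rate: float = 0.02
    sigma2_e: float = 150_000.0  # plot error at full stand, (kg/ha)^2
    sigma2_rep: float = 20_000.0
    sigma2_block: float = 15_000.0
    sigma2_row: float = 10_000.0
    sigma2_col: float = 10_000.0
    sigma_env: float = 500.0  # sd of environment means
    block_size: int = 10
    dtf_sigma_e: float = 3.0  # days
    invert_hills_weight: bool = False  # match the analysis convention


@dataclass
class SimConfig:
    """Study conditions for the synthetic program (defaults = benchmark run)."""

    seed: int = 1
    n_founders: int = 40
    years: int = 40
    burnin_years: int = 20  # pre-observation cycles so cohorts start in steady state
    start_year: int = 1975
    crosses_per_year: int = 25
    progeny_per_cross: int = 2
    founders_per_year: float = 1.0
    introgression_fraction: float = 0.0  # crosses taking a fresh introduction as parent
    cross_type_mix: dict = field(
        default_factory=lambda: {"single": 0.72, "three_way": 0.25, "backcross": 0.03}
    )
    selection_fraction: float = 1.0  # 1.0 = no truncation (benchmark default)
    cycle_lag: int = 5  # years before a line can be used as a parent
    parent_window: int = 10  # how far back the parent pool reaches
    releases_per_year: int = 1
    sigma2_a: float = 62_500.0  # additive variance, (kg/ha)^2
    mu0: float = 3_800.0  # base yield mean, kg/ha
    trend_kg_per_year: float = 10.0
    dtf_mu: float = 85.0
    dtf_sigma2_a: float = 25.0
    dtf_genetic_corr: float = 0.3
    trial_plan: TrialPlan = field(default_factory=TrialPlan)
    map: MapConfig = field(default_factory=MapConfig)

    def __post_init__(self) -> None:
        s = sum(self.cross_type_mix.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("cross_type_mix probabilities must sum to 1")
        if self.sigma2_a < 0 or self.trial_plan.sigma2_e < 0:
            raise ValueError("variances must be non-negative")

    def streams(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ["pedigree", "trials", "genedrop", "wf"]
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


class _Kinship:
    """Incrementally grown kinship matrix for a pedigree under construction."""

    def __init__(self, capacity: int = 1024):
        self.K = np.zeros((capacity, capacity), dtype=np.float32)
        self.n = 0

    def _grow(self) -> None:
        cap = self.K.shape[0] * 2
        K = np.zeros((cap, cap), dtype=np.float32)
        K[: self.n, : self.n] = self.K[: self.n, : self.n]
        self.K = K

    def add(self, sire: int, dam: int) -> int:
        """Append an individual (parents by index, -1 = unknown founder)."""
        if self.n == self.K.shape[0]:
            self._grow()
        i = self.n
        row = np.zeros(self.n, dtype=np.float32)
        if sire >= 0:
            row += 0.5 * self.K[sire, : self.n]
        if dam >= 0:
            row += 0.5 * self.K[dam, : self.n]
        self.K[i, : self.n] = row
        self.K[: self.n, i] = row
        f = self.K[sire, dam] if (sire >= 0 and dam >= 0) else 0.0
        self.K[i, i] = 0.5 * (1.0 + f)
        self.n += 1
        return i

    def inbreeding(self, i: int) -> float:
        return float(2.0 * self.K[i, i] - 1.0)


def simulate_breeding_program(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree plus true breeding values (yield and flowering) per line.

    Offspring get the parental average, the injected per-elapsed-year trend
    gain, and Mendelian noise (bivariate with flowering at the configured
    genetic correlation, variance ``0.5 sigma2_a (1 - mean parental F)``
    less the trend gain's share).  Introductions arrive on-trend
    (competitive with their era).  ``selection_fraction < 1`` truncates the
    yearly parent pool on true breeding value.
    """
    rng = cfg.streams()["pedigree"]
    corr = cfg.dtf_genetic_corr
    Cg = np.array([[1.0, corr], [corr, 1.0]])
    Lg = np.linalg.cholesky(Cg)
    sd = np.array([np.sqrt(cfg.sigma2_a), np.sqrt(cfg.dtf_sigma2_a)])

    kin = _Kinship()
    records: list[PedigreeRecord] = []
    tbv: list[np.ndarray] = []  # per line: (yield, flowering) deviations
    meta: list[dict] = []
    index: dict[str, int] = {}

    def draw_bv(mean_yield: float, scale: float = 1.0) -> np.ndarray:
        z = Lg @ rng.standard_normal(2)
        v = z * sd * np.sqrt(scale)
        v[0] += mean_yield
        return v

    def add(line_id, sire, dam, year, etype, bv, intro_year=None) -> int:
        i = kin.add(index.get(sire, -1) if sire else -1,
                    index.get(dam, -1) if dam else -1)
        records.append(
            PedigreeRecord(line_id, sire or "", dam or "", year, etype)
        )
        tbv.append(bv)
        meta.append(
            {
                "line_id": line_id,
                "cross_year": year,
                "entry_type": etype.value,
                "intro_year": intro_year if intro_year is not None else year,
            }
        )
        index[line_id] = i
        return i

    t0 = 1 - cfg.burnin_years  # simulation starts this many cycles before year 1

    def add_founder(year_offset: float, tag: str, mean: Optional[float] = None) -> str:
        lid = f"FND{len(records):04d}_{tag}"
        if mean is None:
            # introductions are competitive with their era: on-trend means
            mean = cfg.trend_kg_per_year * year_offset
        add(lid, None, None, None, EntryType.FOUNDER, draw_bv(mean),
            intro_year=cfg.start_year + int(year_offset))
        return lid

    for k in range(cfg.n_founders):
        add_founder(float(t0), "init")

    def year_of(i: int) -> float:
        m = meta[i]
        return float(m["cross_year"] if m["cross_year"] is not None
                     else m["intro_year"])

    def cross(sire: str, dam: str, year: int, etype: EntryType, lid: str) -> None:
        i_s, i_d = index[sire], index[dam]
        fbar = 0.5 * (kin.inbreeding(i_s) + kin.inbreeding(i_d))
        scale = max(0.5 * (1.0 - fbar), 0.0)
        # Injected genetic trend: each cross gains trend_kg_per_year for
        # every year of breeding elapsed since the parents' cohorts — the
        # aggregate effect of within-cross selection that is not modelled
        # explicitly.  Telescoping over the pedigree, cohort means advance
        # at exactly the injected rate in expectation.  The within-cross
        # (Mendelian) yield variance is reduced so the second moment of the
        # Mendelian deviation stays at its neutral value (as truncation
        # selection would do); this keeps the generative process consistent
        # with g ~ N(0, A sigma2_a) up to the mean shift.
        elapsed = max(year - 0.5 * (year_of(i_s) + year_of(i_d)), 0.0)
        boost = cfg.trend_kg_per_year * elapsed
        var_y = scale * cfg.sigma2_a
        var_y_resid = max(var_y - boost**2, 0.05 * var_y)
        var_f = scale * cfg.dtf_sigma2_a
        z = Lg @ rng.standard_normal(2)
        noise = z * np.sqrt(np.array([var_y_resid, var_f]))
        bv = 0.5 * (tbv[i_s] + tbv[i_d]) + np.array([boost, 0.0]) + noise
        add(lid, sire, dam, year, etype, bv)

    types = list(cfg.cross_type_mix)
    probs = np.array([cfg.cross_type_mix[t] for t in types])
    n_lines = 0
    for t in range(t0, cfg.years + 1):
        year = cfg.start_year + t
        # background founder introductions follow the injected trend
        n_new = int(rng.poisson(cfg.founders_per_year))
        for _ in range(n_new):
            add_founder(float(t), "intro")
        # parent pool: finished lines from recent cohorts plus recent founders
        # (old introductions age out of the crossing block like old lines do)
        pool = [
            m["line_id"]
            for m in meta
            if (
                m["entry_type"] in ("breeding_line", "released_variety")
                and m["cross_year"] is not None
                and year - cfg.cycle_lag - cfg.parent_window
                <= m["cross_year"]
                <= year - cfg.cycle_lag
            )
            or (
                m["entry_type"] == "founder"
                and m["intro_year"] >= year - cfg.cycle_lag - cfg.parent_window
            )
        ]
        if cfg.selection_fraction < 1.0:
            scores = np.array([tbv[index[p]][0] for p in pool])
            k = int(np.ceil(cfg.selection_fraction * len(pool)))
            if k < 2:
                raise ValueError(
                    f"truncation at {cfg.selection_fraction} leaves fewer than "
                    f"2 parents in the pool in year {year}"
                )
            order = np.argsort(scores)[::-1][:k]
            pool = [pool[j] for j in order]
        if len(pool) < 2:
            raise ValueError(f"parent pool too small in year {year}")

        cohort: list[str] = []
        for c in range(cfg.crosses_per_year):
            ctype = types[rng.choice(len(types), p=probs)]
            if rng.random() < cfg.introgression_fraction:
                # a fresh introduction crossed to program material (most
                # donor parents in real programs are used exactly once)
                p1 = add_founder(float(t), "donor")
                p2 = pool[rng.integers(len(pool))]
                ctype = "single"
            else:
                i1, i2 = rng.choice(len(pool), size=2, replace=False)
                p1, p2 = pool[i1], pool[i2]
            if ctype == "single":
                parents = [(p1, p2)]
            else:
                f1_id = f"F1_{year}_{c:03d}"
                cross(p1, p2, year, EntryType.F1, f1_id)
                if ctype == "three_way":
                    others = [p for p in pool if p not in (p1, p2)]
                    p3 = others[rng.integers(len(others))] if others else p1
                    parents = [(f1_id, p3)]
                else:  # backcross
                    parents = [(f1_id, p1)]
            for s, d in parents:
                for j in range(cfg.progeny_per_cross):
                    lid = f"L{year}_{c:03d}_{j}"
                    cross(s, d, year, EntryType.BREEDING_LINE, lid)
                    cohort.append(lid)
                    n_lines += 1
        # flag the top lines of the cohort as released varieties
        if cohort and cfg.releases_per_year > 0:
            scores = np.array([tbv[index[l]][0] for l in cohort])
            for j in np.argsort(scores)[::-1][: cfg.releases_per_year]:
                i = index[cohort[j]]
                records[i] = PedigreeRecord(
                    records[i].line_id, records[i].sire_id, records[i].dam_id,
                    records[i].cross_year, EntryType.RELEASED_VARIETY,
                )
                meta[i]["entry_type"] = EntryType.RELEASED_VARIETY.value

    ped = build_pedigree(records)
    truth = pd.DataFrame(meta)
    arr = np.vstack(tbv)
    truth["tbv_yield"] = arr[:, 0]
    truth["tbv_flowering"] = arr[:, 1]
    logger.info(
        "simulated pedigree: %d records (%d breeding lines)", len(ped), n_lines
    )
    return ped, truth


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def _make_plots(entries: list[str], design: str, plan: TrialPlan,
                rng: np.random.Generator) -> pd.DataFrame:
    """Plot layout with design-factor levels for one trial."""
    rows = []
    if design == "rcbd":
        for r in range(plan.reps):
            order = rng.permutation(entries)
            for g in order:
                rows.append({"genotype": g, "rep": f"R{r+1}"})
    elif design == "alpha_lattice":
        for r in range(plan.reps):
            order = rng.permutation(entries)
            for i, g in enumerate(order):
                rows.append(
                    {
                        "genotype": g,
                        "rep": f"R{r+1}",
                        "block": f"R{r+1}B{i // plan.block_size + 1}",
                    }
                )
    elif design == "row_column":
        n = len(entries) * plan.reps
        n_rows = int(np.ceil(np.sqrt(n)))
        order = rng.permutation(np.repeat(entries, plan.reps))
        for i, g in enumerate(order):
            rows.append({"genotype": g, "row": f"r{i // n_rows + 1}",
                         "col": f"c{i % n_rows + 1}"})
    elif design == "p_rep":
        n_dup = max(int(0.3 * len(entries)), 1)
        dup = list(rng.choice(entries, size=n_dup, replace=False))
        order = rng.permutation(entries + dup)
        n_rows = int(np.ceil(np.sqrt(len(order))))
        for i, g in enumerate(order):
            rows.append(
                {
                    "genotype": g,
                    "row": f"r{i // n_rows + 1}",
                    "col": f"c{i % n_rows + 1}",
                    "block": f"B{i // (2 * n_rows) + 1}",
                }
            )
    else:
        raise ValueError(f"unsupported simulated design {design!r}")
    return pd.DataFrame(rows)


def simulate_trials(
    ped: Pedigree,
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[TrialTable]:
    """Multi-environment trials of the simulated lines.

    Every breeding line is assigned to ``envs_per_line`` environments;
    released varieties additionally serve as shared checks connecting
    environments.  Plot value = environment mean + true breeding value +
    blocking effects + heteroscedastic error whose variance follows the
    hills convention used by the analysis (``Var(e) = sigma2_e * w(h)``).
    """
    if rng is None:
        rng = cfg.streams()["trials"]
    plan = cfg.trial_plan
    observed = truth["entry_type"].isin(["breeding_line", "released_variety"])
    if "cross_year" in truth.columns:
        # burn-in cohorts predate the phenotyping era (no digitized records)
        observed &= truth["cross_year"].fillna(-(10**9)) > cfg.start_year
    lines = truth.loc[observed, "line_id"].tolist()
    released = truth.loc[
        observed & (truth["entry_type"] == "released_variety"), "line_id"
    ].tolist()
    tbv_y = dict(zip(truth["line_id"], truth["tbv_yield"]))
    tbv_f = dict(zip(truth["line_id"], truth["tbv_flowering"]))

    assignment: dict[int, list[str]] = {e: [] for e in range(plan.n_environments)}
    for line in lines:
        for e in rng.choice(plan.n_environments, size=min(plan.envs_per_line,
                                                          plan.n_environments),
                            replace=False):
            assignment[int(e)].append(line)

    designs = list(plan.design_mix)
    dprobs = np.array([plan.design_mix[d] for d in designs])
    dprobs = dprobs / dprobs.sum()
    trials: list[TrialTable] = []
    for e in range(plan.n_environments):
        entries = sorted(set(assignment[e]))
        if released:
            checks = rng.choice(
                released, size=min(plan.n_checks, len(released)), replace=False
            )
            entries = sorted(set(entries) | set(checks))
        if len(entries) < 10:
            continue
        design = designs[rng.choice(len(designs), p=dprobs)]
        plots = _make_plots(entries, design, plan, rng)
        mu_env = cfg.mu0 + rng.normal(0.0, plan.sigma_env)
        mu_dtf = cfg.dtf_mu + rng.normal(0.0, 2.0)

        effects = np.zeros(len(plots))
        for factor, s2 in (
            ("rep", plan.sigma2_rep), ("block", plan.sigma2_block),
            ("row", plan.sigma2_row), ("col", plan.sigma2_col),
        ):
            if factor in plots.columns:
                levels = plots[factor].unique()
                eff = dict(zip(levels, rng.normal(0.0, np.sqrt(s2), len(levels))))
                effects += plots[factor].map(eff).to_numpy()

        h = plan.hills_max - rng.binomial(plan.hills_max, plan.stand_loss_rate,
                                          len(plots))
        h = np.clip(h, 1, plan.hills_max)
        w = (plan.hills_max / h) if plan.invert_hills_weight else (h / plan.hills_max)
        g_y = plots["genotype"].map(tbv_y).to_numpy()
        g_f = plots["genotype"].map(tbv_f).to_numpy()
        y = mu_env + g_y + effects + rng.normal(0.0, 1.0, len(plots)) * np.sqrt(
            plan.sigma2_e * w
        )
        dtf = mu_dtf + g_f + rng.normal(0.0, plan.dtf_sigma_e, len(plots))

        y[rng.random(len(plots)) < plan.yield_missing_rate] = np.nan
        hills = h.astype(float)
        hills[rng.random(len(plots)) < plan.hills_missing_rate] = np.nan
        plots = plots.assign(
            yield_kg_ha=y, dtf_days=np.round(dtf, 1), hills=hills
        )
        trials.append(TrialTable(f"ENV{e:03d}", design, plots))
    logger.info("simulated %d trials", len(trials))
    return trials


# ---------------------------------------------------------------------------
# Genotypes: gene drop through the pedigree and Wright-Fisher oracle
# ---------------------------------------------------------------------------


def _marker_map(map_cfg: MapConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    for c in range(1, map_cfg.n_chrom + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, map_cfg.chrom_length_bp, dtype=np.int64),
                size=map_cfg.markers_per_chrom,
                replace=False,
            )
        )
        for j, p in enumerate(pos):
            rows.append({"marker": f"S{c}_{j:03d}", "chrom": c, "pos": int(p)})
    return MarkerMap(pd.DataFrame(rows))


def _recomb_fractions(mm: MarkerMap, kb_per_cm: float) -> np.ndarray:
    """Per-interval recombination fraction; chromosome boundaries are 0.5.

    Haldane map function on the bp -> Morgan conversion (kb_per_cm).  The
    leading entry is 0.5 so the starting haplotype of each gamete is random.
    """
    t = mm.table
    r = np.full(len(t), 0.5)
    chrom = t["chrom"].to_numpy()
    pos = t["pos"].to_numpy(dtype=float)
    same = np.zeros(len(t), dtype=bool)
    same[1:] = chrom[1:] == chrom[:-1]
    d_m = np.zeros(len(t))
    d_m[1:] = (pos[1:] - pos[:-1]) / (kb_per_cm * 1000.0) / 100.0
    r[same] = 0.5 * (1.0 - np.exp(-2.0 * d_m[same]))
    return r


def _gametes(H1: np.ndarray, H2: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized gametes: one per row of the (G, L) parental haplotype pair."""
    switches = rng.random(H1.shape) < r[None, :]
    phase = np.cumsum(switches, axis=1) % 2
    return np.where(phase == 0, H1, H2)


def gene_drop(
    ped: Pedigree,
    map_cfg: Optional[MapConfig] = None,
    founder_maf: tuple[float, float] = (0.1, 0.5),
    terminal: str = "self_k",
    self_k: int = 6,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Drop founder alleles through the pedigree to SNP genotypes.

    Founder haplotypes are drawn independently per marker with alt-allele
    frequencies uniform on ``founder_maf``; meiosis recombines under the
    same bp -> Morgan convention used by the LD analyses.  Terminal
    genotypes are made fully homozygous (``terminal='dh'``) or selfed
    ``self_k`` generations (default, mimicking inbred line development).
    """
    if map_cfg is None:
        map_cfg = MapConfig()
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    if terminal not in ("dh", "self_k"):
        raise ValueError("terminal must be 'dh' or 'self_k'")
    mm = _marker_map(map_cfg, rng)
    L = len(mm.table)
    r = _recomb_fractions(mm, map_cfg.kb_per_cm)
    freqs = rng.uniform(*founder_maf, size=L)

    def founder_pair() -> tuple[np.ndarray, np.ndarray]:
        return (
            (rng.random(L) < freqs).astype(np.int8),
            (rng.random(L) < freqs).astype(np.int8),
        )

    def gamete(pair: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        return _gametes(pair[0][None, :], pair[1][None, :], r, rng)[0]

    haplo: list[tuple[np.ndarray, np.ndarray]] = []
    for i, rec in enumerate(ped.records):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            pair = founder_pair()
            if terminal == "dh" or rec.entry_type != EntryType.F1:
                # founder lines are inbred: make them homozygous
                g = gamete(pair)
                pair = (g, g.copy())
            haplo.append(pair)
            continue
        g1 = gamete(haplo[s]) if s >= 0 else gamete(founder_pair())
        g2 = gamete(haplo[d]) if d >= 0 else gamete(founder_pair())
        pair = (g1, g2)
        if rec.entry_type != EntryType.F1:
            if terminal == "dh":
                g = gamete(pair)
                pair = (g, g.copy())
            else:
                for _ in range(self_k):
                    pair = (gamete(pair), gamete(pair))
        haplo.append(pair)

    calls = np.array([p[0] + p[1] for p in haplo], dtype=np.int8)
    gm = GenotypeMatrix(ped.ids, mm.table["marker"].tolist(), calls)
    return gm, mm


def simulate_wf_population(
    true_ne: int,
    generations: Optional[int] = None,
    map_cfg: Optional[MapConfig] = None,
    sample_n: int = 60,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    init_freq: tuple[float, float] = (0.2, 0.5),
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Discrete Wright-Fisher population with recombination.

    ``true_ne`` diploids random-mate for ``generations`` (default
    ``4 * true_ne``) so LD equilibrates to drift-recombination balance;
    ``sample_n`` lines are then drawn and inbred to homozygosity (one
    gamete doubled).
    """
    if true_ne < 2:
        raise ValueError("true_ne must be >= 2")
    if generations is None:
        generations = 4 * true_ne
    if map_cfg is None:
        map_cfg = MapConfig(n_chrom=10, markers_per_chrom=50)
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    mm = _marker_map(map_cfg, rng)
    L = len(mm.table)
    r = _recomb_fractions(mm, map_cfg.kb_per_cm)
    N = int(true_ne)
    freqs = rng.uniform(*init_freq, size=L)
    hap = (rng.random((2 * N, L)) < freqs[None, :]).astype(np.int8)
    for _ in range(int(generations)):
        p1 = rng.integers(0, N, size=N)
        p2 = rng.integers(0, N, size=N)
        g1 = _gametes(hap[2 * p1], hap[2 * p1 + 1], r, rng)
        g2 = _gametes(hap[2 * p2], hap[2 * p2 + 1], r, rng)
        hap = np.empty_like(hap[: 2 * N])
        hap[0::2] = g1
        hap[1::2] = g2
    samp = rng.choice(N, size=min(sample_n, N), replace=sample_n > N)
    g = _gametes(hap[2 * samp], hap[2 * samp + 1], r, rng)
    calls = (2 * g).astype(np.int8)
    lines = [f"WF{j:03d}" for j in range(len(samp))]
    return GenotypeMatrix(lines, mm.table["marker"].tolist(), calls), mm
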