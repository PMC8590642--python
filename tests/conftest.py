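"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ricegain as rg
from ricegain.pedigree import Pedigree, PedigreeRecord


def make_pedigree(pairs: dict[str, tuple[str | None, str | None]],
                  **kwargs) -> Pedigree:
    """Compact pedigree constructor: {'C': ('A', 'B'), ...}."""
    recs = []
    for lid, (s, d) in pairs.items():
        recs.append(PedigreeRecord(lid, s or "", d or "",
                                   entry_type=kwargs.get(lid, "breeding_line")))
    return rg.build_pedigree(recs)


def random_pedigree(rng: np.random.Generator, n_founders: int = 8,
                    n_gen: int = 5, per_gen: int = 6,
                    p_unknown: float = 0.15) -> Pedigree:
    """Random layered pedigree, up to ``n_gen`` generations deep."""
    recs = [PedigreeRecord(f"F{i}") for i in range(n_founders)]
    prev = [r.line_id for r in recs]
    all_ids = list(prev)
    for g in range(n_gen):
        layer = []
        for j in range(per_gen):
            pool = all_ids
            s = pool[rng.integers(len(pool))]
            d = pool[rng.integers(len(pool))]
            while d == s:
                d = pool[rng.integers(len(pool))]
            if rng.random() < p_unknown:
                d = ""
            lid = f"G{g}_{j}"
            recs.append(PedigreeRecord(lid, s, d, cross_year=2000 + g))
            layer.append(lid)
        all_ids += layer
        prev = layer
    return rg.build_pedigree(recs)


def eqg_brute_force(ped: Pedigree, line_id: str) -> float:
    """Independent EqG oracle: explicit enumeration of all ancestor paths,
    each contributing (1/2)^depth."""
    rec = ped.record(line_id)

    def paths(lid: str, depth: int) -> float:
        total = 0.0
        r = ped.record(lid)
        for p in r.parents:
            total += 0.5 ** (depth + 1)
            total += paths(p, depth + 1)
        return total

    return paths(line_id, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated program reused across tests."""
    cfg = rg.SimConfig(
        seed=7, years=20, burnin_years=10, crosses_per_year=12,
        trial_plan=rg.TrialPlan(n_environments=10),
    )
    ped, truth = rg.simulate_breeding_program(cfg)
    trials = rg.simulate_trials(ped, truth, cfg)
    return cfg, ped, truth, trials


def simple_trial(rng: np.random.Generator, n_geno: int = 40, reps: int = 2,
                 sigma_g: float = 250.0, sigma_e: float = 350.0,
                 design: str = "rcbd", rep_sd: float = 0.0,
                 mu: float = 4000.0, hills: bool = True,
                 h_max: int = 20) -> tuple[rg.TrialTable, pd.Series]:
    """RCBD-style trial with known true genotype effects (returned)."""
    genos = [f"G{i:03d}" for i in range(n_geno)]
    eff = pd.Series(rng.normal(0, sigma_g, n_geno), index=genos)
    rows = []
    for r in range(reps):
        rep_eff = rng.normal(0, rep_sd) if rep_sd else 0.0
        for g in genos:
            h = int(rng.integers(max(h_max - 8, 1), h_max + 1)) if hills else h_max
            w = h / h_max
            rows.append(
                {
                    "genotype": g,
                    "rep": f"R{r+1}",
                    "hills": h,
                    "yield_kg_ha": mu + eff[g] + rep_eff
                    + rng.normal(0, sigma_e * np.sqrt(w)),
                    "dtf_days": 85 + rng.normal(0, 3),
                }
            )
    return rg.TrialTable("E1", design, pd.DataFrame(rows)), eff
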