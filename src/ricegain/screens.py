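"""Controlled-condition disease screens and field check comparisons.

Blast screens score up to ten plants per line x isolate on the standard
0 (highly resistant) to 5 (highly susceptible) scale; bacterial leaf blight
(BLB) screens measure lesion length (cm) on up to six inoculated leaves.
Lines are summarized to per-line x isolate means after missing-data filters,
grouped into allele classes at the surveyed resistance genes, and isolates
are compared by rank correlation.  Field trials of the panel reuse the
mixed-model machinery, with a Welch two-sample t-test of panel entries
against local checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .mixed_models import BlupResult, TrialTable, stage1_analyze_trial

logger = logging.getLogger("ricegain")

ROLES = ("test", "susceptible_check", "resistant_check")


def _validate_screen(t: pd.DataFrame) -> pd.DataFrame:
    req = {"line_id", "isolate", "value"}
    if not req <= set(t.columns):
        raise ValueError(f"screen table needs columns {sorted(req)}")
    return t


def summarize_blast(
    t: pd.DataFrame, missing_max: float = 0.5, n_plants: int = 10
) -> pd.DataFrame:
    """Per line x isolate mean infection score (0-5 scale).

    ``value`` may be NaN for unscored plants.  Lines whose overall fraction
    of missing plant scores exceeds ``missing_max`` are dropped (logged).
    Scores outside 0-5 are a validation error.
    """
    t = _validate_screen(t)
    vals = t["value"].dropna()
    if ((vals < 0) | (vals > 5)).any():
        raise ValueError("blast scores must lie in [0, 5]")
    n_isolates = t["isolate"].nunique()
    expected = n_plants * n_isolates
    n_obs = t.loc[t["value"].notna()].groupby("line_id")["value"].count()
    frac_missing = 1.0 - n_obs.reindex(t["line_id"].unique(), fill_value=0) / expected
    drop = frac_missing[frac_missing > missing_max].index
    if len(drop):
        logger.info("summarize_blast: dropped %d lines for missing data", len(drop))
    t = t.loc[~t["line_id"].isin(drop) & t["value"].notna()]
    out = (
        t.groupby(["line_id", "isolate"])["value"].mean().unstack("isolate")
    )
    return out


def summarize_blb(
    t: pd.DataFrame, min_measurements: int = 4, n_leaves: int = 6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per line x isolate mean lesion length plus per-isolate virulence.

    A line x isolate cell with fewer than ``min_measurements`` (of
    ``n_leaves``) non-missing lengths is removed.  Returns the cell-mean
    matrix and a per-isolate summary (mean over lines, rank; most and least
    virulent identifiable as rank extremes).
    """
    t = _validate_screen(t)
    vals = t["value"].dropna()
    if (vals < 0).any():
        raise ValueError("lesion lengths must be non-negative")
    obs = t.loc[t["value"].notna()]
    counts = obs.groupby(["line_id", "isolate"])["value"].count()
    ok_cells = counts[counts >= min_measurements].index
    obs = obs.set_index(["line_id", "isolate"]).loc[
        obs.set_index(["line_id", "isolate"]).index.isin(ok_cells)
    ]
    n_removed = int(len(counts) - len(ok_cells))
    if n_removed:
        logger.info("summarize_blb: removed %d line x isolate cells", n_removed)
    means = obs.groupby(["line_id", "isolate"])["value"].mean().unstack("isolate")
    virulence = (
        means.mean(axis=0)
        .rename("mean_lesion_cm")
        .to_frame()
        .assign(rank=lambda d: d["mean_lesion_cm"].rank(ascending=False))
        .sort_values("mean_lesion_cm", ascending=False)
    )
    return means, virulence


def allele_classes(
    gene_calls: pd.DataFrame,
    genes: Optional[Iterable[str]] = None,
    empty_label: str = "Only fixed favorable alleles",
) -> pd.Series:
    """Assign each line to an allele class from its favorable gene calls.

    Genes fixed favorable in every line or absent (never favorable) are
    excluded from class definitions; the class key is the sorted joined set
    of remaining favorable genes ('+'-separated), and lines carrying none of
    them fall in the ``empty_label`` class.  Lines with missing calls at a
    class-defining gene are grouped by their called alleles only.
    """
    df = gene_calls.copy()
    if genes is not None:
        df = df.loc[df["gene"].isin(set(genes))]
    df["call"] = df["call"].str.lower()
    informative = []
    for gene, grp in df.groupby("gene"):
        called = grp.loc[grp["call"].isin(["favorable", "unfavorable"])]
        if called.empty:
            continue
        fav = (called["call"] == "favorable").mean()
        if 0.0 < fav < 1.0:
            informative.append(gene)
    df = df.loc[df["gene"].isin(informative)]
    out = {}
    for line, grp in df.groupby("line_id"):
        fav_genes = sorted(grp.loc[grp["call"] == "favorable", "gene"])
        out[line] = " + ".join(fav_genes) if fav_genes else empty_label
    return pd.Series(out, name="allele_class")


def class_means(
    scores: pd.DataFrame, classes: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Unweighted class x isolate means with class sizes.

    ``scores`` is the per-line x isolate mean matrix; ``classes`` maps line
    id to class label.  The class-size-weighted average of class means
    reproduces the grand mean (conservation property of unweighted means of
    a partition).
    """
    cls = pd.Series(classes)
    common = scores.index.intersection(cls.index)
    s = scores.loc[common]
    lab = cls.loc[common]
    out = s.groupby(lab).mean()
    out.insert(0, "n_lines", s.groupby(lab).size())
    out.index.name = "allele_class"
    return out


def isolate_correlations(scores: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between isolates (pairwise-complete).

    Pairs with fewer than ``min_shared`` jointly scored lines, and constant
    columns, yield missing correlations.
    """
    return scores.corr(method="spearman", min_periods=min_shared)


@dataclass
class CheckComparison:
    blups: pd.DataFrame  # genotype, blup, pev, reliability, role
    p_value: Optional[float]
    panel_mean: float
    check_mean: float
    significant_5pct: Optional[bool]
    note: str = ""


def field_blups_and_check_test(
    trial: TrialTable,
    check_labels: Iterable[str],
    trait: str = "yield_kg_ha",
    method: str = "welch",
) -> CheckComparison:
    """Entry BLUPs for a panel field trial plus a panel-vs-checks test.

    Entries are random; blocking factors follow the design-specific
    candidate sets; no hills weighting is applied (``hills`` is simply
    absent or ignored in these trials).  ``method='welch'`` (default)
    contrasts panel-entry BLUPs against local-check BLUPs with a Welch
    two-sample t-test; ``method='mixed_contrast'`` instead adds a fixed
    panel-vs-check indicator to the entry-random mixed model and reports
    the Wald p-value of that contrast.  With a single check the Welch test
    is skipped with a note.
    """
    checks = set(check_labels)
    present = set(trial.plots["genotype"])
    missing = sorted(checks - present)
    if len(missing) == len(checks):
        raise ValueError(f"no check entries present; expected any of {sorted(checks)}")
    plots = trial.plots.drop(columns=["hills"], errors="ignore")
    tt = TrialTable(trial.environment_id, trial.design, plots)
    res: BlupResult = stage1_analyze_trial(tt, trait=trait)
    tab = res.table.copy()
    tab["role"] = np.where(tab["genotype"].isin(checks), "check", "panel")
    panel = tab.loc[tab["role"] == "panel", "blup"].to_numpy()
    chk = tab.loc[tab["role"] == "check", "blup"].to_numpy()
    if method == "mixed_contrast":
        return _mixed_contrast(tt, trait, checks, tab, panel, chk)
    if method != "welch":
        raise ValueError("method must be 'welch' or 'mixed_contrast'")
    if len(chk) < 2:
        return CheckComparison(
            blups=tab,
            p_value=None,
            panel_mean=float(panel.mean()),
            check_mean=float(chk.mean()) if len(chk) else np.nan,
            significant_5pct=None,
            note="single check entry; test skipped",
        )
    tstat, p = st.ttest_ind(panel, chk, equal_var=False)
    return CheckComparison(
        blups=tab,
        p_value=float(p),
        panel_mean=float(panel.mean()),
        check_mean=float(chk.mean()),
        significant_5pct=bool(p < 0.05),
    )


def _mixed_contrast(tt: TrialTable, trait: str, checks: set,
                    tab, panel, chk) -> CheckComparison:
    """Wald test of a fixed panel-vs-check indicator in the entry model."""
    from .mixed_models import RandomTerm, _design_matrix_factor, fit_lmm_reml

    df = tt.plots.loc[tt.plots[trait].notna()].reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    ind = (~df["genotype"].isin(checks)).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), ind])
    Zg, levels = _design_matrix_factor(df["genotype"])
    fit = fit_lmm_reml(y, X, [RandomTerm("genotype", Zg, levels)],
                       fixed_names=["intercept", "panel"])
    se = float(np.sqrt(fit.beta_cov[1, 1]))
    z = fit.beta[1] / se if se > 0 else np.nan
    p = float(2 * st.norm.sf(abs(z)))
    return CheckComparison(
        blups=tab,
        p_value=p,
        panel_mean=float(panel.mean()),
        check_mean=float(chk.mean()) if len(chk) else np.nan,
        significant_5pct=bool(p < 0.05),
        note="mixed-model Wald contrast",
    )
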