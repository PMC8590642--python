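"""SNP-based characterization of a line panel.

Genotype calls at biallelic markers are filtered (line heterozygosity,
marker missingness, minor allele frequency), encoded as a 0 / 0.5 / 1
dosage matrix, imputed by an LD-kNN scheme, and characterized by:

* centered principal-component analysis, optionally projecting the panel
  jointly with an external reference collection on shared markers;
* hierarchical clustering with Manhattan distance and Ward agglomeration;
* pairwise same-chromosome linkage disequilibrium (squared Pearson
  correlation of dosages) against genetic distance in Morgans, obtained
  from physical distance under a kb-per-cM map assumption (rice default:
  250 kb/cM);
* effective population size via Sved's relation
  ``Ne = (1 / (4c)) * (1 / E(r2) - 1)``, binned by distance;
* favorable-allele frequencies at named major resistance genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.decomposition import PCA

logger = logging.getLogger("ricegain")

# call codes in GenotypeMatrix.calls
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class FilterError(ValueError):
    """Raised when quality filters remove every line or marker."""


@dataclass
class MarkerMap:
    """Physical map: marker id, chromosome, 1-based bp position."""

    table: pd.DataFrame  # marker, chrom, pos

    def __post_init__(self) -> None:
        req = {"marker", "chrom", "pos"}
        if not req <= set(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(req)}")
        if (self.table["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        if self.table.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in marker map")

    def subset(self, markers: list[str]) -> "MarkerMap":
        t = self.table.set_index("marker").loc[markers].reset_index()
        return MarkerMap(t)


@dataclass
class GenotypeMatrix:
    """Biallelic calls per line x marker (0 hom-ref, 1 het, 2 hom-alt, -1 missing)."""

    lines: list[str]
    markers: list[str]
    calls: np.ndarray  # int8, shape (n_lines, n_markers)
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("calls shape inconsistent with line/marker lists")
        if not self.alleles:
            self.alleles = [("A", "G")] * len(self.markers)

    def het_rate(self) -> np.ndarray:
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.sum(1) > 0, (self.calls == HET).sum(1) / obs.sum(1), 0.0
            )

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency; heterozygotes count half a copy of each allele."""
        obs = self.calls != MISSING
        dose = np.where(obs, self.calls / 2.0, 0.0)
        n = obs.sum(0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, dose.sum(0) / n, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class FilterReport:
    lines_removed_het: int
    markers_removed_missing: int
    markers_removed_maf: int


def filter_genotypes(
    g: GenotypeMatrix,
    het_max: float = 0.15,
    miss_max: float = 0.15,
    maf_min: float = 0.05,
    report: Optional[list] = None,
) -> GenotypeMatrix:
    """Quality filters, in order: lines by heterozygosity, then markers by
    missingness, then markers by MAF computed on the surviving lines."""
    keep_lines = g.het_rate() <= het_max
    g2 = GenotypeMatrix(
        [l for l, k in zip(g.lines, keep_lines) if k],
        list(g.markers),
        g.calls[keep_lines],
        list(g.alleles),
    )
    if not g2.lines:
        raise FilterError("heterozygosity filter removed every line")
    keep_miss = g2.missing_rate() <= miss_max
    maf = GenotypeMatrix(
        g2.lines, list(g2.markers), g2.calls, g2.alleles
    ).maf()
    keep_maf = np.where(np.isnan(maf), False, maf >= maf_min)
    keep_markers = keep_miss & keep_maf
    rep = FilterReport(
        lines_removed_het=int((~keep_lines).sum()),
        markers_removed_missing=int((~keep_miss).sum()),
        markers_removed_maf=int((keep_miss & ~keep_maf).sum()),
    )
    if report is not None:
        report.append(rep)
    logger.info(
        "filter_genotypes: removed %d lines (het), %d markers (missing), "
        "%d markers (maf)",
        rep.lines_removed_het, rep.markers_removed_missing, rep.markers_removed_maf,
    )
    out = GenotypeMatrix(
        g2.lines,
        [m for m, k in zip(g2.markers, keep_markers) if k],
        g2.calls[:, keep_markers],
        [a for a, k in zip(g2.alleles, keep_markers) if k],
    )
    if not out.markers:
        raise FilterError("marker filters removed every marker")
    return out


@dataclass
class DosageMatrix:
    """Lines x markers dosages in [0, 1]; NaN until imputation."""

    lines: list[str]
    markers: list[str]
    values: np.ndarray  # float, entries in [0,1] or NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = np.isnan(self.values) | ((self.values >= 0) & (self.values <= 1))
        if not ok.all():
            raise ValueError("dosage entries must lie in [0, 1] (or NaN)")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.markers)


def to_dosage(g: GenotypeMatrix, orientation: str = "alt_count") -> DosageMatrix:
    """Encode calls as 0 / 0.5 / 1 (het = 0.5); missing becomes NaN.

    ``orientation='minor_count'`` flips columns so 1 counts the minor allele.
    """
    vals = np.where(g.calls == MISSING, np.nan, g.calls / 2.0)
    if orientation == "minor_count":
        flip = g.alt_freq() > 0.5
        vals[:, flip] = 1.0 - vals[:, flip]
    elif orientation != "alt_count":
        raise ValueError("orientation must be 'alt_count' or 'minor_count'")
    return DosageMatrix(list(g.lines), list(g.markers), vals)


def impute_ld_knn(
    d: DosageMatrix,
    marker_map: Optional[MarkerMap] = None,
    k_markers: int = 10,
    k_lines: int = 5,
) -> DosageMatrix:
    """LD-kNN imputation of missing dosages.

    For each marker with missing cells, the ``k_markers`` most correlated
    other markers define a sub-space; each missing cell is filled with the
    marker's mean over the ``k_lines`` nearest lines (Manhattan distance in
    the sub-space, ignoring the lines' own missing cells).  Markers with no
    observed calls are filled with 0.5 and flagged.
    """
    V = d.values.copy()
    n, m = V.shape
    if not np.isnan(V).any():
        return DosageMatrix(list(d.lines), list(d.markers), V)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(V, axis=0)
    entirely_missing = np.isnan(col_mean)
    if entirely_missing.any():
        logger.warning(
            "impute_ld_knn: %d markers entirely missing; filled with 0.5",
            int(entirely_missing.sum()),
        )
        col_mean = np.where(entirely_missing, 0.5, col_mean)
        V[:, entirely_missing] = 0.5
    centered = np.where(np.isnan(V), 0.0, V - col_mean)
    # marker-marker correlation on mean-filled data (cheap proxy for LD)
    sd = centered.std(axis=0)
    sd[sd == 0] = 1.0
    Cz = centered / sd
    corr = np.abs(Cz.T @ Cz) / max(n, 1)
    np.fill_diagonal(corr, -1.0)

    out = V.copy()
    miss_rows, miss_cols = np.where(np.isnan(V))
    for j in np.unique(miss_cols):
        nbr = np.argsort(corr[j])[::-1][:k_markers]
        sub = V[:, nbr]
        sub_filled = np.where(np.isnan(sub), col_mean[nbr], sub)
        rows = miss_rows[miss_cols == j]
        donors_mask = ~np.isnan(V[:, j])
        donors = np.where(donors_mask)[0]
        if donors.size == 0:
            out[rows, j] = col_mean[j]
            continue
        for i in rows:
            dist = np.abs(sub_filled[donors] - sub_filled[i]).sum(axis=1)
            nearest = donors[np.argsort(dist, kind="stable")[:k_lines]]
            out[i, j] = float(np.mean(V[nearest, j]))
    return DosageMatrix(list(d.lines), list(d.markers), out)


def pca_project(
    d: DosageMatrix, reference: Optional[DosageMatrix] = None, n_components: int = 10
) -> pd.DataFrame:
    """Centered (unscaled) PCA, optionally on panel + reference jointly.

    When a reference collection is given, the two matrices are merged on
    their shared markers and decomposed together so the panel can be placed
    within the reference's genetic space.  Returns per-line coordinates with
    a ``source`` column and variance-explained in ``df.attrs['explained']``.
    """
    if reference is not None:
        shared = [m for m in d.markers if m in set(reference.markers)]
        if not shared:
            raise ValueError("no shared markers between panel and reference")
        a = d.frame()[shared]
        b = reference.frame()[shared]
        combined = pd.concat([a, b])
        source = ["panel"] * len(a) + ["reference"] * len(b)
    else:
        combined = d.frame()
        source = ["panel"] * len(combined)
    if combined.shape[1] < 2:
        raise ValueError("PCA requires at least 2 markers")
    if combined.isna().any().any():
        raise ValueError("dosages must be imputed before PCA")
    n_components = min(n_components, combined.shape[1], len(combined) - 1)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(combined.to_numpy())
    out = pd.DataFrame(
        coords, index=combined.index, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    out["source"] = source
    out.attrs["explained"] = pca.explained_variance_ratio_.tolist()
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: Optional[pd.Series]  # line -> cluster id, when k given
    lines: list[str]

    def newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths from merge heights)."""
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_h: float) -> str:
            length = max(parent_h - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.lines[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster_lines(d: DosageMatrix, k: Optional[int] = None) -> ClusterResult:
    """Ward hierarchical clustering of lines on Manhattan dosage distance."""
    if len(d.lines) < 2:
        raise ValueError("clustering requires at least 2 lines")
    if np.isnan(d.values).any():
        raise ValueError("dosages must be imputed before clustering")
    dist = ssd.pdist(d.values, metric="cityblock")
    Z = sch.linkage(dist, method="ward")
    labels = None
    if k is not None:
        lab = sch.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(lab, index=d.lines, name="cluster")
    return ClusterResult(linkage=Z, labels=labels, lines=list(d.lines))


def ld_pairs(
    d: DosageMatrix,
    marker_map: MarkerMap,
    kb_per_cm: float = 250.0,
    literal_250kb_units: bool = False,
    max_pairs_per_chrom: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """All same-chromosome marker pairs with genetic distance and r2.

    Genetic distance: ``c = bp / (kb_per_cm * 1000) / 100`` Morgans under
    the kb-per-cM map assumption; with ``literal_250kb_units=True`` the
    physical distance is literally divided by 250 kb and the result used as
    if it were Morgans.  ``r2`` is the squared Pearson correlation of the
    two dosage columns.  Zero-variance markers are skipped (count logged).
    """
    if np.isnan(d.values).any():
        raise ValueError("dosages must be imputed before LD computation")
    mm = marker_map.table.set_index("marker").loc[d.markers]
    V = d.values
    sd = V.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("ld_pairs: skipping %d zero-variance markers", int(zero_var.sum()))
    rows = []
    for chrom, grp in mm.groupby("chrom", sort=False):
        cols = np.array([d.markers.index(m) for m in grp.index])
        cols = cols[~zero_var[cols]]
        if len(cols) < 2:
            continue
        sub = V[:, cols]
        R = np.corrcoef(sub, rowvar=False)
        pos = mm.loc[[d.markers[c] for c in cols], "pos"].to_numpy(dtype=float)
        iu, ju = np.triu_indices(len(cols), k=1)
        bp = np.abs(pos[iu] - pos[ju])
        keep = bp > 0
        iu, ju, bp = iu[keep], ju[keep], bp[keep]
        if literal_250kb_units:
            c = bp / 250_000.0
        else:
            c = bp / (kb_per_cm * 1000.0) / 100.0
        rows.append(
            pd.DataFrame(
                {
                    "marker1": [d.markers[cols[i]] for i in iu],
                    "marker2": [d.markers[cols[j]] for j in ju],
                    "chrom": chrom,
                    "dist_bp": bp,
                    "c": c,
                    "r2": R[iu, ju] ** 2,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["marker1", "marker2", "chrom", "dist_bp", "c", "r2"]
        )
    out = pd.concat(rows, ignore_index=True)
    if max_pairs_per_chrom is not None and rng is not None:
        out = (
            out.groupby("chrom", group_keys=False)
            .apply(
                lambda g: g.sample(
                    min(len(g), max_pairs_per_chrom), random_state=rng.integers(2**31)
                )
            )
            .reset_index(drop=True)
        )
    return out


@dataclass
class NeEstimate:
    ne: float
    per_bin: pd.DataFrame  # c_mean, r2_mean, n_pairs, ne_bin, floored
    n_pairs: int


def estimate_ne(
    pairs: pd.DataFrame,
    n_bins: int = 10,
    min_pairs_per_bin: int = 30,
    r2_sample_correction_n: Optional[int] = None,
) -> NeEstimate:
    """Sved LD-based effective population size.

    Pairs are binned into ``n_bins`` equal-count quantiles of genetic
    distance; per bin ``Ne = (1/(4 c_mean)) * (1/mean(r2) - 1)``; the overall
    estimate is the median over eligible bins (robust to the hyperbolic
    shape of the r2-distance relation).  Negative per-bin values are floored
    at 0 and flagged.  ``r2_sample_correction_n`` optionally subtracts the
    finite-sample expectation 1/n from mean r2 before inversion (off by
    default, matching the plain Sved formula).
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    df = pairs.loc[pairs["c"] > 0].copy()
    n_bins = max(1, min(n_bins, len(df) // max(min_pairs_per_bin, 1)))
    if n_bins == 0 or len(df) < min_pairs_per_bin:
        raise ValueError(
            f"need at least one bin with >= {min_pairs_per_bin} pairs; "
            f"got {len(df)} pairs"
        )
    df["bin"] = pd.qcut(df["c"], q=n_bins, duplicates="drop")
    recs = []
    for b, grp in df.groupby("bin", observed=True):
        if len(grp) < min_pairs_per_bin:
            continue
        r2m = float(grp["r2"].mean())
        if r2_sample_correction_n:
            r2m = max(r2m - 1.0 / r2_sample_correction_n, 1e-12)
        cm = float(grp["c"].mean())
        ne_bin = (1.0 / (4.0 * cm)) * (1.0 / r2m - 1.0)
        floored = ne_bin < 0
        recs.append(
            {
                "c_mean": cm,
                "r2_mean": r2m,
                "n_pairs": len(grp),
                "ne_bin": max(ne_bin, 0.0),
                "floored": floored,
            }
        )
    if not recs:
        raise ValueError("no distance bin reached the minimum pair count")
    per_bin = pd.DataFrame(recs)
    ne = float(per_bin["ne_bin"].median())
    return NeEstimate(ne=ne, per_bin=per_bin, n_pairs=int(len(df)))


def favorable_allele_frequency(
    calls: pd.DataFrame, coverage_min: float = 0.95
) -> pd.DataFrame:
    """Per-gene favorable-allele frequency (%), coverage (%), confidence flag.

    ``calls`` is long form: line_id, gene, call in {favorable, unfavorable,
    missing}.  Frequency = favorable / (favorable + unfavorable) x 100;
    coverage = fraction of lines with a non-missing call; genes with
    coverage at or below ``coverage_min`` are flagged low-confidence.  Genes
    with zero calls report a missing frequency.
    """
    req = {"line_id", "gene", "call"}
    if not req <= set(calls.columns):
        raise ValueError(f"gene-call table needs columns {sorted(req)}")
    n_lines = calls["line_id"].nunique()
    recs = []
    for gene, grp in calls.groupby("gene", sort=True):
        c = grp["call"].str.lower()
        fav = int((c == "favorable").sum())
        unf = int((c == "unfavorable").sum())
        called = fav + unf
        coverage = called / n_lines * 100.0 if n_lines else 0.0
        freq = fav / called * 100.0 if called else np.nan
        recs.append(
            {
                "gene": gene,
                "frequency_pct": freq,
                "coverage_pct": coverage,
                "n_called": called,
                "low_confidence": coverage <= coverage_min * 100.0,
            }
        )
    return pd.DataFrame(recs)
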