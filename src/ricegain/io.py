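"""File formats, configuration, and run logging.

CSV layouts:

* pedigree: ``line_id,sire_id,dam_id,cross_year,entry_type`` (empty/NA
  parent = unknown; header required; UTF-8);
* phenotypes: long format with ``environment_id,design,genotype,
  yield_kg_ha,dtf_days,hills,row,col,rep,block`` (unused factor columns may
  be empty);
* gene calls: ``line_id,gene,call`` with call in favorable / unfavorable /
  missing;
* disease screens: ``line_id,isolate,rep_index,value,role``.

SNP genotypes use the HapMap text format (``rs#  alleles  chrom  pos ...``
followed by per-line calls as IUPAC single-letter or two-letter codes;
``N``/``NN`` = missing; positions 1-based).  Pipeline configuration is YAML
with unknown keys rejected; a run writes its resolved configuration next to
its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .mixed_models import TrialTable
from .pedigree import PedigreeRecord, EntryType
from .snp import GenotypeMatrix, MarkerMap, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger("ricegain")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Pedigree CSV
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ["line_id", "sire_id", "dam_id", "cross_year", "entry_type"]


def read_pedigree_csv(path: PathLike) -> list[PedigreeRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("line_id", "sire_id", "dam_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pedigree columns {missing}")
    dup = df["line_id"][df["line_id"].duplicated(keep=False)]
    if not dup.empty:
        rows = [int(i) + 2 for i in dup.index]  # 1-based incl. header
        raise FormatError(
            f"{path}: duplicated line_id {sorted(set(dup))} at file rows {rows}"
        )
    records = []
    for i, row in df.iterrows():
        year = row.get("cross_year", "")
        try:
            cross_year = int(float(year)) if str(year).strip() not in ("", "NA") else None
        except ValueError:
            raise FormatError(
                f"{path}: malformed cross_year {year!r} in row {int(i) + 2}"
            ) from None
        etype = str(row.get("entry_type", "") or "breeding_line").strip()
        try:
            records.append(
                PedigreeRecord(
                    line_id=str(row["line_id"]).strip(),
                    sire_id=row["sire_id"],
                    dam_id=row["dam_id"],
                    cross_year=cross_year,
                    entry_type=EntryType(etype),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {int(i) + 2}: {exc}") from None
    logger.info("read %d pedigree records from %s", len(records), path)
    return records


def write_pedigree_csv(records: Iterable[PedigreeRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "line_id": r.line_id,
                "sire_id": r.sire_id,
                "dam_id": r.dam_id,
                "cross_year": "" if r.cross_year is None else r.cross_year,
                "entry_type": r.entry_type.value,
            }
            for r in records
        ],
        columns=PEDIGREE_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotype CSV (long format, one or many environments)
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "environment_id", "design", "genotype", "yield_kg_ha", "dtf_days",
    "hills", "row", "col", "rep", "block",
]


def read_trials_csv(path: PathLike) -> list[TrialTable]:
    df = pd.read_csv(path)
    req = {"environment_id", "design", "genotype"}
    if not req <= set(df.columns):
        raise FormatError(f"{path}: phenotype file needs columns {sorted(req)}")
    trials = []
    for env, grp in df.groupby("environment_id", sort=True):
        designs = grp["design"].unique()
        if len(designs) != 1:
            raise FormatError(f"{path}: environment {env} has mixed designs {designs}")
        plots = grp.drop(columns=["environment_id", "design"]).reset_index(drop=True)
        trials.append(TrialTable(str(env), str(designs[0]), plots))
    logger.info("read %d trials (%d plots) from %s", len(trials), len(df), path)
    return trials


def write_trials_csv(trials: Iterable[TrialTable], path: PathLike) -> None:
    frames = []
    for t in trials:
        f = t.plots.copy()
        f.insert(0, "design", t.design)
        f.insert(0, "environment_id", t.environment_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    for c in PHENOTYPE_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out[PHENOTYPE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HapMap
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def _decode_call(token: str, ref: str, alt: str, marker: str) -> int:
    token = token.strip().upper()
    if token in ("N", "NN", "", "--", "NA"):
        return MISSING
    if len(token) == 1:
        pair = _IUPAC_HET.get(token, token + token)
    elif len(token) == 2:
        pair = token
    else:
        raise FormatError(f"marker {marker}: unparseable genotype {token!r}")
    a, b = pair[0], pair[1]
    for x in (a, b):
        if x not in (ref, alt):
            raise FormatError(
                f"marker {marker}: call {token!r} carries allele {x!r} not in "
                f"{ref}/{alt}"
            )
    if a == b:
        return HOM_REF if a == ref else HOM_ALT
    return HET


def read_hapmap(path: PathLike) -> tuple[GenotypeMatrix, MarkerMap]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] not in ("rs#", "rs"):
        raise FormatError(f"{path}: not a HapMap file (first column {df.columns[0]!r})")
    sample_cols = [c for c in df.columns if c not in _HAPMAP_META and c != "rs"]
    markers, alleles, calls_cols, map_rows = [], [], [], []
    for _, row in df.iterrows():
        marker = row["rs#" if "rs#" in df.columns else "rs"]
        al = str(row["alleles"]).split("/")
        if len(al) != 2:
            raise FormatError(f"{path}: marker {marker}: alleles {row['alleles']!r} "
                              "is not biallelic")
        ref, alt = al[0].strip().upper(), al[1].strip().upper()
        markers.append(marker)
        alleles.append((ref, alt))
        map_rows.append(
            {"marker": marker, "chrom": row["chrom"], "pos": int(row["pos"])}
        )
        calls_cols.append(
            [_decode_call(str(row[c]), ref, alt, marker) for c in sample_cols]
        )
    calls = np.array(calls_cols, dtype=np.int8).T  # lines x markers
    gm = GenotypeMatrix(list(sample_cols), markers, calls, alleles)
    mm = MarkerMap(pd.DataFrame(map_rows))
    logger.info("read %d markers x %d lines from %s", len(markers), len(sample_cols), path)
    return gm, mm


def write_hapmap(g: GenotypeMatrix, m: MarkerMap, path: PathLike) -> None:
    mm = m.table.set_index("marker").loc[g.markers]
    code = {HOM_REF: lambda r, a: r + r, HOM_ALT: lambda r, a: a + a,
            HET: lambda r, a: r + a, MISSING: lambda r, a: "NN"}
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + list(g.lines)) + "\n")
        for j, marker in enumerate(g.markers):
            ref, alt = g.alleles[j]
            meta = [
                marker, f"{ref}/{alt}", str(mm.loc[marker, "chrom"]),
                str(int(mm.loc[marker, "pos"])), "+", "NA", "NA", "NA", "NA",
                "NA", "NA",
            ]
            row = [code[int(c)](ref, alt) for c in g.calls[:, j]]
            fh.write("\t".join(meta + row) + "\n")


# ---------------------------------------------------------------------------
# Gene calls and screens
# ---------------------------------------------------------------------------


def read_gene_calls_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    req = {"line_id", "gene", "call"}
    if not req <= set(df.columns):
        raise FormatError(f"{path}: gene-call file needs columns {sorted(req)}")
    bad = set(df["call"].str.lower()) - {"favorable", "unfavorable", "missing"}
    if bad:
        raise FormatError(f"{path}: unknown call values {sorted(bad)}")
    return df


def read_screens_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"line_id", "isolate", "value"}
    if not req <= set(df.columns):
        raise FormatError(f"{path}: screen file needs columns {sorted(req)}")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: PathLike, schema: type) -> object:
    """Load a YAML config into a (nested) dataclass; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(schema, data, context=str(path))


def _from_dict(schema: type, data: dict, context: str = "") -> object:
    import typing

    if not dataclasses.is_dataclass(schema):
        raise TypeError(f"{schema} is not a dataclass")
    names = {f.name for f in dataclasses.fields(schema)}
    unknown = set(data) - names
    if unknown:
        raise FormatError(f"{context}: unknown config keys {sorted(unknown)}")
    hints = typing.get_type_hints(schema)
    kwargs = {}
    for k, v in data.items():
        ftype = hints.get(k)
        if isinstance(v, dict) and dataclasses.is_dataclass(ftype):
            kwargs[k] = _from_dict(ftype, v, context=f"{context}.{k}")
        else:
            kwargs[k] = v
    return schema(**kwargs)  # type: ignore[arg-type]


def dump_config(cfg: object, path: PathLike) -> None:
    """Record a run's resolved configuration next to its outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def write_json(obj: dict, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
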