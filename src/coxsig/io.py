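"""Tab-delimited loaders and writers for expression, clinical and gene-list
files (UTF-8, Unix newlines)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .deg import ExpressionCohort
from .exceptions import CoxsigError
from .survival import SurvivalCohort

log = logging.getLogger(__name__)

_EVENT_CODES = {"0": 0, "1": 1, "alive": 0, "dead": 1}


def load_expression(
    path,
    class_path=None,
    scale: str = "log2",
    cohort_name: str | None = None,
    pseudocount: float = 1.0,
) -> ExpressionCohort:
    """Load a gene-by-sample matrix (first column = gene/probe id, header
    row = sample ids).  Linear-scale input is log2(x + pseudocount)
    transformed on load."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2 or any(h == "" for h in header[1:]):
        raise CoxsigError(f"{path}:1: malformed header (need id column + sample ids)")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        n = int(df.isna().any(axis=1).sum())
        log.warning("%s: dropped %d rows with missing values", path, n)
        df = df.dropna()
    if scale == "linear":
        vals = df.to_numpy(dtype=float)
        if np.any(vals + pseudocount <= 0):
            raise CoxsigError("linear expression has values <= -pseudocount")
        df = pd.DataFrame(np.log2(vals + pseudocount), index=df.index, columns=df.columns)
        log.info("%s: linear scale log2-transformed with pseudocount %g", path, pseudocount)
    elif scale != "log2":
        raise CoxsigError("scale must be 'log2' or 'linear'")
    sc = None
    if class_path is not None:
        cls = pd.read_csv(class_path, sep="\t", index_col=0).iloc[:, 0]
        sc = cls.rename("sample_class")
    return ExpressionCohort(df, sc, cohort_name or path.stem)


def write_expression(cohort: ExpressionCohort, path, class_path=None) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene_id")
    if class_path is not None and cohort.sample_class is not None:
        cohort.sample_class.rename_axis("sample_id").to_csv(class_path, sep="\t")


def load_clinical(path) -> SurvivalCohort:
    """Load a clinical table with patient_id / os_months / os_event columns.

    Event codes 0/1/alive/dead are normalized; rows missing a required
    field are rejected (count logged); duplicate patient ids are an error.
    Extra columns become covariates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "os_months", "os_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CoxsigError(f"{path}: missing required columns {missing}")
    bad = df[required].isna().any(axis=1) | (df["patient_id"].astype(str).str.strip() == "")
    if bad.any():
        log.warning("%s: rejected %d rows with missing required fields", path, int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise CoxsigError(f"{path}: no usable rows")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].tolist()[:5]
        raise CoxsigError(f"{path}: duplicate patient_id, e.g. {dup}")
    ev = df["os_event"].astype(str).str.strip().str.lower()
    unknown = set(ev.unique()) - set(_EVENT_CODES)
    if unknown:
        raise CoxsigError(f"{path}: unrecognized event codes {sorted(unknown)}")
    df = df.assign(os_event=ev.map(_EVENT_CODES)).reset_index(drop=True)
    return SurvivalCohort.from_dataframe(df)


def write_clinical(surv: SurvivalCohort, path, extra: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame(
        {"patient_id": surv.patient_id, "os_months": surv.time, "os_event": surv.event}
    )
    if surv.covariates is not None:
        df = pd.concat([df, surv.covariates.reset_index(drop=True)], axis=1)
    if extra is not None:
        df = df.merge(extra, left_on="patient_id", right_index=True, how="left")
    df.to_csv(path, sep="\t", index=False)


def load_gene_list(path) -> list:
    """One gene symbol per line; ``#`` comments and blank lines ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.split("#", 1)[0].strip()
            if g:
                genes.append(g)
    if not genes:
        raise CoxsigError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
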