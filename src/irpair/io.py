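"""Input/output for expression matrices, gene annotation and clinical tables.

The pipeline consumes three kinds of tabular input: an FPKM-like expression
matrix (genes x samples, TSV), an Ensembl-style GTF carrying ``gene_biotype``
attributes used to separate lncRNA from protein-coding genes, and a clinical
table with overall-survival follow-up plus categorical covariates.  This
module defines the in-memory containers for those inputs, the TSV/GTF
readers and writers, and the cohort eligibility filter (complete follow-up,
survival time of at least 30 days).
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "ClinicalTable",
    "ParseError",
    "LNCRNA_BIOTYPES",
    "read_expression",
    "write_expression",
    "read_gene_annotation",
    "read_gene_list",
    "read_clinical",
    "write_clinical",
    "split_by_biotype",
    "filter_cohort",
]

#: Ensembl gene biotypes treated as long non-coding RNA.  Ensembl merged most
#: of these into the umbrella "lncRNA" biotype around release 96; earlier GTFs
#: carry the individual labels, so all are accepted by default.
LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "antisense",
        "lincRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)

CLINICAL_CATEGORICAL = (
    "t_stage",
    "n_stage",
    "m_stage",
    "stage",
    "er",
    "pr",
    "her2",
    "pam50",
)


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (FPKM-like), genes x samples.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_class
        Per-sample label, each either ``"tumor"`` or ``"normal"``, indexed
        by sample id in the same order as ``values.columns``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "gene_id"
        self.values.columns = self.values.columns.astype(str)
        self.values.columns.name = None
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if np.isnan(arr).any():
            gi, si = np.argwhere(np.isnan(arr))[0]
            raise ParseError(
                f"missing value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        self.sample_class = self.sample_class.reindex(self.values.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()][0]
            raise ParseError(f"sample {missing!r} has no tumor/normal label")
        bad = set(self.sample_class.unique()) - {"tumor", "normal"}
        if bad:
            raise ParseError(f"unknown sample class labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.sample_class.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[samples].copy(), self.sample_class.loc[samples].copy()
        )

    def tumor_samples(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == "tumor"])

    def normal_samples(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == "normal"])

    def log2p1(self) -> pd.DataFrame:
        """log2(value + 1), the working scale for correlation and DE tests."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneAnnotation:
    """Mapping from gene id to Ensembl gene biotype."""

    biotype: dict[str, str] = field(default_factory=dict)
    lncrna_biotypes: frozenset[str] = LNCRNA_BIOTYPES

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotype

    def is_lncrna(self, gene_id: str) -> bool | None:
        """True/False for annotated genes, None when the gene is unknown."""
        bt = self.biotype.get(gene_id)
        if bt is None:
            return None
        return bt in self.lncrna_biotypes


@dataclass
class ClinicalTable:
    """Per-patient follow-up and clinicopathological covariates.

    ``os_time`` is overall-survival follow-up in days and ``os_event`` is 1
    for death, 0 for censoring.  The categorical columns (``t_stage`` ...
    ``pam50``) may contain missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate sample id in clinical table: {dup!r}")
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise ParseError(f"clinical table lacks required column {col!r}")
        ok_event = df["os_event"].isin([0, 1]) | df["os_event"].isna()
        if not ok_event.all():
            bad = df.index[~ok_event][0]
            raise ParseError(f"os_event outside {{0,1}} for sample {bad!r}")
        neg = df["os_time"] < 0
        if neg.any():
            raise ParseError(f"negative os_time for sample {df.index[neg][0]!r}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def aligned(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = [s for s in sample_ids if s in self.data.index]
        return ClinicalTable(self.data.loc[ids].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, sample_class: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV.

    The first header cell must be ``gene_id`` and the remaining header cells
    are sample ids.  When ``sample_class`` is not given, the class of each
    sample is inferred from an optional second header line of the form
    ``#class<TAB>tumor<TAB>normal...``; otherwise every sample defaults to
    ``tumor``.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise ParseError(
                f"{path}: first header cell must be 'gene_id', got {header[:1]!r}"
            )
        pos = fh.tell()
        second = fh.readline()
        class_row: list[str] | None = None
        if second.startswith("#class"):
            class_row = second.rstrip("\n").split("\t")[1:]
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    df.index.name = "gene_id"
    df.columns = header[1:]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    if sample_class is not None:
        cls = pd.Series({s: sample_class[s] for s in df.columns})
    elif class_row is not None:
        if len(class_row) != df.shape[1]:
            raise ParseError(f"{path}: #class row length mismatch")
        cls = pd.Series(class_row, index=df.columns)
    else:
        cls = pd.Series("tumor", index=df.columns)
    return ExpressionMatrix(df, cls)


def write_expression(expr: ExpressionMatrix, path: str | Path, with_class_row: bool = True) -> None:
    """Write the TSV dialect read by :func:`read_expression`."""
    with _open_text(path, "wt") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        if with_class_row:
            fh.write("#class\t" + "\t".join(expr.sample_class) + "\n")
        expr.values.to_csv(fh, sep="\t", header=False)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path: str | Path, lncrna_biotypes: Iterable[str] | None = None) -> GeneAnnotation:
    """Parse gene records of an Ensembl GTF into a gene_id -> biotype map.

    Only ``gene`` feature lines are used; ``gene_biotype`` (Ensembl) and
    ``gene_type`` (GENCODE) attribute keys are both accepted.
    """
    biotype: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gid = attrs.get("gene_id")
            bt = attrs.get("gene_biotype") or attrs.get("gene_type")
            if gid and bt:
                biotype[gid] = bt
    if not biotype:
        raise ParseError(f"{path}: no gene records with a biotype attribute")
    kwargs = {}
    if lncrna_biotypes is not None:
        kwargs["lncrna_biotypes"] = frozenset(lncrna_biotypes)
    return GeneAnnotation(biotype, **kwargs)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    seen: set[str] = set()
    uniq = [g for g in out if not (g in seen or seen.add(g))]
    return uniq


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: clinical table lacks 'sample_id' column")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_by_biotype(
    expr: ExpressionMatrix, ann: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Partition genes into lncRNA and coding matrices by annotated biotype.

    Returns ``(lnc, coding, unannotated)`` where ``unannotated`` lists genes
    absent from the annotation (dropped from both outputs).
    """
    lnc_ids, coding_ids, unannotated = [], [], []
    for g in expr.gene_ids:
        flag = ann.is_lncrna(g)
        if flag is None:
            unannotated.append(g)
        elif flag:
            lnc_ids.append(g)
        else:
            coding_ids.append(g)
    if not lnc_ids and not coding_ids:
        raise ValueError("no gene of the expression matrix is annotated")
    if unannotated:
        logger.info("split_by_biotype: %d genes lack annotation", len(unannotated))
    cls = expr.sample_class
    lnc = ExpressionMatrix(expr.values.loc[lnc_ids].copy(), cls.copy())
    coding = ExpressionMatrix(expr.values.loc[coding_ids].copy(), cls.copy())
    return lnc, coding, unannotated


def filter_cohort(clin: ClinicalTable, min_days: int = 30) -> ClinicalTable:
    """Keep patients with complete follow-up and survival time >= ``min_days``.

    The day threshold is inclusive: a patient followed exactly ``min_days``
    days is eligible.
    """
    df = clin.data
    complete = df["os_time"].notna() & df["os_event"].notna()
    eligible = complete & (df["os_time"] >= min_days)
    n_incomplete = int((~complete).sum())
    n_short = int((complete & ~eligible).sum())
    if n_incomplete or n_short:
        logger.info(
            "filter_cohort: removed %d with incomplete follow-up, %d with "
            "os_time < %d days",
            n_incomplete,
            n_short,
            min_days,
        )
    out = df[eligible].copy()
    if out.empty:
        raise ValueError(f"no patient satisfies os_time >= {min_days} days")
    out["os_event"] = out["os_event"].astype(int)
    return ClinicalTable(out)
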