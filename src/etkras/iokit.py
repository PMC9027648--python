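"""Reading and writing of every external file the pipeline touches.

Matrices are delimited text with features on rows and samples on columns;
the first column holds feature IDs and the header row holds sample IDs.
Sample metadata lives in a separate table mapping sample IDs to the 2x2
design (genotype x exposure) plus a replicate index.  Gene sets are read
from GMT, networks written as edge tables or SIF.

All writers produce byte-identical output across repeated runs on the same
input: row order is fixed and numbers are formatted with a fixed repr.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default condition labels of the 2x2 design, in canonical order
DEFAULT_CONDITIONS = ("HPNE", "HPNE_EtOH", "HPNE_KRAS", "HPNE_KRAS_EtOH")

#: tokens treated as missing protein values on disk
NA_TOKENS = ("", "NA", "NaN", "nan", "na")

VALID_ASSAYS = ("rna_counts", "protein_ratio")


@dataclass(frozen=True)
class SampleMeta:
    """Design annotation for one sample column.

    ``genotype`` ('WT' or 'MUT') and ``exposure`` ('control' or 'treated')
    jointly determine ``condition``; ``replicate`` is unique within a
    condition.
    """

    sample_id: str
    condition: str
    genotype: str
    exposure: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "MUT"):
            raise ValueError(f"genotype must be WT or MUT, got {self.genotype!r}")
        if self.exposure not in ("control", "treated"):
            raise ValueError(
                f"exposure must be control or treated, got {self.exposure!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with sample metadata.

    ``values`` is a pandas DataFrame (rows = feature IDs, columns = sample
    IDs).  ``assay`` is ``'rna_counts'`` (non-negative integers, no missing
    values) or ``'protein_ratio'`` (positive abundance ratios, NaN allowed).
    """

    values: pd.DataFrame
    assay: str
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature ID: {dup!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample_id in metadata")
        missing_meta = set(cols) - set(meta_ids)
        if missing_meta:
            raise ValueError(
                f"sample {sorted(missing_meta)[0]!r} has no metadata entry"
            )
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.condition, s.replicate)
            if key in seen:
                raise ValueError(
                    f"replicate {s.replicate} duplicated within {s.condition}"
                )
            seen.add(key)
        arr = self.values.to_numpy()
        if self.assay == "rna_counts":
            if np.isnan(arr).any():
                raise ValueError("rna_counts may not contain missing values")
            if (arr < 0).any():
                raise ValueError("rna_counts may not contain negative values")

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order over the columns."""
        order: list[str] = []
        meta = self.meta_by_id()
        for sid in self.values.columns:
            c = meta[sid].condition
            if c not in order:
                order.append(c)
        return order

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {s.sample_id: s for s in self.samples}

    def columns_for(self, condition: str) -> list[str]:
        meta = self.meta_by_id()
        cols = [c for c in self.values.columns if meta[c].condition == condition]
        if not cols:
            raise KeyError(f"condition {condition!r} not present")
        return cols

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.columns_for(condition)]

    def subset_features(self, features: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.loc[list(features)].copy(),
            assay=self.assay,
            samples=list(self.samples),
        )

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        keep = set(values.columns)
        return OmicsMatrix(
            values=values,
            assay=self.assay,
            samples=[s for s in self.samples if s.sample_id in keep],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by term ID: ``{term: (name, frozenset(members))}``."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_sample_meta(meta_path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata table.

    Required columns: sample_id, condition, genotype, exposure, replicate.
    """
    meta_path = Path(meta_path)
    df = pd.read_csv(meta_path, sep=_sep_for(meta_path), dtype=str)
    required = {"sample_id", "condition", "genotype", "exposure", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            condition=row.condition,
            genotype=row.genotype,
            exposure=row.exposure,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_omics_matrix(
    path: str | Path, meta_path: str | Path, assay: str
) -> OmicsMatrix:
    """Read a features x samples matrix plus its sample metadata.

    Protein blanks / NA tokens become NaN; zero protein ratios are treated
    as missing (flagged with a warning, not silently).  Counts are parsed
    as integers; negatives or missing counts are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(NA_TOKENS),
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature ID: {dup!r} in {path}")
    samples = read_sample_meta(meta_path)
    meta_ids = {s.sample_id for s in samples}
    for col in df.columns:
        if col not in meta_ids:
            raise ValueError(f"sample {col!r} in {path} absent from metadata")
    samples = [s for s in samples if s.sample_id in set(df.columns)]
    df = df.astype(float)
    if assay == "rna_counts":
        if df.isna().any().any():
            raise ValueError("missing value in count matrix")
        if (df.to_numpy() < 0).any():
            raise ValueError("negative count in count matrix")
        if not np.allclose(df.to_numpy(), np.round(df.to_numpy())):
            raise ValueError("non-integer count in count matrix")
        df = df.round().astype(np.int64).astype(float)
    elif assay == "protein_ratio":
        n_zero = int((df.to_numpy() == 0).sum())
        if n_zero:
            logger.warning(
                "%d zero protein ratios in %s treated as missing", n_zero, path
            )
            df = df.mask(df == 0)
    return OmicsMatrix(values=df, assay=assay, samples=samples)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path,
                       meta_path: str | Path | None = None) -> None:
    """Write a matrix (and optionally its metadata table) to delimited text."""
    path = Path(path)
    sep = _sep_for(path)
    df = matrix.values
    if matrix.assay == "rna_counts":
        out = df.astype(np.int64)
        out.to_csv(path, sep=sep, index_label="feature_id")
    else:
        df.to_csv(path, sep=sep, index_label="feature_id",
                  na_rep="NA", float_format="%.10g")
    if meta_path is not None:
        meta_path = Path(meta_path)
        rows = [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "genotype": s.genotype,
                "exposure": s.exposure,
                "replicate": s.replicate,
            }
            for s in matrix.samples
        ]
        pd.DataFrame(rows).to_csv(meta_path, sep=_sep_for(meta_path), index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: term <TAB> description <TAB> members...

    Duplicate members within a set are collapsed; lines with no members are
    dropped with a logged warning.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: unreadable GMT line")
            term, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                logger.warning("%s:%d: term %r has no members, dropped",
                               path, lineno, term)
                continue
            sets[term] = (desc, members)
    return GeneSetCollection(sets=sets)


# ----------------------------------------------------------------------
# network writers (DiffCoexpNetwork lives in etkras.diffcoexp)
# ----------------------------------------------------------------------

def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a differential co-expression network.

    ``edge_tsv`` columns: source, target, sign_class, then one Pearson-r
    column per condition.  ``sif`` uses the relation tokens 'pos'/'neg'.
    Rows are ordered lexicographically by (source, target) so output is
    bit-stable.
    """
    path = Path(path)
    edges = sorted(network.edges, key=lambda e: (e.source, e.target))
    if format == "edge_tsv":
        conds = list(network.conditions)
        header = ["source", "target", "sign_class"] + [f"r_{c}" for c in conds]
        lines = ["\t".join(header)]
        for e in edges:
            lines.append(
                "\t".join(
                    [e.source, e.target, e.sign_class]
                    + [f"{e.r[c]:.10g}" for c in conds]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        token = {"positive": "pos", "negative": "neg"}
        lines = [f"{e.source} {token[e.sign_class]} {e.target}" for e in edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edges(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back an ``edge_tsv`` file as (source, target, sign_class) triples."""
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.source), str(r.target), str(r.sign_class)) for r in df.itertuples()
    ]
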