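"""Readers and writers for the external formats the analyses consume.

Datasets are plain :class:`pandas.DataFrame` objects with a validated schema:

* **CFU tables** — one row per individual pupa/pharate adult: ``genotype``,
  ``stage`` (``P0`` or ``pharate``, stored categorical with ``P0`` as the
  reference level), ``bacterium`` (``Lactobacillus`` or ``Acetobacter``),
  ``colonies`` (non-negative integer plate count) and optionally
  ``cfu_per_pupa``.
* **CT tables** — one row per technical qPCR replicate: ``sample_id``,
  ``genotype``, ``stage`` (``L3`` or ``P0``), ``gene``, ``ct`` (positive
  real), ``replicate``.

All readers reject malformed input with an error identifying the first
offending row; nothing is silently coerced.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CFU_STAGES = ("P0", "pharate")
CT_STAGES = ("L3", "P0")
BACTERIA = ("Lactobacillus", "Acetobacter")
NUCLEOTIDES = ("A", "C", "G", "T")


class SchemaError(ValueError):
    """A table violates its declared schema; the message names the first offender."""


@dataclasses.dataclass(frozen=True)
class PfmRecord:
    """A position frequency matrix with rows in fixed A, C, G, T order."""

    motif_id: str
    counts: np.ndarray  # shape (4, L), non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise SchemaError(f"PFM must be 4 x L with L >= 1, got {counts.shape}")
        if (counts < 0).any():
            raise SchemaError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            col = int(np.argmax(counts.sum(axis=0) <= 0))
            raise SchemaError(f"PFM column {col} has no positive entry")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.counts.argmax(axis=0))


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_cfu_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-individual CFU table.

    The ``stage`` column is returned as an ordered categorical with ``P0``
    first, so downstream model matrices code P0 -> 0 and pharate -> 1.
    """
    df = pd.read_csv(path)
    return validate_cfu_table(df, source=str(path))


def validate_cfu_table(df: pd.DataFrame, source: str = "CFU table") -> pd.DataFrame:
    _require_columns(df, ("genotype", "stage", "bacterium", "colonies"), source)
    df = df.copy()
    bad_stage = ~df["stage"].isin(CFU_STAGES)
    if bad_stage.any():
        i = int(np.argmax(bad_stage.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: stage {df['stage'].iloc[i]!r} not in {CFU_STAGES}"
        )
    bad_bact = ~df["bacterium"].isin(BACTERIA)
    if bad_bact.any():
        i = int(np.argmax(bad_bact.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: bacterium {df['bacterium'].iloc[i]!r} not in {BACTERIA}"
        )
    colonies = pd.to_numeric(df["colonies"], errors="coerce")
    bad = colonies.isna() | (colonies < 0) | (colonies != np.floor(colonies))
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: colonies {df['colonies'].iloc[i]!r} is not a "
            "non-negative integer"
        )
    df["colonies"] = colonies.astype(int)
    df["stage"] = pd.Categorical(df["stage"], categories=list(CFU_STAGES), ordered=True)
    if "cfu_per_pupa" in df.columns:
        cfu = pd.to_numeric(df["cfu_per_pupa"], errors="coerce")
        if (cfu.isna() | (cfu < 0)).any():
            i = int(np.argmax((cfu.isna() | (cfu < 0)).to_numpy()))
            raise SchemaError(f"{source} row {i}: cfu_per_pupa must be non-negative")
        df["cfu_per_pupa"] = cfu
    return df


def write_cfu_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["stage"] = out["stage"].astype(str)
    out.to_csv(path, index=False)


def read_ct_table(path: str | Path, reference_gene: str = "rpl32") -> pd.DataFrame:
    """Read and validate a raw CT replicate table.

    Raises if any (sample, gene, replicate) key is duplicated or any sample
    lacks the reference (housekeeping) gene, since ddCT is undefined there.
    """
    df = pd.read_csv(path)
    return validate_ct_table(df, reference_gene=reference_gene, source=str(path))


def validate_ct_table(
    df: pd.DataFrame, reference_gene: str = "rpl32", source: str = "CT table"
) -> pd.DataFrame:
    _require_columns(
        df, ("sample_id", "genotype", "stage", "gene", "ct", "replicate"), source
    )
    df = df.copy()
    bad_stage = ~df["stage"].isin(CT_STAGES)
    if bad_stage.any():
        i = int(np.argmax(bad_stage.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: stage {df['stage'].iloc[i]!r} not in {CT_STAGES}"
        )
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad_ct = ct.isna() | (ct <= 0)
    if bad_ct.any():
        i = int(np.argmax(bad_ct.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: ct {df['ct'].iloc[i]!r} is not a positive number"
        )
    df["ct"] = ct.astype(float)
    dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        raise SchemaError(
            f"{source} row {i}: duplicate (sample_id, gene, replicate) key "
            f"({df['sample_id'].iloc[i]!r}, {df['gene'].iloc[i]!r}, "
            f"{df['replicate'].iloc[i]!r})"
        )
    has_ref = df.groupby("sample_id")["gene"].apply(lambda g: (g == reference_gene).any())
    if not has_ref.all():
        missing = has_ref.index[~has_ref][0]
        raise SchemaError(
            f"{source}: reference gene absent — sample {missing!r} has no "
            f"{reference_gene!r} rows"
        )
    df["stage"] = pd.Categorical(df["stage"], categories=list(CT_STAGES), ordered=True)
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["stage"] = out["stage"].astype(str)
    out.to_csv(path, index=False)


_JASPAR_ROW = re.compile(
    r"^\s*(?P<base>[ACGT])\s*\[?\s*(?P<body>[-0-9.eE+\s]+?)\s*\]?\s*$"
)


def read_jaspar_pfm(path: str | Path) -> PfmRecord:
    """Parse a JASPAR-format position frequency matrix.

    Accepts the classic ``>ID name`` header followed by four labelled rows
    such as ``A  [ 4 19  0 ... ]`` in any row order, or a bare 4-row matrix
    (then taken as A, C, G, T from top to bottom).
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    motif_id = "PFM"
    if lines and lines[0].startswith(">"):
        motif_id = lines[0][1:].split()[0]
        lines = lines[1:]
    if len(lines) != 4:
        raise SchemaError(f"expected 4 matrix rows, found {len(lines)}")
    rows: dict[str, np.ndarray] = {}
    labelled = all(_JASPAR_ROW.match(ln) for ln in lines)
    for i, ln in enumerate(lines):
        if labelled:
            m = _JASPAR_ROW.match(ln)
            base, body = m.group("base"), m.group("body")
        else:
            base, body = NUCLEOTIDES[i], ln.strip().strip("[]")
        try:
            values = np.array([float(x) for x in body.split()])
        except ValueError as exc:
            raise SchemaError(f"non-numeric entry in PFM row {base!r}: {ln!r}") from exc
        if base in rows:
            raise SchemaError(f"duplicate PFM row for base {base!r}")
        rows[base] = values
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise SchemaError(f"PFM rows have unequal lengths: {sorted(lengths)}")
    counts = np.vstack([rows[b] for b in NUCLEOTIDES])
    return PfmRecord(motif_id=motif_id, counts=counts)


def write_jaspar_pfm(pfm: PfmRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.motif_id}\n")
        for base, row in zip(NUCLEOTIDES, pfm.counts):
            body = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {body} ]\n")


def read_fasta(path: str | Path) -> SeqRecord:
    """Read the first record of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return records[0]


def write_fasta(record: SeqRecord | tuple[str, str], path: str | Path) -> None:
    if isinstance(record, tuple):
        name, seq = record
        record = SeqRecord(Seq(seq), id=name, description="")
    SeqIO.write([record], str(path), "fasta")
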