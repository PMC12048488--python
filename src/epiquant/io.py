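"""Readers and writers for the tabular and sequence formats of the pipeline.

The native tabular dialect is TSV (FragPipe/DIA-NN convention; protein
descriptions may contain commas).  Missing intensities are encoded as empty
fields and are distinct from measured zeros.  Protein identifiers are
opaque labels; contaminant entries are recognized by configurable label
prefixes.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "DESIGN_COLUMNS",
    "CONTAMINANT_PREFIXES",
    "load_experiment",
    "load_matrix",
    "load_design",
    "load_gene_sets",
    "load_sequences",
    "write_results",
    "strip_contaminants",
    "FormatError",
]

DESIGN_COLUMNS = (
    "run_id",
    "bait",
    "epitope_class",
    "tissue",
    "genotype",
    "age",
    "replicate",
    "role",
)

#: label prefixes marking contaminant / decoy entries
CONTAMINANT_PREFIXES = ("contam_", "rev_")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """A file failed validation; nothing is silently corrected."""


def load_matrix(path, integer: bool = False) -> pd.DataFrame:
    """Read a proteins x runs TSV matrix (first column ``Protein``).

    With ``integer=True`` the matrix is validated as spectral counts:
    every entry must be a non-negative integer (a value such as ``3.5``
    is rejected).  Otherwise missing (empty) fields become NaN and zeros
    stay measured zeros.
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "Protein":
        raise FormatError(f"{path}: first column must be 'Protein', "
                          f"found {frame.columns[0]!r}")
    if frame["Protein"].duplicated().any():
        dup = frame["Protein"][frame["Protein"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate protein label {dup!r}")
    frame = frame.set_index("Protein")
    values = frame.to_numpy(dtype=float, copy=False)
    if integer:
        if np.isnan(values).any():
            raise FormatError(f"{path}: missing values are not allowed in a "
                              "count matrix")
        if (values < 0).any():
            raise FormatError(f"{path}: negative spectral count")
        if not np.array_equal(values, np.round(values)):
            bad = frame.columns[np.where(values != np.round(values))[1][0]]
            raise FormatError(
                f"{path}: non-integer spectral count in column {bad!r}"
            )
        return frame.astype(int)
    if (values[~np.isnan(values)] < 0).any():
        raise FormatError(f"{path}: negative intensity")
    return frame.astype(float)


def load_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"{path}: design is missing columns {missing}")
    if design["run_id"].duplicated().any():
        dup = design["run_id"][design["run_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate run_id {dup!r}")
    return design


def _check_columns(matrix: pd.DataFrame, design: pd.DataFrame, name: str) -> None:
    known = set(design["run_id"])
    unknown = [c for c in matrix.columns if c not in known]
    if unknown:
        raise FormatError(
            f"{name} column(s) {unknown} are not described in the design; "
            "every matrix column must map to exactly one design row"
        )


def load_experiment(
    counts_path, intensities_path, design_path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a counts/intensities/design bundle.

    Every matrix column must be described by a design row; an unreferenced
    column is a hard error naming the run.
    """
    design = load_design(design_path)
    counts = load_matrix(counts_path, integer=True)
    intensities = load_matrix(intensities_path, integer=False)
    _check_columns(counts, design, Path(str(counts_path)).name)
    _check_columns(intensities, design, Path(str(intensities_path)).name)
    return counts, intensities, design


def load_gene_sets(path) -> dict[str, dict]:
    """Parse a GMT-style gene-set catalog.

    Each line: ``set_id<TAB>description<TAB>member1<TAB>member2...``.
    Duplicate members within a line are stored once (order preserved);
    a set with no members is an error.
    """
    catalog: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no members"
                )
            set_id, name = fields[0], fields[1]
            if set_id in catalog:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(
                    f"{path}:{lineno}: gene set {set_id!r} has no members"
                )
            catalog[set_id] = {"name": name, "members": members}
    return catalog


def load_sequences(path) -> dict[str, str]:
    """Read a FASTA file into ``{label: uppercase amino-acid sequence}``.

    Wrapped sequence lines are concatenated; lowercase letters are
    uppercased; duplicate headers and empty or non-amino-acid sequences
    are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {record.id!r}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"{path}: sequence {record.id!r} contains non-amino-acid "
                f"letters {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def write_results(table: pd.DataFrame, path) -> Path:
    """Write a result table as TSV with deterministic order.

    Rows are sorted by the first column, missing values are written as
    empty fields (never ``0``), and floats are rendered at six significant
    digits.  The written file round-trips through ``pd.read_csv``.
    """
    path = Path(path)
    frame = table.copy()
    if isinstance(frame, pd.Series):
        frame = frame.to_frame()
    if frame.index.name is not None:
        frame = frame.reset_index()
    frame = frame.sort_values(frame.columns[0], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")
    return path


def strip_contaminants(
    matrix: pd.DataFrame,
    prefixes: tuple[str, ...] = CONTAMINANT_PREFIXES,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Drop contaminant-prefixed proteins plus an optional explicit list."""
    labels = matrix.index.astype(str)
    mask = np.zeros(len(labels), dtype=bool)
    for prefix in prefixes:
        mask |= labels.str.startswith(prefix)
    if exclude:
        mask |= labels.isin(exclude)
    if mask.any():
        warnings.warn(
            f"removed {int(mask.sum())} contaminant entries", stacklevel=2
        )
    return matrix.loc[~mask]
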