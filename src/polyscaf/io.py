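"""Readers and writers: FASTA, Hi-C pairs TSV, truth/assignment TSVs, AGP, config.

Conventions: all internal coordinates are 0-based half-open; only the AGP
writer converts to the 1-based inclusive coordinates AGP v2.1 mandates.
All TSV writers emit a header line beginning with '#'; readers tolerate
trailing newlines and CRLF.
"""

from __future__ import annotations

import io as _io
import sys
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParameterError

IUPAC = set("ACGTRYSWKMBDHVN")

TRUTH_COLUMNS = ["contig", "subgenome", "chromosome", "start", "end", "orientation", "order_index"]
PAIRS_HEADER = "#contig1\tpos1\tcontig2\tpos2"


# ---------------------------------------------------------------- sequences

def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping.

    Ids are the first whitespace token of each header; duplicates, empty
    files and non-IUPAC characters are format errors naming the record.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name in seqs:
                raise FormatError(f"{path}: duplicate sequence id {name!r}")
            s = str(rec.seq).upper()
            bad = set(s) - IUPAC
            if bad:
                raise FormatError(
                    f"{path}: record {name!r} contains non-IUPAC characters {sorted(bad)}"
                )
            seqs[name] = s
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------- pairs TSV

def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write contact pairs as TSV with the canonical '#contig1 pos1 contig2 pos2' header."""
    with open(path, "w") as fh:
        fh.write(PAIRS_HEADER + "\n")
        pairs.to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(
    path: str | Path,
    contigs: dict[str, str] | None = None,
    max_reject_fraction: float = 0.01,
) -> pd.DataFrame:
    """Read and validate a contact-pairs TSV.

    When ``contigs`` is given, records naming unknown contigs or carrying
    out-of-range offsets are rejected and counted; more than
    ``max_reject_fraction`` rejected records is a hard error.  Pair storage
    order is canonicalised (lexicographically smaller contig id first).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        if header != PAIRS_HEADER:
            raise FormatError(
                f"{path}: expected header {PAIRS_HEADER!r}, found {header!r}"
            )
        df = pd.read_csv(
            fh, sep="\t", names=["contig1", "pos1", "contig2", "pos2"],
            dtype={"contig1": str, "pos1": "int64", "contig2": str, "pos2": "int64"},
        )
    n_total = len(df)
    if contigs is not None and n_total:
        lengths = {k: len(v) for k, v in contigs.items()}
        l1 = df["contig1"].map(lengths)
        l2 = df["contig2"].map(lengths)
        ok = (
            l1.notna() & l2.notna()
            & (df["pos1"] >= 0) & (df["pos2"] >= 0)
            & (df["pos1"] < l1.fillna(0)) & (df["pos2"] < l2.fillna(0))
        )
        n_rej = int((~ok).sum())
        if n_rej:
            if n_rej / n_total > max_reject_fraction:
                raise FormatError(
                    f"{path}: {n_rej}/{n_total} records rejected "
                    "(unknown contig or out-of-range offset)"
                )
            df = df[ok].reset_index(drop=True)
        df.attrs["n_rejected"] = n_rej
    # canonical unordered-pair storage
    swap = df["contig1"] > df["contig2"]
    if swap.any():
        df.loc[swap, ["contig1", "pos1", "contig2", "pos2"]] = df.loc[
            swap, ["contig2", "pos2", "contig1", "pos1"]
        ].to_numpy()
    return df


# ------------------------------------------------------------ truth and TSVs

def _write_tsv(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=columns)


def _read_tsv(path: str | Path, columns: list[str], dtypes: dict) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        expected = "#" + "\t".join(columns)
        if header != expected:
            raise FormatError(f"{path}: expected header {expected!r}, found {header!r}")
        return pd.read_csv(fh, sep="\t", names=columns, dtype=dtypes)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write TruthRecords (contig, subgenome, chromosome, start, end, orientation, order_index)."""
    _write_tsv(truth, path, TRUTH_COLUMNS)


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read_tsv(
        path, TRUTH_COLUMNS,
        {"contig": str, "subgenome": "int64", "chromosome": str,
         "start": "int64", "end": "int64", "orientation": str, "order_index": "int64"},
    )


ASSIGNMENT_COLUMNS = ["contig", "label", "confidence", "provenance"]


def write_assignment(assignment: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(assignment, path, ASSIGNMENT_COLUMNS)


def read_assignment(path: str | Path) -> pd.DataFrame:
    return _read_tsv(
        path, ASSIGNMENT_COLUMNS,
        {"contig": str, "label": str, "confidence": "float64", "provenance": str},
    )


FEATURE_COLUMNS = ["chromosome", "feature", "start", "end", "copies"]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(features, path, FEATURE_COLUMNS)


def read_features(path: str | Path) -> pd.DataFrame:
    return _read_tsv(
        path, FEATURE_COLUMNS,
        {"chromosome": str, "feature": str, "start": "int64", "end": "int64",
         "copies": "int64"},
    )


# ----------------------------------------------------------------------- AGP

def write_agp(rows: list[tuple], path: str | Path) -> None:
    """Write AGP v2.1 rows (already 1-based, as produced by build_agp)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# -------------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    """Load a YAML (.yaml/.yml) or TOML (.toml) configuration file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    elif suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        raise ParameterError(f"unrecognised config extension {suffix!r} (use .yaml or .toml)")
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
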