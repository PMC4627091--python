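"""Delimited-text schemas and FASTA I/O for the pipeline.

All tables are UTF-8 tab-separated text with explicit headers and a
decimal point; every reader validates its schema and reports the
offending file and columns.  Round-trip (write then read) is the
identity on the data model.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import MutantSpec, PointMutation

SEP = "\t"

TITRATION_COLUMNS = ["mutant_id", "replicate", "temperature_C", "conc_uM", "signal"]
MELT_COLUMNS = ["mutant_id", "replicate", "temperature_C", "signal"]
LANDSCAPE_COLUMNS = [
    "mutant_id", "positions", "s_m", "ddg", "ddh", "dtm",
    "sigma_s_m", "sigma_ddg", "sigma_ddh", "sigma_dtm", "fluorogenic", "flags",
]
LAYOUT_COLUMNS = ["cell", "row", "col", "mutant_id", "replicate", "control"]
MUTANT_COLUMNS = ["id", "substitutions", "deletions"]
SIGNAL_COLUMNS = ["cell", "mutant_id", "replicate", "s_i", "s_b", "s_p", "s_m", "flags"]


class ValidationError(ValueError):
    """Schema violation, reported with the file and the offending columns."""


def read_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return str(records[0].seq).upper().replace("T", "U")


def write_fasta(path, seq: str, name: str = "reference") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=SEP)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty input table") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: table has a header but no rows")
    return df


def write_table(path, frame: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=SEP, index=False, float_format="%.10g")


def _coerce(df: pd.DataFrame, floats=(), ints=()) -> pd.DataFrame:
    for c in floats:
        df[c] = df[c].astype(float)
    for c in ints:
        df[c] = df[c].astype(int)
    return df


def read_titrations(path) -> pd.DataFrame:
    df = read_table(path, TITRATION_COLUMNS)
    return _coerce(df, floats=("temperature_C", "conc_uM", "signal"), ints=("replicate",))


def read_melts(path) -> pd.DataFrame:
    df = read_table(path, MELT_COLUMNS)
    return _coerce(df, floats=("temperature_C", "signal"), ints=("replicate",))


def _normalize_positions(v) -> str:
    if pd.isna(v):
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def read_landscape(path) -> pd.DataFrame:
    df = read_table(path, LANDSCAPE_COLUMNS)
    # controls have no positions, so pandas parses the column as float
    df["positions"] = df["positions"].map(_normalize_positions)
    df["flags"] = df["flags"].fillna("")
    return df


def _parse_substitution(token: str) -> PointMutation:
    token = token.strip()
    if len(token) < 3:
        raise ValidationError(f"bad substitution token {token!r}")
    return PointMutation(position=int(token[1:-1]), wt_base=token[0], alt_base=token[-1])


def mutants_to_frame(specs) -> pd.DataFrame:
    rows = []
    for s in specs:
        rows.append(
            {
                "id": s.id,
                "substitutions": "+".join(m.label for m in s.substitutions),
                "deletions": "+".join(str(p) for p in s.deletions),
            }
        )
    return pd.DataFrame(rows, columns=MUTANT_COLUMNS)


def frame_to_mutants(frame: pd.DataFrame) -> list[MutantSpec]:
    specs = []
    for row in frame.itertuples(index=False):
        subs = tuple(
            _parse_substitution(t)
            for t in str(row.substitutions).split("+")
            if t and t != "nan"
        )
        dels = tuple(
            int(float(t)) for t in str(row.deletions).split("+") if t and t != "nan"
        )
        specs.append(MutantSpec(id=str(row.id), substitutions=subs, deletions=dels))
    return specs


def read_mutants(path) -> list[MutantSpec]:
    return frame_to_mutants(read_table(path, MUTANT_COLUMNS))


def write_mutants(path, specs) -> None:
    write_table(path, mutants_to_frame(specs))
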