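"""AIRR rearrangement tables: reading, call parsing, repertoire filters.

Input is the AIRR Community Rearrangement TSV schema (sequence_id, v_call,
j_call, clone_id, ...).  The filters implement the pre-genotyping clean-up
for naive, full-length repertoires: one representative per clone (fewest
mutations), no mutations in the V region up to position 316, 5'-complete V
coverage, and at least 312 nt of V alignment.  Positions are IMGT gapped
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import SchemaError

REQUIRED_COLUMNS = ["sequence_id", "v_call"]

#: Last V position in which mutations disqualify a "naive" read; mutations
#: beyond it are tolerated as likely sequencing error at the V 3' end.
UNMUTATED_MAX_POS = 316
#: Minimum V alignment length for sufficient 3' coverage.
MIN_V_LENGTH = 312


def parse_call(call) -> list[str]:
    """Split a (possibly comma-separated) allele call into distinct names."""
    if call is None or (isinstance(call, float) and pd.isna(call)):
        return []
    out: list[str] = []
    for n in str(call).split(","):
        n = n.strip()
        if n and n not in out:
            out.append(n)
    return out


@dataclass
class RearrangementTable:
    """An annotated repertoire for one subject, backed by a DataFrame."""

    df: pd.DataFrame
    subject_id: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"missing required AIRR column {col!r}")
        if self.df["sequence_id"].duplicated().any():
            dup = self.df["sequence_id"][self.df["sequence_id"].duplicated()]
            raise SchemaError(
                f"duplicate sequence_id values: {sorted(set(dup))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def _with(self, df: pd.DataFrame) -> "RearrangementTable":
        return replace(self, df=df.reset_index(drop=True))

    def v_calls(self) -> list[list[str]]:
        return [parse_call(c) for c in self.df["v_call"]]

    def require(self, *columns: str) -> None:
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise SchemaError(
                f"operation needs AIRR column(s) {missing}; "
                f"available: {list(self.df.columns)}"
            )


def read_airr(path: str | Path, subject_id: str = "") -> RearrangementTable:
    """Read an AIRR Rearrangement TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "clone_id": str})
    if len(df) == 0:
        raise SchemaError(f"empty rearrangement table: {path}")
    return RearrangementTable(
        df=df, subject_id=subject_id or path.stem, provenance=str(path)
    )


def write_airr(table: RearrangementTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def select_clone_representative(table: RearrangementTable) -> RearrangementTable:
    """Keep one record per clone: fewest V mutations, ties by sequence_id.

    A clone is a set of reads descended from one rearrangement; its least
    mutated member best approximates the germline state.  Records without a
    clone_id are treated as singleton clones and kept.
    """
    table.require("v_mutation_count")
    df = table.df
    if "clone_id" not in df.columns:
        return table._with(df)
    has_clone = df["clone_id"].notna() & (df["clone_id"].astype(str) != "")
    clones = df[has_clone].sort_values(
        ["v_mutation_count", "sequence_id"]
    ).groupby("clone_id", sort=False).head(1)
    out = pd.concat([clones, df[~has_clone]]).sort_index()
    return table._with(out)


def _mutations_up_to(df: pd.DataFrame, max_pos: int) -> pd.Series:
    """Per-record mutation count restricted to IMGT positions 1..max_pos.

    Preferred source is a ``v_mutation_positions`` column (comma-separated
    gapped positions); otherwise gapped ``sequence_alignment`` /
    ``germline_alignment`` strings are compared; as a last resort the plain
    ``v_mutation_count`` is used, which is only correct if it was already
    restricted to positions <= max_pos upstream.
    """
    if "v_mutation_positions" in df.columns:
        def count(val) -> int:
            if val is None or (isinstance(val, float) and pd.isna(val)):
                return 0
            s = str(val).strip()
            if not s:
                return 0
            return sum(1 for p in s.split(",") if int(p) <= max_pos)

        return df["v_mutation_positions"].map(count)
    if {"sequence_alignment", "germline_alignment"} <= set(df.columns):
        def mismatches(row) -> int:
            obs = str(row["sequence_alignment"])[:max_pos]
            germ = str(row["germline_alignment"])[:max_pos]
            return sum(
                1
                for o, g in zip(obs, germ)
                if o != g and o != "." and g != "." and g != "N" and o != "N"
            )

        return df.apply(mismatches, axis=1)
    if "v_mutation_count" in df.columns:
        return df["v_mutation_count"]
    raise SchemaError(
        "no mutation information: need v_mutation_positions, alignment "
        "strings, or v_mutation_count"
    )


def filter_unmutated(
    table: RearrangementTable, max_pos: int = UNMUTATED_MAX_POS
) -> RearrangementTable:
    """Keep records with zero mutations in V positions 1..max_pos."""
    counts = _mutations_up_to(table.df, max_pos)
    return table._with(table.df[counts == 0])


def filter_five_prime_complete(table: RearrangementTable) -> RearrangementTable:
    """Keep records whose V alignment starts at germline position 1."""
    col = (
        "v_germline_start"
        if "v_germline_start" in table.df.columns
        else "v_coverage_start"
    )
    table.require(col)
    return table._with(table.df[table.df[col] == 1])


def filter_three_prime_coverage(
    table: RearrangementTable, min_len: int = MIN_V_LENGTH
) -> RearrangementTable:
    """Keep records whose V alignment spans at least ``min_len`` nt."""
    df = table.df
    if "v_alignment_length" in df.columns:
        length = df["v_alignment_length"]
    elif {"v_germline_start", "v_germline_end"} <= set(df.columns):
        length = df["v_germline_end"] - df["v_germline_start"] + 1
    else:
        raise SchemaError(
            "no V coverage information: need v_alignment_length or "
            "v_germline_start/v_germline_end"
        )
    return table._with(df[length >= min_len])


def filter_report(
    table: RearrangementTable,
    filters: list[Callable[[RearrangementTable], RearrangementTable]],
) -> tuple[RearrangementTable, pd.DataFrame]:
    """Apply filters in order; report records removed by each."""
    rows = []
    for f in filters:
        before = len(table)
        table = f(table)
        rows.append({"filter": f.__name__, "removed": before - len(table),
                     "remaining": len(table)})
    return table, pd.DataFrame(rows)
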