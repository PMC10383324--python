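"""Readers and writers for every external artifact the pipeline touches.

Formats (all UTF-8, tab-separated):

* abundance table -- header row of sample ids, first column protein ids,
  empty cells are missing values;
* sample sheet -- columns ``sample_id`` and ``group``;
* edge list -- two or more tab-separated columns, ``#`` comment lines
  ignored, extra columns ignored (so trimmed BioGRID TAB exports parse
  without conversion), duplicate and reversed edges deduplicated, self-loops
  dropped with a warning;
* signed GMT -- standard GMT (``id TAB description TAB member...``) where a
  member token may carry a ``|-1`` suffix marking a repressor;
* results -- fixed-schema TSV with floats at 6 significant digits.

All readers validate strictly and raise :class:`~egopath.errors.FormatError`
naming the offending line or cell rather than silently coercing.
Identifiers are case-sensitive and matched exactly across files.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, InteractionNetwork, PathwayDefinition
from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["id", "statistic", "observed", "null_mean", "null_sd", "p", "n_perm", "seed"]


# ---------------------------------------------------------------- abundance


def read_abundance(table_path, sheet_path) -> AbundanceMatrix:
    """Read an abundance TSV plus its sample sheet into an AbundanceMatrix.

    The sheet must assign a group to every sample column; a ``control``
    column value of ``1``/``true`` marks the control group, otherwise the
    first group listed is taken as control.
    """
    table_path, sheet_path = Path(table_path), Path(sheet_path)
    raw = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{table_path}: duplicate protein ids {dups[:5]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"{table_path}: duplicate sample ids {dups[:5]}")
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = values.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{table_path}: non-numeric cell at protein {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )

    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"{sheet_path}: missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{sheet_path}: duplicate sample ids {dups}")
    sample_to_group = dict(zip(sheet["sample_id"], sheet["group"]))
    unsheeted = [s for s in values.columns if s not in sample_to_group]
    if unsheeted:
        raise FormatError(f"{sheet_path}: samples without group: {unsheeted}")
    extra = [s for s in sheet["sample_id"] if s not in values.columns]
    if extra:
        logger.warning("%s: %d sheet samples absent from table: %s",
                       sheet_path, len(extra), extra[:5])

    if "control" in sheet.columns:
        flag = sheet["control"].fillna("").str.strip().str.lower().isin({"1", "true", "yes"})
        marked = sheet.loc[flag, "group"].unique().tolist()
        if len(marked) != 1:
            raise FormatError(f"{sheet_path}: exactly one control group required, got {marked}")
        control = marked[0]
    else:
        control = sheet["group"].iloc[0]
    keep = {s: g for s, g in sample_to_group.items() if s in values.columns}
    return AbundanceMatrix(values=values.astype(float), sample_to_group=keep,
                           control_group=control)


def write_abundance(matrix: AbundanceMatrix, table_path, sheet_path) -> None:
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(table_path, sep="\t", index_label="protein_id", na_rep="")
    rows = []
    for s in matrix.sample_ids:
        g = matrix.sample_to_group[s]
        rows.append({"sample_id": s, "group": g,
                     "control": "1" if g == matrix.control_group else "0"})
    pd.DataFrame(rows).to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------- edge list


def read_edge_list(path) -> InteractionNetwork:
    """Parse a two-column (or wider) TSV edge list into an undirected network."""
    path = Path(path)
    edges: set[frozenset] = set()
    nodes: set[str] = set()
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            a, b = fields[0].strip(), fields[1].strip()
            nodes.update((a, b))
            if a == b:
                n_loops += 1
                continue
            edges.add(frozenset((a, b)))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return InteractionNetwork.from_edges((tuple(sorted(e)) for e in edges), nodes=nodes)


def write_edge_list(network: InteractionNetwork, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# interactor_a\tinteractor_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edge_set()):
            fh.write(f"{a}\t{b}\n")
        for n in sorted(network.nodes - {x for e in network.edge_set() for x in e}):
            fh.write(f"{n}\t{n}\n")  # isolated node, recorded as a dropped loop


# ---------------------------------------------------------------- signed GMT


def read_signed_gmt(path) -> list[PathwayDefinition]:
    """Parse a signed GMT file.

    A member token is either a plain id (sign +1) or ``ID|-1`` (repressor).
    Plain unsigned GMT files therefore parse with every sign +1.
    """
    path = Path(path)
    pathways: list[PathwayDefinition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            pid, name = fields[0], fields[1]
            members: dict[str, int] = {}
            for tok in fields[2:]:
                tok = tok.strip()
                if not tok:
                    continue
                if "|" in tok:
                    mid, _, suffix = tok.partition("|")
                    if suffix != "-1":
                        raise FormatError(
                            f"{path}:{lineno}: unknown sign suffix {tok!r} "
                            "(only '|-1' is recognised)")
                    sign = -1
                else:
                    mid, sign = tok, 1
                if mid in members:
                    raise FormatError(f"{path}:{lineno}: duplicate member {mid!r}")
                members[mid] = sign
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no members")
            pathways.append(PathwayDefinition(pathway_id=pid, name=name, members=members))
    return pathways


def write_signed_gmt(pathways: Sequence[PathwayDefinition], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            toks = [m if s == 1 else f"{m}|-1" for m, s in pw.members.items()]
            fh.write("\t".join([pw.pathway_id, pw.name, *toks]) + "\n")


# ---------------------------------------------------------------- results


def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return "" if x is None else str(x)


def write_results(records: Iterable[dict] | pd.DataFrame, path) -> None:
    """Write permutation-result records as a fixed-column-order TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"result records missing columns {missing}")
    df = df[RESULT_COLUMNS]
    bad_p = df["p"].dropna().astype(float)
    if ((bad_p < 0) | (bad_p > 1)).any():
        raise ConfigurationError("p-values outside [0, 1] refused")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS) + "\n")


# ---------------------------------------------------------------- behavior


def write_behavior(sequences_df: pd.DataFrame, explorations_df: pd.DataFrame,
                   seq_path, expl_path) -> None:
    """Write arm-entry sequences (entries as e.g. "ABCAB") and exploration
    time records as two TSVs."""
    Path(seq_path).parent.mkdir(parents=True, exist_ok=True)
    sequences_df.to_csv(seq_path, sep="\t", index=False)
    explorations_df.to_csv(expl_path, sep="\t", index=False)


def read_behavior(seq_path, expl_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    seqs = pd.read_csv(seq_path, sep="\t", dtype=str)
    for col in ("animal_id", "group", "entries"):
        if col not in seqs.columns:
            raise FormatError(f"{seq_path}: missing column {col!r}")
    expl = pd.read_csv(expl_path, sep="\t")
    for col in ("animal_id", "group", "phase", "time_novel", "time_familiar"):
        if col not in expl.columns:
            raise FormatError(f"{expl_path}: missing column {col!r}")
    return seqs, expl


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
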