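"""Readers and writers for the plain-text formats the pipeline consumes.

Counts are features × samples TSV with a header row of sample ids;
phenotypes are CSV with one row per bird; annotations are 9-column GTF
with 1-based inclusive coordinates; gene sets are GMT. All readers
validate and fail with the offending line or column named.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .phenotypes import RAW_COLUMNS

logger = logging.getLogger(__name__)

GTF_COLUMNS = (
    "seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attributes",
)
_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_counts(path) -> pd.DataFrame:
    """Count matrix TSV: first column feature id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups[:10]}")
    if df.isna().any().any():
        raise ValueError(f"missing values in count matrix {path}")
    if (df < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} is missing columns: {missing}")
    return df


def parse_gtf_attributes(attr: str) -> dict:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path) -> pd.DataFrame:
    """Parse a GTF into a frame with coordinates kept 1-based inclusive.

    Adds ``gene_id`` / ``transcript_id`` / ``feature_type`` columns pulled
    from the attribute field when present.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            rec = dict(zip(GTF_COLUMNS, parts))
            try:
                rec["start"], rec["end"] = int(rec["start"]), int(rec["end"])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from err
            if rec["start"] > rec["end"]:
                raise ValueError(f"{path}:{lineno}: start > end")
            rec.update(parse_gtf_attributes(rec["attributes"]))
            rows.append(rec)
    return pd.DataFrame(rows)


def write_gtf(features: pd.DataFrame, path=None) -> str:
    """Write GTF lines from a frame with id/chrom/start/end/strand/feature_type.

    Returns the text; also writes it when ``path`` is given.
    """
    lines = []
    for fid, row in features.iterrows():
        attrs = f'gene_id "{fid}"; transcript_id "{fid}.1"; feature_type "{row["feature_type"]}";'
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]), "hybridvigor", "transcript",
                    str(int(row["start"])), str(int(row["end"])), ".",
                    str(row.get("strand", "+")), ".", attrs,
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gmt(path) -> tuple[dict, dict]:
    """GMT gene sets: returns ({set_id: members}, {set_id: description}).

    Duplicate members within a set are dropped with a warning.
    """
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description, >=1 member")
            set_id, desc, members = parts[0], parts[1], parts[2:]
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                n_dup = len([m for m in members if m]) - len(unique)
                logger.warning("%s:%d: set %s had %d duplicate member(s)", path, lineno, set_id, n_dup)
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = set(unique)
            descriptions[set_id] = desc
    return sets, descriptions
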