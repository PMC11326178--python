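"""Readers for rMATS-style junction-count tables and cohort harmonization.

The package consumes the tab-delimited ``*.MATS.JC.txt`` output of rMATS
turbo (one file per splice type per sample).  PSI (percent spliced-in) is
the length-normalized inclusion ratio

    psi = (ijc / inc_form_len) / (ijc / inc_form_len + sjc / skip_form_len)

and is undefined when no junction reads support the event at all.  All
genomic coordinates are kept 0-based half-open internally (the rMATS
``exonStart_0base`` convention); conversion to 1-based GTF coordinates
happens only inside :mod:`spliceburden.functional_impact`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPLICE_TYPES = ("SE", "A5SS", "A3SS", "RI")

#: rMATS turbo 4.1.0 JC column names holding the four coordinate pairs,
#: per splice type, mapped onto the internal (exon, upstream, downstream)
#: slots.  For A5SS/A3SS the "exon" is the long exon and the flanking exon
#: fills the downstream slot; for RI the retained-intron span is the exon.
_COORD_COLUMNS: Mapping[str, Sequence[str]] = {
    "SE": (
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "A5SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "A3SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "RI": (
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
}

_COUNT_COLUMNS = ("IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncFormLen", "SkipFormLen")
_ID_COLUMNS = ("ID", "GeneID", "geneSymbol", "chr", "strand")

#: internal column order of an EventTable's DataFrame
EVENT_COLUMNS = [
    "event_id", "splice_type", "gene_id", "gene_symbol", "chrom", "strand",
    "exon_start", "exon_end", "upstream_start", "upstream_end",
    "downstream_start", "downstream_end",
    "ijc", "sjc", "inc_form_len", "skip_form_len", "psi", "support",
]


class RmatsFormatError(ValueError):
    """Raised when an input table does not conform to the rMATS JC layout."""


def event_ids(df: pd.DataFrame) -> pd.Series:
    """Canonical event key string.

    The key is (splice_type, chrom, strand, exon_start, exon_end,
    upstream_end, downstream_start): the coordinates that define the
    junctions being counted.  GeneID differences on identical coordinates
    are annotation drift, not distinct events, and are reconciled when
    tables are merged.
    """
    return (
        df["splice_type"].astype(str)
        + ":" + df["chrom"].astype(str)
        + ":" + df["strand"].astype(str)
        + ":" + df["exon_start"].astype(int).astype(str)
        + "-" + df["exon_end"].astype(int).astype(str)
        + ":" + df["upstream_end"].astype(int).astype(str)
        + ":" + df["downstream_start"].astype(int).astype(str)
    )


@dataclass
class EventTable:
    """One sample's splice events of a single type with junction support."""

    sample_id: str
    splice_type: str
    df: pd.DataFrame  # columns = EVENT_COLUMNS
    #: per-replicate PSI lists when the file came from a multi-replicate
    #: (paired-mode) rMATS run; length-1 lists in single-sample mode
    psi_replicates: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.splice_type not in SPLICE_TYPES:
            raise ValueError(f"unknown splice type {self.splice_type!r}")
        if not self.psi_replicates:
            self.psi_replicates = [[v] for v in self.df["psi"]]

    def __len__(self) -> int:
        return len(self.df)


def compute_psi(ijc, sjc, inc_form_len, skip_form_len):
    """Length-normalized PSI; NaN where ijc + sjc == 0.

    Accepts scalars or array-likes; raises on non-positive form lengths.
    """
    ijc = np.asarray(ijc, dtype=float)
    sjc = np.asarray(sjc, dtype=float)
    inc_form_len = np.asarray(inc_form_len, dtype=float)
    skip_form_len = np.asarray(skip_form_len, dtype=float)
    if np.any(inc_form_len <= 0) or np.any(skip_form_len <= 0):
        raise ValueError("form lengths must be positive")
    if np.any(ijc < 0) or np.any(sjc < 0):
        raise ValueError("junction counts must be non-negative")
    inc = ijc / inc_form_len
    skip = sjc / skip_form_len
    total = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(ijc + sjc > 0, inc / np.where(total > 0, total, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def _parse_count_list(value) -> list[int]:
    """rMATS writes replicate counts as a comma-separated list."""
    if pd.isna(value):
        return []
    parts = str(value).split(",")
    out = []
    for p in parts:
        p = p.strip()
        if p in ("", "NA"):
            continue
        out.append(int(float(p)))
    return out


def _parse_psi_list(value) -> list[float]:
    if pd.isna(value):
        return []
    out = []
    for p in str(value).split(","):
        p = p.strip()
        out.append(np.nan if p in ("", "NA") else float(p))
    return out


def read_rmats_table(path, splice_type: str, sample_id: str | None = None) -> EventTable:
    """Read one ``*.MATS.JC.txt`` file into an :class:`EventTable`.

    PSI is taken from ``IncLevel1`` when present (first replicate), and
    recomputed from the counts otherwise.  Multi-replicate cells are kept
    in ``psi_replicates``.
    """
    path = Path(path)
    if splice_type not in SPLICE_TYPES:
        raise ValueError(f"unknown splice type {splice_type!r}")
    if sample_id is None:
        sample_id = path.stem.split(".")[0]
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RmatsFormatError(f"{path}: cannot parse as tab-delimited: {exc}") from exc

    coord_cols = _COORD_COLUMNS[splice_type]
    mandatory = list(_ID_COLUMNS) + list(coord_cols) + list(_COUNT_COLUMNS)
    for col in mandatory:
        if col not in raw.columns:
            raise RmatsFormatError(f"{path}: missing mandatory column {col!r}")

    n = len(raw)
    if n == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
        return EventTable(sample_id=sample_id, splice_type=splice_type, df=df)

    ijc_lists, sjc_lists, psi_lists = [], [], []
    has_inclevel = "IncLevel1" in raw.columns
    for i, row in enumerate(raw.itertuples(index=False)):
        rowmap = dict(zip(raw.columns, row))
        try:
            ijc_lists.append(_parse_count_list(rowmap["IJC_SAMPLE_1"]))
            sjc_lists.append(_parse_count_list(rowmap["SJC_SAMPLE_1"]))
        except ValueError as exc:
            raise RmatsFormatError(
                f"{path}: line {i + 2}: non-numeric junction count"
            ) from exc
        psi_lists.append(_parse_psi_list(rowmap["IncLevel1"]) if has_inclevel else [])

    def _col_int(col):
        try:
            return raw[col].astype(float).astype(int).to_numpy()
        except ValueError as exc:
            raise RmatsFormatError(f"{path}: non-numeric value in column {col!r}") from exc

    inc_len = _col_int("IncFormLen")
    skip_len = _col_int("SkipFormLen")
    ijc0 = np.array([(lst[0] if lst else 0) for lst in ijc_lists])
    sjc0 = np.array([(lst[0] if lst else 0) for lst in sjc_lists])

    recomputed = compute_psi(ijc0, sjc0, inc_len, skip_len)
    psi0 = np.array(
        [lst[0] if lst and not np.isnan(lst[0]) else np.nan for lst in psi_lists]
    )
    psi = np.where(np.isnan(psi0), recomputed, psi0)

    df = pd.DataFrame(
        {
            "splice_type": splice_type,
            "gene_id": raw["GeneID"].str.strip('"'),
            "gene_symbol": raw["geneSymbol"].str.strip('"'),
            "chrom": raw["chr"],
            "strand": raw["strand"],
            "exon_start": _col_int(coord_cols[0]),
            "exon_end": _col_int(coord_cols[1]),
            "upstream_start": _col_int(coord_cols[2]),
            "upstream_end": _col_int(coord_cols[3]),
            "downstream_start": _col_int(coord_cols[4]),
            "downstream_end": _col_int(coord_cols[5]),
            "ijc": ijc0,
            "sjc": sjc0,
            "inc_form_len": inc_len,
            "skip_form_len": skip_len,
            "psi": psi,
        }
    )
    df["support"] = df["ijc"] + df["sjc"]
    df.insert(0, "event_id", event_ids(df))

    # per-replicate PSI, recomputed when IncLevel had gaps
    psi_reps: list[list[float]] = []
    for k in range(n):
        reps_i, reps_s = ijc_lists[k], sjc_lists[k]
        nrep = max(len(reps_i), len(reps_s), len(psi_lists[k]), 1)
        vals = []
        for r in range(nrep):
            given = psi_lists[k][r] if r < len(psi_lists[k]) else np.nan
            if not np.isnan(given):
                vals.append(given)
            else:
                i_r = reps_i[r] if r < len(reps_i) else 0
                s_r = reps_s[r] if r < len(reps_s) else 0
                vals.append(compute_psi(i_r, s_r, inc_len[k], skip_len[k]))
        psi_reps.append(vals)

    return EventTable(sample_id=sample_id, splice_type=splice_type, df=df,
                      psi_replicates=psi_reps)


def write_rmats_table(table: EventTable, path) -> None:
    """Write an EventTable back to the rMATS JC layout (inverse of the reader)."""
    coord_cols = _COORD_COLUMNS[table.splice_type]
    df = table.df
    out = pd.DataFrame({"ID": np.arange(1, len(df) + 1)})
    out["GeneID"] = df["gene_id"].to_numpy()
    out["geneSymbol"] = df["gene_symbol"].to_numpy()
    out["chr"] = df["chrom"].to_numpy()
    out["strand"] = df["strand"].to_numpy()
    out[coord_cols[0]] = df["exon_start"].to_numpy()
    out[coord_cols[1]] = df["exon_end"].to_numpy()
    out[coord_cols[2]] = df["upstream_start"].to_numpy()
    out[coord_cols[3]] = df["upstream_end"].to_numpy()
    out[coord_cols[4]] = df["downstream_start"].to_numpy()
    out[coord_cols[5]] = df["downstream_end"].to_numpy()
    out["IJC_SAMPLE_1"] = df["ijc"].to_numpy()
    out["SJC_SAMPLE_1"] = df["sjc"].to_numpy()
    out["IncFormLen"] = df["inc_form_len"].to_numpy()
    out["SkipFormLen"] = df["skip_form_len"].to_numpy()
    out["IncLevel1"] = [
        "NA" if np.isnan(v) else repr(float(v)) for v in df["psi"]
    ]
    out.to_csv(path, sep="\t", index=False)


def apply_junction_filter(table: EventTable, min_reads: int = 10) -> EventTable:
    """Keep events with ijc + sjc >= ``min_reads`` (row order preserved)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = (table.df["support"] >= min_reads).to_numpy()
    df = table.df.loc[keep].reset_index(drop=True)
    reps = [r for r, k in zip(table.psi_replicates, keep) if k]
    return EventTable(sample_id=table.sample_id, splice_type=table.splice_type,
                      df=df, psi_replicates=reps)


@dataclass
class PsiMatrix:
    """Events x samples PSI with missingness and junction support."""

    values: pd.DataFrame   # index = event_id, columns = sample_id, float PSI
    support: pd.DataFrame  # same shape, ijc + sjc (0 where absent)
    events: pd.DataFrame   # event metadata indexed by event_id

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def write(self, values_path, events_path=None) -> None:
        self.values.rename_axis("event_id").to_csv(values_path, sep="\t")
        if events_path is not None:
            self.events.rename_axis("event_id").to_csv(events_path, sep="\t")


def read_psi_matrix(values_path, events_path=None) -> PsiMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="event_id")
    events = (
        pd.read_csv(events_path, sep="\t", index_col="event_id")
        if events_path is not None
        else pd.DataFrame(index=values.index)
    )
    support = values.notna().astype(float)
    return PsiMatrix(values=values, support=support, events=events)


def build_psi_matrix(
    tables: Iterable[EventTable],
    min_sample_fraction: float = 0.8,
) -> PsiMatrix:
    """Harmonize per-sample event tables into a cohort PSI matrix.

    Events are keyed by their canonical coordinates; a cell is missing
    where the sample lacks the event (or it was filtered out upstream).
    Events measured in fewer than ``min_sample_fraction`` of samples are
    dropped, so downstream variance ranking is not driven by missingness.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one EventTable")
    sample_ids = [t.sample_id for t in tables]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among input tables")
    stypes = {t.splice_type for t in tables}
    if len(stypes) > 1:
        raise ValueError(f"mixed splice types in one matrix: {sorted(stypes)}")

    frames = []
    for t in tables:
        sub = t.df[["event_id", "psi", "support"]].copy()
        sub["sample_id"] = t.sample_id
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    if long.duplicated(["event_id", "sample_id"]).any():
        long = long.drop_duplicates(["event_id", "sample_id"], keep="first")

    values = long.pivot(index="event_id", columns="sample_id", values="psi")
    support = long.pivot(index="event_id", columns="sample_id", values="support")
    values = values.reindex(columns=sample_ids)
    support = support.reindex(columns=sample_ids).fillna(0.0)

    # event metadata: first-seen wins; differing gene ids on the same key
    # are annotation drift and get a logged warning
    meta_cols = [c for c in EVENT_COLUMNS if c not in ("ijc", "sjc", "psi", "support",
                                                       "inc_form_len", "skip_form_len")]
    meta = pd.concat([t.df[meta_cols] for t in tables], ignore_index=True)
    conflicts = meta.groupby("event_id")["gene_id"].nunique()
    n_conf = int((conflicts > 1).sum())
    if n_conf:
        logger.warning(
            "%d events had conflicting GeneIDs on identical coordinates; "
            "first-seen annotation kept", n_conf,
        )
    events = meta.drop_duplicates("event_id", keep="first").set_index("event_id")
    events = events.loc[values.index]

    completeness = values.notna().mean(axis=1)
    keep = completeness >= min_sample_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d events measured in < %.0f%% of samples",
            n_dropped, 100 * min_sample_fraction,
        )
    return PsiMatrix(values=values.loc[keep], support=support.loc[keep],
                     events=events.loc[keep])


CLINICAL_COLUMNS = {
    "sample_id": str,
    "histology": str,
    "molecular_subtype": str,
    "age_at_diagnosis": float,
    "resection": str,
    "os_days": float,
    "os_status": int,
    "efs_days": float,
    "efs_status": int,
}


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical TSV; ``tmb`` is optional, times must be >= 0."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise RmatsFormatError(f"clinical table missing columns: {missing}")
    for col, typ in CLINICAL_COLUMNS.items():
        df[col] = df[col].astype(typ)
    for col in ("os_days", "efs_days"):
        if (df[col] < 0).any():
            raise ValueError(f"negative survival time in {col}")
    for col in ("os_status", "efs_status"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            raise ValueError(f"{col} must be 0/1")
    if "tmb" in df.columns:
        df["tmb"] = df["tmb"].astype(float)
    return df
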