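"""Map cassette exons onto protein residues and UniProt-style features.

A skipped-exon event alters the protein wherever its exon overlaps a
transcript's CDS.  The exon's genomic interval (0-based half-open) is
projected through the transcript's CDS onto 1-based residue coordinates
(residue = floor(cds_offset / 3) + 1, strand-aware), then intersected
with feature residue intervals (closed, 1-based).  Event-level impact
follows the call direction: a feature hit on an included exon is a
functional-site *gain*, on a skipped exon a *loss*, and *mixed* when the
supporting samples disagreed on direction.

Impact is evaluated on the cassette exon's own residue span only;
frame-disrupting events (exon length not divisible by 3) are flagged via
``frame_preserving`` but their downstream consequences are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = (
    "domain", "disulfide_bond", "modified_residue", "localization_signal", "other",
)

#: Normalization of UniProt feature-type keys into the four reported
#: categories plus "other".  Keys are matched case-insensitively.
FEATURE_TYPE_MAP: Mapping[str, str] = {
    "domain": "domain",
    "dna_bind": "domain",
    "zn_fing": "domain",
    "repeat": "domain",
    "motif": "domain",
    "region": "domain",
    "active_site": "domain",
    "binding": "domain",
    "disulfid": "disulfide_bond",
    "disulfide_bond": "disulfide_bond",
    "mod_res": "modified_residue",
    "modified_residue": "modified_residue",
    "lipid": "modified_residue",
    "carbohyd": "modified_residue",
    "crosslnk": "modified_residue",
    "signal": "localization_signal",
    "transit": "localization_signal",
    "localization_signal": "localization_signal",
    "transmem": "localization_signal",
}


def normalize_feature_type(raw: str) -> str:
    return FEATURE_TYPE_MAP.get(str(raw).strip().lower(), "other")


@dataclass
class TranscriptModel:
    """A transcript's exon/CDS structure in 0-based half-open coordinates."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]       # genomic order (ascending)
    cds: list[tuple[int, int]]         # genomic order (ascending)
    protein_id: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def is_valid(self) -> bool:
        return not self.flags

    def validate(self) -> None:
        """Flag structural problems instead of dropping the model."""
        exon_union = sorted(self.exons)
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in exon_union):
                self.flags.append("cds_outside_exons")
                break
        if self.cds and self.cds_length % 3 != 0:
            self.flags.append("cds_length_not_multiple_of_3")

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


def load_transcript_models(gtf_path) -> list[TranscriptModel]:
    """Parse a GTF (1-based inclusive) into transcript models.

    Coordinates convert to 0-based half-open via (start-1, end).  Invalid
    models are flagged, not silently dropped.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons, cds = [], []
        protein_id = ""
        for ex in db.children(tx, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))
        for c in db.children(tx, featuretype="CDS", order_by="start"):
            cds.append((c.start - 1, c.end))
            if "protein_id" in c.attributes:
                protein_id = c.attributes["protein_id"][0]
        model = TranscriptModel(
            transcript_id=tx.id,
            gene_id=tx.attributes.get("gene_id", [""])[0],
            gene_symbol=tx.attributes.get("gene_name", [tx.attributes.get("gene_id", [""])[0]])[0],
            chrom=tx.seqid,
            strand=tx.strand,
            exons=sorted(exons),
            cds=sorted(cds),
            protein_id=protein_id or tx.attributes.get("protein_id", [""])[0],
        )
        model.validate()
        if not model.is_valid:
            logger.warning("transcript %s flagged: %s", model.transcript_id, model.flags)
        models.append(model)
    return models


def genomic_to_protein(
    tm: TranscriptModel, interval: tuple[int, int]
) -> tuple[int, int] | None:
    """Project a genomic interval onto 1-based residue coordinates.

    Returns the (first_res, last_res) span of CDS bases covered by the
    interval, or None when the interval misses the CDS entirely (pure
    UTR/intron).  Offsets run 5'→3' in transcript orientation.
    """
    start, end = interval
    if start >= end:
        raise ValueError("empty interval")
    cds = tm.cds
    if not cds:
        return None
    # transcript-orientation walk over CDS blocks, tracking the cds offset
    blocks = cds if tm.strand == "+" else list(reversed(cds))
    offset = 0
    first = last = None
    for bs, be in blocks:
        blen = be - bs
        ov_s, ov_e = max(bs, start), min(be, end)
        if ov_s < ov_e:
            if tm.strand == "+":
                o1 = offset + (ov_s - bs)
                o2 = offset + (ov_e - 1 - bs)
            else:
                o1 = offset + (be - ov_e)
                o2 = offset + (be - 1 - ov_s)
            lo, hi = min(o1, o2), max(o1, o2)
            first = lo if first is None else min(first, lo)
            last = hi if last is None else max(last, hi)
        offset += blen
    if first is None:
        return None
    return (first // 3 + 1, last // 3 + 1)


def read_protein_features(path) -> pd.DataFrame:
    """Feature TSV: protein_id, feature_type, start_res, end_res, description."""
    df = pd.read_csv(path, sep="\t")
    required = ["protein_id", "feature_type", "start_res", "end_res"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    df["start_res"] = df["start_res"].astype(int)
    df["end_res"] = df["end_res"].astype(int)
    if (df["start_res"] < 1).any() or (df["start_res"] > df["end_res"]).any():
        raise ValueError("feature residue intervals must satisfy 1 <= start <= end")
    df["category"] = df["feature_type"].map(normalize_feature_type)
    if "description" not in df.columns:
        df["description"] = ""
    return df


def annotate_events(
    events: pd.DataFrame,
    models: Iterable[TranscriptModel],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate recurrent SE events with residue spans and feature hits.

    ``events`` needs columns event_id, gene_id, chrom, strand, exon_start,
    exon_end, direction.  Every transcript of the gene whose CDS overlaps
    the exon is evaluated; one output row per event x transcript, plus a
    transcript-less row (impact ``none``) when nothing maps.  The
    event-level "functional" verdict is the union over transcripts.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in models:
        by_gene.setdefault(tm.gene_id, []).append(tm)
    feats_by_protein = dict(tuple(features.groupby("protein_id")))

    rows = []
    for ev in events.itertuples(index=False):
        exon = (int(ev.exon_start), int(ev.exon_end))
        frame_preserving = (exon[1] - exon[0]) % 3 == 0
        gene_models = sorted(
            by_gene.get(ev.gene_id, []), key=lambda t: t.transcript_id
        )
        mapped_any = False
        for tm in gene_models:
            if tm.chrom != ev.chrom:
                continue
            span = genomic_to_protein(tm, exon)
            if span is None:
                continue
            mapped_any = True
            hits = []
            pf = feats_by_protein.get(tm.protein_id)
            if pf is not None:
                for f in pf.itertuples(index=False):
                    lo = max(span[0], f.start_res)
                    hi = min(span[1], f.end_res)
                    if lo <= hi:
                        hits.append((f.feature_type, f.category, hi - lo + 1,
                                     getattr(f, "description", "")))
            if ev.direction == "mixed":
                impact = "mixed" if hits else "none"
            elif ev.direction == "inclusion_gain":
                impact = "gain" if hits else "none"
            else:
                impact = "loss" if hits else "none"
            cat_counts = {c: 0 for c in FEATURE_CATEGORIES}
            for _, cat, _, _ in hits:
                cat_counts[cat] += 1
            rows.append({
                "event_id": ev.event_id, "gene_id": ev.gene_id,
                "gene_symbol": getattr(ev, "gene_symbol", ev.gene_id),
                "direction": ev.direction, "transcript_id": tm.transcript_id,
                "protein_id": tm.protein_id,
                "residue_first": span[0], "residue_last": span[1],
                "frame_preserving": frame_preserving,
                "n_hits": len(hits), "impact": impact,
                "hit_features": ";".join(h[0] for h in hits),
                **{f"n_{c}": cat_counts[c] for c in FEATURE_CATEGORIES},
            })
        if not mapped_any:
            rows.append({
                "event_id": ev.event_id, "gene_id": ev.gene_id,
                "gene_symbol": getattr(ev, "gene_symbol", ev.gene_id),
                "direction": ev.direction, "transcript_id": "",
                "protein_id": "", "residue_first": np.nan, "residue_last": np.nan,
                "frame_preserving": frame_preserving,
                "n_hits": 0, "impact": "none", "hit_features": "",
                **{f"n_{c}": 0 for c in FEATURE_CATEGORIES},
            })
            if ev.gene_id not in by_gene:
                logger.info("event %s: gene %s has no transcript model",
                            ev.event_id, ev.gene_id)
    return pd.DataFrame(rows)


def summarize_functional(annotations: pd.DataFrame) -> dict:
    """Event-level and event x transcript counts of functional hits."""
    per_event = annotations.groupby("event_id").agg(
        n_hits=("n_hits", "sum"),
        impact=("impact", lambda s: next((x for x in s if x != "none"), "none")),
    )
    functional = per_event[per_event["n_hits"] > 0]
    cats = {
        c: int(annotations[f"n_{c}"].sum()) for c in FEATURE_CATEGORIES
    }
    return {
        "n_events": int(per_event.shape[0]),
        "n_functional_events": int(functional.shape[0]),
        "n_event_transcript_hits": int((annotations["n_hits"] > 0).sum()),
        "category_counts": cats,
    }


def filter_kinases(
    annotations: pd.DataFrame,
    kinase_genes: Sequence[str],
    splicing_regulator_kinases: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict annotations to kinases, then to splicing-regulator kinases."""
    kinase_genes = set(kinase_genes)
    if not kinase_genes:
        raise ValueError("empty kinase gene list")
    kin = annotations[annotations["gene_symbol"].isin(kinase_genes)].copy()
    if splicing_regulator_kinases is None:
        return kin, kin.iloc[0:0].copy()
    reg = set(splicing_regulator_kinases)
    return kin, kin[kin["gene_symbol"].isin(reg)].copy()


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    return genes
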