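"""Synthetic rMATS-like cohorts, paired designs, and toy annotations.

The generator emulates the statistical structure of a single-sample
splicing cohort with known ground truth, so every pipeline stage can be
verified against planted parameters:

- per-event baseline PSI centers drawn from Beta(5, 5) (polymorphic,
  mid-range events — mirroring the upstream selection of variable
  cassette exons); one center per cluster per event;
- per-sample PSI = Gaussian noise (sd ``within_cluster_sd``) around the
  sample's cluster center, clipped to [0, 1];
- each sample carries an *aberrant fraction* f_i: that fraction of its
  events is shifted by ``aberrant_shift`` standard deviations in a random
  direction (the quantity the Splicing Burden Index should recover);
- junction counts are back-computed from the drawn PSI at a fixed read
  depth with the SE form lengths (2, 1), so the length-normalized PSI
  recomputed from counts matches the drawn value to ~1/depth;
- histology labels are sampled conditionally on the true cluster through
  a configurable confusion probability;
- survival times follow an exponential proportional-hazards model with
  log-HR coefficients on cluster membership and f_i, with independent
  exponential censoring calibrated to the requested censoring fraction;
- gene TPM for designated "splicing factor" genes is linearly coupled to
  f_i (expression-burden correlation truth); other genes are noise.

A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rmats_io import EventTable, event_ids, write_rmats_table

SE_INC_FORM_LEN = 2
SE_SKIP_FORM_LEN = 1


def psi_to_counts(psi: np.ndarray, depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic junction counts reproducing ``psi`` at a given depth.

    With form lengths (2, 1): psi = (i/2) / (i/2 + s) and i + s = depth
    solve to i = 2*depth*psi / (1 + psi); i is rounded, s = depth - i.
    """
    i = np.rint(2 * depth * psi / (1 + psi)).astype(int)
    s = depth - i
    return i, s


def counts_to_psi(ijc: np.ndarray, sjc: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = ijc / SE_INC_FORM_LEN
        return np.where(ijc + sjc > 0, inc / (inc + sjc), np.nan)


@dataclass
class CohortSpec:
    """Parameters of a simulated splicing cohort."""

    n_samples: int = 100
    n_events: int = 1000
    splice_type: str = "SE"
    n_clusters: int = 1
    within_cluster_sd: float = 0.05
    center_beta: tuple[float, float] = (5.0, 5.0)
    #: per-sample aberrant fraction; scalar, or array-like of length
    #: n_samples, or list of values cycled over samples
    aberrant_fraction: float | list = 0.0
    aberrant_shift: float = 3.0
    depth: int = 100
    #: probability a sample's histology label matches its true cluster
    histology_fidelity: float = 0.9
    n_genes: int = 50
    #: genes whose TPM is coupled to f_i: tpm = a + b * f_i + noise
    n_coupled_genes: int = 5
    expr_intercept: float = 10.0
    expr_slope: float = 100.0
    expr_noise_sd: float = 1.0
    #: log hazard ratios per cluster (length n_clusters, first is baseline)
    cluster_log_hr: list = field(default_factory=list)
    f_log_hr: float = 0.0
    baseline_hazard: float = 1.0 / 365.0
    censoring_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.aberrant_fraction) > 1) or \
                np.any(np.asarray(self.aberrant_fraction) < 0):
            raise ValueError("aberrant_fraction must lie in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")

    def fractions(self) -> np.ndarray:
        f = np.asarray(self.aberrant_fraction, dtype=float)
        if f.ndim == 0:
            return np.full(self.n_samples, float(f))
        if len(f) == self.n_samples:
            return f
        return np.resize(f, self.n_samples)


@dataclass
class GroundTruth:
    cluster: np.ndarray            # true cluster per sample (1..k)
    aberrant_fraction: np.ndarray  # true f_i
    aberrant_events: list          # per sample, indices of shifted events
    centers: np.ndarray            # clusters x events baseline PSI
    drawn_psi: np.ndarray          # events x samples PSI before count rounding
    coupled_genes: list            # gene names coupled to f_i
    cluster_log_hr: np.ndarray
    f_log_hr: float


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    tables: list          # one EventTable per sample
    clinical: pd.DataFrame
    gene_tpm: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir) -> dict:
        """Write rMATS JC files, clinical and TPM TSVs; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"rmats": []}
        for t in self.tables:
            p = out / f"{t.sample_id}.{t.splice_type}.MATS.JC.txt"
            write_rmats_table(t, p)
            paths["rmats"].append(str(p))
        cp = out / "clinical.tsv"
        self.clinical.to_csv(cp, sep="\t", index=False)
        paths["clinical"] = str(cp)
        tp = out / "gene_tpm.tsv"
        self.gene_tpm.rename_axis("gene").to_csv(tp, sep="\t")
        paths["gene_tpm"] = str(tp)
        return paths


def _event_coordinates(rng: np.random.Generator, n_events: int) -> pd.DataFrame:
    """Distinct toy SE coordinates on a handful of chromosomes."""
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n_events)])
    strands = np.where(rng.random(n_events) < 0.5, "+", "-")
    anchor = rng.integers(10_000, 10_000_000, size=n_events)
    # spread anchors so canonical keys cannot collide
    anchor = anchor + np.arange(n_events) * 50_000
    exon_len = rng.integers(30, 300, size=n_events)
    up_len = rng.integers(50, 200, size=n_events)
    down_len = rng.integers(50, 200, size=n_events)
    up_gap = rng.integers(100, 5000, size=n_events)
    down_gap = rng.integers(100, 5000, size=n_events)
    exon_start = anchor
    exon_end = exon_start + exon_len
    upstream_end = exon_start - up_gap
    upstream_start = upstream_end - up_len
    downstream_start = exon_end + down_gap
    downstream_end = downstream_start + down_len
    return pd.DataFrame({
        "splice_type": "SE",
        "gene_id": [f"GENE{i % max(n_events // 3, 1):05d}" for i in range(n_events)],
        "gene_symbol": [f"G{i % max(n_events // 3, 1):05d}" for i in range(n_events)],
        "chrom": chroms, "strand": strands,
        "exon_start": exon_start, "exon_end": exon_end,
        "upstream_start": upstream_start, "upstream_end": upstream_end,
        "downstream_start": downstream_start, "downstream_end": downstream_end,
    })


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a cohort with planted clusters, burden, expression and survival."""
    rng = np.random.default_rng(spec.seed)
    n, e, k = spec.n_samples, spec.n_events, spec.n_clusters

    coords = _event_coordinates(rng, e)
    a, b = spec.center_beta
    centers = rng.beta(a, b, size=(k, e))
    cluster = rng.integers(1, k + 1, size=n)
    f = spec.fractions()

    psi = centers[cluster - 1, :].T  # events x samples
    psi = psi + rng.normal(0.0, spec.within_cluster_sd, size=(e, n))

    aberrant_events: list[np.ndarray] = []
    for j in range(n):
        n_ab = int(round(f[j] * e))
        idx = rng.choice(e, size=n_ab, replace=False) if n_ab else np.array([], int)
        if n_ab:
            signs = rng.choice([-1.0, 1.0], size=n_ab)
            psi[idx, j] += signs * spec.aberrant_shift * spec.within_cluster_sd
        aberrant_events.append(np.sort(idx))
    psi = np.clip(psi, 0.0, 1.0)

    ijc, sjc = psi_to_counts(psi, spec.depth)
    psi_obs = counts_to_psi(ijc, sjc)

    base_meta = coords.copy()
    base_meta.insert(0, "event_id", event_ids(coords))
    tables = []
    for j in range(n):
        df = base_meta.copy()
        df["ijc"] = ijc[:, j]
        df["sjc"] = sjc[:, j]
        df["inc_form_len"] = SE_INC_FORM_LEN
        df["skip_form_len"] = SE_SKIP_FORM_LEN
        df["psi"] = psi_obs[:, j]
        df["support"] = df["ijc"] + df["sjc"]
        tables.append(EventTable(sample_id=f"S{j:04d}", splice_type="SE", df=df))

    # histology labels: match the true cluster with given fidelity
    histologies = np.array([f"hist{c}" for c in cluster])
    flip = rng.random(n) >= spec.histology_fidelity
    if k > 1:
        wrong = ((cluster - 1 + rng.integers(1, k, size=n)) % k) + 1
        histologies = np.where(flip, [f"hist{c}" for c in wrong], histologies)

    # survival under exponential PH
    log_hr_cluster = np.asarray(
        spec.cluster_log_hr if spec.cluster_log_hr else np.zeros(k), dtype=float
    )
    if len(log_hr_cluster) != k:
        raise ValueError("cluster_log_hr must have one entry per cluster")
    lp = log_hr_cluster[cluster - 1] + spec.f_log_hr * f
    rate = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_fraction > 0:
        c_rate = spec.baseline_hazard * spec.censoring_fraction / \
            max(1 - spec.censoring_fraction, 1e-9)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame({
        "sample_id": [t.sample_id for t in tables],
        "histology": histologies,
        "molecular_subtype": [f"subtype{c}" for c in cluster],
        "age_at_diagnosis": np.round(rng.uniform(0.5, 18.0, size=n), 2),
        "resection": rng.choice(["gross_total", "partial", "biopsy"], size=n),
        "os_days": np.round(time, 1),
        "os_status": status,
        "efs_days": np.round(time * rng.uniform(0.5, 1.0, size=n), 1),
        "efs_status": status,
        "tmb": np.round(rng.lognormal(0.0, 1.0, size=n), 3),
    })

    genes = [f"SF{i:03d}" for i in range(spec.n_coupled_genes)] + [
        f"BG{i:03d}" for i in range(spec.n_genes - spec.n_coupled_genes)
    ]
    tpm = np.empty((spec.n_genes, n))
    for gi in range(spec.n_genes):
        coupled = gi < spec.n_coupled_genes
        mean = spec.expr_intercept + (spec.expr_slope * f if coupled else 0.0)
        tpm[gi] = np.maximum(mean + rng.normal(0, spec.expr_noise_sd, size=n), 0.0)
    gene_tpm = pd.DataFrame(np.round(tpm, 4), index=genes,
                            columns=[t.sample_id for t in tables])

    truth = GroundTruth(
        cluster=cluster, aberrant_fraction=f, aberrant_events=aberrant_events,
        centers=centers, drawn_psi=psi, coupled_genes=genes[: spec.n_coupled_genes],
        cluster_log_hr=log_hr_cluster, f_log_hr=spec.f_log_hr,
    )
    return SimulatedCohort(spec=spec, tables=tables, clinical=clinical,
                           gene_tpm=gene_tpm, truth=truth)


def simulate_perturbation(
    n_events: int = 200,
    n_ds: int = 20,
    true_dpsi: float = 0.4,
    reps_per_arm: int = 3,
    depth: int = 100,
    within_sd: float = 0.02,
    seed: int = 0,
):
    """Paired replicate design with ``n_ds`` planted ΔPSI events.

    Returns (PairedDesign, truth DataFrame).  Arm-B PSI of planted events
    is shifted by ``true_dpsi`` (clipped to [0, 1] with a warning).
    """
    from .perturbation_compare import PairedDesign

    if n_ds > n_events:
        raise ValueError("n_ds cannot exceed n_events")
    rng = np.random.default_rng(seed)
    coords = _event_coordinates(rng, n_events)
    base = rng.beta(5, 5, size=n_events)
    ds_idx = rng.choice(n_events, size=n_ds, replace=False) if n_ds else np.array([], int)
    shift = np.zeros(n_events)
    shift[ds_idx] = true_dpsi
    target_b = base + shift
    if np.any(target_b < 0) or np.any(target_b > 1):
        import warnings

        warnings.warn("planted ΔPSI pushes PSI outside [0, 1]; clipped")
        target_b = np.clip(target_b, 0.0, 1.0)

    base_meta = coords.copy()
    base_meta.insert(0, "event_id", event_ids(coords))

    def _arm(center: np.ndarray, prefix: str) -> list[EventTable]:
        tables = []
        for r in range(reps_per_arm):
            drawn = np.clip(center + rng.normal(0, within_sd, n_events), 0, 1)
            ijc, sjc = psi_to_counts(drawn, depth)
            df = base_meta.copy()
            df["ijc"], df["sjc"] = ijc, sjc
            df["inc_form_len"] = SE_INC_FORM_LEN
            df["skip_form_len"] = SE_SKIP_FORM_LEN
            df["psi"] = counts_to_psi(ijc, sjc)
            df["support"] = df["ijc"] + df["sjc"]
            tables.append(EventTable(sample_id=f"{prefix}{r + 1}",
                                     splice_type="SE", df=df))
        return tables

    design = PairedDesign(condition_a=_arm(base, "ctrl"),
                          condition_b=_arm(target_b, "trt"))
    truth = pd.DataFrame({
        "event_id": base_meta["event_id"],
        "true_dpsi": target_b - base,
        "is_ds": np.isin(np.arange(n_events), ds_idx),
    })
    return design, truth


# ---------------------------------------------------------------------------
# toy transcript/feature annotation fixtures with per-base ground truth


def residue_of_base(exons_tx_order, strand, cds_intervals) -> dict:
    """Per-base oracle: map every genomic CDS base to its 1-based residue.

    Walks the CDS base by base in transcript orientation, assigning
    residue floor(offset / 3) + 1.  Used by the generator to record exact
    expected overlaps, independently of the interval arithmetic in
    :mod:`spliceburden.functional_impact`.
    """
    blocks = sorted(cds_intervals)
    if strand == "-":
        blocks = list(reversed(blocks))
    mapping = {}
    offset = 0
    for bs, be in blocks:
        positions = range(bs, be) if strand == "+" else range(be - 1, bs - 1, -1)
        for pos in positions:
            mapping[pos] = offset // 3 + 1
            offset += 1
    return mapping


def simulate_annotation(n_transcripts: int = 20, seed: int = 0,
                        features_per_protein: int = 3):
    """Toy GTF text, feature table, SE events, and exact expected truth.

    Each transcript has 3-7 exons on a random strand with a CDS covering
    an internal stretch; features sit at known residues.  For every
    internal exon an SE event is emitted along with the expected residue
    span and feature hits computed by the per-base oracle.
    """
    rng = np.random.default_rng(seed)
    gtf_lines = []
    feature_rows = []
    events = []
    expected = []
    for t in range(n_transcripts):
        chrom = f"chr{rng.integers(1, 23)}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"TGENE{t:04d}"
        tx_id = f"TX{t:04d}"
        protein_id = f"PROT{t:04d}"
        n_exons = int(rng.integers(3, 8))
        pos = int(rng.integers(1_000, 1_000_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(30, 200))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 2000))
        # CDS: from inside the first exon to inside the last, trimmed to
        # a multiple of 3 by moving the end
        cds_start = exons[0][0] + int(rng.integers(0, exons[0][1] - exons[0][0] - 3))
        cds_end_max = exons[-1][1]
        cds_end_min = exons[-1][0] + 3
        cds_end = int(rng.integers(cds_end_min, cds_end_max))
        cds = []
        for s, e in exons:
            cs, ce = max(s, cds_start), min(e, cds_end)
            if cs < ce:
                cds.append((cs, ce))
        total = sum(e - s for s, e in cds)
        trim = total % 3
        if trim:
            # shrink the 3'-most CDS block
            if strand == "+":
                s, e = cds[-1]
                cds[-1] = (s, e - trim)
            else:
                s, e = cds[0]
                cds[0] = (s + trim, e)
        n_res = sum(e - s for s, e in cds) // 3

        base2res = residue_of_base(exons, strand, cds)

        gtf_lines.append(
            f"{chrom}\ttoy\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t"
            f'{strand}\t.\tgene_id "{gene_id}"; transcript_id "{tx_id}"; '
            f'gene_name "{gene_id}";'
        )
        for s, e in exons:
            gtf_lines.append(
                f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            )
        for s, e in cds:
            gtf_lines.append(
                f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                f'protein_id "{protein_id}";'
            )

        ftypes = ["DOMAIN", "DISULFID", "MOD_RES", "SIGNAL", "UNKNOWN_KIND"]
        tx_features = []
        for fi in range(features_per_protein):
            if n_res < 2:
                break
            fs = int(rng.integers(1, n_res))
            fe = min(n_res, fs + int(rng.integers(0, max(n_res // 3, 1))))
            ftype = ftypes[int(rng.integers(0, len(ftypes)))]
            feature_rows.append({
                "protein_id": protein_id, "feature_type": ftype,
                "start_res": fs, "end_res": fe,
                "description": f"feat{t}_{fi}",
            })
            tx_features.append((ftype, fs, fe))

        # SE events on internal exons, alternating direction
        for xi in range(1, n_exons - 1):
            s, e = exons[xi]
            direction = ["inclusion_gain", "skipping", "mixed"][xi % 3]
            eid = f"SE:{chrom}:{strand}:{s}-{e}:{exons[xi - 1][1]}:{exons[xi + 1][0]}"
            events.append({
                "event_id": eid, "gene_id": gene_id, "gene_symbol": gene_id,
                "chrom": chrom, "strand": strand,
                "exon_start": s, "exon_end": e, "direction": direction,
            })
            residues = sorted({base2res[p] for p in range(s, e) if p in base2res})
            if residues:
                span = (residues[0], residues[-1])
                hits = [
                    (ft, fs, fe) for ft, fs, fe in tx_features
                    if max(span[0], fs) <= min(span[1], fe)
                ]
            else:
                span, hits = None, []
            if hits:
                impact = {"inclusion_gain": "gain", "skipping": "loss",
                          "mixed": "mixed"}[direction]
            else:
                impact = "none"
            expected.append({
                "event_id": eid, "transcript_id": tx_id,
                "residue_first": span[0] if span else np.nan,
                "residue_last": span[1] if span else np.nan,
                "n_hits": len(hits), "impact": impact,
                "frame_preserving": (e - s) % 3 == 0,
            })

    gtf_text = "\n".join(gtf_lines) + "\n"
    features = pd.DataFrame(feature_rows)
    events = pd.DataFrame(events)
    expected = pd.DataFrame(expected)
    return gtf_text, features, events, expected
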