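"""Genomic-to-protein mapping and functional-site overlap classification."""

import numpy as np
import pandas as pd
import pytest

from spliceburden.functional_impact import (
    TranscriptModel,
    annotate_events,
    filter_kinases,
    genomic_to_protein,
    load_transcript_models,
    normalize_feature_type,
    read_protein_features,
)
from spliceburden.synthetic import residue_of_base


def _model(strand="+", exons=((100, 200), (300, 400)), cds=((100, 200), (300, 400))):
    m = TranscriptModel(
        transcript_id="tx", gene_id="g", gene_symbol="G", chrom="chr1",
        strand=strand, exons=[tuple(e) for e in exons],
        cds=[tuple(c) for c in cds], protein_id="p",
    )
    m.validate()
    return m


class TestGtfLoading:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        gtf = "\n".join([
            'chr1\tx\ttranscript\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tx\tCDS\t101\t200\t.\t+\t0\tgene_id "g"; transcript_id "t"; protein_id "p";',
            'chr1\tx\tCDS\t301\t351\t.\t+\t0\tgene_id "g"; transcript_id "t"; protein_id "p";',
        ]) + "\n"
        path = tmp_path / "t.gtf"
        path.write_text(gtf)
        (model,) = load_transcript_models(path)
        assert model.exons == [(100, 200), (300, 400)]
        assert model.cds == [(100, 200), (300, 351)]
        assert model.protein_id == "p"

    def test_negative_strand_transcript_order_reversed(self):
        m = _model(strand="-")
        assert m.exons_in_transcript_order() == [(300, 400), (100, 200)]

    def test_cds_not_multiple_of_three_flagged(self):
        m = _model(cds=((100, 200), (300, 301)))  # 101 nt
        assert "cds_length_not_multiple_of_3" in m.flags

    def test_cds_outside_exons_flagged(self):
        m = _model(cds=((100, 250),))
        assert "cds_outside_exons" in m.flags


class TestGenomicToProtein:
    def test_thirty_nt_exon_spans_ten_residues(self):
        m = _model(exons=((100, 130),), cds=((100, 130),))
        assert genomic_to_protein(m, (100, 130)) == (1, 10)

    def test_utr_only_interval_maps_to_none(self):
        m = _model(exons=((50, 100), (100, 130)), cds=((100, 130),))
        assert genomic_to_protein(m, (50, 100)) is None

    def test_negative_strand_offsets(self):
        # on '-' the CDS 3' end is the genomic start: last codon is leftmost
        m = _model(strand="-", exons=((100, 130),), cds=((100, 130),))
        assert genomic_to_protein(m, (127, 130)) == (1, 1)
        assert genomic_to_protein(m, (100, 103)) == (10, 10)

    def test_matches_per_base_oracle_on_random_models(self):
        """Interval arithmetic equals the per-base residue walk exactly."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n_exons = int(rng.integers(1, 5))
            pos = int(rng.integers(0, 1000))
            exons = []
            for _ in range(n_exons):
                length = int(rng.integers(6, 60))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(10, 100))
            total = sum(e - s for s, e in exons)
            trim = total % 3
            exons[-1] = (exons[-1][0], exons[-1][1] - trim)
            strand = "+" if rng.random() < 0.5 else "-"
            m = _model(strand=strand, exons=exons, cds=exons)
            base2res = residue_of_base(exons, strand, exons)
            lo = exons[0][0] - 20
            hi = exons[-1][1] + 20
            for _ in range(20):
                s = int(rng.integers(lo, hi - 1))
                e = int(rng.integers(s + 1, hi + 1))
                res = sorted({base2res[p] for p in range(s, e) if p in base2res})
                expected = (res[0], res[-1]) if res else None
                assert genomic_to_protein(m, (s, e)) == expected

    def test_span_bounded_by_cds_length(self):
        m = _model(exons=((100, 160),), cds=((100, 160),))
        span = genomic_to_protein(m, (0, 10_000))
        assert span == (1, m.cds_length // 3)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            genomic_to_protein(_model(), (100, 100))


class TestAnnotateEvents:
    def _event(self, direction, exon=(300, 330), gene="g"):
        return pd.DataFrame([{
            "event_id": "ev1", "gene_id": gene, "gene_symbol": "G",
            "chrom": "chr1", "strand": "+",
            "exon_start": exon[0], "exon_end": exon[1], "direction": direction,
        }])

    def _feats(self, ftype="DOMAIN", start=30, end=40):
        df = pd.DataFrame([{
            "protein_id": "p", "feature_type": ftype,
            "start_res": start, "end_res": end, "description": "d",
        }])
        df["category"] = df["feature_type"].map(normalize_feature_type)
        return df

    def test_skipping_inside_domain_is_loss(self):
        # exon (300,330) is CDS offset 100..129 -> residues 34..44
        m = _model(exons=((100, 200), (300, 400)), cds=((100, 200), (300, 400)))
        ann = annotate_events(self._event("skipping"), [m], self._feats(start=30, end=50))
        assert ann.iloc[0]["impact"] == "loss"
        assert ann.iloc[0]["n_hits"] == 1
        assert ann.iloc[0]["n_domain"] == 1

    def test_inclusion_on_utr_exon_is_none(self):
        m = _model(exons=((50, 90), (100, 200)), cds=((100, 200),))
        ann = annotate_events(self._event("inclusion_gain", exon=(50, 90)), [m],
                              self._feats())
        assert ann.iloc[0]["impact"] == "none"
        assert np.isnan(ann.iloc[0]["residue_first"])

    def test_single_residue_feature_hit(self):
        m = _model(exons=((100, 200),), cds=((100, 200),))
        # exon residues ~ (1, 34); disulfide at residue 10 overlaps by 1
        ann = annotate_events(
            self._event("skipping", exon=(100, 200)), [m],
            self._feats(ftype="DISULFID", start=10, end=10),
        )
        assert ann.iloc[0]["n_hits"] == 1
        assert ann.iloc[0]["n_disulfide_bond"] == 1

    def test_mixed_direction_propagates(self):
        m = _model(exons=((100, 200),), cds=((100, 200),))
        ann = annotate_events(self._event("mixed", exon=(100, 200)), [m],
                              self._feats(start=1, end=5))
        assert ann.iloc[0]["impact"] == "mixed"

    def test_frame_preservation_flag(self):
        m = _model(exons=((100, 200),), cds=((100, 200),))
        ann30 = annotate_events(self._event("skipping", exon=(100, 130)), [m],
                                self._feats())
        ann31 = annotate_events(self._event("skipping", exon=(100, 131)), [m],
                                self._feats())
        assert bool(ann30.iloc[0]["frame_preserving"])
        assert not bool(ann31.iloc[0]["frame_preserving"])

    def test_gene_without_model_gets_none(self):
        m = _model(exons=((100, 200),), cds=((100, 200),))
        ann = annotate_events(self._event("skipping", gene="other"), [m],
                              self._feats())
        assert ann.iloc[0]["impact"] == "none"
        assert ann.iloc[0]["transcript_id"] == ""

    def test_generator_truth_recovered_exactly(self, annotation_fixture, toy_models):
        """Full annotation equals the per-base ground truth of the generator."""
        _, features, events, expected = annotation_fixture
        features = features.copy()
        features["category"] = features["feature_type"].map(normalize_feature_type)
        ann = annotate_events(events, toy_models, features)
        merged = ann.merge(expected, on="event_id", suffixes=("", "_exp"))
        assert len(merged) == len(expected)
        mapped = merged[merged["residue_first_exp"].notna()]
        assert (mapped["residue_first"] == mapped["residue_first_exp"]).all()
        assert (mapped["residue_last"] == mapped["residue_last_exp"]).all()
        assert (mapped["n_hits"] == mapped["n_hits_exp"]).all()
        assert (mapped["impact"] == mapped["impact_exp"]).all()
        unmapped = merged[merged["residue_first_exp"].isna()]
        assert (unmapped["impact"] == "none").all()
        assert (merged["frame_preserving"] == merged["frame_preserving_exp"]).all()


class TestFeatureNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("DOMAIN", "domain"), ("ZN_FING", "domain"),
        ("DISULFID", "disulfide_bond"), ("MOD_RES", "modified_residue"),
        ("SIGNAL", "localization_signal"), ("TRANSIT", "localization_signal"),
        ("SOMETHING_ELSE", "other"),
    ])
    def test_mapping_table(self, raw, expected):
        assert normalize_feature_type(raw) == expected

    def test_category_counts_sum_to_hits(self, annotation_fixture, toy_models):
        _, features, events, _ = annotation_fixture
        feats = features.copy()
        feats["category"] = feats["feature_type"].map(normalize_feature_type)
        ann = annotate_events(events, toy_models, feats)
        cat_cols = [c for c in ann.columns if c.startswith("n_") and c != "n_hits"]
        assert (ann[cat_cols].sum(axis=1) == ann["n_hits"]).all()


class TestKinaseFilter:
    def _ann(self):
        return pd.DataFrame({
            "gene_symbol": ["A", "B", "C"], "impact": ["loss", "gain", "loss"],
        })

    def test_only_listed_genes_retained(self):
        kin, _ = filter_kinases(self._ann(), ["B"])
        assert list(kin["gene_symbol"]) == ["B"]

    def test_disjoint_list_gives_empty(self):
        kin, _ = filter_kinases(self._ann(), ["Z"])
        assert len(kin) == 0

    def test_regulator_subset_nested(self):
        kin, reg = filter_kinases(self._ann(), ["A", "B"], ["B"])
        assert set(reg["gene_symbol"]) <= set(kin["gene_symbol"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            filter_kinases(self._ann(), [])
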