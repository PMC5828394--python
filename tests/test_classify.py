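"""Element curation: genomic classes, TSS filtering, DHS refinement."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernascope.classify import (
    ClassifierConfig,
    classify_element,
    classify_elements,
    filter_unannotated_tss,
    refine_enhancers,
)
from ernascope.io_formats import Element, Gene, GenomeAnnotation, ValidationError

from conftest import element


def brute_force_class(e, ann, cfg):
    """Independent all-pairs re-derivation of the classification rules."""
    genes = [g for g in ann.genes if g.chrom == e.chrom]
    if any(e.start <= g.tss < e.end for g in genes):
        return "promoter", False
    if any(e.start < g.end and e.end > g.start for g in genes):
        return "intragenic", False
    def dist(point):
        if point <= e.start:
            return e.start - point
        if point >= e.end:
            return point - e.end
        return 0
    for g in genes:
        p5 = g.start if g.strand == "+" else g.end
        p3 = g.end if g.strand == "+" else g.start
        if dist(p5) < cfg.min_dist_5prime or dist(p3) < cfg.min_dist_3prime:
            return "intergenic", True
    return "intergenic", False


class TestClassifyElement:
    def test_intergenic_distance_rules(self, simple_annotation):
        # + gene at 1000-5000: element 100-200 clears 800 bp to the 5' end
        # and 4800 bp to the 3' end
        ce = classify_element(element(100, 200), simple_annotation)
        assert ce.genomic_class == "intergenic" and not ce.tss_filtered

    def test_promoter_on_tss_overlap(self, simple_annotation):
        ce = classify_element(element(950, 1050), simple_annotation)
        assert ce.genomic_class == "promoter"

    def test_intragenic_inside_gene_body(self, simple_annotation):
        ce = classify_element(element(2000, 2100), simple_annotation)
        assert ce.genomic_class == "intragenic"

    def test_too_close_flagged_not_reclassified(self, simple_annotation):
        # 400 bp from the 5' end of gA: intergenic but filtered
        ce = classify_element(element(500, 600), simple_annotation)
        assert ce.genomic_class == "intergenic" and ce.tss_filtered

    def test_promoter_beats_intragenic_for_nested_tss(self):
        ann = GenomeAnnotation(genes=[
            Gene("outer", "c", 0, 10_000, "+"),
            Gene("inner", "c", 4000, 6000, "+"),
        ])
        ce = classify_element(element(3990, 4010, chrom="c"), ann)
        assert ce.genomic_class == "promoter"

    def test_unknown_chromosome_rejected(self, simple_annotation):
        with pytest.raises(ValidationError, match="chromosome"):
            classify_element(element(0, 10, chrom="chrU"), simple_annotation)

    def test_minus_strand_gene_ends(self):
        # - gene: 5' boundary at end, 3' at start
        ann = GenomeAnnotation(genes=[Gene("g", "c", 10_000, 14_000, "-")])
        # 600 bp beyond the 5' (right) end: clears 500 but that is the 5' rule
        ce = classify_element(element(14_600, 14_700, chrom="c"), ann)
        assert ce.genomic_class == "intergenic" and not ce.tss_filtered
        # 600 bp left of start violates the 1500 bp 3' clearance
        ce = classify_element(element(9300, 9400, chrom="c"), ann)
        assert ce.tss_filtered


@st.composite
def toy_instances(draw):
    n_genes = draw(st.integers(1, 12))
    genes = []
    for i in range(n_genes):
        start = draw(st.integers(0, 40_000))
        length = draw(st.integers(100, 4000))
        strand = draw(st.sampled_from("+-"))
        genes.append(Gene(f"g{i}", "c", start, start + length, strand))
    n_el = draw(st.integers(1, 12))
    elements = []
    for i in range(n_el):
        start = draw(st.integers(0, 45_000))
        width = draw(st.integers(10, 3000))
        elements.append(Element("c", start, start + width, id=f"e{i}"))
    return GenomeAnnotation(genes=genes), elements


class TestClassifierProperties:
    @given(toy_instances())
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_brute_force(self, instance):
        ann, elements = instance
        cfg = ClassifierConfig()
        for e in elements:
            ce = classify_element(e, ann, cfg)
            cls, flagged = brute_force_class(e, ann, cfg)
            assert (ce.genomic_class, ce.tss_filtered) == (cls, flagged)

    @given(toy_instances())
    @settings(max_examples=60, deadline=None)
    def test_partition_every_element_one_class(self, instance):
        ann, elements = instance
        for ce in classify_elements(elements, ann):
            assert ce.genomic_class in ("intergenic", "intragenic", "promoter")

    @given(toy_instances(), st.integers(0, 2000), st.integers(0, 2000))
    @settings(max_examples=60, deadline=None)
    def test_intergenic_count_monotone_in_5prime_clearance(
        self, instance, d_small, d_extra
    ):
        ann, elements = instance

        def n_clean_intergenic(d5):
            cfg = ClassifierConfig(min_dist_5prime=d5)
            return sum(
                ce.genomic_class == "intergenic" and not ce.tss_filtered
                for ce in classify_elements(elements, ann, cfg)
            )

        assert n_clean_intergenic(d_small + d_extra) <= n_clean_intergenic(d_small)


class TestFilterUnannotatedTss:
    def _classified(self, ann, *elements):
        return classify_elements(list(elements), ann)

    def test_near_lncrna_tss_removed(self, simple_annotation):
        simple_annotation.tss_sets["lncrna"] = [("chr2L", 450, "+")]
        # TSS at 450 < 200 + 500: inside the expanded interval
        kept = filter_unannotated_tss(
            self._classified(simple_annotation, element(100, 200)),
            simple_annotation,
        )
        assert kept == []

    def test_distant_tss_retained(self, simple_annotation):
        simple_annotation.tss_sets["lncrna"] = [("chr2L", 10_000, "+")]
        kept = filter_unannotated_tss(
            self._classified(simple_annotation, element(100, 200)),
            simple_annotation,
        )
        assert len(kept) == 1

    def test_empty_aux_sets_identity(self, simple_annotation):
        classified = self._classified(simple_annotation, element(100, 200))
        assert filter_unannotated_tss(classified, simple_annotation) == classified


class TestRefineEnhancers:
    def test_single_peak_replaces_enhancer(self):
        enh = element(0, 2000, id="E")
        peak = element(800, 1100, summit=900)
        (out,) = refine_enhancers([enh], [peak])
        assert (out.start, out.end, out.id, out.summit) == (800, 1100, "E", 900)

    def test_multi_and_zero_peak_enhancers_dropped(self):
        enh2 = element(0, 2000, id="E2")
        enh0 = element(50_000, 52_000, id="E0")
        peaks = [element(100, 300), element(900, 1100)]
        assert refine_enhancers([enh2, enh0], peaks) == []
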