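"""Architecture -> class decision tree, gene collapse, per-subgenome counts."""

from __future__ import annotations

import itertools

import pytest

from cherry_rga.classify import (
    CLASS_PRIORITY,
    COMPLETE_CLASSES,
    CountsTable,
    RGAClass as C,
    TranscriptClassification,
    classify_transcript,
    collapse_genes,
    completeness_percentage,
    count_by_class,
)
from cherry_rga.domains import CanonicalDomain as D
from cherry_rga.domains import TranscriptDomains
from cherry_rga.io.interproscan import Analysis, DomainHit


def td(domains, tid="t1"):
    ev = {
        d: (
            DomainHit(
                transcript_id=tid, analysis=Analysis.PFAM, signature_id="X", start=1, end=9
            ),
        )
        for d in domains
    }
    return TranscriptDomains(transcript_id=tid, domains=frozenset(domains), evidence=ev)


ARCHITECTURE_CASES = [
    ({D.TIR, D.NB, D.LRR}, C.TNL),
    ({D.CC, D.NB, D.LRR}, C.CNL),
    ({D.RPW8, D.NB, D.LRR}, C.RNL),
    ({D.NB, D.LRR}, C.PARTIAL),  # no N-terminal domain -> not complete
    ({D.TIR, D.NB}, C.PARTIAL),  # LRR required for completeness
    ({D.LRR, D.TM, D.KIN}, C.RLK),
    ({D.LRR, D.TM}, C.RLP),
    ({D.LRR, D.TM, D.SP}, C.RLP),  # SP never required, never decisive
    ({D.LYSM, D.TM}, C.LYSM),
    ({D.LYSM, D.TM, D.LRR, D.KIN}, C.LYSM),  # LysM precedence over RLK
    ({D.TIR, D.CC, D.NB, D.LRR}, C.TNL),  # N-terminal precedence TIR > CC
    ({D.RPW8, D.CC, D.NB, D.LRR}, C.RNL),  # RPW8 > CC
    ({D.TIR, D.RPW8, D.NB, D.LRR}, C.TNL),  # TIR > RPW8
    ({D.NB}, C.PARTIAL),
    ({D.LRR}, C.PARTIAL),
    ({D.KIN}, C.PARTIAL),
    ({D.LYSM}, C.PARTIAL),  # LysM without TM is not a receptor
    ({D.SP, D.TM}, C.PARTIAL),
]


@pytest.mark.parametrize("domains,expected", ARCHITECTURE_CASES, ids=str)
def test_decision_tree(domains, expected):
    tc = classify_transcript(td(domains))
    assert tc.rga_class is expected
    assert tc.complete == (expected in COMPLETE_CLASSES)


def test_empty_domain_set_is_an_error():
    with pytest.raises(ValueError):
        classify_transcript(
            TranscriptDomains(transcript_id="t1", domains=frozenset(), evidence={})
        )


def test_totality_and_determinism_over_all_511_subsets():
    """Every non-empty subset of the 9 canonical domains maps to exactly one
    class, twice in a row; NB-bearing subsets never map to receptor classes."""
    all_domains = list(D)
    assert len(all_domains) == 9
    seen = {}
    for r in range(1, 10):
        for combo in itertools.combinations(all_domains, r):
            first = classify_transcript(td(set(combo))).rga_class
            second = classify_transcript(td(set(combo))).rga_class
            assert first is second
            assert isinstance(first, C)
            seen[frozenset(combo)] = first
            if D.NB in combo:
                assert first in {C.TNL, C.CNL, C.RNL, C.PARTIAL}
            else:
                assert first in {C.RLK, C.RLP, C.LYSM, C.PARTIAL}
    assert len(seen) == 511


class TestGeneCollapse:
    def test_partial_variant_does_not_mask_complete(self):
        tcs = [
            classify_transcript(td({D.TIR, D.NB, D.LRR}, "g.1")),
            classify_transcript(td({D.NB}, "g.2")),
        ]
        assert collapse_genes(tcs) == {"g": C.TNL}

    def test_single_transcript_identity_collapse(self):
        tcs = [classify_transcript(td({D.LRR, D.TM, D.KIN}, "PCE_F_Chro4G0199100.1"))]
        assert collapse_genes(tcs) == {"PCE_F_Chro4G0199100": C.RLK}

    @pytest.mark.parametrize("a,b", list(itertools.combinations(CLASS_PRIORITY, 2)))
    def test_priority_order_brute_force(self, a, b):
        """For every class pair, the collapsed gene class is the one earlier
        in the priority order, independent of transcript order."""
        expected = min((a, b), key=CLASS_PRIORITY.index)
        tcs = [
            TranscriptClassification("g.1", a, a in COMPLETE_CLASSES, frozenset({D.NB})),
            TranscriptClassification("g.2", b, b in COMPLETE_CLASSES, frozenset({D.NB})),
        ]
        assert collapse_genes(tcs) == {"g": expected}
        assert collapse_genes(tcs[::-1]) == {"g": expected}


class TestCounts:
    def test_published_completeness_percentages(self):
        """The completeness shares implied by the printed transcript totals."""
        assert completeness_percentage(804, 19_570) == 4.1
        assert completeness_percentage(817, 19_142) == 4.3

    def test_counts_match_construction(self):
        tcs = []
        for i in range(5):
            tcs.append(classify_transcript(td({D.TIR, D.NB, D.LRR}, f"PCE_A_Chro1G{i:07d}.1")))
        for i in range(3):
            tcs.append(classify_transcript(td({D.LRR, D.TM}, f"PCE_A_Chro2G{i:07d}.1")))
        counts = count_by_class(collapse_genes(tcs), tcs)
        assert counts.gene_counts["A"][C.TNL] == 5
        assert counts.gene_counts["A"][C.RLP] == 3
        assert counts.n_any_domain["A"] == 8
        assert counts.n_complete["A"] == 8
        assert counts.pct_complete["A"] == 100.0

    def test_unknown_subgenome_counted_under_other(self):
        tcs = [classify_transcript(td({D.TIR, D.NB, D.LRR}, "weird_id.1"))]
        counts = count_by_class(collapse_genes(tcs), tcs)
        assert counts.gene_counts["OTHER"][C.TNL] == 1

    def test_complete_cannot_exceed_any_domain(self):
        with pytest.raises(ValueError):
            CountsTable(gene_counts={}, n_any_domain={"A": 5}, n_complete={"A": 6})

    def test_gene_count_bounded_by_transcript_count(self, small_dataset):
        from cherry_rga.domains import canonicalize

        tcs = [classify_transcript(x) for x in canonicalize(small_dataset.hits).values()]
        genes = collapse_genes(tcs)
        # a gene of class X needs at least one transcript of class X
        for cls in C:
            n_genes = sum(1 for v in genes.values() if v is cls)
            n_tx = sum(1 for t in tcs if t.rga_class is cls)
            assert n_genes <= n_tx or n_genes == 0
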