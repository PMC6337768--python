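"""Internal annotation: PBS/PPT search, domain hits, filter, TIR/MITE."""

import numpy as np
import pytest

from repeatscape.alignment import revcomp
from repeatscape.annotate import (
    AnnotatedElement,
    TirConfig,
    detect_tir_elements,
    filter_full_length,
    find_domains,
    find_pbs,
    find_ppt,
    flag_intact,
    PbsHit,
    PptHit,
    DomainHit,
)
from repeatscape.references import back_translate, default_library
from repeatscape.simulate import (
    build_tir_element,
    evolve_sequence,
    generate_background,
    plant_tir_element,
)


class TestFindPbs:
    def test_exact_match_at_offset_three(self, refs):
        trna = refs.trna["tRNA-iMet"]
        internal = "ACG" + revcomp(trna[-15:]) + generate_background(200, 0.4, seed=1)
        hit = find_pbs(internal, refs.trna)
        assert hit is not None
        assert (hit.offset_from_5ltr, hit.length, hit.mismatches) == (3, 15, 0)
        assert hit.trna_id == "tRNA-iMet"

    def test_too_many_mismatches_absent(self, refs):
        trna = refs.trna["tRNA-iMet"]
        probe = list(revcomp(trna[-15:]))
        probe[2] = "A" if probe[2] != "A" else "C"
        probe[7] = "A" if probe[7] != "A" else "C"
        internal = "ACG" + "".join(probe) + generate_background(200, 0.4, seed=2)
        assert find_pbs(internal, refs.trna, max_mismatch=1) is None

    def test_tie_broken_by_lexicographic_id(self):
        library = {"tRNA-B": "G" * 18, "tRNA-A": "G" * 18}
        internal = revcomp("G" * 18) + "ACGT" * 20
        hit = find_pbs(internal, library)
        assert hit.trna_id == "tRNA-A"
        assert hit.length == 18

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            find_pbs("ACGT" * 30, {})

    def test_reported_offsets_reproduce_hit_sequence(self, refs):
        trna = refs.trna["tRNA-Gly"]
        internal = "AC" + revcomp(trna[-17:]) + generate_background(150, 0.4, seed=4)
        hit = find_pbs(internal, refs.trna)
        sliced = internal[hit.offset_from_5ltr : hit.offset_from_5ltr + hit.length]
        assert sliced == revcomp(refs.trna[hit.trna_id][-hit.length:])


class TestFindPpt:
    def test_pure_purine_tract_adjacent_to_3ltr(self):
        internal = generate_background(200, 0.4, seed=5) + "GGGAAGGAGGGAAA" + "CT"
        hit = find_ppt(internal)
        assert hit is not None
        assert hit.purine_fraction == 1.0
        assert hit.length >= 14
        assert hit.offset_from_3ltr <= 30

    def test_weak_tract_absent_at_085_floor(self):
        # best window is 8/10 purines = 0.8
        internal = "CT" * 100 + "AAGGCAGACT" + "CT"
        assert find_ppt(internal) is None

    def test_long_run_capped_at_30(self):
        internal = "CT" * 100 + "A" * 35 + "C"
        hit = find_ppt(internal)
        assert hit.length == 30
        assert hit.purine_fraction == 1.0

    def test_reported_offsets_reproduce_hit_window(self):
        internal = generate_background(300, 0.4, seed=6) + "G" * 20 + "TC"
        hit = find_ppt(internal)
        end = len(internal) - hit.offset_from_3ltr
        window = internal[end - hit.length : end]
        purine_frac = sum(b in "AG" for b in window) / len(window)
        assert purine_frac == pytest.approx(hit.purine_fraction)


class TestFindDomains:
    def test_planted_rt_recovered_with_lineage(self, refs, rng):
        pep = refs.rt_for("Copia", "Angela")
        internal = (generate_background(300, 0.4, rng) + back_translate(pep)
                    + generate_background(300, 0.4, rng))
        internal = evolve_sequence(internal, 0.013, 2.0, rng)  # ~1 My of divergence
        hits = find_domains(internal, refs)
        rt = [h for h in hits if h.domain == "RT"]
        assert len(rt) == 1
        assert rt[0].best_ref == ("Copia", "Angela")
        assert rt[0].score >= 50

    def test_background_has_no_hits_at_50_bit_floor(self, rng):
        internal = generate_background(3000, 0.4, rng)
        assert find_domains(internal, default_library()) == []

    def test_all_five_domains_recovered_when_planted(self, refs, rng):
        parts = []
        for domain in ("GAG", "PR", "INT", "RT", "RH"):
            parts.append(back_translate(refs.domain_consensus[domain]))
            parts.append(generate_background(30, 0.4, rng))
        internal = evolve_sequence("".join(parts), 0.005, 2.0, rng)
        hits = find_domains(internal, refs)
        assert {h.domain for h in hits} == {"GAG", "PR", "INT", "RT", "RH"}


def _fake_element(pbs=False, ppt=False, domains=()):
    from repeatscape.detect import LTRCandidate

    cand = LTRCandidate(contig="chr1", start=0, end=5000, ltr5=(0, 300),
                        ltr3=(4700, 5000), ltr_similarity=0.95)
    return AnnotatedElement(
        candidate=cand,
        pbs=PbsHit(2, 15, "tRNA-A", 0) if pbs else None,
        ppt=PptHit(3, 12, 1.0) if ppt else None,
        domains=[DomainHit(d, 1, (1000, 1600), 80.0, ("unknown", "unknown"), 0.9)
                 for d in domains],
    )


class TestFilterAndIntact:
    def test_ppt_alone_retains(self):
        element = _fake_element(ppt=True)
        assert filter_full_length([element]) == [element]

    def test_featureless_discarded_and_counts(self):
        featured = [_fake_element(pbs=True) for _ in range(3)] + \
                   [_fake_element(domains=("RT",)) for _ in range(3)]
        bare = [_fake_element() for _ in range(4)]
        retained = filter_full_length(featured + bare)
        assert retained == featured  # order preserved, exactly the featured six

    def test_filter_is_monotone_in_features(self):
        base = _fake_element()
        assert filter_full_length([base]) == []
        for kwargs in ({"pbs": True}, {"ppt": True}, {"domains": ("GAG",)},
                       {"pbs": True, "ppt": True, "domains": ("RT", "INT")}):
            assert filter_full_length([_fake_element(**kwargs)]) != []

    def test_intact_requires_everything(self):
        assert flag_intact(_fake_element(pbs=True, ppt=True,
                                         domains=("GAG", "PR", "RT", "RH", "INT")))
        assert not flag_intact(_fake_element(pbs=True, ppt=True,
                                             domains=("GAG", "PR", "RT", "INT")))
        assert not flag_intact(_fake_element(ppt=True,
                                             domains=("GAG", "PR", "RT", "RH", "INT")))


class TestTirDetection:
    def test_planted_mite_with_ta_tsd_detected(self, rng):
        genome = generate_background(5000, 0.4, rng)
        element = build_tir_element(rng, tir_length=25, total_length=300, tsd="TA")
        genome, truth = plant_tir_element(genome, 2500, element)
        hits = detect_tir_elements(genome)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.element_class == "MITE"
        assert abs(hit.start - truth.start) <= 3
        assert abs(hit.end - truth.end) <= 3

    def test_direct_repeat_not_reported(self, rng):
        tir = generate_background(25, 0.4, rng)
        genome = (generate_background(2000, 0.4, rng) + "TA" + tir
                  + generate_background(250, 0.4, rng) + tir + "TA"
                  + generate_background(2000, 0.4, rng))
        assert detect_tir_elements(genome) == []

    def test_diverged_tir_below_identity_floor_rejected(self, rng):
        # 0.80-identity TIR pair: exact-seed chains cannot span it and the
        # identity floor rejects any residual candidate
        tir = generate_background(40, 0.4, rng)
        mutated = evolve_sequence(tir, 0.23, 2.0, rng)
        genome = (generate_background(2000, 0.4, rng) + "CAG" + tir
                  + generate_background(250, 0.4, rng) + revcomp(mutated) + "CAG"
                  + generate_background(2000, 0.4, rng))
        for hit in detect_tir_elements(genome):
            assert hit.tir_identity >= 0.85
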