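import numpy as np
import pytest

from coflank.exon_model import (
    ACCEPTOR_POSITIONS,
    DD,
    DP,
    ExonRecord,
    InsufficientFlankError,
    RegionPairConfig,
    RegionSpec,
    SpliceSitePWM,
    UD,
    UP,
    UPDP,
    classify_pseudo_exon,
    estimate_pwm,
    extract_region,
    filter_corpus,
    find_pseudo_splice_sites,
    gc_content,
    score_splice_site,
)


def _exon(up="A" * 100, down="C" * 100, exon_id="e1", gene_id="g1", **kw):
    defaults = dict(splice_class="constitutive", exon_seq="ATG" * 30)
    defaults.update(kw)
    return ExonRecord(exon_id=exon_id, gene_id=gene_id, up_flank=up, down_flank=down, **defaults)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


class TestExtractRegion:
    def test_window_index_arithmetic(self, rng):
        """Up=[-64,-15] on a 100-nt flank maps to 0-based indices 36..85."""
        up = _random_seq(rng, 100)
        down = _random_seq(rng, 100)
        e = _exon(up=up, down=down)
        assert extract_region(e, UP) == up[36:86]
        assert extract_region(e, UD) == up[0:50]
        assert extract_region(e, DP) == down[6:56]
        assert extract_region(e, DD) == down[50:100]
        assert len(extract_region(e, UP)) == 50

    def test_full_span_identity(self, rng):
        up = _random_seq(rng, 100)
        e = _exon(up=up)
        assert extract_region(e, RegionSpec("all", "upstream", -100, -1)) == up

    def test_adjacent_windows_concatenate(self, rng):
        """Extractions of adjacent windows concatenate to the union window."""
        e = _exon(up=_random_seq(rng, 100), down=_random_seq(rng, 100))
        left = extract_region(e, RegionSpec("a", "upstream", -100, -51))
        right = extract_region(e, RegionSpec("b", "upstream", -50, -1))
        union = extract_region(e, RegionSpec("ab", "upstream", -100, -1))
        assert left + right == union
        d1 = extract_region(e, RegionSpec("c", "downstream", 1, 40))
        d2 = extract_region(e, RegionSpec("d", "downstream", 41, 100))
        assert d1 + d2 == extract_region(e, RegionSpec("cd", "downstream", 1, 100))

    def test_insufficient_flank_names_exon_and_region(self):
        e = _exon(up="A" * 60, exon_id="short1")
        with pytest.raises(InsufficientFlankError, match="short1.*Ud"):
            extract_region(e, UD)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("ACGTN", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestSpliceSiteScoring:
    def test_estimate_from_two_windows(self):
        pwm = estimate_pwm(["GA", "GC"], "donor")
        np.testing.assert_allclose(pwm.freq[0], [0, 0, 1.0, 0])
        np.testing.assert_allclose(pwm.freq[1], [0.5, 0.5, 0, 0])

    def test_identical_windows_degenerate(self):
        pwm = estimate_pwm(["GTAAGT"] * 5, "donor")
        assert (pwm.freq.max(axis=1) == 1.0).all()
        assert score_splice_site("GTAAGT", pwm) == 100.0

    def test_n_window_policy(self):
        with pytest.raises(ValueError):
            estimate_pwm(["GN"], "donor")
        pwm = estimate_pwm(["GA", "GN"], "donor", on_n="drop")
        np.testing.assert_allclose(pwm.freq[1], [1.0, 0, 0, 0])

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            estimate_pwm([], "donor")

    def test_hand_computed_cv(self):
        """2 positions, freqs {A:.7,C:.3} and {G:.9,T:.1}; window CG:
        s=1.2, s_min=0.4, s_max=1.6 -> cv = 100*(1.2-0.4)/1.2 = 66.67."""
        pwm = SpliceSitePWM(
            "donor", (1, 2), np.array([[0.7, 0.3, 0, 0], [0, 0, 0.9, 0.1]])
        )
        assert pwm.s_min == pytest.approx(0.4)
        assert pwm.s_max == pytest.approx(1.6)
        assert score_splice_site("CG", pwm) == pytest.approx(66.6667, abs=1e-3)
        assert score_splice_site("AG", pwm) == 100.0
        assert score_splice_site("CT", pwm) == 0.0

    def test_monotone_in_base_frequency(self, rng):
        """Swapping one base for a more frequent one never lowers the CV."""
        freq = rng.dirichlet(np.ones(4), size=9)
        pwm = SpliceSitePWM("donor", tuple(range(9)), freq)
        window = list("ACGTACGTA")
        base_cv = score_splice_site("".join(window), pwm)
        pos = 4
        cur = freq[pos, "ACGT".index(window[pos])]
        for b, f in zip("ACGT", freq[pos]):
            w2 = window.copy()
            w2[pos] = b
            cv2 = score_splice_site("".join(w2), pwm)
            if f >= cur:
                assert cv2 >= base_cv - 1e-12

    def test_length_mismatch(self):
        pwm = estimate_pwm(["GA", "GC"], "donor")
        with pytest.raises(ValueError):
            score_splice_site("GAT", pwm)


class TestPseudoExon:
    def _cand(self, length):
        return _exon(
            up="T" * 98 + "AG", down="GT" + "C" * 98, exon_seq="A" * length
        )

    def test_boundary_inclusive_accept(self):
        assert classify_pseudo_exon(self._cand(100), 75.0, 78.0, 150)

    @pytest.mark.parametrize(
        "length,cv3,cv5,dist",
        [(49, 90, 90, 500), (251, 90, 90, 500), (100, 74.9, 90, 500),
         (100, 90, 77.9, 500), (100, 90, 90, 99)],
    )
    def test_threshold_violations(self, length, cv3, cv5, dist):
        assert not classify_pseudo_exon(self._cand(length), cv3, cv5, dist)

    def test_noncanonical_bounds_rejected(self):
        e = _exon(up="T" * 100, down="GT" + "C" * 98, exon_seq="A" * 100)
        assert not classify_pseudo_exon(e, 90, 90, 500)


class TestPseudoSpliceSites:
    def _setup(self, rng):
        # authentic acceptor window (15 nt: intron -14..-1 + first exon base)
        window = "TTTTCTTTTCTCAGG"
        assert window[12:14] == "AG"
        flank = list("TTCTTC" * 34)[:200]
        # remove stray AGs so only the planted site qualifies
        exon = _exon(
            up="".join(flank), down="GT" + "C" * 198,
            acceptor_window=window, donor_window="CAGGTAAGT",
        )
        corpus = [exon] + [
            _exon(
                up=_random_seq(rng, 200), down=_random_seq(rng, 200),
                exon_id=f"bg{i}",
                acceptor_window=_random_seq(rng, 15),
                donor_window=_random_seq(rng, 9),
            )
            for i in range(20)
        ]
        pwms = {
            "acceptor": estimate_pwm([window] * 3 + [e.acceptor_window for e in corpus[1:]], "acceptor"),
            "donor": estimate_pwm(["CAGGTAAGT"] * 3 + [e.donor_window for e in corpus[1:]], "donor"),
        }
        return exon, pwms

    def test_no_ag_means_no_candidates(self, rng):
        exon, pwms = self._setup(rng)
        assert find_pseudo_splice_sites(exon, "upstream", pwms) == []

    def test_planted_copy_found_at_minus_150(self, rng):
        exon, pwms = self._setup(rng)
        # write the authentic window so its -1 position lands at offset -150
        up = list(exon.up_flank)
        i = 200 - 150
        up[i - 13 : i + 2] = list(exon.acceptor_window)
        planted = ExonRecord(
            exon_id="p", gene_id="g", splice_class="constitutive",
            exon_seq=exon.exon_seq, up_flank="".join(up), down_flank=exon.down_flank,
            acceptor_window=exon.acceptor_window, donor_window=exon.donor_window,
        )
        hits = find_pseudo_splice_sites(planted, "upstream", pwms)
        offsets = [o for o, _ in hits]
        assert -150 in offsets
        auth_cv = score_splice_site(exon.acceptor_window, pwms["acceptor"])
        cv = dict(hits)[-150]
        assert cv == pytest.approx(auth_cv)

    def test_copy_at_minus_50_excluded_by_distance(self, rng):
        exon, pwms = self._setup(rng)
        up = list(exon.up_flank)
        i = 200 - 50
        up[i - 13 : i + 2] = list(exon.acceptor_window)
        planted = ExonRecord(
            exon_id="p", gene_id="g", splice_class="constitutive",
            exon_seq=exon.exon_seq, up_flank="".join(up), down_flank=exon.down_flank,
            acceptor_window=exon.acceptor_window, donor_window=exon.donor_window,
        )
        offsets = [o for o, _ in find_pseudo_splice_sites(planted, "upstream", pwms)]
        assert -50 not in offsets


class TestFilterCorpus:
    def _random_corpus(self, rng, n=30):
        return [
            _exon(
                up=_random_seq(rng, 100), down=_random_seq(rng, 100),
                exon_id=f"e{i}", gene_id=f"g{i}",
            )
            for i in range(n)
        ]

    def test_clean_corpus_unchanged(self, rng):
        corpus = self._random_corpus(rng)
        kept, log = filter_corpus(corpus, UPDP, seed=0)
        assert [e.exon_id for e in kept] == [e.exon_id for e in corpus]
        assert log == []

    def test_identical_regions_purge_both(self, rng):
        corpus = self._random_corpus(rng, 10)
        twin = ExonRecord(
            exon_id="twin", gene_id="gx", splice_class="constitutive",
            exon_seq="ATG" * 30, up_flank=corpus[0].up_flank,
            down_flank=corpus[0].down_flank,
        )
        kept, log = filter_corpus(corpus + [twin], UPDP, seed=0)
        ids = {e.exon_id for e in kept}
        assert "e0" not in ids and "twin" not in ids
        assert {x[0] for x in log} == {"e0", "twin"}
        assert all(rule == "similarity_purge" for _, rule in log)

    def test_extreme_gc_removed(self, rng):
        corpus = self._random_corpus(rng, 5)
        at_only = _exon(up="AT" * 50, down=_random_seq(rng, 100), exon_id="gc0")
        kept, log = filter_corpus(corpus + [at_only], UPDP, seed=0)
        assert "gc0" not in {e.exon_id for e in kept}
        assert ("gc0", "extreme_gc") in log

    def test_alt_site_dedup_within_50(self, rng):
        """Two alt-3'ss records of one gene whose acceptor sites are 30 nt
        apart collapse to one kept record; 60 nt apart keeps both."""
        intron = _random_seq(rng, 200)
        down = _random_seq(rng, 100)

        def rec(eid, site):
            return ExonRecord(
                exon_id=eid, gene_id="g", splice_class="alt_3ss",
                exon_seq="ATG" * 30, up_flank=intron[site - 100 : site],
                down_flank=down,
            )

        near = [rec("a", 150), rec("b", 180)]
        kept, log = filter_corpus(near + self._random_corpus(rng, 5), UPDP, seed=1)
        assert sum(e.exon_id in ("a", "b") for e in kept) == 1

        far = [rec("c", 120), rec("d", 200)]
        kept2, _ = filter_corpus(far + self._random_corpus(rng, 5), UPDP, seed=1)
        assert sum(e.exon_id in ("c", "d") for e in kept2) == 2

    def test_idempotent(self, rng):
        corpus = self._random_corpus(rng, 20) + [
            _exon(up="AT" * 50, down=_random_seq(rng, 100), exon_id="bad")
        ]
        once, _ = filter_corpus(corpus, UPDP, seed=3)
        twice, log2 = filter_corpus(once, UPDP, seed=3)
        assert [e.exon_id for e in twice] == [e.exon_id for e in once]
        assert log2 == []


class TestRecordValidation:
    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="invalid characters"):
            _exon(up="AX" + "A" * 98)

    def test_unknown_splice_class(self):
        with pytest.raises(ValueError, match="splice_class"):
            _exon(splice_class="nope")

    def test_region_spec_validation(self):
        with pytest.raises(ValueError):
            RegionSpec("bad", "upstream", -10, 5)
        with pytest.raises(ValueError):
            RegionSpec("bad", "downstream", -3, 10)
        with pytest.raises(ValueError):
            RegionPairConfig(DP, DP)
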