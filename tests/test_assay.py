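"""Digestion engine: site scanning, virtual PCR, fragments, band matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eelid.assay import (
    Amplicon,
    BandProfile,
    Marker,
    PrimerPair,
    ReferenceSequence,
    RestrictionEnzyme,
    amplify,
    digest,
    iupac_compatible,
    profile_match,
    reverse_complement,
    scan_sites,
)
from eelid.errors import AlphabetError, AmplificationError, InputError

HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)
PAUI = RestrictionEnzyme("PauI", "GCGCGC", 1)
# asymmetric motif to exercise the reverse-strand rule
ASYM = RestrictionEnzyme("asym", "GGTCTC", 1)


def naive_scan(seq, enzyme):
    """All-windows IUPAC matcher, one cut per window (forward precedence)."""
    seq = seq.upper()
    m = len(enzyme.recognition)
    rc = reverse_complement(enzyme.recognition)
    cuts = set()
    fwd = set()
    for i in range(len(seq) - m + 1):
        win = seq[i : i + m]
        if all(iupac_compatible(a, b) for a, b in zip(win, enzyme.recognition)):
            fwd.add(i)
            cuts.add(i + enzyme.cut_offset)
    for i in range(len(seq) - m + 1):
        win = seq[i : i + m]
        if i not in fwd and all(
            iupac_compatible(a, b) for a, b in zip(win, rc)
        ):
            cuts.add(i + m - enzyme.cut_offset)
    return sorted(cuts)


class TestScanSites:
    def test_uncut_sequence_gives_no_positions(self):
        assert scan_sites("ACGTACGTACGT", HINFI) == []

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAGACTCAAA", [3]),          # window at 2, G^ACTC
            ("GACTCGAGTC", [1, 6]),       # two non-overlapping matches
        ],
    )
    def test_known_cut_positions(self, seq, expected):
        assert scan_sites(seq, HINFI) == expected

    def test_degenerate_n_matches_any_base(self):
        for mid in "ACGT":
            assert scan_sites(f"TTGA{mid}TCTT", HINFI) == [3]

    def test_ambiguous_sequence_codes_match_by_intersection(self):
        # R = A/G intersects the A required at GANTC's second position...
        assert scan_sites("TTGRCTCTT", HINFI) == [3]
        # ...but Y = C/T does not
        assert scan_sites("TTGYCTCTT", HINFI) == []

    def test_invalid_characters_raise_alphabet_error(self):
        with pytest.raises(AlphabetError):
            scan_sites("ACGTXACGT", HINFI)

    def test_reverse_orientation_site_found_with_adjusted_cut(self):
        # rc(GGTCTC) = GAGACC present forward; GGTCTC absent
        seq = "TTTTGAGACCTTTT"
        assert scan_sites(seq, ASYM, both_strands=False) == []
        # reverse-only window at 4: cut at 4 + 6 - 1 = 9
        assert scan_sites(seq, ASYM, both_strands=True) == [9]

    def test_agrees_with_biopython_on_random_sequences(self):
        """Independent oracle: Bio.Restriction reports 1-based positions of
        the base following the cut, i.e. ours + 1."""
        from Bio.Restriction import HinfI as BioHinfI
        from Bio.Restriction import PauI as BioPauI
        from Bio.Seq import Seq

        rng = np.random.default_rng(42)
        pairs = [(HINFI, BioHinfI), (PAUI, BioPauI)]
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for ours, theirs in pairs:
                expected = sorted(p - 1 for p in theirs.search(Seq(seq)))
                assert scan_sites(seq, ours) == expected

    def test_agrees_with_naive_matcher_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for i in range(1000):
            n = int(rng.integers(20, 200))
            seq = "".join(rng.choice(list("ACGTN"), size=n,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            enzyme = [HINFI, PAUI, ASYM][i % 3]
            assert scan_sites(seq, enzyme) == naive_scan(seq, enzyme)


class TestDigest:
    @pytest.mark.parametrize(
        "length,cuts,fragments,visible",
        [
            (350, [280], (280, 70), (280,)),
            (350, [117, 281], (117, 164, 69), (164, 117)),
            (412, [], (412,), (412,)),
            (412, [167], (167, 245), (245, 167)),
        ],
    )
    def test_diagnostic_fragment_profiles(self, length, cuts, fragments, visible):
        """The four gel outcomes of the eel assay, built synthetically."""
        seq = _sequence_with_cuts(length, cuts)
        amp = Amplicon(marker=Marker.CYTB, sequence=seq)
        res = digest(amp, HINFI, visibility_threshold=100)
        assert res.fragments == fragments
        assert res.visible_bands == visible
        assert tuple(res.cut_positions) == tuple(cuts)

    def test_negative_threshold_rejected(self):
        amp = Amplicon(marker=Marker.CYTB, sequence="ACGT" * 20)
        with pytest.raises(InputError):
            digest(amp, HINFI, visibility_threshold=-1)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=400),
           st.sampled_from([HINFI, PAUI]),
           st.integers(min_value=0, max_value=200))
    @settings(max_examples=200, deadline=None)
    def test_fragment_sum_conservation(self, seq, enzyme, threshold):
        amp = Amplicon(marker=Marker.CYTB, sequence=seq)
        res = digest(amp, enzyme, visibility_threshold=threshold)
        assert sum(res.fragments) == len(seq)
        assert len(res.fragments) == len(res.cut_positions) + 1
        # visible bands are a sub-multiset of fragments
        frags = list(res.fragments)
        for b in res.visible_bands:
            frags.remove(b)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=400))
    @settings(max_examples=100, deadline=None)
    def test_raising_threshold_never_adds_bands(self, seq):
        amp = Amplicon(marker=Marker.CYTB, sequence=seq)
        counts = [
            len(digest(amp, HINFI, visibility_threshold=t).visible_bands)
            for t in (0, 50, 100, 200, 400)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=400))
    @settings(max_examples=100, deadline=None)
    def test_rejoined_fragments_digest_identically(self, seq):
        amp = Amplicon(marker=Marker.CYTB, sequence=seq)
        res = digest(amp, HINFI, visibility_threshold=0)
        bounds = (0,) + res.cut_positions + (len(seq),)
        pieces = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
        rejoined = "".join(pieces)
        res2 = digest(
            Amplicon(marker=Marker.CYTB, sequence=rejoined), HINFI,
            visibility_threshold=0,
        )
        assert sorted(res2.fragments) == sorted(res.fragments)


class TestAmplify:
    def _template(self, insert_len, fwd, rev, flank=20, rng_seed=3):
        rng = np.random.default_rng(rng_seed)
        mid = "".join(rng.choice(list("ACGT"), size=insert_len))
        flanks = ["".join(rng.choice(list("ACGT"), size=flank)) for _ in range(2)]
        return flanks[0] + fwd + mid + reverse_complement(rev) + flanks[1]

    def test_product_spans_both_primers(self, cfg):
        primers = cfg.primer_for(Marker.CYTB)
        insert = 350 - len(primers.forward) - len(primers.reverse)
        seq = self._template(insert, primers.forward, primers.reverse)
        tpl = ReferenceSequence("t", "A. rostrata", Marker.CYTB, seq)
        amp = amplify(tpl, primers)
        assert amp.length == 350

    def test_template_equal_to_amplicon_is_identity(self, cfg):
        primers = cfg.primer_for(Marker.S18)
        rng = np.random.default_rng(11)
        mid = "".join(rng.choice(list("ACGT"), size=372))
        seq = primers.forward + mid + reverse_complement(primers.reverse)
        tpl = ReferenceSequence("t", "x", Marker.S18, seq)
        assert amplify(tpl, primers).sequence == seq

    def test_missing_reverse_site_fails(self, cfg):
        primers = cfg.primer_for(Marker.CYTB)
        rng = np.random.default_rng(5)
        seq = primers.forward + "".join(rng.choice(list("ACGT"), size=200))
        tpl = ReferenceSequence("t", "x", Marker.CYTB, seq)
        with pytest.raises(AmplificationError):
            amplify(tpl, primers)

    def test_shortest_product_wins_with_repeated_sites(self, cfg):
        primers = cfg.primer_for(Marker.CYTB)
        rev_site = reverse_complement(primers.reverse)
        rng = np.random.default_rng(9)
        mid1 = "".join(rng.choice(list("ACGT"), size=60))
        mid2 = "".join(rng.choice(list("ACGT"), size=300))
        seq = primers.forward + mid1 + rev_site + mid2 + rev_site
        tpl = ReferenceSequence("t", "x", Marker.CYTB, seq)
        amp = amplify(tpl, primers)
        assert amp.length == len(primers.forward) + 60 + len(rev_site)

    def test_oversized_product_rejected(self, cfg):
        primers = cfg.primer_for(Marker.CYTB)
        seq = self._template(600, primers.forward, primers.reverse)
        tpl = ReferenceSequence("t", "x", Marker.CYTB, seq)
        with pytest.raises(AmplificationError):
            amplify(tpl, primers, max_product_length=500)


class TestProfileMatch:
    def _result(self, bands):
        return digest(
            Amplicon(marker=Marker.CYTB,
                     sequence=_sequence_with_cuts(sum(bands), _cuts_for(bands))),
            HINFI, visibility_threshold=0,
        )

    @pytest.mark.parametrize(
        "visible,profile,expected",
        [
            ((280,), (280,), True),
            ((282,), (280,), True),       # within 5%
            ((300,), (280,), False),      # 7% off
            ((164, 117), (280,), False),  # cardinality mismatch
        ],
    )
    def test_tolerance_and_cardinality(self, visible, profile, expected):
        res = self._result(visible)
        prof = BandProfile(Marker.CYTB, profile, tolerance=0.05)
        assert profile_match(res, prof) is expected

    def test_band_profile_validation(self):
        with pytest.raises(InputError):
            BandProfile(Marker.CYTB, ())
        with pytest.raises(InputError):
            BandProfile(Marker.CYTB, (0,))
        with pytest.raises(InputError):
            BandProfile(Marker.CYTB, (100,), tolerance=1.0)


def _sequence_with_cuts(length, cuts):
    """A/T sequence with a concrete HinfI site realised before each cut."""
    seq = list("AT" * (length // 2 + 1))[:length]
    for cut in cuts:
        seq[cut - 1 : cut + 4] = list("GACTC")
    return "".join(seq)


def _cuts_for(bands):
    cuts, acc = [], 0
    for b in bands[:-1]:
        acc += b
        cuts.append(acc)
    return cuts
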