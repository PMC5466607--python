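"""In-silico AFLP engine: digestion, selective amplification, size selection."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyexpress.aflp_insilico import (
    ECORI,
    MSEI,
    DigestFragment,
    EnzymeEnd,
    PredictedBand,
    PrimerSpec,
    RestrictionEnzyme,
    digest,
    ecoRI_primer,
    locate_sites,
    mseI_primer,
    predict_profile,
    selective_filter,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def naive_cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sliding-window oracle: test every window against the site."""
    k = len(enzyme.recognition_site)
    return [
        i + enzyme.cut_offset
        for i in range(len(sequence) - k + 1)
        if sequence[i : i + k] == enzyme.recognition_site
    ]


class TestLocateSites:
    @pytest.mark.parametrize(
        "sequence,enzyme,expected",
        [
            ("CCCC", ECORI, []),
            ("GAATTC", ECORI, [1]),
            ("TTAATTAA", MSEI, [1, 5]),  # overlapping occurrences both cut
            ("", ECORI, []),
        ],
    )
    def test_examples(self, sequence, enzyme, expected):
        assert locate_sites(sequence, enzyme) == expected

    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_sliding_window_oracle(self, sequence):
        for enzyme in (ECORI, MSEI):
            assert locate_sites(sequence, enzyme) == naive_cut_positions(
                sequence, enzyme
            )

    def test_rejects_ambiguity_codes_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            locate_sites("GANTTC", ECORI)

    def test_invalid_enzyme_definitions_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "GAXTTC", 1, EnzymeEnd.ECORI)
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "TTAA", 7, EnzymeEnd.MSEI)


class TestDigest:
    def test_no_sites_single_terminus_fragment(self):
        frags = digest("CCCCCC", [ECORI, MSEI])
        assert len(frags) == 1
        assert (frags[0].left_enzyme, frags[0].right_enzyme) == (
            EnzymeEnd.TERMINUS,
            EnzymeEnd.TERMINUS,
        )

    def test_double_digest_end_labels(self):
        # EcoRI cut at 3, MseI cut at 11: three fragments
        frags = digest("AAGAATTCAATTAACC", [ECORI, MSEI])
        labels = [(f.left_enzyme, f.right_enzyme) for f in frags]
        assert labels == [
            (EnzymeEnd.TERMINUS, EnzymeEnd.ECORI),
            (EnzymeEnd.ECORI, EnzymeEnd.MSEI),
            (EnzymeEnd.MSEI, EnzymeEnd.TERMINUS),
        ]
        assert [f.sequence for f in frags] == ["AAG", "AATTCAAT", "TAACC"]

    def test_empty_sequence_empty_digest(self):
        assert digest("", [ECORI, MSEI]) == []

    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_tiling_conservation(self, sequence):
        frags = digest(sequence, [ECORI, MSEI])
        assert "".join(f.sequence for f in frags) == sequence
        for f in frags:
            assert f.sequence == sequence[f.start : f.end]

    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_reverse_complement_symmetry(self, sequence):
        """Digestion is strand-symmetric: same molecules either way round.

        Fragment counts match, and so do duplex extents (top-strand lengths
        alone cannot match, since both enzymes cut off-centre and the
        overhangs swap strands under reverse complement).
        """
        rc = sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = digest(sequence, [ECORI, MSEI])
        rev = digest(rc, [ECORI, MSEI])
        assert len(fwd) == len(rev)
        assert sorted(f.duplex_length for f in fwd) == sorted(
            f.duplex_length for f in rev
        )

    def test_conservation_on_random_kilobase_sequences(self, random_dna):
        for _ in range(100):
            seq = random_dna(1000)
            frags = digest(seq, [ECORI, MSEI])
            assert sum(len(f) for f in frags) == len(seq)


def _fragment(seq, left, right):
    return DigestFragment("tx", 0, len(seq), left, right, seq)


class TestSelectiveFilter:
    def test_plus_zero_matches_every_mixed_fragment(self):
        frag = _fragment("AATTCGGGGT", EnzymeEnd.ECORI, EnzymeEnd.MSEI)
        assert selective_filter(frag, ecoRI_primer(""), mseI_primer(""))

    def test_ecoRI_plus3_match_and_mismatch(self):
        frag = _fragment("AATTCAGCGGGT", EnzymeEnd.ECORI, EnzymeEnd.MSEI)
        assert selective_filter(frag, ecoRI_primer("AGC"), mseI_primer(""))
        assert not selective_filter(frag, ecoRI_primer("ACG"), mseI_primer(""))

    def test_mseI_side_reads_reverse_complement(self):
        # MseI right end: remnant "T"; interior GTG == revcomp("CAC")
        frag = _fragment("AATTCAGCGTGT", EnzymeEnd.ECORI, EnzymeEnd.MSEI)
        assert selective_filter(frag, ecoRI_primer("AGC"), mseI_primer("CAC"))
        assert not selective_filter(frag, ecoRI_primer("AGC"), mseI_primer("CAA"))

    def test_flipped_orientation(self):
        # MseI left end (remnant TAA, direct match), EcoRI right end
        # (remnant G, interior GCT == revcomp("AGC"))
        frag = _fragment("TAACACGGGGCTG", EnzymeEnd.MSEI, EnzymeEnd.ECORI)
        assert selective_filter(frag, ecoRI_primer("AGC"), mseI_primer("CAC"))
        assert not selective_filter(frag, ecoRI_primer("AGC"), mseI_primer("CAG"))

    def test_same_end_fragment_is_contract_violation(self):
        frag = _fragment("AATTCGGG", EnzymeEnd.ECORI, EnzymeEnd.ECORI)
        with pytest.raises(ValueError, match="EcoRI"):
            selective_filter(frag, ecoRI_primer(""), mseI_primer(""))

    def test_primer_spec_validation(self):
        with pytest.raises(ValueError):
            PrimerSpec(EnzymeEnd.ECORI, "CORE", "AG")  # +2 not a design
        with pytest.raises(ValueError):
            PrimerSpec(EnzymeEnd.MSEI, "CORE", "CAX")


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def brute_force_bands(transcripts, eco_ext, mse_ext, window, offset=0):
    """Independent enumeration: regex digestion, end-remnant string checks."""
    by_size = {}
    for _, seq in transcripts:
        cuts = {m.start() + 1: "E" for m in re.finditer("(?=GAATTC)", seq)}
        cuts.update({m.start() + 1: "M" for m in re.finditer("(?=TTAA)", seq)})
        bounds = sorted(c for c in cuts if 0 < c < len(seq))
        edges = [(0, None), *[(c, cuts[c]) for c in bounds], (len(seq), None)]
        for (s, left), (e, right) in zip(edges, edges[1:]):
            piece = seq[s:e]
            if left == "E" and right == "M":
                ok = piece[5 : 5 + len(eco_ext)] == eco_ext and (
                    not mse_ext or _rc(piece[-1 - len(mse_ext) : -1]) == mse_ext
                )
            elif left == "M" and right == "E":
                ok = piece[3 : 3 + len(mse_ext)] == mse_ext and (
                    not eco_ext or _rc(piece[-1 - len(eco_ext) : -1]) == eco_ext
                )
            else:
                ok = False
            size = len(piece) + offset
            if ok and window[0] <= size <= window[1]:
                by_size[size] = by_size.get(size, 0) + 1
    return by_size


class TestPredictProfile:
    def test_no_ecoRI_site_no_bands(self):
        assert predict_profile([("t", "TTAACCCCTTAA" * 30)], ecoRI_primer(), mseI_primer(), (1, 1000)) == []

    def test_comigration_merges_equal_sizes(self):
        # both transcripts yield the same 101 bp EcoRI-MseI fragment
        transcripts = [("t1", "CC" + "GAATTC" + "G" * 95 + "TTAA" + "CC"),
                       ("t2", "AA" + "GAATTC" + "G" * 95 + "TTAA" + "GG")]
        bands = predict_profile(transcripts, ecoRI_primer(), mseI_primer(), (50, 600))
        assert len(bands) == 1
        assert len(bands[0].member_fragments) == 2

    def test_gel_order_size_descending(self, random_dna):
        transcripts = [(f"t{i}", random_dna(800)) for i in range(20)]
        bands = predict_profile(transcripts, ecoRI_primer(), mseI_primer(), (1, 10_000))
        sizes = [b.size_bp for b in bands]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_brute_force_enumeration(self, random_dna):
        transcripts = [(f"t{i}", random_dna(1200)) for i in range(10)]
        for eco_ext, mse_ext in [("", ""), ("A", "C"), ("AGC", "CAC")]:
            bands = predict_profile(
                transcripts, ecoRI_primer(eco_ext), mseI_primer(mse_ext), (100, 600)
            )
            got = {b.size_bp: len(b.member_fragments) for b in bands}
            assert got == brute_force_bands(transcripts, eco_ext, mse_ext, (100, 600))

    def test_size_window_and_offset(self, random_dna):
        transcripts = [(f"t{i}", random_dna(1000)) for i in range(10)]
        plain = predict_profile(transcripts, ecoRI_primer(), mseI_primer(), (100, 300))
        assert all(100 <= b.size_bp <= 300 for b in plain)
        shifted = predict_profile(
            transcripts, ecoRI_primer(), mseI_primer(), (1, 10_000), size_offset=32
        )
        raw = predict_profile(transcripts, ecoRI_primer(), mseI_primer(), (1, 10_000))
        assert {b.size_bp for b in shifted} == {b.size_bp + 32 for b in raw}

    def test_selectivity_monotone_in_extension_length(self, random_dna):
        # nested extensions (+0 prefix of +1 prefix of +3) can only lose bands
        transcripts = [(f"t{i}", random_dna(2000)) for i in range(30)]

        def n_fragments(eco, mse):
            bands = predict_profile(
                transcripts, ecoRI_primer(eco), mseI_primer(mse), (1, 10_000)
            )
            return sum(len(b.member_fragments) for b in bands)

        assert n_fragments("AGC", "CAC") <= n_fragments("A", "C") <= n_fragments("", "")

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            predict_profile([], ecoRI_primer(), mseI_primer(), (300, 100))

    def test_band_size_must_be_positive(self):
        with pytest.raises(ValueError):
            PredictedBand((ecoRI_primer(), mseI_primer()), 0)
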