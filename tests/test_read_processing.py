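"""Read merging, filtering, orientation, and translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbmine import (
    MergedRead,
    ReadPair,
    Rejection,
    merge_read_pair,
    orient_read,
    quality_length_filter,
    translate_validate,
)
from nbmine._util import revcomp
from nbmine.read_processing import (
    FR1_PRIMER,
    PrimerSpec,
    ProcessParams,
    _translate_matrix,
    process_read_pairs,
    read_fastq_pairs,
    translate_frame,
)
from nbmine._util import encode
from nbmine.synthetic_data import _amplicon, write_fastq

RNG = np.random.default_rng(2024)
BASES = "ACGT"


def _rand_dna(n, rng=RNG):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _pair(fwd, rev, q=40, pid="r1", sample="S"):
    return ReadPair(
        id=pid,
        fwd_seq=fwd,
        fwd_qual=np.full(len(fwd), q),
        rev_seq=rev,
        rev_qual=np.full(len(rev), q),
        sample=sample,
    )


def _merged(seq, q=40):
    return MergedRead(id="m", seq=seq, qual=np.full(len(seq), q))


# ---------------------------------------------------------------------------
# merging

class TestMerge:
    def test_error_free_reconstruction(self):
        # mates covering the first and last 60 bases of a 90-mer share a
        # 30-base error-free overlap and must reassemble the template
        template = _rand_dna(90)
        pair = _pair(template[:60], revcomp(template[-60:]))
        out = merge_read_pair(pair)
        assert isinstance(out, MergedRead)
        assert out.seq == template
        assert len(out.seq) == 60 + 60 - out.overlap_len
        assert out.overlap_len == 30
        assert out.mismatches_in_overlap == 0

    @pytest.mark.parametrize("n_mismatch,accepted", [(2, True), (3, False)])
    def test_mismatch_rate_boundary(self, n_mismatch, accepted):
        # a 10-base overlap carrying 2 mismatches is rate 0.20 <= 0.25;
        # 3 mismatches (0.30) must be rejected
        rng = np.random.default_rng(5)
        overlap = "ACGTACGTAC"
        mutated = list(overlap)
        for i in range(n_mismatch):
            pos = 3 * i
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        left, right = "GGGGGGGGGGGGGGG", "CCCCCCCCCCCCCCC"
        fwd = left + overlap
        rev_sense = "".join(mutated) + right
        pair = _pair(fwd, revcomp(rev_sense))
        out = merge_read_pair(pair, min_overlap=10, max_mismatch_rate=0.25)
        if accepted:
            assert isinstance(out, MergedRead)
            assert out.overlap_len == 10
            assert out.mismatches_in_overlap == n_mismatch
        else:
            assert isinstance(out, Rejection)
            assert out.reason == "unjoinable"

    def test_simulated_pairs_recover_template(self):
        # pairs carry shared (template-level) substitutions; merging must
        # reconstruct each pair's own template essentially always
        rng = np.random.default_rng(7)
        exact = 0
        for _ in range(200):
            template = list(_rand_dna(360, rng))
            subs = rng.random(360) < 0.005
            for p in np.flatnonzero(subs):
                template[p] = BASES[(BASES.index(template[p]) + int(rng.integers(1, 4))) % 4]
            template = "".join(template)
            pair = _pair(template[:250], revcomp(template[-250:]))
            out = merge_read_pair(pair)
            if isinstance(out, MergedRead) and out.seq == template:
                exact += 1
        assert exact >= 198  # >= 99%

    def test_higher_quality_base_wins_in_overlap(self):
        template = _rand_dna(60)
        fwd = template[:40]
        rev_sense = list(template[20:])
        rev_sense[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[rev_sense[5]]  # pos 25
        pair = ReadPair(
            id="q",
            fwd_seq=fwd,
            fwd_qual=np.full(40, 20),
            rev_seq=revcomp("".join(rev_sense)),
            rev_qual=np.full(40, 38),
            sample="S",
        )
        out = merge_read_pair(pair)
        assert isinstance(out, MergedRead)
        assert out.seq[25] == rev_sense[5]  # reverse mate had higher quality
        assert out.qual[25] == 18  # |q1 - q2|

    def test_empty_mate_is_an_input_error(self):
        with pytest.raises(ValueError):
            _pair("", "ACGT")

    def test_no_admissible_overlap_is_unjoinable(self):
        out = merge_read_pair(_pair("A" * 30, "A" * 30))  # rev rc = T*30
        assert isinstance(out, Rejection) and out.reason == "unjoinable"


# ---------------------------------------------------------------------------
# quality / length filter

@pytest.mark.parametrize(
    "length,q,expected",
    [(200, 40, True), (200, 30, False), (149, 40, False), (150, 38, True)],
)
def test_quality_length_filter(length, q, expected):
    ok, _ = quality_length_filter(_merged("A" * length, q))
    assert ok is expected


def test_quality_filter_empty_read():
    ok, reason = quality_length_filter(_merged(""))
    assert not ok and reason == "empty"


# ---------------------------------------------------------------------------
# orientation

AMPLICON = _amplicon("ACDEFGHIKLMNPQRSTVWY" * 5 + "ACDEFG", "L")  # 106 aa interior


class TestOrient:
    def test_already_oriented_read_unchanged(self):
        out = orient_read(_merged(AMPLICON))
        assert isinstance(out, MergedRead)
        assert out.seq == AMPLICON

    def test_strand_symmetry(self):
        flipped = orient_read(_merged(revcomp(AMPLICON)))
        assert isinstance(flipped, MergedRead)
        assert flipped.seq == AMPLICON

    @pytest.mark.parametrize("w_base", ["A", "T"])
    def test_fr4_degenerate_position(self, w_base):
        # the FR4 primer's W tolerates A and T; on the sense strand that is
        # the complementary base at the mirrored position
        variant = "L" if w_base == "T" else "Q"
        amplicon = _amplicon("ARNDCQEGHILKMFPSTWYV" * 5 + "ARNDCQ", variant)
        out = orient_read(_merged(amplicon))
        assert isinstance(out, MergedRead)

    def test_no_primer(self):
        out = orient_read(_merged(_rand_dna(100, np.random.default_rng(3))))
        assert isinstance(out, Rejection) and out.reason == "no_primer"

    def test_partial_amplicon(self):
        out = orient_read(_merged(FR1_PRIMER + "A" * 60))
        assert isinstance(out, Rejection) and out.reason == "partial_amplicon"

    def test_n_never_matches_a_primer(self):
        broken = "N" + AMPLICON[1:]
        out = orient_read(_merged(broken))
        assert isinstance(out, Rejection)

    def test_one_mismatch_tolerance_flag(self):
        broken = "T" + AMPLICON[1:]  # FR1 starts with G
        assert isinstance(orient_read(_merged(broken)), Rejection)
        out = orient_read(_merged(broken), max_primer_mismatches=1)
        assert isinstance(out, MergedRead)


# ---------------------------------------------------------------------------
# translation

class TestTranslate:
    def test_in_frame_amplicon(self):
        out = translate_validate(orient_read(_merged(AMPLICON)))
        assert len(out.full_peptide) == 120
        assert len(out.trimmed_peptide) == 106
        assert out.full_peptide.startswith("EVQLVES")
        assert out.full_peptide.endswith("TLVTVSS")

    def test_single_deletion_is_frameshift(self):
        broken = AMPLICON[:180] + AMPLICON[181:]
        out = translate_validate(_merged(broken))
        assert isinstance(out, Rejection) and out.reason == "frameshift"

    def test_stop_codon_rejected(self):
        broken = AMPLICON[:147] + "TAG" + AMPLICON[150:]  # codon 50
        out = translate_validate(_merged(broken))
        assert isinstance(out, Rejection) and out.reason == "premature_stop"

    def test_n_codon_is_ambiguous(self):
        broken = AMPLICON[:90] + "N" + AMPLICON[91:]
        out = translate_validate(_merged(broken))
        assert isinstance(out, Rejection) and out.reason == "ambiguous"

    def test_batch_translation_matches_scalar(self, rng):
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, size=60)) for _ in range(50)]
        batch = _translate_matrix(np.vstack([encode(s) for s in seqs]))
        assert batch == [translate_frame(s) for s in seqs]


# ---------------------------------------------------------------------------
# properties

@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_error_free_round_trip_recovers_translation(seed):
    """Error-free pairs from any in-frame template round-trip exactly."""
    rng = np.random.default_rng(seed)
    interior = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=60))
    amplicon = _amplicon(interior, "L")
    cut = int(rng.integers(30, len(amplicon) - 30))
    overlap = int(rng.integers(10, 25))
    pair = _pair(amplicon[: cut + overlap], revcomp(amplicon[cut:]))
    merged = merge_read_pair(pair)
    assert isinstance(merged, MergedRead)
    out = translate_validate(orient_read(merged), min_trimmed_len=36)
    assert out.trimmed_peptide == interior


def test_filters_commute_on_pass_fail(small_sim):
    """Quality/length and primer/frame checks agree on the accepted set in either order."""
    _, _, reads = small_sim
    merged = []
    for p in reads.pairs["CTRL"][:300]:
        m = merge_read_pair(p)
        if isinstance(m, MergedRead):
            merged.append(m)
    def qc_first(m):
        if not quality_length_filter(m)[0]:
            return False
        o = orient_read(m)
        return isinstance(o, MergedRead) and not isinstance(translate_validate(o), Rejection)
    def orient_first(m):
        o = orient_read(m)
        if isinstance(o, Rejection) or isinstance(translate_validate(o), Rejection):
            return False
        return quality_length_filter(m)[0]
    assert [qc_first(m) for m in merged] == [orient_first(m) for m in merged]


def test_counts_conservation(small_sim):
    _, _, reads = small_sim
    res = process_read_pairs(reads.pairs["SEL"], "SEL", ProcessParams())
    c = res.counts
    c.check_conservation()
    assert c.raw == len(reads.pairs["SEL"])
    assert c.validated == sum(res.tally.values())
    # every read appears exactly once: validated plus logged rejections
    assert c.raw == c.validated + len(res.rejections)


def test_fastq_round_trip(tmp_path, small_sim):
    _, _, reads = small_sim
    subset = reads.pairs["CTRL"][:50]
    write_fastq(subset, tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz")
    back = list(read_fastq_pairs(tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz", "CTRL"))
    assert len(back) == 50
    for orig, rt in zip(subset, back):
        assert rt.id == orig.id
        assert rt.fwd_seq == orig.fwd_seq
        assert rt.rev_seq == orig.rev_seq
        assert np.array_equal(rt.fwd_qual, orig.fwd_qual)


def test_primer_spec_validates_fr1_translation():
    with pytest.raises(ValueError):
        PrimerSpec(fr1_dna="ATGATGATGATGATGATGATG")
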