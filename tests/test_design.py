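import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaspike import design
from srnaspike.design import (
    DesignConstraints,
    MixSpec,
    Oligo,
    SpikeInSet,
    build_erdn_set,
    build_srqc_set,
    check_constraints,
    gc_content,
    generate_candidates,
    kmer_dissimilar,
    ladder_mix,
    max_homopolymer_run,
    passes_constraints,
    rebalance_mix,
)
from srnaspike.exceptions import (
    AlphabetError,
    DesignInfeasibleError,
    ParameterError,
    RebalanceError,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=40)


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0),
    ("AAUU", 0.0),
    ("ACGU", 0.5),
    ("GCA", 2 / 3),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_rejects_bad_alphabet():
    with pytest.raises(AlphabetError):
        gc_content("ACGT")  # DNA not allowed here
    with pytest.raises(AlphabetError):
        gc_content("")


@pytest.mark.parametrize("seq,expected", [
    ("ACGU", 1),
    ("AACCGGUU", 2),
    ("ACGGGU", 3),
    ("A", 1),
    ("UUUUU", 5),
])
def test_max_homopolymer_run(seq, expected):
    assert max_homopolymer_run(seq) == expected


@given(rna)
@settings(deadline=None, derandomize=True)
def test_gc_complement_symmetry(seq):
    """GC content is invariant under complementation; homopolymer under reversal."""
    from srnaspike._seq import reverse_complement
    assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))
    assert max_homopolymer_run(seq) == max_homopolymer_run(seq[::-1])


class TestKmerDissimilar:
    def test_empty_pool(self):
        assert kmer_dissimilar("ACGUACGUACGUA", set(), 12)

    def test_self_match(self):
        s = "ACGUACGUACGUA"
        assert not kmer_dissimilar(s, {s}, 12)

    def test_single_shared_kmer(self, rng):
        """A pool member sharing exactly one 12-mer must be rejected.

        Verified against brute-force k-mer set intersection.
        """
        bases = np.array(list("ACGU"))
        seq = "".join(rng.choice(bases, 25))
        shared = seq[5:17]
        other = "".join(rng.choice(bases, 10)) + shared
        km = {seq[i:i + 12] for i in range(len(seq) - 11)}
        km_other = {other[i:i + 12] for i in range(len(other) - 11)}
        assert km & km_other  # brute-force ground truth: overlap exists
        assert not kmer_dissimilar(seq, {other}, 12)

    def test_reverse_complement_detected(self):
        from srnaspike._seq import reverse_complement
        seq = "ACGUAGCUGAUCGGAUCCAGUAAGC"
        rc_fragment = reverse_complement(seq[3:15])
        other = "AAAA" + rc_fragment + "CCCC"
        assert not kmer_dissimilar(seq, {other}, 12)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            kmer_dissimilar("ACGU", set(), 0)
        with pytest.raises(ParameterError):
            kmer_dissimilar("ACGU", set(), 5)


class TestPassesConstraints:
    def test_homopolymer_fails(self, constraints):
        seq = "GGGACUACGUACGUACGUACGAUCG"  # run of 3 at the start
        rep = check_constraints(seq, constraints)
        assert not rep.ok and "homopolymer" in rep.failed

    def test_short_oligo_skips_structure_checks(self, constraints):
        """A 10-mer is exempt from the hairpin and similarity screens."""
        # self-complementary 10-mer that would fold if checked
        seq = "GCGCAAGCGC"
        rep = check_constraints(seq, constraints, pool={seq})
        assert not rep.structure_checked
        assert rep.ok == (rep.homopolymer_ok and rep.gc_ok)

    def test_all_filters_pass(self, constraints):
        seq = "GCAAUGACGGUCGACUUGCGAGGUA"
        rep = check_constraints(seq, constraints)
        # each filter re-derived independently
        assert max_homopolymer_run(seq) <= 2
        assert 0.4 <= gc_content(seq) <= 0.6
        from srnaspike.thermo import min_hairpin_dG
        assert min_hairpin_dG(seq) >= -0.5
        assert rep.ok
        assert passes_constraints(Oligo("x", seq), constraints)


class TestGenerateCandidates:
    def test_determinism(self, constraints):
        a = generate_candidates(5, 25, constraints, seed=7)
        b = generate_candidates(5, 25, constraints, seed=7)
        assert [o.seq for o in a] == [o.seq for o in b]
        c = generate_candidates(5, 25, constraints, seed=8)
        assert [o.seq for o in a] != [o.seq for o in c]

    def test_mutual_dissimilarity_and_filters(self, constraints):
        oligos = generate_candidates(6, 25, constraints, seed=3)
        seqs = [o.seq for o in oligos]
        assert len(set(seqs)) == 6
        for i, s in enumerate(seqs):
            assert check_constraints(
                s, constraints, [q for j, q in enumerate(seqs) if j != i]).ok

    def test_infeasible_raises(self):
        tight = DesignConstraints(gc_min=0.49, gc_max=0.51,
                                  max_draws_per_oligo=20)
        with pytest.raises(DesignInfeasibleError) as exc:
            generate_candidates(3, 25, tight, seed=0)
        assert exc.value.binding_constraint is not None


class TestSpikeSets:
    def test_srqc_lengths_and_ids(self, srqc_set):
        assert len(srqc_set) == 11
        assert sorted(o.length for o in srqc_set) == list(design.SRQC_LENGTHS)
        assert srqc_set.ids == [f"SS-{L}" for L in design.SRQC_LENGTHS]

    def test_erdn_is_nineteen_25mers(self, erdn_set):
        assert len(erdn_set) == 19
        assert all(o.length == 25 for o in erdn_set)
        assert erdn_set.ids == [f"DN-{i:02d}" for i in range(1, 20)]

    def test_cross_set_kmer_dissimilarity(self, srqc_set, erdn_set):
        """No ERDN oligo shares a 12-mer with any SRQC oligo (brute force)."""
        srqc_kmers = set()
        for o in srqc_set:
            srqc_kmers |= {o.seq[i:i + 12]
                           for i in range(o.length - 11)}
        for o in erdn_set:
            kmers = {o.seq[i:i + 12] for i in range(o.length - 11)}
            assert not (kmers & srqc_kmers), o.id

    def test_reproducible(self, srqc_set):
        again = build_srqc_set(seed=0)
        assert [o.seq for o in again] == [o.seq for o in srqc_set]


class TestLadderMix:
    def test_dynamic_range_2_to_18(self, erdn_set):
        mix = ladder_mix(erdn_set, 2.0)
        concs = [mix.entries[o.id] for o in erdn_set]
        assert max(concs) / min(concs) == pytest.approx(2 ** 18)
        ratios = np.array(concs[1:]) / np.array(concs[:-1])
        assert np.allclose(ratios, 2.0)
        assert sum(concs) == pytest.approx(1.0)

    def test_two_oligos(self):
        pair = SpikeInSet((Oligo("a", "ACGUACGUAC"), Oligo("b", "UGCAUGCAUG")))
        mix = ladder_mix(pair, 2.0)
        assert mix.entries["a"] == pytest.approx(1 / 3)
        assert mix.entries["b"] == pytest.approx(2 / 3)

    def test_fold_step_one_is_equimolar(self):
        pair = SpikeInSet((Oligo("a", "ACGUACGUAC"), Oligo("b", "UGCAUGCAUG")))
        mix = ladder_mix(pair, 1.0)
        assert mix.entries["a"] == pytest.approx(0.5)
        with pytest.raises(ParameterError):
            ladder_mix(pair, 0.5)


class TestRebalanceMix:
    def test_already_balanced_is_fixed_point(self):
        mix = MixSpec({"a": 0.5, "b": 0.5})
        out = rebalance_mix(mix, {"a": 100, "b": 100})
        assert out.entries == pytest.approx(mix.entries)

    def test_derived_two_oligo_case(self):
        """Equimolar mix with counts (100, 400) rebalances to (0.8, 0.2)."""
        mix = MixSpec({"a": 0.5, "b": 0.5})
        out = rebalance_mix(mix, {"a": 100, "b": 400})
        assert out.entries["a"] == pytest.approx(0.8)
        assert out.entries["b"] == pytest.approx(0.2)

    def test_zero_count_raises(self):
        mix = MixSpec({"a": 0.5, "b": 0.5})
        with pytest.raises(RebalanceError, match="b"):
            rebalance_mix(mix, {"a": 10, "b": 0})

    def test_round_trip_with_simulated_efficiencies(self, rng):
        """One rebalance corrects known per-oligo efficiencies exactly.

        Simulated observed counts follow reads ∝ concentration × efficiency;
        after rebalancing, re-simulated fractions equal the targets.
        """
        eff = {"a": 1.0, "b": 0.25, "c": 3.0}
        mix = MixSpec({k: 1 / 3 for k in eff})
        counts = {k: 1e6 * mix.entries[k] * eff[k] for k in eff}
        new = rebalance_mix(mix, counts)
        reads = {k: new.entries[k] * eff[k] for k in eff}
        total = sum(reads.values())
        for k in eff:
            assert reads[k] / total == pytest.approx(1 / 3)


def test_fasta_round_trip(tmp_path, erdn_set):
    path = tmp_path / "erdn.fasta"
    design.write_fasta(list(erdn_set), path)
    back = design.read_fasta(path, role=design.ROLE_ERDN)
    assert back.sequences == erdn_set.sequences
    design.write_fasta(list(erdn_set), path, dna=True)
    assert "U" not in path.read_text().splitlines()[1]


def test_mix_tsv_round_trip(tmp_path, erdn_set):
    mix = ladder_mix(erdn_set)
    path = tmp_path / "mix.tsv"
    design.write_mix(mix, path)
    back = design.read_mix(path)
    assert back.molecules_per_ug == mix.molecules_per_ug
    for k, v in mix.entries.items():
        assert back.entries[k] == pytest.approx(v)
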