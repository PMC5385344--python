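"""Pairwise identity and the greedy clustering engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbmine import (
    ClusterParams,
    SequenceTally,
    cluster_at_grid,
    greedy_cluster,
    pairwise_identity,
    simulate_repertoire,
)
from nbmine.clustering import (
    IDENTITY_GRID,
    lcs_length,
    read_members_tsv,
    read_tally_tsv,
    sorted_tally_order,
    write_members_tsv,
    write_tally_tsv,
)
from nbmine.synthetic_data import SimConfig

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent oracle: naive quadratic DP for max identical aligned pairs

def oracle_lcs(a: str, b: str) -> int:
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            if a[i] == b[j]:
                dp[i + 1][j + 1] = dp[i][j] + 1
            else:
                dp[i + 1][j + 1] = max(dp[i][j + 1], dp[i + 1][j])
    return dp[m][n]


def oracle_identity(a: str, b: str) -> float:
    return oracle_lcs(a, b) / len(a)


def oracle_greedy(tally: SequenceTally, c: float) -> list[list[str]]:
    """Brute-force reference of the sorted greedy rule (partition only)."""
    clusters: list[list[str]] = []
    reps: list[str] = []
    for pep in sorted_tally_order(tally):
        best, best_ident = None, -1.0
        for k, rep in enumerate(reps):
            if len(rep) != len(pep):
                continue
            ident = oracle_identity(pep, rep)
            if ident > best_ident + 1e-12:
                best, best_ident = k, ident
        if best is not None and best_ident >= c - 1e-9:
            clusters[best].append(pep)
        else:
            reps.append(pep)
            clusters.append([pep])
    return clusters


def _tally(peps_counts, samples=("S",)):
    t = SequenceTally(samples=tuple(samples))
    for pep, n in peps_counts:
        t.entries[pep] = np.atleast_1d(np.asarray(n, dtype=np.int64))
    return t


# ---------------------------------------------------------------------------
# pairwise identity

class TestIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("PEPTIDE", "PEPTIDE") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKV") == 0.9

    def test_adjacent_swap_matches_dp_oracle(self):
        a, b = "ACDEFGHIKL", "ACDEGFHIKL"
        # the gapped alignment keeps 9 of 10 residues although Hamming says 8
        assert oracle_lcs(a, b) == 9
        assert pairwise_identity(a, b) == oracle_identity(a, b) == 0.9

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("AAA", "AAAA")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_oracle_on_random_pairs(self, data):
        n = data.draw(st.integers(1, 30))
        a = data.draw(st.text(alphabet="ACDEF", min_size=n, max_size=n))
        b = data.draw(st.text(alphabet="ACDEF", min_size=n, max_size=n))
        assert pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=1, max_size=50))
    def test_self_identity_is_one(self, s):
        assert pairwise_identity(s, s) == 1.0


def test_bitparallel_lcs_agrees_with_oracle_on_long_sequences():
    rng = np.random.default_rng(9)
    for _ in range(20):
        a = "".join(AA[i] for i in rng.integers(0, 20, size=106))
        b = list(a)
        for p in rng.choice(106, size=8, replace=False):
            b[p] = AA[int(rng.integers(0, 20))]
        b = "".join(b)
        assert lcs_length(a, b) == oracle_lcs(a, b)


# ---------------------------------------------------------------------------
# greedy clustering

class TestGreedy:
    def test_identical_peptides_one_cluster(self):
        t = _tally([("PEPTIDESEQ", 3)])
        clusters = greedy_cluster(t, ClusterParams(0.9))
        assert len(clusters) == 1
        assert int(clusters[0].sample_counts()[0]) == 3

    def test_only_representatives_are_compared(self):
        # A founds; B (1 mismatch, 0.95) joins A; C is 3 mismatches from A
        # (0.85 < 0.90) and must found its own cluster even though it is
        # within 0.90 of member B
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = a[:19] + "A"          # 1 sub vs A
        c = "W" + a[1:10] + "C" + a[11:19] + "A"  # subs at 0, 10, 19
        assert oracle_identity(a, b) == pytest.approx(0.95)
        assert oracle_identity(a, c) == pytest.approx(0.85)
        assert oracle_identity(b, c) >= 0.90
        t = _tally([(a, 10), (b, 5), (c, 1)])
        clusters = greedy_cluster(t, ClusterParams(0.90))
        assert [cl.representative for cl in clusters] == [a, c]
        assert sorted(m.peptide for m in clusters[0].members) == sorted([a, b])

    def test_threshold_one_gives_unique_peptides(self, rng):
        peps = {"".join(AA[i] for i in rng.integers(0, 20, size=12)) for _ in range(40)}
        t = _tally([(p, 1) for p in peps])
        clusters = greedy_cluster(t, ClusterParams(1.0))
        assert len(clusters) == len(peps)

    def test_lineage_recovery_at_working_threshold(self):
        # 10 lineages x 10 variants within 5% divergence: clusters at 0.90
        # must reproduce the lineage partition exactly
        cfg = SimConfig(
            n_lineages=10, n_binders=0, variants_per_lineage=10,
            intra_lineage_divergence=0.05, reads_per_sample=1, seed=3,
        )
        truth = simulate_repertoire(cfg)
        # founders are the abundant sequences, so they lead the sorted input
        # and anchor their lineage's cluster
        t = _tally([(v.peptide_trimmed, 10 if v.variant_id == 0 else 1)
                    for v in truth.variants])
        clusters = greedy_cluster(t, ClusterParams(0.90))
        assert len(clusters) == 10
        by_pep = {v.peptide_trimmed: v.lineage_id for v in truth.variants}
        for cl in clusters:
            assert len({by_pep[m.peptide] for m in cl.members}) == 1

    def test_empty_tally_is_an_error(self):
        with pytest.raises(ValueError):
            greedy_cluster(_tally([]))

    def test_counts_never_affect_geometry(self, rng):
        peps = [("".join(AA[i] for i in rng.integers(0, 20, size=15)), k + 1)
                for k in range(30)]
        part1 = [cl.members for cl in greedy_cluster(_tally(peps), ClusterParams(0.8))]
        # same peptides, all counts equal: sort order may change but the
        # pairwise geometry (set of member sets) must not
        part2 = [cl.members for cl in greedy_cluster(_tally([(p, 1) for p, _ in peps]),
                                                     ClusterParams(0.8))]
        s1 = {frozenset(m.peptide for m in ms) for ms in part1}
        s2 = {frozenset(m.peptide for m in ms) for ms in part2}
        # random unrelated 15-mers: every cluster is a singleton either way
        assert s1 == s2


class TestGrid:
    def test_full_grid_returns_seven_clusterings(self):
        t = _tally([("ACDEFGHIKL", 1), ("ACDEFGHIKV", 2)])
        out = cluster_at_grid(t)
        assert len(out) == 7
        assert set(out) == set(IDENTITY_GRID)

    def test_singleton_tally(self):
        out = cluster_at_grid(_tally([("ACDEFGHIKL", 1)]))
        assert all(len(cls) == 1 for cls in out.values())

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_at_grid(_tally([("AAA", 1)]), [])

    def test_cluster_count_non_increasing_as_threshold_drops(self):
        cfg = SimConfig(n_lineages=8, n_binders=0, variants_per_lineage=6,
                        intra_lineage_divergence=0.05, reads_per_sample=1, seed=5)
        truth = simulate_repertoire(cfg)
        t = _tally([(v.peptide_trimmed, 1) for v in truth.variants])
        out = cluster_at_grid(t)
        counts = [len(out[c]) for c in sorted(out, reverse=True)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# invariants and oracle equivalence

def _random_structured_tally(seed, n_seqs=150):
    """Founder/mutant mixtures with several lengths and count ties."""
    rng = np.random.default_rng(seed)
    peps = {}
    founders = []
    for length in (18, 20, 22):
        for _ in range(4):
            founders.append("".join(AA[i] for i in rng.integers(0, 20, size=length)))
    while len(peps) < n_seqs:
        f = founders[int(rng.integers(0, len(founders)))]
        k = int(rng.integers(0, 6))
        s = list(f)
        for p in rng.choice(len(f), size=min(k, len(f)), replace=False):
            s[p] = AA[int(rng.integers(0, 20))]
        peps["".join(s)] = int(rng.integers(1, 9))
    return _tally(list(peps.items()))


@pytest.mark.parametrize("seed,c", [(0, 0.9), (1, 0.8), (2, 0.7), (3, 1.0)])
def test_partition_matches_naive_reference(seed, c):
    t = _random_structured_tally(seed)
    ours = [[m.peptide for m in cl.members] for cl in greedy_cluster(t, ClusterParams(c))]
    theirs = oracle_greedy(t, c)
    assert ours == theirs


def test_membership_soundness_and_representative_separation():
    t = _random_structured_tally(7)
    c = 0.85
    clusters = greedy_cluster(t, ClusterParams(c))
    for cl in clusters:
        assert cl.members[0].peptide == cl.representative
        for m in cl.members:
            assert oracle_identity(m.peptide, cl.representative) >= c - 1e-9
            assert m.identity == pytest.approx(oracle_identity(m.peptide, cl.representative))
    reps = [cl.representative for cl in clusters]
    for i, r1 in enumerate(reps):
        for r2 in reps[i + 1:]:
            if len(r1) == len(r2):
                assert oracle_identity(r1, r2) < c


def test_count_conservation(small_sim):
    _, _, reads = small_sim
    from nbmine.read_processing import ProcessParams, process_read_pairs

    results = {s: process_read_pairs(reads.pairs[s][:1500], s, ProcessParams())
               for s in ("CTRL", "SEL")}
    tally = SequenceTally.from_counters({s: r.tally for s, r in results.items()})
    clusters = greedy_cluster(tally, ClusterParams(0.9))
    total = np.sum([cl.sample_counts() for cl in clusters], axis=0)
    assert dict(zip(tally.samples, total.tolist())) == tally.sample_totals


def test_determinism_byte_identical_report(tmp_path):
    t = _random_structured_tally(11)
    paths = []
    for k in range(2):
        clusters = greedy_cluster(t, ClusterParams(0.9))
        p = tmp_path / f"members{k}.tsv"
        write_members_tsv(clusters, ("S",), p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_tally_and_members_round_trip(tmp_path):
    t = _random_structured_tally(13)
    write_tally_tsv(t, tmp_path / "tally.tsv")
    back = read_tally_tsv(tmp_path / "tally.tsv")
    assert back.samples == t.samples
    assert {k: v.tolist() for k, v in back.entries.items()} == {
        k: v.tolist() for k, v in t.entries.items()
    }
    clusters = greedy_cluster(t, ClusterParams(0.9))
    write_members_tsv(clusters, t.samples, tmp_path / "members.tsv")
    back_clusters, samples = read_members_tsv(tmp_path / "members.tsv")
    assert samples == t.samples
    assert [(c.cluster_id, c.representative, [m.peptide for m in c.members])
            for c in back_clusters] == [
        (c.cluster_id, c.representative, [m.peptide for m in c.members]) for c in clusters
    ]
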