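import numpy as np
import pytest

from ecbs import (
    FeatureSpec,
    Fingerprint,
    FingerprintKind,
    ScreenError,
    abstract_compound,
    butina_cluster,
    apply_exclusion_hook,
    flag_pains,
    novelty_report,
    parse_compound,
    screen_library,
    select_cluster_centers,
    similarity_filter,
    substructure_match,
    tanimoto,
    write_hits,
)
from ecbs.screen import Cluster, ScreeningHit

MACCS = FingerprintKind.MACCS166


class FakeModel:
    """Deterministic stand-in scoring pairs by shared-bit count / 100."""

    feature_spec = FeatureSpec((MACCS,))

    def score_matrix(self, X):
        return np.clip(X[:, :166].sum(axis=1) / 100.0, 0, 1)


def bits_compound(cid, on):
    return abstract_compound(cid, {MACCS: Fingerprint.from_on_bits(MACCS, on)})


@pytest.fixture
def reference_active():
    return bits_compound("REF", range(166))


class TestScreenLibrary:
    def test_empty_library_is_empty_result(self, reference_active):
        assert screen_library(FakeModel(), [], [reference_active]) == []

    def test_empty_actives_rejected(self):
        with pytest.raises(ScreenError):
            screen_library(FakeModel(), [bits_compound("q", [1])], [])

    def test_threshold_is_inclusive(self, reference_active):
        lib = [
            bits_compound("q90", range(90)),   # score 0.90
            bits_compound("q79", range(79)),   # score 0.79
            bits_compound("q81", range(81)),   # score 0.81
            bits_compound("q80", range(80)),   # score 0.80 exactly
        ]
        hits = screen_library(FakeModel(), lib, [reference_active], 0.8)
        assert [h.compound_id for h in hits] == ["q90", "q81", "q80"]
        assert hits[0].best_active_id == "REF"

    def test_sorted_by_score_then_id(self, reference_active):
        lib = [bits_compound(f"q{i}", range(85)) for i in range(3)]
        lib += [bits_compound("top", range(95))]
        hits = screen_library(FakeModel(), lib, [reference_active], 0.8)
        scores = [h.ecbs_score for h in hits]
        assert scores == sorted(scores, reverse=True)
        assert [h.compound_id for h in hits][1:] == ["q0", "q1", "q2"]


class TestSimilarityFilter:
    def _setup(self, hit_bits):
        active = bits_compound("ACT", range(100))
        hit_comp = bits_compound("HIT", hit_bits)
        hit = ScreeningHit("HIT", 0.9, "ACT")
        return hit, {"HIT": hit_comp}, [active]

    def test_identical_hit_excluded(self):
        hit, comp, actives = self._setup(range(100))
        similarity_filter([hit], comp, actives, MACCS, 0.47)
        assert "similarity" in hit.excluded_by

    def test_exactly_at_cutoff_kept(self):
        hit, comp, actives = self._setup(range(47))  # tanimoto 47/100 = 0.47
        assert tanimoto(comp["HIT"].fingerprint(MACCS),
                        actives[0].fingerprint(MACCS)) == pytest.approx(0.47)
        similarity_filter([hit], comp, actives, MACCS, 0.47)
        assert hit.excluded_by == set()

    def test_just_above_cutoff_excluded(self):
        hit, comp, actives = self._setup(range(48))  # 0.48 > 0.47
        similarity_filter([hit], comp, actives, MACCS, 0.47)
        assert "similarity" in hit.excluded_by

    def test_dissimilar_kept(self):
        hit, comp, actives = self._setup(range(120, 140))
        similarity_filter([hit], comp, actives, MACCS, 0.47)
        assert hit.excluded_by == set()

    def test_lowering_cutoff_never_unexcludes(self):
        rng = np.random.default_rng(3)
        actives = [bits_compound("A", np.flatnonzero(rng.random(166) < 0.4))]
        comp, hits = {}, []
        for i in range(20):
            c = bits_compound(f"h{i}", np.flatnonzero(rng.random(166) < 0.4))
            comp[c.id] = c
            hits.append(ScreeningHit(c.id, 0.9, "A"))
        excluded_at = {}
        for cutoff in (0.6, 0.45, 0.3, 0.15):
            trial = [ScreeningHit(h.compound_id, 0.9, "A") for h in hits]
            similarity_filter(trial, comp, actives, MACCS, cutoff)
            excluded_at[cutoff] = {h.compound_id for h in trial if h.excluded}
        assert (excluded_at[0.6] <= excluded_at[0.45]
                <= excluded_at[0.3] <= excluded_at[0.15])


class TestExclusionHooks:
    def _hits(self):
        comps = {f"h{i}": parse_compound(f"h{i}", smi)
                 for i, smi in enumerate(["CCO", "c1ccccc1", "CCN"])}
        hits = [ScreeningHit(cid, 0.9, "A") for cid in comps]
        return hits, comps

    def test_always_false_predicate_changes_nothing(self):
        hits, comps = self._hits()
        apply_exclusion_hook(hits, lambda c: False, "pharmacophore", comps)
        assert all(not h.excluded for h in hits)

    def test_always_true_predicate_excludes_all(self):
        hits, comps = self._hits()
        apply_exclusion_hook(hits, lambda c: True, "pharmacophore", comps)
        assert all(h.excluded_by == {"pharmacophore"} for h in hits)

    def test_pains_hook_flags_without_excluding(self):
        # rhodanine core is a canonical pan-assay interference scaffold
        pains_smiles = "O=C1CSC(=S)N1c1ccccc1"
        comps = {"p": parse_compound("p", pains_smiles),
                 "ok": parse_compound("ok", "CCO")}
        hits = [ScreeningHit("p", 0.9, "A"), ScreeningHit("ok", 0.9, "A")]
        flag_pains(hits, comps)
        assert hits[0].pains_flag and not hits[0].excluded
        assert not hits[1].pains_flag

    def test_predicate_exception_aborts_with_hit_id(self):
        hits, comps = self._hits()

        def broken(c):
            raise RuntimeError("boom")

        with pytest.raises(ScreenError, match="h0"):
            apply_exclusion_hook(hits, broken, "bad", comps)

    def test_filter_then_hook_equals_hook_then_filter(self):
        rng = np.random.default_rng(9)
        actives = [bits_compound("A", np.flatnonzero(rng.random(166) < 0.4))]

        def run(first_similarity):
            comp, hits = {}, []
            for i in range(15):
                c = bits_compound(f"h{i}", np.flatnonzero(rng.random(166) < 0.4))
                comp[c.id] = c
                hits.append(ScreeningHit(c.id, 0.9, "A"))
            # reseed per run so both orders see identical compounds
            ops = [
                lambda: similarity_filter(hits, comp, actives, MACCS, 0.4),
                lambda: apply_exclusion_hook(
                    hits, lambda c: c.id.endswith(("1", "3")), "hook", comp),
            ]
            if not first_similarity:
                ops.reverse()
            for op in ops:
                op()
            return {h.compound_id for h in hits if not h.excluded}

        rng = np.random.default_rng(9)
        surviving_a = run(True)
        rng = np.random.default_rng(9)
        surviving_b = run(False)
        assert surviving_a == surviving_b


def brute_force_leader_clustering(fps, ids, cutoff):
    """Independent oracle: literal leader simulation with python sets."""
    n = len(fps)
    neighbors = {
        i: {j for j in range(n)
            if j != i and tanimoto(fps[i], fps[j]) >= cutoff}
        for i in range(n)
    }
    unassigned = set(range(n))
    partition = []
    while unassigned:
        best = None
        for i in sorted(unassigned, key=lambda i: ids[i]):
            size = len(neighbors[i] & unassigned)
            if best is None or size > best[0]:
                best = (size, i)
        leader = best[1]
        members = {leader} | (neighbors[leader] & unassigned)
        unassigned -= members
        partition.append((ids[leader], frozenset(ids[i] for i in members)))
    return partition


class TestButinaCluster:
    def test_identical_molecules_one_cluster(self):
        comps = [bits_compound(f"c{i}", range(30)) for i in range(5)]
        clusters = butina_cluster(comps, MACCS, 0.6)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_pairwise_dissimilar_all_singletons(self):
        comps = [bits_compound(f"c{i}", [10 * i, 10 * i + 1]) for i in range(6)]
        clusters = butina_cluster(comps, MACCS, 0.5)
        assert len(clusters) == 6
        assert all(c.center_id == c.members[0] for c in clusters)

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(17)
        comps = [bits_compound(f"c{i:02d}", np.flatnonzero(rng.random(166) < 0.25))
                 for i in range(20)]
        clusters = butina_cluster(comps, MACCS, 0.4)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(c.id for c in comps)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            comps = [
                bits_compound(f"c{i:02d}",
                              np.flatnonzero(rng.random(64) < 0.35) + 50)
                for i in range(n)
            ]
            fps = [c.fingerprint(MACCS) for c in comps]
            ids = [c.id for c in comps]
            expected = brute_force_leader_clustering(fps, ids, 0.5)
            got = butina_cluster(comps, MACCS, 0.5)
            assert [(c.center_id, frozenset(c.members)) for c in got] == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ScreenError):
            butina_cluster([], MACCS, 0.5)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ScreenError):
            butina_cluster([bits_compound("a", [1])], MACCS, 0.0)


class TestSelectClusterCenters:
    def test_one_center_per_cluster(self):
        hits = [ScreeningHit(f"h{i}", 0.9, "A") for i in range(6)]
        clusters = [
            Cluster(("h0", "h1", "h2"), "h1"),
            Cluster(("h3",), "h3"),
            Cluster(("h4", "h5"), "h4"),
        ]
        select_cluster_centers(clusters, hits)
        assert [h.compound_id for h in hits if h.is_center] == ["h1", "h3", "h4"]
        assert all(h.cluster_id is not None for h in hits)

    def test_unknown_member_rejected(self):
        hits = [ScreeningHit("h0", 0.9, "A")]
        with pytest.raises(ScreenError, match="ghost"):
            select_cluster_centers([Cluster(("h0", "ghost"), "h0")], hits)

    def test_excluded_hit_cannot_be_center(self):
        hit = ScreeningHit("h0", 0.9, "A", excluded_by={"similarity"})
        with pytest.raises(ScreenError):
            select_cluster_centers([Cluster(("h0",), "h0")], [hit])


class TestNoveltyReport:
    def test_query_among_references_tops_at_one(self):
        q = parse_compound("q", "c1ccc2ncccc2c1")
        refs = [q, parse_compound("r", "CCO")]
        frame = novelty_report(q, refs, [FingerprintKind.MORGAN_R2_1024])
        assert frame.iloc[0]["reference_id"] == "q"
        assert frame.iloc[0]["tanimoto"] == pytest.approx(1.0)

    def test_sorted_descending_within_kind_with_activities(self):
        q = parse_compound("q", "c1ccccc1CCN")
        refs = [parse_compound(f"r{i}", smi)
                for i, smi in enumerate(["c1ccccc1CCO", "CC", "c1ccccc1"])]
        frame = novelty_report(
            q, refs, [FingerprintKind.MACCS166, FingerprintKind.MORGAN_R2_1024],
            activities={"r0": "POC 5%"},
        )
        for kind, block in frame.groupby("kind"):
            sims = list(block["tanimoto"])
            assert sims == sorted(sims, reverse=True)
        assert set(frame[frame["reference_id"] == "r0"]["activity"]) == {"POC 5%"}

    def test_empty_references_rejected(self):
        with pytest.raises(ScreenError):
            novelty_report(parse_compound("q", "CC"), [])


class TestSubstructureMatch:
    def test_benzene_core_matches_toluene(self):
        core = parse_compound("core", "c1ccccc1")
        cands = [parse_compound("tol", "Cc1ccccc1"), parse_compound("hex", "C1CCCCC1")]
        assert substructure_match(core, cands) == ["tol"]

    def test_core_larger_than_candidate_no_match(self):
        core = parse_compound("core", "c1ccc2ncccc2c1")
        assert substructure_match(core, [parse_compound("b", "c1ccccc1")]) == []

    def test_core_matches_itself(self):
        core = parse_compound("core", "c1ccc2ncccc2c1")
        assert substructure_match(core, [core]) == ["core"]

    def test_ignoring_substituents_recovers_scaffold_match(self):
        # amino + iodo decorated ring; plain-ring candidates match only
        # once those substituent atoms are ignored
        core = parse_compound("core", "Nc1ccc(I)cc1")
        plain = parse_compound("plain", "c1ccccc1C")
        assert substructure_match(core, [plain]) == []
        idx = [a.GetIdx() for a in core.mol.GetAtoms()
               if a.GetSymbol() in ("N", "I")]
        assert substructure_match(core, [plain], ignore_atom_indices=idx) == ["plain"]

    def test_out_of_range_ignore_index(self):
        core = parse_compound("core", "CC")
        with pytest.raises(ScreenError):
            substructure_match(core, [core], ignore_atom_indices=[99])


class TestHitTable:
    def test_written_table_roundtrips_fields(self, tmp_path):
        import csv

        hits = [
            ScreeningHit("a", 0.91, "R1", excluded_by={"similarity"},
                         pains_flag=True, cluster_id=0, is_center=False),
            ScreeningHit("b", 0.85, "R2", cluster_id=1, is_center=True),
        ]
        path = tmp_path / "hits.csv"
        write_hits(hits, path)
        with path.open() as fh:
            rows = list(csv.DictReader(fh))
        assert rows[0]["excluded_by"] == "similarity"
        assert rows[1]["is_center"] == "1"
        assert float(rows[1]["score"]) == pytest.approx(0.85)
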