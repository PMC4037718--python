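import numpy as np
import pytest

from flspace.lbvs import (
    FragranceFamily,
    _roc_auc,
    curate_families,
    enrichment_table,
    run_enrichment,
    select_reference,
)
from flspace.molio import records_from_smiles_list

ALKANES = ["C" * n for n in range(3, 30)]  # propane, butane, ... nonacosane


def family_from(smiles, name="fam"):
    return FragranceFamily(
        name, records_from_smiles_list(smiles, ids=[f"{name}:{i:03d}" for i in range(len(smiles))])
    )


def brute_force_auc(distances, is_active):
    """Pairwise Mann-Whitney count: wins + half-ties over all active/decoy pairs."""
    wins = ties = 0
    n_pairs = 0
    for i, (da, act) in enumerate(zip(distances, is_active)):
        if not act:
            continue
        for dd, other_act in zip(distances, is_active):
            if other_act:
                continue
            n_pairs += 1
            if da < dd:
                wins += 1
            elif da == dd:
                ties += 1
    return 100.0 * (wins + 0.5 * ties) / n_pairs


class TestCuration:
    def make_raw(self):
        # 8 disjoint toy families (one functional group each, all FL);
        # 'CCO' planted in 6 of them
        caps = ("O", "C(C)=O", "OC(C)=O", "C=O", "OC", "SC", "S", "C(=O)OC")
        base = {
            f"fam{i}": ["C" * (n + 3) + cap for n in range(8)]
            for i, cap in enumerate(caps)
        }
        for i in range(6):
            base[f"fam{i}"] = ["CCO"] + base[f"fam{i}"]
        return base

    def test_promiscuous_molecule_removed_everywhere(self):
        families = curate_families(self.make_raw(), min_size=3, max_membership=5)
        assert len(families) == 8
        for fam in families:
            assert "CCO" not in [r.smiles for r in fam.members]

    def test_membership_at_threshold_is_kept(self):
        raw = {f"f{i}": ["CCCO", "CCCC"] + ["C" * (i + 5)] * 1 for i in range(5)}
        families = curate_families(raw, min_size=1, max_membership=5)
        # present in exactly 5 families: not promiscuous (rule is "> 5")
        assert all("CCCO" in [r.smiles for r in f.members] for f in families)

    def test_non_fl_members_removed(self):
        raw = {"fam": ["CCO", "c1cnccn1", "OCC(O)CO"] + ALKANES[:9]}
        (fam,) = curate_families(raw, min_size=5)
        assert fam.n_removed_non_fl == 2
        assert len(fam) == 10

    def test_hac_cap(self):
        raw = {"fam": ALKANES[:15]}
        (fam,) = curate_families(raw, min_size=5, hac_cap=13)
        assert all(r.hac <= 13 for r in fam.members)
        assert fam.n_removed_hac_cap == 4  # C14 to C17

    def test_small_family_dropped(self):
        raw = {"big": ALKANES[:10], "small": ALKANES[:9]}
        families = curate_families(raw, min_size=10)
        assert [f.name for f in families] == ["big"]

    def test_constructed_three_family_outcome(self):
        raw = {
            "A": ["CCO", "CCCO", "CCCCO", "c1cnccn1"],  # one non-FL
            "B": ["CCO", "CC(C)O", "CCC(C)O"],
            "C": ["CCCCCO", "CCCCCCO"],
        }
        families = curate_families(raw, min_size=2, max_membership=1)
        got = {f.name: [r.smiles for r in f.members] for f in families}
        # CCO sits in two families (> max_membership 1): removed from both
        assert got == {
            "A": ["CCCO", "CCCCO"],
            "B": ["CC(C)O", "CCC(C)O"],
            "C": ["CCCCCO", "CCCCCCO"],
        }


class TestSelectReference:
    def test_single_member(self):
        fam = family_from(["CCO"])
        assert select_reference(fam, "MW") == fam.members[0].id

    def test_collinear_mw_medoid(self):
        # MW roughly 100 / 110 / 200: the middle compound minimizes the sum
        fam = family_from(["CCCCCCC", "CCCCCCCC", "CCCCCCCCCCCCCC"])
        assert select_reference(fam, "MW") == fam.members[1].id

    def test_matches_exhaustive_double_loop(self, decoys):
        from flspace.fingerprints import get_space

        members = decoys[:20]
        fam = FragranceFamily("rnd", list(members))
        for space_name in ("MQN", "ECfp4", "MW"):
            space = get_space(space_name)
            encoded = [space.encode(r) for r in members]
            sums = np.array([
                sum(space.distance(encoded[i], encoded[j]) for j in range(20) if j != i)
                for i in range(20)
            ])
            tied = np.flatnonzero(np.abs(sums - sums.min()) < 1e-6)
            best = min(members[i].id for i in tied)
            assert select_reference(fam, space_name) == best


class TestROCAUC:
    def test_perfect_ranking(self):
        d = np.array([1.0, 2.0, 3.0, 10, 11, 12, 13])
        act = np.array([True] * 3 + [False] * 4)
        _, auc = _roc_auc(d, act)
        assert auc == 100.0

    def test_inverted_ranking(self):
        d = np.array([10.0, 11, 12, 1, 2, 3, 4])
        act = np.array([True] * 3 + [False] * 4)
        _, auc = _roc_auc(d, act)
        assert auc == 0.0

    def test_random_instances_match_pairwise_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(20, 120))
            n_act = int(rng.integers(3, 10))
            distances = rng.integers(0, 15, n).astype(float)  # heavy ties
            is_active = np.zeros(n, dtype=bool)
            is_active[rng.choice(n, n_act, replace=False)] = True
            _, auc = _roc_auc(distances, is_active)
            assert auc == pytest.approx(brute_force_auc(distances, is_active), abs=1e-9)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 10, 60).astype(float)
        act = np.zeros(60, dtype=bool)
        act[:7] = True
        _, auc = _roc_auc(d, act)
        _, auc_rev = _roc_auc(-d, act)
        assert auc + auc_rev == pytest.approx(100.0)

    def test_roc_curve_endpoints(self):
        d = np.array([1.0, 1.0, 2.0, 3.0])
        act = np.array([True, False, True, False])
        roc, _ = _roc_auc(d, act)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)


class TestRunEnrichment:
    def test_analog_family_in_decoys(self, decoys):
        from flspace.fixtures import generate_analog_family

        fam = generate_analog_family(
            "CC1CCC(C(C)C)C(=O)C1", 12, seed=1, name="menthoids"
        ).as_fragrance_family()
        res = run_enrichment(fam, decoys[:2000], "MQN")
        assert res.n_actives == 12  # 13 members minus the reference
        assert 0 <= res.auc <= 100
        assert res.recovery[1.0] == 100.0
        # recovery non-decreasing in the screened fraction
        fracs = sorted(res.recovery)
        recs = [res.recovery[f] for f in fracs]
        assert recs == sorted(recs)

    def test_reference_excluded_from_ranking(self, decoys):
        fam = family_from(["CCCCO", "CCCCCO", "CCCCCCO"])
        res = run_enrichment(fam, decoys[:100], "MQN")
        ranked_ids = [rid for rid, _, _ in res.ranking]
        assert res.reference_id not in ranked_ids
        assert len(ranked_ids) == res.n_actives + res.n_background

    def test_background_overlap_removed(self):
        fam = family_from(["CCCCO", "CCCCCO", "CCCCCCO"])
        background = records_from_smiles_list(
            ["CCCCO", "CCCCC", "CCCCCC"], ids=["bg1", "bg2", "bg3"]
        )  # bg1 duplicates a family member
        res = run_enrichment(fam, background, "MQN")
        assert res.n_background == 2

    def test_too_small_family_is_error(self):
        fam = family_from(["CCO", "CCCO"])
        with pytest.raises(ValueError, match="fewer than 2"):
            run_enrichment(fam, [], "MQN")

    def test_recovery_cutoff_uses_floor_with_minimum_one(self):
        # 3 actives + 97 decoys: at 0.1% the cutoff is max(1, floor(0.1)) = 1
        fam = family_from(["CCCO", "CCC(C)O", "CCCC(C)O", "CC(C)CO"])
        background = records_from_smiles_list(ALKANES[10:27], ids=[f"b{i}" for i in range(17)])
        res = run_enrichment(fam, background, "MW", fractions=(0.001, 0.5))
        n = res.n_actives + res.n_background
        top = res.ranking[:1]
        expected = 100.0 * sum(a for _, _, a in top) / res.n_actives
        assert res.recovery[0.001] == expected


class TestEnrichmentTable:
    def test_two_family_means(self, decoys):
        fams = [
            family_from(["CCCCO", "CCCCCO", "CCCCCCO"], "alcohols"),
            family_from(["CCOC(C)=O", "CCCOC(C)=O", "CCCCOC(C)=O"], "esters"),
        ]
        results = [run_enrichment(f, decoys[:500], sp) for f in fams for sp in ("MQN", "MW")]
        table, auc_table = enrichment_table(results, fams, fraction=0.01)
        assert list(table["family"]) == ["alcohols", "esters", "Average"]
        avg = table.iloc[-1]
        assert avg["recov_MQN"] == pytest.approx(
            table["recov_MQN"].iloc[:2].mean(), abs=0.051
        )
        assert set(auc_table["space"]) == {"MQN", "MW"}

    def test_single_family_average_row_equals_it(self, decoys):
        fams = [family_from(["CCCCO", "CCCCCO", "CCCCCCO"], "solo")]
        results = [run_enrichment(fams[0], decoys[:200], "MQN")]
        table, _ = enrichment_table(results, fams)
        assert table.iloc[0]["recov_MQN"] == table.iloc[1]["recov_MQN"]

    def test_empty_results(self):
        table, auc_table = enrichment_table([])
        assert len(table) == 0 and len(auc_table) == 0
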