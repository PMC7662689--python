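"""NSM/NSR statistics, biomarker selection, and key-triplet screening."""

import numpy as np
import pytest

from lcenet.biomarkers import (
    NSMProfile,
    NSRProfile,
    compute_nsm_profiles,
    compute_nsr_profiles,
    screen_key_triplets,
    select_lncrna_biomarkers,
    select_mirna_biomarkers,
)
from lcenet.context import ContextLceNET


def _net(triplets):
    return ContextLceNET("toy", triplets)


def test_nsm_counts_shared_mirnas_per_pair():
    net = _net([("L", "m1", "A"), ("L", "m2", "A"), ("L", "m3", "A"),
                ("L", "m1", "B")])
    profiles = compute_nsm_profiles(net)
    assert sorted(profiles["L"].pair_nsm_values) == [1, 3]


def test_nsm_single_lncrna_flagged_degenerate():
    net = _net([("L", "m1", "A"), ("L", "m2", "A")])
    profiles = compute_nsm_profiles(net)
    assert profiles["L"].degenerate
    assert 0 <= profiles["L"].test_p <= 1


def test_nsm_selection_threshold_is_strict():
    profiles = {
        "a": NSMProfile("a", [5], 0.04),
        "b": NSMProfile("b", [5], 0.05),
    }
    assert select_lncrna_biomarkers(profiles) == {"a"}


def test_nsm_permutation_invariant_to_labels():
    triplets = [("L1", "m1", "A1"), ("L1", "m2", "A1"), ("L2", "m1", "A2")]
    relabel = {"L1": "LX", "L2": "LY", "A1": "AQ", "A2": "AZ",
               "m1": "u1", "m2": "u2"}
    renamed = [(relabel[l], relabel[m], relabel[a]) for l, m, a in triplets]
    p1 = {l: p.test_p for l, p in compute_nsm_profiles(_net(triplets)).items()}
    p2 = {l: p.test_p for l, p in compute_nsm_profiles(_net(renamed)).items()}
    assert p1["L1"] == pytest.approx(p2["LX"])
    assert p1["L2"] == pytest.approx(p2["LY"])


def test_nsr_hand_counted_toy():
    # m1 -> {L, g1, g2}, m2 -> {L, g2, g3}: g1 and g3 are single-line
    net = _net([("L", "m1", "g1"), ("L", "m1", "g2"),
                ("L", "m2", "g2"), ("L", "m2", "g3")])
    profiles = compute_nsr_profiles(net)
    assert profiles["m1"].nsr == 1 and profiles["m2"].nsr == 1


def test_nsr_complete_bipartite_all_zero():
    triplets = [
        (f"L{i}", m, f"A{i}") for i in range(3) for m in ("m1", "m2", "m3")
    ]
    profiles = compute_nsr_profiles(_net(triplets))
    assert all(p.nsr == 0 for p in profiles.values())


def brute_force_nsr(edges):
    """Recount single-line targets directly from the raw edge list."""
    regs = {}
    for m, t in edges:
        regs.setdefault(t, set()).add(m)
    nsr = {}
    for m, t in edges:
        nsr.setdefault(m, 0)
        if len(regs[t]) == 1:
            nsr[m] += 1
    return nsr


def test_nsr_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(19)
    for _ in range(30):
        n_l, n_m, n_a = rng.integers(2, 8, size=3)
        triplets = []
        for _ in range(int(rng.integers(3, 40))):
            triplets.append(
                (f"L{rng.integers(n_l)}", f"m{rng.integers(n_m)}",
                 f"A{rng.integers(n_a)}")
            )
        net = _net(triplets)
        profiles = compute_nsr_profiles(net)
        brute = brute_force_nsr(net.edges)
        assert {m: p.nsr for m, p in profiles.items()} == brute
        for p in profiles.values():
            assert p.nsr <= p.n_targets


def test_nsr_selection_requires_mean_and_significance():
    profiles = {
        "a": NSRProfile("a", nsr=5, n_targets=6, passes_mean=True, test_p=0.01),
        "b": NSRProfile("b", nsr=2, n_targets=6, passes_mean=False, test_p=0.01),
        "c": NSRProfile("c", nsr=5, n_targets=6, passes_mean=True, test_p=0.2),
    }
    assert select_mirna_biomarkers(profiles) == {"a"}
    assert select_mirna_biomarkers(profiles, require_mean=False) == {"a", "b"}


def test_screen_key_triplets_rules():
    net = _net([("L", "m", "A"), ("L", "m", "B"), ("L2", "m", "A"),
                ("L", "m2", "C")])
    directions = {"L": "up", "m": "down", "A": "up", "B": "up", "L2": "up",
                  "m2": "up", "C": "up"}
    kept = screen_key_triplets(
        net, {"L"}, {"m", "m2"}, directions, tag_genes={"A", "C"},
        prognosis_genes={"B"},
    )
    found = {(t.lncrna, t.mirna, t.mrna) for t in kept}
    # (L,m,A): all rules hold; (L,m,B): prognosis route; (L2,..): not biomarker;
    # (L,m2,C): miRNA direction not opposite
    assert found == {("L", "m", "A"), ("L", "m", "B")}
    for t in kept:
        assert t.directions[t.mirna] != t.directions[t.lncrna]
        assert t.directions[t.mirna] != t.directions[t.mrna]


def test_screen_skips_missing_direction():
    net = _net([("L", "m", "A")])
    kept = screen_key_triplets(net, {"L"}, {"m"}, {"L": "up", "m": "down"},
                               {"A"}, set())
    assert kept == []


def test_fixture_biomarkers_recovered(fixture_study, pipeline_result):
    truth = fixture_study.truth
    for label in pipeline_result.context_nets:
        assert pipeline_result.lnc_biomarkers[label] == set(truth.lncrna_biomarkers)
        assert pipeline_result.mir_biomarkers[label] == set(truth.mirna_biomarkers)


def test_fixture_key_triplets_exact(fixture_study, pipeline_result):
    want = set(map(tuple, fixture_study.truth.key_triplets))
    for label, kept in pipeline_result.key_triplets.items():
        assert {(t.lncrna, t.mirna, t.mrna) for t in kept} == want
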