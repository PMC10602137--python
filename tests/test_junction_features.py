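"""Hydrophobicity, germline decomposition, region lengths, stitching and
clonality flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitmatch.errors import ContractError
from pitmatch.junction_features import (
    EISENBERG,
    classify_public_expanded,
    compute_features,
    decompose_bruteforce,
    decompose_junction,
    hydrophobicity,
    region_lengths,
    stitch_junction,
)
from pitmatch.repertoire_io import Repertoire, translate_nt
from pitmatch.synthetic_data import (
    JunctionGenerator,
    SimulationConfig,
    simulate_repertoire,
)
from conftest import make_record

aa_junction = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1,
                      max_size=20)


class TestHydrophobicity:
    def test_printed_scale_constants(self):
        assert EISENBERG["P"] == 0.12
        assert EISENBERG["Y"] == 0.26
        assert hydrophobicity("P") == 0.12
        assert hydrophobicity("PY") == pytest.approx(0.19)

    def test_scale_has_20_residues_with_known_extremes(self):
        assert len(EISENBERG) == 20
        assert min(EISENBERG.values()) == -2.53  # arginine
        assert max(EISENBERG.values()) == 1.38   # isoleucine

    def test_empty_and_unknown_errors(self):
        with pytest.raises(ContractError):
            hydrophobicity("")
        with pytest.raises(ContractError):
            hydrophobicity("CAXF")

    @settings(max_examples=80)
    @given(aa_junction, st.randoms(use_true_random=False))
    def test_permutation_invariance_and_bounds(self, junction, rnd):
        h = hydrophobicity(junction)
        shuffled = list(junction)
        rnd.shuffle(shuffled)
        assert hydrophobicity("".join(shuffled)) == pytest.approx(h)
        assert -2.53 <= h <= 1.38


class TestDecomposition:
    def test_constructed_split(self, germline):
        v = germline["TRAV12-2*01"]
        j = germline["TRAJ8*01"]
        # choose boundary N nucleotides that differ from the germline
        # continuation on both sides, so the split is unambiguous
        n1 = next(c for c in "ACGT" if c != v.v_junction_nt()[9])
        n3 = next(c for c in "ACGT" if c != j.j_junction_nt()[-13])
        junction = v.v_junction_nt()[:9] + n1 + "G" + n3 \
            + j.j_junction_nt()[-12:]
        dec = decompose_junction(junction, v, j)
        assert (dec.v3_len_nt, dec.n_len_nt, dec.j5_len_nt) == (9, 3, 12)
        assert dec.ok

    def test_zero_n_case(self, germline):
        v = germline["TRAV41*01"]
        j = germline["TRAJ49*01"]
        junction = v.v_junction_nt()[:10] + j.j_junction_nt()[-14:]
        dec = decompose_junction(junction, v, j)
        assert dec.n_len_nt == 0
        assert dec.v3_len_nt + dec.j5_len_nt == len(junction)

    def test_failed_decomposition_flagged_not_raised(self, germline):
        v = germline["TRAV12-2*01"]
        j = germline["TRAJ8*01"]
        dec = decompose_junction("AAAAAAGGG", v, j)
        assert not dec.ok

    def test_greedy_bounds_against_simulator_truth(self, germline):
        cfg = SimulationConfig(seed=13)
        gen = JunctionGenerator(cfg, germline)
        checked_equal = 0
        for _ in range(1000):
            gj = gen.generate()
            v = germline[gj.v_name]
            j = germline[gj.j_name]
            dec = decompose_junction(gj.junction_nt, v, j)
            assert dec.ok
            # conservation
            assert dec.v3_len_nt + dec.n_len_nt + dec.j5_len_nt \
                == len(gj.junction_nt)
            # greedy can only over-assign germline
            assert dec.v3_len_nt >= gj.true_v3
            assert dec.n_len_nt <= gj.true_n
            # greedy split is the (max v3, then max j5) feasible split
            feasible = decompose_bruteforce(gj.junction_nt, v, j)
            best_v3 = max(s[0] for s in feasible)
            best_j5 = max(s[2] for s in feasible if s[0] == best_v3)
            assert (dec.v3_len_nt, dec.j5_len_nt) == (best_v3, best_j5)
            # equality when the boundary nucleotides break the ambiguity
            v_cont = v.v_junction_nt()
            j_cont = j.j_junction_nt()
            n_start, n_end = gj.true_v3, gj.true_v3 + gj.true_n
            if gj.true_n > 0:
                first_n = gj.junction_nt[n_start]
                last_n = gj.junction_nt[n_end - 1]
                v_next = (v_cont[gj.true_v3] if gj.true_v3 < len(v_cont)
                          else None)
                j_prev_idx = len(j_cont) - gj.true_j5 - 1
                j_prev = j_cont[j_prev_idx] if j_prev_idx >= 0 else None
                if (v_next is not None and first_n != v_next
                        and j_prev is not None and last_n != j_prev):
                    assert (dec.v3_len_nt, dec.n_len_nt, dec.j5_len_nt) \
                        == (gj.true_v3, gj.true_n, gj.true_j5)
                    checked_equal += 1
        assert checked_equal > 300  # the unambiguous case must be common


class TestRegionLengths:
    def test_cdr3_is_junction_minus_anchors(self, germline):
        v = germline["TRAV12-2*01"]
        j = germline["TRAJ8*01"]
        out = region_lengths("C" + "A" * 12 + "F", v, j)  # 14 AA junction
        assert out["cdr3_len_nt"] == 36  # 42 - 6

    def test_cdr1_from_annotation(self, germline):
        out = region_lengths("CAVNQAGTALIF", germline["TRAV12-2*01"],
                             germline["TRAJ15*01"])
        assert out["cdr1_len_nt"] == 15

    def test_fr_lengths_constant_per_allele(self, germline):
        v = germline["TRAV41*01"]
        j = germline["TRAJ49*01"]
        outs = [region_lengths(jx, v, j)
                for jx in ("CAAAGNQFYF", "CAASNTGNQFYF")]
        for key in ("fr1_len_nt", "fr2_len_nt", "fr3_len_nt", "fr4_len_nt"):
            assert outs[0][key] == outs[1][key]


class TestStitch:
    def test_pure_germline_roundtrip(self, germline):
        v = germline["TRAV41*01"]
        j = germline["TRAJ49*01"]
        nt_true = v.v_junction_nt()[:12] + j.j_junction_nt()[-30:]
        aa = translate_nt(nt_true)
        stitched = stitch_junction(aa, v, j)
        assert translate_nt(stitched) == aa
        dec = decompose_junction(stitched, v, j)
        assert dec.n_len_nt == 0

    def test_translation_identity_on_simulated_junctions(self, germline):
        gen = JunctionGenerator(SimulationConfig(seed=17), germline)
        for _ in range(200):
            gj = gen.generate()
            v, j = germline[gj.v_name], germline[gj.j_name]
            assert translate_nt(stitch_junction(gj.junction_aa, v, j)) \
                == gj.junction_aa

    def test_stitched_and_direct_analyses_agree(self, germline):
        # nt lengths derived from stitched sequences must reproduce the
        # AA-level comparison decisions exactly
        from pitmatch.enrichment_stats import ks_compare
        gen = JunctionGenerator(SimulationConfig(seed=19), germline)
        base = [gen.generate() for _ in range(300)]
        shift = [gen.generate(shifted=True) for _ in range(300)]
        aa_len = lambda xs: [len(x.junction_aa) for x in xs]
        nt_len = lambda xs: [
            len(stitch_junction(x.junction_aa,
                                germline[x.v_name], germline[x.j_name]))
            for x in xs]
        _, p_aa = ks_compare(aa_len(shift), aa_len(base))
        _, p_nt = ks_compare(nt_len(shift), nt_len(base))
        assert p_nt == pytest.approx(p_aa)


class TestClonalityFlags:
    def test_public_and_expanded_definitions(self):
        rep = Repertoire([
            make_record("CAVRMNTGFQKLVF", record_id="r1", cell_id="c1",
                        donor_id="A"),
            make_record("CAVRMNTGFQKLVF", record_id="r2", cell_id="c2",
                        donor_id="B"),
            make_record("CAASNTGNQFYF", record_id="r3", cell_id="c3",
                        donor_id="A"),
            make_record("CAASNTGNQFYF", record_id="r4", cell_id="c4",
                        donor_id="A"),
            make_record("CAASNTGNQFYF", record_id="r5", cell_id="c5",
                        donor_id="A"),
        ])
        flags = classify_public_expanded(rep)
        assert flags["CAVRMNTGFQKLVF"].is_public
        assert not flags["CAVRMNTGFQKLVF"].is_expanded
        assert not flags["CAASNTGNQFYF"].is_public
        assert flags["CAASNTGNQFYF"].is_expanded  # 3 cells, one donor

    def test_flags_match_simulator_truth(self):
        cfg = SimulationConfig(seed=23, n_donors={"HC": 3},
                               cells_per_donor=40, clone_size_p=0.5)
        rep, truth = simulate_repertoire(cfg)
        flags = classify_public_expanded(rep)
        per_j = truth.groupby("junction_aa").agg(
            donors=("donor_id", "nunique"),
            max_clone=("clone_size", "max"))
        for jx, row in per_j.iterrows():
            assert flags[jx].is_public == (row.donors >= 2)
            # expanded iff some clone of the junction holds > 1 cell
            clones = truth[truth.junction_aa == jx]
            expanded_truth = (clones.groupby("donor_id")["clone_size"]
                              .sum() > 1).any()
            assert flags[jx].is_expanded == expanded_truth

    def test_singleton_config_never_expanded(self):
        cfg = SimulationConfig(seed=29, n_donors={"HC": 2},
                               cells_per_donor=20, clone_size_p=1.0)
        rep, truth = simulate_repertoire(cfg)
        flags = classify_public_expanded(rep)
        # p = 1 forces singleton clones; expansion only via junction
        # collisions within a donor, which the truth table exposes
        for jx, f in flags.items():
            coll = truth[truth.junction_aa == jx]
            within = coll.groupby("donor_id").size().max()
            assert f.is_expanded == (within > 1)


def test_compute_features_fills_germline_columns(germline):
    cfg = SimulationConfig(seed=31, n_donors={"HC": 2}, cells_per_donor=15)
    rep, _ = simulate_repertoire(cfg)
    feats = compute_features(rep, germline)
    assert len(feats) == len(rep.unique_junctions)
    some = next(iter(feats.values()))
    assert some.v3_len_nt is not None
    assert some.v3_len_nt + some.n_len_nt + some.j5_len_nt == some.length_nt
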